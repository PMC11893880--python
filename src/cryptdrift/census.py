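"""Per-patient clone census records and their TSV serialisation.

A census summarises the immunodetection scoring of one patient's colonic
tissue: how many crypts were scored, how many were wholly populated by a
staining-deficient clone (WPCs), how many carried a partial clone (PPCs),
and the sizes of the contiguous multi-crypt patches the WPCs form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["CloneCensus", "read_census_tsv", "write_census_tsv"]

#: TSV column order for census tables.
CENSUS_COLUMNS = ["patient_id", "age", "n_crypts", "wpc_count", "ppc_count", "patch_sizes"]


@dataclass
class CloneCensus:
    """One patient's clone census.

    Parameters
    ----------
    patient_id : str
        Unique patient identifier.
    age : float
        Patient age in years; must be positive.
    n_crypts : int
        Total crypts scored for this patient.
    wpc_count : int
        Number of wholly populated (fixed-clone) crypts. Every WPC belongs
        to exactly one patch, so ``wpc_count == sum(patch_sizes)``.
    ppc_count : int
        Number of partially populated crypts (unfixed clones).
    patch_sizes : list of int
        Crypt count of each contiguous patch; a size of 1 is an isolated WPC.
    """

    patient_id: str
    age: float
    n_crypts: int
    wpc_count: int
    ppc_count: int
    patch_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.n_crypts < 0 or self.wpc_count < 0 or self.ppc_count < 0:
            raise ValueError("crypt counts must be non-negative")
        if any(s < 1 for s in self.patch_sizes):
            raise ValueError("patch sizes must be positive integers")
        if self.wpc_count != sum(self.patch_sizes):
            raise ValueError(
                f"wpc_count ({self.wpc_count}) must equal the sum of patch_sizes "
                f"({sum(self.patch_sizes)}): every WPC belongs to exactly one patch"
            )
        if self.wpc_count > self.n_crypts or self.ppc_count > self.n_crypts:
            raise ValueError("WPC/PPC counts cannot exceed the number of crypts scored")

    @property
    def n_clones(self) -> int:
        """Number of distinct fixed clones (patches, counting isolated WPCs)."""
        return len(self.patch_sizes)


def write_census_tsv(censuses: list[CloneCensus], path: str | Path) -> None:
    """Write census records as TSV (patch sizes comma-joined)."""
    rows = [
        {
            "patient_id": c.patient_id,
            "age": c.age,
            "n_crypts": c.n_crypts,
            "wpc_count": c.wpc_count,
            "ppc_count": c.ppc_count,
            "patch_sizes": ",".join(str(s) for s in c.patch_sizes),
        }
        for c in censuses
    ]
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_census_tsv(path: str | Path) -> list[CloneCensus]:
    """Read census records written by :func:`write_census_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "patch_sizes": str})
    out = []
    for row in df.itertuples(index=False):
        raw = row.patch_sizes
        sizes = [] if pd.isna(raw) or raw == "" else [int(s) for s in str(raw).split(",")]
        out.append(
            CloneCensus(
                patient_id=str(row.patient_id),
                age=float(row.age),
                n_crypts=int(row.n_crypts),
                wpc_count=int(row.wpc_count),
                ppc_count=int(row.ppc_count),
                patch_sizes=sizes,
            )
        )
    return out
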