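"""Classification of tumours by their truncal driver-gene sets.

Truncal mutations — those present in every sampled region of a tumour —
mark the drivers present in the last common ancestor clone. Tumours are
tallied by truncal hit count against a user-supplied driver reference list,
and tumours with three or more hits are partitioned by their relation to
the canonical APC/KRAS/TP53 ("AKP") genotype: exactly AKP, AKP plus at
least one further driver, or any other combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["AKP", "TruncalTable", "TruncalCategory", "classify", "summarise",
           "read_truncal_tsv", "write_truncal_tsv"]

#: The canonical adenoma-carcinoma driver trio.
AKP = frozenset({"APC", "KRAS", "TP53"})


@dataclass(frozen=True)
class TruncalCategory:
    """Category record for one tumour's truncal gene set."""

    n_hits: int
    is_single_hit: bool
    single_hit_gene: str | None
    has_apc: bool
    class_a: bool  # exactly {APC}
    class_ak: bool  # exactly {APC, KRAS}
    three_plus_class: str | None  # AKP_only / AKP_plus / Other, when n_hits >= 3


@dataclass
class TruncalTable:
    """Tumour -> truncal driver genes, restricted to a driver reference list."""

    records: dict[str, frozenset[str]]  # tumour_id -> genes
    driver_list: frozenset[str]

    def __post_init__(self) -> None:
        if not self.driver_list:
            raise ValueError("driver list must not be empty")
        for tid, genes in self.records.items():
            extra = genes - self.driver_list
            if extra:
                raise ValueError(f"tumour {tid} carries genes outside the driver list: {sorted(extra)}")


def classify(tumour_genes: frozenset[str] | set[str], driver_list: frozenset[str] | set[str]) -> TruncalCategory:
    """Classify one tumour's truncal gene set.

    Only genes on the driver reference list count as hits. Tumours with
    >= 3 hits fall in exactly one of AKP_only (exactly APC+KRAS+TP53),
    AKP_plus (those three plus at least one more driver), or Other.
    """
    if not driver_list:
        raise ValueError("driver list must not be empty")
    genes = frozenset(tumour_genes) & frozenset(driver_list)
    n = len(genes)
    three_plus = None
    if n >= 3:
        if genes == AKP:
            three_plus = "AKP_only"
        elif genes >= AKP:
            three_plus = "AKP_plus"
        else:
            three_plus = "Other"
    return TruncalCategory(
        n_hits=n,
        is_single_hit=n == 1,
        single_hit_gene=next(iter(genes)) if n == 1 else None,
        has_apc="APC" in genes,
        class_a=genes == frozenset({"APC"}),
        class_ak=genes == frozenset({"APC", "KRAS"}),
        three_plus_class=three_plus,
    )


def summarise(table: TruncalTable) -> dict:
    """Tally category frequencies over the table.

    Returns hit-count percentages over all tumours, the composition of
    single-hit tumours, and AKP_only/AKP_plus/Other percentages over the
    tumours with >= 3 hits; exact counts are retained alongside every
    percentage.
    """
    if not table.records:
        raise ValueError("table is empty")
    cats = {tid: classify(genes, table.driver_list) for tid, genes in table.records.items()}
    n_tot = len(cats)

    hit_counts: dict[int, int] = {}
    for c in cats.values():
        hit_counts[c.n_hits] = hit_counts.get(c.n_hits, 0) + 1
    single = [c for c in cats.values() if c.is_single_hit]
    single_genes: dict[str, int] = {}
    for c in single:
        single_genes[c.single_hit_gene] = single_genes.get(c.single_hit_gene, 0) + 1
    three_plus = [c for c in cats.values() if c.n_hits >= 3]
    akp_classes: dict[str, int] = {"AKP_only": 0, "AKP_plus": 0, "Other": 0}
    for c in three_plus:
        akp_classes[c.three_plus_class] += 1

    def pct(counts: dict, denom: int) -> dict:
        return {k: {"count": v, "percent": 100.0 * v / denom} for k, v in sorted(counts.items())}

    return {
        "n_tumours": n_tot,
        "hit_counts": pct(hit_counts, n_tot),
        "single_hit_composition": pct(single_genes, len(single)) if single else {},
        "akp_classes": pct(akp_classes, len(three_plus)) if three_plus else {},
        "n_three_plus": len(three_plus),
    }


def read_truncal_tsv(path: str | Path, driver_list: frozenset[str]) -> TruncalTable:
    """Read a tumour table (columns: tumour_id, genes comma-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = {}
    for row in df.itertuples(index=False):
        if row.tumour_id in records:
            raise ValueError(f"duplicate tumour id {row.tumour_id}")
        raw = "" if pd.isna(row.genes) else row.genes
        records[row.tumour_id] = frozenset(g for g in raw.split(",") if g)
    return TruncalTable(records=records, driver_list=driver_list)


def write_truncal_tsv(table: TruncalTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"tumour_id": tid, "genes": ",".join(sorted(genes))}
            for tid, genes in table.records.items()
        ],
        columns=["tumour_id", "genes"],
    ).to_csv(path, sep="\t", index=False)
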