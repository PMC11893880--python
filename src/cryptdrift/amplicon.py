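"""Amplicon SNV calling for laser-capture microdissected patches.

The caller genotypes low-input amplicon sequencing of staining-deficient
patches. Merged reads are assigned to amplicons by exact primer match at
both ends plus exact expected length, tabulated into per-position base
counts, and screened for variants with a cross-sample outlier statistic:
at each (amplicon, position, alternate base) the mean and SD of the variant
allele frequency (VAF) across samples define the background error, and a
sample is a candidate when its VAF is at least 1%, exceeds the mean by
3.29 SDs (two-sided normal p < 0.001), and is supported by at least two
reads. A call must be a candidate in both amplicons of its dual-coverage
replicate group, samples under 500 reads are excluded outright, and any
variant called in three or more independent samples is discarded as a
recurrent artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import norm

__all__ = [
    "Amplicon",
    "AmpliconPanel",
    "AmpliconCountMatrix",
    "CallThresholds",
    "SnvCall",
    "zscore_threshold",
    "merge_pairs",
    "filter_amplicons",
    "tabulate",
    "call_snvs",
    "read_panel_tsv",
    "write_panel_tsv",
    "write_calls_tsv",
    "write_calls_vcf",
]

BASES = ("A", "C", "G", "T")

#: TSV schema for serialised count matrices.
MATRIX_COLUMNS = ["sample", "amplicon", "replicate", "position", "ref_base", "A", "C", "G", "T", "depth"]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Amplicon:
    """One amplicon of the panel.

    ``reference_sequence`` is the merged-read sense sequence (forward primer
    through the reverse-complemented reverse primer) and must have the
    expected length when provided. ``replicate_group`` names the
    dual-coverage pair covering the same locus.
    """

    name: str
    forward_primer: str
    reverse_primer: str
    expected_length: int
    replicate_group: str
    reference_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.expected_length < len(self.forward_primer) + len(self.reverse_primer):
            raise ValueError(
                f"amplicon {self.name}: expected_length shorter than the two primers"
            )
        if self.reference_sequence is not None:
            ref = self.reference_sequence
            if len(ref) != self.expected_length:
                raise ValueError(f"amplicon {self.name}: reference length != expected_length")
            if not ref.startswith(self.forward_primer) or not ref.endswith(
                revcomp(self.reverse_primer)
            ):
                raise ValueError(
                    f"amplicon {self.name}: reference must begin with the forward primer "
                    "and end with the reverse-complemented reverse primer"
                )


@dataclass(frozen=True)
class AmpliconPanel:
    """Panel definition: amplicons grouped into dual-coverage pairs.

    A replicate group may contain two amplicons covering the same locus, or
    a single amplicon sequenced as two library replicates (the synthetic
    generator's representation); either way the caller sees two replicate
    count vectors per locus.
    """

    amplicons: list[Amplicon]

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValueError("amplicon names must be unique")
        for grp, members in self.groups().items():
            if len(members) > 2:
                raise ValueError(f"replicate group {grp} has more than two amplicons")

    def groups(self) -> dict[str, list[Amplicon]]:
        out: dict[str, list[Amplicon]] = {}
        for a in self.amplicons:
            out.setdefault(a.replicate_group, []).append(a)
        return out

    def __getitem__(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)


def read_panel_tsv(path: str | Path) -> AmpliconPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    amps = []
    for row in df.itertuples(index=False):
        ref = getattr(row, "reference_sequence", None)
        if isinstance(ref, float) and pd.isna(ref):
            ref = None
        amps.append(
            Amplicon(
                name=row.name,
                forward_primer=row.fwd_primer,
                reverse_primer=row.rev_primer,
                expected_length=int(row.expected_length),
                replicate_group=row.replicate_group,
                reference_sequence=ref,
            )
        )
    return AmpliconPanel(amps)


def write_panel_tsv(panel: AmpliconPanel, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": a.name,
                "fwd_primer": a.forward_primer,
                "rev_primer": a.reverse_primer,
                "expected_length": a.expected_length,
                "replicate_group": a.replicate_group,
                "reference_sequence": a.reference_sequence or "",
            }
            for a in panel.amplicons
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class AmpliconCountMatrix:
    """Per (sample, amplicon, replicate, position) base counts.

    Backed by a tidy DataFrame with columns ``sample, amplicon, replicate,
    position, ref_base, A, C, G, T, depth``. Positions are 0-based within
    the amplicon; ``depth`` is the retained read count at that position and
    base counts sum to at most ``depth`` (reads with N contribute no count).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MATRIX_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"count matrix missing columns: {sorted(missing)}")
        sums = self.df[list(BASES)].sum(axis=1)
        if (sums > self.df["depth"]).any():
            raise ValueError("base counts exceed depth at some positions")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AmpliconCountMatrix":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str, "amplicon": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df[MATRIX_COLUMNS].to_csv(path, sep="\t", index=False)

    def unit_reads(self) -> pd.DataFrame:
        """Reads per (sample, amplicon, replicate) unit: the per-unit depth
        (maximum positional depth, constant across positions for
        length-filtered amplicon reads)."""
        return (
            self.df.groupby(["sample", "amplicon", "replicate"], sort=False)["depth"]
            .max()
            .reset_index(name="reads")
        )


def zscore_threshold(p_two_sided: float) -> float:
    """Standard normal two-sided quantile; z(0.001) = 3.2905."""
    if not 0.0 < p_two_sided < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(norm.isf(p_two_sided / 2.0))


@dataclass(frozen=True)
class CallThresholds:
    """Caller thresholds (defaults are the published settings)."""

    min_depth: int = 500
    min_vaf: float = 0.01
    z: float = 3.29
    min_alt_reads: int = 2
    max_recurrent_samples: int = 2
    leave_one_out: bool = False


@dataclass
class SnvCall:
    """One screened variant cell with its full filter record."""

    sample: str
    amplicon: str
    position: int
    ref_base: str
    alt_base: str
    vaf: float
    z: float
    depth: int
    alt_reads: int
    replicate_support: str  # "both" or "one"
    n_samples_recurrent: int
    verdict: str  # "pass" or "fail"
    fail_reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# read handling


def merge_pairs(forward: str, reverse: str, min_overlap: int = 20) -> str | None:
    """Naive exact overlap merge of one read pair.

    The reverse read is reverse-complemented and the longest exact
    suffix/prefix overlap of at least ``min_overlap`` bases is used; no
    mismatches are tolerated. Returns None when no such overlap exists.
    (A minimal stand-in for a paired-end assembler, sufficient for
    length-exact amplicon reads.)
    """
    rc = revcomp(reverse)
    max_k = min(len(forward), len(rc))
    for k in range(max_k, min_overlap - 1, -1):
        if forward[-k:] == rc[:k]:
            return forward + rc[k:]
    return None


def filter_amplicons(
    merged_reads: list[str], panel: AmpliconPanel
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Assign merged reads to amplicons by exact primer + exact length.

    A read is retained for an amplicon iff it begins with the forward
    primer, ends with the reverse-complemented reverse primer, and has
    exactly the expected length. Reads matching no amplicon, or more than
    one, are discarded and tallied by reason.
    """
    ends = {
        a.name: (a.forward_primer, revcomp(a.reverse_primer), a.expected_length)
        for a in panel.amplicons
    }
    retained: dict[str, list[str]] = {a.name: [] for a in panel.amplicons}
    stats = {"retained": 0, "no_match": 0, "ambiguous": 0}
    for read in merged_reads:
        hits = [
            name
            for name, (fwd, rc_rev, length) in ends.items()
            if len(read) == length and read.startswith(fwd) and read.endswith(rc_rev)
        ]
        if len(hits) == 1:
            retained[hits[0]].append(read)
            stats["retained"] += 1
        elif not hits:
            stats["no_match"] += 1
        else:
            stats["ambiguous"] += 1
    return retained, stats


def tabulate(
    reads_by_amplicon: dict[str, list[str]],
    panel: AmpliconPanel,
    sample: str,
    replicate: int = 1,
) -> AmpliconCountMatrix:
    """Count A/C/G/T per position for one sample's retained reads.

    Reference bases come from the panel reference sequence when present,
    otherwise from the per-position majority base. ``N`` and other
    ambiguity codes contribute to no base count (depth still counts the
    read, so base counts sum to <= depth).
    """
    rows = []
    for name, reads in reads_by_amplicon.items():
        amp = panel[name]
        length = amp.expected_length
        counts = np.zeros((length, 4), dtype=int)
        base_idx = {b: i for i, b in enumerate(BASES)}
        for read in reads:
            for pos, base in enumerate(read):
                i = base_idx.get(base)
                if i is not None:
                    counts[pos, i] += 1
        for pos in range(length):
            if amp.reference_sequence is not None:
                ref = amp.reference_sequence[pos]
            else:
                ref = BASES[int(np.argmax(counts[pos]))] if reads else "N"
            rows.append(
                {
                    "sample": sample,
                    "amplicon": name,
                    "replicate": replicate,
                    "position": pos,
                    "ref_base": ref,
                    **{b: int(counts[pos, i]) for i, b in enumerate(BASES)},
                    "depth": len(reads),
                }
            )
    return AmpliconCountMatrix(pd.DataFrame(rows, columns=MATRIX_COLUMNS))


# ---------------------------------------------------------------------------
# calling


def _replicate_key(matrix_df: pd.DataFrame, panel: AmpliconPanel | None) -> pd.Series:
    """Locus (replicate-group) label per row: the panel's group when given,
    else the amplicon name (replicates then live in the replicate column)."""
    if panel is None:
        return matrix_df["amplicon"].astype(str)
    group_of = {a.name: a.replicate_group for a in panel.amplicons}
    unknown = set(matrix_df["amplicon"].unique()) - set(group_of)
    if unknown:
        raise ValueError(f"amplicons absent from panel: {sorted(unknown)}")
    return matrix_df["amplicon"].map(group_of)


def call_snvs(
    matrix: AmpliconCountMatrix,
    panel: AmpliconPanel | None = None,
    thresholds: CallThresholds | None = None,
) -> list[SnvCall]:
    """Run the cross-sample VAF-outlier caller on a count matrix.

    Returns one record per screened cell — any (sample, locus, position,
    alt) whose VAF reaches the detection floor in at least one replicate —
    with ``verdict == "pass"`` iff every filter succeeded. Filters, in
    order: per-unit depth >= min_depth (failing units are removed before
    background statistics are formed); VAF >= min_vaf; VAF > mean + z*SD of
    that cell's cross-sample background (SD with n-1 denominator; the
    tested sample is included unless ``leave_one_out``); alt reads >=
    min_alt_reads; candidate in both replicates of the locus; and finally
    the variant must not pass in more than ``max_recurrent_samples``
    independent samples. With a zero background SD a candidate passes the
    outlier test iff its VAF exceeds the mean.
    """
    th = thresholds or CallThresholds()
    df = matrix.df.copy()

    # depth exclusion: drop whole (sample, amplicon, replicate) units
    units = matrix.unit_reads()
    bad_units = units[units["reads"] < th.min_depth][["sample", "amplicon", "replicate"]]
    if len(bad_units):
        df = df.merge(bad_units.assign(_bad=True), how="left",
                      on=["sample", "amplicon", "replicate"])
        df = df[df["_bad"].isna()].drop(columns="_bad")
    if df["sample"].nunique() < 3:
        raise ValueError("need >= 3 samples passing the depth filter to form background statistics")

    df["locus"] = _replicate_key(df, panel)
    df["member"] = df["amplicon"].astype(str) + "/" + df["replicate"].astype(str)
    n_members = df.groupby("locus")["member"].transform("nunique")
    if (n_members > 2).any():
        raise ValueError("a replicate group maps to more than two count units")

    long = df.melt(
        id_vars=["sample", "locus", "member", "amplicon", "replicate", "position", "ref_base", "depth"],
        value_vars=list(BASES),
        var_name="alt_base",
        value_name="alt_reads",
    )
    long = long[long["alt_base"] != long["ref_base"]].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        long["vaf"] = np.where(long["depth"] > 0, long["alt_reads"] / long["depth"], 0.0)

    grp = long.groupby(["member", "position", "alt_base"])["vaf"]
    m = grp.transform("size")
    total = grp.transform("sum")
    total2 = long["vaf"].pow(2).groupby(
        [long["member"], long["position"], long["alt_base"]]
    ).transform("sum")
    if th.leave_one_out:
        mm = m - 1
        mean = (total - long["vaf"]) / mm
        var = (total2 - long["vaf"] ** 2 - mm * mean**2) / (mm - 1)
    else:
        mean = total / m
        var = (total2 - m * mean**2) / (m - 1)
    sd = np.sqrt(var.clip(lower=0.0))
    long["bg_mean"] = mean
    long["bg_sd"] = sd
    diff = long["vaf"] - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        long["z"] = np.select(
            [sd > 0, diff > 0, diff < 0], [diff / sd.replace(0.0, np.nan), np.inf, -np.inf], 0.0
        )

    long["ok_vaf"] = long["vaf"] >= th.min_vaf
    long["ok_z"] = np.where(
        long["bg_sd"] > 0,
        long["vaf"] > long["bg_mean"] + th.z * long["bg_sd"],
        long["vaf"] > long["bg_mean"],
    )
    long["ok_alt"] = long["alt_reads"] >= th.min_alt_reads
    long["candidate"] = long["ok_vaf"] & long["ok_z"] & long["ok_alt"]

    # keep only cells worth reporting: detection floor reached in >= 1 replicate
    long["any_floor"] = long.groupby(["sample", "locus", "position", "alt_base"])[
        "ok_vaf"
    ].transform("any")
    screened = long[long["any_floor"]].copy()
    if screened.empty:
        return []

    agg = (
        screened.groupby(["sample", "locus", "position", "alt_base"])
        .agg(
            amplicon=("amplicon", "first"),
            ref_base=("ref_base", "first"),
            vaf=("vaf", "mean"),
            z=("z", "min"),
            depth=("depth", "min"),
            alt_reads=("alt_reads", "min"),
            n_candidate=("candidate", "sum"),
            n_rep=("member", "nunique"),
            ok_vaf=("ok_vaf", "all"),
            ok_z=("ok_z", "all"),
            ok_alt=("ok_alt", "all"),
        )
        .reset_index()
    )
    agg["replicated"] = (agg["n_candidate"] == agg["n_rep"]) & (agg["n_rep"] == 2)

    # recurrence: variants that replicate in too many independent samples
    rec = (
        agg[agg["replicated"]]
        .groupby(["locus", "position", "alt_base"])["sample"]
        .transform("nunique")
    )
    agg["n_samples_recurrent"] = 0
    agg.loc[agg["replicated"], "n_samples_recurrent"] = rec
    agg["ok_recurrence"] = agg["n_samples_recurrent"] <= th.max_recurrent_samples

    calls: list[SnvCall] = []
    for row in agg.itertuples(index=False):
        reasons = []
        if not row.ok_vaf:
            reasons.append("min_vaf")
        if not row.ok_z:
            reasons.append("z_test")
        if not row.ok_alt:
            reasons.append("min_alt_reads")
        if not row.replicated:
            reasons.append("replicate")
        if not row.ok_recurrence:
            reasons.append("recurrence")
        calls.append(
            SnvCall(
                sample=str(row.sample),
                amplicon=str(row.locus),
                position=int(row.position),
                ref_base=str(row.ref_base),
                alt_base=str(row.alt_base),
                vaf=float(row.vaf),
                z=float(row.z),
                depth=int(row.depth),
                alt_reads=int(row.alt_reads),
                replicate_support="both" if row.replicated else "one",
                n_samples_recurrent=int(row.n_samples_recurrent),
                verdict="pass" if not reasons else "fail",
                fail_reasons=reasons,
            )
        )
    calls.sort(key=lambda c: (c.sample, c.amplicon, c.position, c.alt_base))
    return calls


def write_calls_tsv(calls: list[SnvCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": c.sample,
                "amplicon": c.amplicon,
                "pos": c.position,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "vaf": c.vaf,
                "z": c.z,
                "depth": c.depth,
                "alt_reads": c.alt_reads,
                "replicate_support": c.replicate_support,
                "verdict": c.verdict,
                "filters": ";".join(c.fail_reasons) or "PASS",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls: list[SnvCall], path: str | Path) -> None:
    """Minimal single-sample-per-record VCF of the passing calls.

    Positions are 1-based within the amplicon (used as the contig); INFO
    carries the outlier z score and replicate support. Indel records from
    external pipelines can be concatenated after the header.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=Z,Number=1,Type=Float,Description="SDs above background mean VAF">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample of origin">',
        '##INFO=<ID=REPS,Number=1,Type=String,Description="Replicate support">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        if c.verdict != "pass":
            continue
        info = f"Z={c.z:.3f};VAF={c.vaf:.5f};SAMPLE={c.sample};REPS={c.replicate_support}"
        lines.append(
            f"{c.amplicon}\t{c.position + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
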