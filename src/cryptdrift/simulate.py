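"""Synthetic cohorts, patch censuses, amplicon counts and truncal tables.

The generators realise exactly the statistical structure the inference
stages assume, so the whole pipeline is testable without patient data:

* fixation events arrive as a Poisson process at rate ``delta_cfix *
  n_crypts`` per year over a patient's life, with event times uniform on
  [0, age] (the constant-rate assumption behind the patch-size law);
* each founded patch grows by a Yule pure-birth process at per-crypt rate
  ``rho``, so a patch founded a duration ``d`` before observation has a
  geometric size distribution with success probability ``exp(-rho d)`` and
  the marginal patch size is logarithmic-series with ``q = 1 - e^{-rho t}``;
* patient fission rates are Student-t distributed and truncated to be
  positive (a crypt cannot un-fission);
* partially populated crypts are an age-independent binomial frequency;
* amplicon background errors are Normal on the VAF scale across samples,
  then binomial on reads — precisely the error model the caller's
  mean + z*SD outlier rule presumes — with dual replicate count vectors
  per amplicon and spiked variants present in both replicates.

Defaults mirror the study conditions of the cohort the pipeline was built
around: ~100 patients aged 30-91, ~20,000 scored crypts each, a fixation
slope of order 1e-6 per crypt-year, and fission location/scale/dof of
0.019 / 0.004 / 10 per year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import BASES, MATRIX_COLUMNS, Amplicon, AmpliconCountMatrix, AmpliconPanel
from .census import CloneCensus
from .truncal import AKP, TruncalTable

__all__ = [
    "CohortSimParams",
    "truncated_student_t",
    "simulate_patches",
    "simulate_cohort",
    "simulate_amplicon_counts",
    "simulate_truncal_table",
    "random_panel",
    "synthetic_merged_reads",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator settings (defaults = the emulated study conditions)."""

    n_patients: int = 100
    age_range: tuple[float, float] = (30.0, 91.0)
    crypts_per_patient: int = 20_000
    delta_cfix_true: float = 1.6e-6
    cpart_true: float = 5e-5
    fission_location: float = 0.019
    fission_scale: float = 0.004
    fission_df: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.delta_cfix_true < 0:
            raise ValueError("delta_cfix_true must be non-negative")
        if not 0.0 <= self.cpart_true <= 1.0:
            raise ValueError("cpart_true must lie in [0, 1]")
        if self.fission_scale <= 0 or self.fission_df <= 0:
            raise ValueError("fission_scale and fission_df must be positive")
        lo, hi = self.age_range
        if not (0.0 < lo <= hi < 120.0):
            raise ValueError("age_range must satisfy 0 < min <= max < 120")
        if self.crypts_per_patient < 1:
            raise ValueError("crypts_per_patient must be >= 1")


def truncated_student_t(
    nu: float, mu: float, sigma: float, size: int, rng, lower: float = 0.0
) -> np.ndarray:
    """Student-t(nu, mu, sigma) draws rejected below ``lower``.

    Rejection sampling; raises if the acceptance region has vanishing mass
    (location many scales below the bound).
    """
    rng = _as_rng(rng)
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        need = size - filled
        if need == 0:
            break
        draw = mu + sigma * rng.standard_t(nu, size=2 * need + 16)
        good = draw[draw > lower][:need]
        out[filled : filled + good.size] = good
        filled += good.size
    else:
        raise RuntimeError("truncated Student-t rejection sampler failed to fill; "
                           "location is too far below the truncation bound")
    return out


def simulate_patches(
    delta_cfix: float, rho: float, age: float, n_crypts: int, seed
) -> list[int]:
    """Forward-simulate one patient's patch sizes.

    Poisson(delta_cfix * n_crypts * age) fixation events at uniform times;
    each patch then grows as a Yule process for its remaining time ``d``,
    giving size ~ Geometric(exp(-rho d)). The marginal size law is the
    logarithmic series with q = 1 - exp(-rho * age).
    """
    if delta_cfix < 0 or rho < 0 or age < 0:
        raise ValueError("rates and age must be non-negative")
    if n_crypts < 1:
        raise ValueError("n_crypts must be >= 1")
    rng = _as_rng(seed)
    n_events = rng.poisson(delta_cfix * n_crypts * age)
    if n_events == 0:
        return []
    growth_time = age - rng.uniform(0.0, age, size=n_events)
    if rho == 0.0:
        return [1] * int(n_events)
    sizes = rng.geometric(np.exp(-rho * growth_time))
    return [int(s) for s in sizes]


def simulate_cohort(params: CohortSimParams) -> list[CloneCensus]:
    """Generate a cohort of clone censuses under the generative assumptions.

    Ages are uniform over the cohort span; each patient's fission rate is a
    positive-truncated Student-t draw; patch sizes come from
    :func:`simulate_patches`; ``wpc_count`` is the total crypt count of the
    patches, and ``ppc_count`` is Binomial(n_crypts, cpart_true).
    """
    rng = np.random.default_rng(params.seed)
    out = []
    for i in range(params.n_patients):
        age = rng.uniform(*params.age_range)
        rho_i = truncated_student_t(
            params.fission_df, params.fission_location, params.fission_scale, 1, rng
        )[0]
        sizes = simulate_patches(
            params.delta_cfix_true, rho_i, age, params.crypts_per_patient, rng
        )
        out.append(
            CloneCensus(
                patient_id=f"P{i:03d}",
                age=float(age),
                n_crypts=params.crypts_per_patient,
                wpc_count=int(sum(sizes)),
                ppc_count=int(rng.binomial(params.crypts_per_patient, params.cpart_true)),
                patch_sizes=sorted(sizes),
            )
        )
    return out


# ---------------------------------------------------------------------------
# amplicon data


def random_panel(
    n_amplicons: int = 2,
    insert_length: int = 60,
    primer_length: int = 20,
    seed=0,
) -> AmpliconPanel:
    """A synthetic amplicon panel with random reference sequences.

    Each amplicon is its own dual-coverage replicate group (the generator
    emits two replicate count vectors per amplicon).
    """
    rng = _as_rng(seed)
    amps = []
    for k in range(n_amplicons):
        seq = "".join(rng.choice(list(BASES), size=2 * primer_length + insert_length))
        fwd = seq[:primer_length]
        rev_rc = seq[-primer_length:]
        from .amplicon import revcomp

        amps.append(
            Amplicon(
                name=f"amp{k:02d}",
                forward_primer=fwd,
                reverse_primer=revcomp(rev_rc),
                expected_length=len(seq),
                replicate_group=f"locus{k:02d}",
                reference_sequence=seq,
            )
        )
    return AmpliconPanel(amps)


def simulate_amplicon_counts(
    panel: AmpliconPanel,
    n_samples: int,
    background_vaf_mean: float,
    background_vaf_sd: float,
    spike_ins: list[tuple[str, str, int, str, float]],
    depth: int | dict[str, int],
    seed=0,
) -> AmpliconCountMatrix:
    """Background-error amplicon base counts with spiked variants.

    Per (sample, amplicon, replicate, position, alternate base) the error
    VAF is max(0, Normal(background_vaf_mean, background_vaf_sd)) and alt
    reads are Binomial(depth, VAF). Spike-ins, given as (sample, amplicon,
    position, alt_base, vaf), add their VAF on top of the background in
    BOTH replicates. ``depth`` is a single read count or a per-sample
    mapping; samples are named ``S00`` .. ``S{n-1:02d}``.
    """
    if not 0.0 <= background_vaf_mean < 0.01:
        raise ValueError("background_vaf_mean must lie in [0, 0.01)")
    if background_vaf_sd < 0:
        raise ValueError("background_vaf_sd must be non-negative")
    rng = _as_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    depth_of = {s: (depth[s] if isinstance(depth, dict) else int(depth)) for s in samples}
    if min(depth_of.values(), default=1) < 1:
        raise ValueError("depths must be >= 1")

    spikes: dict[tuple[str, str, int, str], float] = {}
    for sample, amp_name, pos, alt, vaf in spike_ins:
        amp = panel[amp_name]
        if not 0 <= pos < amp.expected_length:
            raise ValueError(f"spike position {pos} outside amplicon {amp_name}")
        if amp.reference_sequence and amp.reference_sequence[pos] == alt:
            raise ValueError(f"spike base {alt} equals the reference at {amp_name}:{pos}")
        if vaf + background_vaf_mean > 1.0:
            raise ValueError("spike VAF plus background exceeds 1")
        spikes[(sample, amp_name, pos, alt)] = vaf

    frames = []
    for amp in panel.amplicons:
        if amp.reference_sequence is None:
            raise ValueError(f"amplicon {amp.name} needs a reference sequence to simulate")
        length = amp.expected_length
        ref = np.array(list(amp.reference_sequence))
        for sample in samples:
            d = depth_of[sample]
            for rep in (1, 2):
                p = np.clip(
                    rng.normal(background_vaf_mean, background_vaf_sd, size=(length, 4)),
                    0.0, 1.0,
                )
                for (s, a, pos, alt), vaf in spikes.items():
                    if s == sample and a == amp.name:
                        j = BASES.index(alt)
                        if p[pos, j] + vaf > 1.0:
                            raise ValueError("spike VAF plus background exceeds 1")
                        p[pos, j] += vaf
                p[np.arange(length), [BASES.index(b) for b in ref]] = 0.0  # ref base: no error vs itself
                alt_counts = rng.binomial(d, p)
                ref_counts = d - alt_counts.sum(axis=1)
                if (ref_counts < 0).any():
                    raise ValueError("alt counts exceed depth; background/spike VAFs too large")
                counts = alt_counts
                counts[np.arange(length), [BASES.index(b) for b in ref]] = ref_counts
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": sample,
                            "amplicon": amp.name,
                            "replicate": rep,
                            "position": np.arange(length),
                            "ref_base": ref,
                            "A": counts[:, 0],
                            "C": counts[:, 1],
                            "G": counts[:, 2],
                            "T": counts[:, 3],
                            "depth": d,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)[MATRIX_COLUMNS] if frames else pd.DataFrame(
        columns=MATRIX_COLUMNS
    )
    return AmpliconCountMatrix(df)


def synthetic_merged_reads(
    amp: Amplicon,
    n_reads: int,
    variants: list[tuple[int, str, float]] | None = None,
    corrupt_fraction: float = 0.0,
    seed=0,
) -> list[str]:
    """Merged reads from one amplicon's reference, for the read-filtering path.

    ``variants`` are (position, alt_base, vaf) substitutions applied
    per-read with probability vaf. ``corrupt_fraction`` of reads get their
    first primer base flipped (so exact-primer filtering must discard
    exactly those).
    """
    if amp.reference_sequence is None:
        raise ValueError("amplicon needs a reference sequence")
    rng = _as_rng(seed)
    n_corrupt = int(round(corrupt_fraction * n_reads))
    reads = []
    for i in range(n_reads):
        seq = list(amp.reference_sequence)
        for pos, alt, vaf in variants or []:
            if rng.random() < vaf:
                seq[pos] = alt
        if i < n_corrupt:
            seq[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[0]]
        reads.append("".join(seq))
    rng.shuffle(reads)
    return reads


# ---------------------------------------------------------------------------
# truncal tables


def simulate_truncal_table(
    n_tumours: int,
    gene_repertoire: list[str],
    category_mix: dict[str, float],
    seed=0,
) -> TruncalTable:
    """Tumour truncal gene sets drawn from requested category proportions.

    Categories: ``A`` (exactly APC), ``AK`` (exactly APC+KRAS),
    ``AKP_only``, ``AKP_plus`` (AKP plus one extra driver), ``Other``
    (three drivers not containing the full AKP trio), and ``single:<GENE>``.
    Proportions must sum to 1; tumour counts per category are multinomial.
    """
    if not gene_repertoire:
        raise ValueError("gene repertoire must not be empty")
    if category_mix and abs(sum(category_mix.values()) - 1.0) > 1e-9:
        raise ValueError("category_mix proportions must sum to 1")
    rng = _as_rng(seed)
    repertoire = list(dict.fromkeys(gene_repertoire))
    extras = [g for g in repertoire if g not in AKP]
    cats = list(category_mix)
    counts = rng.multinomial(n_tumours, [category_mix[c] for c in cats]) if n_tumours else []

    records: dict[str, frozenset[str]] = {}
    i = 0
    for cat, cnt in zip(cats, counts):
        for _ in range(cnt):
            if cat == "A":
                genes = {"APC"}
            elif cat == "AK":
                genes = {"APC", "KRAS"}
            elif cat == "AKP_only":
                genes = set(AKP)
            elif cat == "AKP_plus":
                if not extras:
                    raise ValueError("AKP_plus needs a driver outside APC/KRAS/TP53")
                genes = set(AKP) | {extras[rng.integers(len(extras))]}
            elif cat == "Other":
                if not extras:
                    raise ValueError("'Other' needs a driver outside APC/KRAS/TP53")
                genes = {"APC", "KRAS", extras[rng.integers(len(extras))]}
            elif cat.startswith("single:"):
                gene = cat.split(":", 1)[1]
                if gene not in repertoire:
                    raise ValueError(f"single-hit gene {gene} not in repertoire")
                genes = {gene}
            else:
                raise ValueError(f"unknown category {cat!r}")
            records[f"T{i:04d}"] = frozenset(genes)
            i += 1
    driver_list = frozenset(repertoire) | AKP
    return TruncalTable(records=records, driver_list=driver_list)


def write_cohort_tsv(censuses: list[CloneCensus], path: str | Path) -> None:
    """Convenience re-export of the census TSV writer."""
    from .census import write_census_tsv

    write_census_tsv(censuses, path)
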