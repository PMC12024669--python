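"""Panel validation, a simplified allele-ratio genotype caller, and the
coverage/completeness filters applied before ancestry scoring.

The screen keeps a diagnostic locus only if it behaves diagnostically in
reference individuals of known origin: the foreign reference pool must be
(nearly) fixed for the foreign allele, and the native reference pool must
carry the foreign allele at no more than a small tolerated frequency —
low-frequency standing variation for the "foreign" allele inside the native
gene pool is expected and must not disqualify a locus outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix import (
    HET,
    HOM_FOREIGN,
    HOM_NATIVE,
    MISSING,
    AlleleCounts,
    GenotypeMatrix,
)

PASS = "PASS"
FAIL_POOL_A = "FAIL_POOL_A"  # native pool carries too much foreign allele
FAIL_POOL_B = "FAIL_POOL_B"  # foreign pool not fixed enough for foreign allele
FAIL_COVERAGE = "FAIL_COVERAGE"


@dataclass(frozen=True)
class LocusQC:
    """Per-locus genotyping summary (mean depth, call rate, frequencies)."""

    locus_id: str
    mean_depth: float | None
    genotype_rate: float
    freq_foreign: float
    freq_native: float
    fixation_status: str = PASS


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the pre-scoring filters.

    min_locus_depth
        Minimum mean read depth (across all calls) for a locus to be kept;
        strict: a mean of exactly the threshold passes, anything below fails.
    max_missing_loci_per_individual
        Individuals with more missing calls than this are removed; the
        default 0 removes any individual with one or more missing loci.
    tolerance_native_pool
        Maximum foreign-allele frequency allowed in the native reference
        pool during validation.
    tolerance_foreign_pool
        Maximum native-allele frequency allowed in the foreign reference
        pool (i.e. the foreign pool's foreign-allele frequency must be at
        least ``1 - tolerance_foreign_pool``).
    """

    min_locus_depth: float = 150.0
    max_missing_loci_per_individual: int = 0
    tolerance_native_pool: float = 0.2
    tolerance_foreign_pool: float = 0.15

    def __post_init__(self) -> None:
        if self.min_locus_depth < 0 or self.max_missing_loci_per_individual < 0:
            raise ValueError("QC thresholds must be non-negative")
        for t in (self.tolerance_native_pool, self.tolerance_foreign_pool):
            if not 0.0 <= t <= 1.0:
                raise ValueError("fixation tolerances must be in [0, 1]")


@dataclass
class QCReport:
    dropped_loci: dict[str, str] = field(default_factory=dict)
    dropped_samples: dict[str, str] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.dropped_loci and not self.dropped_samples


def call_from_counts(
    counts: AlleleCounts,
    pops: dict[str, str],
    het_band: tuple[float, float] = (0.2, 0.8),
) -> GenotypeMatrix:
    """Call genotypes from per-allele read counts by the foreign-read fraction.

    A call is HOM_NATIVE when the foreign-read fraction is below ``lo``,
    HOM_FOREIGN when above ``hi``, HET inside ``[lo, hi]``, and MISSING at
    zero total depth.
    """
    lo, hi = het_band
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"het_band must satisfy 0 < lo <= hi < 1, got {het_band}")
    total = counts.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, counts.n_foreign / np.maximum(total, 1), np.nan)
    calls = np.full(total.shape, MISSING, dtype=np.int8)
    ok = total > 0
    calls[ok & (frac < lo)] = HOM_NATIVE
    calls[ok & (frac > hi)] = HOM_FOREIGN
    calls[ok & (frac >= lo) & (frac <= hi)] = HET
    return GenotypeMatrix(
        samples=list(counts.samples),
        loci=list(counts.loci),
        calls=calls,
        pops={s: pops[s] for s in counts.samples},
        depths=total,
    )


def _locus_frequencies(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (freq_foreign, freq_native, genotype_rate) by allele counting."""
    observed = calls != MISSING
    n_called = observed.sum(axis=0)
    dosage = np.where(observed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_foreign = np.where(n_called > 0, dosage / np.maximum(2 * n_called, 1), np.nan)
    rate = n_called / calls.shape[0] if calls.shape[0] else np.zeros(calls.shape[1])
    return freq_foreign, 1.0 - freq_foreign, rate


def panel_summary(matrix: GenotypeMatrix) -> list[LocusQC]:
    """Per-locus mean depth, genotype rate and allele frequencies."""
    ff, fn, rate = _locus_frequencies(matrix.calls)
    if matrix.depths is not None:
        mean_depth = matrix.depths.mean(axis=0).astype(float)
    else:
        mean_depth = [None] * matrix.n_loci
    return [
        LocusQC(
            locus_id=matrix.loci[j],
            mean_depth=None if matrix.depths is None else float(mean_depth[j]),
            genotype_rate=float(rate[j]),
            freq_foreign=float(ff[j]) if not np.isnan(ff[j]) else float("nan"),
            freq_native=float(fn[j]) if not np.isnan(fn[j]) else float("nan"),
        )
        for j in range(matrix.n_loci)
    ]


def apply_qc_filters(
    matrix: GenotypeMatrix, cfg: QCConfig = QCConfig()
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-coverage loci, then incompletely genotyped individuals.

    Loci whose mean depth (over all current calls) falls below
    ``cfg.min_locus_depth`` are removed first; individuals are then removed
    if, over the surviving loci, they have more than
    ``cfg.max_missing_loci_per_individual`` missing calls.  Because removing
    individuals changes the per-locus mean depths, the two rules are
    repeated until nothing more is removed, which makes the operation
    idempotent; the first pass is exactly the single-pass rule.
    """
    if cfg.min_locus_depth > 0 and matrix.depths is None:
        raise ValueError("depth filtering requested but matrix has no depth table")
    report = QCReport()
    out = matrix
    while True:
        changed = False
        if cfg.min_locus_depth > 0:
            mean_depth = out.depths.mean(axis=0)
            keep_loci = [
                j for j in range(out.n_loci) if mean_depth[j] >= cfg.min_locus_depth
            ]
            if len(keep_loci) < out.n_loci:
                for j in range(out.n_loci):
                    if mean_depth[j] < cfg.min_locus_depth:
                        report.dropped_loci[out.loci[j]] = (
                            f"mean depth {mean_depth[j]:.1f} < {cfg.min_locus_depth:g}"
                        )
                if not keep_loci:
                    raise ValueError("all loci removed by the coverage filter")
                out = out.take_loci(keep_loci)
                changed = True

        n_missing = out.missing_per_sample()
        keep_samples = [
            i
            for i in range(out.n_samples)
            if n_missing[i] <= cfg.max_missing_loci_per_individual
        ]
        if len(keep_samples) < out.n_samples:
            for i in range(out.n_samples):
                if n_missing[i] > cfg.max_missing_loci_per_individual:
                    report.dropped_samples[out.samples[i]] = (
                        f"{int(n_missing[i])} missing loci > "
                        f"{cfg.max_missing_loci_per_individual}"
                    )
            if not keep_samples:
                raise ValueError("all individuals removed by the completeness filter")
            out = out.take_samples(keep_samples)
            changed = True
        if not changed:
            return out, report


def validate_fixation(
    matrix: GenotypeMatrix,
    pool_native: Iterable[str],
    pool_foreign: Iterable[str],
    cfg: QCConfig = QCConfig(),
) -> list[LocusQC]:
    """Check each locus for (near-)fixation in two reference pools.

    A locus FAILs for the native pool when that pool's foreign-allele
    frequency exceeds ``cfg.tolerance_native_pool``, and for the foreign
    pool when that pool's foreign-allele frequency is below
    ``1 - cfg.tolerance_foreign_pool``.  Allele counting uses two gene
    copies per homozygote and one per heterozygote.
    """
    pool_native = list(pool_native)
    pool_foreign = list(pool_foreign)
    if not pool_native or not pool_foreign:
        raise ValueError("reference pools must be non-empty")
    overlap = set(pool_native) & set(pool_foreign)
    if overlap:
        raise ValueError(f"reference pools overlap: {sorted(overlap)}")
    idx_a = [matrix.sample_index(s) for s in pool_native]
    idx_b = [matrix.sample_index(s) for s in pool_foreign]

    ff_a, _, _ = _locus_frequencies(matrix.calls[idx_a, :])
    ff_b, _, _ = _locus_frequencies(matrix.calls[idx_b, :])
    ff_all, fn_all, rate = _locus_frequencies(matrix.calls)
    mean_depth = None if matrix.depths is None else matrix.depths.mean(axis=0)

    out = []
    for j in range(matrix.n_loci):
        status = PASS
        if not np.isnan(ff_b[j]) and ff_b[j] < 1.0 - cfg.tolerance_foreign_pool:
            status = FAIL_POOL_B
        if not np.isnan(ff_a[j]) and ff_a[j] > cfg.tolerance_native_pool:
            status = FAIL_POOL_A
        out.append(
            LocusQC(
                locus_id=matrix.loci[j],
                mean_depth=None if mean_depth is None else float(mean_depth[j]),
                genotype_rate=float(rate[j]),
                freq_foreign=float(ff_all[j]),
                freq_native=float(fn_all[j]),
                fixation_status=status,
            )
        )
    return out
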