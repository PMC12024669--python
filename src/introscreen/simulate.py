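"""Synthetic-data generators matching the statistical structure the screen
assumes: diagnostic panels with low-frequency standing foreign alleles in
the native gene pool, amplicon read depths, hybrid cohorts drawn from the
six-class model, Balding-Nichols structured populations, and a
Wright-Fisher sampler for checking the LD effective-size estimator.

Every generator is exactly reproducible under a fixed seed and returns a
truth record with the latent values needed to score the downstream
estimators.

The default panel emulates a 16-locus diagnostic screen in which the
"foreign" allele segregates in the native pool at low frequency
(0.03-0.24), with mean amplicon depths drawn log-uniformly over
2,000-9,500 reads per locus — the foreign alleles seen in natives are
modeled as standing variation, not recent admixture, which is exactly the
confounder a diagnostic screen must not mistake for introgression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .hybrid import CLASSES, PHI, _CLASS_INDEX
from .matrix import (
    HET,
    HOM_FOREIGN,
    HOM_NATIVE,
    MISSING,
    AlleleCounts,
    DiagnosticLocus,
    DiagnosticPanel,
    GenotypeMatrix,
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PanelSimConfig:
    """Diagnostic-panel simulation settings.

    foreign_freq_in_native
        Per-locus frequency of the foreign allele segregating in the native
        gene pool; a scalar, a length-L vector, or None to draw each locus
        uniformly from [0.03, 0.24].
    depth_mean_range
        Per-locus mean read depth is drawn log-uniformly over this range.
    depth_dispersion
        Negative-binomial size parameter (smaller = more overdispersed).
    error_rate
        Per-read miscall probability in the read-count model.
    missing_rate
        Per-call dropout probability (depth set to zero).
    """

    L: int = 16
    foreign_freq_in_native: float | np.ndarray | None = None
    depth_mean_range: tuple[float, float] = (2_000.0, 9_500.0)
    depth_dispersion: float = 5.0
    error_rate: float = 0.001
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("need at least one locus")
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def _panel_latents(cfg: PanelSimConfig, rng: np.random.Generator):
    if cfg.foreign_freq_in_native is None:
        f = rng.uniform(0.03, 0.24, size=cfg.L)
    else:
        f = np.broadcast_to(np.asarray(cfg.foreign_freq_in_native, dtype=float), (cfg.L,)).copy()
    if ((f < 0) | (f > 1)).any():
        raise ValueError("foreign_freq_in_native must be in [0, 1]")
    lo, hi = cfg.depth_mean_range
    depth_means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.L))
    return f, depth_means


def make_panel(L: int = 16, seed: int = 0) -> DiagnosticPanel:
    """A synthetic L-locus diagnostic panel with arbitrary allele symbols."""
    rng = np.random.default_rng(seed)
    loci = []
    for j in range(L):
        native, foreign = rng.choice(4, size=2, replace=False)
        loci.append(
            DiagnosticLocus(
                locus_id=f"L{j + 1:03d}",
                native_allele=_BASES[native],
                foreign_allele=_BASES[foreign],
                read_position=int(rng.integers(5, 60)),
            )
        )
    return DiagnosticPanel(tuple(loci))


def _read_counts(
    genotypes: np.ndarray,
    depth_means: np.ndarray,
    cfg: PanelSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial depths split binomially by genotype with error."""
    n, L = genotypes.shape
    size = cfg.depth_dispersion
    p_nb = size / (size + depth_means)
    depth = rng.negative_binomial(size, p_nb[None, :], size=(n, L))
    if cfg.missing_rate > 0:
        depth = np.where(rng.random((n, L)) < cfg.missing_rate, 0, depth)
    e = cfg.error_rate
    p_foreign_read = np.choose(genotypes, [e, 0.5, 1.0 - e])
    n_foreign = rng.binomial(depth, p_foreign_read)
    return n_foreign, depth - n_foreign


def simulate_reference_pools(
    cfg: PanelSimConfig,
    n_native: int,
    n_foreign: int,
    native_freq_in_foreign: float = 0.0,
) -> tuple[GenotypeMatrix, AlleleCounts, dict]:
    """Reference individuals of known origin for panel validation.

    Native-pool genotypes are drawn in Hardy-Weinberg proportions from the
    per-locus foreign-allele frequencies; the foreign pool is fixed for the
    foreign allele unless ``native_freq_in_foreign`` > 0.  Returns the
    genotype matrix (with depths), the raw allele read counts, and a truth
    record of all latent values.
    """
    if min(n_native, n_foreign) < 1:
        raise ValueError("both pools need at least one individual")
    rng = np.random.default_rng(cfg.seed)
    f, depth_means = _panel_latents(cfg, rng)

    g_native = rng.binomial(2, f[None, :], size=(n_native, cfg.L))
    g_foreign = 2 - rng.binomial(2, native_freq_in_foreign, size=(n_foreign, cfg.L))
    genotypes = np.vstack([g_native, g_foreign])

    n_for, n_nat = _read_counts(genotypes, depth_means, cfg, rng)
    samples = [f"NAT{i + 1:03d}" for i in range(n_native)] + [
        f"FOR{i + 1:03d}" for i in range(n_foreign)
    ]
    loci = [f"L{j + 1:03d}" for j in range(cfg.L)]
    pops = {s: ("native_ref" if s.startswith("NAT") else "foreign_ref") for s in samples}
    depth = n_for + n_nat
    calls = np.where(depth > 0, genotypes, MISSING).astype(np.int8)
    matrix = GenotypeMatrix(
        samples=samples, loci=loci, calls=calls, pops=pops, depths=depth
    )
    counts = AlleleCounts(samples=samples, loci=loci, n_native=n_nat, n_foreign=n_for)
    truth = {
        "foreign_freq_in_native": f,
        "native_freq_in_foreign": native_freq_in_foreign,
        "depth_means": depth_means,
        "genotypes": genotypes,
    }
    return matrix, counts, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Hybrid-cohort composition: per population, a class -> count map."""

    composition: Mapping[str, Mapping[str, int]]
    seed: int = 0

    def __post_init__(self) -> None:
        total = 0
        for pop, classes in self.composition.items():
            for cls, count in classes.items():
                if cls not in _CLASS_INDEX:
                    raise ValueError(f"unknown hybrid class {cls!r}")
                if count < 0:
                    raise ValueError("class counts must be >= 0")
                total += count
        if total < 1:
            raise ValueError("cohort must contain at least one individual")


def simulate_hybrid_cohort(
    panel_cfg: PanelSimConfig,
    cohort_cfg: CohortSimConfig,
    native_freq_in_foreign: float = 0.0,
) -> tuple[GenotypeMatrix, dict]:
    """Draw a cohort of hybrids from the six-class gene-copy-origin model.

    For each individual, the origin pair of the two gene copies at every
    locus is drawn from its class's phi, and each copy's allele from the
    corresponding parental pool frequency (species A carries the foreign
    allele at the panel's standing-variation frequency; species B carries
    the native allele at ``native_freq_in_foreign``).  The truth record
    stores the class of every individual and each class's expected ancestry
    score under the latent frequencies.
    """
    rng = np.random.default_rng(cohort_cfg.seed)
    f, depth_means = _panel_latents(panel_cfg, np.random.default_rng(panel_cfg.seed))
    p_A = 1.0 - f  # native-allele frequency in species A
    p_B = np.full(panel_cfg.L, native_freq_in_foreign)

    samples: list[str] = []
    pops: dict[str, str] = {}
    classes: list[str] = []
    for pop, comp in cohort_cfg.composition.items():
        for cls in CLASSES:
            for _ in range(comp.get(cls, 0)):
                sid = f"{pop}_{cls}_{len(samples) + 1:04d}"
                samples.append(sid)
                pops[sid] = pop
                classes.append(cls)
    n = len(samples)
    L = panel_cfg.L
    zidx = np.array([_CLASS_INDEX[c] for c in classes])

    # origin pair per cell: 0 both-A, 1 one-each, 2 both-B
    u = rng.random((n, L))
    cum = PHI[zidx].cumsum(axis=1)  # (n, 3)
    w = (cum[:, :2, None].transpose(0, 2, 1) < u[:, :, None]).sum(axis=2)
    copies_from_A = 2 - w
    # draw native-allele copies contributed by each species
    nat_from_A = rng.binomial(copies_from_A, p_A[None, :])
    nat_from_B = rng.binomial(2 - copies_from_A, p_B[None, :])
    genotypes = 2 - (nat_from_A + nat_from_B)  # foreign-allele dosage

    calls = genotypes.astype(np.int8)
    if panel_cfg.missing_rate > 0:
        drop = rng.random((n, L)) < panel_cfg.missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int8)

    matrix = GenotypeMatrix(
        samples=samples,
        loci=[f"L{j + 1:03d}" for j in range(L)],
        calls=calls,
        pops=pops,
    )
    # expected per-class ancestry score under the latent frequencies
    exp_native = {
        cls: float(
            100.0
            * np.mean(
                PHI[i, 0] * p_A + PHI[i, 1] * (p_A + p_B) / 2.0 + PHI[i, 2] * p_B
            )
        )
        for cls, i in _CLASS_INDEX.items()
    }
    truth = {
        "classes": dict(zip(samples, classes)),
        "p_native_in_A": p_A,
        "p_native_in_B": p_B,
        "expected_ancestry_by_class": exp_native,
        "genotypes": genotypes,
    }
    return matrix, truth


@dataclass(frozen=True)
class StructureSimConfig:
    """Balding-Nichols structured-population settings."""

    n_pops: int = 5
    n_loci: int = 1000
    n_per_pop: int = 30
    target_F: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_F < 1.0:
            raise ValueError("target_F must be in (0, 1)")
        if min(self.n_pops, self.n_loci, self.n_per_pop) < 1:
            raise ValueError("counts must be positive")


def simulate_structured_populations(cfg: StructureSimConfig) -> GenotypeMatrix:
    """Multi-population SNP matrix with Balding-Nichols differentiation.

    Per locus an ancestral frequency p is drawn uniformly, then each
    population's frequency from Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are
    Hardy-Weinberg within populations.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_loci)
    F = cfg.target_F
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    pop_freqs = rng.beta(a[None, :], b[None, :], size=(cfg.n_pops, cfg.n_loci))

    calls = np.concatenate(
        [
            rng.binomial(2, pop_freqs[k][None, :], size=(cfg.n_per_pop, cfg.n_loci))
            for k in range(cfg.n_pops)
        ]
    ).astype(np.int8)
    samples = [
        f"P{k + 1:02d}_S{i + 1:03d}"
        for k in range(cfg.n_pops)
        for i in range(cfg.n_per_pop)
    ]
    pops = {s: s.split("_")[0] for s in samples}
    return GenotypeMatrix(
        samples=samples,
        loci=[f"snp{j + 1:05d}" for j in range(cfg.n_loci)],
        calls=calls,
        pops=pops,
    )


def simulate_wright_fisher(
    n_diploids: int = 50,
    n_loci: int = 500,
    n_generations: int = 15,
    init_freq_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
    population: str = "wf",
) -> GenotypeMatrix:
    """Unlinked-locus Wright-Fisher population for LD-Ne checks.

    A closed, randomly mating population of ``n_diploids`` is evolved for
    ``n_generations``; each offspring draws two parents uniformly and one
    gamete per parent per locus.  The final generation is returned as a
    genotype matrix; its drift-generated LD is what the effective-size
    estimator measures.
    """
    rng = np.random.default_rng(seed)
    lo, hi = init_freq_range
    p0 = rng.uniform(lo, hi, size=n_loci)
    D = rng.binomial(2, p0[None, :], size=(n_diploids, n_loci))
    for _ in range(n_generations):
        mothers = rng.integers(n_diploids, size=n_diploids)
        fathers = rng.integers(n_diploids, size=n_diploids)
        gm = rng.binomial(1, D[mothers] / 2.0)
        gf = rng.binomial(1, D[fathers] / 2.0)
        D = gm + gf
    samples = [f"{population}_S{i + 1:03d}" for i in range(n_diploids)]
    return GenotypeMatrix(
        samples=samples,
        loci=[f"snp{j + 1:05d}" for j in range(n_loci)],
        calls=D.astype(np.int8),
        pops={s: population for s in samples},
    )
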