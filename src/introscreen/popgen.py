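"""Dataset filters and diversity / divergence / effective-size estimators.

Implements the per-population machinery of a SNP-based population-genomic
baseline: locus presence and minor-allele-count filters, observed and
expected heterozygosity, nucleotide diversity (sample-size-corrected
expected heterozygosity averaged over analyzed variant sites), an exact
conditional Hardy-Weinberg test, private-allele counts, Weir & Cockerham
(1984) F_ST from variance components, Watterson's theta and Tajima's D from
the segregating-site count, and the linkage-disequilibrium (Burrows r^2)
effective-population-size estimator with the Waples sample-size correction.

A note on "per nucleotide": on SNP-only data the site denominator M is the
number of analyzed variant sites, so theta_W (and pi) are comparable only
within a dataset, not across datasets with different ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import HET, HOM_FOREIGN, HOM_NATIVE, MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# dataset filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Locus filters applied before the diversity/divergence estimators.

    min_presence
        Minimum fraction of genotyped individuals a locus needs within each
        population (inclusive: exactly the threshold passes).
    require_all_pops
        If true (default) the presence rule is enforced in every population;
        otherwise it is applied to the pooled dataset.
    min_mac
        Minimum global minor-allele count; 3 removes singletons/doubletons.
    single_snp_per_locus
        Keep only the first SNP of each parent locus (RAD-tag) when parent
        ids are available, to avoid tightly linked sites.
    """

    min_presence: float = 0.8
    require_all_pops: bool = True
    min_mac: int = 3
    single_snp_per_locus: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_presence <= 1.0:
            raise ValueError("min_presence must be in [0, 1]")
        if self.min_mac < 0:
            raise ValueError("min_mac must be >= 0")


@dataclass
class FilterReport:
    dropped_presence: list[str] = field(default_factory=list)
    dropped_mac: list[str] = field(default_factory=list)
    dropped_linked: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_presence) + len(self.dropped_mac) + len(self.dropped_linked)


def filter_dataset(
    matrix: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply presence, minor-allele-count and one-SNP-per-locus filters."""
    report = FilterReport()
    calls = matrix.calls
    observed = calls != MISSING
    pops = matrix.pop_labels()

    keep = np.ones(matrix.n_loci, dtype=bool)
    if cfg.require_all_pops:
        for pop in matrix.populations:
            rows = pops == pop
            presence = observed[rows].mean(axis=0)
            keep &= presence >= cfg.min_presence
    else:
        keep &= observed.mean(axis=0) >= cfg.min_presence
    report.dropped_presence = [matrix.loci[j] for j in np.where(~keep)[0]]

    n_called = observed.sum(axis=0)
    dosage = np.where(observed, calls, 0).sum(axis=0)
    mac = np.minimum(dosage, 2 * n_called - dosage)
    fail_mac = keep & (mac < cfg.min_mac)
    report.dropped_mac = [matrix.loci[j] for j in np.where(fail_mac)[0]]
    keep &= ~fail_mac

    if cfg.single_snp_per_locus and matrix.parent_locus is not None:
        seen: set[str] = set()
        for j in range(matrix.n_loci):
            if not keep[j]:
                continue
            pid = matrix.parent_locus[j]
            if pid in seen:
                keep[j] = False
                report.dropped_linked.append(matrix.loci[j])
            else:
                seen.add(pid)

    if not keep.any():
        raise ValueError("no loci survive the dataset filters")
    return matrix.take_loci(list(np.where(keep)[0])), report


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(matrix: GenotypeMatrix, per_population: bool = False) -> pd.DataFrame:
    """Per-locus allele frequencies and counts over non-missing calls.

    Returns one row per locus (or per population x locus) with the foreign
    (alternate) allele count/frequency, the native (reference) frequency,
    and the number of genotyped diploids.
    """

    def _one(calls: np.ndarray, label: str | None) -> pd.DataFrame:
        observed = calls != MISSING
        n_called = observed.sum(axis=0)
        dosage = np.where(observed, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ff = np.where(n_called > 0, dosage / np.maximum(2 * n_called, 1), np.nan)
        df = pd.DataFrame(
            {
                "locus": matrix.loci,
                "n_called": n_called,
                "count_foreign": dosage,
                "count_native": 2 * n_called - dosage,
                "freq_foreign": ff,
                "freq_native": 1.0 - ff,
            }
        )
        if label is not None:
            df.insert(0, "population", label)
        return df

    if not per_population:
        return _one(matrix.calls, None)
    pops = matrix.pop_labels()
    return pd.concat(
        [_one(matrix.calls[pops == p], p) for p in matrix.populations],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (two alleles).

    Conditional on the allele margins, the p-value sums the probabilities
    of all heterozygote counts no more probable than the observed one.
    Monomorphic samples return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    N = n_AA + n_Aa + n_aa
    if N < 2:
        raise ValueError("need at least two diploids")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)
    if rare == 0:
        return 1.0

    log_const = lgamma(N + 1) + lgamma(nA + 1) + lgamma(na + 1) - lgamma(2 * N + 1)

    def log_prob(h: int) -> float:
        homA = (nA - h) // 2
        homa = (na - h) // 2
        return (
            log_const
            - lgamma(homA + 1)
            - lgamma(h + 1)
            - lgamma(homa + 1)
            + h * log(2.0)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_Aa)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------


@dataclass
class PopGenStats:
    """Per-population diversity summary (Watterson/Tajima/Ne fields optional)."""

    population: str
    n: int
    P: float
    prop_polymorphic: float
    n_private: int
    pi: float
    pi_se: float
    Ho: float
    Ho_se: float
    He: float
    He_se: float
    n_hwe_out: int
    pct_hwe_out: float
    Fis: float
    Fis_se: float
    theta_w: float | None = None
    tajima_d: float | None = None
    ne: float | None = None
    ne_ci: tuple[float, float] | None = None


def _se(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def diversity_stats(matrix: GenotypeMatrix, alpha: float = 0.05) -> list[PopGenStats]:
    """Per-population heterozygosity, diversity, HWE and inbreeding summary.

    Averages are taken over the dataset's analyzed loci; pi applies the
    2n/(2n-1) small-sample correction to expected heterozygosity; Fis is
    the per-locus 1 - Ho/He averaged over loci polymorphic within the
    population; HWE uses the exact conditional test at level ``alpha``
    with the out-of-HWE percentage reported against all analyzed loci.
    """
    pops_arr = matrix.pop_labels()
    pop_names = matrix.populations
    private = _private_allele_counts(matrix)

    out = []
    for pop in pop_names:
        calls = matrix.calls[pops_arr == pop]
        n_ind = calls.shape[0]
        if n_ind < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        observed = calls != MISSING
        n_called = observed.sum(axis=0)
        dosage = np.where(observed, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, dosage / np.maximum(2 * n_called, 1), np.nan)
            ho = np.where(
                n_called > 0,
                np.where(observed, calls == HET, False).sum(axis=0) / np.maximum(n_called, 1),
                np.nan,
            )
        q = 1.0 - p
        he = 2.0 * p * q
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (2.0 * n_called) / np.maximum(2.0 * n_called - 1.0, 1.0)
        pi = he * corr
        maj = np.maximum(p, q)
        poly = (p > 0) & (p < 1) & (n_called > 0)

        # Fis over loci polymorphic within this population
        with np.errstate(invalid="ignore", divide="ignore"):
            fis = np.where(he > 0, 1.0 - ho / np.where(he > 0, he, 1.0), np.nan)

        # exact HWE over polymorphic loci
        n_out = 0
        for j in np.where(poly)[0]:
            col = calls[observed[:, j], j]
            counts = np.bincount(col, minlength=3)
            if hwe_exact(int(counts[0]), int(counts[1]), int(counts[2])) < alpha:
                n_out += 1

        n_loci = matrix.n_loci
        out.append(
            PopGenStats(
                population=pop,
                n=n_ind,
                P=float(np.nanmean(maj)),
                prop_polymorphic=float(poly.sum() / n_loci),
                n_private=private.get(pop, 0),
                pi=float(np.nanmean(pi)),
                pi_se=_se(pi),
                Ho=float(np.nanmean(ho)),
                Ho_se=_se(ho),
                He=float(np.nanmean(he)),
                He_se=_se(he),
                n_hwe_out=n_out,
                pct_hwe_out=100.0 * n_out / n_loci,
                Fis=float(np.nanmean(fis)) if np.isfinite(fis).any() else float("nan"),
                Fis_se=_se(fis),
            )
        )
    return out


def _private_allele_counts(matrix: GenotypeMatrix) -> dict[str, int]:
    """Alleles observed in exactly one population, counted per population."""
    pops_arr = matrix.pop_labels()
    pop_names = matrix.populations
    presence = {}  # pop -> (has_native, has_foreign) boolean arrays per locus
    for pop in pop_names:
        calls = matrix.calls[pops_arr == pop]
        observed = calls != MISSING
        dosage = np.where(observed, calls, 0)
        n_called = observed.sum(axis=0)
        has_foreign = dosage.sum(axis=0) > 0
        has_native = (2 * n_called - dosage.sum(axis=0)) > 0
        presence[pop] = (has_native, has_foreign)
    counts = {pop: 0 for pop in pop_names}
    for allele_idx in (0, 1):
        carrier = np.stack([presence[pop][allele_idx] for pop in pop_names])
        n_carriers = carrier.sum(axis=0)
        for i, pop in enumerate(pop_names):
            counts[pop] += int((carrier[i] & (n_carriers == 1)).sum())
    return counts


def stats_frame(stats: Sequence[PopGenStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        d = dict(s.__dict__)
        ci = d.pop("ne_ci")
        d["ne_ci_low"] = None if ci is None else ci[0]
        d["ne_ci_high"] = None if ci is None else ci[1]
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Watterson's theta and Tajima's D
# ---------------------------------------------------------------------------


def harmonic(k_minus_1: int, power: int = 1) -> float:
    """Sum of 1/i**power for i = 1 .. k-1."""
    i = np.arange(1, k_minus_1 + 1, dtype=float)
    return float((1.0 / i**power).sum())


def watterson_theta(S: int, k: int, M: int) -> float:
    """Watterson's estimator per analyzed site: S / (a1 * M) with k sequences."""
    if k < 2 or M < 1:
        raise ValueError("need k >= 2 sequences and M >= 1 sites")
    if S == 0:
        return 0.0
    return S / (harmonic(k - 1) * M)


def tajimas_d(k: int, S: int, pi_total: float) -> float:
    """Tajima's D from k sequences, S segregating sites, total pairwise diversity."""
    if k < 2:
        raise ValueError("need at least 2 sequences")
    if S == 0:
        return float("nan")
    a1 = harmonic(k - 1)
    a2 = harmonic(k - 1, power=2)
    b1 = (k + 1) / (3.0 * (k - 1))
    b2 = 2.0 * (k * k + k + 3) / (9.0 * k * (k - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (k + 2) / (a1 * k) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = pi_total - S / a1
    if num == 0.0:
        return 0.0
    return float(num / np.sqrt(var))


def watterson_tajima(matrix: GenotypeMatrix, population: str) -> tuple[float, float]:
    """Within-population Watterson's theta (per analyzed site) and Tajima's D.

    Uses k = 2n sequences (n diploids in the population), S = loci
    segregating within the population, and M = loci analyzed.  Pairwise
    diversity per locus is the unbiased 2*p*q * 2n/(2n-1) with the locus's
    genotyped sample size.
    """
    sub = matrix.subset_population(population)
    observed = sub.calls != MISSING
    n_called = observed.sum(axis=0)
    dosage = np.where(observed, sub.calls, 0).sum(axis=0)
    usable = n_called > 0
    if not usable.any():
        raise ValueError(f"population {population!r} has no genotyped loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage[usable] / (2.0 * n_called[usable])
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    M = int(usable.sum())
    k = 2 * sub.n_samples
    theta = watterson_theta(S, k, M)
    if S == 0:
        return theta, float("nan")
    nk = 2.0 * n_called[usable]
    pi_total = float((2.0 * p * (1.0 - p) * nk / (nk - 1.0)).sum())
    return theta, tajimas_d(k, S, pi_total)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus variance components a, b, c.

    Parameters are arrays of shape (r_pops, L): per-population sample sizes
    (diploids genotyped), allele frequencies, and observed heterozygote
    proportions.  Returns the among-population (a), among-individual (b)
    and within-individual (c) components per locus.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / nsum

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
    c = hbar / 2.0
    return a, b, c


def wc_fst(
    matrix: GenotypeMatrix, populations: Sequence[str] | None = None
) -> tuple[float, pd.DataFrame]:
    """Multi-locus Weir-Cockerham theta for a set of populations.

    The estimate is the ratio of sums sum(a) / sum(a + b + c) over loci
    with a non-zero denominator; per-locus components are returned for
    inspection.  Loci without at least two genotyped diploids in every
    population are skipped.
    """
    pops = populations if populations is not None else matrix.populations
    if len(pops) < 2:
        raise ValueError("F_ST needs at least two populations")
    labels = matrix.pop_labels()
    n_list, p_list, h_list = [], [], []
    for pop in pops:
        calls = matrix.calls[labels == pop]
        if calls.shape[0] == 0:
            raise ValueError(f"population {pop!r} not present in matrix")
        observed = calls != MISSING
        n_called = observed.sum(axis=0)
        dosage = np.where(observed, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, dosage / np.maximum(2.0 * n_called, 1.0), np.nan)
            het = np.where(
                n_called > 0,
                np.where(observed, calls == HET, False).sum(axis=0)
                / np.maximum(n_called, 1.0),
                np.nan,
            )
        n_list.append(n_called)
        p_list.append(p)
        h_list.append(het)
    n = np.stack(n_list)
    p = np.stack(p_list)
    h = np.stack(h_list)

    usable = (n >= 2).all(axis=0)
    if not usable.any():
        raise ValueError("no locus is genotyped in >= 2 diploids in every population")
    a, b, c = wc_components(n[:, usable], p[:, usable], h[:, usable])
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        raise ValueError("all loci have zero total variance; F_ST undefined")
    theta = float(a[ok].sum() / denom[ok].sum())
    per_locus = pd.DataFrame(
        {
            "locus": [matrix.loci[j] for j in np.where(usable)[0]],
            "a": a,
            "b": b,
            "c": c,
        }
    )
    return theta, per_locus


def fst_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric pairwise Weir-Cockerham theta matrix (diagonal 0)."""
    pops = matrix.populations
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            theta, _ = wc_fst(matrix, [p1, p2])
            out.loc[p1, p2] = out.loc[p2, p1] = theta
    return out


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeEstimate:
    population: str
    ne: float  # may be inf
    ci_low: float
    ci_high: float
    r2: float
    r2_drift: float
    n_loci: int
    n_pairs: int
    S: int


def ne_from_r2_drift(r2_drift: float) -> float:
    """Random-mating LD relation inverted for Ne (Waples 2006 large-S form)."""
    if r2_drift <= 0:
        return float("inf")
    disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_drift)


def expected_sample_r2(S: int) -> float:
    """Expected squared correlation from finite sampling alone."""
    if S < 2:
        raise ValueError("need at least two sampled individuals")
    return 1.0 / S + 3.19 / S**2


def ld_ne(
    matrix: GenotypeMatrix,
    population: str,
    maf_threshold: float = 0.05,
    alpha: float = 0.05,
) -> NeEstimate:
    """LD effective population size from mean squared genotypic correlation.

    r^2 is the squared Pearson correlation of genotype dosages (the Burrows
    composite measure) over all pairs of loci passing the minor-allele-
    frequency threshold; pairs of SNPs sharing a parent locus are skipped as
    potentially physically linked.  The drift component
    ``r2_drift = r2 - (1/S + 3.19/S^2)`` is inverted for Ne under random
    mating; a non-positive drift component yields an infinite estimate.
    The confidence interval is the parametric chi-square interval on the
    mean r^2, with the pair count as the degrees of freedom.
    """
    sub = matrix.subset_population(population)
    S = sub.n_samples
    if S < 2:
        raise ValueError("need at least two sampled individuals")
    D = np.where(sub.calls == MISSING, np.nan, sub.calls).astype(float)
    with np.errstate(invalid="ignore"):
        n_called = (~np.isnan(D)).sum(axis=0)
        mean_d = np.nanmean(D, axis=0)
    freq = mean_d / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = (n_called >= 2) & (maf >= maf_threshold) & (np.nanstd(D, axis=0) > 0)
    idx = np.where(keep)[0]
    if idx.size < 2:
        raise ValueError(
            f"population {population!r}: fewer than 2 loci pass the MAF threshold"
        )
    Dk = D[:, idx]
    parent = (
        None
        if matrix.parent_locus is None
        else [matrix.parent_locus[j] for j in idx]
    )

    if np.isnan(Dk).any():
        corr = pd.DataFrame(Dk).corr(min_periods=2).to_numpy()
    else:
        corr = np.corrcoef(Dk.T)
    iu, ju = np.triu_indices(idx.size, k=1)
    r2_pairs = corr[iu, ju] ** 2
    if parent is not None:
        parr = np.array(parent, dtype=object)
        unlinked = parr[iu] != parr[ju]
        r2_pairs = r2_pairs[unlinked]
    r2_pairs = r2_pairs[np.isfinite(r2_pairs)]
    if r2_pairs.size == 0:
        raise ValueError("no unlinked locus pairs available")

    r2 = float(r2_pairs.mean())
    exp_r2 = expected_sample_r2(S)
    r2_drift = r2 - exp_r2
    ne = ne_from_r2_drift(r2_drift)

    df = r2_pairs.size
    lo_r2 = r2 * df / sps.chi2.ppf(1.0 - alpha / 2.0, df)
    hi_r2 = r2 * df / sps.chi2.ppf(alpha / 2.0, df)
    ci_high = ne_from_r2_drift(lo_r2 - exp_r2)
    ci_low = ne_from_r2_drift(hi_r2 - exp_r2)
    return NeEstimate(
        population=population,
        ne=float(ne),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        r2=r2,
        r2_drift=float(r2_drift),
        n_loci=int(idx.size),
        n_pairs=int(df),
        S=S,
    )


def full_stats(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    maf_threshold: float = 0.05,
    with_ne: bool = True,
) -> list[PopGenStats]:
    """Diversity stats augmented with Watterson/Tajima and (optionally) Ne."""
    stats = diversity_stats(matrix, alpha=alpha)
    for s in stats:
        theta, d = watterson_tajima(matrix, s.population)
        s.theta_w = theta
        s.tajima_d = d
        if with_ne:
            try:
                est = ld_ne(matrix, s.population, maf_threshold=maf_threshold)
                s.ne = est.ne
                s.ne_ci = (est.ci_low, est.ci_high)
            except ValueError:
                s.ne = None
                s.ne_ci = None
    return stats
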