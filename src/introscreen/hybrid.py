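"""Six-class Bayesian hybrid-category classifier for two hybridizing species.

The model follows the genotype-frequency-class formulation used for
first-generation hybrid screens: each individual belongs to one of six
classes — pure native (LMB), pure foreign (FB), F1, F2, and the two first
backcrosses (LMB_Bx, FB_Bx) — and each class is characterized by the
probabilities ``phi = (phi_AA, phi_AB, phi_BB)`` that, at any locus, the
individual's two gene copies both descend from species A, one from each
species, or both from species B.  Given per-locus native-allele frequencies
``p_A`` and ``p_B`` in the two parental gene pools, the genotype
probabilities at a locus are the phi-mixture of the three corresponding
Hardy-Weinberg laws.

Two inference routes are provided:

* :func:`posterior_fixed` — exact class posteriors when the parental allele
  frequencies are known (e.g. a strictly diagnostic panel), by direct
  evaluation of the likelihood product;
* :func:`gibbs_classify` — Gibbs sampling over latent classes, per-gene-copy
  origins, and parental frequencies (Beta priors), for the realistic case
  where parental frequencies must be learned from the sample itself.

Assignment uses the >80% posterior rule: an individual whose top class
exceeds the threshold gets that single label, otherwise it is reported with
a dual "TOP/SECOND" label naming the two most probable classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix import HET, HOM_FOREIGN, HOM_NATIVE, MISSING, GenotypeMatrix

#: Class names in canonical order.
CLASSES: tuple[str, ...] = ("LMB", "FB", "F1", "F2", "FB_Bx", "LMB_Bx")

#: Gene-copy-origin probabilities (phi_AA, phi_AB, phi_BB) per class.
PHI = np.array(
    [
        [1.0, 0.0, 0.0],  # LMB: both copies from species A
        [0.0, 0.0, 1.0],  # FB: both copies from species B
        [0.0, 1.0, 0.0],  # F1: one copy from each
        [0.25, 0.5, 0.25],  # F2
        [0.0, 0.5, 0.5],  # FB_Bx: F1 x pure foreign
        [0.5, 0.5, 0.0],  # LMB_Bx: F1 x pure native
    ]
)

_CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}


@dataclass(frozen=True)
class ParentalFrequencies:
    """Per-locus native-allele frequencies in species A and species B."""

    p_native_in_A: np.ndarray
    p_native_in_B: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.p_native_in_A, dtype=float)
        b = np.asarray(self.p_native_in_B, dtype=float)
        object.__setattr__(self, "p_native_in_A", a)
        object.__setattr__(self, "p_native_in_B", b)
        if a.shape != b.shape:
            raise ValueError("frequency vectors must share a length")
        for v in (a, b):
            if ((v < 0) | (v > 1)).any():
                raise ValueError("frequencies must lie in [0, 1]")

    @classmethod
    def diagnostic(cls, n_loci: int) -> "ParentalFrequencies":
        """Strictly diagnostic panel: native allele fixed in A, absent in B."""
        return cls(np.ones(n_loci), np.zeros(n_loci))


def genotype_probabilities(p_A: np.ndarray, p_B: np.ndarray) -> np.ndarray:
    """Genotype probabilities per class: array of shape (6, L, 3).

    The last axis indexes foreign-allele dosage (0: hom-native, 1: het,
    2: hom-foreign).  For every class and locus the three probabilities
    sum to 1.
    """
    p_A = np.atleast_1d(np.asarray(p_A, dtype=float))
    p_B = np.atleast_1d(np.asarray(p_B, dtype=float))
    q_A, q_B = 1.0 - p_A, 1.0 - p_B
    # P(g | origin pair w), shape (3 origins, L, 3 genotypes)
    per_origin = np.stack(
        [
            np.stack([p_A * p_A, 2 * p_A * q_A, q_A * q_A], axis=-1),
            np.stack([p_A * p_B, p_A * q_B + q_A * p_B, q_A * q_B], axis=-1),
            np.stack([p_B * p_B, 2 * p_B * q_B, q_B * q_B], axis=-1),
        ]
    )
    return np.einsum("cw,wlg->clg", PHI, per_origin)


def class_likelihood(call: int, p_A: float, p_B: float, cls: str) -> float:
    """Likelihood of one genotype call under one hybrid class."""
    if call == MISSING:
        raise ValueError("cannot evaluate the likelihood of a missing call")
    probs = genotype_probabilities(np.array([p_A]), np.array([p_B]))
    return float(probs[_CLASS_INDEX[cls], 0, call])


@dataclass(frozen=True)
class ClassPosterior:
    sample_id: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior for {self.sample_id!r} sums to {total}")

    def top_two(self) -> tuple[tuple[str, float], tuple[str, float]]:
        ranked = sorted(self.probs.items(), key=lambda kv: -kv[1])
        return ranked[0], ranked[1]


@dataclass(frozen=True)
class ClassificationLabel:
    sample_id: str
    label: str
    top_prob: float
    second_prob: float


def classify_posterior(post: ClassPosterior, threshold: float = 0.8) -> ClassificationLabel:
    """Assign a single or dual class label from a posterior.

    The single label requires strictly more than ``threshold`` posterior
    probability; at or below it the two highest classes are reported as
    "TOP/SECOND".
    """
    (top, p1), (second, p2) = post.top_two()
    if p1 > threshold:
        label = top
    else:
        label = f"{top}/{second}"
    return ClassificationLabel(post.sample_id, label, p1, p2)


def posterior_fixed(
    calls: Sequence[int] | np.ndarray,
    freqs: ParentalFrequencies,
    prior: Mapping[str, float] | None = None,
    sample_id: str = "",
) -> ClassPosterior:
    """Exact class posterior for known parental allele frequencies.

    posterior(z) is proportional to prior(z) times the product over loci of
    the genotype likelihood under class z.  Classes with zero likelihood
    get exactly zero posterior mass.
    """
    calls = np.asarray(calls)
    if (calls == MISSING).any():
        raise ValueError("missing calls are not allowed; filter first")
    L = calls.size
    if freqs.p_native_in_A.size != L:
        raise ValueError("frequency vectors do not match the number of calls")
    probs = genotype_probabilities(freqs.p_native_in_A, freqs.p_native_in_B)
    with np.errstate(divide="ignore"):
        loglik = np.log(probs[:, np.arange(L), calls]).sum(axis=1)
    log_prior = _log_prior(prior)
    logpost = loglik + log_prior
    if np.all(np.isneginf(logpost)):
        raise ValueError(
            f"genotypes of {sample_id!r} are impossible under every class"
        )
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    return ClassPosterior(sample_id, {c: float(w[i]) for i, c in enumerate(CLASSES)})


def _log_prior(prior: Mapping[str, float] | None) -> np.ndarray:
    if prior is None:
        return np.zeros(len(CLASSES))
    vec = np.array([prior.get(c, 0.0) for c in CLASSES], dtype=float)
    if (vec < 0).any() or vec.sum() <= 0:
        raise ValueError("class prior must be non-negative with positive mass")
    vec = vec / vec.sum()
    with np.errstate(divide="ignore"):
        return np.log(vec)


@dataclass(frozen=True)
class MCMCConfig:
    """Gibbs-sampler settings.

    burn_in, sweeps
        Discarded and retained sweeps per run (defaults 10,000 each).
    runs
        Independent chains; posteriors are averaged across runs and the
        across-run standard deviation is reported as a convergence
        diagnostic (classes with SD > ``sd_flag`` are flagged).
    allele_freq_prior
        Beta prior on every parental allele frequency (Jeffreys by default).
    """

    burn_in: int = 10_000
    sweeps: int = 10_000
    runs: int = 6
    seed: int = 0
    allele_freq_prior: tuple[float, float] = (0.5, 0.5)
    sd_flag: float = 0.05

    def __post_init__(self) -> None:
        if min(self.burn_in, self.sweeps, self.runs) < 1:
            raise ValueError("burn_in, sweeps and runs must all be >= 1")
        if min(self.allele_freq_prior) <= 0:
            raise ValueError("Beta prior parameters must be positive")


@dataclass
class GibbsResult:
    posteriors: list[ClassPosterior]
    run_sd: np.ndarray  # (n_samples, 6) across-run posterior SD
    flagged: dict[str, list[str]] = field(default_factory=dict)
    classes: tuple[str, ...] = CLASSES

    def labels(self, threshold: float = 0.8) -> list[ClassificationLabel]:
        return [classify_posterior(p, threshold) for p in self.posteriors]


def gibbs_classify(
    matrix: GenotypeMatrix,
    cfg: MCMCConfig = MCMCConfig(),
    known_origin: Mapping[str, str] | None = None,
    fixed_frequencies: ParentalFrequencies | None = None,
    prior: Mapping[str, float] | None = None,
) -> GibbsResult:
    """Classify every individual by Gibbs sampling over the six classes.

    Each sweep (i) samples, per individual and locus, the latent
    gene-copy-origin pair given the current class and frequencies,
    (ii) redraws the parental allele frequencies from their Beta posteriors
    given the origin-attributed allele counts, and (iii) redraws each
    individual's class from its conditional posterior.  Samples listed in
    ``known_origin`` (values "A" or "B") are pinned to the corresponding
    pure class and contribute to the frequency updates only.  When
    ``fixed_frequencies`` is given, steps (i)-(ii) are skipped and the
    frequencies stay pinned (the chain then samples the closed-form
    posterior directly).

    Orientation of the two species labels is broken deterministically by
    initializing classes under the diagnostic assumption that species A is
    (nearly) fixed for the native allele — the same polarity the panel
    defines.
    """
    G = matrix.calls.astype(np.int64)
    n, L = G.shape
    if n < 2:
        raise ValueError("need at least two samples")
    observed = G != MISSING
    if not observed.any(axis=1).all():
        bad = [matrix.samples[i] for i in np.where(~observed.any(axis=1))[0]]
        raise ValueError("samples with no genotyped loci: " + ", ".join(bad))
    Gc = np.where(observed, G, 0)

    pinned = np.full(n, -1, dtype=np.int64)
    if known_origin:
        for s, sp in known_origin.items():
            if sp not in ("A", "B"):
                raise ValueError(f"known origin for {s!r} must be 'A' or 'B'")
            pinned[matrix.sample_index(s)] = _CLASS_INDEX["LMB" if sp == "A" else "FB"]
    free = pinned < 0

    log_prior = _log_prior(prior)
    a0, b0 = cfg.allele_freq_prior
    rows = np.arange(n)

    post_runs = np.zeros((cfg.runs, n, len(CLASSES)))
    for run in range(cfg.runs):
        rng = np.random.default_rng([cfg.seed, run])
        if fixed_frequencies is not None:
            pA = np.clip(fixed_frequencies.p_native_in_A, 0.0, 1.0).copy()
            pB = np.clip(fixed_frequencies.p_native_in_B, 0.0, 1.0).copy()
        else:
            pA = np.full(L, 1.0 - 1e-3)
            pB = np.full(L, 1e-3)
        z = _sample_classes(rng, Gc, observed, pA, pB, log_prior, pinned)
        counts = np.zeros((n, len(CLASSES)))
        for sweep in range(cfg.burn_in + cfg.sweeps):
            if fixed_frequencies is None:
                pA, pB = _update_frequencies(rng, Gc, observed, z, pA, pB, a0, b0)
            z = _sample_classes(rng, Gc, observed, pA, pB, log_prior, pinned)
            if sweep >= cfg.burn_in:
                counts[rows, z] += 1
        post_runs[run] = counts / cfg.sweeps

    mean_post = post_runs.mean(axis=0)
    run_sd = post_runs.std(axis=0, ddof=0)
    posteriors = []
    flagged: dict[str, list[str]] = {}
    for i, s in enumerate(matrix.samples):
        p = mean_post[i] / mean_post[i].sum()
        posteriors.append(ClassPosterior(s, {c: float(p[j]) for j, c in enumerate(CLASSES)}))
        hot = [CLASSES[j] for j in range(len(CLASSES)) if run_sd[i, j] > cfg.sd_flag]
        if hot:
            flagged[s] = hot
    return GibbsResult(posteriors=posteriors, run_sd=run_sd, flagged=flagged)


def _sample_classes(rng, Gc, observed, pA, pB, log_prior, pinned):
    """Draw each free individual's class from its conditional posterior."""
    probs = genotype_probabilities(pA, pB)  # (6, L, 3)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    L = Gc.shape[1]
    cell = logp[:, np.arange(L)[None, :], Gc]  # (6, n, L)
    cell = np.where(observed[None, :, :], cell, 0.0)
    ll = cell.sum(axis=2).T + log_prior  # (n, 6)
    mx = ll.max(axis=1, keepdims=True)
    if np.isneginf(mx).any():
        raise ValueError("non-finite likelihood: some individual fits no class")
    w = np.exp(ll - mx)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(w.shape[0])
    z = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
    z = np.minimum(z, len(CLASSES) - 1)
    z[pinned >= 0] = pinned[pinned >= 0]
    return z


def _update_frequencies(rng, Gc, observed, z, pA, pB, a0, b0):
    """Sample origin pairs per cell, then redraw frequencies from Betas."""
    n, L = Gc.shape
    qA, qB = 1.0 - pA, 1.0 - pB
    # P(g | origin pair w): (3, L, 3)
    T = np.stack(
        [
            np.stack([pA * pA, 2 * pA * qA, qA * qA], axis=-1),
            np.stack([pA * pB, pA * qB + qA * pB, qA * qB], axis=-1),
            np.stack([pB * pB, 2 * pB * qB, qB * qB], axis=-1),
        ]
    )
    cell = T[:, np.arange(L)[None, :], Gc]  # (3, n, L)
    weights = PHI[z].T[:, :, None] * cell  # (3, n, L)
    tot = weights.sum(axis=0)
    # cells with zero total weight (impossible genotype) should not occur for
    # a freshly sampled z, but guard against numerical underflow
    tot = np.where(tot > 0, tot, 1.0)
    weights = weights / tot
    u = rng.random((n, L))
    worig = (np.cumsum(weights, axis=0)[:2] < u[None, :, :]).sum(axis=0)  # (n, L) in {0,1,2}
    worig = np.where(observed, worig, -1)

    # heterozygote with mixed origin: which species contributed the native copy
    het_mixed = (worig == 1) & (Gc == 1) & observed
    pnatA = pA * qB
    pnatB = qA * pB
    denom = pnatA + pnatB
    denom = np.where(denom > 0, denom, 1.0)
    bern = rng.random((n, L)) < (pnatA / denom)[None, :]

    g = Gc
    natA = ((worig == 0) * (2 - g) + ((worig == 1) & (g == 0)) + (het_mixed & bern)).astype(float)
    forA = ((worig == 0) * g + ((worig == 1) & (g == 2)) + (het_mixed & ~bern)).astype(float)
    natB = ((worig == 2) * (2 - g) + ((worig == 1) & (g == 0)) + (het_mixed & ~bern)).astype(float)
    forB = ((worig == 2) * g + ((worig == 1) & (g == 2)) + (het_mixed & bern)).astype(float)
    obs = observed.astype(float)
    natA_l = (natA * obs).sum(axis=0)
    forA_l = (forA * obs).sum(axis=0)
    natB_l = (natB * obs).sum(axis=0)
    forB_l = (forB * obs).sum(axis=0)

    newA = rng.beta(a0 + natA_l, b0 + forA_l)
    newB = rng.beta(a0 + natB_l, b0 + forB_l)
    eps = 1e-12
    return np.clip(newA, eps, 1 - eps), np.clip(newB, eps, 1 - eps)
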