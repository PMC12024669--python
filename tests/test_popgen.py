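"""Filters, diversity estimators, HWE, Weir-Cockerham F_ST, Tajima, LD-Ne.

The F_ST, HWE and Tajima checks run against independent oracles written
here from first principles (scalar arithmetic, exact fractions, full
enumeration) rather than against the vectorized implementations.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from introscreen.matrix import HET, HOM_FOREIGN, HOM_NATIVE, MISSING
from introscreen.popgen import (
    FilterConfig,
    allele_frequencies,
    diversity_stats,
    expected_sample_r2,
    filter_dataset,
    fst_matrix,
    hwe_exact,
    ld_ne,
    ne_from_r2_drift,
    tajimas_d,
    watterson_tajima,
    watterson_theta,
    wc_fst,
)

from conftest import make_matrix

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-fraction enumeration over all heterozygote counts."""
    N = n_AA + n_Aa + n_aa
    nA, na = 2 * n_AA + n_Aa, 2 * n_aa + n_Aa
    rare = min(nA, na)
    if rare == 0:
        return 1.0
    f = math.factorial
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        homA, homa = (nA - h) // 2, (na - h) // 2
        probs[h] = Fraction(
            f(N) * 2**h * f(nA) * f(na), f(homA) * f(h) * f(homa) * f(2 * N)
        )
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def wc_theta_oracle(calls, pop_sizes):
    """Scalar re-derivation of the 1984 variance components from raw calls."""
    r = len(pop_sizes)
    bounds = np.cumsum([0] + list(pop_sizes))
    sum_a = sum_all = 0.0
    for locus in range(calls.shape[1]):
        n, p, h = [], [], []
        for k in range(r):
            col = calls[bounds[k]:bounds[k + 1], locus]
            col = col[col != MISSING]
            if col.size < 2:
                break
            n.append(col.size)
            p.append(float((col == 2).sum() * 2 + (col == 1).sum()) / (2 * col.size))
            h.append(float((col == 1).sum()) / col.size)
        else:
            nsum = sum(n)
            nbar = nsum / r
            nc = (nsum - sum(x * x for x in n) / nsum) / (r - 1)
            pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
            s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
            hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            if a + b + c != 0:
                sum_a += a
                sum_all += a + b + c
    return sum_a / sum_all


def tajima_oracle(k, S, pi_total):
    """Tajima's D evaluated with exact-fraction constants."""
    a1 = sum(Fraction(1, i) for i in range(1, k))
    a2 = sum(Fraction(1, i * i) for i in range(1, k))
    b1 = Fraction(k + 1, 3 * (k - 1))
    b2 = Fraction(2 * (k * k + k + 3), 9 * k * (k - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(k + 2) / (a1 * k) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / float(a1)) / math.sqrt(
        float(e1) * S + float(e2) * S * (S - 1)
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


class TestFilterDataset:
    def test_presence_boundary_inclusive(self):
        # pop of 100: locus 1 typed in 79 -> dropped, locus 2 in 80 -> kept
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[:50, :] = HET  # keep both loci polymorphic
        calls[79:, 0] = MISSING
        calls[80:, 1] = MISSING
        m = make_matrix(calls)
        out, report = filter_dataset(m, FilterConfig(min_mac=0))
        assert out.loci == ["L002"]
        assert report.dropped_presence == ["L001"]

    def test_minor_allele_count_boundary(self):
        calls = np.zeros((30, 2), dtype=np.int8)
        calls[0, 0] = HET
        calls[1, 0] = HET  # mac 2 -> dropped
        calls[0, 1] = HET
        calls[1, 1] = HOM_FOREIGN  # mac 3 -> kept
        out, report = filter_dataset(make_matrix(calls), FilterConfig())
        assert out.loci == ["L002"]
        assert report.dropped_mac == ["L001"]

    def test_single_snp_per_parent_locus(self):
        calls = np.tile([[0], [1], [2], [1]], (1, 3)).astype(np.int8)
        m = make_matrix(calls, parent_locus=["tag1", "tag1", "tag2"])
        out, report = filter_dataset(m, FilterConfig(min_mac=0))
        assert out.loci == ["L001", "L003"]
        assert report.dropped_linked == ["L002"]

    def test_presence_and_mac_commute(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            calls = rng.choice([-1, 0, 1, 2], size=(40, 25), p=[0.2, 0.4, 0.2, 0.2])
            m = make_matrix(calls, pops=["a"] * 20 + ["b"] * 20)
            only_presence = FilterConfig(min_presence=0.8, min_mac=0)
            only_mac = FilterConfig(min_presence=0.0, min_mac=3)
            try:
                ab, _ = filter_dataset(filter_dataset(m, only_presence)[0], only_mac)
                ba, _ = filter_dataset(filter_dataset(m, only_mac)[0], only_presence)
            except ValueError:
                continue
            assert ab.loci == ba.loci

    def test_nothing_left_is_error(self):
        calls = np.full((10, 1), MISSING, dtype=np.int8)
        calls[0] = 0
        with pytest.raises(ValueError, match="survive"):
            filter_dataset(make_matrix(calls), FilterConfig())


class TestAlleleFrequencies:
    def test_counting(self):
        calls = np.array([[HET]] * 3 + [[HOM_NATIVE]] * 7)
        df = allele_frequencies(make_matrix(calls))
        assert df.loc[0, "freq_foreign"] == pytest.approx(0.15)
        assert df.loc[0, "count_foreign"] == 3

    def test_monomorphic_and_absent(self):
        calls = np.array([[0, -1], [0, -1], [0, 0]], dtype=np.int8)
        m = make_matrix(calls, pops=["a", "a", "b"])
        df = allele_frequencies(m, per_population=True)
        a = df[df["population"] == "a"].set_index("locus")
        assert a.loc["L001", "freq_foreign"] == 0.0
        assert a.loc["L002", "n_called"] == 0
        assert np.isnan(a.loc["L002", "freq_foreign"])


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


class TestDiversityStats:
    def test_pi_with_small_sample_correction(self):
        calls = np.array([[HOM_NATIVE]] * 5 + [[HOM_FOREIGN]] * 5)
        s = diversity_stats(make_matrix(calls))[0]
        assert s.Ho == 0.0
        assert s.He == pytest.approx(0.5)
        assert s.pi == pytest.approx(0.5 * 20 / 19)
        assert s.Fis == pytest.approx(1.0)

    def test_all_het_gives_negative_fis(self):
        calls = np.array([[HET]] * 6)
        s = diversity_stats(make_matrix(calls))[0]
        assert s.Ho == 1.0
        assert s.Fis == pytest.approx(-1.0)

    def test_private_alleles(self):
        # foreign allele appears only in pop a at locus 1; both alleles of
        # locus 2 are shared
        calls = np.array(
            [[HET, HET], [HOM_NATIVE, HOM_NATIVE],
             [HOM_NATIVE, HET], [HOM_NATIVE, HOM_NATIVE],
             [HOM_NATIVE, HET], [HOM_NATIVE, HOM_NATIVE]],
            dtype=np.int8,
        )
        m = make_matrix(calls, pops=["a", "a", "b", "b", "c", "c"])
        stats = {s.population: s for s in diversity_stats(m)}
        assert stats["a"].n_private == 1
        assert stats["b"].n_private == 0

    def test_fis_sign_tracks_het_deficit(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            counts = rng.integers(0, 8, size=3)
            if counts.sum() < 2 or counts[1] == counts.sum():
                continue
            calls = np.repeat([[0], [1], [2]], counts, axis=0).astype(np.int8)
            m = make_matrix(calls)
            s = diversity_stats(m)[0]
            if np.isnan(s.Fis):
                continue
            assert (s.He >= s.Ho) == (s.Fis >= 0) or s.He == pytest.approx(s.Ho)

    def test_hwe_counts(self):
        # (5,0,5) is far out of HWE at alpha 0.05; a balanced locus is not
        calls = np.array(
            [[HOM_NATIVE, HOM_NATIVE]] * 5 + [[HOM_FOREIGN, HET]] * 5, dtype=np.int8
        )
        s = diversity_stats(make_matrix(calls))[0]
        assert s.n_hwe_out == 1
        assert s.pct_hwe_out == pytest.approx(50.0)


class TestHWEExact:
    def test_five_five_split(self):
        assert hwe_exact(5, 0, 5) == pytest.approx(252 / 184756, rel=1e-12)

    def test_monomorphic(self):
        assert hwe_exact(10, 0, 0) == 1.0

    def test_all_het_matches_enumeration(self):
        assert hwe_exact(0, 10, 0) == pytest.approx(hwe_oracle(0, 10, 0), rel=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_counts_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_AA, n_Aa, n_aa = rng.integers(0, 25, size=3)
        if n_AA + n_Aa + n_aa < 2:
            n_AA += 2
        assert hwe_exact(int(n_AA), int(n_Aa), int(n_aa)) == pytest.approx(
            hwe_oracle(int(n_AA), int(n_Aa), int(n_aa)), rel=1e-9
        )


# ---------------------------------------------------------------------------
# Watterson / Tajima
# ---------------------------------------------------------------------------


class TestWattersonTajima:
    def test_theta_hand_value(self):
        a19 = sum(1.0 / i for i in range(1, 20))
        assert watterson_theta(3, 20, 3) == pytest.approx(3 / (a19 * 3), rel=1e-12)
        assert watterson_theta(3, 20, 3) == pytest.approx(0.2818, abs=2e-4)

    def test_d_matches_fraction_oracle(self):
        assert tajimas_d(4, 2, 1.5) == pytest.approx(tajima_oracle(4, 2, 1.5), rel=1e-12)
        assert tajimas_d(4, 2, 1.5) == pytest.approx(3.19, abs=0.01)

    def test_d_zero_when_estimators_agree(self):
        k, S = 10, 4
        a1 = sum(1.0 / i for i in range(1, k))
        assert tajimas_d(k, S, S / a1) == 0.0

    def test_matrix_level(self):
        # one pop, 10 diploids, 3 loci all segregating
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(10, 3)).astype(np.int8)
        m = make_matrix(calls)
        theta, d = watterson_tajima(m, "pop1")
        S = sum(1 for j in range(3) if 0 < calls[:, j].mean() / 2 < 1)
        assert theta == pytest.approx(watterson_theta(S, 20, 3))
        assert np.isfinite(d)

    def test_no_segregation(self):
        m = make_matrix(np.zeros((5, 4)))
        theta, d = watterson_tajima(m, "pop1")
        assert theta == 0.0
        assert np.isnan(d)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


class TestWCFst:
    def test_fixed_difference_gives_one(self):
        calls = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        m = make_matrix(calls, pops=["a"] * 10 + ["b"] * 10)
        theta, _ = wc_fst(m)
        assert theta == pytest.approx(1.0)

    def test_balanced_homozygote_split(self):
        calls = np.array(([[0]] * 5 + [[2]] * 5) * 2, dtype=np.int8)
        m = make_matrix(calls, pops=["a"] * 10 + ["b"] * 10)
        theta, _ = wc_fst(m)
        assert theta == pytest.approx(-1.0 / 9.0, abs=1e-12)

    def test_duplicated_population_not_positive(self):
        rng = np.random.default_rng(12)
        half = rng.integers(0, 3, size=(15, 10))
        calls = np.vstack([half, half]).astype(np.int8)
        m = make_matrix(calls, pops=["a"] * 15 + ["b"] * 15)
        theta, _ = wc_fst(m)
        assert theta <= 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            r = int(rng.integers(2, 4))
            sizes = [int(rng.integers(4, 21)) for _ in range(r)]
            L = int(rng.integers(1, 11))
            calls = rng.integers(0, 3, size=(sum(sizes), L)).astype(np.int8)
            pops = sum([[f"p{k}"] * sizes[k] for k in range(r)], [])
            m = make_matrix(calls, pops=pops)
            try:
                theta, _ = wc_fst(m)
            except ValueError:
                continue  # no locus with variance; oracle would divide by zero
            assert theta == pytest.approx(
                wc_theta_oracle(calls, sizes), abs=1e-10
            )

    def test_fst_matrix_symmetric(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        m = make_matrix(calls, pops=["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        fm = fst_matrix(m)
        assert np.allclose(fm.values, fm.values.T)
        assert np.allclose(np.diag(fm.values), 0.0)


# ---------------------------------------------------------------------------
# LD-based Ne
# ---------------------------------------------------------------------------


class TestLDNe:
    def test_plugin_value(self):
        assert ne_from_r2_drift(0.01) == pytest.approx(31.1, abs=0.1)

    def test_infinite_branch(self):
        assert ne_from_r2_drift(0.0) == math.inf
        assert ne_from_r2_drift(-0.005) == math.inf

    def test_strictly_decreasing_on_valid_branch(self):
        grid = np.linspace(1e-4, 0.04, 50)
        vals = [ne_from_r2_drift(x) for x in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sampling_correction(self):
        assert expected_sample_r2(50) == pytest.approx(1 / 50 + 3.19 / 2500)

    def test_too_few_loci_rejected(self):
        calls = np.zeros((10, 3), dtype=np.int8)  # monomorphic -> no MAF pass
        with pytest.raises(ValueError, match="MAF"):
            ld_ne(make_matrix(calls), "pop1")

    def test_linked_pairs_skipped(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
        m_unlinked = make_matrix(calls)
        m_linked = make_matrix(calls, parent_locus=["t1"] * 3 + ["t2"] * 3)
        full = ld_ne(m_unlinked, "pop1")
        part = ld_ne(m_linked, "pop1")
        assert part.n_pairs < full.n_pairs

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(14)
        calls = rng.integers(0, 3, size=(60, 40)).astype(np.int8)
        est = ld_ne(make_matrix(calls), "pop1")
        assert est.ci_low <= est.ne <= est.ci_high
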