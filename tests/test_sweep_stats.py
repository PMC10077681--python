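import itertools
import math

import numpy as np
import pytest

from cnvsweep.genomic_io import CnvSweepError, HaplotypeMatrix, Window
from cnvsweep.sweep_stats import (
    SfsBackground,
    background_sfs,
    clr_at,
    clr_max,
    default_alpha_grid,
    ehh,
    escape_kernel,
    ihs,
    standardize_ihs,
    sweep_scan,
    tajima_constants,
    tajimas_d,
    wc_fst_components,
    wc_fst_site,
    window_fst,
    window_pi,
)
from conftest import random_haplotypes


def _hm(alleles, positions, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    samples = [f"S{i}" for i in range(alleles.shape[0] // 2)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=alleles,
        sample_ids=[s for s in samples for _ in range(2)],
    )


# ---------------------------------------------------------------------------
# pi and Tajima's D
# ---------------------------------------------------------------------------


def brute_force_pi(hm, window):
    """Mean per-pair per-bp differences over all haplotype pairs."""
    sl = hm.site_slice(window)
    sub = hm.alleles[:, sl]
    n = hm.n_hap
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((sub[i] != sub[j]).sum())
    return total / (n * (n - 1) / 2) / window.length


class TestWindowPi:
    def test_single_site_derived_count_two(self):
        hm = _hm([[1], [1], [0], [0]], [50])
        pi, S = window_pi(hm, Window("1", 0, 100))
        assert pi == pytest.approx((2 * 2 / 6) / 100)
        assert S == 1

    def test_monomorphic_window(self):
        hm = _hm([[0], [0], [0], [0]], [50])
        pi, S = window_pi(hm, Window("1", 0, 100))
        assert pi == 0.0 and S == 0

    def test_two_haplotypes_one_difference(self):
        hm = _hm([[1], [0]], [50])
        pi, S = window_pi(hm, Window("1", 0, 100))
        assert pi == pytest.approx(0.01)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(5):
            hm = random_haplotypes(rng, n_hap=20, n_sites=200, length=5_000)
            w = Window("1", 0, 5_000)
            pi, _ = window_pi(hm, w)
            assert pi == pytest.approx(brute_force_pi(hm, w), abs=1e-10)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        k = tajima_constants(12)
        d, defined = tajimas_d(7, 7 / k["a1"], 12)
        assert defined and d == pytest.approx(0.0)

    def test_no_segregating_sites_flagged(self):
        d, defined = tajimas_d(0, 0.0, 10)
        assert d == 0.0 and not defined

    def test_small_sample_worked_example(self):
        # n=4, S=1, derived count 2: independent evaluation from first
        # principles of the eight constants and the D formula
        n, S = 4, 1
        pi_total = 2 * 2 * (4 - 2) / (4 * 3)  # heterozygosity of the site
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        d, defined = tajimas_d(S, pi_total, n)
        assert defined and d == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_haplotypes_rejected(self):
        with pytest.raises(CnvSweepError):
            tajimas_d(1, 0.5, 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def wc84_oracle(n1, p1, n2, p2):
    """Independent direct evaluation of the WC84 a and b components for two
    haploid samples (h_bar = 0)."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = ((n1 + n2) - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (ssq - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * ssq))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * ssq)
    return a, b


class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        comp = wc_fst_site((10, 0), (0, 10))
        assert comp.theta == pytest.approx(1.0)
        assert comp.a == pytest.approx(comp.s2)
        assert comp.b == pytest.approx(0.0)

    def test_identical_frequencies_nonpositive(self):
        comp = wc_fst_site((5, 5), (5, 5))
        assert comp.theta <= 0  # reported as computed, not clipped

    def test_nine_one_example_matches_oracle(self):
        comp = wc_fst_site((9, 1), (1, 9))
        a, b = wc84_oracle(10, 0.1, 10, 0.9)
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)

    def test_empty_population_skipped(self):
        assert wc_fst_site((0, 0), (3, 4)) is None

    def test_label_invariance(self, rng):
        for _ in range(20):
            c1 = tuple(rng.integers(0, 10, 2) + [1, 0])
            c2 = tuple(rng.integers(0, 10, 2) + [0, 1])
            f = wc_fst_site(c1, c2)
            g = wc_fst_site(c2, c1)
            assert f.theta == pytest.approx(g.theta, abs=1e-12)

    def test_window_ratio_of_sums(self):
        comps = [wc_fst_site((10, 0), (0, 10)), wc_fst_site((5, 5), (5, 5))]
        expected = (comps[0].a + comps[1].a) / sum(c.a + c.b + c.c for c in comps)
        assert window_fst(comps) == pytest.approx(expected)

    def test_vectorized_matches_scalar_on_random_sites(self, rng):
        n1, n2 = 12, 18
        alt1 = rng.integers(0, n1 + 1, size=100)
        alt2 = rng.integers(0, n2 + 1, size=100)
        a_vec, b_vec = wc_fst_components(alt1, n1, alt2, n2)
        for j in range(100):
            comp = wc_fst_site((n1 - alt1[j], alt1[j]), (n2 - alt2[j], alt2[j]))
            assert a_vec[j] == pytest.approx(comp.a, abs=1e-10)
            assert b_vec[j] == pytest.approx(comp.b, abs=1e-10)


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


def ehh_pairwise_oracle(alleles, positions, core, allele, direction):
    """Enumerate homozygous carrier pairs at each extension distance."""
    carriers = [i for i in range(alleles.shape[0]) if alleles[i, core] == allele]
    n_pairs = len(carriers) * (len(carriers) - 1) / 2
    out_pos, out_val = [positions[core]], [1.0]
    j = core + direction
    while 0 <= j < alleles.shape[1]:
        lo, hi = (min(core, j), max(core, j))
        same = 0
        for a, b in itertools.combinations(carriers, 2):
            if np.array_equal(alleles[a, lo : hi + 1], alleles[b, lo : hi + 1]):
                same += 1
        out_pos.append(positions[j])
        out_val.append(same / n_pairs)
        if out_val[-1] < 0.05:
            break
        j += direction
    return np.array(out_pos), np.array(out_val)


class TestEhh:
    def test_core_value_is_one(self, small_hm):
        _, vals, _ = ehh(small_hm, 5, 1, 1)
        assert vals[0] == 1.0

    def test_two_two_split(self):
        hm = _hm([[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]], [10, 20])
        _, vals, _ = ehh(hm, 0, 1, 1)
        assert vals[1] == pytest.approx((1 + 1) / 6)

    def test_identical_carriers_stay_at_one(self):
        hm = _hm([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 0, 1]], [10, 20, 30])
        _, vals, reached = ehh(hm, 0, 1, 1)
        assert np.all(vals == 1.0) and not reached

    def test_non_increasing_and_matches_pairwise_oracle(self, rng):
        for _ in range(5):
            hm = random_haplotypes(rng, n_hap=10, n_sites=30, length=3_000)
            core = 15
            for allele in (0, 1):
                if (hm.alleles[:, core] == allele).sum() < 2:
                    continue
                for direction in (1, -1):
                    pos, vals, _ = ehh(hm, core, allele, direction)
                    assert np.all(np.diff(vals) <= 1e-12)
                    opos, ovals = ehh_pairwise_oracle(
                        hm.alleles, hm.positions, core, allele, direction
                    )
                    np.testing.assert_array_equal(pos, opos)
                    np.testing.assert_allclose(vals, ovals, atol=1e-12)


def ihs_oracle(hm, site):
    """Naive O(n^2 L) iHS: pairwise EHH enumeration + trapezoid integration."""
    D = hm.derived()
    ihh = {}
    for allele in (0, 1):
        total = 0.0
        for direction in (-1, 1):
            pos, vals = ehh_pairwise_oracle(D, hm.positions, site, allele, direction)
            total += np.trapezoid(vals, np.abs(pos - pos[0]).astype(float))
        ihh[allele] = total
    return math.log(ihh[0] / ihh[1])


class TestIhs:
    def test_symmetric_decay_gives_zero(self):
        # ancestral and derived cores with mirrored haplotype structure
        alleles = [
            [1, 1, 0, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 0, 1, 1],
        ]
        hm = _hm(alleles, [10, 20, 30, 40])
        rec = ihs(hm, 1, maf=0.0)
        assert rec is not None

    def test_identical_derived_haplotypes_negative(self):
        # derived carriers identical over a long span; ancestral decays fast
        alleles = [
            [0, 1, 0, 1, 0], [1, 1, 1, 1, 1], [0, 0, 1, 0, 1],
            [1, 0, 1, 1, 0], [0, 0, 0, 0, 0], [1, 0, 0, 1, 1],
        ]
        hm = _hm(np.array(alleles).T.tolist() and alleles, [10, 30, 50, 70, 90])
        # core site 2: derived carriers are rows 1,2,3 -> make them identical
        A = np.array(
            [
                [1, 1, 1, 1, 1],
                [1, 1, 1, 1, 1],
                [1, 1, 1, 1, 1],
                [0, 1, 0, 0, 1],
                [1, 0, 0, 1, 0],
                [0, 0, 0, 1, 1],
            ],
            dtype=np.uint8,
        )
        hm = _hm(A, [10, 30, 50, 70, 90])
        rec = ihs(hm, 2, maf=0.0)
        assert rec.ihh_d > rec.ihh_a
        assert rec.ihs_raw < 0

    def test_matches_naive_oracle(self, rng):
        checked = 0
        for _ in range(4):
            hm = random_haplotypes(rng, n_hap=10, n_sites=40, length=4_000)
            for site in (18, 20, 22):
                cnt = hm.derived()[:, site].sum()
                if cnt < 2 or hm.n_hap - cnt < 2:
                    continue
                rec = ihs(hm, site, maf=0.0)
                assert rec.ihs_raw == pytest.approx(ihs_oracle(hm, site), abs=1e-8)
                checked += 1
        assert checked >= 5


class TestStandardizeIhs:
    def _rec(self, freq, raw):
        from cnvsweep.sweep_stats import IhsRecord

        return IhsRecord(0, 0, freq, 1.0, 1.0, raw)

    def test_two_values_one_bin(self):
        recs = standardize_ihs([self._rec(0.31, -1.0), self._rec(0.312, 1.0)])
        assert [r.ihs_std for r in recs] == [-1.0, 1.0]

    def test_singleton_bin_flagged_missing(self):
        recs = standardize_ihs([self._rec(0.5, 2.0)])
        assert recs[0].ihs_std is None

    def test_bin_moments_after_standardization(self, rng):
        recs = [self._rec(rng.uniform(0.05, 0.95), rng.normal()) for _ in range(1000)]
        recs = standardize_ihs(recs)
        freqs = np.array([r.derived_freq for r in recs])
        stds = np.array([r.ihs_std if r.ihs_std is not None else np.nan for r in recs])
        bins = np.clip(np.digitize(freqs, np.linspace(0, 1, 51)) - 1, 0, 49)
        for b in np.unique(bins):
            vals = stds[bins == b]
            vals = vals[~np.isnan(vals)]
            if vals.size >= 2:
                assert abs(vals.mean()) < 1e-8
                assert abs(vals.std(ddof=0) - 1) < 1e-8


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------


class TestBackgroundSfs:
    def test_counting(self):
        hm = _hm([[1, 1, 0], [0, 0, 1], [0, 0, 1], [0, 0, 0]], [10, 20, 30])
        bg = background_sfs(hm)
        np.testing.assert_allclose(bg.probs[1:4], [2 / 3, 1 / 3, 0.0])

    def test_monomorphic_rejected(self):
        hm = _hm([[0, 0], [0, 0], [0, 0], [0, 0]], [10, 20])
        with pytest.raises(CnvSweepError):
            background_sfs(hm)


def clr_site_likelihood_oracle(j_obs, n, p_e, bg_probs):
    """Exhaustive enumeration over escapee count k and subsample count c."""
    from scipy.stats import binom, hypergeom

    def p_sweep(j):
        total = 0.0
        for k in range(n + 1):
            wk = binom.pmf(k, n, p_e)
            if k == n:
                total += wk * bg_probs[j]
                continue
            m = k + 1
            for c in range(m + 1):
                pc = sum(
                    bg_probs[i] * hypergeom.pmf(c, n, i, m) for i in range(n + 1)
                )
                if pc == 0:
                    continue
                # representative of the swept class: one random of the m
                if c >= 1 and (c - 1) + (n - k) == j:
                    total += wk * pc * (c / m)
                if c == j:
                    total += wk * pc * (1 - c / m)
        return total

    z = sum(p_sweep(jj) for jj in range(1, n))
    return p_sweep(j_obs) / z


class TestClr:
    def _bg(self, n=4):
        probs = np.zeros(n + 1)
        probs[1:n] = [0.6, 0.3, 0.1]
        return SfsBackground(n=n, probs=probs)

    def test_background_limit_reproduces_background(self):
        bg = self._bg()
        fit = clr_at(0, np.inf, np.array([100, 300]), np.array([1, 2]), bg)
        assert fit.clr == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_matches_enumeration_oracle(self):
        bg = self._bg()
        Q = escape_kernel(bg)
        alpha = 1e-3
        for d, j in [(100, 1), (500, 2), (2000, 3)]:
            p_e = 1 - math.exp(-alpha * d)
            fit = clr_at(0, alpha, np.array([d]), np.array([j]), bg, Q=Q)
            expected = math.log(clr_site_likelihood_oracle(j, 4, p_e, bg.probs))
            got = fit.loglik_sweep
            assert got == pytest.approx(expected, abs=1e-10)

    def test_maximized_clr_nonnegative(self, rng):
        hm = random_haplotypes(rng, n_hap=12, n_sites=80, length=50_000)
        bg = background_sfs(hm)
        cnt = hm.derived_counts()
        seg = (cnt > 0) & (cnt < hm.n_hap)
        for g in (0, 25_000, 49_999):
            fit = clr_max(g, hm.positions[seg] - 1, cnt[seg], bg)
            assert fit.clr >= 0.0

    def test_escape_kernel_rows_are_distributions(self):
        bg = self._bg()
        Q = escape_kernel(bg)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------


class TestSweepScan:
    def test_empty_window_row_emitted(self, small_hm):
        windows = [Window("1", 0, 5_000), Window("1", 900_000, 950_000)]
        table = sweep_scan(small_hm, windows, methods=("pi", "tajima_d"))
        assert len(table) == 2
        empty = table.iloc[1]
        assert empty["n_sites"] == 0
        assert empty["pi"] == 0.0
        assert np.isnan(empty["tajima_d"])

    def test_fst_requires_groups(self, small_hm):
        with pytest.raises(CnvSweepError):
            sweep_scan(small_hm, [Window("1", 0, 1_000)], methods=("fst",))

    def test_full_scan_columns(self, rng, two_groups):
        hm = random_haplotypes(rng, n_hap=20, n_sites=120, length=40_000)
        windows = [Window("1", s, s + 10_000) for s in range(0, 40_000, 10_000)]
        table = sweep_scan(
            hm, windows, methods=("pi", "tajima_d", "fst", "clr", "ihs"),
            groups=two_groups, chrom_length=40_000, grid_spacing=10_000,
        )
        for col in ("pi", "tajima_d", "fst", "clr", "mean_abs_ihs"):
            assert col in table.columns
        assert (table["clr"].dropna() >= 0).all()
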