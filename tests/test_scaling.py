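"""Contact-probability decay: P(s), regimes, domain squares, gap shift."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dinochrom import genome_io as gio
from dinochrom import scaling as sca
from dinochrom import simulate as sim


def pairs_df(chrom, p1, p2):
    n = len(p1)
    return pd.DataFrame(
        {
            "chrom1": chrom,
            "pos1": p1,
            "strand1": "+",
            "chrom2": chrom,
            "pos2": p2,
            "strand2": "-",
        }
    )


def sample_power_law_pairs(alpha, L, n, rng, s_min=1000.0):
    """Inverse-CDF sampling oracle, independent of the generator module."""
    a1 = alpha + 1.0
    u = rng.random(n)
    hi = L - 1.0
    if abs(a1) < 1e-9:
        s = s_min * (hi / s_min) ** u
    else:
        s = (s_min**a1 + u * (hi**a1 - s_min**a1)) ** (1 / a1)
    keep = rng.random(n) < (hi - s) / hi  # density per locus pair = s**alpha
    s = s[keep]
    x = rng.random(len(s)) * (L - s)
    return pairs_df("chr1", (x + 1).astype(int), (x + s + 1).astype(int))


ASM_10MB = gio.GenomeAssembly(chromosomes=[("chr1", 10_000_000)])


class TestPsFromPairs:
    def test_recovers_power_law_exponent(self):
        rng = np.random.default_rng(0)
        pairs = sample_power_law_pairs(-1.0, 10_000_000, 1_000_000, rng)
        curve = sca.ps_from_pairs(pairs, ASM_10MB)
        slope, err = sca.fit_exponent(curve, (50_000, 2_000_000))
        assert slope == pytest.approx(-1.0, abs=0.02)

    def test_uniform_positions_give_flat_ps(self):
        rng = np.random.default_rng(1)
        n = 500_000
        p1 = rng.integers(1, 10_000_000, n)
        p2 = rng.integers(1, 10_000_000, n)
        curve = sca.ps_from_pairs(pairs_df("chr1", p1, p2), ASM_10MB)
        slope, err = sca.fit_exponent(curve, (50_000, 2_000_000))
        assert slope == pytest.approx(0.0, abs=0.02)

    def test_no_cis_pairs_rejected(self):
        pairs = pd.DataFrame(
            [("chr1", 5, "+", "chr2", 9, "-")], columns=gio.PAIRS_COLUMNS
        )
        asm = gio.GenomeAssembly(chromosomes=[("chr1", 100), ("chr2", 100)])
        with pytest.raises(ValueError, match="cis"):
            sca.ps_from_pairs(pairs, asm)

    def test_pairs_and_matrix_views_agree(self, desk):
        """P(s) from raw pairs and from the binned matrix of the same pairs
        differ only by binning error on well-populated separations."""
        curve = sca.ps_from_pairs(desk.pairs, desk.assembly)
        mcurve = sca.ps_from_matrix(desk.matrix, balanced=False)
        for s_bp in (100_000, 300_000, 700_000):
            i = np.argmin(np.abs(curve.s - s_bp))
            j = np.argmin(np.abs(mcurve.s - s_bp))
            assert curve.P[i] == pytest.approx(mcurve.P[j], rel=0.05)


def synthetic_curve(slopes, breaks, s_min=1e3, s_max=1e7, n=80, amp=1e-3):
    """Piecewise power-law curve constructed in closed form."""
    s = np.geomspace(s_min, s_max, n)
    logp = np.zeros(n)
    level = np.log10(amp)
    prev = np.log10(s[0])
    cur = 0
    vals = []
    for x in np.log10(s):
        while cur < len(breaks) and x > np.log10(breaks[cur]):
            level += slopes[cur] * (np.log10(breaks[cur]) - prev)
            prev = np.log10(breaks[cur])
            cur += 1
        vals.append(level + slopes[cur] * (x - prev))
    return sca.ScalingCurve(
        s=s, P=10 ** np.asarray(vals), n_obs=np.full(n, 1e4)
    )


class TestSegmentRegimes:
    def test_pure_power_law_collapses_to_single_slope(self):
        curve = synthetic_curve([-0.7], [])
        fit = sca.segment_regimes(curve)
        assert fit.collapsed
        assert fit.slopes[0] == pytest.approx(-0.7, abs=1e-6)
        assert fit.breakpoints[0] == pytest.approx(curve.s[0])
        assert fit.breakpoints[-1] == pytest.approx(curve.s[-1])

    def test_two_slope_break_located_within_one_bin(self):
        curve = synthetic_curve([-0.4, -2.5], [3_000_000.0])
        fit = sca.segment_regimes(curve, knots=1)
        ratio = curve.s[1] / curve.s[0]
        assert abs(np.log(fit.breakpoints[0] / 3_000_000)) <= np.log(ratio)
        assert fit.slopes[0] == pytest.approx(-0.4, abs=0.05)
        assert fit.slopes[1] == pytest.approx(-2.5, abs=0.2)

    def test_three_regime_slopes_ordered(self):
        curve = synthetic_curve([-1.5, -0.4, -3.0], [5_000.0, 3_000_000.0])
        fit = sca.segment_regimes(curve, knots=2)
        assert not fit.collapsed
        s1, s2, s3 = fit.slopes
        assert s1 < s2  # steep then shallow
        assert s3 < s2  # then the drop
        assert s2 == pytest.approx(-0.4, abs=0.05)

    def test_too_few_bins_rejected(self):
        curve = sca.ScalingCurve(
            s=np.geomspace(1e3, 1e4, 5), P=np.ones(5), n_obs=np.ones(5)
        )
        with pytest.raises(ValueError):
            sca.segment_regimes(curve)


class TestDetectDrop:
    def test_hard_truncation_located(self):
        # a two-decade cliff one bin wide at 1 Mb, shallow decay either side
        ratio = (1e7 / 1e3) ** (1 / 79)
        curve = synthetic_curve(
            [-0.4, -40.0, -0.4], [1_000_000.0, 1_000_000.0 * ratio]
        )
        drop = sca.detect_drop(curve)
        assert abs(np.log(drop / 1_000_000)) <= np.log(ratio)


def balanced_matrix(dense, res=50_000):
    n = len(dense)
    asm = gio.GenomeAssembly(chromosomes=[("chr1", n * res)])
    bt = gio.bin_genome(asm, res)
    return gio.ContactMatrix(
        bin_table=bt,
        counts=sp.csr_matrix(np.asarray(dense, float)),
        weights=np.ones(n),
        balanced=True,
    )


class TestDomainSquares:
    def test_single_domain_equals_whole_chromosome_diagonal_means(self):
        rng = np.random.default_rng(2)
        A = rng.poisson(5, (12, 12)).astype(float)
        A = (A + A.T) / 2
        m = balanced_matrix(A)
        sq = sca.ps_domain_squares(m, pd.DataFrame(columns=["chrom", "start"]))
        curve = sq[("chr1", 0, 0)]
        for d in range(12):
            expect = np.diagonal(A, d).mean()
            got = curve.loc[curve["s"] == d * 50_000, "P"]
            assert got.iloc[0] == pytest.approx(expect)

    def test_offdiagonal_square_trims_extreme_diagonals(self):
        A = np.ones((8, 8))
        m = balanced_matrix(A)
        b = pd.DataFrame({"chrom": ["chr1"], "start": [200_000]})
        sq = sca.ps_domain_squares(m, b)
        off = sq[("chr1", 0, 1)]
        # 4x4 square has 7 diagonals; the single-cell extremes are trimmed
        assert len(off) == 5

    def test_bruteforce_diagonal_means_on_explicit_matrix(self):
        # explicit 6x6 with distinct entries
        A = np.arange(36, dtype=float).reshape(6, 6)
        A = (A + A.T) / 2
        m = balanced_matrix(A)
        b = pd.DataFrame({"chrom": ["chr1"], "start": [150_000]})
        sq = sca.ps_domain_squares(m, b)
        off = sq[("chr1", 0, 1)]
        sub = A[0:3, 3:6]
        means = {}
        for i in range(3):
            for j in range(3):
                k = (j + 3) - i
                means.setdefault(k, []).append(sub[i, j])
        expect = {k * 50_000: np.mean(v) for k, v in means.items()}
        inner = dict(sorted(expect.items())[1:-1])
        assert dict(zip(off["s"], off["P"])) == pytest.approx(inner)

    def test_small_squares_skipped(self):
        m = balanced_matrix(np.ones((5, 5)))
        b = pd.DataFrame({"chrom": ["chr1"], "start": [100_000]})
        sq = sca.ps_domain_squares(m, b)
        assert ("chr1", 0, 0) not in sq  # 2x2 block: undefined


class TestGapShift:
    def make_curve(self, shift=0.0):
        s = np.arange(1, 60) * 50_000.0
        P = 1e-3 * (s - shift).clip(1) ** -0.4
        return pd.DataFrame({"s": s, "P": P})

    def test_identical_curves_give_zero_shift(self):
        r = sca.gap_shift(self.make_curve(), self.make_curve())
        assert r["shift"] == 0.0 and not r["censored"]

    def test_planted_shift_recovered(self):
        r = sca.gap_shift(self.make_curve(shift=500_000), self.make_curve())
        assert abs(r["shift"] - 500_000) <= 50_000

    def test_result_at_grid_limit_flagged_censored(self):
        r = sca.gap_shift(
            self.make_curve(shift=1_500_000), self.make_curve(),
            max_shift=500_000,
        )
        assert r["censored"]


class TestTerminalVsInternal:
    def test_homogeneous_chromosome_ratio_near_one(self):
        spec = sim.SyntheticSpec(seed=3, beta=1.0, tau=1.0, stripe_factor=1.0)
        truth = sim.SyntheticTruth(
            spec=spec,
            chrom_lengths={"chr1": 8_000_000},
            boundaries={"chr1": np.array([2_000_000, 4_000_000, 6_000_000])},
            divergent={"chr1": np.array([])},
        )
        m = sim.expected_contact_matrix(truth, 50_000)
        b = pd.DataFrame(
            {"chrom": "chr1", "start": truth.boundaries["chr1"]}
        )
        r = sca.terminal_vs_internal(m, b, s_max=1_000_000)
        assert r["ratio"] == pytest.approx(1.0, abs=0.05)

    def test_two_domain_chromosome_excluded(self):
        m = balanced_matrix(np.ones((40, 40)))
        b = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000]})
        r = sca.terminal_vs_internal(m, b)
        assert r["excluded"] == ["chr1"]
        assert np.isnan(r["ratio"])


class TestExponentUnbiased:
    def test_mean_fitted_slope_over_seeds(self):
        """The P(s) slope estimator has no systematic bias on the
        generating family (20 independent replicates)."""
        slopes = []
        for seed in range(20):
            spec = sim.SyntheticSpec(
                seed=100 + seed,
                n_chromosomes=1,
                chrom_lengths=(10_000_000,),
                beta=1.0,
                tau=1.0,
                stripe_factor=1.0,
                trans_fraction=0.0,
                n_pairs=200_000,
            )
            asm, _, _, truth = sim.generate_genome(spec, sequence=False)
            pairs = sim.generate_contacts(asm, truth, spec)
            curve = sca.ps_from_pairs(pairs, asm)
            slope, _ = sca.fit_exponent(curve, (50_000, 0.8 * spec.d_max))
            slopes.append(slope)
        assert np.mean(slopes) == pytest.approx(-0.4, abs=0.02)
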