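import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epleio import (
    EstimationError,
    HEstimate,
    InputError,
    PipelineOptions,
    RateRatioInput,
    SiteChangeProfile,
    bootstrap_h,
    conservation_curve,
    default_tree,
    draw_site_rates,
    estimate_pipeline,
    g_function,
    h_statistic,
    phi,
    selection_intensities,
    simulate_alignment,
    solve_ke,
    var_ke,
    var_ratio,
)

from conftest import make_alignment


def profile_from_counts(counts) -> SiteChangeProfile:
    counts = np.asarray(counts)
    return SiteChangeProfile(
        raw_counts=counts.astype(int),
        corrected_counts=counts.astype(float),
        correction_factor=1.0,
        correction_mode="none",
        n_sites_used=len(counts),
    )


class TestHStatistic:
    @pytest.mark.parametrize(
        "m,v,h", [(2, 2, 0.0), (2, 6, 0.5), (1, 1, 0.0)]
    )
    def test_values(self, m, v, h):
        assert h_statistic(m, v) == pytest.approx(h)

    def test_underdispersion_clamps_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert h_statistic(2, 1) == 0.0
        assert "clamping" in caplog.text

    def test_no_substitutions(self):
        with pytest.raises(EstimationError, match="no substitutions"):
            h_statistic(0, 0)

    def test_consistent_for_gamma_rate_mixture(self):
        """H estimates Var(lam)/(Var(lam)+E[lam]^2) = 1/(1+a) for
        Poisson counts with Gamma(a)-distributed site rates."""
        rng = np.random.default_rng(123)
        a = 2.0
        lam = rng.gamma(shape=a, scale=1 / a, size=5000)
        counts = rng.poisson(2.0 * lam)
        h = h_statistic(counts.mean(), counts.var(ddof=1))
        se = np.sqrt(bootstrap_h(profile_from_counts(counts), 200, 1).var_h)
        assert abs(h - 1 / (1 + a)) < 3 * se


class TestPhiAndCurve:
    @pytest.mark.parametrize(
        "k,val", [(0.0, 0.0), (1.0, 0.0624 / 1.289), (7.29, 0.45341)]
    )
    def test_phi_values(self, k, val):
        assert phi(k) == pytest.approx(val, abs=1e-5)

    def test_curve_strictly_decreasing(self):
        grid = np.arange(0, 100 + 1e-9, 0.01)
        f = conservation_curve(grid)
        assert f[0] == pytest.approx(1.0)
        assert np.all(np.diff(f) < 0)


class TestGFunction:
    def test_worked_example_inputs(self):
        assert g_function(0.045, 0.614) == pytest.approx(0.11658, abs=1e-5)

    def test_identity_at_h_zero(self):
        assert g_function(0.3, 0.0) == 0.3

    def test_unconstrained_gene_rejected(self):
        with pytest.raises(EstimationError, match="g = 1"):
            g_function(0.5, 0.5)


class TestSolveKe:
    def test_neutral_boundary(self):
        assert solve_ke(1.0) == 0.0

    def test_worked_example(self):
        assert solve_ke(0.11658) == pytest.approx(7.28, abs=0.01)

    def test_out_of_range(self):
        with pytest.raises(InputError):
            solve_ke(1.5)
        with pytest.raises(EstimationError, match="out of supported range"):
            solve_ke(1e-20)

    @given(st.floats(min_value=0.5, max_value=30.0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_inverts_forward_curve(self, k):
        assert solve_ke(conservation_curve(k)) == pytest.approx(k, abs=1e-6)

    def test_monotone_decreasing_in_g(self):
        gs = np.linspace(0.02, 0.95, 40)
        kes = [solve_ke(g) for g in gs]
        assert np.all(np.diff(kes) < 0)


class TestSelectionIntensities:
    def test_worked_example(self):
        be, se = selection_intensities(7.2785, 0.11658)
        assert be == pytest.approx(1.60, rel=0.02)
        assert se == pytest.approx(-11.65, rel=0.02)

    def test_neutral_limit(self):
        be, se = selection_intensities(5.0, 1 - 1e-12)
        assert be == pytest.approx(0.0, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_sign_and_identity(self):
        for ke, g in [(1.0, 0.5), (7.3, 0.1), (20.0, 0.01)]:
            be, se = selection_intensities(ke, g)
            assert be >= 0 and se <= 0
            assert se == pytest.approx(-ke * be, abs=1e-9)

    def test_ke_zero_returns_zeros(self, caplog):
        with caplog.at_level("WARNING"):
            assert selection_intensities(0.0, 0.5) == (0.0, 0.0)


class TestVariances:
    def test_defaults_zero(self):
        assert var_ratio(RateRatioInput(dn=0.1, ds=0.5)) == 0.0

    def test_relative_sum(self):
        rr = RateRatioInput(dn=0.1, ds=0.5, var_dn=0.0004, var_ds=0.0025)
        assert var_ratio(rr) == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "vr,vh,h,expect",
        [
            (0.0, 0.0, 0.3, 0.0),
            (0.0, 0.001, 0.614, 0.006473),
            (0.05, 0.0, 0.3, 0.048216),
        ],
    )
    def test_var_ke(self, vr, vh, h, expect):
        rr = RateRatioInput(dn=0.1, ds=1.0, var_dn=vr * 0.1**2)
        hest = HEstimate(m=2, v=4, h=h, var_h=vh, n_boot=100, seed=0)
        assert var_ke(rr, hest) == pytest.approx(expect, abs=1e-6)

    def test_additive_nonnegative(self):
        rr = RateRatioInput(dn=0.1, ds=1.0, var_dn=0.001, var_ds=0.002)
        h0 = HEstimate(m=2, v=4, h=0.5, var_h=0.0, n_boot=100, seed=0)
        h1 = HEstimate(m=2, v=4, h=0.5, var_h=0.003, n_boot=100, seed=0)
        both = var_ke(rr, h1)
        assert both == pytest.approx(
            var_ke(rr, h0)
            + var_ke(RateRatioInput(dn=0.1, ds=1.0), h1)
        )
        assert both >= 0


class TestBootstrap:
    def test_degenerate_equal_counts(self):
        prof = profile_from_counts([3, 3, 3, 3, 3])
        est = bootstrap_h(prof, 50, 0)
        assert est.h == 0.0 and est.var_h == 0.0

    def test_seed_determinism(self):
        prof = profile_from_counts([0, 1, 3, 2, 5, 1, 0, 4])
        a = bootstrap_h(prof, 100, 7)
        b = bootstrap_h(prof, 100, 7)
        assert a == b

    def test_too_few_replicates(self):
        with pytest.raises(InputError):
            bootstrap_h(profile_from_counts([1, 2, 3]), 1, 0)

    def test_calibrated_against_regeneration(self):
        """Bootstrap Var(H) within a factor of 2 of the regeneration truth."""
        rng = np.random.default_rng(2024)
        a, t, n = 2.0, 2.0, 1000

        def fresh_h():
            lam = rng.gamma(shape=a, scale=1 / a, size=n)
            c = rng.poisson(t * lam)
            return h_statistic(c.mean(), c.var(ddof=1))

        emp_var = np.var([fresh_h() for _ in range(200)], ddof=1)
        lam = rng.gamma(shape=a, scale=1 / a, size=n)
        counts = rng.poisson(t * lam)
        boot_var = bootstrap_h(profile_from_counts(counts), 100, 3).var_h
        assert 0.5 < boot_var / emp_var < 2.0


class TestPipeline:
    def test_bad_ratio_rejected_before_computation(self):
        with pytest.raises(InputError, match=r"\(0, 1\)"):
            RateRatioInput(dn=0.6, ds=0.5)

    def test_full_run_and_determinism(self):
        rng = np.random.default_rng(5)
        tree = default_tree(8, total_length=3.0)
        # strongly heterogeneous site rates so that H (and Var(H)) are > 0
        from epleio.simulator import SiteRates

        lam = rng.gamma(shape=0.5, scale=1.0, size=1500).clip(max=1.0)
        rates = SiteRates(intensity=np.zeros(1500), rate=lam)
        aln = simulate_alignment(tree, rates, rng)
        rr = RateRatioInput(dn=0.045, ds=1.0)
        opts = PipelineOptions(n_boot=50, seed=9)
        r1 = estimate_pipeline(aln, None, rr, opts)
        r2 = estimate_pipeline(aln, None, rr, opts)
        assert r1 == r2
        assert r1.tree_source == "nj"
        # internal consistency of the estimate chain
        assert r1.g == pytest.approx(r1.ratio / (1 - r1.h))
        assert conservation_curve(r1.ke) == pytest.approx(r1.g, abs=1e-9)
        assert r1.se == pytest.approx(-r1.ke * r1.be, abs=1e-9)
        assert r1.ke > 0 and r1.var_ke > 0

    def test_high_identity_warns_but_completes(self):
        base = list("ACDEFGHIKLMNPQRSTVWY" * 5)
        seqs = {}
        for i in range(8):
            s = base.copy()
            s[2 * i] = "W" if s[2 * i] != "W" else "Y"
            seqs[f"s{i}"] = "".join(s)
        aln = make_alignment(seqs)
        rep = estimate_pipeline(aln, None, RateRatioInput(dn=0.045, ds=1.0))
        assert any("identity" in w for w in rep.warnings)

    def test_ds_above_one_warns(self):
        rng = np.random.default_rng(5)
        tree = default_tree(8, total_length=3.0)
        rates = draw_site_rates(np.full(4, 1.0), 800, rng)
        aln = simulate_alignment(tree, rates, rng)
        rep = estimate_pipeline(aln, None, RateRatioInput(dn=0.09, ds=2.0))
        assert any("dS" in w for w in rep.warnings)
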