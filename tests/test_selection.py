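"""Standardization, differentials, gradients, ANCOVA and Holm control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenosel as ps

from _util import surface_table


def _tiny_table(z_vals, w_vals, trait="BT"):
    """Pre-standardized single-treatment table wrapper."""
    df = pd.DataFrame({"treatment": "control", f"z_{trait}": z_vals, "w": w_vals})
    df.attrs["level"] = "phenotypic"
    return df


class TestStandardize:
    def test_three_point_example(self):
        t = pd.DataFrame(
            {
                "treatment": "control",
                "line_id": ["a", "b", "c"],
                "BT": [1.0, 2.0, 3.0],
                "FITNESS": [2.0, 2.0, 2.0],
            }
        )
        std = ps.standardize_and_relativize(t)
        assert np.allclose(std["z_BT"], [-1, 0, 1])  # sample sd = 1
        assert np.allclose(std["w"], 1.0)

    def test_mean_w_is_one_per_treatment(self):
        rng = np.random.default_rng(0)
        t = surface_table(rng, b=-0.3, noise_sd=0.5)
        std = ps.standardize_and_relativize(t)
        for _, sub in std.groupby("treatment"):
            assert abs(sub["w"].mean() - 1.0) < 1e-12
            assert abs(sub["z_BT"].mean()) < 1e-9
            assert abs(sub["z_BT"].std(ddof=1) - 1.0) < 1e-9

    def test_genotypic_level_collapses_to_line_means(self):
        rng = np.random.default_rng(1)
        t = surface_table(rng, b=-0.3, noise_sd=0.5, n_lines=40)
        std = ps.standardize_and_relativize(t, level="genotypic")
        assert len(std) == 40
        assert std.attrs["level"] == "genotypic"

    def test_zero_variance_trait_raises(self):
        t = pd.DataFrame(
            {
                "treatment": "control",
                "line_id": list("abcd"),
                "BT": [2.0, 2.0, 2.0, 2.0],
                "FITNESS": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="zero variance"):
            ps.standardize_and_relativize(t)


class TestSelectionDifferential:
    def test_closed_form_slope(self):
        # z symmetric, var(z)=1 (ddof=1): slope = cov(w, z) by normal equations
        z = np.array([-1.0, 0.0, 1.0])
        w = np.array([0.6, 1.0, 1.4])
        est = ps.selection_differential(_tiny_table(z, w), "BT")[0]
        assert est.S == pytest.approx(0.4, abs=1e-12)

    def test_no_selection_at_large_n(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(10_000)
        z = (z - z.mean()) / z.std(ddof=1)
        w = 1.0 + 0.3 * rng.standard_normal(10_000)
        est = ps.selection_differential(_tiny_table(z, w), "BT")[0]
        assert abs(est.S) < 0.03

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 50))
    def test_differential_equals_covariance_identity(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(20, 5, n)
        if x.std(ddof=1) == 0:
            return
        fit = np.abs(rng.normal(100, 30, n)) + 1
        t = pd.DataFrame(
            {"treatment": "T", "line_id": [str(i) for i in range(n)], "BT": x,
             "FITNESS": fit}
        )
        std = ps.standardize_and_relativize(t)
        est = ps.selection_differential(std, "BT")[0]
        cov = np.cov(std["w"], std["z_BT"], ddof=1)[0, 1]
        assert abs(est.S - cov) < 1e-10

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError, match="< 3"):
            ps.selection_differential(_tiny_table([-0.7071, 0.7071], [0.5, 1.5]), "BT")


class TestSelectionGradients:
    def test_exact_linear_fit(self):
        z = np.linspace(-2, 2, 20)
        z = (z - z.mean()) / z.std(ddof=1)
        w = 1.0 + 0.3 * z
        est = ps.selection_gradients(_tiny_table(z, w), traits=("BT",))[0]
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.gamma == pytest.approx(0.0, abs=1e-10)
        assert est.r2 == pytest.approx(1.0, abs=1e-10)

    def test_doubling_rule_on_fixed_grid(self):
        # raw quadratic coefficient −0.2 must be reported as γ = −0.4,
        # with the SE doubled alongside (t statistic preserved)
        z = np.linspace(-2, 2, 20)
        w = 1.0 + 0.3 * z - 0.2 * z**2
        est = ps.selection_gradients(_tiny_table(z, w), traits=("BT",))[0]
        assert est.gamma == pytest.approx(-0.4, abs=1e-10)
        X = np.column_stack([np.ones(20), z, z**2])
        coef, _, _, _ = np.linalg.lstsq(X, w, rcond=None)
        assert est.gamma == pytest.approx(2 * coef[2], abs=1e-12)

    def test_doubled_se_preserves_t_statistic(self):
        rng = np.random.default_rng(3)
        t = surface_table(rng, b=-0.3, g=-0.2, noise_sd=0.4)
        std = ps.standardize_and_relativize(t)
        est = ps.selection_gradients(std, traits=("BT",))[0]
        # refit raw model to compare
        X = np.column_stack(
            [np.ones(len(std)), std["z_BT"], std["z_BT"] ** 2]
        )
        w = std["w"].to_numpy()
        coef, _, _, _ = np.linalg.lstsq(X, w, rcond=None)
        resid = w - X @ coef
        sigma2 = resid @ resid / (len(w) - 3)
        se_raw = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[2, 2])
        assert est.gamma == pytest.approx(2 * coef[2], rel=1e-9)
        assert est.se_gamma == pytest.approx(2 * se_raw, rel=1e-9)

    def test_ant_rejected(self):
        rng = np.random.default_rng(4)
        t = surface_table(rng, b=-0.3, noise_sd=0.4)
        std = ps.standardize_and_relativize(t)
        with pytest.raises(ValueError, match="ANT"):
            ps.selection_gradients(std, traits=("BT", "ANT"))

    def test_orthogonal_design_beta_equals_s(self):
        # on exactly orthogonal standardized traits, β_k = S_k
        rng = np.random.default_rng(5)
        # balanced 3×3 factorial: traits exactly orthogonal, quadratics non-degenerate
        a = np.repeat([-1.0, 0.0, 1.0], 3 * 4)
        b = np.tile(np.repeat([-1.0, 0.0, 1.0], 4), 3)
        n = len(a)
        a = (a - a.mean()) / a.std(ddof=1)
        b = (b - b.mean()) / b.std(ddof=1)
        w = 1 + 0.4 * a - 0.2 * b + 0.05 * rng.standard_normal(n)
        df = pd.DataFrame({"treatment": "T", "z_GERM": a, "z_BT": b, "w": w})
        df.attrs["level"] = "phenotypic"
        grads = {e.trait: e.beta for e in ps.selection_gradients(df, traits=("GERM", "BT"))}
        s_a = ps.selection_differential(df, "GERM")[0].S
        s_b = ps.selection_differential(df, "BT")[0].S
        assert grads["GERM"] == pytest.approx(s_a, abs=1e-8)
        assert grads["BT"] == pytest.approx(s_b, abs=1e-8)

    def test_negative_beta_means_earlier_is_fitter(self):
        # monotone decreasing fitness in a timing trait ⇒ β < 0
        z = np.linspace(-2, 2, 30)
        w = 2.0 - 0.5 * z
        est = ps.selection_gradients(_tiny_table(z, w), traits=("BT",))[0]
        assert est.beta < 0


class TestCompareTreatments:
    def test_identical_treatments_show_no_interaction(self):
        rng = np.random.default_rng(6)
        ta = surface_table(rng, b=-0.4, noise_sd=0.4, treatment="A")
        tb = ta.copy()
        tb["treatment"] = "B"
        std = ps.standardize_and_relativize(pd.concat([ta, tb], ignore_index=True))
        rep = ps.compare_treatments(std, "A", "B", traits=("BT",))
        assert abs(rep.loc["BT", "delta_beta"]) < 1e-10
        assert rep.loc["BT", "p_linear_interaction"] > 0.99

    def test_power_to_detect_different_directional_selection(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50):
            ta = surface_table(rng, b=-0.2, noise_sd=0.6, treatment="A")
            tb = surface_table(rng, b=-0.9, noise_sd=0.6, treatment="B")
            std = ps.standardize_and_relativize(pd.concat([ta, tb], ignore_index=True))
            rep = ps.compare_treatments(std, "A", "B", traits=("BT",))
            hits += rep.loc["BT", "p_linear_interaction"] < 0.05
        assert hits >= 48  # ≥ 95%

    def test_type_i_error_under_equal_surfaces(self):
        rng = np.random.default_rng(8)
        rej = 0
        for _ in range(100):
            ta = surface_table(rng, b=-0.4, noise_sd=0.6, treatment="A")
            tb = surface_table(rng, b=-0.4, noise_sd=0.6, treatment="B")
            std = ps.standardize_and_relativize(pd.concat([ta, tb], ignore_index=True))
            rep = ps.compare_treatments(std, "A", "B", traits=("BT",))
            rej += rep.loc["BT", "p_linear_interaction"] < 0.05
        assert rej / 100 <= 0.08

    def test_mismatched_trait_sets_rejected(self):
        rng = np.random.default_rng(9)
        ta = surface_table(rng, b=-0.4, noise_sd=0.4, treatment="A")
        tb = surface_table(rng, b=-0.4, noise_sd=0.4, treatment="B", trait="GERM")
        pooled = pd.concat([ta, tb], ignore_index=True)
        std = ps.standardize_and_relativize(pooled)
        with pytest.raises(ValueError, match="trait sets differ"):
            ps.compare_treatments(std, "A", "B", traits=("BT", "GERM"))


class TestSequentialBonferroni:
    def test_hand_computed_holm_thresholds(self):
        p = (0.001, 0.02, 0.04, 0.2, 0.3, 0.5, 0.9)
        flags = ps.sequential_bonferroni(p, k=7, alpha=0.05)
        # 0.001 ≤ 0.05/7; 0.02 > 0.05/6 = 0.00833 stops the procedure
        assert flags.tolist() == [True] + [False] * 6

    def test_all_ones_none_significant(self):
        assert not ps.sequential_bonferroni([1.0] * 7, k=7).any()

    def test_all_zeros_all_significant(self):
        assert ps.sequential_bonferroni([0.0] * 7, k=7).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            ps.sequential_bonferroni([0.5, 1.2], k=7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=7))
    def test_flags_are_subset_of_unadjusted_rejections(self, p):
        flags = ps.sequential_bonferroni(p, k=7, alpha=0.05)
        for pi, fi in zip(p, flags):
            if fi:
                assert pi <= 0.05
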