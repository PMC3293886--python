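"""Heritability, the treatment×genotype GLM, correlations and the
genetic-constraint rule."""

import numpy as np
import pandas as pd
import pytest

import phenosel as ps

from _util import replicated_design, single_trait_family


def _toy_two_way():
    """4 lines × 2 blocks, fixed values for a brute-force SS oracle."""
    return pd.DataFrame(
        {
            "treatment": "control",
            "block": [1, 1, 1, 1, 2, 2, 2, 2],
            "line_id": ["a", "b", "c", "d"] * 2,
            "Y": [10.0, 12.0, 9.0, 15.0, 11.0, 13.5, 10.0, 15.5],
        }
    )


def _brute_force_two_way_ms(d):
    """Projection-based Type-I sums of squares, independent of the package."""
    y = d["Y"].to_numpy()
    n = len(y)

    def proj_rss(cols):
        X = np.column_stack([np.ones(n)] + cols)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum()), rank

    blocks = pd.get_dummies(d["block"]).to_numpy(dtype=float)
    lines = pd.get_dummies(d["line_id"]).to_numpy(dtype=float)
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss_b, rank_b = proj_rss([blocks])
    rss_bg, rank_bg = proj_rss([blocks, lines])
    ss_block = rss0 - rss_b
    ss_geno = rss_b - rss_bg
    df_block, df_geno = rank_b - 1, rank_bg - rank_b
    df_err = n - rank_bg
    return {
        "MS_block": ss_block / df_block,
        "MS_geno": ss_geno / df_geno,
        "MS_err": rss_bg / df_err,
    }


class TestHeritability:
    def test_anova_ms_match_brute_force_oracle(self):
        d = _toy_two_way()
        est = ps.estimate_heritability(d, "Y", "control")
        oracle = _brute_force_two_way_ms(d)
        assert est.MS_genotype == pytest.approx(oracle["MS_geno"], abs=1e-10)
        assert est.MS_error == pytest.approx(oracle["MS_err"], abs=1e-10)
        r = 2
        sigma_g = max((oracle["MS_geno"] - oracle["MS_err"]) / r, 0)
        assert est.H2 == pytest.approx(sigma_g / (sigma_g + oracle["MS_err"]), abs=1e-10)

    def test_noise_free_data_gives_h2_of_one(self):
        rng = np.random.default_rng(0)
        fam = single_trait_family(rng, n_lines=20, h2=1.0)
        t = ps.simulate_phenotypes(fam, replicated_design(fam), seed=rng)
        est = ps.estimate_heritability(t, "BT", "control")
        assert est.H2 == pytest.approx(1.0)

    def test_no_genetic_signal_clamps_at_zero(self):
        # all lines share the same genotypic value: MS_G ≈ MS_E ⇒ H² ≈ 0
        rng = np.random.default_rng(1)
        d = pd.DataFrame(
            {
                "treatment": "control",
                "block": np.repeat([1, 2, 3], 50),
                "line_id": np.tile([f"L{i}" for i in range(50)], 3),
                "Y": rng.normal(10, 2, 150),
            }
        )
        est = ps.estimate_heritability(d, "Y", "control")
        assert 0.0 <= est.H2 < 0.15

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        fam = single_trait_family(rng, n_lines=40, h2=0.4)
        t = ps.simulate_phenotypes(fam, replicated_design(fam), seed=rng)
        h1 = ps.estimate_heritability(t, "BT", "control").H2
        t2 = t.copy()
        t2["BT"] = 3.7 * t2["BT"] - 11.0
        h2 = ps.estimate_heritability(t2, "BT", "control").H2
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_single_block_rejected(self):
        d = _toy_two_way()
        with pytest.raises(ValueError, match="2 blocks"):
            ps.estimate_heritability(d[d["block"] == 1], "Y", "control")


class TestTreatmentGenotypeModel:
    @staticmethod
    def _table(rng, shift=2.0, h2=0.4, n_lines=40, interaction=0.0):
        fam = single_trait_family(rng, n_lines=n_lines, h2=h2)
        rows = [
            (trt, blk, line)
            for trt in ("A", "B")
            for blk in (1, 2, 3)
            for line in fam.line_ids
        ]
        design = ps.DesignLayout(
            pd.DataFrame(rows, columns=["treatment", "block", "line_id"])
        )
        t = ps.simulate_phenotypes(
            fam, design, treatment_shifts={"B": {"BT": shift}}, seed=rng
        )
        if interaction:
            # genotype-specific treatment response
            bump = {
                line: interaction * i / n_lines for i, line in enumerate(fam.line_ids)
            }
            mask = t["treatment"] == "B"
            t.loc[mask, "BT"] += t.loc[mask, "line_id"].map(bump)
        return t

    def test_interaction_dropped_when_absent(self):
        rng = np.random.default_rng(3)
        dropped = 0
        for _ in range(50):
            rep = ps.fit_treatment_genotype_model(self._table(rng), "BT")
            dropped += "treatment:genotype" not in rep.retained
        assert dropped >= 45  # ≥ 90%

    def test_strong_genotype_effect_always_detected(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rep = ps.fit_treatment_genotype_model(
                self._table(rng, h2=0.5, n_lines=80), "BT"
            )
            assert "genotype" in rep.retained
            assert rep.anova.loc["genotype", "p"] < 0.001

    def test_pure_noise_type_i_error(self):
        rng = np.random.default_rng(5)
        rej_t = rej_g = 0
        n_sim = 100
        for _ in range(n_sim):
            d = pd.DataFrame(
                {
                    "treatment": np.repeat(["A", "B"], 60),
                    "block": np.tile(np.repeat([1, 2, 3], 20), 2),
                    "line_id": np.tile([f"L{i}" for i in range(20)], 6),
                    "BT": rng.normal(25, 3, 120),
                }
            )
            rep = ps.fit_treatment_genotype_model(d, "BT")
            if "treatment" in rep.retained:
                rej_t += rep.anova.loc["treatment", "p"] < 0.05
            if "genotype" in rep.retained:
                rej_g += rep.anova.loc["genotype", "p"] < 0.05
        assert rej_t / n_sim <= 0.08
        assert rej_g / n_sim <= 0.08


class TestCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        fam = single_trait_family(rng, n_lines=30)
        t = ps.simulate_phenotypes(fam, replicated_design(fam), seed=rng)
        c = ps.correlation_matrices(t, "control", traits=("BT",))
        assert c.phenotypic.loc["BT", "BT"] == 1.0
        assert c.genotypic.loc["BT", "BT"] == 1.0

    def test_bivariate_recovery_at_n480(self):
        rng = np.random.default_rng(7)
        traits = ["BT", "FLO"]
        corr = pd.DataFrame(
            [[1.0, 0.65], [0.65, 1.0]], index=traits, columns=traits
        )
        fam = ps.make_ril_family(
            160, {"BT": 25.0, "FLO": 20.0}, {"BT": 4.0, "FLO": 4.0}, corr,
            {"BT": 1.0, "FLO": 1.0}, seed=rng,
        )
        t = ps.simulate_phenotypes(fam, replicated_design(fam), seed=rng)
        c = ps.correlation_matrices(t, "control", traits=tuple(traits))
        assert abs(c.phenotypic.loc["BT", "FLO"] - 0.65) < 0.08

    def test_phenotypic_converges_to_genotypic_without_noise(self):
        rng = np.random.default_rng(8)
        traits = ["BT", "FLO"]
        corr = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=traits, columns=traits)
        fam = ps.make_ril_family(
            100, {"BT": 25.0, "FLO": 20.0}, {"BT": 4.0, "FLO": 4.0}, corr,
            {"BT": 1.0, "FLO": 1.0}, seed=rng,
        )
        fam.residual_sd[:] = 1e-6
        t = ps.simulate_phenotypes(fam, replicated_design(fam), seed=rng)
        c = ps.correlation_matrices(t, "control", traits=tuple(traits))
        assert c.phenotypic.loc["BT", "FLO"] == pytest.approx(
            c.genotypic.loc["BT", "FLO"], abs=1e-6
        )

    def test_all_missing_pair_marked_na(self):
        rng = np.random.default_rng(9)
        fam = single_trait_family(rng, n_lines=30)
        t = ps.simulate_phenotypes(fam, replicated_design(fam), seed=rng)
        t["RP"] = np.nan
        c = ps.correlation_matrices(t, "control", traits=("BT", "RP"))
        assert np.isnan(c.phenotypic.loc["BT", "RP"])


def _corr_frames(traits, pairs):
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits),) * 2), index=traits, columns=traits)
    p[:] = 1.0
    np.fill_diagonal(p.values, 0.0)
    for (a, b), (rv, pv) in pairs.items():
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p


class TestGeneticConstraints:
    def test_control_bt_int_pair_flagged(self):
        # joint selection for earlier bolting and a shorter bolting–anthesis
        # interval, but the two are negatively genetically correlated
        est = pd.DataFrame(
            {"trait": ["BT", "INT"], "beta": [-0.09, -0.07], "p_beta": [1e-4, 1e-3]}
        )
        r, p = _corr_frames(["BT", "INT"], {("BT", "INT"): (-0.28, 1e-4)})
        out = ps.detect_genetic_constraints(est, r, p)
        assert len(out) == 1
        assert {out[0]["trait_i"], out[0]["trait_j"]} == {"BT", "INT"}

    def test_severe_water_stress_flowering_pairs_flagged(self):
        est = pd.DataFrame(
            {
                "trait": ["GERM", "BT", "FLO"],
                "beta": [-0.19, -0.93, -0.30],
                "p_beta": [1e-4, 1e-6, 1e-4],
            }
        )
        r, p = _corr_frames(
            ["GERM", "BT", "FLO"],
            {
                ("GERM", "FLO"): (-0.24, 1e-3),
                ("BT", "FLO"): (-0.54, 1e-6),
                ("GERM", "BT"): (-0.08, 0.4),  # ns: no constraint
            },
        )
        out = ps.detect_genetic_constraints(est, r, p)
        pairs = {frozenset((c["trait_i"], c["trait_j"])) for c in out}
        assert pairs == {frozenset(("GERM", "FLO")), frozenset(("BT", "FLO"))}

    def test_nonsignificant_correlation_never_flagged(self):
        est = pd.DataFrame(
            {"trait": ["BT", "INT"], "beta": [-0.9, -0.9], "p_beta": [1e-9, 1e-9]}
        )
        r, p = _corr_frames(["BT", "INT"], {("BT", "INT"): (-0.9, 0.5)})
        assert ps.detect_genetic_constraints(est, r, p) == []

    def test_rule_symmetric_under_relabeling(self):
        est = pd.DataFrame(
            {"trait": ["X", "Y"], "beta": [0.3, -0.3], "p_beta": [1e-4, 1e-4]}
        )
        r, p = _corr_frames(["X", "Y"], {("X", "Y"): (0.5, 1e-4)})
        out_xy = ps.detect_genetic_constraints(est, r, p)
        est2 = est.iloc[::-1].reset_index(drop=True)
        out_yx = ps.detect_genetic_constraints(est2, r, p)
        assert len(out_xy) == len(out_yx) == 1

    def test_missing_trait_raises(self):
        est = pd.DataFrame({"trait": ["BT", "ZZZ"], "beta": [1, 1], "p_beta": [0, 0]})
        r, p = _corr_frames(["BT", "INT"], {})
        with pytest.raises(KeyError):
            ps.detect_genetic_constraints(est, r, p)
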