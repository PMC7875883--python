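"""Factor analyses: Table-2-style correlations, ICC-set comparisons, motion."""

import numpy as np
import pandas as pd
import pytest

from sst_reliability.factors import (
    build_factor_table,
    compare_icc_sets,
    factor_correlations,
    motion_stability,
)
from sst_reliability.icc import batch_icc
from sst_reliability.synth import VarianceSpec, generate_panel


@pytest.fixture(scope="module")
def panel():
    spec = VarianceSpec(n_pairs=100, n_parcels=60, kappa_motion=1.5,
                        magnitude_coupled=True)
    return generate_panel(spec, seed=11)


@pytest.fixture(scope="module")
def factor_table(panel):
    icc = batch_icc(panel, "between_session_full", contrast="stop_vs_go")
    fam = icc.copy()  # shape-compatible stand-in familiality table
    return build_factor_table(panel, icc, fam, contrast="stop_vs_go")


class TestFactorTable:
    def test_cohens_d_arithmetic(self, panel):
        icc = batch_icc(panel, "between_session_full", contrast="stop_vs_go")
        tbl = build_factor_table(panel, icc, None, contrast="stop_vs_go")
        t1 = panel.session_mean("stop_vs_go", 1)
        expected = t1.mean(axis=0) / t1.std(axis=0, ddof=1)
        np.testing.assert_allclose(tbl["cohens_d"], expected.to_numpy())

    def test_zero_variance_parcel_gets_missing_d(self, panel):
        from sst_reliability.synth import PanelSet
        icc = batch_icc(panel, "between_session_full", contrast="stop_vs_go")
        # fabricate a constant parcel on a copy of the panel
        betas = {}
        for key, df in panel.betas.items():
            df = df.copy()
            df.iloc[:, 0] = 0.0
            betas[key] = df
        pan2 = PanelSet(betas, panel.registry, panel.motion,
                        panel.ground_truth)
        tbl = build_factor_table(pan2, icc, None, contrast="stop_vs_go")
        assert tbl["mean_beta"].iloc[0] == 0.0
        assert np.isnan(tbl["cohens_d"].iloc[0])

    def test_magnitude_coupled_generator_yields_positive_icc_d_corr(
            self, factor_table):
        r, _ = factor_correlations(factor_table, "cortical",
                                   ["icc", "cohens_d"])
        assert r.loc["icc", "cohens_d"] > 0.2


class TestFactorCorrelations:
    def test_affine_relation_gives_unit_correlation(self):
        tbl = pd.DataFrame({
            "parcel_id": [f"p{i}" for i in range(20)],
            "icc": np.linspace(0.1, 0.8, 20),
            "cohens_d": 2.0 * np.linspace(0.1, 0.8, 20) + 1.0,
            "cortical": True,
        })
        r, p = factor_correlations(tbl, "cortical", ["icc", "cohens_d"])
        assert r.loc["icc", "cohens_d"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        n = 360
        tbl = pd.DataFrame({
            "parcel_id": [f"p{i}" for i in range(n)],
            "icc": rng.normal(size=n),
            "cohens_d": rng.normal(size=n),
            "cortical": True,
        })
        r, _ = factor_correlations(tbl, "cortical", ["icc", "cohens_d"])
        assert abs(r.loc["icc", "cohens_d"]) < 3.0 / np.sqrt(n)

    def test_determinism_on_duplicated_stratum(self, factor_table):
        r1, p1 = factor_correlations(factor_table, "cortical")
        r2, p2 = factor_correlations(factor_table, "cortical")
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_small_stratum_rejected(self, factor_table):
        sub = factor_table.head(5)
        with pytest.raises(ValueError, match="< 10"):
            factor_correlations(sub, "cortical")


class TestCompareIccSets:
    def test_identical_sets_null(self):
        icc = np.linspace(-0.2, 0.8, 30)
        out = compare_icc_sets(icc, icc)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_antisymmetry(self, rng):
        a = rng.uniform(-0.3, 0.9, 40)
        b = rng.uniform(-0.3, 0.9, 40)
        ab = compare_icc_sets(a, b)
        ba = compare_icc_sets(b, a)
        assert ab["t"] == pytest.approx(-ba["t"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_session_variance_makes_within_beat_between(self, panel):
        within = [
            batch_icc(panel, "within_session", contrast="stop_vs_go", session=t)
            for t in (1, 2)
        ]
        between = [
            batch_icc(panel, "between_session_run", contrast="stop_vs_go", run=r)
            for r in (1, 2)
        ]
        w = np.nanmean([x["icc"].to_numpy() for x in within], axis=0)
        b = np.nanmean([x["icc"].to_numpy() for x in between], axis=0)
        out = compare_icc_sets(w, b, label_a="within", label_b="between")
        assert out["mean_icc_a"] > out["mean_icc_b"]
        assert out["p"] < 0.05

    def test_combined_runs_beat_single_run(self, panel):
        single = batch_icc(panel, "between_session_run",
                           contrast="stop_vs_go", run=1)
        both = batch_icc(panel, "between_session_full", contrast="stop_vs_go")
        out = compare_icc_sets(single["icc"], both["icc"])
        assert out["mean_icc_b"] > out["mean_icc_a"]
        assert out["p"] < 0.05


class TestMotionStability:
    def test_coupled_panel_shows_positive_correlation(self, panel):
        rec, r, p = motion_stability(panel, contrast="stop_vs_go")
        assert r > 0.3 and p < 0.01
        assert (rec["mean_motion_mm"].dropna() >= 0).all()
        assert (rec["mean_abs_beta_diff"].dropna() >= 0).all()

    def test_uncoupled_panel_near_zero(self):
        spec = VarianceSpec(n_pairs=100, n_parcels=60, kappa_motion=0.0,
                            magnitude_coupled=False)
        pan = generate_panel(spec, seed=12)
        _, r, _ = motion_stability(pan, contrast="stop_vs_go")
        assert abs(r) < 3.0 / np.sqrt(200)

    def test_cleaned_mode_attenuates_correlation(self):
        spec = VarianceSpec(n_pairs=22, n_parcels=200, kappa_motion=2.0,
                            magnitude_coupled=False)
        raw = generate_panel(spec, cleaned=False, seed=13)
        cln = generate_panel(spec, cleaned=True, seed=13)
        _, r_raw, _ = motion_stability(raw, contrast="stop_vs_go")
        _, r_cln, _ = motion_stability(cln, contrast="stop_vs_go")
        assert r_raw > 0.5
        assert abs(r_cln) < r_raw

    def test_too_few_subjects_rejected(self):
        spec = VarianceSpec(n_pairs=2, n_parcels=5)
        pan = generate_panel(spec, seed=14)
        from sst_reliability.synth import apply_dropout
        pan = apply_dropout(pan, 0, 0)
        with pytest.raises(ValueError):
            motion_stability(pan, contrast="stop_vs_go")
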