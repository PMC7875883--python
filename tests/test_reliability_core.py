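"""ICC(C,1) estimator, banding, Fisher z, and design-level batch ICCs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sst_reliability.icc import (
    batch_icc,
    classify_icc,
    fisher_z,
    fisher_z_inverse,
    icc_columns,
    icc_consistency,
    twin_icc,
)
from sst_reliability.synth import VarianceSpec, generate_panel, spec_from_icc_targets


def anova_icc_oracle(x: np.ndarray) -> float:
    """Brute-force two-way ANOVA decomposition with explicit loops."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIccConsistency:
    def test_identical_columns_give_unity(self):
        x = np.tile(np.arange(5.0), (2, 1)).T
        assert icc_consistency(x).icc == pytest.approx(1.0)

    def test_perfect_anticorrelation_forced_to_minus_one(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert icc_consistency(x).icc == pytest.approx(-1.0)

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=(n, k))
            res = icc_consistency(x)
            assert res.icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc3(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(15, 2))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(15), 2),
            "raters": np.tile([0, 1], 15),
            "scores": x.ravel(),
        })
        ref = pg.intraclass_corr(df, "targets", "raters", "scores")
        icc3 = ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].item()
        assert icc_consistency(x).icc == pytest.approx(icc3, abs=1e-10)

    def test_complete_case_filtering_and_small_n(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 3.0], [4.0, 5.0]])
        res = icc_consistency(x)
        assert res.n_complete == 3
        tiny = icc_consistency(np.array([[1.0, 2.0], [2.0, 3.0]]))
        assert tiny.category == "undefined" and np.isnan(tiny.icc)

    def test_zero_variance_flagged_undefined(self):
        x = np.ones((6, 2))
        res = icc_consistency(x)
        assert res.category == "undefined" and res.reason is not None

    @given(arrays(np.float64, (8, 2), elements=st.floats(-100, 100)),
           st.floats(0.5, 3.0), st.floats(-50.0, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_location_scale_and_order_invariances(self, x, scale, shift):
        base = icc_consistency(x)
        if not np.isfinite(base.icc):
            return
        # adding a constant to one column is absorbed by the column effect
        shifted = x.copy(); shifted[:, 1] += shift
        assert icc_consistency(shifted).icc == pytest.approx(base.icc, abs=1e-8)
        # common rescaling cancels in the variance ratio
        assert icc_consistency(scale * x).icc == pytest.approx(base.icc, abs=1e-8)
        # row order is immaterial; so is swapping the two columns
        assert icc_consistency(x[::-1]).icc == pytest.approx(base.icc, abs=1e-8)
        assert icc_consistency(x[:, ::-1]).icc == pytest.approx(base.icc, abs=1e-8)


class TestVectorisedColumns:
    def test_equals_scalar_estimator_with_missing(self, rng):
        x1 = rng.normal(size=(20, 6))
        x2 = rng.normal(size=(20, 6))
        x1[rng.random(x1.shape) < 0.15] = np.nan
        x2[rng.random(x2.shape) < 0.15] = np.nan
        vec = icc_columns(x1, x2)
        for j in range(6):
            ref = icc_consistency(np.column_stack([x1[:, j], x2[:, j]]))
            if np.isnan(vec[j]):
                assert np.isnan(ref.icc) or ref.n_complete < 3
            else:
                assert vec[j] == pytest.approx(ref.icc, abs=1e-10)


class TestClassification:
    @pytest.mark.parametrize("icc,category", [
        (0.50, "fair"),      # e.g. the fair-reliability SSRT band
        (-0.2, "poor"),
        (0.39999, "poor"),
        (0.4, "fair"),
        (0.6, "good"),
        (0.74999, "good"),
        (0.75, "excellent"),
        (1.0, "excellent"),
    ])
    def test_bands(self, icc, category):
        assert classify_icc(icc) == category

    def test_nan_is_undefined(self):
        assert classify_icc(float("nan")) == "undefined"


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_round_trip_identity(self):
        r = np.linspace(-0.99, 0.99, 41)
        assert np.allclose(fisher_z_inverse(fisher_z(r)), r, atol=1e-12)

    def test_out_of_range_clipped(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == fisher_z(2.0)


class TestTwinIcc:
    def test_identical_twins_give_unity(self, rng):
        a = rng.normal(size=20)
        assert twin_icc(np.column_stack([a, a])).icc == pytest.approx(1.0)

    def test_independent_twins_near_zero(self, rng):
        pairs = rng.normal(size=(500, 2))
        res = twin_icc(pairs)
        se = 1.0 / np.sqrt(500)
        assert abs(res.icc) < 3 * se

    def test_generator_twin_icc_recovered(self):
        spec = spec_from_icc_targets(0.7, 0.5, n_pairs=1000, n_parcels=1)
        panel = generate_panel(spec, seed=5)
        t1, t2 = panel.twin_frames("stop_vs_go")
        res = twin_icc(np.column_stack([t1.iloc[:, 0], t2.iloc[:, 0]]))
        assert res.icc == pytest.approx(0.5, abs=0.05)


class TestBatchDesigns:
    def test_noiseless_panel_has_unit_icc_everywhere(self):
        spec = VarianceSpec(n_pairs=10, n_parcels=8, sigma_sess=0.0,
                            sigma_run=0.0, kappa_motion=0.0,
                            magnitude_coupled=False)
        panel = generate_panel(spec, seed=1)
        for design, kw in [("between_session_full", {}),
                           ("between_session_run", {"run": 1}),
                           ("within_session", {"session": 1})]:
            out = batch_icc(panel, design, contrast="stop_vs_go", **kw)
            assert np.allclose(out["icc"], 1.0)

    def test_run_averaging_beats_single_run(self):
        # sigma_run > 0, sigma_sess = 0: averaging runs halves the noise
        spec = spec_from_icc_targets(0.5, 0.2, sess_run_split=0.0,
                                     n_pairs=300, n_parcels=30)
        panel = generate_panel(spec, seed=2)
        full = batch_icc(panel, "between_session_full", contrast="stop_vs_go")
        single = batch_icc(panel, "between_session_run", contrast="stop_vs_go",
                           run=1)
        assert full["icc"].mean() > single["icc"].mean()

    def test_within_session_beats_between_when_state_variance(self):
        spec = spec_from_icc_targets(0.4, 0.2, sess_run_split=0.7,
                                     n_pairs=300, n_parcels=30)
        panel = generate_panel(spec, seed=3)
        within = batch_icc(panel, "within_session", contrast="stop_vs_go",
                           session=1)
        between = batch_icc(panel, "between_session_full",
                            contrast="stop_vs_go")
        assert within["icc"].mean() > between["icc"].mean()

    def test_missing_design_cell_raises(self):
        spec = VarianceSpec(n_pairs=5, n_parcels=4)
        panel = generate_panel(spec, seed=0, n_sessions=1)
        with pytest.raises((KeyError, ValueError)):
            batch_icc(panel, "between_session_full", contrast="stop_vs_go")
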