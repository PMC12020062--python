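"""Dose-response metrics: first significant dose, AUC, max effect."""

import numpy as np
import pytest

from htstox.doseresponse import (
    dose_response_auc,
    first_significant_dose,
    max_effect,
    metrics_table,
    pivot_metrics,
)
from htstox.preprocess import ControlStats


def make_controls(median=0.0, sd=1.0, values=None):
    if values is None:
        values = np.array([-1.2, -0.8, -0.4, -0.1, 0.1, 0.4, 0.8, 1.2]) * sd + median
    values = np.asarray(values, dtype=float)
    return ControlStats(
        scope=("test",),
        median=median,
        mean=float(values.mean()),
        sd=sd,
        q1=float(np.quantile(values, 0.25)),
        q3=float(np.quantile(values, 0.75)),
        iqr=float(np.quantile(values, 0.75) - np.quantile(values, 0.25)),
        n_before=len(values),
        n_after=len(values),
        values=values,
    )


class TestFirstSignificantDose:
    def series(self):
        # replicate means by dose: 0.5, 1.5, 8, 9 with tight replicates
        return {
            1.0: [0.4, 0.5, 0.6],
            2.0: [1.4, 1.5, 1.6],
            4.0: [7.9, 8.0, 8.1],
            8.0: [8.9, 9.0, 9.1],
        }

    def test_first_dose_above_threshold_and_significant(self):
        controls = make_controls(median=0.0, sd=1.0)
        s = self.series()
        doses = sorted(s)
        # mean must exceed 2 (resp. 3): first qualifying dose is the 3rd
        assert first_significant_dose(doses, s, controls, k=2) == 4.0
        assert first_significant_dose(doses, s, controls, k=3) == 4.0

    def test_flat_series_never_significant(self):
        controls = make_controls()
        s = {d: [0.0, 0.1, -0.1] for d in (1.0, 2.0, 4.0)}
        assert np.isnan(first_significant_dose(sorted(s), s, controls, k=2))

    def test_3sd_at_least_2sd(self):
        rng = np.random.default_rng(5)
        controls = make_controls(median=0.0, sd=1.0)
        for _ in range(100):
            doses = [1.0, 2.0, 4.0, 8.0, 16.0]
            base = np.sort(rng.uniform(0, 8, size=len(doses)))
            s = {
                d: (b + rng.normal(0, 0.2, size=3)).tolist()
                for d, b in zip(doses, base)
            }
            d2 = first_significant_dose(doses, s, controls, k=2)
            d3 = first_significant_dose(doses, s, controls, k=3)
            if not np.isnan(d2) and not np.isnan(d3):
                assert d3 >= d2
            if np.isnan(d2):  # the 2SD qualifying set contains the 3SD one
                assert np.isnan(d3)

    def test_too_few_replicates_warns(self):
        controls = make_controls()
        with pytest.warns(UserWarning, match="replicates"):
            out = first_significant_dose([1.0], {1.0: [9.0]}, controls, k=2)
        assert np.isnan(out)


class TestAUC:
    def test_hand_trapezoid(self):
        controls = make_controls(median=0.0, sd=1.0)  # threshold 2
        auc = dose_response_auc([1, 10, 100, 1000], [0, 5, 50, 80], controls)
        assert auc == pytest.approx(95.0)  # 2.5 + 27.5 + 65 on x = 0..3

    def test_all_below_threshold(self):
        controls = make_controls(median=0.0, sd=1.0)
        assert dose_response_auc([1, 10, 100], [0.5, 1.0, 1.5], controls) == 0.0

    def test_linearity_above_threshold(self):
        controls = make_controls(median=0.0, sd=1.0)
        doses, effects = [1, 10, 100], [10.0, 40.0, 80.0]
        a1 = dose_response_auc(doses, effects, controls)
        a2 = dose_response_auc(doses, [2 * e for e in effects], controls)
        assert a2 == pytest.approx(2 * a1)

    def test_matches_dense_integration_oracle(self):
        """Trapezoid equals numeric integration of the piecewise-linear
        interpolant on random instances."""
        rng = np.random.default_rng(17)
        controls = make_controls(median=0.0, sd=1.0)
        for _ in range(100):
            n = rng.integers(2, 12)
            doses = np.sort(rng.uniform(0.01, 1000, size=n))
            effects = rng.uniform(-10, 100, size=n)
            auc = dose_response_auc(doses, effects, controls)
            x = np.log10(doses)
            y = np.where(effects < controls.median + 2 * controls.sd, 0.0, effects)
            grid = np.linspace(x[0], x[-1], 20001)
            oracle = np.trapezoid(np.interp(grid, x, y), grid)
            assert auc == pytest.approx(oracle, abs=max(1e-6, 5e-4 * abs(oracle)))

    def test_dose_zero_excluded(self):
        controls = make_controls(median=0.0, sd=1.0)
        with_zero = dose_response_auc([0, 1, 10], [50.0, 50.0, 50.0], controls)
        without = dose_response_auc([1, 10], [50.0, 50.0], controls)
        assert with_zero == pytest.approx(without)

    def test_fewer_than_two_points_warns_zero(self):
        controls = make_controls()
        with pytest.warns(UserWarning):
            assert dose_response_auc([1], [50.0], controls) == 0.0


class TestMaxEffect:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([[10, 80], [20, 90], [30, 100]], 90.0),
            ([[5, 42]], 42.0),
            ([[10, 80], [np.nan, np.nan], [30, 100]], 90.0),
        ],
    )
    def test_median_of_replicate_maxima(self, series, expected):
        assert max_effect(series) == pytest.approx(expected)


class TestMetricsTable:
    def test_group_counts(self, lownoise_processed):
        metrics = metrics_table(
            lownoise_processed["processed"], lownoise_processed["control_stats"]
        )
        n_materials = len(lownoise_processed["truth"].materials)
        # 5 endpoints x 3 time points x 2 serum conditions per material
        # (CTG 0 h plates are baseline only and contribute no metric rows)
        assert len(metrics) == n_materials * 5 * 3 * 2
        assert not (metrics["time_h"] == 0).any()
        assert (metrics["auc"] >= 0).all()

    def test_potent_beats_inert(self, lownoise_processed):
        metrics = metrics_table(
            lownoise_processed["processed"], lownoise_processed["control_stats"]
        )
        truth = lownoise_processed["truth"]
        potent = min(truth.materials, key=lambda m: m.ec50_ugml).material_id
        sub = metrics[(metrics["endpoint"] == "CTG") & (metrics["time_h"] == 72.0)]
        p = sub[sub["material_id"] == potent]
        i = sub[sub["material_id"] == "INERT"]
        assert p["auc"].mean() > i["auc"].mean()
        assert p["max_effect"].mean() > i["max_effect"].mean()
        assert np.isnan(i["first_sig_2sd"]).all()
        assert (p["first_sig_2sd"].dropna() <= 8.0).all()

    def test_first_sig_subset_property_on_campaign(self, lownoise_processed):
        metrics = metrics_table(
            lownoise_processed["processed"], lownoise_processed["control_stats"]
        )
        both = metrics.dropna(subset=["first_sig_2sd", "first_sig_3sd"])
        assert (both["first_sig_3sd"] >= both["first_sig_2sd"]).all()

    def test_first_sig_matches_threshold_oracle(self, lownoise_processed):
        """At low noise, the detected first significant dose sits within one
        dilution step of the smallest tested dose whose replicate-median
        effect exceeds the control threshold (brute force over the grid)."""
        processed = lownoise_processed["processed"]
        control_stats = lownoise_processed["control_stats"]
        metrics = metrics_table(processed, control_stats)
        checked = 0
        for ep in ("DAPI", "H2AX"):
            ds = processed[ep]
            rec = ds.records
            vals = ds.layers["normalized"].to_numpy()
            mask = (rec["role"] == "treated") & rec["material_id"].ne("INERT")
            df = rec.loc[mask, ["material_id", "time_h", "serum", "dose_value"]].copy()
            df["v"] = vals[mask.to_numpy()]
            for (mat, t, serum), grp in df.groupby(["material_id", "time_h", "serum"]):
                ctrl = control_stats[ep][(t, "BEAS-2B", serum)]
                med = grp.groupby("dose_value")["v"].median()
                above = med[med > ctrl.median + 2 * ctrl.sd]
                row = metrics[
                    (metrics["material_id"] == mat)
                    & (metrics["endpoint"] == ep)
                    & (metrics["time_h"] == t)
                    & (metrics["serum"] == serum)
                ].iloc[0]
                detected = row["first_sig_2sd"]
                if above.empty:
                    assert np.isnan(detected)
                    continue
                oracle = above.index.min()
                if np.isnan(detected):
                    continue  # t-test may withhold borderline calls
                ratio = detected / oracle
                assert 0.5 <= ratio <= 2.0, (ep, mat, t, serum)
                checked += 1
        assert checked >= 50

    def test_pivot_column_naming(self, lownoise_processed):
        metrics = metrics_table(
            lownoise_processed["processed"], lownoise_processed["control_stats"]
        )
        wide = pivot_metrics(metrics)
        assert "CTG_72h_first_sig_3sd_with" in wide.columns
        n_materials = len(lownoise_processed["truth"].materials)
        assert wide.shape == (n_materials, 5 * 3 * 2 * 4)
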