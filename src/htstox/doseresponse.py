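"""Dose-response metrics: first significant effect, AUC, maximum effect.

Three metric families summarize each normalized dose-response series per
(material, endpoint, time, cell line, serum):

* **first significant effect** — the lowest tested dose at which the mean
  replicate effect exceeds the control median plus k standard deviations
  (k = 2 and 3 are both reported) *and* a two-tailed Welch t-test of the
  replicate effects against the filtered control values gives p < 0.05;
* **AUC** — trapezoid area under the replicate-median effect vs log10(dose)
  curve, after zeroing effects below the control median + 2 SD to remove
  baseline noise; no extrapolation beyond the highest tested dose;
* **max effect** — the median over replicates of each replicate's maximum
  effect across doses.

The two first-significant cutoffs extend the scoring to low-toxicity
agents while weighting the high-toxicity ones more; the max effect ranks
materials whose responses never clear even the 2 SD cutoff.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plate_io import HTSDataset
from .preprocess import ControlStats

METRICS = ("first_sig_2sd", "first_sig_3sd", "auc", "max_effect")

GROUP_KEY = ["material_id", "endpoint", "time_h", "cell_line", "serum"]


def first_significant_dose(
    doses: Sequence[float],
    effects_by_dose: Mapping[float, Sequence[float]],
    controls: ControlStats,
    k: float = 2.0,
    alpha: float = 0.05,
) -> float:
    """Lowest dose with a significant effect above control median + k*SD.

    Doses are scanned in ascending order; a dose qualifies when the mean
    of its replicate effects exceeds the threshold and the two-tailed
    Welch t-test of those replicates against the control values rejects at
    ``alpha``.  Returns NaN when no dose qualifies (no significant effect)
    or when no dose has the >= 2 replicates the test needs.
    """
    threshold = controls.median + k * controls.sd
    any_testable = False
    for dose in sorted(doses):
        reps = np.asarray(effects_by_dose[dose], dtype=float)
        reps = reps[np.isfinite(reps)]
        if reps.size < 2:
            continue
        any_testable = True
        if reps.mean() <= threshold:
            continue
        p = sps.ttest_ind(reps, controls.values, equal_var=False).pvalue
        if np.isfinite(p) and p < alpha:
            return float(dose)
    if not any_testable:
        warnings.warn("fewer than 2 replicates at every dose", stacklevel=2)
    return float("nan")


def dose_response_auc(
    doses: Sequence[float],
    median_effects: Sequence[float],
    controls: ControlStats,
    k: float = 2.0,
) -> float:
    """Trapezoid area under the thresholded effect vs log10(dose) curve.

    Effects below the control median + k*SD are set to 0 (keeping the dose
    grid intact so areas stay comparable across materials); dose-0 rows
    (controls) and non-finite effects are excluded from the x-axis.  With
    fewer than 2 usable points the area is 0 (with a warning).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(median_effects, dtype=float)
    keep = (d > 0) & np.isfinite(y)
    d, y = d[keep], y[keep]
    order = np.argsort(d)
    d, y = d[order], y[order]
    if d.size < 2:
        warnings.warn("fewer than 2 finite dose points; AUC = 0", stacklevel=2)
        return 0.0
    threshold = controls.median + k * controls.sd
    y = np.where(y < threshold, 0.0, y)
    return float(np.trapezoid(y, np.log10(d)))


def max_effect(replicate_series: Sequence[Sequence[float]]) -> float:
    """Median over replicates of each replicate's maximum effect."""
    maxima = []
    for series in replicate_series:
        arr = np.asarray(series, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            maxima.append(arr.max())
    if not maxima:
        return float("nan")
    return float(np.median(maxima))


def _series_for_group(grp: pd.DataFrame) -> tuple[dict, dict, list]:
    """Pivot one (material x condition) group into per-dose structures."""
    by_dose: dict[float, list[float]] = {}
    by_rep: dict = {}
    for dose, rep, v in zip(grp["dose_value"], grp["replicate"], grp["_value"]):
        by_dose.setdefault(float(dose), []).append(v)
        by_rep.setdefault(rep, []).append(v)
    medians = {d: float(np.nanmedian(v)) if np.isfinite(v).any() else float("nan")
               for d, v in ((d, np.asarray(v, dtype=float)) for d, v in by_dose.items())}
    return by_dose, medians, list(by_rep.values())


def metrics_table(
    datasets: Mapping[str, HTSDataset],
    control_stats: Mapping[str, Mapping[tuple, ControlStats]],
    layer: str = "normalized",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compute all four metrics per (material, endpoint, time, cell, serum).

    Treated wells only; 0-h rows (viability baselines) are excluded.
    ``control_stats`` holds the pooled normalized-scale control statistics
    per endpoint, keyed by (time_h, cell_line, serum).
    """
    rows = []
    for ep, ds in datasets.items():
        rec = ds.records
        mask = (rec["role"] == "treated") & (rec["time_h"] != 0)
        if not mask.any():
            continue
        df = rec.loc[mask, ["material_id", "time_h", "cell_line", "serum",
                            "dose_value", "replicate"]].copy()
        df["_value"] = ds.layers[layer].to_numpy()[mask.to_numpy()]
        for (mat, t, cl, serum), grp in df.groupby(
            ["material_id", "time_h", "cell_line", "serum"], dropna=False, sort=True
        ):
            ctrl = control_stats.get(ep, {}).get((t, cl, serum))
            if ctrl is None:
                continue
            by_dose, medians, rep_series = _series_for_group(grp)
            doses = sorted(by_dose)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(
                    {
                        "material_id": mat,
                        "endpoint": ep,
                        "time_h": t,
                        "cell_line": cl,
                        "serum": serum,
                        "first_sig_2sd": first_significant_dose(
                            doses, by_dose, ctrl, k=2.0, alpha=alpha
                        ),
                        "first_sig_3sd": first_significant_dose(
                            doses, by_dose, ctrl, k=3.0, alpha=alpha
                        ),
                        "auc": dose_response_auc(
                            doses, [medians[d] for d in doses], ctrl, k=2.0
                        ),
                        "max_effect": max_effect(rep_series),
                    }
                )
    return pd.DataFrame(rows, columns=GROUP_KEY + list(METRICS))


def metric_column_name(
    endpoint: str, time_h: float, metric: str,
    cell_line: str | None = None, serum: str | None = None,
) -> str:
    t = int(time_h) if float(time_h).is_integer() else time_h
    name = f"{endpoint}_{t}h_{metric}"
    if cell_line:
        name += f"_{cell_line}"
    if serum:
        name += f"_{serum}"
    return name


def pivot_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Long metrics table -> wide materials x metric-column matrix.

    Column names follow ``<endpoint>_<time>h_<metric>`` with cell-line and
    serum suffixes appended when the table spans more than one of either.
    """
    if table.empty:
        return pd.DataFrame()
    multi_cl = table["cell_line"].nunique(dropna=False) > 1
    multi_serum = table["serum"].nunique(dropna=False) > 1
    out: dict[str, pd.Series] = {}
    for (ep, t, cl, serum), grp in table.groupby(
        ["endpoint", "time_h", "cell_line", "serum"], dropna=False, sort=True
    ):
        for metric in METRICS:
            col = metric_column_name(
                ep, t, metric,
                cell_line=cl if multi_cl else None,
                serum=serum if multi_serum else None,
            )
            out[col] = grp.set_index("material_id")[metric]
    wide = pd.DataFrame(out)
    wide.index.name = "material_id"
    return wide
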