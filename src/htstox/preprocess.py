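"""Endpoint-specific normalization and cleaning.

The preprocessing chain expresses every well as percent of plate-wise
vehicle controls (after IQR outlier removal in the controls), corrects
viability readouts for the 0-h pre-exposure baseline, repairs imaging
wells with failed DAPI staining, rescales caspase activation by the
surviving cell fraction, and finally aggregates biological replicates by
their median.

Sign convention: viability-type endpoints (CTG, DAPI) are expressed as
percent *inhibition* and damage/apoptosis endpoints as percent *effect*,
so that "larger = more toxic" holds uniformly downstream, where the first
significant effect is defined as exceeding the control median plus k
standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import HTSDataset

#: endpoints reported as % inhibition (viability-type); others are % effect
INHIBITION_ENDPOINTS = {"CTG", "DAPI"}

#: replicate-aggregation key
AGG_KEY = ["material_id", "dose_value", "time_h", "cell_line", "serum"]


class PreprocessError(ValueError):
    pass


@dataclass
class ControlStats:
    """Summary of (outlier-filtered) vehicle-control values for one scope."""

    scope: tuple
    median: float
    mean: float
    sd: float
    q1: float
    q3: float
    iqr: float
    n_before: int
    n_after: int
    values: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def iqr_filter_controls(values, scope: tuple = (), multiplier: float = 1.5):
    """Remove control outliers outside [Q1 - m*IQR, Q3 + m*IQR].

    Quantiles use linear interpolation (numpy's default, R type 7).
    Returns the kept values and a :class:`ControlStats` computed on them.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise PreprocessError(f"no finite control values for scope {scope}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    kept = arr[(arr >= lo) & (arr <= hi)]
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    stats = ControlStats(
        scope=scope,
        median=float(np.median(kept)),
        mean=float(np.mean(kept)),
        sd=sd,
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        n_before=int(arr.size),
        n_after=int(kept.size),
        values=kept,
    )
    return kept, stats


def percent_of_control(value, control_median: float, mode: str = "effect"):
    """Express a value relative to the plate control median.

    mode="effect":     value / median * 100       (controls sit at 100)
    mode="inhibition": (1 - value / median) * 100 (controls sit at 0)

    The two modes are complementary: effect + inhibition = 100 for any
    value.
    """
    if control_median == 0:
        raise PreprocessError("control median is 0; percent of control undefined")
    ratio = np.asarray(value, dtype=float) / control_median
    if mode == "effect":
        out = ratio * 100.0
    elif mode == "inhibition":
        out = (1.0 - ratio) * 100.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


def baseline_correct_0h(value, baseline_0h_median: float, mode: str = "subtract"):
    """Correct a viability readout for its 0-h pre-exposure baseline.

    The 0-h plates measure the pre-exposure state and any assay
    interference by the material itself.  The default subtracts the median
    of the replicate 0-h values; a secondary ``ratio`` mode divides by it
    instead.
    """
    v = np.asarray(value, dtype=float)
    if mode == "subtract":
        out = v - baseline_0h_median
    elif mode == "ratio":
        if baseline_0h_median == 0:
            raise PreprocessError("0-h median is 0; ratio baseline undefined")
        out = v / baseline_0h_median
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


def clean_imaging_by_dapi(
    dapi_value: float,
    replicate_dapi_values,
    associated_values: dict[str, float],
    threshold: float = 50.0,
    stat: str = "median",
):
    """Repair an imaging well whose DAPI (cell count) signal is zero.

    A zero DAPI signal means either genuine cell death or a failed image
    focus.  The biological replicates at the same (material, dose, time)
    disambiguate: if their central DAPI value is <= threshold the cells
    really died, so DAPI stays 0 and associated endpoints are set to 0;
    if it exceeds the threshold the image failed, so DAPI and associated
    endpoints become NaN.  Nonzero DAPI values are never touched.  DAPI
    technical duplicates must be averaged before applying this rule.
    """
    if not (np.isfinite(dapi_value) and dapi_value == 0):
        return dapi_value, dict(associated_values)
    reps = np.asarray(replicate_dapi_values, dtype=float)
    reps = reps[np.isfinite(reps)]
    center = 0.0
    if reps.size:
        center = float(np.median(reps) if stat == "median" else np.mean(reps))
    if center > threshold:
        return float("nan"), {k: float("nan") for k in associated_values}
    return 0.0, {k: 0.0 for k in associated_values}


def normalize_caspase(
    casp_percent: float,
    mean_endpoint1_percent: float,
    mean_endpoint2_percent: float,
):
    """Rescale caspase activation by the surviving cell fraction.

    The caspase readout shrinks as cells are lost; dividing by
    ``1 - average(mean loss of the two viability endpoints)/100`` restores
    the per-surviving-cell signal.  When on average all cells are lost the
    correction is undefined and NaN is returned with a warning.
    """
    loss = (mean_endpoint1_percent + mean_endpoint2_percent) / 2.0
    denom = 1.0 - loss / 100.0
    if denom <= 0:
        warnings.warn(
            "caspase normalization undefined: mean cell loss >= 100%", stacklevel=2
        )
        return float("nan")
    return casp_percent / denom


def aggregate_replicates(
    ds: HTSDataset,
    layer: str = "normalized",
    stat: str = "median",
    store_as: str | None = None,
) -> pd.DataFrame:
    """Aggregate biological replicates per (material, dose, time, cell, serum).

    Missing values are ignored; a key whose values are all missing stays
    missing.  The result is stored under ``ds.aggregates`` and returned.
    """
    if layer not in ds.layers:
        raise PreprocessError(f"layer {layer!r} not present")
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    df = ds.records[AGG_KEY].copy()
    df["value"] = ds.layers[layer].to_numpy()
    grouped = df.groupby(AGG_KEY, dropna=False)["value"]
    agg = (grouped.median() if stat == "median" else grouped.mean()).reset_index()
    name = store_as or f"{stat}_of_replicates"
    ds.aggregates[name] = agg
    ds.log("aggregate_replicates", layer=layer, stat=stat)
    return agg


# ---------------------------------------------------------------------------
# dataset-level appliers
# ---------------------------------------------------------------------------

def average_technical_duplicates(ds: HTSDataset, layer: str = "raw") -> HTSDataset:
    """Collapse technical-duplicate rows (same plate & well) by their mean.

    Used for DAPI, which is measured twice per well.  Returns a new dataset
    with one record per (plate, well); all other coordinates are taken from
    the first duplicate.
    """
    key = ["plate_id", "well"]
    df = ds.records.copy()
    df["_value"] = ds.layers[layer].to_numpy()
    first = df.groupby(key, sort=False, dropna=False).first().reset_index()
    means = df.groupby(key, sort=False, dropna=False)["_value"].mean().reset_index()
    merged = first.drop(columns=["_value"]).merge(means, on=key)
    records = merged.drop(columns=["_value"]).reset_index(drop=True)
    raw = pd.Series(merged["_value"].to_numpy(), index=records.index)
    out = HTSDataset(
        endpoint=ds.endpoint,
        records=records,
        layers={layer: raw},
        geometry=ds.geometry,
        provenance=list(ds.provenance),
        aggregates={},
    )
    out.log("average_technical_duplicates", layer=layer)
    return out


def clean_imaging_datasets(
    datasets: dict[str, HTSDataset],
    dapi: str = "DAPI",
    associated: tuple[str, ...] = ("CASP", "H2AX", "8OHG"),
    layer: str = "raw",
    out_layer: str = "clean",
    threshold: float = 50.0,
    stat: str = "median",
) -> dict[str, HTSDataset]:
    """Apply the DAPI zero-signal rule across imaging datasets.

    DAPI technical duplicates are averaged first (the returned DAPI dataset
    has one record per well).  For every well with averaged DAPI == 0 the
    replicate DAPI values at the same (material, dose, time, cell line,
    serum) decide between true cell death (everything set to 0) and focus
    failure (everything set to NaN); the verdict is propagated to the
    associated endpoints at the same plate coordinates.
    """
    out = dict(datasets)
    if dapi not in datasets:
        return out
    dapi_ds = average_technical_duplicates(datasets[dapi], layer=layer)
    rec = dapi_ds.records
    vals = dapi_ds.layers[layer].to_numpy().copy()

    rep_groups = rec.groupby(AGG_KEY, dropna=False).indices
    key_of = list(zip(*(rec[c] for c in AGG_KEY)))

    # verdict per (plate, well) with zero DAPI: True -> focus failure (NaN)
    verdicts: dict[tuple[str, str], bool] = {}
    for i in np.flatnonzero(np.isfinite(vals) & (vals == 0)):
        group = rep_groups[key_of[i]]
        others = vals[[j for j in group if j != i]]
        others = others[np.isfinite(others)]
        center = float(np.median(others) if stat == "median" else np.mean(others)) if others.size else 0.0
        failed = center > threshold
        verdicts[(rec["plate_id"].iat[i], rec["well"].iat[i])] = failed
        vals[i] = np.nan if failed else 0.0

    clean = pd.Series(vals, index=rec.index)
    dapi_ds.layers[out_layer] = clean
    dapi_ds.log("clean_imaging_by_dapi", threshold=threshold, stat=stat, n_zero=len(verdicts))
    out[dapi] = dapi_ds

    for ep in associated:
        if ep not in datasets:
            continue
        ds = datasets[ep].copy()
        v = ds.layers[layer].to_numpy().copy()
        plate_well = list(zip(ds.records["plate_id"], ds.records["well"]))
        for i, pw in enumerate(plate_well):
            if pw in verdicts:
                v[i] = np.nan if verdicts[pw] else 0.0
        ds.layers[out_layer] = pd.Series(v, index=ds.records.index)
        ds.log("clean_imaging_by_dapi", threshold=threshold, stat=stat, via=dapi)
        out[ep] = ds
    return out


def baseline_correct_dataset(
    ds: HTSDataset,
    layer: str = "raw",
    out_layer: str = "baseline_corrected",
    mode: str = "subtract",
    drop_baseline: bool = True,
) -> HTSDataset:
    """Subtract (or divide by) the per-well median of the 0-h plates.

    The 0-h baseline is keyed by (well, cell line, serum): the same well
    position holds the same material and dose on every plate of a screen,
    so this removes material-specific assay interference.  Requires 0-h
    records in the dataset.  The 0-h plates only serve as baseline, so by
    default they are dropped from the returned dataset (their corrected
    values are identically ~0 and would break percent-of-control).
    """
    rec = ds.records
    is0 = rec["time_h"] == 0
    if not is0.any():
        raise PreprocessError(f"no 0-h baseline plates for endpoint {ds.endpoint}")
    vals = ds.layers[layer]
    key = ["well", "cell_line", "serum"]
    base = (
        pd.DataFrame({"value": vals[is0].to_numpy()}, index=rec.index[is0])
        .join(rec.loc[is0, key])
        .groupby(key, dropna=False)["value"]
        .median()
    )
    out = ds.copy()
    keys = pd.MultiIndex.from_frame(rec[key])
    baseline = pd.Series(base.reindex(keys).to_numpy(), index=rec.index)
    if mode == "subtract":
        corrected = vals - baseline
    elif mode == "ratio":
        corrected = vals / baseline
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out.layers[out_layer] = corrected
    if drop_baseline:
        keep = ~is0.to_numpy()
        out.records = out.records.loc[keep].reset_index(drop=True)
        out.layers = {
            name: pd.Series(s.to_numpy()[keep], index=out.records.index)
            for name, s in out.layers.items()
        }
    out.log("baseline_correct_0h", mode=mode, layer=layer, drop_baseline=drop_baseline)
    return out


def normalize_percent_of_control(
    ds: HTSDataset,
    layer: str,
    mode: str,
    out_layer: str = "normalized",
    iqr_multiplier: float = 1.5,
) -> tuple[HTSDataset, dict[str, ControlStats]]:
    """Percent-of-control normalization against plate-wise vehicle controls.

    For each plate, control values on ``layer`` are IQR-filtered and their
    median defines 100%.  Returns the dataset with the new layer plus the
    per-plate control statistics.
    """
    out = ds.copy()
    rec = out.records
    vals = out.layers[layer].to_numpy().astype(float)
    normalized = np.full_like(vals, np.nan)
    stats_by_plate: dict[str, ControlStats] = {}
    for plate, idx in rec.groupby("plate_id", sort=False).indices.items():
        idx = np.asarray(idx)
        ctrl_mask = rec["role"].to_numpy()[idx] == "control"
        ctrl_vals = vals[idx[ctrl_mask]]
        _, stats = iqr_filter_controls(
            ctrl_vals, scope=(plate, ds.endpoint), multiplier=iqr_multiplier
        )
        stats_by_plate[str(plate)] = stats
        normalized[idx] = percent_of_control(vals[idx], stats.median, mode=mode)
    out.layers[out_layer] = pd.Series(normalized, index=rec.index)
    out.log(
        "percent_of_control",
        mode=mode,
        layer=layer,
        iqr_multiplier=iqr_multiplier,
    )
    return out, stats_by_plate


def normalize_caspase_dataset(
    casp_ds: HTSDataset,
    ctg_ds: HTSDataset | None,
    dapi_ds: HTSDataset | None,
    layer: str = "normalized",
    out_layer: str = "normalized",
) -> HTSDataset:
    """Apply the cell-loss correction to a caspase dataset.

    The mean percent inhibition of the two viability endpoints (CTG and
    DAPI) per (material, dose, time, cell line, serum) estimates the cell
    loss; the caspase percent-effect values are divided by the surviving
    fraction.  Endpoints that are absent contribute nothing (their mean
    loss is taken as 0).
    """
    losses = []
    for ref in (ctg_ds, dapi_ds):
        if ref is None:
            continue
        df = ref.records[AGG_KEY].copy()
        df["value"] = ref.layers[layer].to_numpy()
        losses.append(df.groupby(AGG_KEY, dropna=False)["value"].mean())
    out = casp_ds.copy()
    if not losses:
        out.log("normalize_caspase", note="no viability endpoints available")
        return out
    mean_loss = sum(losses) / len(losses)
    keys = pd.MultiIndex.from_frame(out.records[AGG_KEY])
    loss = mean_loss.reindex(keys).to_numpy()
    loss = np.where(np.isfinite(loss), loss, 0.0)
    denom = 1.0 - loss / 100.0
    vals = out.layers[layer].to_numpy().astype(float)
    bad = denom <= 0
    if bad.any():
        warnings.warn(
            f"caspase normalization undefined for {int(bad.sum())} wells "
            "(mean cell loss >= 100%)",
            stacklevel=2,
        )
    corrected = np.where(bad, np.nan, vals / np.where(bad, np.nan, denom))
    out.layers[out_layer] = pd.Series(corrected, index=out.records.index)
    out.log("normalize_caspase", layer=layer, n_undefined=int(bad.sum()))
    return out


def pooled_control_stats(
    ds: HTSDataset,
    layer: str = "normalized",
    iqr_multiplier: float = 1.5,
) -> dict[tuple, ControlStats]:
    """Control statistics pooled over replicate plates.

    Keyed by (time_h, cell_line, serum) — the scope at which dose-response
    metrics compare treated wells against control conditions.
    """
    rec = ds.records
    vals = ds.layers[layer].to_numpy()
    out: dict[tuple, ControlStats] = {}
    ctrl = rec["role"] == "control"
    for key, grp in rec[ctrl].groupby(["time_h", "cell_line", "serum"], dropna=False):
        v = vals[grp.index]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        _, stats = iqr_filter_controls(v, scope=key, multiplier=iqr_multiplier)
        out[key] = stats
    return out


def standard_preprocess(
    datasets: dict[str, HTSDataset],
    dapi_threshold: float = 50.0,
    dapi_stat: str = "median",
    iqr_multiplier: float = 1.5,
    baseline_mode: str = "subtract",
) -> tuple[dict[str, HTSDataset], dict[str, dict[tuple, ControlStats]]]:
    """Run the default per-endpoint preprocessing recipe.

    1. imaging: average DAPI technical duplicates, apply the zero-DAPI
       cleaning rule, propagating to CASP/H2AX/8OHG;
    2. CTG (any endpoint with 0-h plates): baseline-correct against the
       0-h median, then percent of control (baseline-then-percent order);
    3. all endpoints: percent of plate-wise IQR-filtered controls —
       inhibition convention for CTG/DAPI, effect convention otherwise;
    4. CASP: divide by the surviving-cell fraction from CTG+DAPI;
    5. aggregate replicates by their median.

    Returns the processed datasets and per-endpoint pooled control
    statistics on the normalized scale (used by the dose-response stage).
    """
    datasets = clean_imaging_datasets(
        datasets, threshold=dapi_threshold, stat=dapi_stat
    )
    processed: dict[str, HTSDataset] = {}
    for ep, ds in datasets.items():
        layer = "clean" if "clean" in ds.layers else "raw"
        if (ds.records["time_h"] == 0).any():
            ds = baseline_correct_dataset(ds, layer=layer, mode=baseline_mode)
            layer = "baseline_corrected"
        mode = "inhibition" if ep in INHIBITION_ENDPOINTS else "effect"
        ds, _ = normalize_percent_of_control(
            ds, layer=layer, mode=mode, iqr_multiplier=iqr_multiplier
        )
        processed[ep] = ds
    if "CASP" in processed:
        processed["CASP"] = normalize_caspase_dataset(
            processed["CASP"], processed.get("CTG"), processed.get("DAPI")
        )
    control_stats: dict[str, dict[tuple, ControlStats]] = {}
    for ep, ds in processed.items():
        aggregate_replicates(ds, layer="normalized", stat="median")
        control_stats[ep] = pooled_control_stats(ds, iqr_multiplier=iqr_multiplier)
    return processed, control_stats
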