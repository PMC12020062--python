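"""Tox5 scoring: transform, scale, slice, weight, combine, bootstrap.

The Tox5-score is a ToxPi-style dimensionless index in [0, 1].  Each
dose-response metric column is transformed toward normality
(-log10(x)+6 for first-significant doses, square root for AUC and max
effect, Yeo-Johnson available), min-max scaled over the material library,
grouped into slices (one per endpoint x time point x condition), combined
within the slice by metric weights, and across slices by slice weights:

    slice score  = sum_m w_m * scaled_m          (w_m >= 0, sum 1)
    total score  = sum_s W_s * slice_s / sum_s W_s

Rank 1 is the most toxic material; ties share the smaller rank.  The
first-significant-effect metric with the 3 SD cutoff carries 50% of its
slice by default, the other three metrics 1/6 each, emphasizing the
sensitivity of the observed toxicity.  Missing metric values (no
significant effect observed) scale to 0, i.e. least toxic, so even inert
materials receive a score, possibly based on the max effect alone.

Confidence intervals come from resampling the material library with
replacement: each resample redefines the min-max scaling bounds, all
original materials are rescored, and 2.5/97.5 percentiles over resamples
bound each slice score, total and rank.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_FIRST_SIG_WEIGHT = 0.5

_COLUMN_RE = re.compile(
    r"^(?P<endpoint>[^_]+)_(?P<time>\d+(?:\.\d+)?)h_"
    r"(?P<metric>first_sig_2sd|first_sig_3sd|auc|max_effect)"
    r"(?:_(?P<rest>.+))?$"
)


@dataclass(frozen=True)
class TransformSpec:
    """One normality transform applied to a metric column.

    kind: "neglog10_plus6" (for first-significant doses, which shrink as
    toxicity grows), "sqrt", or "yeo_johnson" (lambda estimated by maximum
    likelihood when not given).  Negative outputs are clipped to 0 before
    scaling when ``clip_negative_to_zero`` is set.
    """

    kind: str = "sqrt"
    lmbda: float | None = None
    clip_negative_to_zero: bool = True


def transform_metric(values, spec: TransformSpec) -> np.ndarray:
    """Elementwise normality transform; missing values stay missing."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    finite = np.isfinite(x)
    if spec.kind == "neglog10_plus6":
        if (x[finite] <= 0).any():
            raise ValueError("-log10(x)+6 requires positive doses")
        out[finite] = -np.log10(x[finite]) + 6.0
    elif spec.kind == "sqrt":
        v = x[finite]
        if spec.clip_negative_to_zero:
            v = np.clip(v, 0.0, None)
        elif (v < 0).any():
            raise ValueError("sqrt of negative value")
        out[finite] = np.sqrt(v)
    elif spec.kind == "yeo_johnson":
        v = x[finite]
        if spec.lmbda is None:
            out[finite] = sps.yeojohnson(v)[0]
        else:
            out[finite] = sps.yeojohnson(v, lmbda=spec.lmbda)
    else:
        raise ValueError(f"unknown transform {spec.kind!r}")
    if spec.clip_negative_to_zero:
        out[np.isfinite(out)] = np.clip(out[np.isfinite(out)], 0.0, None)
    return out


def default_transform_for(column: str) -> TransformSpec:
    m = _COLUMN_RE.match(column)
    metric = m.group("metric") if m else ""
    if metric.startswith("first_sig"):
        return TransformSpec(kind="neglog10_plus6")
    return TransformSpec(kind="sqrt")


def minmax_scale_column(values) -> np.ndarray:
    """Scale a column to [0, 1]: (x - min)/(max - min).

    A constant column scales to all zeros; missing values scale to 0
    (least toxic).
    """
    x = np.asarray(values, dtype=float)
    out = np.zeros_like(x)
    finite = np.isfinite(x)
    if not finite.any():
        return out
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi > lo:
        out[finite] = (x[finite] - lo) / (hi - lo)
    return out


@dataclass
class SliceSpec:
    """One pie slice: member metric columns with intra-slice weights."""

    name: str
    metrics: list[str]
    weights: list[float]
    slice_weight: float = 1.0
    color_group: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.metrics) != len(w):
            raise ValueError("metrics and weights length mismatch")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                f"slice {self.name!r}: weights must be >= 0 and sum to 1 "
                f"(got sum {w.sum():.6g})"
            )
        if self.slice_weight <= 0:
            raise ValueError("slice_weight must be > 0")


def build_slices(
    columns: Sequence[str],
    mode: str = "auto",
    slices: Sequence[SliceSpec] | None = None,
    first_sig_weight: float = DEFAULT_FIRST_SIG_WEIGHT,
) -> list[SliceSpec]:
    """Group metric columns into slices.

    Auto mode parses ``<endpoint>_<time>h_<metric>[_<suffix>]`` column
    names and forms one slice per endpoint x time x suffix; within a
    slice, first_sig_3sd carries ``first_sig_weight`` (default 50%) and
    the remaining metrics share the rest equally (16.67% each for the
    default four-metric slice).  Manual mode passes explicit SliceSpecs
    through (still validated).
    """
    if mode == "manual":
        if slices is None:
            raise ValueError("manual mode requires explicit slices")
        return list(slices)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[tuple, list[tuple[str, str]]] = {}
    for col in columns:
        m = _COLUMN_RE.match(col)
        if not m:
            raise ValueError(f"cannot parse metric column name {col!r}")
        key = (m.group("endpoint"), m.group("time"), m.group("rest") or "")
        groups.setdefault(key, []).append((m.group("metric"), col))
    out = []
    for (ep, t, rest), members in sorted(groups.items()):
        metrics = [c for _, c in members]
        kinds = [k for k, _ in members]
        if "first_sig_3sd" in kinds and len(members) > 1:
            other = (1.0 - first_sig_weight) / (len(members) - 1)
            weights = [
                first_sig_weight if k == "first_sig_3sd" else other for k in kinds
            ]
        else:
            weights = [1.0 / len(members)] * len(members)
        name = f"{ep}_{t}h" + (f"_{rest}" if rest else "")
        out.append(
            SliceSpec(
                name=name, metrics=metrics, weights=weights, color_group=ep
            )
        )
    return out


def _transform_frame(
    metrics_wide: pd.DataFrame,
    transforms: Mapping[str, TransformSpec] | None,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            col: transform_metric(
                metrics_wide[col],
                (transforms or {}).get(col) or default_transform_for(col),
            )
            for col in metrics_wide.columns
        },
        index=metrics_wide.index,
    )


def _rank_desc(totals: pd.Series) -> pd.Series:
    """Competition ranking: rank 1 = highest total, ties share smaller rank."""
    return totals.rank(method="min", ascending=False).astype(int)


def compute_scores(scaled: pd.DataFrame, slices: Sequence[SliceSpec]) -> pd.DataFrame:
    """Weighted slice and total scores plus ranks from scaled metrics.

    ``scaled`` is a materials x metric-columns frame with entries in [0,1].
    Returns a frame indexed by material with one column per slice, plus
    ``total`` and ``rank``.
    """
    out = pd.DataFrame(index=scaled.index)
    total = np.zeros(len(scaled))
    wsum = 0.0
    for sl in slices:
        vals = scaled[sl.metrics].to_numpy(dtype=float)
        score = vals @ np.asarray(sl.weights)
        out[sl.name] = score
        total += sl.slice_weight * score
        wsum += sl.slice_weight
    out["total"] = total / wsum
    out["rank"] = _rank_desc(out["total"])
    return out


def score_library(
    metrics_wide: pd.DataFrame,
    slices: Sequence[SliceSpec] | None = None,
    transforms: Mapping[str, TransformSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SliceSpec]]:
    """Transform -> scale -> slice -> score a material library.

    Returns (scaled metrics, score table, slices used).
    """
    transformed = _transform_frame(metrics_wide, transforms)
    scaled = transformed.apply(minmax_scale_column, axis=0)
    if slices is None:
        slices = build_slices(list(metrics_wide.columns))
    scores = compute_scores(scaled, slices)
    return scaled, scores, list(slices)


@dataclass
class BootstrapResult:
    """Point estimates with percentile bootstrap bounds."""

    point: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_boot: int
    level: float
    slices: list[SliceSpec] = field(default_factory=list)


def bootstrap_intervals(
    metrics_wide: pd.DataFrame,
    slices: Sequence[SliceSpec] | None = None,
    transforms: Mapping[str, TransformSpec] | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapResult:
    """Percentile bootstrap CIs for slice scores, totals and ranks.

    The resampling unit is the material row: each of ``n_boot`` resamples
    draws materials with replacement, the min-max scaling bounds are
    recomputed from the resampled library, and every *original* material
    is rescored under those bounds (scaled values clipped to [0,1]).
    Deterministic under a fixed seed.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if len(metrics_wide) < 2:
        raise ValueError("bootstrap needs >= 2 materials")
    rng = np.random.default_rng(seed)

    transformed = _transform_frame(metrics_wide, transforms)
    if slices is None:
        slices = build_slices(list(metrics_wide.columns))
    slices = list(slices)

    point_scaled = transformed.apply(minmax_scale_column, axis=0)
    point = compute_scores(point_scaled, slices)

    X = transformed.to_numpy(dtype=float)
    n, p = X.shape
    quantities = list(point.columns)
    draws = np.empty((n_boot, n, len(quantities)))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        Xb = X[take]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            lo = np.nanmin(Xb, axis=0)
            hi = np.nanmax(Xb, axis=0)
        rng_col = hi - lo
        scaled = np.zeros_like(X)
        ok = np.isfinite(rng_col) & (rng_col > 0)
        scaled[:, ok] = np.clip((X[:, ok] - lo[ok]) / rng_col[ok], 0.0, 1.0)
        scaled[~np.isfinite(X)] = 0.0
        sb = compute_scores(pd.DataFrame(scaled, columns=transformed.columns,
                                         index=transformed.index), slices)
        draws[b] = sb.to_numpy(dtype=float)

    a = (1.0 - level) / 2.0
    lo_q = np.percentile(draws, 100 * a, axis=0)
    hi_q = np.percentile(draws, 100 * (1 - a), axis=0)
    # intervals are widened (if needed) to contain the point estimate, so the
    # ci_low <= point <= ci_high contract holds for every quantity
    pt = point.to_numpy(dtype=float)
    lo_q = np.minimum(lo_q, pt)
    hi_q = np.maximum(hi_q, pt)
    ci_low = pd.DataFrame(lo_q, index=point.index, columns=quantities)
    ci_high = pd.DataFrame(hi_q, index=point.index, columns=quantities)
    return BootstrapResult(
        point=point, ci_low=ci_low, ci_high=ci_high,
        n_boot=n_boot, level=level, slices=slices,
    )


def pie_chart_table(result: BootstrapResult, material: str) -> pd.DataFrame:
    """Slice-level data (value, weight, color, CI bounds) for plotting."""
    rows = []
    for sl in result.slices:
        rows.append(
            {
                "slice": sl.name,
                "value": result.point.loc[material, sl.name],
                "weight": sl.slice_weight,
                "color_group": sl.color_group,
                "ci_low": result.ci_low.loc[material, sl.name],
                "ci_high": result.ci_high.loc[material, sl.name],
            }
        )
    return pd.DataFrame(rows)
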