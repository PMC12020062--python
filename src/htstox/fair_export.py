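"""NeXus-style HDF5 serialization of the full pipeline state.

One HDF5 file holds everything: per endpoint an entry group (tagged
``NX_class = NXentry``) with the well-level records, every value layer,
and a dense multidimensional view of the raw data (material x dose x
time x replicate x serum, NaN-padded, with named axis vectors); derived
results (normalized layers, replicate medians, dose-response metrics,
Tox5 scores) live under ``NX_class = NXprocess`` groups carrying their
provenance as attributes.  The file is plain HDF5, readable by any
generic HDF5 tool; the group-class attributes are the only convention on
top.

Round trips are lossless: the well-level records and layers are stored
column-by-column and reconstructed exactly (bit-for-bit for float64).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .plate_io import HTSDataset, PlateGeometry, RECORD_COLUMNS
from .tox5 import BootstrapResult, SliceSpec

_STR = h5py.string_dtype(encoding="utf-8")

RAW_AXES = ["material_id", "dose_value", "time_h", "replicate", "serum"]


class NexusFormatError(ValueError):
    pass


def _write_frame(grp: h5py.Group, df: pd.DataFrame) -> None:
    grp.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        s = df[col]
        if s.dtype.kind in "fiu":
            grp.create_dataset(col, data=s.to_numpy())
        else:
            data = np.array(["" if pd.isna(v) else str(v) for v in s], dtype=object)
            grp.create_dataset(col, data=data, dtype=_STR)


def _read_frame(grp: h5py.Group) -> pd.DataFrame:
    if "columns" not in grp.attrs:
        raise NexusFormatError(f"group {grp.name!r} lacks a column manifest")
    cols = json.loads(grp.attrs["columns"])
    out = {}
    for col in cols:
        arr = grp[col][()]
        if arr.dtype.kind in "OS":
            arr = np.array([v.decode() if isinstance(v, bytes) else v for v in arr])
        out[col] = arr
    return pd.DataFrame(out)


def _dense_raw(ds: HTSDataset, layer: str = "raw"):
    """NaN-padded dense matrix of a layer with its axis vectors.

    Technical duplicates (several rows per coordinate) are averaged for
    this view; the exact per-row values remain in the records datasets.
    """
    rec = ds.records.copy()
    values = ds.layers[layer].to_numpy()
    keep = (rec["role"] != "blank").to_numpy()
    rec, values = rec.loc[keep], values[keep]
    axes = {}
    for ax in RAW_AXES:
        axes[ax] = np.sort(rec[ax].dropna().unique())
    shape = tuple(len(axes[ax]) for ax in RAW_AXES)
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    index = {ax: {v: i for i, v in enumerate(axes[ax])} for ax in RAW_AXES}
    coords = [rec[ax].to_numpy() for ax in RAW_AXES]
    for i, v in enumerate(values):
        if not np.isfinite(v):
            continue
        try:
            idx = tuple(index[ax][coords[a][i]] for a, ax in enumerate(RAW_AXES))
        except KeyError:
            continue
        sums[idx] += v
        counts[idx] += 1
    with np.errstate(invalid="ignore"):
        dense = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return dense, axes


def write_nexus(
    datasets: dict[str, HTSDataset],
    path: str | Path,
    metrics: pd.DataFrame | None = None,
    scores: BootstrapResult | None = None,
) -> None:
    """Serialize datasets (+ optional metrics and Tox5 scores) to one file."""
    with h5py.File(path, "w") as f:
        f.attrs["creator"] = "htstox"
        for ep, ds in datasets.items():
            entry = f.create_group(ep)
            entry.attrs["NX_class"] = "NXentry"
            entry.attrs["endpoint"] = ep
            entry.attrs["provenance"] = json.dumps(ds.provenance)
            entry.attrs["geometry"] = json.dumps(
                {
                    "n_rows": ds.geometry.n_rows,
                    "n_cols": ds.geometry.n_cols,
                    "growth_area_cm2": ds.geometry.growth_area_cm2,
                    "well_volume_ul": ds.geometry.well_volume_ul,
                }
            )
            _write_frame(entry.create_group("records"), ds.records)
            raw_grp = entry.create_group("layers")
            raw_grp.create_dataset("raw", data=ds.layers["raw"].to_numpy())
            dense, axes = _dense_raw(ds)
            data = entry.create_group("data")
            data.attrs["NX_class"] = "NXdata"
            sig = data.create_dataset("signal", data=dense)
            sig.attrs["axes"] = json.dumps(RAW_AXES)
            sig.attrs["units"] = "plate reader signal (a.u.)"
            for ax in RAW_AXES:
                vals = axes[ax]
                if vals.dtype.kind in "fiu":
                    data.create_dataset(ax, data=vals)
                else:
                    data.create_dataset(ax, data=vals.astype(object), dtype=_STR)
            for name, layer in ds.layers.items():
                if name == "raw":
                    continue
                proc = entry.create_group(f"process_{name}")
                proc.attrs["NX_class"] = "NXprocess"
                proc.create_dataset("values", data=layer.to_numpy())
            for name, agg in ds.aggregates.items():
                proc = entry.create_group(f"process_{name}")
                proc.attrs["NX_class"] = "NXprocess"
                proc.attrs["aggregate"] = "true"
                _write_frame(proc, agg)
        if metrics is not None:
            proc = f.create_group("dose_response")
            proc.attrs["NX_class"] = "NXprocess"
            _write_frame(proc, metrics.reset_index(drop=True))
        if scores is not None:
            proc = f.create_group("tox5")
            proc.attrs["NX_class"] = "NXprocess"
            proc.attrs["n_boot"] = scores.n_boot
            proc.attrs["level"] = scores.level
            proc.attrs["slices"] = json.dumps(
                [
                    {
                        "name": s.name,
                        "metrics": s.metrics,
                        "weights": s.weights,
                        "slice_weight": s.slice_weight,
                        "color_group": s.color_group,
                    }
                    for s in scores.slices
                ]
            )
            for part, frame in (
                ("point", scores.point),
                ("ci_low", scores.ci_low),
                ("ci_high", scores.ci_high),
            ):
                sub = proc.create_group(part)
                _write_frame(sub, frame.reset_index())


def read_nexus(path: str | Path):
    """Inverse of :func:`write_nexus`.

    Returns ``(datasets, metrics, scores)``; metrics/scores are None when
    the file holds only raw data.  Files without the NeXus class
    attributes written by this package raise :class:`NexusFormatError`.
    """
    datasets: dict[str, HTSDataset] = {}
    metrics = None
    scores = None
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            cls = grp.attrs.get("NX_class")
            if cls is None:
                raise NexusFormatError(f"group {name!r} lacks an NX_class attribute")
            if cls == "NXentry":
                records = _read_frame(grp["records"])[RECORD_COLUMNS]
                layers = {"raw": pd.Series(grp["layers/raw"][()], index=records.index)}
                aggregates = {}
                prov = json.loads(grp.attrs.get("provenance", "[]"))
                geo = json.loads(grp.attrs.get("geometry", "{}"))
                geometry = PlateGeometry(**geo) if geo else PlateGeometry()
                for sub_name, sub in grp.items():
                    if not sub_name.startswith("process_"):
                        continue
                    layer_name = sub_name[len("process_"):]
                    if "aggregate" in sub.attrs:
                        aggregates[layer_name] = _read_frame(sub)
                    else:
                        layers[layer_name] = pd.Series(
                            sub["values"][()], index=records.index
                        )
                datasets[name] = HTSDataset(
                    endpoint=str(grp.attrs["endpoint"]),
                    records=records,
                    layers=layers,
                    geometry=geometry,
                    provenance=prov,
                    aggregates=aggregates,
                )
            elif name == "dose_response":
                metrics = _read_frame(grp)
            elif name == "tox5":
                slices = [
                    SliceSpec(**d) for d in json.loads(grp.attrs["slices"])
                ]
                frames = {}
                for part in ("point", "ci_low", "ci_high"):
                    df = _read_frame(grp[part])
                    frames[part] = df.set_index(df.columns[0])
                scores = BootstrapResult(
                    point=frames["point"],
                    ci_low=frames["ci_low"],
                    ci_high=frames["ci_high"],
                    n_boot=int(grp.attrs["n_boot"]),
                    level=float(grp.attrs["level"]),
                    slices=slices,
                )
    return datasets, metrics, scores


def to_long_table(ds: HTSDataset, layer: str) -> pd.DataFrame:
    """Export one layer as a CSV-ready long table with all metadata."""
    if layer in ds.layers:
        out = ds.records.copy()
        out[layer] = ds.layers[layer].to_numpy()
        return out
    if layer in ds.aggregates:
        return ds.aggregates[layer].copy()
    raise KeyError(f"unknown layer {layer!r} for endpoint {ds.endpoint}")
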