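"""Reading raw plate files and the annotation workbook.

Raw data arrive as one file per 384-well plate: plate-reader luminescence
tables (CSV, a 16x24 numeric grid, possibly preceded by header lines) and
imaging well summaries (tab-separated ``well<TAB>endpoint<TAB>value`` rows,
several endpoints per file, DAPI present twice per well as technical
duplicates).  An annotation workbook supplies the plate layout ("Front
sheet": well -> material/dose/role), per-file metadata ("Files": endpoint,
time, replicate, cell line, serum, auto-filled from filenames) and material
properties ("Materials": display name, optional ERM identifier, optional
BET specific surface area in m2/g).

Everything is combined into one long-format :class:`HTSDataset` per
endpoint, carrying the full experimental coordinates for every well.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: canonical record columns of an HTSDataset, in order
RECORD_COLUMNS = [
    "plate_id",
    "well",
    "endpoint",
    "time_h",
    "cell_line",
    "replicate",
    "serum",
    "material_id",
    "dose_value",
    "dose_unit",
    "role",
]


class FormatError(ValueError):
    """A raw file does not match the declared dialect."""


class AnnotationError(ValueError):
    """A file or well cannot be resolved through the annotation template."""


# ---------------------------------------------------------------------------
# label harmonization
# ---------------------------------------------------------------------------

#: default harmonization dictionary: squashed-uppercase key -> canonical label.
#: Inconsistent naming (HepG2 / HEPG2 / HEP-G2) is a recurring blocker for
#: machine-readable HTS metadata, so readers canonicalize through this map.
DEFAULT_SYNONYMS: dict[str, str] = {
    # cell lines
    "HEPG2": "HepG2",
    "BEAS2B": "BEAS-2B",
    "A549": "A549",
    "THP1": "THP-1",
    "DTHP1": "dTHP-1",
    # endpoints
    "CTG": "CTG",
    "CELLTITERGLO": "CTG",
    "ATP": "CTG",
    "DAPI": "DAPI",
    "CELLCOUNT": "DAPI",
    "CASP": "CASP",
    "CASPASE": "CASP",
    "CASPASE3": "CASP",
    "CASP3": "CASP",
    "CASPGLO": "CASP",
    "CASPGLO37": "CASP",
    "H2AX": "H2AX",
    "GAMMAH2AX": "H2AX",
    "GH2AX": "H2AX",
    "YH2AX": "H2AX",
    "PH2AX": "H2AX",
    "8OHG": "8OHG",
    "OHG": "8OHG",
}

#: canonical labels that name measurement endpoints
ENDPOINT_LABELS = {"CTG", "DAPI", "CASP", "H2AX", "8OHG"}
#: canonical labels that name cell lines
CELL_LINE_LABELS = {"HepG2", "BEAS-2B", "A549", "THP-1", "dTHP-1"}

_SERUM_TOKENS = {
    "SERUM": "with",
    "FBS": "with",
    "PLUSFBS": "with",
    "WITHSERUM": "with",
    "NOSERUM": "without",
    "NOFBS": "without",
    "MINUSFBS": "without",
    "SERUMFREE": "without",
    "WITHOUTSERUM": "without",
}


def _squash(label: str) -> str:
    """Case/punctuation-insensitive key for harmonization lookups."""
    return re.sub(r"[^0-9A-Za-z]", "", str(label)).upper()


def canonicalize(label: str, table: Mapping[str, str] | None = None) -> str:
    """Map a label to its canonical spelling.

    Lookup is insensitive to case and punctuation ("HEP-G2", "hepg2" and
    "HepG2" all map to "HepG2").  Unknown labels pass through unchanged, so
    the operation is idempotent.
    """
    if table is None:
        table = DEFAULT_SYNONYMS
    return table.get(_squash(label), label)


# ---------------------------------------------------------------------------
# well addressing
# ---------------------------------------------------------------------------

def parse_well(label: str) -> tuple[int, int]:
    """``"A01"`` or ``"A1"`` -> 0-based ``(row, col)`` inside the 16x24 grid."""
    m = re.fullmatch(r"([A-Pa-p])0*([1-9]\d?)", str(label).strip())
    if not m:
        raise FormatError(f"not a valid 384-well address: {label!r}")
    row = ROW_LETTERS.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if not 0 <= col < 24:
        raise FormatError(f"column out of range in well {label!r}")
    return row, col


def format_well(row: int, col: int) -> str:
    """0-based ``(row, col)`` -> compact well label like ``"A1"``."""
    if not (0 <= row < 16 and 0 <= col < 24):
        raise FormatError(f"(row={row}, col={col}) outside 16x24 geometry")
    return f"{ROW_LETTERS[row]}{col + 1}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateGeometry:
    """Physical geometry of one 384-well assay plate.

    ``growth_area_cm2`` is the cell growth area of a single well (0.1 cm2
    for Greiner u-clear #781091, 0.0795 cm2 for Corning #3771) and
    ``well_volume_ul`` the assay volume per well.
    """

    n_rows: int = 16
    n_cols: int = 24
    growth_area_cm2: float = 0.1
    well_volume_ul: float = 50.0

    def __post_init__(self) -> None:
        if self.growth_area_cm2 <= 0:
            raise ValueError("growth_area_cm2 must be > 0")
        if self.well_volume_ul <= 0:
            raise ValueError("well_volume_ul must be > 0")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class FileMeta:
    """Per-file metadata, auto-filled from the filename and hand-corrected."""

    filename: str
    endpoint: str = ""
    time_h: float | None = None
    replicate: int | None = None
    cell_line: str = ""
    serum: str = ""

    def is_complete(self, require_endpoint: bool = True) -> bool:
        ok = self.time_h is not None and self.replicate is not None
        if require_endpoint:
            ok = ok and bool(self.endpoint)
        return ok


@dataclass
class AnnotationTemplate:
    """In-memory view of the annotation workbook.

    front_sheet: columns ``well, material_id, dose_value, dose_unit, role``
    files_sheet: columns ``filename, endpoint, time_h, replicate, cell_line, serum``
    materials_sheet: columns ``material_id, name, erm_id, sbet_m2g``
    """

    front_sheet: pd.DataFrame
    files_sheet: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["filename", "endpoint", "time_h", "replicate", "cell_line", "serum"]
        )
    )
    materials_sheet: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["material_id", "name", "erm_id", "sbet_m2g"]
        )
    )

    def file_meta(self, filename: str) -> FileMeta:
        rows = self.files_sheet[self.files_sheet["filename"] == filename]
        if len(rows) == 0:
            raise AnnotationError(f"no Files-sheet entry for raw file {filename!r}")
        if len(rows) > 1:
            raise AnnotationError(f"duplicate Files-sheet entries for {filename!r}")
        r = rows.iloc[0]
        t = r["time_h"]
        rep = r["replicate"]
        return FileMeta(
            filename=filename,
            endpoint="" if pd.isna(r["endpoint"]) else str(r["endpoint"]),
            time_h=None if pd.isna(t) else float(t),
            replicate=None if pd.isna(rep) else int(rep),
            cell_line="" if pd.isna(r["cell_line"]) else str(r["cell_line"]),
            serum="" if pd.isna(r["serum"]) else str(r["serum"]),
        )

    def front_lookup(self) -> dict[str, dict]:
        out = {}
        for _, r in self.front_sheet.iterrows():
            row, col = parse_well(r["well"])
            out[format_well(row, col)] = {
                "material_id": "" if pd.isna(r["material_id"]) else str(r["material_id"]),
                "dose_value": float(r["dose_value"]) if not pd.isna(r["dose_value"]) else np.nan,
                "dose_unit": "" if pd.isna(r["dose_unit"]) else str(r["dose_unit"]),
                "role": str(r["role"]),
            }
        return out

    def sbet_lookup(self) -> dict[str, float]:
        out = {}
        for _, r in self.materials_sheet.iterrows():
            if "sbet_m2g" in r and not pd.isna(r["sbet_m2g"]):
                out[str(r["material_id"])] = float(r["sbet_m2g"])
        return out

    # -- workbook round trip ------------------------------------------------

    SHEET_FRONT = "Front sheet"
    SHEET_FILES = "Files"
    SHEET_MATERIALS = "Materials"

    def to_workbook(self, path: str | Path) -> None:
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            self.front_sheet.to_excel(xl, sheet_name=self.SHEET_FRONT, index=False)
            self.files_sheet.to_excel(xl, sheet_name=self.SHEET_FILES, index=False)
            self.materials_sheet.to_excel(xl, sheet_name=self.SHEET_MATERIALS, index=False)

    @classmethod
    def from_workbook(cls, path: str | Path) -> "AnnotationTemplate":
        front = pd.read_excel(path, sheet_name=cls.SHEET_FRONT)
        files = pd.read_excel(path, sheet_name=cls.SHEET_FILES)
        mats = pd.read_excel(path, sheet_name=cls.SHEET_MATERIALS)
        for col in ("material_id", "dose_unit", "role"):
            if col in front:
                front[col] = front[col].where(~front[col].isna(), "")
        return cls(front_sheet=front, files_sheet=files, materials_sheet=mats)


@dataclass
class HTSDataset:
    """Per-endpoint container of layered well-level data.

    ``records`` is a long-format table with one row per measured well (DAPI
    technical duplicates are separate rows until averaged).  ``layers`` maps
    layer names ("raw", "normalized", ...) to value Series aligned 1:1 with
    ``records``.  Replicate-aggregated results live in ``aggregates`` keyed
    by (material, dose, time, cell line, serum).  ``provenance`` is an
    append-only log of applied operations with their parameters.
    """

    endpoint: str
    records: pd.DataFrame
    layers: dict[str, pd.Series]
    geometry: PlateGeometry = field(default_factory=PlateGeometry)
    provenance: list[dict] = field(default_factory=list)
    aggregates: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.layers.items():
            if not s.index.equals(self.records.index):
                raise ValueError(f"layer {name!r} not aligned with records")

    def log(self, op: str, **params) -> None:
        self.provenance.append({"op": op, "params": params})

    def copy(self) -> "HTSDataset":
        return HTSDataset(
            endpoint=self.endpoint,
            records=self.records.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
            geometry=self.geometry,
            provenance=list(self.provenance),
            aggregates={k: v.copy() for k, v in self.aggregates.items()},
        )

    @property
    def n_records(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# filename parsing / files-sheet auto-fill
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"^(\d+(?:\.\d+)?)[hH]$")
_REP_RE = re.compile(r"^[Rr](?:ep)?(\d+)$")


def parse_raw_filename(
    filename: str,
    synonyms: Mapping[str, str] | None = None,
) -> FileMeta:
    """Recognize metadata tokens in a raw-data filename.

    The default dialect splits the stem on ``_``/``-``/whitespace and
    recognizes, in any order: an endpoint label (via the harmonization
    dictionary), a time token like ``24h``, a replicate token like ``R2``,
    a cell-line label, and a serum token (``serum``/``noserum``,
    ``FBS``/``noFBS``).  Unrecognized tokens are ignored and the
    corresponding fields left empty, to be corrected manually in the
    template.  Imaging files carry several endpoints, so their endpoint
    field legitimately stays empty.
    """
    if not filename:
        raise ValueError("filename must be non-empty")
    stem = Path(filename).stem
    meta = FileMeta(filename=filename)
    # hyphens stay inside tokens: cell-line names like HEP-G2 carry them
    for token in re.split(r"[_\s]+", stem):
        if not token:
            continue
        m = _TIME_RE.match(token)
        if m and meta.time_h is None:
            meta.time_h = float(m.group(1))
            continue
        m = _REP_RE.match(token)
        if m and meta.replicate is None:
            meta.replicate = int(m.group(1))
            continue
        canon = canonicalize(token, synonyms)
        if canon in ENDPOINT_LABELS and not meta.endpoint:
            meta.endpoint = canon
            continue
        if canon in CELL_LINE_LABELS and not meta.cell_line:
            meta.cell_line = canon
            continue
        serum = _SERUM_TOKENS.get(_squash(token))
        if serum and not meta.serum:
            meta.serum = serum
    return meta


def autofill_files_sheet(
    filenames: Sequence[str],
    template: AnnotationTemplate,
    synonyms: Mapping[str, str] | None = None,
) -> AnnotationTemplate:
    """Populate the Files sheet from filenames, preserving manual edits.

    One row per filename; rows already present (matched by filename) are
    never overwritten, so re-running on a filled sheet is the identity.
    Duplicate filenames in the input are an error.
    """
    names = list(filenames)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise AnnotationError(f"duplicate filenames in input: {dupes}")
    existing = set(template.files_sheet["filename"].astype(str))
    new_rows = []
    for name in names:
        if name in existing:
            continue
        meta = parse_raw_filename(name, synonyms)
        new_rows.append(
            {
                "filename": name,
                "endpoint": meta.endpoint,
                "time_h": meta.time_h,
                "replicate": meta.replicate,
                "cell_line": meta.cell_line,
                "serum": meta.serum,
            }
        )
    files = template.files_sheet
    if new_rows:
        add = pd.DataFrame(new_rows)
        files = add if files.empty else pd.concat([files, add], ignore_index=True)
    return replace(template, files_sheet=files)


# ---------------------------------------------------------------------------
# raw file readers
# ---------------------------------------------------------------------------

def _try_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return np.nan
    try:
        return float(cell)
    except ValueError:
        return None


def read_plate_reader_table(path: str | Path) -> tuple[np.ndarray, str]:
    """Read one plate-reader CSV into a 16x24 grid.

    Dialect: optional header lines (any line whose fields are not all
    numeric-or-empty), then exactly 16 rows of 24 comma-separated numeric
    cells; an empty cell is a missing value.  Returns ``(grid, plate_id)``
    where ``plate_id`` is the filename stem.
    """
    path = Path(path)
    data_rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(c.strip() == "" for c in row):
                continue
            vals = [_try_float(c) for c in row]
            if any(v is None for v in vals):
                if data_rows:
                    raise FormatError(
                        f"{path.name}: non-numeric cell on line {lineno} "
                        f"inside the data block"
                    )
                continue  # header line before the grid
            if len(vals) != 24:
                raise FormatError(
                    f"{path.name}: line {lineno} has {len(vals)} columns, expected 24"
                )
            data_rows.append(vals)  # type: ignore[arg-type]
    if len(data_rows) != 16:
        raise FormatError(
            f"{path.name}: found {len(data_rows)} data rows, expected 16"
        )
    grid = np.asarray(data_rows, dtype=float)
    return grid, path.stem


def read_imaging_table(
    path: str | Path,
    synonyms: Mapping[str, str] | None = None,
) -> list[tuple[str, str, float]]:
    """Read one imaging well-summary TXT into ``(well, endpoint, value)`` rows.

    Tab-separated columns: well address, endpoint label, well-median
    intensity.  Endpoint labels are canonicalized; an unknown label is
    passed through with a warning.  DAPI technical duplicates appear as
    two separate rows per well and are preserved.
    """
    path = Path(path)
    out: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path.name}: line {lineno} has {len(parts)} fields, expected 3"
                )
            well_raw, label, value_raw = parts[0], parts[1], parts[2]
            value = _try_float(value_raw)
            if value is None:
                if lineno == 1:
                    continue  # header line
                raise FormatError(f"{path.name}: non-numeric value on line {lineno}")
            row, col = parse_well(well_raw)
            canon = canonicalize(label, synonyms)
            if canon not in ENDPOINT_LABELS:
                warnings.warn(
                    f"{path.name}: unknown endpoint label {label!r} passed through",
                    stacklevel=2,
                )
            out.append((format_well(row, col), canon, value))
    return out


# ---------------------------------------------------------------------------
# annotation: combine raw files + template into per-endpoint datasets
# ---------------------------------------------------------------------------

def annotate_dataset(
    plate_grids: Mapping[str, np.ndarray] | None,
    imaging_tables: Mapping[str, list[tuple[str, str, float]]] | None,
    template: AnnotationTemplate,
    geometry: PlateGeometry | None = None,
) -> dict[str, HTSDataset]:
    """Combine raw grids/imaging rows with the template into HTSDatasets.

    ``plate_grids`` maps filename -> 16x24 grid (plate-reader endpoints,
    endpoint taken from the Files sheet); ``imaging_tables`` maps filename
    -> rows from :func:`read_imaging_table` (endpoint per row).  Every file
    must resolve to a Files-sheet entry and every well to a Front-sheet
    entry; violations raise :class:`AnnotationError` naming the culprit.
    Returns one dataset per endpoint with the ``raw`` layer populated and
    provenance initialized.
    """
    geometry = geometry or PlateGeometry()
    front = template.front_lookup()
    per_endpoint: dict[str, list[dict]] = {}

    def well_entry(filename: str, well: str) -> dict:
        entry = front.get(well)
        if entry is None:
            raise AnnotationError(
                f"well {well} of plate {filename!r} has no Front-sheet entry"
            )
        return entry

    def base_record(meta: FileMeta, well: str, entry: dict, value: float) -> dict:
        role = entry["role"]
        dose = entry["dose_value"]
        if role == "control":
            dose = 0.0
        return {
            "plate_id": Path(meta.filename).stem,
            "well": well,
            "time_h": meta.time_h,
            "cell_line": meta.cell_line,
            "replicate": meta.replicate,
            "serum": meta.serum or "NA",
            "material_id": entry["material_id"],
            "dose_value": dose,
            "dose_unit": entry["dose_unit"],
            "role": role,
            "value": value,
        }

    for filename, grid in (plate_grids or {}).items():
        meta = template.file_meta(filename)
        if not meta.endpoint:
            raise AnnotationError(
                f"plate-reader file {filename!r} has no endpoint in the Files sheet"
            )
        if grid.shape != (geometry.n_rows, geometry.n_cols):
            raise FormatError(
                f"{filename!r}: grid shape {grid.shape} != "
                f"({geometry.n_rows}, {geometry.n_cols})"
            )
        for row in range(geometry.n_rows):
            for col in range(geometry.n_cols):
                well = format_well(row, col)
                rec = base_record(meta, well, well_entry(filename, well), grid[row, col])
                rec["endpoint"] = meta.endpoint
                per_endpoint.setdefault(meta.endpoint, []).append(rec)

    for filename, rows in (imaging_tables or {}).items():
        meta = template.file_meta(filename)
        for well, endpoint, value in rows:
            rec = base_record(meta, well, well_entry(filename, well), value)
            rec["endpoint"] = endpoint
            per_endpoint.setdefault(endpoint, []).append(rec)

    out: dict[str, HTSDataset] = {}
    for endpoint, recs in per_endpoint.items():
        df = pd.DataFrame(recs)
        raw = df.pop("value")
        df = df[RECORD_COLUMNS].reset_index(drop=True)
        raw.index = df.index
        ds = HTSDataset(endpoint=endpoint, records=df, layers={"raw": raw}, geometry=geometry)
        ds.log("annotate_dataset", n_records=len(df))
        out[endpoint] = ds
    return out


def ingest_directory(
    raw_dir: str | Path,
    template: AnnotationTemplate | str | Path | None = None,
    geometry: PlateGeometry | None = None,
) -> dict[str, HTSDataset]:
    """Read every raw file in a directory and annotate it.

    CSV files are treated as plate-reader grids, TXT files as imaging
    tables.  ``template`` may be an :class:`AnnotationTemplate` or a path
    to the workbook; by default ``HTS_METADATA.xlsx`` inside ``raw_dir``
    is used.
    """
    raw_dir = Path(raw_dir)
    if template is None:
        template = raw_dir / "HTS_METADATA.xlsx"
    if not isinstance(template, AnnotationTemplate):
        template = AnnotationTemplate.from_workbook(template)
    known = set(template.files_sheet["filename"].astype(str))
    grids, imaging = {}, {}
    for path in sorted(raw_dir.iterdir()):
        if path.name not in known:
            continue
        if path.suffix.lower() == ".csv":
            grids[path.name] = read_plate_reader_table(path)[0]
        elif path.suffix.lower() == ".txt":
            imaging[path.name] = read_imaging_table(path)
    return annotate_dataset(grids, imaging, template, geometry)
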