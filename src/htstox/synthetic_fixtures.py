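"""Synthetic HTS campaigns with known ground truth.

Generates complete raw-data trees — plate-reader CSVs, imaging TXTs (with
DAPI technical duplicates), a filled annotation workbook and a truth
manifest — with the statistical structure the pipeline assumes, so every
stage is testable without real screening data.

The default design mirrors a five-endpoint 384-well campaign: CTG at
0/6/24/72 h (the 0-h plates serve as viability baseline), imaging
endpoints (DAPI, CASP, H2AX, 8OHG) at 6/24/72 h, four biological
replicates, a twelve-dose 2-fold dilution series from 256 ug/ml, screens
with and without serum, and vehicle-control wells on every plate.

Dose-response truth follows a Hill curve on the percent-effect scale,

    effect(d, t) = top * g(t) * d^h / (ec50^h + d^h),

with a saturating time factor g(t).  Signals include exponential control
growth (so 0-h baseline subtraction is meaningful), per-plate effect
multipliers, homoscedastic Gaussian noise on the plate-reader scale, and
injected artifacts: control outliers, focus failures (DAPI = 0 with
healthy replicates, which must become NaN downstream) and dead-well
blocks (DAPI = 0 in all replicates, which must stay 0).  The Hill family
is a fixture-only choice: any monotone dose-response family would do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_io import (
    AnnotationTemplate,
    PlateGeometry,
    autofill_files_sheet,
    format_well,
)

ENDPOINTS = ("CTG", "DAPI", "CASP", "H2AX", "8OHG")
IMAGING_ENDPOINTS = ("DAPI", "CASP", "H2AX", "8OHG")

#: measured signal level of an untreated well at seeding time, per endpoint
CONTROL_LEVEL = {"CTG": 1e5, "DAPI": 1200.0, "CASP": 500.0, "H2AX": 200.0, "8OHG": 200.0}


@dataclass(frozen=True)
class CampaignDesign:
    """Experimental design of one synthetic screening campaign."""

    endpoints: tuple[str, ...] = ENDPOINTS
    times_ctg: tuple[float, ...] = (0.0, 6.0, 24.0, 72.0)
    times_imaging: tuple[float, ...] = (6.0, 24.0, 72.0)
    n_replicates: int = 4
    doses_ugml: tuple[float, ...] = tuple(256.0 / 2**k for k in range(12))
    serum: tuple[str, ...] = ("with", "without")
    cell_line: str = "BEAS-2B"
    geometry: PlateGeometry = field(default_factory=PlateGeometry)
    control_cols: tuple[int, ...] = (12, 13)  # 0-based columns of vehicle wells

    @property
    def n_doses(self) -> int:
        return len(self.doses_ugml)


@dataclass
class MaterialTruth:
    """Hill parameters of one material (shared shape across endpoints)."""

    material_id: str
    ec50_ugml: float
    hill: float = 2.0
    top: dict[str, float] = field(default_factory=dict)  # max % effect per endpoint
    bottom: float = 0.0
    interference_0h: float = 0.0  # fractional CTG signal offset at 0 h

    def effect(self, endpoint: str, dose: float, time_h: float) -> float:
        """True percent effect at a dose and time (0 at dose 0)."""
        if dose <= 0:
            return 0.0
        tf = _time_factor(time_h)
        top = self.top.get(endpoint, 0.0)
        return self.bottom + (top - self.bottom) * tf * dose**self.hill / (
            self.ec50_ugml**self.hill + dose**self.hill
        )


def _time_factor(time_h: float) -> float:
    """Saturating exposure-time scaling of the effect (1 at 72 h)."""
    if time_h <= 0:
        return 0.0
    return min(time_h / 24.0, 1.0) * 0.5 + 0.5 * min(time_h / 72.0, 1.0)


def _growth(time_h: float) -> float:
    """Control-signal growth factor: cells double every 24 h."""
    return 2.0 ** (time_h / 24.0)


@dataclass
class SyntheticTruth:
    """Everything needed to emit and verify one synthetic campaign."""

    design: CampaignDesign
    materials: list[MaterialTruth]
    noise_sd: float
    plate_effect_sd: float
    plate_effects: dict[str, float]
    control_outliers: list[dict]  # {"plate_id", "well", "factor"}
    focus_failures: list[dict]  # {"time_h", "replicate", "serum", "well"}
    dead_wells: list[dict]  # {"well"} — DAPI 0 in ALL imaging replicates
    seed: int

    def layout(self) -> dict[str, dict]:
        """Well -> {material_id, dose_value, dose_unit, role} plate map."""
        design = self.design
        wells: dict[str, dict] = {}
        for mi, mat in enumerate(self.materials):
            if mi >= design.geometry.n_rows:
                raise ValueError("too many materials for one plate row each")
            for di, dose in enumerate(design.doses_ugml):
                wells[format_well(mi, di)] = {
                    "material_id": mat.material_id,
                    "dose_value": dose,
                    "dose_unit": "ug/ml",
                    "role": "treated",
                }
        for row in range(design.geometry.n_rows):
            for col in design.control_cols:
                wells[format_well(row, col)] = {
                    "material_id": "vehicle",
                    "dose_value": 0.0,
                    "dose_unit": "ug/ml",
                    "role": "control",
                }
        for row in range(design.geometry.n_rows):
            for col in range(design.geometry.n_cols):
                wells.setdefault(
                    format_well(row, col),
                    {"material_id": "", "dose_value": 0.0, "dose_unit": "", "role": "blank"},
                )
        return wells

    def material_of_well(self) -> dict[str, MaterialTruth | None]:
        by_id = {m.material_id: m for m in self.materials}
        return {
            w: by_id.get(entry["material_id"])
            for w, entry in self.layout().items()
        }


def simulate_material_library(
    n_materials: int = 8,
    design: CampaignDesign | None = None,
    seed: int = 0,
    noise_sd: float = 0.03,
    plate_effect_sd: float = 0.02,
    n_control_outliers: int = 2,
    n_focus_failures: int = 3,
    n_dead_wells: int = 1,
) -> SyntheticTruth:
    """Draw a reproducible material library with a potency gradient.

    The library always contains one inert material (negligible effect at
    any tested dose) and one potent positive-control-like material; the
    rest interpolate on a log-spaced EC50 grid, so the true potency order
    is strict.  ``noise_sd`` is the Gaussian noise sd as a fraction of the
    seeding-level control signal (homoscedastic).
    """
    if n_materials < 2:
        raise ValueError("need at least 2 materials (one inert, one potent)")
    design = design or CampaignDesign()
    rng = np.random.default_rng(seed)
    max_dose = max(design.doses_ugml)

    ec50s = np.geomspace(max_dose / 128.0, max_dose / 2.0, n_materials - 1)
    materials = []
    for i, ec50 in enumerate(ec50s):
        top = {
            ep: float(np.clip(85.0 - 8.0 * i / max(n_materials - 2, 1) + rng.uniform(-5, 5), 20, 95))
            for ep in design.endpoints
        }
        materials.append(
            MaterialTruth(
                material_id=f"MAT{i + 1:02d}",
                ec50_ugml=float(ec50),
                hill=float(rng.uniform(1.5, 2.5)),
                top=top,
                interference_0h=float(rng.uniform(0.0, 0.08)) if i % 3 == 0 else 0.0,
            )
        )
    materials.append(
        MaterialTruth(
            material_id="INERT",
            ec50_ugml=float(max_dose * 1e3),
            hill=2.0,
            top={ep: 2.0 for ep in design.endpoints},
        )
    )

    plate_effects: dict[str, float] = {}
    for pid in _plate_ids(design):
        plate_effects[pid] = float(rng.normal(1.0, plate_effect_sd)) if plate_effect_sd > 0 else 1.0

    truth = SyntheticTruth(
        design=design,
        materials=materials,
        noise_sd=noise_sd,
        plate_effect_sd=plate_effect_sd,
        plate_effects=plate_effects,
        control_outliers=[],
        focus_failures=[],
        dead_wells=[],
        seed=seed,
    )

    # -- artifacts ---------------------------------------------------------
    layout = truth.layout()
    control_wells = sorted(w for w, e in layout.items() if e["role"] == "control")
    ctg_plates = [p for p in plate_effects if p.startswith("CTG") and "_0h_" not in p]
    for _ in range(n_control_outliers):
        truth.control_outliers.append(
            {
                "plate_id": ctg_plates[int(rng.integers(len(ctg_plates)))],
                "well": control_wells[int(rng.integers(len(control_wells)))],
                "factor": 5.0,
            }
        )
    # focus failures: low-dose treated wells (healthy cell counts) in one
    # replicate only, so the replicate median stays high -> NaN rule fires
    low_dose_wells = sorted(
        w
        for w, e in layout.items()
        if e["role"] == "treated" and e["dose_value"] <= max_dose / 64.0
    )
    chosen = rng.choice(len(low_dose_wells), size=n_focus_failures, replace=False)
    for ci in chosen:
        truth.focus_failures.append(
            {
                "time_h": float(rng.choice(design.times_imaging)),
                "replicate": int(rng.integers(1, design.n_replicates + 1)),
                "serum": str(rng.choice(design.serum)),
                "well": low_dose_wells[int(ci)],
            }
        )
    # dead wells: top dose of the most potent material, all replicates
    potent = min(materials, key=lambda m: m.ec50_ugml)
    top_dose_well = next(
        w
        for w, e in layout.items()
        if e["material_id"] == potent.material_id and e["dose_value"] == max_dose
    )
    for _ in range(n_dead_wells):
        truth.dead_wells.append({"well": top_dose_well})
        break  # one block per campaign; the top-dose well is unique
    return truth


def _plate_ids(design: CampaignDesign):
    for serum in design.serum:
        stoken = "serum" if serum == "with" else "noserum"
        for rep in range(1, design.n_replicates + 1):
            for t in design.times_ctg:
                yield f"CTG_{int(t)}h_R{rep}_BEAS2B_{stoken}"
            for t in design.times_imaging:
                yield f"imaging_{int(t)}h_R{rep}_BEAS2B_{stoken}"


def _signal(
    truth: SyntheticTruth,
    endpoint: str,
    mat: MaterialTruth | None,
    entry: dict,
    time_h: float,
    plate_effect: float,
    rng: np.random.Generator,
) -> float:
    """Noisy raw signal of one well on the plate-reader scale."""
    level = CONTROL_LEVEL[endpoint]
    g = _growth(time_h)
    if entry["role"] == "blank":
        return float("nan")
    effect = mat.effect(endpoint, entry["dose_value"], time_h) if mat else 0.0
    if endpoint == "CTG":
        inter = mat.interference_0h if mat else 0.0
        # seeding signal + interference + growth of the surviving fraction
        mu = level * (1.0 + inter + (g - 1.0) * (1.0 - effect / 100.0))
    elif endpoint == "DAPI":
        mu = level * g * (1.0 - effect / 100.0)
    elif endpoint == "CASP":
        mat_v = mat
        viab = 0.0
        if mat_v is not None:
            viab = (
                mat_v.effect("CTG", entry["dose_value"], time_h)
                + mat_v.effect("DAPI", entry["dose_value"], time_h)
            ) / 2.0
        mu = level * g * (1.0 + effect / 100.0) * (1.0 - viab / 100.0)
    else:  # per-cell nuclear/cytoplasmic intensity
        mu = level * (1.0 + effect / 100.0)
    noise = rng.normal(0.0, truth.noise_sd * level) if truth.noise_sd > 0 else 0.0
    return float(max(mu + noise, 0.0) * plate_effect)


def emit_plates(truth: SyntheticTruth, out_dir: str | Path) -> AnnotationTemplate:
    """Write the campaign's raw files + annotation workbook to ``out_dir``.

    Produces one CSV per CTG plate, one TXT per imaging plate (DAPI twice
    per well), ``HTS_METADATA.xlsx`` and ``truth_manifest.json``; returns
    the filled annotation template.  Artifacts are injected as recorded in
    the truth object.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = truth.design
    rng = np.random.default_rng(truth.seed + 1)
    layout = truth.layout()
    mat_of = truth.material_of_well()
    geometry = design.geometry

    outliers = {(o["plate_id"], o["well"]): o["factor"] for o in truth.control_outliers}
    failures = {
        (f["time_h"], f["replicate"], f["serum"], f["well"])
        for f in truth.focus_failures
    }
    dead = {d["well"] for d in truth.dead_wells}

    filenames: list[str] = []
    for serum in design.serum:
        stoken = "serum" if serum == "with" else "noserum"
        for rep in range(1, design.n_replicates + 1):
            for t in design.times_ctg:
                pid = f"CTG_{int(t)}h_R{rep}_BEAS2B_{stoken}"
                pe = truth.plate_effects[pid]
                grid = np.full((geometry.n_rows, geometry.n_cols), np.nan)
                for row in range(geometry.n_rows):
                    for col in range(geometry.n_cols):
                        well = format_well(row, col)
                        v = _signal(truth, "CTG", mat_of[well], layout[well], t, pe, rng)
                        if (pid, well) in outliers:
                            v *= outliers[(pid, well)]
                        grid[row, col] = v
                fname = pid + ".csv"
                filenames.append(fname)
                with open(out_dir / fname, "w") as fh:
                    fh.write(f"# plate,{pid}\n")
                    for row in range(geometry.n_rows):
                        fh.write(
                            ",".join(
                                "" if np.isnan(grid[row, col]) else f"{grid[row, col]:.6f}"
                                for col in range(geometry.n_cols)
                            )
                            + "\n"
                        )
            for t in design.times_imaging:
                pid = f"imaging_{int(t)}h_R{rep}_BEAS2B_{stoken}"
                pe = truth.plate_effects[pid]
                fname = pid + ".txt"
                filenames.append(fname)
                with open(out_dir / fname, "w") as fh:
                    fh.write("well\tendpoint\tvalue\n")
                    for row in range(geometry.n_rows):
                        for col in range(geometry.n_cols):
                            well = format_well(row, col)
                            entry = layout[well]
                            mat = mat_of[well]
                            is_failure = (t, rep, serum, well) in failures
                            for ep in IMAGING_ENDPOINTS:
                                reps_out = 2 if ep == "DAPI" else 1
                                for _ in range(reps_out):
                                    v = _signal(truth, ep, mat, entry, t, pe, rng)
                                    if entry["role"] != "blank":
                                        if well in dead and ep == "DAPI":
                                            v = 0.0
                                        elif well in dead:
                                            v = float("nan")
                                        if is_failure:
                                            v = 0.0 if ep == "DAPI" else float("nan")
                                    txt = "" if np.isnan(v) else f"{v:.6f}"
                                    fh.write(f"{well}\t{ep}\t{txt}\n")

    front = pd.DataFrame(
        [
            {"well": w, **entry}
            for w, entry in sorted(layout.items())
        ]
    )[["well", "material_id", "dose_value", "dose_unit", "role"]]
    materials = pd.DataFrame(
        [
            {
                "material_id": m.material_id,
                "name": m.material_id,
                "erm_id": "",
                "sbet_m2g": np.nan,
            }
            for m in truth.materials
        ]
    )
    template = AnnotationTemplate(front_sheet=front, materials_sheet=materials)
    template = autofill_files_sheet(filenames, template)
    template.to_workbook(out_dir / "HTS_METADATA.xlsx")
    manifest = truth_manifest(truth)
    manifest.to_csv(out_dir / "truth_manifest.csv", index=False)
    with open(out_dir / "truth_params.json", "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "noise_sd": truth.noise_sd,
                "plate_effect_sd": truth.plate_effect_sd,
                "materials": [asdict(m) for m in truth.materials],
                "control_outliers": truth.control_outliers,
                "focus_failures": truth.focus_failures,
                "dead_wells": truth.dead_wells,
            },
            fh,
            indent=2,
        )
    return template


def truth_manifest(truth: SyntheticTruth) -> pd.DataFrame:
    """Expected qualitative outcomes per material.

    ``expected_potency_rank`` orders materials by true EC50 (1 = most
    potent); ``first_sig_detectable`` flags materials whose maximal true
    effect clearly exceeds plausible control noise; artifact counts are
    campaign totals attributed to the affected material's wells.
    """
    layout = truth.layout()
    mat_of_well = {w: e["material_id"] for w, e in layout.items()}
    order = sorted(truth.materials, key=lambda m: m.ec50_ugml)
    ranks = {m.material_id: i + 1 for i, m in enumerate(order)}
    rows = []
    for m in truth.materials:
        max_effect = max(
            m.effect(ep, max(truth.design.doses_ugml), 72.0)
            for ep in truth.design.endpoints
        )
        rows.append(
            {
                "material_id": m.material_id,
                "ec50_ugml": m.ec50_ugml,
                "expected_potency_rank": ranks[m.material_id],
                "first_sig_detectable": bool(max_effect > 10.0),
                "n_focus_failures": sum(
                    mat_of_well[f["well"]] == m.material_id
                    for f in truth.focus_failures
                ),
                "n_dead_wells": sum(
                    mat_of_well[d["well"]] == m.material_id for d in truth.dead_wells
                ),
                "n_control_outliers": 0,
            }
        )
    return pd.DataFrame(rows)
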