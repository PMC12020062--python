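"""Shared fixtures: synthetic campaigns emitted to disk and re-ingested.

Two session-scoped campaigns cover most integration tests:

* ``noiseless_campaign`` — zero measurement noise and unit plate effects,
  so preprocessing must recover the generator's Hill effects exactly;
* ``lownoise_campaign`` — small but nonzero noise, so significance tests
  are well-defined (zero variance makes every t-test degenerate).
"""

from __future__ import annotations

from pathlib import Path

import pytest

from htstox import plate_io, preprocess, synthetic_fixtures as sf


def make_campaign(tmp_dir: Path, **kwargs):
    truth = sf.simulate_material_library(**kwargs)
    sf.emit_plates(truth, tmp_dir)
    template = plate_io.AnnotationTemplate.from_workbook(tmp_dir / "HTS_METADATA.xlsx")
    datasets = plate_io.ingest_directory(tmp_dir, template)
    return truth, template, datasets


@pytest.fixture(scope="session")
def noiseless_campaign(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("noiseless")
    truth, template, datasets = make_campaign(
        tmp, n_materials=6, seed=11, noise_sd=0.0, plate_effect_sd=0.0
    )
    return {"dir": tmp, "truth": truth, "template": template, "datasets": datasets}


@pytest.fixture(scope="session")
def noiseless_processed(noiseless_campaign):
    datasets = {ep: ds.copy() for ep, ds in noiseless_campaign["datasets"].items()}
    processed, control_stats = preprocess.standard_preprocess(datasets)
    return {"processed": processed, "control_stats": control_stats,
            **noiseless_campaign}


@pytest.fixture(scope="session")
def lownoise_campaign(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("lownoise")
    truth, template, datasets = make_campaign(
        tmp, n_materials=6, seed=23, noise_sd=0.002, plate_effect_sd=0.0
    )
    return {"dir": tmp, "truth": truth, "template": template, "datasets": datasets}


@pytest.fixture(scope="session")
def lownoise_processed(lownoise_campaign):
    datasets = {ep: ds.copy() for ep, ds in lownoise_campaign["datasets"].items()}
    processed, control_stats = preprocess.standard_preprocess(datasets)
    return {"processed": processed, "control_stats": control_stats,
            **lownoise_campaign}
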