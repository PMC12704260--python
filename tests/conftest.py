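"""Shared fixtures.

The full grid + ratio sweep is expensive (~2 min), so one complete pipeline
run is shared session-wide; trend tests read its CSV outputs (the CSVs are
the pipeline's contract).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from morphomech import femesh, template
from morphomech.morphometrics import SpeciesRecord, TernaryCoord
from morphomech.pipeline import PipelineConfig, run_full


@pytest.fixture(scope="session")
def base_params() -> template.SkullParams:
    return template.SkullParams(tern=TernaryCoord(0.6, 0.2, 0.2), ratio=3.0, length=300.0)


@pytest.fixture(scope="session")
def base_outline(base_params) -> template.Outline2D:
    return template.build_outline(base_params)


@pytest.fixture(scope="session")
def base_mesh(base_outline) -> femesh.Mesh2D:
    return femesh.triangulate(base_outline, 300.0 / 60)


@pytest.fixture()
def sample_records() -> list[SpeciesRecord]:
    return [
        SpeciesRecord("Alpha_rex", "Theropoda", "carnivore", "Cretaceous", 300, 180, 60, 60, 100),
        SpeciesRecord("Beta_ops", "Ceratopsia", "herbivore", "Cretaceous", 200, 70, 60, 66, 160),
        SpeciesRecord("Gamma_don", "Ornithopoda", "herbivore", "Jurassic", 250, 125, 63, 62, 110),
    ]


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete pipeline run on the synthetic preset (default config)."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(output_dir=str(out))
    report = run_full(cfg)
    return report, out, cfg


@pytest.fixture(scope="session")
def grid_frame(full_run) -> pd.DataFrame:
    _, out, _ = full_run
    return pd.read_csv(out / "performance_surface.csv")


@pytest.fixture(scope="session")
def ratio_frame(full_run) -> pd.DataFrame:
    _, out, _ = full_run
    return pd.read_csv(out / "ratio_series.csv")
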