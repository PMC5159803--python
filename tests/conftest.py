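"""Shared fixtures: simulated bundles and one full pipeline run per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polarmir import (
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    simulate_counts,
    write_fixture_bundle,
)
from polarmir.design import SampleDesign
from polarmir.synthetic import GroundTruth


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_config):
    """(mrna, mirna, design, truth) at the default study conditions."""
    return simulate_counts(default_config)


@pytest.fixture(scope="session")
def small_sim():
    """A cheap simulation for unit tests that only need shapes and types."""
    config = SimulationConfig(
        seed=3, n_genes=300, n_mirnas=12, n_de_genes_per_archetype=20,
        n_m1_mirnas=2, n_m2_mirnas=2, n_targets_per_mirna=5, n_shared_targets=2,
    )
    return config, simulate_counts(config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, default_config):
    """A written fixture bundle at the default study conditions."""
    directory = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(directory, default_config)
    return directory


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, bundle_dir):
    """One full pipeline run over the default bundle; returns (config, outdir)."""
    outdir = tmp_path_factory.mktemp("results")
    config = PipelineConfig(input_dir=str(bundle_dir), output_dir=str(outdir), seed=1)
    run_pipeline(config)
    return config, outdir


@pytest.fixture(scope="session")
def ground_truth(bundle_dir) -> GroundTruth:
    return GroundTruth.from_json((bundle_dir / "ground_truth.json").read_text())


@pytest.fixture()
def toy_design() -> SampleDesign:
    rows = []
    for cond in ("M1", "M2"):
        for tp in (1.0, 2.0, 4.0, 8.0):
            for rep in (1, 2):
                rows.append((f"{cond}_{tp:g}_{rep}", cond, tp, rep))
    rows += [("M0_1_1", "M0", 1.0, 1), ("M0_1_2", "M0", 1.0, 2)]
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "condition", "time_h", "replicate"]))


def read_result(path, index_col=None) -> pd.DataFrame:
    """Read a written result table, restoring booleans and NA."""
    df = pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {"True", "False"}:
            df[col] = df[col] == "True"
    return df
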