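"""Shared fixtures: small synthetic configurations and a full default bundle.

The default bundle and its pipeline run are session-scoped because the
end-to-end recovery checks and several reporting tests all consume the
same artifacts.
"""
from __future__ import annotations

import pandas as pd
import pytest

import cerna_forge as cf
from cerna_forge.io import read_sif, read_truth, simulate_to_dir


@pytest.fixture(scope="session")
def small_config() -> cf.SimulationConfig:
    """A fast, fully featured configuration for unit-level tests."""
    return cf.SimulationConfig(
        n_mrna=300, n_lncrna=80, n_circrna=120, n_mirna=60,
        n_de_per_class=30, n_triplets=10, n_decoy_triplets=40,
        n_terms=12, term_size_range=(5, 40), seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return cf.generate_bundle(small_config)


@pytest.fixture(scope="session")
def design() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"{g}_{r}" for g in ("E65", "E85") for r in (1, 2, 3)],
            "group": ["E65"] * 3 + ["E85"] * 3,
        }
    )


@pytest.fixture(scope="session")
def default_bundle_run(tmp_path_factory):
    """The default synthetic bundle, written to disk and pushed through the
    full pipeline once per session."""
    base = tmp_path_factory.mktemp("bundle")
    indir = base / "inputs"
    outdir = base / "run"
    config = cf.SimulationConfig(seed=1)
    simulate_to_dir(config, indir)
    pipeline_config = cf.PipelineConfig(
        counts_dir=str(indir),
        annotation=str(indir / "annotation.tsv"),
        targets=str(indir / "targets.tsv"),
        terms=str(indir / "terms.gmt"),
        design=str(indir / "design.tsv"),
        outdir=str(outdir),
        seed=1,
    )
    report = cf.run_pipeline(pipeline_config)
    truth = read_truth(indir / "truth.tsv")
    edges = read_sif(outdir / "network.sif")
    return {
        "config": config,
        "pipeline_config": pipeline_config,
        "indir": indir,
        "outdir": outdir,
        "report": report,
        "truth": truth,
        "edges": edges,
    }
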