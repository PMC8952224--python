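"""Shared fixtures: one default synthetic study and one full pipeline run,
generated once per session and reused by module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cerna_switch.pipeline import PipelineConfig, run_all
from cerna_switch.synthetic_data import (
    SimulationConfig,
    simulate,
    write_study,
)

DEFAULT_SEED = 1

# a compact study for tests that only need structure, not power
SMALL_CONFIG = dict(
    n_mRNA=250, n_lncRNA=80, n_miRNA=30, n_planted_axes=4, n_planted_cis=4
)

NULL_CONFIG = dict(
    n_mRNA=250,
    n_lncRNA=80,
    n_miRNA=30,
    de_fraction_mRNA=0.0,
    de_fraction_lncRNA=0.0,
    de_fraction_miRNA=0.0,
    n_planted_axes=0,
    n_planted_cis=0,
    rho=0.0,
)


@pytest.fixture(scope="session")
def default_study():
    return simulate(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def study_dir(default_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    write_study(d, default_study)
    return d


@pytest.fixture(scope="session")
def pipeline_run(default_study, study_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    run_all(PipelineConfig(study_dir=str(study_dir), out_dir=str(out)))
    return out


@pytest.fixture(scope="session")
def classified_de(pipeline_run):
    return pd.read_csv(pipeline_run / "de.tsv", sep="\t", index_col=0)


@pytest.fixture(scope="session")
def null_stringent_fractions():
    """Stringent-tier and screening-FDR flag rates on 20 all-null studies."""
    from cerna_switch.diffexpr import classify, test_de

    stringent, fdr05, total = 0, 0, 0
    for seed in range(20):
        study = simulate(SimulationConfig(seed=1000 + seed, **NULL_CONFIG))
        de = test_de(study.counts, "contractile", "stent")
        cls = classify(de, study.fpkm, "contractile", "stent")
        stringent += int(cls["stringent"].sum())
        fdr05 += int((cls["fdr"] <= 0.05).sum())
        total += len(cls)
    return {"stringent": stringent / total, "fdr05": fdr05 / total, "n": total}
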