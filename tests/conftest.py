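import warnings

import numpy as np
import pandas as pd
import pytest

from irlncpair.expression_io import ClinicalTable, ExpressionMatrix
from irlncpair.pipeline import PipelineConfig, run_pipeline, simulate_command
from irlncpair.synthetic_data import SimConfig, generate_survival_cohort

warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng):
    """6-gene x 8-sample matrix for hand-checkable operations."""
    genes = ["GENEA", "GENEB", "GENEC", "GENED", "GENEE", "GENEF"]
    samples = [f"S{i}" for i in range(8)]
    values = pd.DataFrame(rng.normal(6, 1, size=(6, 8)), index=genes, columns=samples)
    return ExpressionMatrix(values)


def small_sim_config(**overrides) -> SimConfig:
    """Small-gene-count study conditions used where full-size cohorts are
    not the thing under test."""
    kw = dict(n_immune_genes=20, n_lncRNAs=40, n_linked_lnc=10, n_de_lnc=6,
              noise_sd=0.5, seed=11)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture
def survival_small():
    cfg = small_sim_config(
        n_linked_lnc=0, n_de_lnc=0,
        pair_betas={"LNC0001|LNC0002": 0.7, "LNC0003|LNC0004": 0.4},
    )
    return generate_survival_cohort(cfg)


def no_censoring_clinical(times, events=None, prefix="P") -> ClinicalTable:
    times = np.asarray(times, dtype=float)
    if events is None:
        events = np.ones(len(times), dtype=int)
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"os_time": times, "os_event": events}, index=idx)
    )


@pytest.fixture(scope="session")
def lownoise_pipeline(tmp_path_factory):
    """One full pipeline run on low-noise cohorts, shared by the tests that
    check end-to-end counts (26 planted DE lncRNAs -> 325 pairs etc.)."""
    root = tmp_path_factory.mktemp("lownoise")
    cfg = SimConfig(seed=5, noise_sd=0.3, rho_true=0.9)
    paths = simulate_command(cfg, root / "sim")
    pcfg = PipelineConfig(**{k: str(v) for k, v in paths.items()}, seed=5)
    report = run_pipeline(pcfg, root / "run")
    return cfg, pcfg, report, root / "run"
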