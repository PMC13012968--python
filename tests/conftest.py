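import numpy as np
import pandas as pd
import pytest

from pvsignals.config import SimulationConfig, demo_simulation_config
from pvsignals.simulate import generate_dataset
from pvsignals.tables import SRSTables


@pytest.fixture(scope="session")
def small_dataset():
    """A small deterministic synthetic dataset with injected signals."""
    config = SimulationConfig(
        group_sizes={"COMBO": 200, "BEV_MONO": 300, "TMZ_MONO": 400, "BACKGROUND": 1200},
        signal_multipliers={"TMZ_MONO": {"Thrombocytopenia": 6.0}},
        interaction_multipliers={"Pneumonia cytomegaloviral": 8.0},
        duplicate_rate=0.05,
        seed=42,
    )
    tables, truth = generate_dataset(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """One full pipeline run on the demo configuration, shared across tests."""
    from pvsignals.config import PipelineConfig
    from pvsignals.pipeline import run_pipeline

    config = PipelineConfig(simulate=demo_simulation_config(7), seed=7)
    outdir = tmp_path_factory.mktemp("bundle")
    bundle = run_pipeline(config, output_dir=outdir)
    return config, bundle, outdir


def hand_tables(rows_reports, rows_drugs, rows_events) -> SRSTables:
    """Build SRSTables from terse tuples (used by hand-countable fixtures)."""
    reports = pd.DataFrame(
        rows_reports,
        columns=["report_id", "case_id", "case_version", "receive_date", "database_tag",
                 "sex", "age_group", "weight_group", "reporter_type"],
    )
    drugs = pd.DataFrame(
        rows_drugs,
        columns=["report_id", "drug_name", "role", "therapy_start_date", "indication_text"],
    )
    events = pd.DataFrame(rows_events, columns=["report_id", "event_term", "onset_date"])
    return SRSTables(reports, drugs, events)
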