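"""Shared fixtures: the default synthetic cohort and derived analysis inputs.

The default cohort (seed 1) is generated once per session; tests that need
the study-sized design, the early-pregnancy window selection or the
transformed training matrix reuse it rather than regenerating.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vmptb as v

SIGNATURE_TAXA = frozenset({
    "Lachnospiraceae_BVAB1",
    "Sneathia_amnii",
    "Prevotella_cluster2",
    "TM7_H1",
})


@pytest.fixture(scope="session")
def default_cohort() -> v.SyntheticCohort:
    return v.simulate_cohort(v.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def qc_table(default_cohort):
    """Default cohort's abundance table after the 1,000-read QC floor."""
    return v.filter_min_reads(default_cohort.table)


@pytest.fixture(scope="session")
def qc_records(default_cohort, qc_table):
    rec = default_cohort.records
    return rec[rec["sample_id"].isin(qc_table.sample_ids)]


@pytest.fixture(scope="session")
def window_selection(qc_table, qc_records):
    """Earliest sample per subject in the 42-167 day window, plus features."""
    chosen = v.earliest_sample_in_window(qc_records, (42, 167))
    frame = qc_table.to_frame().loc[chosen["sample_id"]]
    taxa = v.filter_low_abundance(frame)
    outcomes = pd.Series(chosen["outcome"].to_numpy(), index=chosen["sample_id"])
    return {"records": chosen, "frame": frame, "taxa": taxa, "outcomes": outcomes}


@pytest.fixture(scope="session")
def window_training(window_selection):
    data = v.microbiome_training_set(
        window_selection["frame"], window_selection["outcomes"],
        taxa=window_selection["taxa"])
    return data, list(window_selection["records"]["subject_id"])


def null_config(seed: int, **overrides) -> v.SyntheticConfig:
    """Global-null study conditions: no abundance effect, shared dynamics."""
    base = v.SyntheticConfig(seed=seed)
    defaults = dict(
        seed=seed,
        ptb_effect={},
        Q_ptb=base.Q_tb.copy(),
        initial_dist_ptb=base.initial_dist_tb.copy(),
    )
    defaults.update(overrides)
    return v.SyntheticConfig(**defaults)
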