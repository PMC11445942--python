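"""Shared fixtures: small synthetic cohorts and reduced feature tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

from arfpheno.features import load_feature_table
from arfpheno.synth import CohortConfig, default_specs, generate_study

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def feature_table():
    return load_feature_table()


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def small_study():
    """A 300-encounter synthetic study shared across unit tests."""
    return generate_study(config=CohortConfig(n_encounters=300, seed=42))


@pytest.fixture(scope="session")
def tiny_feature_table(feature_table):
    """Five-feature dictionary for fast generator-based tests."""
    keep = ["pf_ratio", "creatinine", "lactate", "platelets", "gcs_total"]
    return feature_table.loc[keep]


def reduced_specs(feature_table, **overrides):
    """default_specs restricted to a reduced dictionary with optional field
    overrides applied to every phenotype."""
    from dataclasses import replace

    specs = default_specs(feature_table)
    return [replace(s, **overrides) for s in specs]
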