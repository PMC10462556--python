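"""Shared fixtures: built-in graphs and synthetic cohorts.

Cohorts are generated programmatically; the large recovery cohort is
session-scoped because several tests reuse it.
"""

from __future__ import annotations

import pytest

from llrsim.process_model import SurgeryCategory, build_category_graph
from llrsim.synthetic import default_params, generate_cohort

CATEGORIES = [c.value for c in SurgeryCategory]


@pytest.fixture(scope="session")
def graphs():
    return {cat: build_category_graph(cat) for cat in CATEGORIES}


@pytest.fixture(scope="session")
def small_cohorts():
    """30 synthetic surgeries per category (fast, for structural checks)."""
    return {
        cat: generate_cohort(default_params(cat), 30, seed=100 + i)
        for i, cat in enumerate(CATEGORIES)
    }


@pytest.fixture(scope="session")
def recovery_cohort_s56():
    """2000 synthetic segments-5&6 surgeries for parameter recovery."""
    return generate_cohort(default_params("S56"), 2000, seed=42)
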