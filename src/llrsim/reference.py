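"""Bundled study parameters: the published per-category summary statistics.

The machine-readable copy of the study's summary tables (module duration and
occurrence mean/SD per category, idle totals, minimum observed resection
times, fixed preparation hour) ships with the package so that the whole
analysis and simulation chain runs without the deposited video dataset.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

from .analyser import ModuleStatsTable
from .process_model import SurgeryCategory

__all__ = ["reference_stats", "min_resection_s", "prep_time_s", "load_reference"]


@lru_cache(maxsize=1)
def load_reference() -> dict:
    """The raw bundled reference document (read-only; cached)."""
    path = resources.files("llrsim.data").joinpath("reference_stats.json")
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def reference_stats(category: SurgeryCategory | str) -> ModuleStatsTable:
    """The published module statistics for a category as a stats table."""
    category = SurgeryCategory.coerce(category)
    doc = load_reference()["categories"][category.value]
    table = pd.DataFrame.from_dict(doc["modules"], orient="index")
    table["n_present"] = float("nan")
    return ModuleStatsTable(
        category=category,
        table=table[["duration_mean_s", "duration_sd_s", "occ_mean", "occ_sd", "n_present"]],
        idle_mean_s=float(doc["idle"]["duration_mean_s"]),
        idle_sd_s=float(doc["idle"]["duration_sd_s"]),
        n_surgeries=None,
    )


def min_resection_s(category: SurgeryCategory | str) -> float:
    """Minimum resection time observed in the study's videos (seconds)."""
    category = SurgeryCategory.coerce(category)
    return float(load_reference()["min_resection_s"][category.value])


def prep_time_s() -> float:
    """Fixed intra-operative preparation time (seconds, about one hour)."""
    return float(load_reference()["prep_time_s"])
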