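"""Packaged reference tables from the source study.

A few small fixtures ship with the package: the baseline prevalence table
(diagnosis counts by severity state), its published percentages, and the
published per-child cost totals with cohort-level incremental budget
figures. They anchor regression tests and let the cost-comparison stage
be exercised against published numbers without the restricted clinical
data set or its supplementary cost inputs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["baseline_prevalence_counts", "baseline_prevalence_percent", "published_per_child_totals",
           "published_cohort_incrementals", "COHORT_SIZES"]

#: Hypothetical affected-cohort sizes used for budget impact.
COHORT_SIZES = {"cohort1": 2342, "cohort2": 16790, "cohort3": 23725}


def _data(name: str) -> Path:
    return Path(resources.files("traumacost") / "data" / name)


def baseline_prevalence_counts() -> pd.DataFrame:
    """Diagnosis counts by severity state, plus the state sizes (row 'state_n')."""
    return pd.read_csv(_data("prevalence_counts.csv"), index_col="variable")


def baseline_prevalence_percent() -> pd.DataFrame:
    """Published prevalence percentages by state (2-decimal)."""
    return pd.read_csv(_data("prevalence_percent.csv"), index_col="variable")


def published_per_child_totals() -> pd.DataFrame:
    """Published per-child total costs by perspective, horizon and policy."""
    return pd.read_csv(_data("per_child_totals.csv"))


def published_cohort_incrementals() -> pd.DataFrame:
    """Published cohort-level incremental budget figures."""
    return pd.read_csv(_data("cohort_incrementals.csv"))
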