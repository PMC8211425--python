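"""Cohort construction: sample filtering and the 3-year-mortality outcome.

The binary outcome is defined at a fixed follow-up horizon (default 3
years): patients dead before the horizon are cases (Y = 1), patients who
survived past it are controls (Y = 0) regardless of later vital status, and
patients alive with follow-up shorter than the horizon carry no outcome
information and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["OutcomeVector", "define_outcome", "filter_samples"]


@dataclass
class OutcomeVector:
    """Binary outcome per retained sample plus itemized exclusions."""

    y: pd.Series  # index: sample_id, values {0, 1}
    excluded: dict[str, str] = field(default_factory=dict)  # id -> reason


def define_outcome(clinical: pd.DataFrame, horizon_years: float = 3.0) -> OutcomeVector:
    """Dichotomize survival at the horizon.

    Y = 1 iff vital_status is dead and os_time < horizon; Y = 0 iff
    os_time >= horizon (dead past the horizon still survived it, hence 0);
    alive with os_time < horizon is excluded as outcome-indeterminate.
    Missing os_time excludes the sample; negative os_time is an error.
    """
    if (clinical["os_time"].dropna() < 0).any():
        raise ValueError("negative os_time encountered")
    y: dict[str, int] = {}
    excluded: dict[str, str] = {}
    for _, row in clinical.iterrows():
        sid = row["sample_id"]
        t, status = row["os_time"], str(row["vital_status"]).lower()
        if pd.isna(t):
            excluded[sid] = "missing os_time"
        elif t >= horizon_years:
            y[sid] = 0
        elif status == "dead":
            y[sid] = 1
        else:
            excluded[sid] = f"alive with os_time < {horizon_years} years"
    for sid, reason in excluded.items():
        logger.info("excluded %s: %s", sid, reason)
    return OutcomeVector(pd.Series(y, dtype=int, name="y"), excluded)


def filter_samples(
    clinical: pd.DataFrame,
    counts: pd.DataFrame,
    horizon_years: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, OutcomeVector]:
    """Build the analysis cohort.

    Keeps samples present in both tables, drops non-primary samples, then
    applies the outcome rule's exclusions.  Outputs share one sample order.
    """
    if clinical["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    clin = clinical.set_index("sample_id", drop=False)

    shared = [s for s in counts.columns if s in clin.index]
    for s in counts.columns:
        if s not in clin.index:
            logger.info("dropped %s: no clinical record", s)
    for s in clin.index:
        if s not in set(counts.columns):
            logger.info("dropped %s: no expression data", s)
    clin = clin.loc[shared]

    if "sample_type" in clin.columns:
        primary = clin["sample_type"] == "primary"
        for s in clin.index[~primary]:
            logger.info("dropped %s: sample_type=%s", s, clin.loc[s, "sample_type"])
        clin = clin.loc[primary]

    outcome = define_outcome(clin, horizon_years)
    kept = [s for s in clin.index if s in outcome.y.index]
    if not kept:
        raise ValueError("no samples survive cohort filters")
    clin = clin.loc[kept].reset_index(drop=True)
    counts = counts.loc[:, kept]
    outcome.y = outcome.y.loc[kept]
    assert not np.isin(list(outcome.excluded), kept).any()
    return clin, counts, outcome
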