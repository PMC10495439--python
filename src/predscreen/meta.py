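"""Per-cancer biomarker-predictiveness meta-analysis.

For every cancer type with trial-level hazard ratios in both the
biomarker-positive and biomarker-negative subgroups, the stage pools each
subgroup with a DerSimonian-Laird random-effects model and summarizes the
biomarker's predictiveness as the hazard-ratio difference

    HRD = (1 - pooled HR_pos) - (1 - pooled HR_neg) = HR_neg - HR_pos,

computed on the hazard-ratio scale.  A positive HRD means
biomarker-positive patients derive more benefit from the checkpoint
inhibitor than biomarker-negative patients.  An interaction p-value comes
from the normal subgroup-difference test on the pooled log HRs, and a
heterogeneity flag is raised when either subgroup pool exceeds an
I-squared threshold (default 75%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (HazardRatioEstimate, ValidationError, log_hr_from_ci,
                    pool_random_effects, spearman, subgroup_difference_test)

__all__ = ["PredictivenessResult", "compute_predictiveness",
           "predictiveness_correlation"]

SUBGROUPS = ("BM_POS", "BM_NEG")
ENDPOINTS = ("OS", "PFS")

TRIAL_COLUMNS = ["trial_id", "cancer", "endpoint", "subgroup",
                 "hr", "ci_low", "ci_high"]


@dataclass
class PredictivenessResult:
    """Per-cancer predictiveness table plus the cancers that were dropped."""

    table: pd.DataFrame                      # one row per cancer
    dropped: dict[str, str] = field(default_factory=dict)  # cancer -> reason
    endpoint: str = "OS"

    def hrd_series(self) -> pd.Series:
        return self.table.set_index("cancer")["hrd"]


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    bad_sub = set(trials["subgroup"]) - set(SUBGROUPS)
    if bad_sub:
        raise ValidationError(f"unknown subgroup labels: {sorted(bad_sub)}")
    key = ["trial_id", "cancer", "endpoint", "subgroup"]
    if trials.duplicated(key).any():
        dup = trials[trials.duplicated(key, keep=False)]
        raise ValidationError(
            f"duplicate (trial, cancer, endpoint, subgroup) rows:\n{dup[key]}")
    return trials


def compute_predictiveness(trials: pd.DataFrame, endpoint: str,
                           i2_threshold: float = 75.0) -> PredictivenessResult:
    """Pool subgroup HRs per cancer and compute the HRD statistic.

    Cancers lacking trials in either subgroup for the requested endpoint
    are dropped (with a reason recorded) rather than half-analyzed.
    """
    if len(trials) == 0:
        raise ValidationError("empty trial table")
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"endpoint must be one of {ENDPOINTS}")
    trials = _validate_trials(trials)
    sub = trials[trials["endpoint"] == endpoint]
    rows = []
    dropped: dict[str, str] = {}
    for cancer, grp in sub.groupby("cancer", sort=True):
        pools = {}
        for sg in SUBGROUPS:
            recs = grp[grp["subgroup"] == sg]
            if len(recs) == 0:
                continue
            ests = [log_hr_from_ci(r.hr, r.ci_low, r.ci_high)
                    for r in recs.itertuples()]
            pools[sg] = pool_random_effects(ests)
        if set(pools) != set(SUBGROUPS):
            missing = sorted(set(SUBGROUPS) - set(pools))
            dropped[cancer] = f"missing subgroup(s): {', '.join(missing)}"
            continue
        pos, neg = pools["BM_POS"], pools["BM_NEG"]
        z, p_int = subgroup_difference_test(pos, neg)
        rows.append({
            "cancer": cancer,
            "endpoint": endpoint,
            "k_pos": pos.k,
            "k_neg": neg.k,
            "hr_pos": pos.hr,
            "hr_neg": neg.hr,
            "hrd": neg.hr - pos.hr,
            "p_interaction": p_int,
            "i2_pos": pos.I2,
            "i2_neg": neg.I2,
            "flagged": bool(pos.I2 > i2_threshold or neg.I2 > i2_threshold),
        })
    table = pd.DataFrame(rows, columns=["cancer", "endpoint", "k_pos", "k_neg",
                                        "hr_pos", "hr_neg", "hrd",
                                        "p_interaction", "i2_pos", "i2_neg",
                                        "flagged"])
    return PredictivenessResult(table=table, dropped=dropped, endpoint=endpoint)


def predictiveness_correlation(a: PredictivenessResult,
                               b: PredictivenessResult) -> tuple[float, float]:
    """Spearman correlation of HRD between two endpoints over shared cancers."""
    sa, sb = a.hrd_series(), b.hrd_series()
    shared = sorted(set(sa.index) & set(sb.index))
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared cancers, found {len(shared)}")
    return spearman(sa.loc[shared].to_numpy(), sb.loc[shared].to_numpy())
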