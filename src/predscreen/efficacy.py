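"""Biomarker-stratified efficacy grids.

The evaluation stage reproduces the trial-style readout: within each
predictiveness group (PH / PL / ALL), patients are stratified by PD-L1 —
IHC percent cutoffs (1%, 5%, or the 1%/50% three-level scheme) or RNA
expression percentiles (median, or 25th/75th) — and efficacy is compared
either between biomarker strata within the ICI arm, or between ICI and
chemotherapy within each stratum.  Survival endpoints report a univariate
Cox hazard ratio with 95% CI and a log-rank p; the response endpoint
reports objective response rates with Clopper-Pearson intervals and a
Fisher exact p.  Cells that cannot be estimated (empty stratum, no
events, degenerate tables) are emitted with ``estimable=False`` so grids
stay rectangular.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import (ValidationError, clopper_pearson, fisher_exact, fit_cox,
                    km_curve, km_logrank)

__all__ = ["STRATA_LABELS", "stratify_pdl1", "efficacy_grid", "km_table"]

RESPONDER_LEVELS = ("CR", "PR")
MODES = ("IHC2", "IHC3", "IHC2_ALT", "RNA2", "RNA3")
COMPARISONS = ("POS_vs_NEG_within_ICI", "ICI_vs_CHEMO_within_stratum")

#: stratum labels, ordered low -> high, per stratification mode
STRATA_LABELS = {
    "IHC2": ["<1%", ">=1%"],
    "IHC2_ALT": ["<5%", ">=5%"],
    "IHC3": ["<1%", "1-50%", ">=50%"],
    "RNA2": ["LOW", "HIGH"],
    "RNA3": ["LOW", "MID", "HIGH"],
}

GRID_COLUMNS = ["group", "stratum", "comparison", "endpoint", "n_a", "n_b",
                "hr", "ci_low", "ci_high", "logrank_p", "orr_a",
                "orr_a_ci_low", "orr_a_ci_high", "orr_b", "orr_b_ci_low",
                "orr_b_ci_high", "fisher_p", "estimable"]


def stratify_pdl1(clinical: pd.DataFrame, expression: pd.DataFrame | None,
                  mode: str, reference: str = "TREATED_ARM",
                  pdl1_gene: str = "CD274") -> tuple[pd.Series, int]:
    """Assign each patient a PD-L1 stratum.

    IHC modes bin the ``pdl1_ihc`` percent: two levels at 1% (or 5% for
    the alternative cutoff), three levels as [0,1), [1,50), [50,100].
    RNA modes split PD-L1 gene expression at the median (two levels) or at
    the 25th/75th percentiles (three levels); percentile cutoffs are
    computed on the reference population (ICI arm or all patients).
    Patients missing the required field are excluded and counted.

    Returns ``(strata, n_excluded)`` where strata is an ordered
    categorical Series indexed by patient_id.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown stratification mode '{mode}'")
    labels = STRATA_LABELS[mode]
    pid = clinical["patient_id"]
    if mode.startswith("IHC"):
        vals = pd.to_numeric(clinical["pdl1_ihc"], errors="coerce").to_numpy()
        cutoffs = {"IHC2": [1.0], "IHC2_ALT": [5.0], "IHC3": [1.0, 50.0]}[mode]
    else:
        if expression is None or pdl1_gene not in expression.index:
            raise ValidationError(f"PD-L1 gene '{pdl1_gene}' expression required "
                                  f"for mode {mode}")
        vals = expression.loc[pdl1_gene, pid].to_numpy(dtype=float)
        if reference == "TREATED_ARM":
            ref_mask = (clinical["arm"] == "ICI").to_numpy()
        else:
            ref_mask = np.ones(len(clinical), dtype=bool)
        ref_vals = vals[ref_mask & ~np.isnan(vals)]
        if ref_vals.size == 0:
            raise ValidationError("no reference-population values to set cutoffs")
        if mode == "RNA2":
            cutoffs = [float(np.median(ref_vals))]
        else:
            cutoffs = [float(np.percentile(ref_vals, 25)),
                       float(np.percentile(ref_vals, 75))]
    idx = np.searchsorted(np.asarray(cutoffs), vals, side="right")
    assigned = np.where(np.isnan(vals), None,
                        np.asarray(labels, dtype=object)[np.minimum(idx, len(labels) - 1)])
    strata = pd.Series(pd.Categorical(assigned, categories=labels, ordered=True),
                       index=pd.Index(pid, name="patient_id"), name="stratum")
    n_excluded = int(strata.isna().sum())
    return strata.dropna(), n_excluded


def _surv_metrics(a: pd.DataFrame, b: pd.DataFrame, endpoint: str) -> dict:
    """Univariate Cox HR of a vs b plus log-rank p for one endpoint."""
    dur = {"OS": "os_time", "PFS": "pfs_time"}[endpoint]
    ev = {"OS": "os_event", "PFS": "pfs_event"}[endpoint]
    out = {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
           "logrank_p": np.nan, "estimable": False}
    if len(a) == 0 or len(b) == 0:
        return out
    df = pd.concat([a.assign(_g=1), b.assign(_g=0)], ignore_index=True)
    try:
        fit = fit_cox(df, dur, ev, ["_g"])
        if not fit.converged:
            return out
        s = fit.summary.loc["_g"]
        _, _, _, p = km_logrank(a[dur], a[ev], b[dur], b[ev])
        out.update(hr=float(s["hr"]), ci_low=float(s["ci_low"]),
                   ci_high=float(s["ci_high"]), logrank_p=p, estimable=True)
    except ValidationError:
        pass
    return out


def _orr_metrics(a: pd.DataFrame, b: pd.DataFrame,
                 evaluable_only: bool = False) -> dict:
    """Response rates with Clopper-Pearson CIs and Fisher exact p."""
    out = {"orr_a": np.nan, "orr_a_ci_low": np.nan, "orr_a_ci_high": np.nan,
           "orr_b": np.nan, "orr_b_ci_low": np.nan, "orr_b_ci_high": np.nan,
           "fisher_p": np.nan, "estimable": False}
    if evaluable_only:
        a = a[a["response"] != "NE"]
        b = b[b["response"] != "NE"]
    if len(a) == 0 or len(b) == 0:
        return out
    ra = int(a["response"].isin(RESPONDER_LEVELS).sum())
    rb = int(b["response"].isin(RESPONDER_LEVELS).sum())
    na, nb = len(a), len(b)
    lo_a, hi_a = clopper_pearson(ra, na)
    lo_b, hi_b = clopper_pearson(rb, nb)
    try:
        p = fisher_exact([[ra, na - ra], [rb, nb - rb]])
    except ValidationError:
        p = np.nan
    out.update(orr_a=ra / na, orr_a_ci_low=lo_a, orr_a_ci_high=hi_a,
               orr_b=rb / nb, orr_b_ci_low=lo_b, orr_b_ci_high=hi_b,
               fisher_p=p, estimable=True)
    return out


def efficacy_grid(clinical: pd.DataFrame, scores: pd.DataFrame,
                  strata: pd.Series, comparison: str,
                  endpoints: Sequence[str] = ("OS", "PFS", "ORR"),
                  groups: Sequence[str] = ("PH", "PL", "ALL"),
                  evaluable_only: bool = False) -> pd.DataFrame:
    """Efficacy rows per (predictiveness group x stratum pair x endpoint).

    ``POS_vs_NEG_within_ICI`` compares each upper biomarker stratum
    against the lowest one among ICI-treated patients (a = upper stratum);
    ``ICI_vs_CHEMO_within_stratum`` compares arms within each stratum
    (a = ICI).  ``scores`` is the output of
    :func:`predscreen.score.score_and_split`.
    """
    if comparison not in COMPARISONS:
        raise ValidationError(f"unknown comparison '{comparison}'")
    df = clinical.merge(scores[["patient_id", "group"]], on="patient_id",
                        how="inner")
    df = df.join(strata.rename("stratum"), on="patient_id", how="inner")
    levels = list(strata.cat.categories)
    rows = []
    for grp in groups:
        gdf = df if grp == "ALL" else df[df["group"] == grp]
        if comparison == "POS_vs_NEG_within_ICI":
            gdf = gdf[gdf["arm"] == "ICI"]
            ref = gdf[gdf["stratum"] == levels[0]]
            cells = [(f"{lv} vs {levels[0]}", gdf[gdf["stratum"] == lv], ref)
                     for lv in levels[1:]]
        else:
            cells = [(lv,
                      gdf[(gdf["stratum"] == lv) & (gdf["arm"] == "ICI")],
                      gdf[(gdf["stratum"] == lv) & (gdf["arm"] == "CHEMO")])
                     for lv in levels]
        for label, a, b in cells:
            for endpoint in endpoints:
                rec = {"group": grp, "stratum": label, "comparison": comparison,
                       "endpoint": endpoint, "n_a": len(a), "n_b": len(b)}
                if endpoint == "ORR":
                    rec.update(_orr_metrics(a, b, evaluable_only=evaluable_only))
                else:
                    rec.update(_surv_metrics(a, b, endpoint))
                rows.append(rec)
    out = pd.DataFrame(rows)
    return out.reindex(columns=GRID_COLUMNS)


def km_table(time, event) -> pd.DataFrame:
    """Kaplan-Meier step function as a (time, survival, at_risk) table."""
    curve = km_curve(time, event)
    t = np.asarray(time, dtype=float)
    at_risk = [int(np.sum(t >= x)) for x in curve.times]
    return pd.DataFrame({"time": curve.times, "survival": curve.survival,
                         "at_risk": at_risk})
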