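"""Transcriptomic modulator screen.

Two steps, mirroring a cross-cancer-then-within-cohort design:

1. *Cross-cancer screen*: per candidate gene, Spearman-correlate the
   per-cancer median expression (reference tumor atlas panel, genes on the
   log2(TPM+0.001) scale) with the per-cancer hazard-ratio difference for
   OS and for PFS.  Genes significant for both endpoints (unadjusted
   p < alpha, default 0.05) pass to step two.

2. *Within-cohort interaction ranking*: in a single treatment arm, fit the
   Cox model  hazard ~ a*B + b*V + d*B*V  per candidate V, where B is the
   biomarker indicator and both B and V are dichotomized at the in-arm
   median (value >= median -> 1).  Candidates are ranked by the Wald
   z = d / se(d); a positive d means high V erodes the favorable
   association between the biomarker and outcome.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .meta import PredictivenessResult
from .stats import ValidationError, fit_cox, spearman

__all__ = ["median_profile", "cross_cancer_screen", "dichotomize",
           "rank_interactions"]


def median_profile(panel: pd.DataFrame, sample_cancer: Mapping[str, str] | pd.Series,
                   genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-cancer median expression (cancers x genes).

    ``panel`` is genes x samples; ``sample_cancer`` maps every sample
    (column) to its cancer type.  Medians use the midpoint convention for
    even counts (numpy default).
    """
    sc = pd.Series(sample_cancer)
    missing_samples = [s for s in panel.columns if s not in sc.index]
    if missing_samples:
        raise ValidationError(
            f"sample->cancer map does not cover samples: {missing_samples[:5]}")
    if panel.isna().any().any():
        raise ValidationError("expression panel contains missing values")
    if genes is not None:
        absent = [g for g in genes if g not in panel.index]
        if absent:
            raise ValidationError(f"genes absent from panel: {absent}")
        panel = panel.loc[list(genes)]
    out = panel.T.groupby(sc.reindex(panel.columns)).median()
    out.index.name = "cancer"
    return out


def cross_cancer_screen(medians: pd.DataFrame,
                        predictiveness_os: PredictivenessResult,
                        predictiveness_pfs: PredictivenessResult,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Correlate gene medians with HRD across cancers for both endpoints.

    Returns one row per gene with rho/p per endpoint, an unadjusted
    ``passes`` flag (p < alpha for OS *and* PFS), and Benjamini-Hochberg
    q-value columns for reference only (never used by ``passes``).
    Rows are sorted by min(p_os, p_pfs).
    """
    hrd_os = predictiveness_os.hrd_series()
    hrd_pfs = predictiveness_pfs.hrd_series()
    rows = []
    for endpoint_name, hrd in (("os", hrd_os), ("pfs", hrd_pfs)):
        shared = sorted(set(medians.index) & set(hrd.index))
        if len(shared) < 3:
            raise ValidationError(
                f"need >= 3 cancers shared with {endpoint_name.upper()} "
                f"predictiveness, found {len(shared)}")
    res = {}
    for gene in medians.columns:
        rec = {"gene": gene}
        for name, hrd in (("os", hrd_os), ("pfs", hrd_pfs)):
            shared = sorted(set(medians.index) & set(hrd.index))
            rho, p = spearman(medians.loc[shared, gene].to_numpy(),
                              hrd.loc[shared].to_numpy())
            rec[f"rho_{name}"] = rho
            rec[f"p_{name}"] = p
        res[gene] = rec
    out = pd.DataFrame(res.values())
    out["passes"] = (out["p_os"] < alpha) & (out["p_pfs"] < alpha)
    for name in ("os", "pfs"):
        pvals = out[f"p_{name}"].fillna(1.0)
        out[f"q_{name}"] = multipletests(pvals, method="fdr_bh")[1]
    out["min_p"] = out[["p_os", "p_pfs"]].min(axis=1)
    out = (out.sort_values(["min_p", "gene"], kind="stable")
              .drop(columns="min_p").reset_index(drop=True))
    return out


def dichotomize(values, cutoff="median") -> np.ndarray:
    """0/1 coding of a vector at a cutoff: 1 iff value >= cutoff.

    ``cutoff="median"`` resolves the cutoff on the supplied vector itself,
    so ties at the median are coded 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot dichotomize an empty vector")
    if isinstance(cutoff, str):
        if cutoff != "median":
            raise ValidationError(f"unknown cutoff '{cutoff}'")
        if np.ptp(v) == 0:
            raise ValidationError(
                "all values identical: median dichotomization would produce "
                "a constant covariate")
        cut = float(np.median(v))
    else:
        cut = float(cutoff)
    return (v >= cut).astype(int)


def rank_interactions(clinical: pd.DataFrame, expression: pd.DataFrame,
                      biomarker: str, candidates: Sequence[str],
                      endpoint: str = "OS") -> pd.DataFrame:
    """Rank candidate modulators by their Cox interaction z with a biomarker.

    ``clinical`` must already be restricted to one treatment arm by the
    caller (the ranking is defined within treated patients); ``expression``
    is genes x patients.  Both the biomarker gene and each candidate are
    dichotomized at the in-arm median.  Output columns: gene, endpoint, d,
    se_d, z, p, estimable — sorted by z descending, non-estimable fits
    last, ties broken lexicographically by gene id.
    """
    if len(list(candidates)) == 0:
        raise ValidationError("empty candidate list")
    endpoint = endpoint.upper()
    dur_col = {"OS": "os_time", "PFS": "pfs_time"}[endpoint]
    ev_col = {"OS": "os_event", "PFS": "pfs_event"}[endpoint]
    patients = [p for p in clinical["patient_id"] if p in expression.columns]
    if len(patients) < len(clinical):
        raise ValidationError("expression matrix does not cover the cohort")
    cl = clinical.set_index("patient_id").loc[patients]
    if biomarker not in expression.index:
        raise ValidationError(f"biomarker gene '{biomarker}' absent from panel")
    bm = dichotomize(expression.loc[biomarker, patients].to_numpy())
    rows = []
    for gene in candidates:
        if gene not in expression.index:
            raise ValidationError(f"candidate gene '{gene}' absent from panel")
        rec = {"gene": gene, "endpoint": endpoint, "d": np.nan,
               "se_d": np.nan, "z": np.nan, "p": np.nan, "estimable": False}
        try:
            v = dichotomize(expression.loc[gene, patients].to_numpy())
            df = pd.DataFrame({
                "time": cl[dur_col].to_numpy(dtype=float),
                "event": cl[ev_col].to_numpy(dtype=int),
                "biomarker": bm,
                "modulator": v,
                "interaction": bm * v,
            })
            fit = fit_cox(df, "time", "event",
                          ["biomarker", "modulator", "interaction"])
            if fit.converged:
                s = fit.summary.loc["interaction"]
                rec.update(d=float(s["coef"]), se_d=float(s["se"]),
                           z=float(s["z"]), p=float(s["p"]), estimable=True)
        except (ValidationError, np.linalg.LinAlgError):
            pass
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["_sortz"] = out["z"].where(out["estimable"], -np.inf)
    out = (out.sort_values(["_sortz", "gene"], ascending=[False, True],
                           kind="stable")
              .drop(columns="_sortz").reset_index(drop=True))
    return out
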