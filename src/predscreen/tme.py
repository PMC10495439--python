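"""Tumor-microenvironment profiling.

Expression preprocessing (quantile normalization plus per-gene centering),
mean-expression immune signature scoring (e.g. the IFN-gamma signature, or
the CD8 score as the mean of CD8A/CD8B), resampled hierarchical consensus
clustering of cell-fraction profiles into immune subtypes, and robustness
subgrouping of the efficacy evaluation by tumor mutation burden (16 mut/Mb
cutoff), neoantigen burden (median), or immune subtype.

Cell fractions are accepted as input (deconvolution happens upstream);
the derived "Stromal" quantity is the sum of the Endothelium and
Fibroblasts fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .efficacy import efficacy_grid
from .stats import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "quantile_normalize", "normalize_expression",
           "signature_scores",
           "ConsensusResult", "consensus_cluster", "assign_immune_subtype",
           "stromal_fraction", "robustness_subgroups"]

LYMPHOCYTE_TYPES = ("T_cells", "CD8_T_cells", "CD4_T_cells", "B_cells",
                    "NK_cells", "Plasma_B_cells")
STROMAL_TYPES = ("Endothelium", "Fibroblasts")


@dataclass(frozen=True)
class GeneSet:
    """Named gene set (GMT record)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValidationError(f"gene set '{self.name}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set '{self.name}' has duplicate ids")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the shared rank-mean distribution.

    Sort each column, average across columns at each rank to build the
    reference distribution, and hand each value the reference value of
    its rank; tied input values share the mean of their reference values
    (midrank averaging).  After this step all columns hold identical
    value multisets.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        return matrix.astype(float).copy()
    ref = np.sort(x, axis=0).mean(axis=1)
    qn = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        qn[:, j] = ref[ranks]
        # midrank averaging: tied input values share the mean reference value
        vals, inv = np.unique(col, return_inverse=True)
        if len(vals) < len(col):
            sums = np.bincount(inv, weights=qn[:, j])
            counts = np.bincount(inv)
            qn[:, j] = (sums / counts)[inv]
    return pd.DataFrame(qn, index=matrix.index, columns=matrix.columns)


def normalize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples, then center every gene at mean zero.

    A single-sample matrix is centered only (a warning is logged).
    """
    if matrix.shape[1] < 2:
        logger.warning("single sample: quantile step skipped, centering only")
        qn = matrix.to_numpy(dtype=float)
    else:
        qn = quantile_normalize(matrix).to_numpy()
    qn = qn - qn.mean(axis=1, keepdims=True)
    return pd.DataFrame(qn, index=matrix.index, columns=matrix.columns)


def signature_scores(matrix: pd.DataFrame,
                     sets: Sequence[GeneSet]) -> tuple[pd.DataFrame, dict]:
    """Mean-expression signature scores (samples x signatures).

    Each score is the unweighted mean over the signature genes present in
    the matrix; the fraction of genes found is reported per signature in
    the coverage dict.  A signature with no present genes scores NaN.
    """
    scores = {}
    coverage = {}
    for gs in sets:
        present = [g for g in gs.genes if g in matrix.index]
        coverage[gs.name] = len(present) / len(gs.genes)
        if not present:
            logger.warning("signature '%s': no genes present, score undefined",
                           gs.name)
            scores[gs.name] = pd.Series(np.nan, index=matrix.columns)
        else:
            scores[gs.name] = matrix.loc[present].mean(axis=0)
    out = pd.DataFrame(scores)
    out.index.name = "sample"
    return out, coverage


@dataclass
class ConsensusResult:
    """Resampled-consensus clustering output across k = 2..maxK."""

    consensus: dict        # k -> (n x n) consensus matrix
    assignments: dict      # k -> int labels (1..k) per sample
    cdf: dict              # k -> (grid, cdf values) of off-diagonal consensus
    delta_area: dict       # k -> relative change in area under the CDF
    chosen_k: int
    samples: list

    def matrix(self, k: int | None = None) -> np.ndarray:
        return self.consensus[k or self.chosen_k]

    def labels(self, k: int | None = None) -> np.ndarray:
        return self.assignments[k or self.chosen_k]


def _pair_distance(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        # 1 - Pearson correlation between sample profiles
        d = pdist(x, metric="correlation")
        return np.nan_to_num(d, nan=1.0)
    return pdist(x, metric="euclidean")


def consensus_cluster(features: pd.DataFrame, max_k: int = 6,
                      reps: int = 1000, p_item: float = 0.8,
                      p_feature: float = 1.0, seed: int | None = None,
                      linkage_method: str = "average",
                      metric: str = "correlation",
                      delta_area_threshold: float = 0.1) -> ConsensusResult:
    """Consensus clustering by resampled hierarchical agglomeration.

    Per repetition: subsample ``p_item`` of the samples (and ``p_feature``
    of the features), cluster hierarchically, and cut at each k in
    2..max_k.  The consensus entry for a sample pair at a given k is the
    fraction of co-sampled repetitions in which the pair co-clustered.
    Final assignments cluster (1 - consensus) hierarchically and cut at k.
    ``chosen_k`` is the largest k whose relative delta area under the
    consensus CDF exceeds the threshold.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    x = features.to_numpy(dtype=float)
    n, m = x.shape
    if n < max_k + 1:
        raise ValidationError(f"need at least max_k+1={max_k + 1} samples, "
                              f"have {n}")
    rng = np.random.default_rng(seed)
    ks = list(range(2, max_k + 1))
    n_item = max(2, int(round(p_item * n)))
    n_feat = max(1, int(round(p_feature * m)))
    co_count = {k: np.zeros((n, n)) for k in ks}
    pair_count = np.zeros((n, n))
    for _ in range(reps):
        items = np.sort(rng.choice(n, size=n_item, replace=False))
        feats = (np.arange(m) if n_feat == m
                 else np.sort(rng.choice(m, size=n_feat, replace=False)))
        sub = x[np.ix_(items, feats)]
        d = _pair_distance(sub, metric)
        z = linkage(d, method=linkage_method)
        ones = np.ones(n_item)
        pair_count[np.ix_(items, items)] += np.outer(ones, ones)
        for k in ks:
            labels = fcluster(z, t=k, criterion="maxclust")
            same = (labels[:, None] == labels[None, :]).astype(float)
            co_count[k][np.ix_(items, items)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {}
        for k in ks:
            c = np.where(pair_count > 0, co_count[k] / np.maximum(pair_count, 1), 0.0)
            np.fill_diagonal(c, 1.0)
            consensus[k] = c
    assignments = {}
    for k in ks:
        d = squareform(1.0 - consensus[k], checks=False)
        z = linkage(d, method=linkage_method)
        assignments[k] = fcluster(z, t=k, criterion="maxclust")
    # CDF of the off-diagonal consensus values and areas under it
    grid = np.linspace(0.0, 1.0, 101)
    iu = np.triu_indices(n, k=1)
    cdf = {}
    areas = {}
    for k in ks:
        vals = consensus[k][iu]
        cdf_vals = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
        cdf[k] = (grid, cdf_vals)
        areas[k] = float(np.trapezoid(cdf_vals, grid))
    delta_area = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta_area[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    chosen = [k for k in ks if delta_area[k] > delta_area_threshold]
    chosen_k = max(chosen) if chosen else ks[0]
    return ConsensusResult(consensus=consensus, assignments=assignments,
                           cdf=cdf, delta_area=delta_area, chosen_k=chosen_k,
                           samples=list(features.index))


def stromal_fraction(cell_fractions: pd.DataFrame) -> pd.Series:
    """Stromal cells = Endothelium + Fibroblasts, per sample."""
    missing = [c for c in STROMAL_TYPES if c not in cell_fractions.columns]
    if missing:
        raise ValidationError(f"missing stromal cell-type columns: {missing}")
    return cell_fractions[list(STROMAL_TYPES)].sum(axis=1).rename("Stromal")


def assign_immune_subtype(cell_fractions: pd.DataFrame, seed: int | None = None,
                          lymphocyte_types: Sequence[str] | None = None,
                          reps: int = 200, metric: str = "euclidean",
                          linkage_method: str = "ward") -> pd.Series:
    """Two-way consensus clustering of cell fractions into immune subtypes.

    The cluster with the higher mean summed lymphocyte fraction is labeled
    ``ImmuneEnriched``; the other ``NonImmune``.  Fraction profiles are
    compositional vectors over a handful of cell types, so the defaults
    here are Euclidean distance with Ward linkage (compact, balanced
    clusters) rather than the correlation/average-linkage defaults of the
    general consensus engine, where chaining on a compositional continuum
    tends to split off singletons.
    """
    lymph = [c for c in (lymphocyte_types or LYMPHOCYTE_TYPES)
             if c in cell_fractions.columns]
    if not lymph:
        raise ValidationError(
            f"no lymphocyte columns found among {lymphocyte_types or LYMPHOCYTE_TYPES}")
    res = consensus_cluster(cell_fractions, max_k=2, reps=reps, seed=seed,
                            metric=metric, linkage_method=linkage_method)
    labels = res.assignments[2]
    lymph_sum = cell_fractions[lymph].sum(axis=1).to_numpy()
    means = {lab: lymph_sum[labels == lab].mean() for lab in np.unique(labels)}
    enriched = max(means, key=means.get)
    out = pd.Series(np.where(labels == enriched, "ImmuneEnriched", "NonImmune"),
                    index=cell_fractions.index, name="immune_subtype")
    return out


def robustness_subgroups(clinical: pd.DataFrame, scores: pd.DataFrame,
                         strata: pd.Series, rule: str,
                         comparison: str = "POS_vs_NEG_within_ICI",
                         endpoints: Sequence[str] = ("OS", "PFS", "ORR"),
                         immune_subtypes: pd.Series | None = None,
                         tmb_cutoff: float = 16.0) -> dict[str, pd.DataFrame]:
    """Re-run the efficacy grid within antigenicity or immune subgroups.

    Rules: ``TMB16`` (tumor mutation burden >= 16 mut/Mb is HIGH),
    ``TNB_MEDIAN`` (neoantigen burden >= cohort median is HIGH), or
    ``IMMUNE_SUBTYPE`` (externally supplied labels).  Patients missing the
    splitting field are excluded; the returned dict maps each level to its
    efficacy grid.
    """
    if rule == "TMB16":
        if "tmb" not in clinical.columns:
            raise ValidationError("TMB column absent from clinical table")
        vals = pd.to_numeric(clinical["tmb"], errors="coerce")
        if vals.isna().all():
            raise ValidationError("TMB missing for all patients")
        levels = pd.Series(np.where(vals >= tmb_cutoff, "TMB_HIGH", "TMB_LOW"),
                           index=clinical.index).where(~vals.isna())
    elif rule == "TNB_MEDIAN":
        if "tnb" not in clinical.columns:
            raise ValidationError("TNB column absent from clinical table")
        vals = pd.to_numeric(clinical["tnb"], errors="coerce")
        if vals.isna().all():
            raise ValidationError("TNB missing for all patients")
        med = float(vals.median())
        levels = pd.Series(np.where(vals >= med, "TNB_HIGH", "TNB_LOW"),
                           index=clinical.index).where(~vals.isna())
    elif rule == "IMMUNE_SUBTYPE":
        if immune_subtypes is None:
            raise ValidationError("IMMUNE_SUBTYPE rule needs subtype labels")
        levels = clinical["patient_id"].map(immune_subtypes)
        levels.index = clinical.index
        if levels.isna().all():
            raise ValidationError("immune subtype missing for all patients")
    else:
        raise ValidationError(f"unknown rule '{rule}'")
    out = {}
    for level in sorted(levels.dropna().unique()):
        sub = clinical[levels == level]
        out[level] = efficacy_grid(sub, scores, strata, comparison,
                                   endpoints=endpoints)
    return out
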