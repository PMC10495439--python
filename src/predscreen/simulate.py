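"""Synthetic inputs with known ground truth.

Three generators emulate the three input kinds the pipeline consumes:

* :func:`simulate_trial_table` — trial-level subgroup hazard ratios with
  between-trial heterogeneity, built so that each cancer's true
  HR(neg) - HR(pos) equals a planted hazard-ratio difference (HRD);
* :func:`simulate_expression_panel` — a per-cancer expression panel in
  which one planted modulator gene's cancer medians lie (up to noise) on
  the inverse of a planted linear HRD-vs-median relationship, among
  decoy genes with cancer-permuted medians;
* :func:`simulate_cohort` — a two-arm patient cohort whose event times
  follow a proportional-hazards model with a planted
  treatment x biomarker x modulator interaction structure, independent
  uniform administrative censoring calibrated to a target rate, a
  logistic response model, and an IHC readout linked monotonically to
  PD-L1 gene expression.

Every generator is a pure function of its configuration (including the
seed) and returns a :class:`TruthManifest` sufficient to recompute every
planted quantity.  :func:`recovery_experiment` chains the whole pipeline
over many seeds and reports recovery statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import efficacy, meta, score, screen
from .stats import Z95, ValidationError

__all__ = ["SimulationConfig", "TruthManifest", "simulate_trial_table",
           "simulate_expression_panel", "simulate_cohort",
           "simulate_cell_fractions", "run_pipeline_once",
           "recovery_experiment", "paper_pattern_config", "null_config"]

COEF_KEYS = ("T", "P", "V", "PV", "TP", "TPV")


def _coef(T=0.0, P=0.0, V=0.0, PV=0.0, TP=0.0, TPV=0.0) -> dict:
    return {"T": T, "P": P, "V": V, "PV": PV, "TP": TP, "TPV": TPV}


@dataclass
class SimulationConfig:
    """All knobs of the three generators.

    The defaults are the study conditions of the qualitative pattern the
    pipeline is meant to recover: ten cancer types with planted HRDs
    spanning the published range (-0.4 to 1.0), a modulator whose cancer
    medians follow PS-line coefficients slope -0.76 / intercept 2.81, and
    a 1200-patient two-arm cohort in which the ICI-arm biomarker effect is
    -0.4 + 0.8*V on the log-hazard scale (modulator-present patients lose
    the benefit association; within-arm interaction d = 0.8).
    """

    seed: int = 0
    # trial table
    n_cancers: int = 10
    trials_per_cancer: int = 3
    per_arm_n: int = 300
    tau: float = 0.05                 # between-trial sd of log-HR
    hrd_range: tuple = (-0.4, 1.0)   # planted per-cancer HRD grid (OS)
    pfs_hrd_scale: float = 0.8       # PFS HRD = scale * OS HRD
    hr_center: float = 0.85          # subgroup HRs straddle this center
    event_fraction: float = 0.7      # trial events per enrolled patient
    # expression panel
    modulator_slope: float = -0.76
    modulator_intercept: float = 2.81
    n_decoy_genes: int = 30
    samples_per_cancer: int = 50
    median_noise_sd: float = 0.05    # on the HRD scale, before inversion
    within_cancer_sd: float = 0.3
    planted_gene: str = "CDKN1C"
    pdl1_gene: str = "CD274"
    # patient cohort
    cohort_n: int = 1200
    coef: dict = field(default_factory=lambda: _coef(
        T=-0.2, P=0.1, V=0.05, PV=0.0, TP=-0.5, TPV=0.8))
    baseline_hazard: float = 0.05    # events per month at covariates 0
    weibull_shape: float = 1.0
    frailty_theta: float = 0.1       # gamma-frailty variance shared OS/PFS
    pfs_rate_ratio: float = 2.0      # PFS hazard multiplier vs OS
    censor_rate: float = 0.3
    response_intercept: float = -1.9
    response_coef: dict = field(default_factory=lambda: _coef(
        T=0.3, P=-0.15, V=0.0, PV=0.0, TP=0.75, TPV=-1.2))
    pdl1_ihc_link: dict = field(default_factory=lambda: {
        "slope": 2.5, "center": 3.5, "noise_sd": 1.0})

    def __post_init__(self):
        for name in ("n_cancers", "trials_per_cancer", "per_arm_n",
                     "samples_per_cancer", "cohort_n"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")

    def planted_hrd(self, endpoint: str = "OS") -> np.ndarray:
        lo, hi = self.hrd_range
        grid = (np.linspace(lo, hi, self.n_cancers) if self.n_cancers > 1
                else np.array([(lo + hi) / 2]))
        return grid if endpoint == "OS" else self.pfs_hrd_scale * grid

    def cancers(self) -> list[str]:
        return [f"cancer_{i + 1:02d}" for i in range(self.n_cancers)]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def paper_pattern_config(seed: int = 0, **kw) -> SimulationConfig:
    """Preset with the full planted interaction pattern (the defaults)."""
    return SimulationConfig(seed=seed, **kw)


def null_config(seed: int = 0, **kw) -> SimulationConfig:
    """Preset with no planted effects anywhere."""
    base = dict(
        hrd_range=(0.0, 0.0),
        coef=_coef(),
        response_coef=_coef(),
        median_noise_sd=0.3,   # decouples the modulator from the (flat) HRD
    )
    base.update(kw)
    return SimulationConfig(seed=seed, **base)


@dataclass
class TruthManifest:
    """Planted quantities of one simulation, serializable to JSON."""

    seed: int
    planted_gene: str
    hrd_os: dict = field(default_factory=dict)      # cancer -> true OS HRD
    hrd_pfs: dict = field(default_factory=dict)
    slope: float = 0.0
    intercept: float = 0.0
    coef: dict = field(default_factory=dict)
    response_coef: dict = field(default_factory=dict)
    realized_censoring_os: float = float("nan")
    realized_censoring_pfs: float = float("nan")
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TruthManifest":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# trial tables


def simulate_trial_table(config: SimulationConfig
                         ) -> tuple[pd.DataFrame, TruthManifest]:
    """Trial-level subgroup HRs for both endpoints with planted HRDs.

    Per cancer, the true subgroup HRs are ``hr_center -/+ HRD/2`` (so
    HR_neg - HR_pos is exactly the planted HRD); per trial, a
    Normal(0, tau) heterogeneity shift and finite-sample noise with
    standard error implied by the per-arm event count are added on the
    log scale.
    """
    rng = np.random.default_rng(config.seed)
    cancers = config.cancers()
    rows = []
    truth = TruthManifest(seed=config.seed, planted_gene=config.planted_gene)
    for endpoint in ("OS", "PFS"):
        hrds = config.planted_hrd(endpoint)
        store = truth.hrd_os if endpoint == "OS" else truth.hrd_pfs
        for cancer, hrd in zip(cancers, hrds):
            store[cancer] = float(hrd)
            hr_true = {"BM_POS": config.hr_center - hrd / 2.0,
                       "BM_NEG": config.hr_center + hrd / 2.0}
            if min(hr_true.values()) <= 0:
                raise ValidationError(
                    f"planted HRD {hrd} incompatible with hr_center "
                    f"{config.hr_center} (non-positive subgroup HR)")
            events = max(2.0, config.event_fraction * config.per_arm_n)
            se = float(np.sqrt(2.0 / events))
            for t in range(config.trials_per_cancer):
                for sg, hr0 in hr_true.items():
                    y = (np.log(hr0)
                         + rng.normal(0.0, config.tau)
                         + rng.normal(0.0, se))
                    rows.append({
                        "trial_id": f"{cancer}_trial{t + 1}",
                        "cancer": cancer,
                        "endpoint": endpoint,
                        "subgroup": sg,
                        "hr": float(np.exp(y)),
                        "ci_low": float(np.exp(y - Z95 * se)),
                        "ci_high": float(np.exp(y + Z95 * se)),
                        "n": int(2 * config.per_arm_n),
                    })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# expression panels


def simulate_expression_panel(config: SimulationConfig
                              ) -> tuple[pd.DataFrame, pd.Series, TruthManifest]:
    """Per-cancer expression panel with a planted modulator gradient.

    The planted gene's cancer median is the planted line inverted at that
    cancer's (noised) OS HRD: median = (HRD - intercept) / slope.  Decoy
    genes receive the same medians permuted across cancers, destroying
    any systematic association while preserving the marginal spread.
    Per-sample values are the cancer median plus within-cancer noise.

    Returns (panel genes x samples, sample->cancer map, truth).
    """
    rng = np.random.default_rng(config.seed + 1)
    cancers = config.cancers()
    hrd = config.planted_hrd("OS")
    truth = TruthManifest(seed=config.seed, planted_gene=config.planted_gene,
                          slope=config.modulator_slope,
                          intercept=config.modulator_intercept,
                          hrd_os=dict(zip(cancers, map(float, hrd))),
                          hrd_pfs=dict(zip(cancers,
                                           map(float, config.planted_hrd("PFS")))))
    noisy = hrd + rng.normal(0.0, config.median_noise_sd, size=len(cancers))
    planted_medians = (noisy - config.modulator_intercept) / config.modulator_slope
    genes = [config.planted_gene] + [f"DECOY_{i + 1:03d}"
                                     for i in range(config.n_decoy_genes)]
    medians = {config.planted_gene: planted_medians}
    for g in genes[1:]:
        medians[g] = rng.permutation(planted_medians)
    samples, sample_cancer, cols = [], [], []
    for ci, cancer in enumerate(cancers):
        for s in range(config.samples_per_cancer):
            sid = f"{cancer}_s{s + 1:03d}"
            samples.append(sid)
            sample_cancer.append(cancer)
            cols.append(np.array([medians[g][ci] for g in genes])
                        + rng.normal(0.0, config.within_cancer_sd, len(genes)))
    panel = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="gene"),
                         columns=samples)
    truth.extras["planted_medians"] = dict(
        zip(cancers, map(float, planted_medians)))
    return panel, pd.Series(sample_cancer, index=samples, name="cancer"), truth


# ---------------------------------------------------------------------------
# patient cohorts


def _calibrate_censor_window(times: np.ndarray, target: float) -> float:
    """Upper bound c of U(0, c) censoring so E[fraction censored] = target."""
    if target <= 0:
        return float(np.inf)

    def frac_censored(c):
        return float(np.mean(np.minimum(times, c) / c)) - target

    lo, hi = 1e-9, float(times.max()) * 1e6
    return float(brentq(frac_censored, lo, hi))


def _draw_survival(rng, rate, shape, frailty):
    """Event times from a (Weibull) proportional-hazards model."""
    e = rng.exponential(1.0, size=rate.shape)
    t = e / (rate * frailty)
    if shape != 1.0:
        t = t ** (1.0 / shape)
    return t


def _linpred(coef: dict, T, P, V) -> np.ndarray:
    return (coef["T"] * T + coef["P"] * P + coef["V"] * V
            + coef["PV"] * P * V + coef["TP"] * T * P
            + coef["TPV"] * T * P * V)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """Two-arm patient cohort with planted interaction structure.

    Hazard: baseline * exp(bT*T + bP*P + bV*V + bPV*P*V + bTP*T*P +
    bTPV*T*P*V) with T the ICI-arm indicator and P, V the biomarker /
    modulator indicators dichotomized at their generating medians.  OS and
    PFS share a gamma frailty so their interaction patterns correlate.
    Censoring is uniform administrative, calibrated to the target rate.
    Response is Bernoulli from the logistic analogue; IHC percent is a
    noisy logistic transform of PD-L1 gene expression.

    Returns (clinical table, expression genes x patients, truth).
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.cohort_n
    pid = [f"pt_{i + 1:04d}" for i in range(n)]
    arm = np.array(["ICI", "CHEMO"])[rng.permutation(n) % 2]
    T = (arm == "ICI").astype(int)

    genes = [config.pdl1_gene, config.planted_gene] + [
        f"DECOY_{i + 1:03d}" for i in range(config.n_decoy_genes)]
    gene_means = {config.pdl1_gene: 2.0, config.planted_gene: 3.3}
    for g in genes[2:]:
        gene_means[g] = float(rng.uniform(1.0, 6.0))
    expr = np.vstack([gene_means[g] + rng.normal(0.0, 0.8, n) for g in genes])
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                              columns=pid)

    pdl1 = expression.loc[config.pdl1_gene].to_numpy()
    mod = expression.loc[config.planted_gene].to_numpy()
    P = (pdl1 >= np.median(pdl1)).astype(int)
    V = (mod >= np.median(mod)).astype(int)

    link = config.pdl1_ihc_link
    logit = (link["slope"] * (pdl1 - link["center"])
             + rng.normal(0.0, link["noise_sd"], n))
    ihc = np.clip(100.0 / (1.0 + np.exp(-logit)), 0.0, 100.0)

    frailty = (rng.gamma(1.0 / config.frailty_theta,
                         config.frailty_theta, size=n)
               if config.frailty_theta > 0 else np.ones(n))
    lp = _linpred(config.coef, T, P, V)
    rate_os = config.baseline_hazard * np.exp(lp)
    t_os = _draw_survival(rng, rate_os, config.weibull_shape, frailty)
    t_pfs = _draw_survival(rng, rate_os * config.pfs_rate_ratio,
                           config.weibull_shape, frailty)
    t_pfs = np.minimum(t_pfs, t_os)  # progression precedes or equals death

    clin = {"patient_id": pid, "arm": arm}
    realized = {}
    for name, t in (("os", t_os), ("pfs", t_pfs)):
        c = _calibrate_censor_window(t, config.censor_rate)
        cens = rng.uniform(0.0, c, n) if np.isfinite(c) else np.full(n, np.inf)
        observed = np.minimum(t, cens)
        event = (t <= cens).astype(int)
        clin[f"{name}_time"] = np.maximum(observed, 1e-6)
        clin[f"{name}_event"] = event
        realized[name] = float(1.0 - event.mean())

    logit_r = config.response_intercept + _linpred(config.response_coef, T, P, V)
    responder = rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit_r))
    resp = np.where(responder, "PR", np.where(rng.uniform(size=n) < 0.4,
                                              "SD", "PD"))
    ne = rng.uniform(size=n) < 0.03  # a small non-evaluable fraction
    resp = np.where(ne, "NE", resp)

    clinical = pd.DataFrame(clin)
    clinical["response"] = resp
    clinical["pdl1_ihc"] = ihc
    clinical["tmb"] = np.exp(rng.normal(np.log(8.0), 0.8, n))
    clinical["tnb"] = np.exp(rng.normal(np.log(50.0), 1.0, n))

    truth = TruthManifest(
        seed=config.seed, planted_gene=config.planted_gene,
        slope=config.modulator_slope, intercept=config.modulator_intercept,
        coef=dict(config.coef), response_coef=dict(config.response_coef),
        realized_censoring_os=realized["os"],
        realized_censoring_pfs=realized["pfs"],
        extras={"ici_arm_interaction": config.coef["PV"] + config.coef["TPV"]},
    )
    return clinical, expression, truth


def simulate_cell_fractions(clinical: pd.DataFrame, expression: pd.DataFrame,
                            config: SimulationConfig,
                            stromal_shift: float = 0.1) -> pd.DataFrame:
    """Cell-fraction table with a stromal shift tied to the modulator.

    Modulator-high patients (the PL side under a negative score slope)
    receive ``stromal_shift`` extra Fibroblast+Endothelium fraction;
    PD-L1-high patients receive extra lymphocytes.  Rows sum to 1.
    """
    rng = np.random.default_rng(config.seed + 3)
    pid = clinical["patient_id"].tolist()
    n = len(pid)
    mod = expression.loc[config.planted_gene, pid].to_numpy()
    pdl1 = expression.loc[config.pdl1_gene, pid].to_numpy()
    v = (mod >= np.median(mod)).astype(float)
    p = (pdl1 >= np.median(pdl1)).astype(float)
    base = {
        "T_cells": 0.12 + 0.08 * p, "B_cells": 0.05, "NK_cells": 0.04,
        "Macrophages": 0.08,
        "Fibroblasts": 0.10 + stromal_shift * v * 0.6,
        "Endothelium": 0.05 + stromal_shift * v * 0.4,
    }
    cols = {}
    for name, mean in base.items():
        vals = np.maximum(mean + rng.normal(0.0, 0.02, n), 1e-4)
        cols[name] = vals
    frac = pd.DataFrame(cols, index=pd.Index(pid, name="patient_id"))
    other = np.maximum(1.0 - frac.sum(axis=1), 1e-4)
    frac["Other"] = other
    return frac.div(frac.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# end-to-end recovery


def run_pipeline_once(config: SimulationConfig, stratify_mode: str = "RNA2"
                      ) -> dict:
    """One full pipeline pass on fresh simulations; returns key outcomes."""
    trials, truth_t = simulate_trial_table(config)
    pred_os = meta.compute_predictiveness(trials, "OS")
    pred_pfs = meta.compute_predictiveness(trials, "PFS")

    panel, sample_cancer, truth_p = simulate_expression_panel(config)
    medians = screen.median_profile(panel, sample_cancer)
    screened = screen.cross_cancer_screen(medians, pred_os, pred_pfs)

    clinical, expression, truth_c = simulate_cohort(config)
    ici = clinical[clinical["arm"] == "ICI"]
    candidates = [g for g in expression.index if g != config.pdl1_gene]
    ranked = screen.rank_interactions(ici, expression, config.pdl1_gene,
                                      candidates, endpoint="OS")
    top_gene = str(ranked.iloc[0]["gene"])
    planted_rank = int(np.flatnonzero(
        ranked["gene"].to_numpy() == config.planted_gene)[0]) + 1

    model = score.fit_ps_model(medians[config.planted_gene],
                               pred_os.hrd_series(), gene=config.planted_gene)
    scores = score.score_and_split(clinical, expression, model,
                                   reference="TREATED_ARM")
    strata, _ = efficacy.stratify_pdl1(clinical, expression, stratify_mode,
                                       pdl1_gene=config.pdl1_gene)
    grid = efficacy.efficacy_grid(clinical, scores, strata,
                                  "POS_vs_NEG_within_ICI", endpoints=("OS",))

    def _hr(group):
        row = grid[(grid["group"] == group) & (grid["endpoint"] == "OS")]
        return float(row["hr"].iloc[0]) if len(row) and row["estimable"].iloc[0] \
            else float("nan")

    hrd_err = float(np.max(np.abs(
        pred_os.hrd_series().reindex(truth_t.hrd_os.keys()).to_numpy()
        - np.array(list(truth_t.hrd_os.values())))))
    return {
        "screen_planted_passes": bool(
            screened.set_index("gene").loc[config.planted_gene, "passes"]),
        "planted_rank": planted_rank,
        "top_gene": top_gene,
        "interaction_d": float(
            ranked.set_index("gene").loc[config.planted_gene, "d"]),
        "slope": model.slope,
        "intercept": model.intercept,
        "loocv_rmse": model.loocv_rmse,
        "hr_ph": _hr("PH"),
        "hr_pl": _hr("PL"),
        "max_hrd_error": hrd_err,
        "p_interaction_os": pred_os.table["p_interaction"].tolist(),
    }


def recovery_experiment(config: SimulationConfig, n_seeds: int = 200,
                        stratify_mode: str = "RNA2") -> dict:
    """Run the full pipeline over ``n_seeds`` seeds; summarize recovery.

    Reports the planted modulator's rank distribution and top-1 rate, the
    score-model slope/intercept recovery errors, the frequency of the
    qualitative PH/PL pattern (PH hazard ratio < 1 and PL > 1), and the
    null-calibration rate of the meta-analytic interaction test.
    """
    per_seed = []
    for i in range(n_seeds):
        cfg = config.replace(seed=config.seed + 1000 * i)
        per_seed.append(run_pipeline_once(cfg, stratify_mode=stratify_mode))
    df = pd.DataFrame(per_seed)
    p_int = np.concatenate([np.asarray(p) for p in df["p_interaction_os"]])
    return {
        "n_seeds": n_seeds,
        "top1_rate": float((df["planted_rank"] == 1).mean()),
        "rank_distribution": df["planted_rank"].value_counts().sort_index()
                                               .to_dict(),
        "screen_pass_rate": float(df["screen_planted_passes"].mean()),
        "slope_mean": float(df["slope"].mean()),
        "slope_abs_err_q90": float(
            np.quantile(np.abs(df["slope"] - config.modulator_slope), 0.9)),
        "intercept_mean": float(df["intercept"].mean()),
        "pattern_rate": float(((df["hr_ph"] < 1) & (df["hr_pl"] > 1)).mean()),
        "ph_lt1_rate": float((df["hr_ph"] < 1).mean()),
        "pl_gt1_rate": float((df["hr_pl"] > 1).mean()),
        "meta_interaction_reject_rate": float((p_int < 0.05).mean()),
        "mean_max_hrd_error": float(df["max_hrd_error"].mean()),
        "per_seed": df,
    }
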