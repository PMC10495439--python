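import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def null_survival_cohort():
    """Factory for cohorts where covariates carry no signal."""

    def make(n=400, seed=0, censor=0.2):
        r = np.random.default_rng(seed)
        df = pd.DataFrame({
            "P": r.integers(0, 2, n),
            "V": r.integers(0, 2, n),
        })
        df["PV"] = df["P"] * df["V"]
        t = r.exponential(12.0, n)
        c = r.uniform(0, np.quantile(t, 1 - censor) * 2.5, n)
        df["time"] = np.minimum(t, c)
        df["event"] = (t <= c).astype(int)
        return df

    return make


@pytest.fixture
def small_cohort():
    """Deterministic two-arm clinical table + expression for grid tests."""
    r = np.random.default_rng(11)
    n = 240
    pid = [f"p{i:03d}" for i in range(n)]
    arm = np.where(np.arange(n) % 2 == 0, "ICI", "CHEMO")
    clinical = pd.DataFrame({
        "patient_id": pid,
        "arm": arm,
        "os_time": r.exponential(14.0, n) + 0.1,
        "os_event": r.integers(0, 2, n),
        "pfs_time": r.exponential(7.0, n) + 0.1,
        "pfs_event": r.integers(0, 2, n),
        "response": r.choice(["CR", "PR", "SD", "PD", "NE"], n,
                             p=[0.05, 0.2, 0.3, 0.4, 0.05]),
        "pdl1_ihc": r.uniform(0, 100, n),
        "tmb": r.uniform(2, 30, n),
        "tnb": r.uniform(5, 200, n),
    })
    expression = pd.DataFrame(
        r.normal(3.0, 1.0, size=(3, n)),
        index=pd.Index(["CD274", "CDKN1C", "DECOY_001"], name="gene"),
        columns=pid,
    )
    return clinical, expression
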