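import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from netseg.cohort import CohortSpec, SubjectRecord, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-subject cohort shared by read-only tests."""
    return generate_cohort(CohortSpec(n_subjects=25, seed=7))


@pytest.fixture
def subject():
    return SubjectRecord(subject_id="sub-1", age=30.0, age_z=-0.6,
                         true_bias=50.0, accuracy_clear=1.0,
                         spike_rate=0.0, _seeds=(11, 12, 13, 14))


def make_trials(n_amb_pos, n_amb=48, n_clear_correct=48, n_clear=48,
                omitted_amb=0, omitted_clear=0):
    """Build a trial table with exact response counts for scoring tests."""
    rows = []
    for i in range(n_amb):
        if i < omitted_amb:
            resp = "none"
        else:
            resp = "positive" if i - omitted_amb < n_amb_pos else "negative"
        rows.append(("ambiguous", resp))
    half = n_clear // 2
    for i in range(n_clear):
        cls = "clear_positive" if i < half else "clear_negative"
        correct = "positive" if cls == "clear_positive" else "negative"
        wrong = "negative" if cls == "clear_positive" else "positive"
        if i < omitted_clear:
            resp = "none"
        else:
            resp = correct if i - omitted_clear < n_clear_correct else wrong
        rows.append((cls, resp))
    df = pd.DataFrame(rows, columns=["valence_class", "response"])
    df.insert(0, "trial_id", np.arange(1, len(df) + 1))
    df["block"] = 1 + (df.trial_id - 1) % 4
    df["stimulus_type"] = np.where(df.block.isin([1, 3]), "face", "scene")
    return df


def ols_oracle(y, X):
    """Independent normal-equations OLS: beta, residuals, coefficient cov."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    return beta, resid, sigma2 * np.linalg.inv(xtx)
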