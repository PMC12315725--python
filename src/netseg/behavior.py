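"""Valence-bias task scoring and the behavioral inclusion rule.

The task is a two-alternative forced choice: each image (surprised face or
ambiguous scene, plus clearly positive/negative control images) is
categorized as positive or negative.  Valence bias is the percentage of
positive categorizations on the ambiguous trials; accuracy on the clear
trials gates inclusion (participants below 60% correct are excluded).
"""

from __future__ import annotations

import pathlib

import pandas as pd

__all__ = [
    "UndefinedScoreError",
    "ACCURACY_CUTOFF",
    "score_clear_accuracy",
    "compute_valence_bias",
    "score_trials",
    "score_cohort",
]

ACCURACY_CUTOFF = 0.60

_CORRECT = {"clear_positive": "positive", "clear_negative": "negative"}


class UndefinedScoreError(ValueError):
    """Raised when a score has no answerable trials to be computed from."""


def _answered(trials: pd.DataFrame) -> pd.DataFrame:
    # a non-response is not a categorization: drop from numerator and denominator
    return trials[trials["response"].isin(["positive", "negative"])]


def score_clear_accuracy(trials: pd.DataFrame) -> float:
    """Fraction of answered clearly-valenced trials categorized correctly."""
    clear = _answered(trials[trials["valence_class"].isin(_CORRECT)])
    if len(clear) == 0:
        raise UndefinedScoreError("no answerable clearly-valenced trials")
    correct = clear["valence_class"].map(_CORRECT) == clear["response"]
    return float(correct.mean())


def compute_valence_bias(trials: pd.DataFrame) -> float:
    """Percentage of answered ambiguous trials categorized as positive."""
    amb = _answered(trials[trials["valence_class"] == "ambiguous"])
    if len(amb) == 0:
        raise UndefinedScoreError("no answerable ambiguous trials")
    return float(100.0 * (amb["response"] == "positive").mean())


def score_trials(trials: pd.DataFrame, cutoff: float = ACCURACY_CUTOFF) -> dict:
    """Score one subject's trial table.

    Returns ``valence_bias`` (percent, 0-100), ``clear_accuracy`` (fraction)
    and ``included`` (accuracy at or above the cutoff; participants *below*
    60% are excluded).
    """
    acc = score_clear_accuracy(trials)
    bias = compute_valence_bias(trials)
    return {"valence_bias": bias, "clear_accuracy": acc,
            "included": bool(acc >= cutoff)}


def score_cohort(trial_tables: dict, cutoff: float = ACCURACY_CUTOFF) -> pd.DataFrame:
    """Score a mapping of subject_id -> trial table into a tidy frame."""
    rows = []
    for sid, trials in trial_tables.items():
        row = {"subject_id": sid}
        row.update(score_trials(trials, cutoff=cutoff))
        rows.append(row)
    return pd.DataFrame(rows)


def read_trials_dir(path) -> dict:
    """Read ``<subject_id>.csv`` trial tables from a directory."""
    out = {}
    for f in sorted(pathlib.Path(path).glob("*.csv")):
        out[f.stem] = pd.read_csv(f)
    return out
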