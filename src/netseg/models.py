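"""Lifespan statistical models for network measures and valence bias.

Implements the full inferential stage: head-motion (RMS-FD)
residualization of connectivity measures, linear/quadratic standardized-age
models with Benjamini-Hochberg FDR across the 12 networks, valence-bias
regressions with age forced as a covariate, AIC backward elimination over
the 11 DMN pairwise between-network connectivities, age-moderation
screening, simple slopes, and Johnson-Neyman significance intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FitResult",
    "AgeScale",
    "EliminationTrace",
    "ModerationResult",
    "residualize_fd",
    "standardize_age",
    "unstandardize_age",
    "fit_ols",
    "fit_age_model",
    "fdr_adjust",
    "fit_bias_model",
    "backward_eliminate",
    "screen_interactions",
    "simple_slopes",
    "johnson_neyman",
    "detect_outliers",
]


@dataclass
class AgeScale:
    """Mean/SD (years) used to map ages to standardized units and back."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("age SD must be positive")


def standardize_age(ages, scale: AgeScale | None = None) -> np.ndarray:
    """(age - mean) / sd; sample statistics (ddof=1) when no scale is given."""
    ages = np.asarray(ages, dtype=float)
    if scale is None:
        scale = AgeScale(float(ages.mean()), float(ages.std(ddof=1)))
    return (ages - scale.mean) / scale.sd


def unstandardize_age(age_z, scale: AgeScale) -> np.ndarray:
    """Inverse map: mean + z * sd, in years."""
    return scale.mean + np.asarray(age_z, dtype=float) * scale.sd


@dataclass
class FitResult:
    """A fitted linear model: coefficients with inference and fit summaries."""

    terms: list
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    df_resid: float
    nobs: int
    rsquared: float = np.nan
    fvalue: float = np.nan
    f_pvalue: float = np.nan
    df_model: float = np.nan
    aic: float = np.nan
    _sm_result: object = field(default=None, repr=False)

    @classmethod
    def from_statsmodels(cls, res) -> "FitResult":
        terms = list(res.params.index)
        return cls(terms=terms, params=res.params, bse=res.bse,
                   tvalues=res.tvalues, pvalues=res.pvalues,
                   cov_params=res.cov_params(), df_resid=float(res.df_resid),
                   nobs=int(res.nobs), rsquared=float(res.rsquared),
                   fvalue=float(res.fvalue), f_pvalue=float(res.f_pvalue),
                   df_model=float(res.df_model), aic=float(res.aic),
                   _sm_result=res)

    @classmethod
    def from_coefficients(cls, params: dict, bse: dict | None = None,
                          cov: pd.DataFrame | None = None,
                          df_resid: float = np.inf,
                          nobs: int = 0) -> "FitResult":
        """Build a result from printed coefficients (e.g., a published table)."""
        terms = list(params)
        p = pd.Series(params, dtype=float)
        se = pd.Series(bse, dtype=float) if bse else pd.Series(np.nan, index=terms)
        if cov is None:
            cov = pd.DataFrame(np.diag(se.reindex(terms).fillna(0.0) ** 2),
                               index=terms, columns=terms)
        t = p / se
        if np.isfinite(df_resid):
            pv = 2 * stats.t.sf(np.abs(t), df_resid)
        else:
            pv = 2 * stats.norm.sf(np.abs(t))
        return cls(terms=terms, params=p, bse=se, tvalues=t,
                   pvalues=pd.Series(pv, index=terms), cov_params=cov,
                   df_resid=df_resid, nobs=nobs)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"B": self.params, "SE": self.bse,
                             "t": self.tvalues, "p": self.pvalues})


def fit_ols(y, X: pd.DataFrame, add_intercept: bool = True) -> FitResult:
    """OLS with an explicit design; refuses near-saturated fits."""
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "Intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "Intercept", 1.0)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 2:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} model terms")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("rank-deficient design")
    return FitResult.from_statsmodels(sm.OLS(y, X).fit())


def residualize_fd(df: pd.DataFrame, measure_cols, fd_col: str = "rms_fd",
                   add_mean_back: bool = False) -> pd.DataFrame:
    """Regress RMS-FD out of each measure column, replacing it by residuals.

    Controls for residual motion-related variance in connectivity measures.
    Constant FD leaves the measures unchanged (with a warning).
    """
    import warnings

    out = df.copy()
    fd = np.asarray(df[fd_col], dtype=float)
    if np.ptp(fd) == 0:
        warnings.warn("rms_fd is constant; residualization skipped")
        return out
    x = np.column_stack([np.ones(len(fd)), fd])
    for col in measure_cols:
        yv = np.asarray(df[col], dtype=float)
        beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
        resid = yv - x @ beta
        out[col] = resid + yv.mean() if add_mean_back else resid
    return out


def fit_age_model(y, age_z, quadratic: str = "auto") -> FitResult:
    """Linear or quadratic standardized-age model for one network measure.

    ``quadratic='auto'`` reports the quadratic model when its squared-age
    term is significant at p < .05, else the linear model; ``'on'``/``'off'``
    force the choice.
    """
    age_z = np.asarray(age_z, dtype=float)
    lin = fit_ols(y, pd.DataFrame({"age_z": age_z}))
    if quadratic == "off":
        return lin
    quad = fit_ols(y, pd.DataFrame({"age_z": age_z, "age_z2": age_z**2}))
    if quadratic == "on":
        return quad
    if quadratic != "auto":
        raise ValueError("quadratic must be 'auto', 'on' or 'off'")
    # a numerically-null curvature term is never "significant", even when a
    # perfect linear fit drives the residual variance to machine zero
    scale = max(1.0, float(np.std(np.asarray(y, dtype=float))))
    if abs(quad.params["age_z2"]) <= 1e-10 * scale:
        return lin
    return quad if quad.pvalues["age_z2"] < 0.05 else lin


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_bias_model(bias, predictors: pd.DataFrame, age_z) -> FitResult:
    """Valence bias on standardized age plus connectivity predictors."""
    X = pd.DataFrame({"age_z": np.asarray(age_z, dtype=float)})
    for c in predictors.columns:
        X[c] = np.asarray(predictors[c], dtype=float)
    return fit_ols(bias, X)


@dataclass
class EliminationTrace:
    """Record of an AIC backward elimination."""

    steps: list  # (step, removed term, aic_before, aic_after)
    final_terms: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "removed", "aic_before", "aic_after"])


def backward_eliminate(y, candidates: pd.DataFrame, forced: pd.DataFrame,
                       change_in_estimate: float | None = None) -> tuple:
    """AIC backward elimination with forced-in covariates.

    Starting from the full model (forced + all candidates), repeatedly
    remove the candidate whose removal most decreases the AIC; stop when no
    removal decreases it.  Forced terms are never candidates.  Ties break
    lexicographically by term name.  ``change_in_estimate`` optionally
    retains a candidate whose removal shifts any remaining coefficient by
    more than that relative amount (augmented elimination guard).

    Returns ``(EliminationTrace, FitResult of the final model)``.
    """
    forced = pd.DataFrame(forced).astype(float)
    candidates = pd.DataFrame(candidates).astype(float)
    current = list(candidates.columns)

    def _fit(terms):
        X = pd.concat([forced, candidates[terms]], axis=1)
        return fit_ols(y, X)

    fit = _fit(current)
    steps = []
    step = 0
    while current:
        options = []
        for term in sorted(current):
            rest = [t for t in current if t != term]
            cand_fit = _fit(rest)
            if change_in_estimate is not None:
                base = fit.params.drop(term)
                new = cand_fit.params
                rel = np.abs((new - base.reindex(new.index)) /
                             base.reindex(new.index).replace(0, np.nan))
                if np.nanmax(rel.values) > change_in_estimate:
                    continue  # guard: removal distorts remaining estimates
            options.append((cand_fit.aic, term, cand_fit))
        if not options:
            break
        options.sort(key=lambda o: (o[0], o[1]))
        best_aic, best_term, best_fit = options[0]
        if best_aic >= fit.aic:
            break
        step += 1
        steps.append((step, best_term, fit.aic, best_aic))
        current.remove(best_term)
        fit = best_fit
    return EliminationTrace(steps=steps, final_terms=list(forced.columns) + current), fit


def screen_interactions(y, selected: pd.DataFrame, forced: pd.DataFrame,
                        moderator: str = "age_z", alpha: float = 0.05) -> tuple:
    """Test each selected term x age interaction; keep significant ones jointly.

    Each interaction is screened one model at a time (selected main effects
    + that single interaction); interactions with p < alpha then enter the
    final joint model together.  Returns ``(final FitResult, kept names)``.
    """
    forced = pd.DataFrame(forced).astype(float)
    selected = pd.DataFrame(selected).astype(float)
    mod = np.asarray(forced[moderator], dtype=float)
    kept = []
    for term in selected.columns:
        name = f"{term}:{moderator}"
        X = pd.concat([forced, selected], axis=1)
        X[name] = selected[term].values * mod
        fit = fit_ols(y, X)
        if fit.pvalues[name] < alpha:
            kept.append(term)
    X = pd.concat([forced, selected], axis=1)
    for term in kept:
        X[f"{term}:{moderator}"] = selected[term].values * mod
    return fit_ols(y, X), [f"{t}:{moderator}" for t in kept]


def simple_slopes(fit: FitResult, focal: str, interaction: str,
                  moderator_values=(-1.0, 0.0, 1.0)) -> pd.DataFrame:
    """Conditional slopes of the focal term at chosen moderator values.

    slope(a) = B_focal + B_int * a;
    SE(a) = sqrt(V_focal + a^2 V_int + 2 a Cov); t against residual df.
    """
    for term in (focal, interaction):
        if term not in fit.terms:
            raise KeyError(f"term {term!r} not in fit")
    if fit.cov_params is None:
        raise ValueError("fit has no coefficient covariance matrix")
    b_f = float(fit.params[focal])
    b_i = float(fit.params[interaction])
    v_f = float(fit.cov_params.loc[focal, focal])
    v_i = float(fit.cov_params.loc[interaction, interaction])
    c = float(fit.cov_params.loc[focal, interaction])
    rows = []
    for a in np.atleast_1d(moderator_values):
        slope = b_f + b_i * a
        se = np.sqrt(v_f + a**2 * v_i + 2 * a * c)
        t = slope / se if se > 0 else np.nan
        if np.isfinite(fit.df_resid):
            p = 2 * stats.t.sf(abs(t), fit.df_resid)
        else:
            p = 2 * stats.norm.sf(abs(t))
        rows.append({"moderator": float(a), "slope": slope, "se": se,
                     "t": t, "p": p})
    return pd.DataFrame(rows)


@dataclass
class ModerationResult:
    """Simple slopes plus the Johnson-Neyman significance region."""

    slopes: pd.DataFrame
    boundaries_z: tuple  # standardized moderator units, ascending
    boundaries_raw: tuple | None  # years, when an AgeScale is supplied
    significant_outside: bool  # True: significant outside the boundaries
    everywhere: bool
    nowhere: bool
    t_crit: float


def johnson_neyman(fit: FitResult, focal: str, interaction: str,
                   alpha: float = 0.05,
                   age_scale: AgeScale | None = None) -> ModerationResult:
    """Johnson-Neyman boundaries of the focal term's conditional significance.

    Solves ``(B_f + B_i a)^2 = t_crit^2 (V_f + a^2 V_i + 2 a Cov)`` for the
    moderator values where the conditional slope's |t| equals the pointwise
    critical value; reports boundaries in standardized and, when an
    ``AgeScale`` is given, raw-year units, plus the direction of the
    significant region.  With no real roots the slope is significant
    everywhere or nowhere, decided at a = 0.
    """
    b_f = float(fit.params[focal])
    b_i = float(fit.params[interaction])
    v_f = float(fit.cov_params.loc[focal, focal])
    v_i = float(fit.cov_params.loc[interaction, interaction])
    c = float(fit.cov_params.loc[focal, interaction])
    if np.isfinite(fit.df_resid):
        t_crit = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    else:
        t_crit = float(stats.norm.ppf(1 - alpha / 2))

    slopes = simple_slopes(fit, focal, interaction)
    if abs(b_i) < 1e-12 and v_i < 1e-24:
        # no moderation: slope and its SE do not depend on the moderator
        sig = abs(slopes.loc[slopes.moderator == 0, "t"].iloc[0]) > t_crit
        return ModerationResult(slopes, (), None, False, bool(sig), not sig, t_crit)

    A = b_i**2 - t_crit**2 * v_i
    Bq = 2 * (b_f * b_i - t_crit**2 * c)
    C = b_f**2 - t_crit**2 * v_f
    disc = Bq**2 - 4 * A * C
    roots = ()
    if abs(A) < 1e-300:
        if abs(Bq) > 0:
            roots = (-C / Bq,)
    elif disc >= 0:
        r1 = (-Bq - np.sqrt(disc)) / (2 * A)
        r2 = (-Bq + np.sqrt(disc)) / (2 * A)
        roots = tuple(sorted((float(r1), float(r2))))

    if not roots:
        t0 = abs(b_f) / np.sqrt(v_f) if v_f > 0 else np.inf
        sig = t0 > t_crit
        return ModerationResult(slopes, (), None, False, bool(sig), not sig, t_crit)

    # region direction: test a point inside the root interval
    if len(roots) == 2:
        mid = 0.5 * (roots[0] + roots[1])
    else:
        mid = roots[0] - 1.0
    s = b_f + b_i * mid
    se = np.sqrt(max(v_f + mid**2 * v_i + 2 * mid * c, 0.0))
    inside_sig = bool(se > 0 and abs(s) / se > t_crit)
    raw = tuple(float(unstandardize_age(a, age_scale)) for a in roots) \
        if age_scale is not None else None
    return ModerationResult(slopes, roots, raw,
                            significant_outside=not inside_sig,
                            everywhere=False, nowhere=False, t_crit=t_crit)


def detect_outliers(values, k: float = 3.0) -> np.ndarray:
    """Indices of extreme values beyond median +/- k * IQR (default k = 3)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(v - med) > k * iqr)
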