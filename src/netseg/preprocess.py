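"""Motion QC and ROI time-series cleaning.

Framewise displacement (FD) is computed from six realignment parameters —
the sum of absolute frame-to-frame changes in three translations (mm) plus
three rotations converted to mm on a 50 mm sphere — after zero-phase
low-pass filtering of the realignment traces to suppress respiratory
pseudo-motion.  Frames with FD above 0.2 mm are censored, surviving
segments shorter than five contiguous frames are removed, runs retaining
fewer than 50 frames are dropped entirely, and only subjects with at least
800 surviving frames are analyzed (the earliest 800 are kept).

Cleaning follows a fixed, recorded order per run: demean/detrend ->
nuisance regression (27 columns: a 24-parameter motion set plus global and
two tissue signals) estimated on retained frames -> interpolation over
censored frames -> zero-phase band-pass (0.009-0.08 Hz) -> re-censoring.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

__all__ = [
    "DegenerateInputError",
    "compute_fd",
    "build_censor_mask",
    "select_frame_budget",
    "FrameSelection",
    "demean_detrend",
    "build_nuisance_regressors",
    "nuisance_regress",
    "interpolate_and_bandpass",
    "fd_summary",
    "clean_subject",
    "PIPELINE_STAGES",
]

ROTATION_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.2
MIN_SEGMENT = 5
MIN_RUN_FRAMES = 50
FRAME_BUDGET = 800

PIPELINE_STAGES = ("demean_detrend", "nuisance_regression",
                   "censor_interpolate", "bandpass", "recensor")


class DegenerateInputError(ValueError):
    """Raised for inputs too short or degenerate to process."""


def _as_runs(x) -> list:
    if isinstance(x, np.ndarray):
        return [x]
    return list(x)


from functools import lru_cache


@lru_cache(maxsize=32)
def _butter(order: int, lo: float, hi: float | None, btype: str) -> tuple:
    wn = lo if hi is None else (lo, hi)
    b, a = signal.butter(order, wn, btype=btype)
    return b, a


def _zero_phase_lowpass(x: np.ndarray, cutoff_hz: float, tr: float,
                        order: int = 2) -> np.ndarray:
    nyq = 0.5 / tr
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    b, a = _butter(order, cutoff_hz / nyq, None, "low")
    padlen = min(3 * max(len(a), len(b)), x.shape[0] - 1)
    return signal.filtfilt(b, a, x, axis=0, padlen=padlen)


def compute_fd(trace, tr: float = 1.0, rotation_radius_mm: float = ROTATION_RADIUS_MM,
               lowpass_hz: float | None = 0.1) -> list:
    """Per-run framewise displacement traces in mm.

    ``trace`` is a frames x 6 array (trans x/y/z in mm, rot in radians) or a
    list of such arrays, one per run.  The realignment estimates are
    optionally low-pass filtered (zero-phase Butterworth, ``lowpass_hz``)
    before differencing; pass ``lowpass_hz=None`` for unfiltered FD.  The
    first frame of each run has FD 0 by convention.
    """
    if rotation_radius_mm <= 0:
        raise ValueError("rotation radius must be positive")
    fds = []
    for run in _as_runs(trace):
        run = np.asarray(run, dtype=float)
        if run.ndim != 2 or run.shape[1] != 6:
            raise ValueError("motion trace must be frames x 6")
        if run.shape[0] < 2:
            raise DegenerateInputError("motion run needs at least 2 frames")
        if not np.all(np.isfinite(run)):
            raise ValueError("motion trace contains non-finite values")
        est = run
        if lowpass_hz is not None:
            est = _zero_phase_lowpass(run, lowpass_hz, tr)
        mm = est.copy()
        mm[:, 3:] *= rotation_radius_mm
        d = np.abs(np.diff(mm, axis=0)).sum(axis=1)
        fds.append(np.concatenate([[0.0], d]))
    return fds


def build_censor_mask(fd_runs, threshold_mm: float = FD_THRESHOLD_MM,
                      min_segment: int = MIN_SEGMENT,
                      min_run_frames: int = MIN_RUN_FRAMES) -> list:
    """Boolean retain masks per run.

    Frames with FD above ``threshold_mm`` are censored; surviving contiguous
    segments shorter than ``min_segment`` frames are removed (within runs
    only); any run retaining fewer than ``min_run_frames`` frames is dropped
    entirely.  Empty retention is a valid result.
    """
    masks = []
    for fd in _as_runs(fd_runs):
        fd = np.asarray(fd, dtype=float)
        if not np.all(np.isfinite(fd)):
            raise ValueError("FD trace contains non-finite values")
        keep = fd <= threshold_mm
        # remove maximal retained segments shorter than min_segment
        edges = np.flatnonzero(np.diff(np.concatenate([[0], keep.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start < min_segment:
                keep[start:stop] = False
        if keep.sum() < min_run_frames:
            keep = np.zeros_like(keep)
        masks.append(keep)
    return masks


class FrameSelection:
    """Outcome of the frame-budget rule.

    ``masks`` retains only the earliest ``budget`` surviving frames in
    acquisition order across runs; ``included`` is False (and ``masks`` all
    False) when fewer than ``budget`` frames survive censoring — exclusion
    is a reportable status, not an exception.
    """

    def __init__(self, masks: list, included: bool, retained_total: int,
                 budget: int):
        self.masks = masks
        self.included = included
        self.retained_total = retained_total
        self.budget = budget

    def __repr__(self):
        status = "included" if self.included else "excluded:frames"
        return (f"FrameSelection({status}, retained={self.retained_total}, "
                f"budget={self.budget})")


def select_frame_budget(masks, budget: int = FRAME_BUDGET) -> FrameSelection:
    """Apply the minimum-data rule and keep the earliest ``budget`` frames."""
    masks = [np.asarray(m, dtype=bool) for m in _as_runs(masks)]
    total = int(sum(m.sum() for m in masks))
    if total < budget:
        return FrameSelection([np.zeros_like(m) for m in masks], False, total, budget)
    selected = []
    remaining = budget
    for m in masks:
        take = m.copy()
        if remaining <= 0:
            take[:] = False
        else:
            csum = np.cumsum(take)
            take[csum > remaining] = False
            remaining -= int(take.sum())
        selected.append(take)
    return FrameSelection(selected, True, total, budget)


def demean_detrend(ts_runs) -> list:
    """Remove per-run constant and linear trend from each ROI column (OLS)."""
    out = []
    for run in _as_runs(ts_runs):
        run = np.asarray(run, dtype=float)
        n = run.shape[0]
        if n < 3:
            raise DegenerateInputError("run too short to detrend (need >= 3 frames)")
        # {1, t} with t centered is an orthogonal basis: project directly
        t = np.linspace(-1.0, 1.0, n)
        mean = run.mean(axis=0)
        slope = (t @ run) / (t @ t)
        out.append(run - mean - np.outer(t, slope))
    return out


def build_nuisance_regressors(motion_run: np.ndarray,
                              global_signal: np.ndarray,
                              tissue_signals: np.ndarray) -> np.ndarray:
    """27-column nuisance design for one run.

    Columns: 6 realignment parameters, their 6 backward differences, 12
    Volterra-expansion squares (of the current and one-frame-lagged
    parameters; together the standard 24-parameter motion set), the global
    signal, and two tissue (CSF/white-matter) signals.
    """
    r = np.asarray(motion_run, dtype=float)
    g = np.asarray(global_signal, dtype=float).reshape(-1, 1)
    tis = np.asarray(tissue_signals, dtype=float)
    if tis.ndim == 1:
        tis = tis.reshape(-1, 1)
    if tis.shape[1] != 2:
        raise ValueError("expected exactly two tissue signals")
    if not (len(r) == len(g) == len(tis)):
        raise ValueError("regressor lengths do not match")
    dr = np.vstack([np.zeros((1, 6)), np.diff(r, axis=0)])
    lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    return np.hstack([r, dr, r**2, lag**2, g, tis])


def nuisance_regress(ts_runs, regressors, masks=None) -> list:
    """Remove nuisance variance by per-run OLS.

    The fit is estimated on retained frames only (when ``masks`` is given),
    so high-motion frames exert no leverage, but fitted values are
    subtracted from every frame.  Rank-deficient designs drop collinear
    columns with a warning.
    """
    ts_runs = _as_runs(ts_runs)
    regressors = _as_runs(regressors)
    masks = [None] * len(ts_runs) if masks is None else _as_runs(masks)
    out = []
    for run, reg, m in zip(ts_runs, regressors, masks):
        run = np.asarray(run, dtype=float)
        reg = np.asarray(reg, dtype=float)
        if reg.ndim == 1:
            reg = reg.reshape(-1, 1)
        if len(reg) != len(run):
            raise ValueError("regressor length does not match run length")
        x = np.column_stack([np.ones(len(run)), reg])
        fit_rows = np.ones(len(run), dtype=bool) if m is None else np.asarray(m, bool)
        if fit_rows.sum() <= x.shape[1]:
            raise DegenerateInputError("not enough retained frames for regression")
        xf = x[fit_rows]
        keep = np.ones(x.shape[1], dtype=bool)
        xtx = xf.T @ xf
        scale = np.sqrt(np.diag(xtx))
        scale[scale == 0] = 1.0
        xtx_n = xtx / np.outer(scale, scale)
        if np.linalg.cond(xtx_n) > 1e10:
            # rank deficient: greedily drop columns that add no rank
            keep = np.zeros(x.shape[1], dtype=bool)
            cur = np.empty((int(fit_rows.sum()), 0))
            for j in range(x.shape[1]):
                cand = np.column_stack([cur, xf[:, j]])
                if np.linalg.matrix_rank(cand) > cur.shape[1]:
                    keep[j] = True
                    cur = cand
            warnings.warn("nuisance design rank deficient; dropped "
                          f"{int((~keep).sum())} collinear column(s)")
            xf = xf[:, keep]
            xtx = xf.T @ xf
        beta = np.linalg.solve(xtx, xf.T @ run[fit_rows])
        out.append(run - x[:, keep] @ beta)
    return out


def _interpolate_censored(run: np.ndarray, keep: np.ndarray,
                          method: str = "linear", tr: float = 1.0,
                          high_hz: float = 0.08) -> np.ndarray:
    if keep.all():
        return run
    if not keep.any():
        return run
    t = np.arange(len(run), dtype=float)
    out = run.copy()
    if method == "linear":
        # uniform grid: locate bracketing retained frames once for all ROIs
        kept = np.flatnonzero(keep)
        gaps = np.flatnonzero(~keep)
        hi = np.searchsorted(kept, gaps)
        lo = np.clip(hi - 1, 0, len(kept) - 1)
        hi = np.clip(hi, 0, len(kept) - 1)
        t0, t1 = kept[lo].astype(float), kept[hi].astype(float)
        denom = np.where(t1 > t0, t1 - t0, 1.0)
        w = np.clip((gaps - t0) / denom, 0.0, 1.0)[:, None]
        out[gaps] = (1.0 - w) * run[kept[lo]] + w * run[kept[hi]]
        return out
    if method == "spectral":
        # least-squares sinusoid fit on retained frames up to the passband edge
        freqs = np.arange(1, int(np.floor(2 * high_hz * tr * len(run))) + 1)
        if len(freqs) == 0:
            return out
        ang = 2 * np.pi * np.outer(t, freqs) / len(run)
        x = np.column_stack([np.ones(len(run)), np.cos(ang), np.sin(ang)])
        beta, *_ = np.linalg.lstsq(x[keep], run[keep], rcond=None)
        recon = x @ beta
        out[~keep] = recon[~keep]
        return out
    raise ValueError(f"unknown interpolation method: {method}")


def interpolate_and_bandpass(ts_runs, masks, low_hz: float = 0.009,
                             high_hz: float = 0.08, tr: float = 1.0,
                             method: str = "linear", order: int = 2) -> list:
    """Interpolate over censored frames, then zero-phase band-pass per run.

    Censored frames remain flagged by the caller's mask and must be excluded
    from later correlation; interpolation exists only to prevent censored
    spikes from ringing through the filter.
    """
    nyq = 0.5 / tr
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError("require 0 < low < high < Nyquist")
    b, a = _butter(order, low_hz / nyq, high_hz / nyq, "band")
    need = 3 * (max(len(a), len(b)) - 1)
    out = []
    for run, m in zip(_as_runs(ts_runs), _as_runs(masks)):
        run = np.asarray(run, dtype=float)
        if run.shape[0] <= need:
            raise DegenerateInputError(
                f"run of {run.shape[0]} frames is shorter than the filter "
                f"warm-up ({need}); exclude this run")
        m = np.asarray(m, dtype=bool)
        interp = _interpolate_censored(run, m, method=method, tr=tr, high_hz=high_hz)
        # filter along the contiguous axis (frames last) for speed
        out.append(np.ascontiguousarray(
            signal.filtfilt(b, a, interp.T, axis=-1)).T)
    return out


def fd_summary(fd_runs) -> float:
    """Root-mean-square FD over all frames of the included runs."""
    fd = np.concatenate([np.asarray(f, float) for f in _as_runs(fd_runs)])
    if fd.size == 0:
        raise DegenerateInputError("no frames to summarize")
    return float(np.sqrt(np.mean(fd**2)))


def clean_subject(ts_runs, motion_runs, tr: float = 1.0,
                  fd_threshold: float = FD_THRESHOLD_MM,
                  min_segment: int = MIN_SEGMENT,
                  min_run_frames: int = MIN_RUN_FRAMES,
                  budget: int = FRAME_BUDGET,
                  low_hz: float = 0.009, high_hz: float = 0.08,
                  fd_lowpass_hz: float | None = 0.1,
                  interp_method: str = "linear",
                  tissue_rng: np.random.Generator | None = None) -> dict:
    """Run the full per-subject cleaning pipeline.

    Returns a dict with ``runs`` (cleaned frames x ROI arrays),
    ``selection`` (FrameSelection), ``rms_fd``, ``masks`` and the recorded
    stage ``provenance``.  Tissue signals are synthesized white noise unless
    a dedicated source is supplied upstream (ROI tables carry no tissue
    masks); the global signal is the mean ROI time course.
    """
    ts_runs = _as_runs(ts_runs)
    motion_runs = _as_runs(motion_runs)
    fd = compute_fd(motion_runs, tr=tr, lowpass_hz=fd_lowpass_hz)
    masks = build_censor_mask(fd, threshold_mm=fd_threshold,
                              min_segment=min_segment,
                              min_run_frames=min_run_frames)
    rms = fd_summary(fd)
    selection = select_frame_budget(masks, budget=budget)
    if not selection.included:
        return {"runs": None, "selection": selection, "rms_fd": rms,
                "masks": masks, "provenance": []}

    detrended = demean_detrend(ts_runs)
    if tissue_rng is None:
        tissue_rng = np.random.default_rng(0)
    regs = []
    for run, mot in zip(detrended, motion_runs):
        gs = run.mean(axis=1)
        tissue = tissue_rng.standard_normal((len(run), 2))
        regs.append(build_nuisance_regressors(mot, gs, tissue))
    resid = nuisance_regress(detrended, regs, masks)
    cleaned = interpolate_and_bandpass(resid, masks, low_hz=low_hz,
                                       high_hz=high_hz, tr=tr,
                                       method=interp_method)
    return {"runs": cleaned, "selection": selection, "rms_fd": rms,
            "masks": masks, "provenance": list(PIPELINE_STAGES)}
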