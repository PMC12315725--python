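"""Fisher-z connectivity matrices and network segregation metrics.

Within-network connectivity (Zw) is the mean Fisher-z correlation over all
ROI pairs inside a network; between-network connectivity (Zb) is the mean z
of a network's ROIs to all ROIs outside it; segregation is
``S = (Zw - Zb) / Zw``.  Negative correlations are zeroed before averaging
(global-signal regression can induce spurious negatives), and every network
receives equal weight in the global summaries regardless of its ROI count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ANALYSIS_NETWORKS

__all__ = [
    "correlate",
    "fisher_z",
    "merge_networks",
    "threshold_negative",
    "network_measures",
    "NetworkMeasures",
    "cohort_measures",
    "subject_connectivity",
]

Z_CLIP = 1.0 - 1e-7


def correlate(ts_runs, masks=None) -> np.ndarray:
    """Pearson correlation matrix over selected frames, pooled across runs.

    ``masks`` flags the selected (non-censored, within-budget) frames per
    run; frames are concatenated across runs before correlating.
    Zero-variance ROIs yield NaN rows/columns with a warning.
    """
    if isinstance(ts_runs, np.ndarray):
        ts_runs = [ts_runs]
    if masks is None:
        masks = [np.ones(len(r), dtype=bool) for r in ts_runs]
    data = np.vstack([np.asarray(r)[np.asarray(m, bool)]
                      for r, m in zip(ts_runs, masks)])
    if data.shape[1] < 2:
        raise ValueError("need at least 2 ROIs")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 selected frames")
    sd = data.std(axis=0)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance ROI(s); "
                      "their correlations are undefined")
        r[dead, :] = np.nan
        r[:, dead] = np.nan
    np.fill_diagonal(r, 1.0)
    r[dead, dead] = np.nan
    return r


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform off-diagonal entries; the diagonal is excluded (NaN)."""
    r = np.asarray(r, dtype=float)
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    np.fill_diagonal(z, np.nan)
    return z


def merge_networks(labels) -> tuple:
    """Map the 14-network labeling to the 12 analysis networks.

    Somatomotor-dorsal and -lateral merge into a single SM network and
    Unassigned ROIs are dropped.  Returns ``(analysis_labels, keep_mask)``
    where ``analysis_labels`` covers only the kept ROIs.
    """
    labels = np.asarray(labels, dtype=object)
    mapping = {"SMd": "SM", "SMl": "SM"}
    known = set(ANALYSIS_NETWORKS) | {"SMd", "SMl", "Unassigned"}
    unknown = set(labels) - known
    if unknown:
        raise ValueError(f"unknown network label(s): {sorted(unknown)}")
    keep = labels != "Unassigned"
    merged = np.array([mapping.get(l, l) for l in labels[keep]], dtype=object)
    return merged, keep


def threshold_negative(z: np.ndarray) -> np.ndarray:
    """Zero all negative entries; positive entries and NaNs untouched."""
    out = np.asarray(z, dtype=float).copy()
    out[out < 0] = 0.0
    return out


@dataclass
class NetworkMeasures:
    """Per-network and global connectivity summaries for one subject."""

    networks: list
    within: pd.Series
    between: pd.Series
    segregation: pd.Series
    pairwise: pd.DataFrame  # columns net_a, net_b, z (unordered pairs)
    W: float
    B: float
    S_global: float
    #: alternative global summary: unweighted mean of per-network S_k
    S_mean_of_networks: float = field(default=np.nan)


def network_measures(z: np.ndarray, labels) -> NetworkMeasures:
    """Compute Zw, Zb, pairwise Zb and segregation from a thresholded matrix.

    ``labels`` assigns each row/column of ``z`` to an analysis network.
    Global W and B are unweighted means over networks; S_global = (W-B)/W.
    Networks with non-positive Zw get undefined segregation with a warning.
    """
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if z.shape[0] != z.shape[1] or len(labels) != z.shape[0]:
        raise ValueError("labels must match the matrix dimension")
    names = [n for n in ANALYSIS_NETWORKS if n in set(labels)]
    if not names:
        names = sorted(set(labels))

    # block sums via indicator-matrix products: one pass for all networks
    ind = np.stack([(labels == n).astype(float) for n in names])
    zz = z.copy()
    nan = ~np.isfinite(zz)
    zz[nan] = 0.0
    np.fill_diagonal(zz, 0.0)
    np.fill_diagonal(nan, True)  # diagonal never counts as a pair
    sums = ind @ zz @ ind.T
    counts = (ind @ np.ones_like(zz) @ ind.T) - (ind @ nan.astype(float) @ ind.T)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    within, between, seg = {}, {}, {}
    rows = []
    for i, a in enumerate(names):
        within[a] = float(means[i, i])
        bsum = sums[i].sum() - sums[i, i]
        bcnt = counts[i].sum() - counts[i, i]
        between[a] = float(bsum / bcnt) if bcnt else np.nan
        if not within[a] > 0:
            warnings.warn(f"network {a}: non-positive within-network "
                          "connectivity; segregation undefined")
            seg[a] = np.nan
        else:
            seg[a] = (within[a] - between[a]) / within[a]
        for j in range(i + 1, len(names)):
            rows.append({"net_a": a, "net_b": names[j],
                         "z": float(means[i, j])})

    w = float(np.mean(list(within.values())))
    b_ = float(np.mean(list(between.values())))
    return NetworkMeasures(
        networks=names,
        within=pd.Series(within), between=pd.Series(between),
        segregation=pd.Series(seg),
        pairwise=pd.DataFrame(rows, columns=["net_a", "net_b", "z"]),
        W=w, B=b_, S_global=(w - b_) / w if w > 0 else np.nan,
        S_mean_of_networks=float(np.nanmean(list(seg.values()))),
    )


def subject_connectivity(ts_runs, masks, labels14,
                         threshold: bool = True) -> tuple:
    """Cleaned runs -> (Fisher-z matrix on analysis ROIs, analysis labels).

    Correlates selected frames, Fisher-transforms, restricts to the merged
    12-network ROI set and (by default) zeroes negative entries.
    """
    r = correlate(ts_runs, masks)
    merged, keep = merge_networks(labels14)
    z = fisher_z(r)[np.ix_(keep, keep)]
    if threshold:
        z = threshold_negative(z)
    return z, merged


def cohort_measures(measures: dict, rms_fd: dict | None = None,
                    behavior: pd.DataFrame | None = None) -> tuple:
    """Assemble per-subject NetworkMeasures into long-format tables.

    ``measures`` maps subject_id -> NetworkMeasures.  Returns
    ``(long_df, pairwise_df)``: one row per subject x network x measure plus
    global rows, joined with rms_fd and behavioral scores when provided.
    Orphan subject ids in the joins raise an error listing them.
    """
    rows, prows = [], []
    for sid, m in measures.items():
        for net in m.networks:
            rows.append({"subject_id": sid, "network": net,
                         "within": m.within[net], "between": m.between[net],
                         "segregation": m.segregation[net]})
        rows.append({"subject_id": sid, "network": "__global__",
                     "within": m.W, "between": m.B, "segregation": m.S_global})
        p = m.pairwise.copy()
        p.insert(0, "subject_id", sid)
        prows.append(p)
    long = pd.DataFrame(rows)
    pairwise = pd.concat(prows, ignore_index=True)

    if rms_fd is not None:
        fd = pd.DataFrame({"subject_id": list(rms_fd), "rms_fd": list(rms_fd.values())})
        _check_orphans(long, fd, "rms_fd")
        long = long.merge(fd, on="subject_id", how="left")
    if behavior is not None:
        _check_orphans(long, behavior, "behavior")
        long = long.merge(behavior, on="subject_id", how="left")
    return long, pairwise


def _check_orphans(long: pd.DataFrame, other: pd.DataFrame, what: str) -> None:
    orphans = sorted(set(long["subject_id"]) - set(other["subject_id"]))
    if orphans:
        raise ValueError(f"subjects missing from {what} table: {orphans}")
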