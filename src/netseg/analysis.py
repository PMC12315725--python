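"""End-to-end in-memory analysis of a cohort.

Chains the stages in fixed order — behavior scoring, motion QC and
time-series cleaning, connectivity and network measures, then the
statistical models — and returns every intermediate table.  The disk-backed
pipeline (``netseg.pipeline``) wraps these functions with file I/O.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import connectivity as conn
from . import models as mdl
from . import preprocess as prep
from .cohort import ANALYSIS_NETWORKS, Cohort

__all__ = ["process_cohort", "run_statistics", "analyze_cohort",
           "DMN_PAIR_TERMS"]

#: the 11 DMN pairwise between-network predictors, in report order
DMN_PAIR_TERMS = tuple(f"DMN-{n}" for n in ANALYSIS_NETWORKS if n != "DMN")


def _dmn_pair_name(net_a: str, net_b: str) -> str | None:
    if net_a == "DMN":
        return f"DMN-{net_b}"
    if net_b == "DMN":
        return f"DMN-{net_a}"
    return None


def process_cohort(cohort: Cohort, fd_threshold: float = 0.2,
                   min_segment: int = 5, min_run_frames: int = 50,
                   budget: int = 800, low_hz: float = 0.009,
                   high_hz: float = 0.08, accuracy_cutoff: float = 0.60,
                   threshold_negatives: bool = True) -> dict:
    """Score, clean and measure every subject of a cohort.

    Returns behavior/QC tables, long-format network measures, pairwise
    connectivity, and a per-subject status map
    (``included`` / ``excluded:behavior`` / ``excluded:frames``).
    Subjects excluded at one stage are not carried into later ones.
    """
    labels14 = cohort.network_labels()
    statuses = {}
    behavior_rows = []
    qc_rows = []
    measures = {}
    rms_fd = {}

    for i, s in enumerate(cohort.subjects):
        score = bhv.score_trials(cohort.trials(i), cutoff=accuracy_cutoff)
        behavior_rows.append({"subject_id": s.subject_id, **score})
        if not score["included"]:
            statuses[s.subject_id] = "excluded:behavior"
            continue

        cleaned = prep.clean_subject(
            cohort.timeseries(i), cohort.motion(i), tr=cohort.spec.tr,
            fd_threshold=fd_threshold, min_segment=min_segment,
            min_run_frames=min_run_frames, budget=budget,
            low_hz=low_hz, high_hz=high_hz,
            tissue_rng=np.random.default_rng(s._seeds[3]))
        qc_rows.append({"subject_id": s.subject_id,
                        "retained_frames": cleaned["selection"].retained_total,
                        "rms_fd": cleaned["rms_fd"],
                        "included": cleaned["selection"].included})
        if not cleaned["selection"].included:
            statuses[s.subject_id] = "excluded:frames"
            continue

        z, merged = conn.subject_connectivity(
            cleaned["runs"], cleaned["selection"].masks, labels14,
            threshold=threshold_negatives)
        measures[s.subject_id] = conn.network_measures(z, merged)
        rms_fd[s.subject_id] = cleaned["rms_fd"]
        statuses[s.subject_id] = "included"

    behavior_df = pd.DataFrame(behavior_rows)
    qc_df = pd.DataFrame(qc_rows)
    if measures:
        long_df, pairwise_df = conn.cohort_measures(measures, rms_fd,
                                                    behavior_df)
    else:
        long_df = pd.DataFrame()
        pairwise_df = pd.DataFrame()
    return {"behavior": behavior_df, "qc": qc_df, "long": long_df,
            "pairwise": pairwise_df, "statuses": statuses,
            "measures": measures, "rms_fd": rms_fd}


def _wide_table(processed: dict, ages: pd.DataFrame) -> pd.DataFrame:
    """Subject-level wide table: measures, DMN pairwise z, bias, FD, age."""
    long = processed["long"]
    glob = long[long.network == "__global__"][
        ["subject_id", "within", "between", "segregation", "rms_fd",
         "valence_bias"]].rename(columns={
             "within": "W", "between": "B", "segregation": "S_global"})
    seg = long[long.network != "__global__"].pivot(
        index="subject_id", columns="network", values="segregation")
    seg.columns = [f"seg_{c}" for c in seg.columns]
    pw = processed["pairwise"].copy()
    pw["term"] = [_dmn_pair_name(a, b) for a, b in zip(pw.net_a, pw.net_b)]
    pw = pw.dropna(subset=["term"]).pivot(index="subject_id",
                                          columns="term", values="z")
    wide = glob.merge(seg, on="subject_id").merge(pw, on="subject_id")
    wide = wide.merge(ages, on="subject_id")
    return wide


def run_statistics(processed: dict, ages: pd.DataFrame,
                   alpha: float = 0.05, outlier_k: float = 3.0) -> dict:
    """The full inferential stage on processed cohort tables.

    ``ages`` is a frame with subject_id and age (years).  Steps: sample
    standardization of age; RMS-FD residualization of every connectivity
    measure; extreme-outlier removal on global segregation for the age
    models; linear/quadratic age models for the global measures and
    per-network segregation with BH-FDR over the 12 model fits; valence-bias
    models per network; AIC backward elimination of the 11 DMN pairwise
    connectivities with age forced in; age-moderation screening; simple
    slopes and Johnson-Neyman intervals for retained interactions.
    """
    wide = _wide_table(processed, ages)
    scale = mdl.AgeScale(float(wide.age.mean()), float(wide.age.std(ddof=1)))
    wide["age_z"] = mdl.standardize_age(wide.age, scale)

    seg_cols = [c for c in wide.columns if c.startswith("seg_")]
    pair_cols = [c for c in DMN_PAIR_TERMS if c in wide.columns]
    rsfc_cols = ["W", "B", "S_global"] + seg_cols + pair_cols
    resid = mdl.residualize_fd(wide, rsfc_cols)

    out_idx = mdl.detect_outliers(resid["S_global"], k=outlier_k)
    age_data = resid.drop(resid.index[out_idx])

    # global age models (Table-1 shape)
    table1 = {}
    for name, col in (("Segregation", "S_global"), ("Within-Network", "W"),
                      ("Between-Network", "B")):
        table1[name] = mdl.fit_age_model(age_data[col], age_data.age_z)

    # per-network segregation vs age, FDR across the 12 model fits
    net_fits = {}
    for col in seg_cols:
        net_fits[col.removeprefix("seg_")] = mdl.fit_age_model(
            age_data[col], age_data.age_z)
    nets = list(net_fits)
    fdr = mdl.fdr_adjust([net_fits[n].f_pvalue for n in nets])
    network_age = pd.DataFrame({
        "network": nets,
        "B_age": [net_fits[n].params["age_z"] for n in nets],
        "p_model": [net_fits[n].f_pvalue for n in nets],
        "p_model_fdr": fdr,
        "quadratic": ["age_z2" in net_fits[n].terms for n in nets],
    })

    # valence bias ~ age + per-network segregation
    bias_seg = {}
    for col in seg_cols:
        bias_seg[col.removeprefix("seg_")] = mdl.fit_bias_model(
            resid.valence_bias, resid[[col]], resid.age_z)

    # DMN between-network follow-up: AIC elimination + moderation
    forced = pd.DataFrame({"age_z": resid.age_z.values},
                          index=resid.index)
    trace, elim_fit = mdl.backward_eliminate(
        resid.valence_bias.values, resid[pair_cols], forced)
    selected = [t for t in trace.final_terms if t != "age_z"]
    final_fit, interactions = mdl.screen_interactions(
        resid.valence_bias.values, resid[selected], forced, alpha=alpha)

    moderation = {}
    for name in interactions:
        focal = name.split(":")[0]
        moderation[name] = mdl.johnson_neyman(final_fit, focal, name,
                                              alpha=alpha, age_scale=scale)

    return {"wide": wide, "residualized": resid, "age_scale": scale,
            "outliers": list(resid.subject_id.iloc[out_idx]),
            "table1": table1, "network_age": network_age,
            "network_age_fits": net_fits, "bias_segregation": bias_seg,
            "elimination": trace, "elimination_fit": elim_fit,
            "final_model": final_fit, "interactions": interactions,
            "moderation": moderation}


def analyze_cohort(cohort: Cohort, alpha: float = 0.05, **process_kwargs) -> dict:
    """Process a cohort and run the statistical stage; merges both outputs."""
    processed = process_cohort(cohort, **process_kwargs)
    ages = pd.DataFrame({
        "subject_id": [s.subject_id for s in cohort.subjects],
        "age": [s.age for s in cohort.subjects]})
    if processed["long"].empty or processed["long"]["subject_id"].nunique() < 20:
        raise RuntimeError("too few included subjects for the model stage")
    stats = run_statistics(processed, ages, alpha=alpha)
    return {**processed, **stats}
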