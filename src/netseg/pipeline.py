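"""Disk-backed pipeline orchestration: config, staged outputs, reports.

One YAML config drives the whole chain — simulate -> score-behavior -> qc ->
connectivity -> metrics -> models -> report — with deterministic outputs
given (config, seed) and a run manifest giving every subject a terminal
status (included or excluded with a reason).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .cohort import CohortSpec, ConfigurationError, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "RunManifest"]

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All thresholds and paths for one pipeline run."""

    out_dir: str = "netseg_out"
    seed: int = 0
    n_subjects: int = 20
    fd_threshold: float = 0.2
    min_segment: int = 5
    min_run_frames: int = 50
    frame_budget: int = 800
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    accuracy_cutoff: float = 0.60
    alpha: float = 0.05
    outlier_k: float = 3.0
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides

    def validate(self) -> None:
        for name in ("fd_threshold", "min_segment", "min_run_frames",
                     "frame_budget", "alpha", "outlier_k"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigurationError("band: require 0 < low < high")
        if not 0 < self.accuracy_cutoff <= 1:
            raise ConfigurationError("accuracy_cutoff: must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_subjects=self.n_subjects, seed=self.seed,
                          **self.cohort)


@dataclass
class RunManifest:
    """Terminal status for every input subject plus run provenance."""

    statuses: dict
    config_hash: str
    stages: list
    version: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": list(self.statuses),
                             "status": list(self.statuses.values())})

    def counts(self) -> dict:
        out = {}
        for s in self.statuses.values():
            out[s] = out.get(s, 0) + 1
        return out


def _fit_rows(fit, model_name: str) -> list:
    rows = []
    for term in fit.terms:
        rows.append({"model": model_name, "term": term,
                     "B": fit.params[term], "SE": fit.bse[term],
                     "t_value": fit.tvalues[term], "p_value": fit.pvalues[term],
                     "F": fit.fvalue, "df_model": fit.df_model,
                     "df_resid": fit.df_resid, "R2": fit.rsquared})
    return rows


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all tables under ``config.out_dir``."""
    from . import __version__

    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if not config.simulate:
        raise NotImplementedError(
            "external ingestion is limited to the stage CLIs; the end-to-end "
            "runner expects a simulated cohort")
    cohort = generate_cohort(config.cohort_spec())
    cohort.subject_table().to_csv(out / "subjects.tsv", sep="\t", index=False,
                                  float_format=FLOAT_FMT)
    cohort.parcellation().to_csv(out / "parcellation.tsv", sep="\t", index=False)

    results = analysis.analyze_cohort(
        cohort, alpha=config.alpha,
        fd_threshold=config.fd_threshold, min_segment=config.min_segment,
        min_run_frames=config.min_run_frames, budget=config.frame_budget,
        low_hz=config.band_low_hz, high_hz=config.band_high_hz,
        accuracy_cutoff=config.accuracy_cutoff)

    results["behavior"].to_csv(out / "behavior_scores.tsv", sep="\t",
                               index=False, float_format=FLOAT_FMT)
    results["qc"].to_csv(out / "qc_report.tsv", sep="\t", index=False,
                         float_format=FLOAT_FMT)
    results["long"].to_csv(out / "measures.tsv", sep="\t", index=False,
                           float_format=FLOAT_FMT)
    results["pairwise"].to_csv(out / "pairwise.tsv", sep="\t", index=False,
                               float_format=FLOAT_FMT)

    t1 = []
    for name, fit in results["table1"].items():
        t1.extend(_fit_rows(fit, name))
    pd.DataFrame(t1).to_csv(out / "table1.tsv", sep="\t", index=False,
                            float_format=FLOAT_FMT)
    results["network_age"].to_csv(out / "network_age_models.tsv", sep="\t",
                                  index=False, float_format=FLOAT_FMT)
    pd.DataFrame(_fit_rows(results["final_model"], "final_bias_model")).to_csv(
        out / "table2.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    results["elimination"].to_frame().to_csv(out / "elimination_trace.tsv",
                                             sep="\t", index=False,
                                             float_format=FLOAT_FMT)

    mod_rows = []
    for name, res in results["moderation"].items():
        for _, r in res.slopes.iterrows():
            mod_rows.append({"interaction": name, "kind": "simple_slope",
                             "moderator": r.moderator, "value": r.slope,
                             "se": r.se, "t": r.t, "p": r.p})
        for j, b in enumerate(res.boundaries_z):
            raw = res.boundaries_raw[j] if res.boundaries_raw else np.nan
            mod_rows.append({"interaction": name, "kind": "jn_boundary",
                             "moderator": b, "value": raw, "se": np.nan,
                             "t": res.t_crit, "p": np.nan})
    pd.DataFrame(mod_rows).to_csv(out / "moderation.tsv", sep="\t",
                                  index=False, float_format=FLOAT_FMT)

    manifest = RunManifest(statuses=results["statuses"],
                           config_hash=config.digest(),
                           stages=["simulate", "behavior", "qc",
                                   "connectivity", "metrics", "models",
                                   "report"],
                           version=__version__)
    manifest.to_frame().to_csv(out / "manifest.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    make_report(results, manifest, out / "report.txt")
    return manifest


def make_report(results: dict, manifest: RunManifest, path) -> None:
    """Render text tables in the published layouts plus the exclusion flow."""
    lines = ["# Models predicting network measures from age", ""]
    for name, fit in results["table1"].items():
        lines.append(f"{name} (F({fit.df_model:.0f}, {fit.df_resid:.0f}) = "
                     f"{fit.fvalue:.2f}, p = {fit.f_pvalue:.3g}, "
                     f"R2 = {fit.rsquared:.3f})")
        lines.append(f"{'term':<14}{'B':>10}{'SE':>10}{'t':>10}{'p':>10}")
        for term in fit.terms:
            label = {"age_z": "Age", "age_z2": "Age (quadratic)"}.get(term, term)
            lines.append(f"{label:<14}{fit.params[term]:>10.4f}"
                         f"{fit.bse[term]:>10.4f}{fit.tvalues[term]:>10.3f}"
                         f"{fit.pvalues[term]:>10.3g}")
        lines.append("")

    fit = results["final_model"]
    lines += ["# Final model predicting valence bias from DMN connectivity",
              "",
              f"F({fit.df_model:.0f}, {fit.df_resid:.0f}) = {fit.fvalue:.3f}, "
              f"p = {fit.f_pvalue:.3g}, R2 = {fit.rsquared:.3f}"]
    order = (["Intercept", "age_z"]
             + [t for t in fit.terms if t not in ("Intercept", "age_z")
                and ":" not in t]
             + [t for t in fit.terms if ":" in t])
    lines.append(f"{'term':<22}{'B':>10}{'SE':>10}{'t':>10}{'p':>10}")
    for term in order:
        label = "Age" if term == "age_z" else term.replace(":age_z", " x Age")
        lines.append(f"{label:<22}{fit.params[term]:>10.3f}"
                     f"{fit.bse[term]:>10.3f}{fit.tvalues[term]:>10.3f}"
                     f"{fit.pvalues[term]:>10.3g}")
    lines.append("")

    if results["moderation"]:
        for name, res in results["moderation"].items():
            lines.append(f"# Moderation: {name}")
            for _, r in res.slopes.iterrows():
                lines.append(f"  slope at moderator {r.moderator:+.0f} SD: "
                             f"{r.slope:.3f} (SE {r.se:.3f}, t {r.t:.3f}, "
                             f"p {r.p:.3g})")
            if res.boundaries_raw:
                where = "outside" if res.significant_outside else "inside"
                bounds = ", ".join(f"{b:.2f} years" for b in res.boundaries_raw)
                lines.append(f"  Johnson-Neyman: significant {where} "
                             f"[{bounds}]")
            lines.append("")
    else:
        lines += ["# Moderation", "no moderation detected", ""]

    lines.append("# Exclusion flow")
    counts = manifest.counts()
    for status in sorted(counts):
        lines.append(f"  {status}: {counts[status]}")
    lines.append(f"  total: {sum(counts.values())}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
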