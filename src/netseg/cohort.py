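"""Seeded synthetic lifespan cohorts with planted network / behavior structure.

The generator emulates a cross-sectional resting-state study: each subject
gets an age, per-network connectivity targets that follow lifespan profiles
(within-network coupling declining linearly with standardized age,
between-network coupling following an inverted-U), a valence-bias score
driven by age and by specific default-mode (DMN) pairwise connectivities,
a 96-trial behavioral table, realistic six-parameter motion traces with
age-dependent spike rates, and ROI time series drawn from a block covariance
that realizes the planted targets exactly.

Covariance construction uses correlated network factors: ROI *i* in network
*k* is ``x_i = lambda_k * f_k + sqrt(1 - lambda_k**2) * eps_i`` where the
factor vector ``f`` has correlation matrix ``Phi``.  Then the within-network
ROI correlation is ``lambda_k**2`` and the between-network correlation is
``lambda_k * lambda_l * Phi[k, l]``, so loadings and factor correlations are
solved directly from the targets (with a PSD projection when the implied
``Phi`` is indefinite; recorded targets are always the realized ones).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS_14",
    "ANALYSIS_NETWORKS",
    "ConfigurationError",
    "CohortSpec",
    "SubjectRecord",
    "Cohort",
    "default_network_sizes",
    "generate_cohort",
    "generate_trials",
    "generate_motion",
    "make_parcellation",
]

#: The 14 functional networks of the 300-ROI parcellation.
NETWORKS_14 = (
    "SMd", "SMl", "CO", "Auditory", "DMN", "PM", "Visual",
    "FPN", "SAL", "VAN", "DAN", "MTL", "Reward", "Unassigned",
)

#: The 12 networks analyzed after merging SMd+SMl and dropping Unassigned.
ANALYSIS_NETWORKS = (
    "SM", "CO", "Auditory", "DMN", "PM", "Visual",
    "FPN", "SAL", "VAN", "DAN", "MTL", "Reward",
)


class ConfigurationError(ValueError):
    """Raised when a cohort specification field is invalid."""


def default_network_sizes(n_rois: int = 300) -> dict:
    """Equal network sizes, remainder assigned to the Unassigned network."""
    base = n_rois // len(NETWORKS_14)
    if base < 2:
        raise ConfigurationError("n_rois: too few ROIs for 14 networks")
    sizes = {name: base for name in NETWORKS_14}
    sizes["Unassigned"] += n_rois - base * len(NETWORKS_14)
    return sizes


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Age profiles act on standardized age ``a`` (population mean/SD of the
    uniform age distribution).  Within-network Fisher-z targets follow
    ``z_within0 + beta_age_seg * a``; between-network targets follow
    ``z_between0 + beta_between_lin * a + beta_between_quad * a**2`` plus a
    subject-level pairwise deviation with SD ``pair_sd``.  Valence bias (in
    percentage points) is ``bias_intercept + beta_bias_age * a
    + gamma_co * dz(DMN,CO) + gamma_van * dz(DMN,VAN)
    + gamma_reward * dz(DMN,Reward)
    + gamma_reward_by_age * a * dz(DMN,Reward) + noise`` where ``dz`` is the
    planted pairwise z minus the age-profile baseline, clipped to [0, 100].

    Effect magnitudes are set so that, at the default cohort size, each
    planted effect is detectable through the full measurement chain (block
    time series, censoring, band-pass, global-signal regression, negative
    thresholding) — they are true-scale coefficients and deliberately larger
    than the measured-scale estimates a study would print.
    """

    n_subjects: int = 250
    age_range: tuple = (6.0, 80.0)
    n_rois: int = 300
    network_sizes: dict | None = None
    n_frames: int = 1000
    n_runs: int = 2
    tr: float = 1.0
    # planted connectivity profiles (Fisher-z units per standardized-age unit)
    z_within0: float = 0.6
    beta_age_seg: float = -0.05
    z_between0: float = 0.15
    beta_between_lin: float = 0.02
    beta_between_quad: float = -0.01
    within_sd: float = 0.05
    pair_sd: float = 0.14
    # planted behavioral model (valence-bias percentage points per unit z)
    bias_intercept: float = 50.0
    beta_bias_age: float = 5.0
    gamma_co: float = 70.0
    gamma_van: float = 20.0
    gamma_reward: float = -55.0
    gamma_reward_by_age: float = -70.0
    bias_noise_sd: float = 8.0
    accuracy_clear_range: tuple = (0.85, 1.0)
    # motion model: spike rate is U-shaped in age
    motion_spike_base: float = 0.005
    motion_spike_amp: float = 0.02
    motion_drift_sd: float = 0.01
    seed: int = 0

    def resolved_network_sizes(self) -> dict:
        if self.network_sizes is None:
            return default_network_sizes(self.n_rois)
        return dict(self.network_sizes)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects: must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range: min must be < max")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames: must be >= 1")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs: must be >= 1")
        if self.tr <= 0:
            raise ConfigurationError("tr: must be positive")
        sizes = self.resolved_network_sizes()
        if set(sizes) != set(NETWORKS_14):
            raise ConfigurationError("network_sizes: must name the 14 networks")
        if sum(sizes.values()) != self.n_rois:
            raise ConfigurationError("network_sizes: must sum to n_rois")
        if any(v < 2 for v in sizes.values()):
            raise ConfigurationError("network_sizes: every network needs >= 2 ROIs")
        for name in ("motion_spike_base", "motion_spike_amp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: rate must be in [0, 1]")
        if self.bias_noise_sd < 0:
            raise ConfigurationError("bias_noise_sd: must be >= 0")
        if not 0 <= self.accuracy_clear_range[0] <= self.accuracy_clear_range[1] <= 1:
            raise ConfigurationError("accuracy_clear_range: must be within [0, 1]")

    # population moments of the uniform age distribution: used to define
    # standardized age for the planted profiles (sample standardization is
    # applied downstream, in the analysis, like any real study would).
    @property
    def age_mean(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def age_sd(self) -> float:
        return (self.age_range[1] - self.age_range[0]) / np.sqrt(12.0)


@dataclass
class SubjectRecord:
    """Ground truth for one synthetic subject."""

    subject_id: str
    age: float
    age_z: float
    true_bias: float
    accuracy_clear: float
    spike_rate: float
    #: planted within-network Fisher z per 14 networks (realized)
    true_within: np.ndarray = field(repr=False, default=None)
    #: planted pairwise between-network Fisher z, 14 x 14 (realized)
    true_between: np.ndarray = field(repr=False, default=None)
    #: per-subject child seeds (trials, motion, timeseries, tissue)
    _seeds: tuple = field(repr=False, default=None)


def _nearest_corr(phi: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and rescale to unit diagonal."""
    w, v = np.linalg.eigh(phi)
    if w.min() >= floor:
        return phi
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _plant_targets(spec: CohortSpec, age_z: np.ndarray, rng: np.random.Generator):
    """Draw planted z targets and return realized (PSD-consistent) values.

    Returns per-subject arrays ``within_z (n, 14)``, ``between_z (n, 14, 14)``
    plus the pairwise deviations from the age baseline used for the bias model.
    """
    n = len(age_z)
    k = len(NETWORKS_14)
    zw = spec.z_within0 + spec.beta_age_seg * age_z[:, None]
    zw = zw + rng.normal(0.0, spec.within_sd, size=(n, k))
    zw = np.clip(zw, 0.08, 1.4)

    zb_base = (spec.z_between0 + spec.beta_between_lin * age_z
               + spec.beta_between_quad * age_z**2)
    iu = np.triu_indices(k, 1)
    dev = rng.normal(0.0, spec.pair_sd, size=(n, len(iu[0])))
    zb = np.zeros((n, k, k))
    zb[:, iu[0], iu[1]] = zb_base[:, None] + dev
    zb = zb + np.transpose(zb, (0, 2, 1))
    zb = np.clip(zb, -0.8, 1.2)

    # solve factor model and re-record realized targets
    lam = np.sqrt(np.tanh(zw))  # loadings from within-corr targets
    rb = np.tanh(zb)
    realized_w = np.empty_like(zw)
    realized_b = np.empty_like(zb)
    phis = np.empty((n, k, k))
    for i in range(n):
        denom = np.outer(lam[i], lam[i])
        phi = rb[i] / denom
        np.fill_diagonal(phi, 1.0)
        phi = _nearest_corr(np.clip(phi, -0.97, 0.97))
        phis[i] = phi
        r_real = denom * phi
        realized_w[i] = np.arctanh(lam[i] ** 2)
        off = r_real.copy()
        np.fill_diagonal(off, 0.0)
        realized_b[i] = np.arctanh(np.clip(off, -0.999, 0.999))
    return realized_w, realized_b, lam, phis, zb_base


def generate_cohort(spec: CohortSpec) -> "Cohort":
    """Generate a deterministic cohort bundle from a validated spec.

    Subject-level ground truth (ages, planted targets, true bias) is drawn
    up front; trial tables, motion traces and ROI time series are produced
    lazily per subject from child seeds so large cohorts never need to be
    held in memory at once.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    age_z = (ages - spec.age_mean) / spec.age_sd

    within_z, between_z, lam, phis, zb_base = _plant_targets(spec, age_z, rng)

    idx = {name: i for i, name in enumerate(NETWORKS_14)}
    d_co = between_z[:, idx["DMN"], idx["CO"]] - zb_base
    d_van = between_z[:, idx["DMN"], idx["VAN"]] - zb_base
    d_rew = between_z[:, idx["DMN"], idx["Reward"]] - zb_base
    noise = rng.normal(0.0, spec.bias_noise_sd, size=n) if spec.bias_noise_sd else 0.0
    bias = (spec.bias_intercept
            + spec.beta_bias_age * age_z
            + spec.gamma_co * d_co
            + spec.gamma_van * d_van
            + spec.gamma_reward * d_rew
            + spec.gamma_reward_by_age * age_z * d_rew
            + noise)
    bias = np.clip(bias, 0.0, 100.0)

    acc = rng.uniform(*spec.accuracy_clear_range, size=n)
    mid = spec.age_mean
    half = 0.5 * (spec.age_range[1] - spec.age_range[0])
    spike = spec.motion_spike_base + spec.motion_spike_amp * ((ages - mid) / half) ** 2
    child_seeds = rng.integers(0, 2**31 - 1, size=(n, 4))

    width = len(str(n))
    subjects = []
    for i in range(n):
        subjects.append(SubjectRecord(
            subject_id=f"sub-{i + 1:0{width}d}",
            age=float(ages[i]),
            age_z=float(age_z[i]),
            true_bias=float(bias[i]),
            accuracy_clear=float(acc[i]),
            spike_rate=float(spike[i]),
            true_within=within_z[i],
            true_between=between_z[i],
            _seeds=tuple(int(s) for s in child_seeds[i]),
        ))
    return Cohort(spec=spec, subjects=subjects, _lam=lam, _phi=phis)


def generate_trials(subject: SubjectRecord, seed: int | None = None,
                    exact_counts: bool = False) -> pd.DataFrame:
    """96-trial valence-bias task table: 4 blocks (2 faces, 2 scenes), each
    12 ambiguous + 12 clearly valenced trials (6 positive, 6 negative).

    Ambiguous responses are positive with probability ``true_bias / 100``;
    clear responses are correct with probability ``accuracy_clear``.  With
    ``exact_counts=True`` exactly ``round(true_bias / 100 * 48)`` ambiguous
    responses are positive (in a seeded random arrangement), so scoring
    recovers the planted bias without binomial noise whenever it is a
    multiple of 100/48.
    """
    if not 0.0 <= subject.true_bias <= 100.0:
        raise ConfigurationError("true_bias: must lie in [0, 100]")
    if seed is None:
        seed = subject._seeds[0]
    rng = np.random.default_rng(seed)

    blocks = np.repeat([1, 2, 3, 4], 24)
    stim = np.repeat(["face", "scene", "face", "scene"], 24)
    per_block = ["ambiguous"] * 12 + ["clear_positive"] * 6 + ["clear_negative"] * 6
    valence = np.array(per_block * 4)

    resp = np.empty(96, dtype=object)
    amb = valence == "ambiguous"
    if exact_counts:
        n_pos = int(round(subject.true_bias / 100.0 * amb.sum()))
        pos = np.zeros(amb.sum(), dtype=bool)
        pos[rng.permutation(amb.sum())[:n_pos]] = True
        resp[amb] = np.where(pos, "positive", "negative")
    else:
        resp[amb] = np.where(rng.random(amb.sum()) < subject.true_bias / 100.0,
                             "positive", "negative")
    for cls, correct, wrong in (("clear_positive", "positive", "negative"),
                                ("clear_negative", "negative", "positive")):
        m = valence == cls
        resp[m] = np.where(rng.random(m.sum()) < subject.accuracy_clear,
                           correct, wrong)
    return pd.DataFrame({
        "trial_id": np.arange(1, 97),
        "block": blocks,
        "stimulus_type": stim,
        "valence_class": valence,
        "response": resp,
    })


def generate_motion(subject: SubjectRecord, n_frames: int, tr: float,
                    spike_rate: float | None = None, seed: int | None = None,
                    drift_sd: float = 0.01, n_runs: int = 1) -> list:
    """Per-run realignment traces: columns are x/y/z translation (mm) then
    pitch/roll/yaw rotation (radians).

    The baseline is a low-amplitude random walk whose framewise displacement
    stays well below the 0.2 mm censoring threshold; spikes are sustained
    translation steps of ~1 mm whose filtered-FD signature exceeds the
    threshold over a small cluster of frames.  ``spike_rate`` is the expected
    fraction of frames that start a spike.
    """
    if spike_rate is None:
        spike_rate = subject.spike_rate
    if not 0.0 <= spike_rate <= 1.0:
        raise ConfigurationError("spike_rate: must be in [0, 1]")
    if seed is None:
        seed = subject._seeds[1]
    rng = np.random.default_rng(seed)

    per_run = _split_frames(n_frames, n_runs)
    runs = []
    for nf in per_run:
        trans = np.cumsum(rng.normal(0.0, drift_sd, size=(nf, 3)), axis=0)
        rot = np.cumsum(rng.normal(0.0, drift_sd / 100.0, size=(nf, 3)), axis=0)
        if drift_sd == 0:
            trans[:] = 0.0
            rot[:] = 0.0
        onsets = np.flatnonzero(rng.random(nf) < spike_rate)
        for t in onsets:
            axis = rng.integers(0, 3)
            step = rng.uniform(0.8, 1.5) * rng.choice([-1.0, 1.0])
            trans[t:, axis] += step
        runs.append(np.hstack([trans, rot]))
    return runs


def _split_frames(n_frames: int, n_runs: int) -> list:
    base = n_frames // n_runs
    sizes = [base] * n_runs
    for i in range(n_frames - base * n_runs):
        sizes[i] += 1
    return sizes


@dataclass
class Cohort:
    """A generated cohort: eager subject-level truth, lazy per-subject data."""

    spec: CohortSpec
    subjects: list
    _lam: np.ndarray = field(repr=False, default=None)
    _phi: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_table(self) -> pd.DataFrame:
        """Ground-truth subject table (columns prefixed true_ are planted)."""
        rows = []
        idx = {name: i for i, name in enumerate(NETWORKS_14)}
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id,
                "age": s.age,
                "age_z": s.age_z,
                "true_bias": s.true_bias,
                "accuracy_clear": s.accuracy_clear,
                "spike_rate": s.spike_rate,
                "true_dmn_co_z": s.true_between[idx["DMN"], idx["CO"]],
                "true_dmn_van_z": s.true_between[idx["DMN"], idx["VAN"]],
                "true_dmn_reward_z": s.true_between[idx["DMN"], idx["Reward"]],
            })
        return pd.DataFrame(rows)

    def parcellation(self) -> pd.DataFrame:
        return make_parcellation(self.spec)

    def network_labels(self) -> np.ndarray:
        sizes = self.spec.resolved_network_sizes()
        return np.repeat(list(NETWORKS_14), [sizes[k] for k in NETWORKS_14])

    def trials(self, i: int) -> pd.DataFrame:
        return generate_trials(self.subjects[i])

    def motion(self, i: int) -> list:
        s = self.subjects[i]
        return generate_motion(s, self.spec.n_frames, self.spec.tr,
                               drift_sd=self.spec.motion_drift_sd,
                               n_runs=self.spec.n_runs)

    def _net_idx(self) -> np.ndarray:
        if not hasattr(self, "_net_idx_cache"):
            idx = {name: j for j, name in enumerate(NETWORKS_14)}
            self._net_idx_cache = np.array([idx[l] for l in self.network_labels()])
        return self._net_idx_cache

    def timeseries(self, i: int) -> list:
        """Per-run frames x ROI matrices realizing the planted block covariance."""
        s = self.subjects[i]
        rng = np.random.default_rng(s._seeds[2])
        lam = self._lam[i]
        chol = np.linalg.cholesky(self._phi[i] + 1e-10 * np.eye(len(NETWORKS_14)))
        net_idx = self._net_idx()
        runs = []
        load = lam[net_idx]
        noise_scale = np.sqrt(1.0 - load**2)
        for nf in _split_frames(self.spec.n_frames, self.spec.n_runs):
            factors = rng.standard_normal((nf, len(NETWORKS_14))) @ chol.T
            x = rng.standard_normal((nf, self.spec.n_rois))
            x *= noise_scale
            x += factors[:, net_idx] * load
            runs.append(x)
        return runs

    def planted_measures(self, i: int) -> dict:
        """Expected network measures implied by subject i's planted targets.

        Computed on the 12 analysis networks (SMd+SMl merged, Unassigned
        dropped) with exact pair counts, mirroring the downstream metric
        definitions: per-network within/between mean z, segregation, and the
        equal-weight global summaries.
        """
        s = self.subjects[i]
        sizes = self.spec.resolved_network_sizes()
        k14 = list(NETWORKS_14)
        # ROI-level block values in z units
        zw14, zb14 = s.true_within, s.true_between
        groups = {"SM": ["SMd", "SMl"]}
        for name in ANALYSIS_NETWORKS:
            if name != "SM":
                groups[name] = [name]
        within = {}
        between = {}
        names = list(ANALYSIS_NETWORKS)
        for a in names:
            mem = groups[a]
            npairs = 0
            tot = 0.0
            for m in mem:
                nm = sizes[m]
                npairs += nm * (nm - 1) // 2
                tot += zw14[k14.index(m)] * (nm * (nm - 1) // 2)
            for p in range(len(mem)):
                for q in range(p + 1, len(mem)):
                    na, nb = sizes[mem[p]], sizes[mem[q]]
                    tot += zb14[k14.index(mem[p]), k14.index(mem[q])] * na * nb
                    npairs += na * nb
            within[a] = tot / npairs
        for a in names:
            tot = 0.0
            cnt = 0
            for b in names:
                if b == a:
                    continue
                for m in groups[a]:
                    for m2 in groups[b]:
                        na, nb = sizes[m], sizes[m2]
                        tot += zb14[k14.index(m), k14.index(m2)] * na * nb
                        cnt += na * nb
            between[a] = tot / cnt
        seg = {a: (within[a] - between[a]) / within[a] for a in names}
        w = float(np.mean(list(within.values())))
        b = float(np.mean(list(between.values())))
        return {"within": within, "between": between, "segregation": seg,
                "W": w, "B": b, "S_global": (w - b) / w}

    def write(self, outdir) -> None:
        """Materialize the cohort to plain-text files under ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        for sub in ("trials", "motion", "timeseries"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        self.subject_table().to_csv(out / "subjects.tsv", sep="\t", index=False,
                                    float_format="%.6g")
        self.parcellation().to_csv(out / "parcellation.tsv", sep="\t", index=False)
        for i, s in enumerate(self.subjects):
            self.trials(i).to_csv(out / "trials" / f"{s.subject_id}.csv", index=False)
            for k, run in enumerate(self.motion(i), start=1):
                df = pd.DataFrame(run, columns=["trans_x", "trans_y", "trans_z",
                                                "rot_x", "rot_y", "rot_z"])
                df.insert(0, "frame", np.arange(1, len(df) + 1))
                df.to_csv(out / "motion" / f"{s.subject_id}_run{k}.tsv",
                          sep="\t", index=False, float_format="%.6g")
            for k, run in enumerate(self.timeseries(i), start=1):
                df = pd.DataFrame(run, columns=[f"roi{j + 1}"
                                                for j in range(run.shape[1])])
                df.to_csv(out / "timeseries" / f"{s.subject_id}_run{k}.tsv",
                          sep="\t", index=False, float_format="%.6g")


def make_parcellation(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic parcellation table (roi_id, display coordinates, network)."""
    sizes = spec.resolved_network_sizes()
    labels = np.repeat(list(NETWORKS_14), [sizes[k] for k in NETWORKS_14])
    rng = np.random.default_rng(987654321)  # display-only coordinates
    coords = np.round(rng.uniform(-70, 70, size=(spec.n_rois, 3)), 1)
    return pd.DataFrame({
        "roi_id": np.arange(1, spec.n_rois + 1),
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "network": labels,
    })
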