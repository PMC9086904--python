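"""Synthetic three-group cohort generator.

Produces per-subject ROI voxel-value samples plus a clinical table with the
statistical structure the downstream analysis assumes:

* per-ROI values come from two-component Gaussian mixtures whose means and
  weights vary smoothly around a ring of ROI positions and load on shared
  latent factors, so inter-ROI similarity decays with ring distance and the
  thresholded networks are small-world;
* a global-integration effect can be planted in one group by blending the
  ring profile with fixed random per-ROI coordinates (a higher-dimensional
  parameter geometry gives shorter graph distances, i.e. higher Eglob, at
  every fixed sparsity);
* edge-level effects pull one ROI's mixture parameters toward its partner's
  within the stated group only;
* tremor severity can be rewritten as a linear function of one node's
  expected similarity strength to plant a degree <-> TRS correlation.

One global seed expands to per-subject substreams keyed by a stable hash of
the subject ID, so any subject is reproducible independent of cohort order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kls_network import GridSpec, target_strengths
from .roi_io import RoiSampleSet, default_roi_names

GROUPS = ("SleET", "NorET", "HC")

# ring-structure amplitudes (tuned so default networks are small-world at
# every sparsity in [0.10, 0.35] while leaving room for the global effect)
_MU1_BASE = 2.8
_MU2_BASE = 5.2
_MU_AMP = 0.70
_COMP_SD = 0.55
_LOGIT_AMP = 1.2
_LATENT_AMP = 0.45
_LOGIT_NOISE_SD = 0.18
_MU_JITTER_SD = 0.04
_VALUE_FLOOR = 0.01


@dataclass
class ClinicalModel:
    """Group-conditional clinical score distributions (means, sds)."""

    age: tuple = (54.0, 13.0)
    education: tuple = (11.0, 4.0)
    male_fraction: float = 0.35
    trs: dict = field(default_factory=lambda: {
        "SleET": (25.8, 12.0), "NorET": (17.0, 10.0)})
    psqi: dict = field(default_factory=lambda: {
        "SleET": (13.0, 4.0), "NorET": (3.9, 1.6), "HC": (2.6, 1.5)})
    mmse: dict = field(default_factory=lambda: {
        "SleET": (27.0, 1.6), "NorET": (27.2, 1.6), "HC": (27.9, 1.4)})
    hama: dict = field(default_factory=lambda: {
        "SleET": (9.2, 3.0), "NorET": (4.7, 2.5), "HC": (3.8, 2.2)})
    hamd: dict = field(default_factory=lambda: {
        "SleET": (9.9, 3.5), "NorET": (4.3, 2.5), "HC": (2.9, 2.0)})
    duration: tuple = (11.8, 8.0)
    degree_trs_rho: float = 0.0


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort."""

    group_sizes: dict = field(default_factory=lambda: {
        "SleET": 45, "NorET": 59, "HC": 66})
    n_rois: int = 116
    voxels_per_roi: tuple = (100, 300)
    latent_dim: int = 3
    planted_edges: list = field(default_factory=list)  # (roi_a, roi_b, group, effect)
    planted_global_effect: float = 0.0
    planted_global_group: str = "SleET"
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    roi_names: list | None = None
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group(s): {sorted(unknown)}")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g} must have >= 2 subjects, got {n}")
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        vmin, vmax = self.voxels_per_roi
        if not (2 <= vmin <= vmax):
            raise ValueError("voxels_per_roi must satisfy 2 <= min <= max")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not np.isfinite(self.planted_global_effect):
            raise ValueError("planted_global_effect must be finite")
        if self.planted_global_group not in GROUPS:
            raise ValueError(f"unknown group: {self.planted_global_group}")
        for a, b, g, eff in self.planted_edges:
            if not (0 <= a < self.n_rois and 0 <= b < self.n_rois):
                raise ValueError(f"planted edge ROI index out of range: ({a}, {b})")
            if a == b:
                raise ValueError("planted edge must join two distinct ROIs")
            if g not in GROUPS:
                raise ValueError(f"unknown group in planted edge: {g}")
            if not np.isfinite(eff):
                raise ValueError("planted edge effect size must be finite")
        if self.roi_names is None:
            if self.n_rois == 116:
                self.roi_names = default_roi_names()
            else:
                self.roi_names = [f"ROI_{k + 1:03d}" for k in range(self.n_rois)]
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length does not match n_rois")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: int
    sex: str
    education: int
    onset_age: float
    duration: float
    TRS: float
    TRS_A: float
    TRS_B: float
    TRS_C: float
    PSQI: int
    MMSE: int
    HAMA: int
    HAMD: int


@dataclass
class Cohort:
    spec: CohortSpec
    sample_sets: list
    table: pd.DataFrame
    # per-subject mixture parameters (mu1, mu2, logit), kept for planting
    params: dict = field(default_factory=dict, repr=False)

    def __iter__(self):
        return iter((self.sample_sets, self.table))


def _subject_seed(global_seed: int, subject_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([global_seed, zlib.crc32(subject_id.encode())])


def _roi_structure(spec: CohortSpec):
    """Cohort-level ROI parameters: smooth ring structure + latent loadings.

    ``offsets`` are fixed per-ROI random coordinates used by the planted
    global-integration effect: adding them to the smooth ring profile lifts
    the affected group's parameter geometry into a higher-dimensional
    scatter, whose thresholded similarity graphs have shorter paths (higher
    Eglob) at every fixed sparsity while remaining clustered.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_rois
    theta = 2.0 * np.pi * np.arange(n) / n
    phi0 = rng.uniform(0, 2 * np.pi)
    dev1 = _MU_AMP * np.cos(theta)
    dev2 = _MU_AMP * np.sin(theta)
    logit0 = _LOGIT_AMP * np.cos(theta + phi0)
    loadings = np.empty((n, spec.latent_dim))
    for l in range(spec.latent_dim):
        phi = rng.uniform(0, 2 * np.pi)
        loadings[:, l] = _LATENT_AMP * np.cos((l + 2) * theta + phi)
    offsets = rng.normal(size=(n, 5))
    return dev1, dev2, logit0, loadings, offsets


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_scores(rng, mean, sd, lo, hi):
    return int(np.clip(np.round(rng.normal(mean, sd)), lo, hi))


def _subject_params(spec: CohortSpec, group: str, rng, structure):
    dev1, dev2, logit0, loadings, offsets = structure
    n = spec.n_rois
    z = rng.normal(size=spec.latent_dim)
    struct1, struct2, struct_l = dev1, dev2, logit0 + loadings @ z
    g_eff = max(spec.planted_global_effect, 0.0)
    if group == spec.planted_global_group and g_eff > 0:
        # variance-preserving blend of the 1-D ring profile with fixed random
        # per-ROI coordinates: the affected group's parameter geometry becomes
        # effectively higher-dimensional, which shortens graph distances
        # (higher Eglob/lower Lp) at every fixed sparsity
        beta = g_eff / (1.0 + g_eff)
        a, b = np.sqrt(1.0 - beta), np.sqrt(beta)
        struct1 = a * dev1 + b * (_MU_AMP / np.sqrt(2)) * offsets[:, 0]
        struct2 = a * dev2 + b * (_MU_AMP / np.sqrt(2)) * offsets[:, 1]
        struct_l = a * struct_l + b * (_LOGIT_AMP / np.sqrt(2)) * offsets[:, 2]
    mu1 = _MU1_BASE + struct1 + rng.normal(0, _MU_JITTER_SD, n)
    mu2 = _MU2_BASE + struct2 + rng.normal(0, _MU_JITTER_SD, n)
    logit = struct_l + rng.normal(0, _LOGIT_NOISE_SD, n)
    sd1 = np.full(n, _COMP_SD)
    sd2 = np.full(n, _COMP_SD)
    for ra, rb, g, eff in spec.planted_edges:
        if g == group:
            mu1[rb] += eff * (mu1[ra] - mu1[rb])
            mu2[rb] += eff * (mu2[ra] - mu2[rb])
            logit[rb] += eff * (logit[ra] - logit[rb])
            sd1[rb] += eff * (sd1[ra] - sd1[rb])
            sd2[rb] += eff * (sd2[ra] - sd2[rb])
    return mu1, mu2, logit, sd1, sd2


def _sample_rois(spec: CohortSpec, rng, params):
    mu1, mu2, logit, sd1, sd2 = params
    vmin, vmax = spec.voxels_per_roi
    w2 = _sigmoid(logit)
    samples = []
    for r in range(spec.n_rois):
        n_vox = int(rng.integers(vmin, vmax + 1))
        comp2 = rng.random(n_vox) < w2[r]
        vals = np.where(comp2,
                        rng.normal(mu2[r], sd2[r], n_vox),
                        rng.normal(mu1[r], sd1[r], n_vox))
        samples.append(np.maximum(vals, _VALUE_FLOOR))
    return samples


def _clinical_record(spec: CohortSpec, subject_id: str, group: str, rng) -> SubjectRecord:
    cm = spec.clinical_model
    age = _draw_scores(rng, *cm.age, 20, 80)
    sex = "M" if rng.random() < cm.male_fraction else "F"
    education = _draw_scores(rng, *cm.education, 0, 22)
    if group == "HC":
        duration = np.nan
        onset = np.nan
        trs = trs_a = trs_b = trs_c = np.nan
    else:
        duration = float(np.clip(np.round(rng.normal(*cm.duration)), 3, age - 18))
        onset = age - duration
        trs = float(np.clip(np.round(rng.normal(*cm.trs[group])), 0, 100))
        trs_a, trs_b, trs_c = _split_trs(trs, rng)
    if group == "SleET":
        psqi = _draw_scores(rng, *cm.psqi[group], 6, 21)
    else:
        psqi = _draw_scores(rng, *cm.psqi[group], 0, 5)
    mmse = _draw_scores(rng, *cm.mmse[group], 24, 30)
    hama = _draw_scores(rng, *cm.hama[group], 0, 14)
    hamd = _draw_scores(rng, *cm.hamd[group], 0, 17)
    return SubjectRecord(subject_id=subject_id, group=group, age=age, sex=sex,
                         education=education, onset_age=onset, duration=duration,
                         TRS=trs, TRS_A=trs_a, TRS_B=trs_b, TRS_C=trs_c,
                         PSQI=psqi, MMSE=mmse, HAMA=hama, HAMD=hamd)


def _split_trs(trs: float, rng) -> tuple:
    fa = float(np.clip(0.25 + rng.normal(0, 0.04), 0.05, 0.5))
    fb = float(np.clip(0.55 + rng.normal(0, 0.04), 0.3, 0.9 - fa))
    trs_a = float(np.round(fa * trs))
    trs_b = float(np.round(fb * trs))
    trs_c = max(trs - trs_a - trs_b, 0.0)
    return trs_a, trs_b, trs_c


def generate_cohort(spec: CohortSpec) -> Cohort:
    """One RoiSampleSet per subject plus the cohort clinical table.

    Deterministic given ``spec.seed``; per-ROI samples are drawn from
    subject-specific mixtures whose parameters share latent factors across
    ROIs, and planted effects apply only to their stated group.
    """
    structure = _roi_structure(spec)
    sample_sets, records, params_by_subject = [], [], {}
    for group in GROUPS:
        n_g = spec.group_sizes.get(group, 0)
        for k in range(n_g):
            sid = f"{group}{k + 1:03d}"
            rng = np.random.default_rng(_subject_seed(spec.seed, sid))
            params = _subject_params(spec, group, rng, structure)
            samples = _sample_rois(spec, rng, params)
            sample_sets.append(RoiSampleSet(subject_id=sid,
                                            roi_labels=list(spec.roi_names),
                                            samples=samples))
            records.append(_clinical_record(spec, sid, group, rng))
            params_by_subject[sid] = params
    table = pd.DataFrame([vars(r) for r in records])
    return Cohort(spec=spec, sample_sets=sample_sets, table=table,
                  params=params_by_subject)


def plant_degree_trs_correlation(cohort: Cohort, target_roi: int, rho: float,
                                 grid_spec: GridSpec | None = None) -> Cohort:
    """Rewrite TRS as a linear function of the target ROI's expected degree.

    Expected degree is measured as the subject's summed KLS of the target
    ROI against all other ROIs (its network row strength, a sampling-free
    monotone proxy of thresholded degree). Within each ET group, TRS is set
    to rho * z(strength) + sqrt(1 - rho^2) * noise on the group's TRS scale,
    so the population partial correlation is approximately rho.
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("|rho| must be < 1")
    spec = cohort.spec
    if not (0 <= target_roi < spec.n_rois):
        raise ValueError(f"target ROI {target_roi} out of range")
    grid_spec = grid_spec or GridSpec(n_points=128)

    strengths = {}
    for ss in cohort.sample_sets:
        strengths[ss.subject_id] = float(
            target_strengths(ss, target_roi, grid_spec).sum())

    table = cohort.table.copy()
    cm = spec.clinical_model
    for group in ("SleET", "NorET"):
        idx = table.index[table["group"] == group]
        if len(idx) == 0:
            continue
        deg = np.array([strengths[s] for s in table.loc[idx, "subject_id"]])
        sd_deg = deg.std(ddof=1)
        if sd_deg < 1e-9:
            raise ValueError("degenerate degree variance: cannot plant correlation")
        z = (deg - deg.mean()) / sd_deg
        mean_trs, sd_trs = cm.trs[group]
        noise_rng = np.random.default_rng(np.random.SeedSequence(
            [spec.seed, zlib.crc32(b"plant-trs"), zlib.crc32(group.encode())]))
        eps = noise_rng.normal(size=len(idx))
        trs = mean_trs + sd_trs * (rho * z + np.sqrt(1.0 - rho ** 2) * eps)
        trs = np.clip(np.round(trs), 0, 100)
        table.loc[idx, "TRS"] = trs
        split_rng = np.random.default_rng(np.random.SeedSequence(
            [spec.seed, zlib.crc32(b"plant-trs-split"), zlib.crc32(group.encode())]))
        parts = [_split_trs(t, split_rng) for t in trs]
        table.loc[idx, "TRS_A"] = [p[0] for p in parts]
        table.loc[idx, "TRS_B"] = [p[1] for p in parts]
        table.loc[idx, "TRS_C"] = [p[2] for p in parts]
    return replace(cohort, table=table)
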