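"""Synthetic study generator.

Every input the analysis pipeline consumes can be generated here: a
brain-like template geometry (nested ellipsoids standing in for an MNI-space
template), a streamline atlas of smooth synthetic bundles, per-subject
infarct and WMH lesion masks, tract-disconnection count corpora drawn from
an exact K-factor mixed-membership generative model, and cognitive outcomes
in which one latent factor carries a planted effect with age/education
confounding.

Two corpus routes exist by design: :func:`sample_disconnection_corpus`
draws counts directly from the factor model (so estimator-recovery tests
are exact-model tests), while the geometric route (lesions ->
disconnectome -> pseudo-count encoding) exercises the full chain and is
assembled by the pipeline module.

Default configuration mirrors the emulated cohort: 105 subjects, 24
tracts, 3 latent factors, one causal factor with a planted log-odds of
log(10) per unit loading, age ~ N(63, 12) years, education ~ N(12, 4)
years, PSCI prevalence near 52% at month 6 and 38% at month 36.

All generators are pure functions of (config, seed): same seed, same bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy import interpolate, ndimage

from .disconnectome import Streamline, StreamlineAtlas, Tract, canonical_registry
from .lesion_mapping import LesionMask

__all__ = [
    "TemplateSpace",
    "SynthConfig",
    "GroundTruth",
    "make_template",
    "make_atlas",
    "sample_lesions",
    "sample_disconnection_corpus",
    "sample_cognition",
    "DOMAINS",
]

DOMAINS = ("memory", "attention", "visuospatial", "language")

# Relative causal-factor weight per cognitive domain.  The planted factor
# hits attention/executive hardest, then language and visuospatial, memory
# least — the profile reported for WMH-driven disconnection.
_DOMAIN_WEIGHTS = {"memory": 0.35, "attention": 1.0, "visuospatial": 0.75, "language": 0.85}

# Domain baselines per timepoint, fixed so that the default configuration
# yields impairment prevalence near the emulated cohort (~52% at month 6,
# ~38% at month 36) under the z <= -1.5 rule.
_BASELINES = {
    6: {"memory": -0.41, "attention": -0.36, "visuospatial": -0.36, "language": -0.36},
    36: {"memory": -0.12, "attention": -0.07, "visuospatial": -0.07, "language": -0.07},
}

_SHARED_SD = 0.5  # per-subject general-ability SD shared across domains/timepoints


@dataclass
class TemplateSpace:
    """Brain-like synthetic template geometry.

    A nested-ellipsoid stand-in for a registered template: an outer brain
    ellipsoid whose outermost shell is "cortex", a central ventricular
    ellipsoid, 9 lobar sectors (8 supratentorial angular sectors plus one
    infratentorial lobe) and 10 vascular territories (6 supratentorial,
    4 infratentorial) that partition the brain volume.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    cortex_mask: np.ndarray
    lobe_labels: np.ndarray
    territory_labels: np.ndarray

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class GroundTruth:
    """Planted generative parameters behind a synthetic corpus."""

    beta_true: np.ndarray   # k_true x n_tracts, rows on the simplex
    theta_true: np.ndarray  # n_subjects x k_true, rows on the simplex
    causal_factor_index: int
    outcome_coeffs: dict


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with cohort-scale defaults."""

    n_subjects: int = 105
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_tracts: int = 24
    streamlines_per_tract: int = 20
    k_true: int = 3
    dirichlet_alpha: float = 1.0 / 3.0
    total_pseudocount: int = 1000
    effect_beta: float = log(10.0)          # log-odds per unit causal loading
    confound_coeffs: tuple[float, float] = (-0.35, 0.25)  # age, education
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_tracts <= 0 or self.k_true <= 0:
            raise ValueError("counts must be positive")
        if self.streamlines_per_tract <= 0 or self.total_pseudocount <= 0:
            raise ValueError("counts must be positive")
        if self.k_true > self.n_tracts:
            raise ValueError("k_true must not exceed n_tracts")
        if self.dirichlet_alpha <= 0 or self.noise_sd <= 0:
            raise ValueError("dirichlet_alpha and noise_sd must be positive")

    @property
    def causal_factor_index(self) -> int:
        # factor "2" when K >= 2, mirroring the emulated study's causal factor
        return 1 if self.k_true >= 2 else 0


# --------------------------------------------------------------------------
# template geometry
# --------------------------------------------------------------------------

def make_template(
    grid_shape: tuple[int, int, int] = (48, 56, 48),
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
) -> TemplateSpace:
    """Build the synthetic template space.

    Deterministic for a fixed seed; the seed only jitters ellipsoid axes
    slightly so distinct templates can be produced.  Grids smaller than 16
    voxels per axis cannot host the ventricle plus cortical shell and are
    rejected.
    """
    shape = tuple(int(s) for s in grid_shape)
    if min(shape) < 16:
        raise ValueError("grid too small: need >= 16 voxels per axis to host ventricle and shell")
    rng = np.random.default_rng(seed)
    vox = np.asarray(voxel_mm, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vox)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * vox  # mm origin at grid center

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    x = ii * vox[0] + affine[0, 3]
    y = jj * vox[1] + affine[1, 3]
    z = kk * vox[2] + affine[2, 3]

    half = (np.asarray(shape) - 1) / 2.0 * vox
    jitter = 1.0 + 0.03 * rng.uniform(-1.0, 1.0, size=3)
    a = 0.88 * half * jitter  # brain semi-axes (mm)
    brain = (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0

    # ventricle: central ellipsoid, elongated antero-posteriorly, dipping
    # inferiorly so every lobe sees a finite ventricular distance gradient
    vc = np.array([0.0, -0.05 * a[1], -0.10 * a[2]]) + rng.uniform(-1.0, 1.0, 3) * vox * 0.5
    va = np.array([0.18 * a[0], 0.45 * a[1], 0.40 * a[2]])
    ventricle = ((x - vc[0]) / va[0]) ** 2 + ((y - vc[1]) / va[1]) ** 2 + ((z - vc[2]) / va[2]) ** 2 <= 1.0
    ventricle &= brain

    cortex = brain & ~ndimage.binary_erosion(brain, iterations=2)
    ventricle &= ~cortex
    if not ventricle.any() or not (brain & ~ventricle & ~cortex).any():
        raise ValueError("grid too small: ventricle or white matter empty after construction")

    infratentorial = brain & (z < -0.45 * a[2])
    theta = np.arctan2(y, x)
    sector8 = np.minimum((np.floor((theta + np.pi) / (2 * np.pi) * 8)).astype(np.int32), 7)
    lobes = np.zeros(shape, dtype=np.int32)
    lobes[brain] = sector8[brain] + 1
    lobes[infratentorial] = 9

    territories = np.zeros(shape, dtype=np.int32)
    supra = brain & ~infratentorial
    left = x < 0
    anterior = y > a[1] / 3.0
    posterior = y < -a[1] / 3.0
    middle = ~anterior & ~posterior
    territories[supra & anterior & left] = 1
    territories[supra & anterior & ~left] = 2
    territories[supra & middle & left] = 3
    territories[supra & middle & ~left] = 4
    territories[supra & posterior & left] = 5
    territories[supra & posterior & ~left] = 6
    upper = z >= -0.7 * a[2]
    territories[infratentorial & upper & left] = 7
    territories[infratentorial & upper & ~left] = 8
    territories[infratentorial & ~upper & left] = 9
    territories[infratentorial & ~upper & ~left] = 10

    return TemplateSpace(
        shape=shape,
        affine=affine,
        brain_mask=brain,
        ventricle_mask=ventricle,
        cortex_mask=cortex,
        lobe_labels=lobes,
        territory_labels=territories,
    )


# --------------------------------------------------------------------------
# streamline atlas
# --------------------------------------------------------------------------

def _spline_through(points: np.ndarray, n_samples: int) -> np.ndarray:
    t = np.zeros(len(points))
    t[1:] = np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))
    if t[-1] == 0:
        t = np.arange(len(points), dtype=float)
    t /= t[-1]
    k = min(3, len(points) - 1)
    spl = interpolate.make_interp_spline(t, points, k=k)
    return np.asarray(spl(np.linspace(0.0, 1.0, n_samples)))


def make_atlas(
    template: TemplateSpace,
    n_tracts: int = 24,
    streamlines_per_tract: int = 20,
    seed: int = 0,
    points_per_streamline: int = 40,
) -> StreamlineAtlas:
    """Synthesize a streamline atlas of smooth bundles inside the template.

    Each tract is defined by a backbone of control points spanning the
    brain interior; each streamline is a cubic spline through a jittered
    copy of the backbone, clipped to the grid bounding box.  Tract names
    are taken from the canonical 70-tract registry when enough are
    available.
    """
    if n_tracts < 2:
        raise ValueError("need at least 2 tracts")
    rng = np.random.default_rng(seed)
    interior = ndimage.binary_erosion(template.brain_mask, iterations=3) & ~template.ventricle_mask
    coords_vox = np.argwhere(interior)
    affine = template.affine
    coords_mm = coords_vox @ affine[:3, :3].T + affine[:3, 3]
    lo_vox = np.zeros(3)
    hi_vox = np.asarray(template.shape, dtype=float) - 1.0
    inv = np.linalg.inv(affine)

    registry = canonical_registry()
    names = registry[:n_tracts] if n_tracts <= len(registry) else [f"Tract {i+1:03d}" for i in range(n_tracts)]

    tracts = []
    for ti in range(n_tracts):
        # backbone: two far-apart endpoints plus intermediate waypoints
        for _ in range(50):
            ends = coords_mm[rng.integers(0, len(coords_mm), size=2)]
            if np.linalg.norm(ends[0] - ends[1]) > 0.7 * np.max(np.abs(coords_mm)):
                break
        n_ctrl = 5
        frac = np.linspace(0.0, 1.0, n_ctrl)[:, None]
        backbone = ends[0] * (1 - frac) + ends[1] * frac
        backbone[1:-1] += rng.normal(0.0, 6.0, size=(n_ctrl - 2, 3))
        streamlines = []
        for _ in range(streamlines_per_tract):
            ctrl = backbone + rng.normal(0.0, 1.5, size=backbone.shape)
            pts = _spline_through(ctrl, points_per_streamline)
            # clip to the grid bounding box in voxel space, back to mm
            v = pts @ inv[:3, :3].T + inv[:3, 3]
            v = np.clip(v, lo_vox, hi_vox)
            pts = v @ affine[:3, :3].T + affine[:3, 3]
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
            pts = pts[keep]
            if len(pts) < 2:
                pts = np.vstack([pts, pts + 1e-3])
            streamlines.append(Streamline(points=pts))
        tracts.append(Tract(name=names[ti], streamlines=streamlines))
    return StreamlineAtlas(tracts=tracts, space_tag=f"synthetic-{template.shape}")


# --------------------------------------------------------------------------
# lesion masks
# --------------------------------------------------------------------------

# territory propensities for infarct placement: middle-artery territories
# dominate, infratentorial territories are uncommon
_TERRITORY_WEIGHTS = np.array([0.08, 0.08, 0.30, 0.30, 0.07, 0.07, 0.025, 0.025, 0.025, 0.025])


def sample_lesions(
    template: TemplateSpace,
    kind: str,
    n_subjects: int,
    seed: int = 0,
    rim_mm: tuple[float, float] = (1.5, 6.0),
) -> list[LesionMask]:
    """Draw per-subject binary lesion masks on the template grid.

    infarct
        One compact ellipsoidal blob confined to a randomly chosen
        vascular territory (middle-artery territories most likely),
        excluded from the ventricles.  Blob placement varies freely, so
        pairwise overlap across subjects is low.
    wmh
        A periventricular shell: all white-matter voxels within a
        per-subject rim distance of the ventricle surface, with a wider
        rim anteriorly (frontal predominance).  Because every subject's
        cap hugs the same ventricle, overlap across subjects is high.
    """
    if kind not in ("infarct", "wmh"):
        raise ValueError("kind must be 'infarct' or 'wmh'")
    rng = np.random.default_rng(seed)
    vox = template.voxel_mm
    dv = ndimage.distance_transform_edt(~template.ventricle_mask, sampling=vox)
    affine = template.affine
    shape = template.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    x = ii * vox[0] + affine[0, 3]
    y = jj * vox[1] + affine[1, 3]
    z = kk * vox[2] + affine[2, 3]

    wm_ok = template.brain_mask & ~template.ventricle_mask
    masks: list[LesionMask] = []
    for s in range(n_subjects):
        sid = f"S{s+1:03d}"
        if kind == "infarct":
            grid = np.zeros(shape, dtype=np.uint8)
            for _attempt in range(20):
                code = int(rng.choice(10, p=_TERRITORY_WEIGHTS)) + 1
                cand = np.argwhere((template.territory_labels == code) & (dv > 4.0))
                if len(cand) == 0:
                    continue
                c = cand[rng.integers(0, len(cand))]
                cx, cy, cz = c[0] * vox[0] + affine[0, 3], c[1] * vox[1] + affine[1, 3], c[2] * vox[2] + affine[2, 3]
                radii = np.exp(rng.normal(np.log(15.0), 0.55)) * rng.uniform(0.8, 1.2, size=3)
                blob = ((x - cx) / radii[0]) ** 2 + ((y - cy) / radii[1]) ** 2 + ((z - cz) / radii[2]) ** 2 <= 1.0
                blob &= (template.territory_labels == code) & ~template.ventricle_mask
                if blob.any():
                    grid = blob.astype(np.uint8)
                    break
        else:
            rim = rng.uniform(*rim_mm)
            rim_map = np.where(y > 0, rim * 1.3, rim)  # anterior (frontal) predominance
            shell = (dv > 0) & (dv <= rim_map) & wm_ok & ~template.cortex_mask
            grid = shell.astype(np.uint8)
        masks.append(LesionMask(subject_id=sid, kind=kind, grid=grid, affine=affine))
    return masks


# --------------------------------------------------------------------------
# factor-model corpus
# --------------------------------------------------------------------------

def sample_disconnection_corpus(config: SynthConfig) -> tuple[np.ndarray, GroundTruth]:
    """Draw an N x T disconnection count corpus from the exact factor model.

    theta rows ~ Dirichlet(alpha); beta rows ~ Dirichlet with a strong
    bias toward disjoint per-factor tract blocks; each subject's count
    vector ~ Multinomial(total_pseudocount, theta_d . beta).
    """
    rng = np.random.default_rng(config.seed)
    K, T, N = config.k_true, config.n_tracts, config.n_subjects

    conc = np.full((K, T), 0.05)
    bounds = np.linspace(0, T, K + 1).astype(int)
    for k in range(K):
        conc[k, bounds[k]:bounds[k + 1]] = 2.0
    beta = np.vstack([rng.dirichlet(conc[k]) for k in range(K)])

    theta = rng.dirichlet(np.full(K, config.dirichlet_alpha), size=N) if K > 1 else np.ones((N, 1))

    rates = theta @ beta
    counts = np.vstack([rng.multinomial(config.total_pseudocount, r) for r in rates])
    truth = GroundTruth(
        beta_true=beta,
        theta_true=theta,
        causal_factor_index=config.causal_factor_index,
        outcome_coeffs={
            "effect_beta": config.effect_beta,
            "age": config.confound_coeffs[0],
            "education": config.confound_coeffs[1],
        },
    )
    return counts, truth


# --------------------------------------------------------------------------
# cognitive outcomes
# --------------------------------------------------------------------------

def sample_cognition(theta_true: np.ndarray, config: SynthConfig, seed: int = 0):
    """Simulate the cohort table given planted factor loadings.

    Domain z-scores at months 6 and 36 are a baseline minus a causal-factor
    term (weights concentrated on attention/language/visuospatial) plus
    age/education confounds, a shared subject-level ability term, and
    independent noise.  PSCI at each timepoint is the z <= -1.5 any-domain
    rule; MoCA at 72 h correlates with overall ability.  The causal-factor
    weights are scaled so the induced log-odds of impairment per unit
    loading approximates ``config.effect_beta``.
    """
    import pandas as pd

    from .association_stats import psci_classify

    theta = np.asarray(theta_true, dtype=float)
    if not np.allclose(theta.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("theta_true rows must sum to 1")
    n = theta.shape[0]
    rng = np.random.default_rng(seed)
    causal = config.causal_factor_index if theta.shape[1] > config.causal_factor_index else 0
    xload = theta[:, causal]

    age = np.clip(rng.normal(63.0, 12.0, n), 40.0, 90.0)
    education = np.clip(np.rint(rng.normal(12.0, 4.0, n)), 5, 22)
    icv = np.clip(rng.normal(1450.0, 130.0, n), 1000.0, None)
    age_c = (age - 63.0) / 12.0
    edu_c = (education - 12.0) / 4.0
    ability = rng.normal(0.0, _SHARED_SD, n)

    sigma_tot = float(np.hypot(config.noise_sd, _SHARED_SD))
    weight_scale = config.effect_beta * sigma_tot / 1.7  # probit->logit slope calibration
    c_age, c_edu = config.confound_coeffs

    cols: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i+1:03d}" for i in range(n)]),
        "age": np.round(age, 1),
        "education": education.astype(int),
        "icv_cm3": np.round(icv, 1),
        "wmh_cm3": np.round(np.exp(rng.normal(1.494, 1.187, n)), 2),
        "infarct_cm3": np.round(np.exp(rng.normal(1.667, 1.152, n)), 2),
    }
    zmats = {}
    for tp in (6, 36):
        zs = np.empty((n, len(DOMAINS)))
        for di, d in enumerate(DOMAINS):
            w = weight_scale * _DOMAIN_WEIGHTS[d]
            zs[:, di] = (
                _BASELINES[tp][d]
                - w * xload
                + c_age * age_c
                + c_edu * edu_c
                + ability
                + rng.normal(0.0, config.noise_sd, n)
            )
            cols[f"z_{d}_m{tp}"] = np.round(zs[:, di], 4)
        zmats[tp] = zs
        cols[f"psci_m{tp}"] = np.array([psci_classify(row) for row in zs], dtype=int)

    moca = 26.0 + 1.8 * ability + 0.6 * zmats[6].mean(axis=1) + rng.normal(0.0, 1.2, n)
    cols["moca"] = np.clip(np.rint(moca), 0, 30).astype(int)

    for k in range(theta.shape[1]):
        cols[f"loading_{k+1}"] = np.round(theta[:, k], 6)

    order = (
        ["subject_id", "age", "education", "moca", "icv_cm3", "wmh_cm3", "infarct_cm3"]
        + [f"z_{d}_m{tp}" for tp in (6, 36) for d in DOMAINS]
        + ["psci_m6", "psci_m36"]
        + [f"loading_{k+1}" for k in range(theta.shape[1])]
    )
    return pd.DataFrame({c: cols[c] for c in order})
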