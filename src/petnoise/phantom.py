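"""Synthetic whole-body-like SUV phantoms with known ground-truth noise.

Generates piecewise-constant volumes (air background, elliptical body, a
"liver" and a "lung" sphere) plus additive Gaussian noise inside the body
whose SD follows the count-statistics law σ(t) = σ_ref · sqrt(120 / t) for a
bed time of t seconds. A per-reconstruction Gaussian smoothing stands in for
stronger regularization: the noise field is smoothed before being added, so
organ borders stay sharp, air stays exactly zero, and smoothing can only
lower the noise level.

All generators are pure functions of (spec, seed, condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import BadPhantomSpecError
from .io import PatientMeta, SuvVolume

AIR, BODY, LIVER, LUNG = 0, 1, 2, 3
LABEL_NAMES = {AIR: "air", BODY: "body", LIVER: "liver", LUNG: "lung"}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_BED_TIMES = (15, 30, 60, 90, 120)
REFERENCE_BED_TIME_S = 120.0


@dataclass
class Organ:
    label: str
    center_frac: tuple[float, float, float]  # (x, y, z) as fractions of the grid
    radius_frac: float  # sphere radius as fraction of nx
    mean_suv: float


@dataclass
class PhantomSpec:
    """Geometry, intensity, and noise model of one synthetic subject."""

    grid_size: tuple[int, int, int] = (96, 96, 48)  # (nx, ny, nz)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_semiaxes_frac: tuple[float, float] = (0.42, 0.35)  # in-plane, fractions of nx/ny
    body_suv: float = 1.0
    organs: tuple[Organ, ...] = (
        Organ("liver", (0.66, 0.50, 0.40), 0.13, 2.5),
        Organ("lung", (0.34, 0.45, 0.72), 0.11, 0.4),
    )
    sigma_ref: float = 0.15  # noise SD at the reference bed time (120 s)
    bed_times_s: tuple[int, ...] = DEFAULT_BED_TIMES
    smoothing_mm: dict[str, float] = field(
        default_factory=lambda: {"Q.Clear 450": 0.0, "Q.Clear 600": 2.0}
    )
    background_noise_sd: float = 0.0  # optional air noise, for mask robustness tests
    seed: int = 0


@dataclass
class PhantomTruth:
    labels: np.ndarray  # organ id per voxel, [z, y, x]
    sigma_true: float  # noise SD before smoothing
    organ_centers_mm: dict[str, tuple[float, float, float]]
    means: dict[str, float]


def true_sigma(spec: PhantomSpec, bed_time_s: float) -> float:
    """Pre-smoothing noise SD: σ(t) = σ_ref · sqrt(120 / t)."""
    return spec.sigma_ref * np.sqrt(REFERENCE_BED_TIME_S / bed_time_s)


def _validate_spec(spec: PhantomSpec) -> None:
    nx, ny, nz = spec.grid_size
    if min(nx, ny, nz) < 8:
        raise BadPhantomSpecError("bad phantom spec: grid must be at least 8 per axis")
    if any(s <= 0 for s in spec.spacing_mm):
        raise BadPhantomSpecError("bad phantom spec: spacing must be positive")
    if spec.sigma_ref < 0 or spec.background_noise_sd < 0:
        raise BadPhantomSpecError("bad phantom spec: noise SDs must be non-negative")
    if spec.body_suv < 0 or any(o.mean_suv < 0 for o in spec.organs):
        raise BadPhantomSpecError("bad phantom spec: mean SUVs must be non-negative")
    ax, ay = spec.body_semiaxes_frac
    if not (0 < ax <= 0.5 and 0 < ay <= 0.5):
        raise BadPhantomSpecError("bad phantom spec: body semi-axes must be in (0, 0.5]")
    for o in spec.organs:
        # organ sphere must fit inside the body ellipse cylinder
        ex = (o.center_frac[0] - 0.5) / ax
        ey = (o.center_frac[1] - 0.5) / ay
        margin = o.radius_frac / (min(ax, ay) * 1.0)
        if np.hypot(ex, ey) + margin > 1.0:
            raise BadPhantomSpecError(f"bad phantom spec: organ {o.label!r} leaves the body")


def _label_volume(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_size
    ix = np.arange(nx)[None, None, :]
    iy = np.arange(ny)[None, :, None]
    iz = np.arange(nz)[:, None, None]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = spec.body_semiaxes_frac[0] * nx, spec.body_semiaxes_frac[1] * ny
    body = ((ix - cx) / ax) ** 2 + ((iy - cy) / ay) ** 2 <= 1.0
    body = np.broadcast_to(body, (nz, ny, nx)).copy()
    labels = np.where(body, BODY, AIR).astype(np.int8)
    for organ in spec.organs:
        ox, oy, oz = (
            organ.center_frac[0] * (nx - 1),
            organ.center_frac[1] * (ny - 1),
            organ.center_frac[2] * (nz - 1),
        )
        r = organ.radius_frac * nx
        sphere = (ix - ox) ** 2 + (iy - oy) ** 2 + (iz - oz) ** 2 <= r * r
        code = LIVER if organ.label == "liver" else LUNG
        labels[sphere & body] = code
    return labels


def _organ_centers_mm(spec: PhantomSpec) -> dict[str, tuple[float, float, float]]:
    nx, ny, nz = spec.grid_size
    dx, dy, dz = spec.spacing_mm
    out = {}
    for o in spec.organs:
        out[o.label] = (
            o.center_frac[0] * (nx - 1) * dx,
            o.center_frac[1] * (ny - 1) * dy,
            o.center_frac[2] * (nz - 1) * dz,
        )
    return out


def _condition_rng(spec: PhantomSpec, bed_time_s: int) -> np.random.Generator:
    # Shared across recon labels so that smoothing acts on the same noise field.
    return np.random.default_rng(np.random.SeedSequence([spec.seed & 0xFFFFFFFF, int(bed_time_s)]))


def make_phantom(
    spec: PhantomSpec, bed_time_s: int, recon_label: str
) -> tuple[SuvVolume, PhantomTruth]:
    """Generate one synthetic SUV volume for a (bed time, reconstruction) condition.

    Organ means are piecewise constant; Gaussian noise of SD σ(t) is added
    inside the body only (air stays exactly 0 unless ``background_noise_sd``
    is set); the per-reconstruction smoothing (mm FWHM) is applied to the
    noise field before addition. Deterministic given (spec, bed_time,
    recon_label); the noise realization is shared across recon labels.
    """
    _validate_spec(spec)
    if bed_time_s not in spec.bed_times_s:
        raise BadPhantomSpecError(f"bad phantom spec: bed time {bed_time_s} not in {spec.bed_times_s}")
    if recon_label not in spec.smoothing_mm:
        raise BadPhantomSpecError(f"bad phantom spec: unknown recon label {recon_label!r}")

    labels = _label_volume(spec)
    means = {BODY: spec.body_suv, AIR: 0.0}
    for o in spec.organs:
        means[LIVER if o.label == "liver" else LUNG] = o.mean_suv
    lut = np.zeros(4)
    for code, mu in means.items():
        lut[code] = mu
    voxels = lut[labels]

    sigma = true_sigma(spec, bed_time_s)
    rng = _condition_rng(spec, bed_time_s)
    body_mask = labels != AIR
    if sigma > 0:
        noise = rng.standard_normal(labels.shape) * sigma
        fwhm = spec.smoothing_mm[recon_label]
        if fwhm > 0:
            sig_vox = [
                fwhm * _FWHM_TO_SIGMA / s for s in (spec.spacing_mm[2], spec.spacing_mm[1], spec.spacing_mm[0])
            ]
            noise = ndimage.gaussian_filter(noise, sigma=sig_vox)
        voxels = voxels + np.where(body_mask, noise, 0.0)
    if spec.background_noise_sd > 0:
        bg = rng.standard_normal(labels.shape) * spec.background_noise_sd
        voxels = voxels + np.where(body_mask, 0.0, bg)

    meta = PatientMeta(
        weight_kg=75.0,
        injected_activity_MBq=250.0,
        uptake_time_min=60.0,
        bed_time_s=float(bed_time_s),
        recon_label=recon_label,
    )
    vol = SuvVolume(voxels=voxels, spacing=spec.spacing_mm, origin=(0.0, 0.0, 0.0), meta=meta)
    truth = PhantomTruth(
        labels=labels,
        sigma_true=float(sigma),
        organ_centers_mm=_organ_centers_mm(spec),
        means={LABEL_NAMES[k]: v for k, v in means.items()},
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortItem:
    subject_id: str
    bed_time_s: int
    recon_label: str
    volume: SuvVolume
    truth: PhantomTruth


@dataclass
class Cohort:
    """A lazily generated phantom cohort plus its noise-table skeleton."""

    subject_specs: dict[str, PhantomSpec]
    recon_labels: tuple[str, ...]
    table: pd.DataFrame  # skeleton: keys + sigma_true; gni/liver_sd/lung_sd NaN

    def items(self) -> Iterator[CohortItem]:
        for subject_id, spec in self.subject_specs.items():
            for bed_time in spec.bed_times_s:
                for recon in self.recon_labels:
                    vol, truth = make_phantom(spec, bed_time, recon)
                    vol.meta.study_id = subject_id
                    yield CohortItem(subject_id, bed_time, recon, vol, truth)

    def __len__(self) -> int:
        return len(self.table)


def make_cohort(spec: PhantomSpec, n_subjects: int, seed: int = 0) -> Cohort:
    """Per-subject randomized cohort over all bed-time × reconstruction conditions.

    Each subject gets a randomized body size and reference noise level; the
    condition grid mirrors a bed-time reduction series with two
    reconstruction labels. Deterministic given (spec, n_subjects, seed).
    """
    if n_subjects < 1:
        raise BadPhantomSpecError("bad phantom spec: n_subjects must be >= 1")
    _validate_spec(spec)
    rng = np.random.default_rng(seed)
    recon_labels = tuple(spec.smoothing_mm.keys())
    subject_specs: dict[str, PhantomSpec] = {}
    rows = []
    for i in range(n_subjects):
        body_scale = rng.uniform(0.85, 1.08)
        sigma_scale = rng.uniform(0.85, 1.2)
        subj_seed = int(rng.integers(0, 2**31 - 1))
        ax, ay = spec.body_semiaxes_frac
        subj_spec = replace(
            spec,
            body_semiaxes_frac=(min(0.5, ax * body_scale), min(0.5, ay * body_scale)),
            sigma_ref=spec.sigma_ref * sigma_scale,
            seed=subj_seed,
        )
        subject_id = f"subj{i:03d}"
        subject_specs[subject_id] = subj_spec
        for bed_time in spec.bed_times_s:
            for recon in recon_labels:
                rows.append(
                    {
                        "subject_id": subject_id,
                        "bed_time_s": bed_time,
                        "recon_label": recon,
                        "sigma_true": true_sigma(subj_spec, bed_time),
                        "gni": np.nan,
                        "liver_sd": np.nan,
                        "lung_sd": np.nan,
                        "quality_label": "",
                    }
                )
    return Cohort(subject_specs=subject_specs, recon_labels=recon_labels, table=pd.DataFrame(rows))


def simulate_quality_labels(
    gni_values, latent_cutoff: float, label_noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Stand-in for consensus reader labels.

    A study is labeled insufficient iff its GNI plus Gaussian reader noise
    exceeds ``latent_cutoff``. With ``label_noise_sd = 0`` the labels are a
    deterministic threshold on the GNI.
    """
    if label_noise_sd < 0:
        raise ValueError("label_noise_sd must be >= 0")
    gni_values = np.asarray(gni_values, dtype=np.float64)
    rng = np.random.default_rng(seed)
    latent = gni_values + rng.standard_normal(gni_values.shape) * label_noise_sd
    return np.where(latent > latent_cutoff, "insufficient", "sufficient")
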