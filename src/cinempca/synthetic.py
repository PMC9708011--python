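"""Synthetic cine-MRI cohorts with planted prognostic signal.

Generates per-subject 2D+time image tensors for two cardiac views (short-axis
``SA`` and four-chamber ``4Ch``) together with landmark tables and
proportional-hazards survival outcomes.  A hidden per-subject latent risk
(standard normal) drives both a localized intensity shift inside a
configurable spatio-temporal region (the planted "lesion", by default a
septal patch around end-systole) and the subject's hazard, so classification,
Cox-regression recovery and saliency localization all have known ground
truth.

The background image is a crude two-ellipse heart template (left-ventricular
disc plus right-ventricular crescent) whose cavities contract and re-expand
over the cycle, overlaid on a smooth Gaussian-filtered noise field.  This is
deliberately schematic: it gives landmark registration and masking realistic
structure to act on without attempting any MRI physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter
from scipy.optimize import brentq

VIEWS = ("SA", "4Ch")

#: Landmark labels, in fixed order, per view.
LANDMARK_LABELS = {
    "SA": ("superior_insertion", "rv_free_wall_inflexion", "lv_lateral_wall"),
    "4Ch": ("lv_apex", "lateral_mitral_annulus", "lateral_tricuspid_annulus"),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic cine cohort.

    ``effect_size`` is the intensity shift planted per unit latent risk, in
    units of the background noise SD.  ``log_hazard_ratio_per_unit_risk`` is
    the Cox log-hazard ratio per 1-SD increment of latent risk; the baseline
    hazard, when left ``None``, is calibrated numerically so that the marginal
    1-year event probability equals ``event_prevalence_1yr``.
    """

    n_subjects: int = 100
    image_size: int = 64
    n_frames: int = 20
    views: Sequence[str] = VIEWS
    signal_region: dict | None = None  # view -> (rows, cols, frames) index arrays
    effect_size: float = 2.0
    event_prevalence_1yr: float = 0.10
    baseline_hazard: float | None = None  # events / subject-year; None => calibrated
    log_hazard_ratio_per_unit_risk: float = 2.0
    censor_horizon: float = 5.0  # years, administrative
    random_censoring_rate: float = 0.0  # optional exponential censoring hazard
    landmark_jitter_sd: float = 1.0  # pixels
    pose_rotation_sd: float = 5.0  # degrees, subject-to-subject pose variation
    pose_translation_sd: float = 2.0  # pixels
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.event_prevalence_1yr <= 1.0:
            raise ValueError("event_prevalence_1yr must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        unknown = set(self.views) - set(VIEWS)
        if unknown:
            raise ValueError(f"unknown views: {sorted(unknown)}")
        if self.signal_region is not None:
            for view, (rr, cc, ff) in self.signal_region.items():
                rr, cc, ff = np.asarray(rr), np.asarray(cc), np.asarray(ff)
                if rr.size == 0:
                    raise ValueError(f"{view}: empty signal region")
                bad_sp = (rr < 0) | (rr >= self.image_size) | (cc < 0) | (cc >= self.image_size)
                bad_t = (ff < 0) | (ff >= self.n_frames)
                if bad_sp.any() or bad_t.any():
                    raise ValueError(
                        f"{view}: signal region outside bounds; offending rows="
                        f"{rr[bad_sp].tolist()} cols={cc[bad_sp].tolist()} "
                        f"frames={np.asarray(ff)[bad_t].tolist()}"
                    )


@dataclass
class CineStudy:
    """One subject's raw material for one view."""

    subject_id: str
    view: str
    tensor: np.ndarray  # H x W x T
    landmarks: dict  # label -> (row, col)
    covariates: dict
    survival_time: float  # years
    event: bool
    latent_risk: float | None = None  # synthetic ground truth
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("tensor contains non-finite values")
        expected = LANDMARK_LABELS.get(self.view)
        if expected is not None and set(self.landmarks) != set(expected):
            raise ValueError(
                f"view {self.view} expects landmarks {expected}, got {sorted(self.landmarks)}"
            )
        if self.survival_time <= 0:
            raise ValueError("survival_time must be positive")


# ---------------------------------------------------------------------------
# heart template
# ---------------------------------------------------------------------------

def _ellipse_mask(size, center, semi, angle=0.0):
    r, c = np.mgrid[0:size, 0:size].astype(float)
    dr, dc = r - center[0], c - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def _contraction(t, n_frames):
    """Cavity scale over the cycle: 1 at end-diastole (frame 0), minimum at
    end-systole (~40% through the cycle)."""
    phase = t / n_frames
    return 1.0 - 0.35 * np.exp(-((phase - 0.4) ** 2) / (2 * 0.12**2))


def end_systole_frame(n_frames: int) -> int:
    """Frame of smallest template cavity area."""
    scales = [_contraction(t, n_frames) for t in range(n_frames)]
    return int(np.argmin(scales))


def template_frame(size: int, t: int, n_frames: int) -> np.ndarray:
    """One frame of the noiseless two-ellipse heart template."""
    s = _contraction(t, n_frames)
    img = np.zeros((size, size))
    lv_c = (0.55 * size, 0.55 * size)
    rv_c = (0.42 * size, 0.36 * size)
    # myocardium (outer shells) bright, blood pools mid-grey
    img[_ellipse_mask(size, lv_c, (0.20 * size, 0.20 * size))] = 2.0
    img[_ellipse_mask(size, rv_c, (0.17 * size, 0.22 * size), angle=0.5)] = 2.0
    img[_ellipse_mask(size, lv_c, (0.13 * size * s, 0.13 * size * s))] = 1.0
    img[_ellipse_mask(size, rv_c, (0.10 * size * s, 0.15 * size * s), angle=0.5)] = 1.0
    return img


def template_landmarks(view: str, size: int) -> dict:
    """True (un-jittered) landmark positions in template coordinates."""
    pts = {
        "SA": ((0.30 * size, 0.42 * size), (0.42 * size, 0.16 * size), (0.58 * size, 0.74 * size)),
        "4Ch": ((0.78 * size, 0.52 * size), (0.40 * size, 0.74 * size), (0.36 * size, 0.22 * size)),
    }[view]
    return dict(zip(LANDMARK_LABELS[view], pts))


def default_signal_region(view: str, size: int, n_frames: int):
    """Septal patch between the two template ventricles, around end-systole."""
    center = (0.49 * size, 0.45 * size)
    radius = 0.07 * size
    r, c = np.mgrid[0:size, 0:size].astype(float)
    disc = (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2
    rows, cols = np.nonzero(disc)
    es = end_systole_frame(n_frames)
    frames = np.arange(max(es - 2, 0), min(es + 3, n_frames))
    return rows, cols, frames


def signal_region_mask(config: SyntheticConfig, view: str) -> np.ndarray:
    """Boolean H x W x T mask of the planted region in template coordinates."""
    region = (config.signal_region or {}).get(view)
    if region is None:
        region = default_signal_region(view, config.image_size, config.n_frames)
    rows, cols, frames = (np.asarray(a) for a in region)
    mask = np.zeros((config.image_size, config.image_size, config.n_frames), dtype=bool)
    for f in frames:
        mask[rows, cols, f] = True
    return mask


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _solve_baseline_hazard(beta: float, target: float) -> float:
    # Gauss-Hermite quadrature over the latent risk distribution
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    weights = weights / weights.sum()

    def prevalence(h0):
        return float(np.sum(weights * (1.0 - np.exp(-h0 * np.exp(beta * nodes)))))

    if target <= 0:
        raise ValueError("cannot calibrate baseline hazard for zero prevalence")
    return brentq(lambda h: prevalence(h) - target, 1e-8, 1e3)


def calibrated_baseline_hazard(config: SyntheticConfig) -> float:
    """Baseline hazard h0 such that E_r[1 - exp(-h0 e^{beta r})] equals the
    configured 1-year prevalence, with r ~ N(0, 1)."""
    if config.baseline_hazard is not None:
        return config.baseline_hazard
    return _solve_baseline_hazard(
        float(config.log_hazard_ratio_per_unit_risk), float(config.event_prevalence_1yr)
    )


def sample_survival(latent_risk: float, config: SyntheticConfig, rng=None):
    """Draw (time in years, event flag) from the exponential proportional-
    hazards model with administrative censoring at ``censor_horizon``."""
    if not np.isfinite(latent_risk):
        raise ValueError("latent_risk must be finite")
    h0 = calibrated_baseline_hazard(config)
    if h0 <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    hazard = h0 * np.exp(config.log_hazard_ratio_per_unit_risk * latent_risk)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = config.censor_horizon
    if config.random_censoring_rate > 0:
        t_cens = min(t_cens, rng.exponential(1.0 / config.random_censoring_rate))
    if t_event <= t_cens:
        return float(t_event), True
    return float(t_cens), False


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def plant_signal(tensor: np.ndarray, region, frames, shift: float) -> np.ndarray:
    """Return a copy of ``tensor`` with ``shift`` added inside region x frames."""
    rows, cols = (np.asarray(a) for a in region)
    frames = np.atleast_1d(np.asarray(frames))
    if rows.size == 0:
        raise ValueError("empty signal region")
    out = tensor.copy()
    for f in frames:
        out[rows, cols, f] += shift
    return out


def _rigid_warp(tensor, angle_rad, shift, order=1):
    """Rotate about the image centre then translate, frame by frame."""
    size = tensor.shape[0]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[ca, -sa], [sa, ca]])
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    # output coord y maps to input coord R^T (y - shift - c) + c
    inv_rot = rot.T
    offset = center - inv_rot @ (center + np.asarray(shift))
    out = np.empty_like(tensor)
    for t in range(tensor.shape[2]):
        out[:, :, t] = affine_transform(
            tensor[:, :, t], inv_rot, offset=offset, order=order, cval=0.0
        )
    return out


def _transform_point(point, angle_rad, shift, size):
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[ca, -sa], [sa, ca]])
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    return rot @ (np.asarray(point, dtype=float) - center) + center + np.asarray(shift)


def _background(size, n_frames, rng, noise_sd):
    """Smooth random field, unit-ish SD before scaling."""
    noise = rng.standard_normal((size, size, n_frames))
    smooth = gaussian_filter(noise, sigma=(2.0, 2.0, 1.0))
    smooth /= smooth.std()
    return noise_sd * smooth


def generate_cohort(config: SyntheticConfig) -> list[CineStudy]:
    """Generate ``n_subjects`` studies per requested view.

    The latent risk r_i ~ N(0,1) sets both the planted intensity shift
    (``effect_size * noise_sd * r_i`` inside the signal region) and the
    survival draw.  Landmarks are the template positions mapped through the
    subject's random pose plus Gaussian jitter.  Identical seed, identical
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    size, T = config.image_size, config.n_frames
    es_frame = end_systole_frame(T)
    template = np.stack([template_frame(size, t, T) for t in range(T)], axis=-1)

    regions = {}
    for view in config.views:
        region = (config.signal_region or {}).get(view)
        regions[view] = region if region is not None else default_signal_region(view, size, T)

    studies = []
    for i in range(config.n_subjects):
        risk = float(rng.standard_normal())
        time, event = sample_survival(risk, config, rng=rng)
        # an observed covariate correlated with (but not equal to) latent risk,
        # standing in for a clinical composite score
        clinical = 0.6 * risk + 0.8 * rng.standard_normal()
        for view in config.views:
            rows, cols, frames = regions[view]
            img = template + _background(size, T, rng, config.noise_sd)
            shift = config.effect_size * config.noise_sd * risk
            if config.effect_size != 0.0:
                img = plant_signal(img, (rows, cols), frames, shift)
            angle = np.deg2rad(rng.normal(0.0, config.pose_rotation_sd))
            trans = rng.normal(0.0, config.pose_translation_sd, size=2)
            img = _rigid_warp(img, angle, trans)
            lms = {}
            for label, pt in template_landmarks(view, size).items():
                moved = _transform_point(pt, angle, trans, size)
                lms[label] = tuple(moved + rng.normal(0.0, config.landmark_jitter_sd, size=2))
            studies.append(
                CineStudy(
                    subject_id=f"S{i:04d}",
                    view=view,
                    tensor=img,
                    landmarks=lms,
                    covariates={"clinical_score": clinical},
                    survival_time=time,
                    event=event,
                    latent_risk=risk,
                    metadata={
                        "end_diastole_frame": 0,
                        "end_systole_frame": es_frame,
                        "pose_angle_rad": float(angle),
                        "pose_translation": tuple(float(x) for x in trans),
                    },
                )
            )
    return studies


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: same configuration, different seed."""
    return replace(config, seed=seed)
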