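"""Synthetic inputs: digital two-kidney phantom, simulated SPECT/planar
acquisitions, and patient cohorts with known ground-truth kinetics.

The phantom is two ellipsoidal kidneys inside an ellipsoidal soft-tissue
body; a chosen fraction of the injected activity sits uniformly in the
kidneys and the remainder uniformly in the body background (neighbouring
organs are at background level).  Attenuation is uniform soft tissue at
140 keV inside the body and zero outside.

The acquisition simulator is the forward counterpart of the quantification
chain: physical decay to the imaging time, projection through the system
model (attenuation + distance-dependent collimator response), conversion to
expected counts via the detector sensitivity and view duration, and Poisson
noise.  The scatter window is phenomenological — a broad-blurred, scaled
copy of the primary projections — sufficient to exercise the body-contour
attenuation-map procedure, not a physics model.

Cohorts follow a specified generating biokinetic model with lognormal
between-patient variability on F_S, an additive plateau offset for female
patients, multiplicative Gaussian measurement noise, and the three-arm
sampling-time scheme (early / clinical / delayed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .kinetics import BiokineticModel, KidneyUptakeRecord, load_model, model_fraction
from .planar import PlanarImage
from .projector import (
    AcquisitionGeometry,
    CollimatorResponse,
    ProjectionSet,
    SystemModel,
    decay_factor,
)
from .spect import SOFT_TISSUE_MU_140KEV, SensitivityFactor

__all__ = [
    "DigitalPhantom",
    "CohortSpec",
    "TimeScheme",
    "make_phantom",
    "sample_cohort",
    "simulate_acquisition",
    "simulate_planar_pair",
    "planar_rois_from_phantom",
    "body_thickness_at_kidneys_cm",
    "DEFAULT_SENSITIVITY",
]

#: Default detector sensitivity, a typical LEUHR value (CPM/MBq).
DEFAULT_SENSITIVITY = SensitivityFactor(cpm_per_mbq=5000.0)


@dataclass
class DigitalPhantom:
    """Voxelized activity (MBq/voxel) and attenuation (1/cm) volumes with
    kidney/body masks and injected-activity metadata."""

    activity_grid: np.ndarray
    mu_grid: np.ndarray
    voxel_size_cm: float
    left_kidney_mask: np.ndarray
    right_kidney_mask: np.ndarray
    body_mask: np.ndarray
    injected_activity_a0_mbq: float
    injection_time_h: float = 0.0

    def __post_init__(self):
        a, mu, body = self.activity_grid, self.mu_grid, self.body_mask
        lk, rk = self.left_kidney_mask, self.right_kidney_mask
        if np.any(a < 0):
            raise ValueError("activity must be non-negative")
        if np.any(a[~body] != 0):
            raise ValueError("activity outside the body mask must be zero")
        if (lk & rk).any():
            raise ValueError("kidney masks must be disjoint")
        if (lk & ~body).any() or (rk & ~body).any():
            raise ValueError("kidney masks must be subsets of the body mask")
        if np.any(mu[~body] != 0):
            raise ValueError("mu must be zero outside the body")
        inside = mu[body]
        if inside.size and not np.allclose(inside, inside.flat[0]):
            raise ValueError("mu must be uniform inside the body")

    @property
    def kidney_mask(self) -> np.ndarray:
        return self.left_kidney_mask | self.right_kidney_mask

    @property
    def kidney_activity_mbq(self) -> float:
        return float(self.activity_grid[self.kidney_mask].sum())

    def body_half_width_cm(self) -> float:
        """Largest in-plane distance of a body voxel from the volume centre."""
        nx, ny, _ = self.body_mask.shape
        xs = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_size_cm
        ys = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_size_cm
        r2 = np.broadcast_to(
            xs[:, None, None] ** 2 + ys[None, :, None] ** 2, self.body_mask.shape
        )
        return float(np.sqrt(r2[self.body_mask].max()))


def _ellipsoid(grid_shape, voxel, center_cm, semi_axes_cm):
    nx, ny, nz = grid_shape
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * voxel - c
        for n, c in zip(grid_shape, center_cm)
    ]
    X = coords[0][:, None, None] / semi_axes_cm[0]
    Y = coords[1][None, :, None] / semi_axes_cm[1]
    Z = coords[2][None, None, :] / semi_axes_cm[2]
    return X**2 + Y**2 + Z**2 <= 1.0


def make_phantom(
    body_axes_cm: tuple[float, float, float] = (12.0, 8.0, 12.0),
    kidney_axes_cm: tuple[float, float, float] = (1.5, 1.5, 3.0),
    kidney_separation_cm: float = 12.0,
    kidney_fraction_of_a0: float = 0.3,
    a0_mbq: float = 74.0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_cm: float = 0.4375,
    mu_soft: float = SOFT_TISSUE_MU_140KEV,
    kidney_center_y_cm: float = -2.0,
) -> DigitalPhantom:
    """Two ellipsoidal kidneys in an ellipsoidal body.

    Axes are semi-axes in cm; the kidney default is an adult 6x3x3 cm
    (semi-axes) organ scaled by a pediatric factor of one half, long axis
    axial.  Kidneys are centred at x = +/- separation/2, slightly posterior.
    ``kidney_fraction_of_a0`` of the injected activity is spread uniformly
    over the kidney voxels and the rest uniformly over the body background.
    """
    if not 0 <= kidney_fraction_of_a0 <= 1:
        raise ValueError("kidney_fraction_of_a0 must lie in [0, 1]")
    if a0_mbq < 0:
        raise ValueError("a0_mbq must be non-negative")
    body = _ellipsoid(grid_shape, voxel_size_cm, (0, 0, 0), body_axes_cm)
    half = kidney_separation_cm / 2.0
    left = _ellipsoid(
        grid_shape, voxel_size_cm, (-half, kidney_center_y_cm, 0.0), kidney_axes_cm
    )
    right = _ellipsoid(
        grid_shape, voxel_size_cm, (half, kidney_center_y_cm, 0.0), kidney_axes_cm
    )
    if (left & right).any():
        raise ValueError("kidney ellipsoids overlap; increase the separation")
    kidneys = left | right
    if (kidneys & ~body).any():
        raise ValueError(
            "kidney ellipsoids extend outside the body ellipsoid; shrink the "
            "kidneys, reduce the separation, or enlarge the body"
        )
    if not kidneys.any():
        raise ValueError("kidney ellipsoids are empty at this grid resolution")

    activity = np.zeros(grid_shape)
    activity[kidneys] = kidney_fraction_of_a0 * a0_mbq / kidneys.sum()
    background = body & ~kidneys
    activity[background] = (1.0 - kidney_fraction_of_a0) * a0_mbq / background.sum()
    mu = np.where(body, mu_soft, 0.0)
    return DigitalPhantom(
        activity_grid=activity,
        mu_grid=mu,
        voxel_size_cm=voxel_size_cm,
        left_kidney_mask=left,
        right_kidney_mask=right,
        body_mask=body,
        injected_activity_a0_mbq=a0_mbq,
    )


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------


def _broad_blur(projections: np.ndarray, sigma_cm: float, voxel: float) -> np.ndarray:
    sig = sigma_cm / voxel
    return np.stack([gaussian_filter(p, sig, mode="constant") for p in projections])


def simulate_acquisition(
    phantom: DigitalPhantom,
    geometry: AcquisitionGeometry,
    sensitivity: SensitivityFactor = DEFAULT_SENSITIVITY,
    time_post_injection_h: float = 3.0,
    noise: bool = True,
    seed: int | None = None,
    response: CollimatorResponse | None = CollimatorResponse(),
    half_life_h: float = 6.0,
    photopeak_scatter_fraction: float = 0.0,
    scatter_window_scale: float = 0.5,
    scatter_blur_cm: float = 3.0,
    attenuation: bool = True,
) -> ProjectionSet:
    """Simulate a SPECT acquisition of the decayed phantom.

    Photopeak expectation = primary projections x sensitivity x view
    duration, plus (optionally) a phenomenological scatter component equal
    to ``photopeak_scatter_fraction`` x a ``scatter_blur_cm``-blurred copy
    of the primary counts; the scatter-window image is the same blurred copy
    scaled by ``scatter_window_scale``.  ``noise=False`` returns the exact
    expectations; otherwise both windows are Poisson realisations from
    ``seed``.  The stored ``scatter_expectation`` is the matched photopeak
    scatter term used for compensation in reconstruction.
    """
    if time_post_injection_h < 0:
        raise ValueError("time_post_injection_h must be non-negative")
    radii = geometry.orbit_radii_cm
    half_width = phantom.body_half_width_cm()
    if np.any(radii < half_width):
        raise ValueError(
            f"orbit radius {radii.min():.1f} cm is inside the body half-width "
            f"{half_width:.1f} cm"
        )
    decayed = phantom.activity_grid * decay_factor(time_post_injection_h, half_life_h)
    sm = SystemModel(
        phantom.mu_grid if attenuation else None,
        geometry,
        response,
        phantom.voxel_size_cm,
        grid_shape=phantom.activity_grid.shape,
    )
    primary = sm.forward(decayed) * sensitivity.cps_per_mbq * geometry.seconds_per_view
    broad = _broad_blur(primary, scatter_blur_cm, phantom.voxel_size_cm)
    scatter_in_peak = photopeak_scatter_fraction * broad
    peak_expect = primary + scatter_in_peak
    scat_expect = scatter_window_scale * broad
    if noise:
        rng = np.random.default_rng(seed)
        peak = rng.poisson(peak_expect).astype(float)
        scat = rng.poisson(scat_expect).astype(float)
    else:
        peak, scat = peak_expect, scat_expect
    return ProjectionSet(
        counts={"photopeak": peak, "scatter": scat},
        geometry=geometry,
        voxel_size_cm=phantom.voxel_size_cm,
        time_post_injection_h=time_post_injection_h,
        scatter_expectation=scatter_in_peak,
    )


def simulate_planar_pair(
    phantom: DigitalPhantom,
    sensitivity: SensitivityFactor = DEFAULT_SENSITIVITY,
    time_post_injection_h: float = 3.0,
    duration_s: float = 300.0,
    noise: bool = True,
    seed: int | None = None,
    response: CollimatorResponse | None = CollimatorResponse(),
    orbit_radius_cm: float = 15.0,
    half_life_h: float = 6.0,
    photopeak_scatter_fraction: float = 0.0,
    scatter_window_scale: float = 0.5,
    scatter_blur_cm: float = 3.0,
) -> PlanarImage:
    """Anterior (0 deg) / posterior (180 deg) conjugate planar pair."""
    geom = AcquisitionGeometry(
        n_views=2,
        arc_deg=360.0,
        orbit_radius_cm=orbit_radius_cm,
        seconds_per_view=duration_s,
    )
    proj = simulate_acquisition(
        phantom,
        geom,
        sensitivity,
        time_post_injection_h,
        noise=noise,
        seed=seed,
        response=response,
        half_life_h=half_life_h,
        photopeak_scatter_fraction=photopeak_scatter_fraction,
        scatter_window_scale=scatter_window_scale,
        scatter_blur_cm=scatter_blur_cm,
    )
    return PlanarImage(
        anterior=proj.counts["photopeak"][0],
        posterior=proj.counts["photopeak"][1],
        scatter_anterior=proj.counts["scatter"][0],
        scatter_posterior=proj.counts["scatter"][1],
        time_post_injection_h=time_post_injection_h,
        duration_s=duration_s,
        pixel_size_cm=phantom.voxel_size_cm,
    )


def body_thickness_at_kidneys_cm(phantom: DigitalPhantom) -> float:
    """Mean anterior-posterior body thickness over the columns the kidneys
    project onto — the thickness the conjugate-view correction should use."""
    kid_proj = phantom.kidney_mask.any(axis=1)
    thickness = phantom.body_mask.sum(axis=1) * phantom.voxel_size_cm
    return float(thickness[kid_proj].mean())


def planar_rois_from_phantom(
    phantom: DigitalPhantom, dilate: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Anterior-view kidney and background ROIs from the phantom masks.

    The kidney ROI is the anterior projection (along y) of both kidney
    masks, dilated by ``dilate`` pixels; the background ROI is the body
    projection minus a further-dilated kidney region.
    """
    kid = phantom.kidney_mask.any(axis=1)
    body = phantom.body_mask.any(axis=1)
    kid_roi = binary_dilation(kid, iterations=dilate) if dilate else kid
    guard = binary_dilation(kid_roi, iterations=3 * max(dilate, 1))
    bg_roi = body & ~guard
    return kid_roi, bg_roi


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeScheme:
    """Sampling-time windows (hours) per study arm: every patient has a
    clinical SPECT time; prospective arms add one planar point."""

    early: tuple[float, float] = (0.25, 1.5)
    clinical: tuple[float, float] = (1.9, 3.75)
    delayed: tuple[float, float] = (4.0, 6.0)

    def __post_init__(self):
        for lo, hi in (self.early, self.clinical, self.delayed):
            if not (0 <= lo <= hi <= 6.0):
                raise ValueError("sampling windows must lie within 0-6 h")


def _default_truth() -> BiokineticModel:
    return load_model("current_study")


@dataclass
class CohortSpec:
    """Generating conditions for a synthetic cohort.

    Defaults mirror the study population: 77 patients (17 male / 60 female),
    54 retrospective (clinical SPECT only), 13 prospective-early and 10
    prospective-delayed (clinical SPECT + one planar point); ~25%
    between-patient variability on F_S; an additive plateau offset of 0.064
    for female patients; 10% multiplicative measurement noise.
    """

    n_patients: int = 77
    sex_counts: tuple[int, int] = (17, 60)  # (male, female)
    group_counts: tuple[int, int, int] = (54, 13, 10)
    truth_model: BiokineticModel = field(default_factory=_default_truth)
    sex_uptake_offset: float = 0.064
    between_patient_cv: float = 0.25
    measurement_cv: float = 0.10
    time_scheme: TimeScheme = field(default_factory=TimeScheme)
    age_median_y: float = 4.0
    age_log_sd: float = 0.7
    weight_noise_cv: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if sum(self.sex_counts) != self.n_patients:
            raise ValueError("sex_counts must sum to n_patients")
        if sum(self.group_counts) != self.n_patients:
            raise ValueError("group_counts must sum to n_patients")
        for cv in (self.between_patient_cv, self.measurement_cv, self.weight_noise_cv):
            if cv < 0:
                raise ValueError("CVs must be non-negative")


def _lognormal_unit_mean(rng, cv, size):
    """Lognormal multipliers with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def sample_cohort(spec: CohortSpec) -> list[KidneyUptakeRecord]:
    """Draw a cohort; every random quantity flows from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    sexes = np.array(["male"] * spec.sex_counts[0] + ["female"] * spec.sex_counts[1])
    rng.shuffle(sexes)
    groups = np.array(
        ["retrospective"] * spec.group_counts[0]
        + ["prospective_early"] * spec.group_counts[1]
        + ["prospective_delayed"] * spec.group_counts[2]
    )
    rng.shuffle(groups)
    ages = np.clip(
        rng.lognormal(mean=math.log(spec.age_median_y), sigma=spec.age_log_sd, size=n),
        1.0 / 3.0,
        16.0,
    )
    # coarse pediatric growth curve (~2 kg per year + 8 kg) with lognormal spread
    weights = (2.0 * ages + 8.0) * _lognormal_unit_mean(rng, spec.weight_noise_cv, n)
    fs_mult = _lognormal_unit_mean(rng, spec.between_patient_cv, n)

    truth = spec.truth_model
    (a1, T1), (a2, T2) = truth.components

    records: list[KidneyUptakeRecord] = []
    for i in range(n):
        fs_i = truth.F_S * fs_mult[i]
        a2_i = a2 + (spec.sex_uptake_offset / fs_i if sexes[i] == "female" else 0.0)
        patient_model = BiokineticModel(F_S=fs_i, components=((a1, T1), (a2_i, T2)))
        times = [("SPECT", rng.uniform(*spec.time_scheme.clinical))]
        if groups[i] == "prospective_early":
            times.append(("planar", rng.uniform(*spec.time_scheme.early)))
        elif groups[i] == "prospective_delayed":
            times.append(("planar", rng.uniform(*spec.time_scheme.delayed)))
        for modality, t in times:
            true_frac = float(model_fraction(patient_model, t))
            if spec.measurement_cv > 0:
                meas = true_frac * (1.0 + rng.normal(0.0, spec.measurement_cv))
            else:
                meas = true_frac
            meas = min(max(meas, 0.0), 1.0)
            records.append(
                KidneyUptakeRecord(
                    patient_id=f"P{i:03d}",
                    age_y=float(ages[i]),
                    weight_kg=float(weights[i]),
                    sex=str(sexes[i]),
                    group=str(groups[i]),
                    time_h=float(t),
                    fraction=meas,
                    modality=modality,
                    fraction_true=true_frac,
                )
            )
    return records
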