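"""Projectional X-ray simulator with controllable physical imaging parameters (PIPs).

The generative model is a discretized Beer–Lambert projection: for a tissue
phantom with per-pixel column thickness ``r(i, j)`` and a two-tissue
(glandular/adipose) composition, the detector intensity is

    G(i, j) = sum_k  w_k * E0 * cos^2(theta) * exp(-mu_mix(E_k, i, j) * r(i, j))  [+ noise]

where ``E_k`` are energy-bin centers with discrete spectral weights ``w_k``
(summing to 1), ``E0`` is the entrance intensity derived from the exposure
PIP, ``theta`` the positioner angle, and ``mu_mix`` the glandular/adipose
mixture attenuation.  Twelve machine-logged acquisition parameters (tube
current, exposure, doses, angle, body thickness, ...) are carried per image;
only a documented subset reaches the pixels, the rest vary per synthetic
"hospital" so that metadata-space distance is not trivially identical to
image-statistic shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PIP_FIELDS",
    "IMAGE_RELEVANT_FIELDS",
    "Spectrum",
    "Phantom",
    "PIPVector",
    "AttenuationModel",
    "NoiseModel",
    "RawImage",
    "HospitalProfile",
    "GenerationConfig",
    "Dataset",
    "make_spectrum",
    "make_phantom",
    "project",
    "air_intensity",
    "to_display",
    "sample_pips",
    "generate_dataset",
    "default_hospitals",
    "null_shift_hospitals",
]

#: Canonical column order of the 12 per-image physical imaging parameters.
PIP_FIELDS = (
    "tube_current_kev",
    "exposure_uas",
    "relative_exposure",
    "detector_temp_c",
    "exposure_time_ms",
    "organ_dose_mgy",
    "entrance_dose_mgy",
    "pixel_padding_limit",
    "positioner_angle_deg",
    "body_thickness_mm",
    "compression_force_n",
    "focal_spot_mm",
)

#: PIP fields that enter the forward model (pixels); the remaining four
#: (detector temperature, padding limit, compression force, focal spot) vary
#: per hospital but never touch the image.
IMAGE_RELEVANT_FIELDS = (
    "tube_current_kev",
    "exposure_uas",
    "relative_exposure",
    "exposure_time_ms",
    "organ_dose_mgy",
    "entrance_dose_mgy",
    "positioner_angle_deg",
    "body_thickness_mm",
)

#: Fields allowed to be negative when sampling hospital profiles.
_SIGNED_FIELDS = frozenset({"positioner_angle_deg", "detector_temp_c"})

#: Strictly positive physical quantities get a small floor when sampling, so
#: a rare tail draw cannot produce a degenerate (zero-intensity) acquisition.
_POSITIVE_FLOORS = {
    "tube_current_kev": 10.0,
    "exposure_uas": 1000.0,
    "exposure_time_ms": 50.0,
    "body_thickness_mm": 10.0,
    "focal_spot_mm": 0.05,
}

#: Entrance intensity per microampere-second of exposure (calibration constant).
E0_PER_UAS = 1.0e-3

#: Reference compressed-breast thickness; phantom thickness maps peak at this
#: value and are rescaled by the per-image ``body_thickness_mm`` PIP.
REF_THICKNESS_MM = 50.0

#: Reference exposure time for the additive-noise scaling (longer integration
#: averages more photons, so the noise standard deviation shrinks as 1/sqrt(t)).
REF_EXPOSURE_TIME_MS = 600.0


class InvalidParameterError(ValueError):
    """A simulator argument violates its documented precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """Discrete incident X-ray spectrum: bin centers (keV) and weights (sum 1)."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)
        if e.ndim != 1 or w.shape != e.shape:
            raise InvalidParameterError("energies and weights must be equal-length 1-D")
        if np.any(np.diff(e) <= 0):
            raise InvalidParameterError("energies must be strictly increasing")
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise InvalidParameterError("weights must be non-negative and sum to 1")

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])


@dataclass(frozen=True)
class Phantom:
    """Synthetic compressed-breast description on a pixel grid.

    ``thickness_map`` is the tissue column length in mm (0 outside the
    tissue), ``glandular_fraction`` the per-pixel dense-tissue fraction in
    [0, 1] (0 outside), ``latent_class`` the tissue latent ("young" = dense,
    "old" = fatty) that serves as the label proxy.
    """

    thickness_map: np.ndarray
    glandular_fraction: np.ndarray
    tissue_mask: np.ndarray
    latent_class: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness_map.shape


@dataclass(frozen=True)
class PIPVector:
    """The 12 machine-logged physical imaging parameters for one image."""

    tube_current_kev: float
    exposure_uas: float
    relative_exposure: float
    detector_temp_c: float
    exposure_time_ms: float
    organ_dose_mgy: float
    entrance_dose_mgy: float
    pixel_padding_limit: float
    positioner_angle_deg: float
    body_thickness_mm: float
    compression_force_n: float
    focal_spot_mm: float

    def __post_init__(self):
        if not -90.0 < self.positioner_angle_deg < 90.0:
            raise InvalidParameterError("positioner angle must lie in (-90, 90) degrees")
        for name in ("exposure_uas", "organ_dose_mgy", "entrance_dose_mgy",
                     "body_thickness_mm", "compression_force_n"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PIP_FIELDS], dtype=float)

    @classmethod
    def from_mapping(cls, row) -> "PIPVector":
        return cls(**{f: float(row[f]) for f in PIP_FIELDS})


@dataclass(frozen=True)
class AttenuationModel:
    """Two-tissue attenuation curves mu(E) in 1/mm, E in keV.

    The default is a power-law decay ``mu(E) = a * E**(-b)`` with a larger
    coefficient for glandular than for adipose tissue; the constants are
    package conventions chosen for plausible soft-tissue contrast, not
    dosimetric claims.
    """

    mu_glandular: Callable[[np.ndarray], np.ndarray]
    mu_adipose: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def power_law(cls, a_glandular: float = 1.8, a_adipose: float = 0.7,
                  exponent: float = 1.5) -> "AttenuationModel":
        if a_glandular <= 0 or a_adipose <= 0 or exponent <= 0:
            raise InvalidParameterError("power-law attenuation constants must be positive")
        return cls(
            mu_glandular=lambda e: a_glandular * np.asarray(e, float) ** -exponent,
            mu_adipose=lambda e: a_adipose * np.asarray(e, float) ** -exponent,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: additive Gaussian (scale) plus optional Poisson.

    ``gaussian_sd`` is the additive standard deviation at the reference
    exposure time; the effective sd scales as sqrt(t_ref / t) with the
    per-image exposure time.  ``poisson_scale`` > 0 enables photon-count
    noise at that many counts per intensity unit; 0 disables it.
    """

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0

    def __post_init__(self):
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise InvalidParameterError("noise scales must be non-negative")

    @property
    def enabled(self) -> bool:
        return self.gaussian_sd > 0 or self.poisson_scale > 0


@dataclass(frozen=True)
class RawImage:
    """Simulator detector output G(i, j) (non-negative when noise is off)."""

    pixels: np.ndarray

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class HospitalProfile:
    """Per-domain PIP distribution: independent normals plus derived links.

    ``derived_links`` is a sequence of ``(source, target, coef, noise_sd)``
    tuples applied after the independent draws: ``target = coef * source +
    N(0, noise_sd)``.  Links mirror the redundancy of real acquisition
    metadata (dose fields computed from exposure by the machine).
    """

    name: str
    pip_means: dict
    pip_sds: dict
    derived_links: tuple = ()

    def __post_init__(self):
        missing = [f for f in PIP_FIELDS if f not in self.pip_means or f not in self.pip_sds]
        if missing:
            raise InvalidParameterError(f"profile {self.name!r} missing fields: {missing}")
        if any(self.pip_sds[f] < 0 for f in PIP_FIELDS):
            raise InvalidParameterError("pip_sds must be non-negative")
        targets = [t for (_, t, _, _) in self.derived_links]
        sources = {s for (s, _, _, _) in self.derived_links}
        if len(set(targets)) != len(targets) or sources & set(targets):
            raise InvalidParameterError("derived_links must be acyclic with unique targets")


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def make_spectrum(peak_energy: float, n_bins: int = 16) -> Spectrum:
    """Triangular (Kramers-like) bremsstrahlung approximation.

    Bin centers are ``E_k = peak * (k + 1/2) / n`` for ``k = 0..n-1`` and the
    weight of bin k is proportional to ``peak - E_k`` (linearly decreasing to
    zero at the peak), normalized to sum to one.  ``n_bins=1`` degenerates to
    a monoenergetic beam at ``peak_energy``.
    """
    if peak_energy <= 0:
        raise InvalidParameterError("peak_energy must be positive")
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    if n_bins == 1:
        return Spectrum(np.array([float(peak_energy)]), np.array([1.0]))
    k = np.arange(n_bins)
    energies = peak_energy * (k + 0.5) / n_bins
    weights = peak_energy - energies
    return Spectrum(energies, weights / weights.sum())


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


def make_phantom(latent_class: str, grid: tuple[int, int], seed: int, *,
                 density_margin: float = 0.15, base_fraction_old: float = 0.35,
                 texture_rel_sd: float = 0.40) -> Phantom:
    """Generate a half-elliptical compressed-breast phantom on ``grid``.

    The tissue is a single connected half-ellipse attached to the left image
    edge; thickness is a flat plateau rolling off at the edge; glandular
    fraction is seeded low-pass-filtered noise, multiplicative around a
    class-dependent base level (dense "young" = fatty "old" + margin).  The
    texture correlation length is also class-dependent — dense breasts show
    coarse confluent fibroglandular patches, fatty breasts fine scattered
    strands — so the label remains detectable after contrast equalization,
    which removes per-image global brightness.  At a matched seed the two
    classes share geometry and noise and the mean glandular fraction
    separates by roughly ``density_margin``.
    """
    if latent_class not in ("young", "old"):
        raise InvalidParameterError("latent_class must be 'young' or 'old'")
    h, w = grid
    if h < 16 or w < 16:
        raise InvalidParameterError("grid must be at least 16x16")
    rng = np.random.default_rng(seed)

    # geometry: half-ellipse centred on the left edge, seeded axis jitter
    cy = h / 2.0 + rng.uniform(-0.04, 0.04) * h
    a = h * rng.uniform(0.36, 0.45)
    b = w * rng.uniform(0.55, 0.70)
    yy, xx = np.mgrid[0:h, 0:w]
    ell = ((yy + 0.5 - cy) / a) ** 2 + ((xx + 0.5) / b) ** 2
    mask = ell <= 1.0

    # compressed breast: flat plateau in the interior, rolling off at the edge
    thickness = REF_THICKNESS_MM * np.clip(1.0 - ell, 0.0, 1.0) ** 0.25
    thickness[~mask] = 0.0

    base = base_fraction_old + (density_margin if latent_class == "young" else 0.0)
    sigma = max(h, w) / (10.0 if latent_class == "young" else 28.0)
    texture = rng.normal(size=(h, w))
    texture = ndimage.gaussian_filter(texture, sigma=sigma)
    sd = texture[mask].std()
    if sd > 0:
        texture = texture / sd * texture_rel_sd
    frac = np.clip(base * (1.0 + texture), 0.0, 1.0)
    frac[~mask] = 0.0
    return Phantom(thickness, frac, mask, latent_class)


# ---------------------------------------------------------------------------
# forward projection
# ---------------------------------------------------------------------------


def _e0(pips: PIPVector) -> float:
    return E0_PER_UAS * pips.exposure_uas


def project(phantom: Phantom, pips: PIPVector, spectrum: Spectrum,
            atten: AttenuationModel, noise: NoiseModel = NoiseModel(),
            seed: int | None = None, *, inverse_square: bool = False,
            source_distance_m: float = 0.65) -> RawImage:
    """Project a phantom to a detector image under the discretized forward model.

    The entrance intensity is ``E0 = E0_PER_UAS * exposure_uas`` and the beam
    obliquity factor ``cos^2(positioner_angle)``.  The path integral of the
    attenuation collapses to ``mu_mix(E) * r`` with a homogeneous column per
    pixel; the per-image column length is the phantom thickness rescaled by
    ``body_thickness_mm / REF_THICKNESS_MM``.  ``inverse_square`` optionally
    multiplies by ``1 / source_distance_m**2`` (off by default, so the
    projection is exactly the obliquity-attenuation product).
    """
    r = phantom.thickness_map * (pips.body_thickness_mm / REF_THICKNESS_MM)
    f = phantom.glandular_fraction
    e0 = _e0(pips)
    cos2 = math.cos(math.radians(pips.positioner_angle_deg)) ** 2
    scale = e0 * cos2
    if inverse_square:
        if source_distance_m <= 0:
            raise InvalidParameterError("source_distance_m must be positive")
        scale /= source_distance_m ** 2

    g = np.zeros(phantom.shape, dtype=float)
    mu_g = atten.mu_glandular(spectrum.energies)
    mu_a = atten.mu_adipose(spectrum.energies)
    for wk, mg, ma in zip(spectrum.weights, mu_g, mu_a):
        mu_mix = f * mg + (1.0 - f) * ma
        g += wk * np.exp(-mu_mix * r)
    g *= scale

    if noise.enabled:
        rng = np.random.default_rng(seed)
        if noise.poisson_scale > 0:
            g = rng.poisson(np.clip(g, 0, None) * noise.poisson_scale) / noise.poisson_scale
        if noise.gaussian_sd > 0:
            t = max(pips.exposure_time_ms, 1.0)
            sd = noise.gaussian_sd * math.sqrt(REF_EXPOSURE_TIME_MS / t)
            g = g + rng.normal(0.0, sd, size=g.shape)
    return RawImage(g)


def air_intensity(pips: PIPVector, spectrum: Spectrum, *,
                  inverse_square: bool = False, source_distance_m: float = 0.65) -> float:
    """Noiseless detector reading through air (r = 0) — the flat-field level."""
    scale = _e0(pips) * math.cos(math.radians(pips.positioner_angle_deg)) ** 2
    if inverse_square:
        scale /= source_distance_m ** 2
    return scale * float(spectrum.weights.sum())


def to_display(raw: RawImage, air_level: float) -> np.ndarray:
    """Flat-field and invert a raw projection to an 8-bit display image.

    Real detectors divide out the unattenuated (air) level and display
    attenuation inverted, so tissue is bright and background dark:
    ``x = 255 * clip(1 - G / G_air, 0, 1)``.  The entrance-intensity scale
    cancels here; exposure still reaches the displayed image through the
    signal-to-noise ratio because the additive noise is not rescaled.
    """
    if air_level <= 0:
        raise InvalidParameterError("air_level must be positive")
    x = 1.0 - raw.pixels / air_level
    return np.round(255.0 * np.clip(x, 0.0, 1.0)).astype(np.uint8)


# ---------------------------------------------------------------------------
# PIP sampling and dataset generation
# ---------------------------------------------------------------------------


def sample_pips(profile: HospitalProfile, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` PIP rows from a hospital profile (independent normals, then
    derived links), clipping sign-constrained fields at zero."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    link_targets = {t for (_, t, _, _) in profile.derived_links}
    cols = {}
    for fname in PIP_FIELDS:
        if fname in link_targets:
            cols[fname] = np.zeros(n)
            continue
        cols[fname] = rng.normal(profile.pip_means[fname], profile.pip_sds[fname], size=n)
    for src, tgt, coef, noise_sd in profile.derived_links:
        cols[tgt] = coef * cols[src] + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    df = pd.DataFrame(cols, columns=list(PIP_FIELDS))
    for fname in PIP_FIELDS:
        if fname not in _SIGNED_FIELDS:
            df[fname] = df[fname].clip(lower=_POSITIVE_FLOORS.get(fname, 0.0))
    df["positioner_angle_deg"] = df["positioner_angle_deg"].clip(-89.9, 89.9)
    df["domain"] = profile.name
    return df


@dataclass(frozen=True)
class GenerationConfig:
    """Study conditions for synthetic dataset generation.

    ``n_per_class`` images are generated per hospital per latent class; labels
    are assigned by construction independently of the PIP draws, with exact
    class balance inside every hospital.
    """

    hospitals: tuple
    n_per_class: int
    grid: tuple[int, int] = (64, 64)
    seed: int = 0
    spectrum_bins: int = 16
    density_margin: float = 0.15
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(gaussian_sd=1.5))
    atten: AttenuationModel = field(default_factory=AttenuationModel.power_law)
    inverse_square: bool = False

    def __post_init__(self):
        if self.n_per_class < 1 or len(self.hospitals) < 1:
            raise InvalidParameterError("need >= 1 hospital and >= 1 image per class")


@dataclass
class Dataset:
    """Generated study data: raw projections, labels, PIP table, provenance."""

    images: np.ndarray          # (N, h, w) raw detector intensities
    labels: np.ndarray          # (N,) int, 1 = young/dense, 0 = old/fatty
    pips: pd.DataFrame          # 12 PIP columns + domain, label, image_id
    air_levels: np.ndarray      # (N,) flat-field level per image
    config: GenerationConfig
    seed: int

    def display_images(self) -> np.ndarray:
        """8-bit flat-fielded display stack (N, h, w) uint8."""
        out = np.empty(self.images.shape, dtype=np.uint8)
        for i in range(len(self.images)):
            out[i] = to_display(RawImage(self.images[i]), float(self.air_levels[i]))
        return out


LABEL_OF_CLASS = {"young": 1, "old": 0}
CLASS_OF_LABEL = {1: "young", 0: "old"}


def generate_dataset(config: GenerationConfig) -> Dataset:
    """Generate images, labels and the PIP table for all configured hospitals.

    Each image gets its own phantom (class-dependent) and PIP row
    (class-independent); the incident spectrum peaks at the image's
    ``tube_current_kev``, linking that PIP to beam quality.  All randomness
    descends from ``config.seed`` through a spawned seed tree, so repeated
    calls are byte-identical.
    """
    root = np.random.SeedSequence(config.seed)
    h, w = config.grid
    images, labels, air, frames = [], [], [], []
    for profile, ss_h in zip(config.hospitals, root.spawn(len(config.hospitals))):
        ss_pips, ss_imgs = ss_h.spawn(2)
        n_rows = 2 * config.n_per_class
        table = sample_pips(profile, n_rows, int(ss_pips.generate_state(1)[0] % (2 ** 31)))
        row_labels = np.repeat([1, 0], config.n_per_class)
        child_seeds = ss_imgs.generate_state(2 * n_rows) % (2 ** 31)
        for i in range(n_rows):
            y = int(row_labels[i])
            pips = PIPVector.from_mapping(table.iloc[i])
            phantom = make_phantom(CLASS_OF_LABEL[y], config.grid,
                                   int(child_seeds[2 * i]),
                                   density_margin=config.density_margin)
            spectrum = make_spectrum(max(pips.tube_current_kev, 1.0), config.spectrum_bins)
            raw = project(phantom, pips, spectrum, config.atten, config.noise,
                          int(child_seeds[2 * i + 1]),
                          inverse_square=config.inverse_square)
            images.append(raw.pixels.astype(np.float32))
            labels.append(y)
            air.append(air_intensity(pips, spectrum,
                                     inverse_square=config.inverse_square))
        table = table.copy()
        table["label"] = row_labels
        frames.append(table)
    pips = pd.concat(frames, ignore_index=True)
    pips.insert(0, "image_id", [f"img{k:06d}" for k in range(len(pips))])
    return Dataset(np.stack(images), np.asarray(labels), pips,
                   np.asarray(air), config, config.seed)


# ---------------------------------------------------------------------------
# reference hospital profiles (the demo study conditions)
# ---------------------------------------------------------------------------

#: Dose/exposure redundancy links shared by all synthetic hospitals:
#: relative exposure, organ dose and entrance dose are machine-derived from
#: the exposure reading, with small metering noise.
_DOSE_LINKS = (
    ("exposure_uas", "relative_exposure", 0.09, 60.0),
    ("exposure_uas", "organ_dose_mgy", 2.0e-7, 5.0e-4),
    ("exposure_uas", "entrance_dose_mgy", 1.0e-4, 0.25),
)


def default_hospitals() -> tuple[HospitalProfile, HospitalProfile]:
    """Two synthetic hospitals whose PIP differences alter image statistics.

    Hospital A images at higher exposure (better SNR), thinner compression and
    harder beam than hospital B; the non-image fields (detector temperature,
    padding limit, compression force, focal spot) also separate the domains.
    """
    a = HospitalProfile(
        name="A",
        pip_means=dict(
            tube_current_kev=30.0, exposure_uas=60000.0, relative_exposure=0.0,
            detector_temp_c=25.0, exposure_time_ms=600.0, organ_dose_mgy=0.0,
            entrance_dose_mgy=0.0, pixel_padding_limit=350.0,
            positioner_angle_deg=0.0, body_thickness_mm=48.0,
            compression_force_n=80.0, focal_spot_mm=0.3),
        pip_sds=dict(
            tube_current_kev=1.5, exposure_uas=12000.0, relative_exposure=0.0,
            detector_temp_c=1.5, exposure_time_ms=60.0, organ_dose_mgy=0.0,
            entrance_dose_mgy=0.0, pixel_padding_limit=20.0,
            positioner_angle_deg=8.0, body_thickness_mm=5.0,
            compression_force_n=15.0, focal_spot_mm=0.02),
        derived_links=_DOSE_LINKS,
    )
    b = replace(
        a, name="B",
        pip_means=dict(
            a.pip_means, tube_current_kev=26.0, exposure_uas=30000.0,
            detector_temp_c=29.0, exposure_time_ms=400.0,
            pixel_padding_limit=250.0, positioner_angle_deg=15.0,
            body_thickness_mm=62.0, compression_force_n=110.0, focal_spot_mm=0.6),
        pip_sds=dict(a.pip_sds, exposure_uas=8000.0, exposure_time_ms=50.0),
    )
    return (a, b)


def null_shift_hospitals() -> tuple[HospitalProfile, HospitalProfile]:
    """Two hospitals differing only in PIPs that never reach the pixels.

    Detector temperature, padding limit, compression force and focal spot are
    shifted between the domains while every image-relevant field shares one
    distribution — the negative control for distance-versus-gap analyses.
    """
    base, _ = default_hospitals()
    tight = dict(
        base.pip_sds, tube_current_kev=0.5, exposure_uas=1500.0,
        exposure_time_ms=10.0, positioner_angle_deg=2.0, body_thickness_mm=1.5,
        detector_temp_c=3.0, pixel_padding_limit=60.0, compression_force_n=30.0,
        focal_spot_mm=0.1,
    )
    links = tuple((s, t, c, sd * 0.2) for (s, t, c, sd) in base.derived_links)
    a = replace(base, name="N1", pip_sds=tight, derived_links=links)
    b = replace(
        a, name="N2",
        pip_means=dict(a.pip_means, detector_temp_c=33.0, pixel_padding_limit=200.0,
                       compression_force_n=140.0, focal_spot_mm=0.6),
    )
    return (a, b)
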