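"""Scanner description: source, masks, detector, geometry and acquisition.

An edge-illumination (EI) system places an absorbing "sample mask" before
the object, splitting the beam into independent beamlets, and a matched
"detector mask" in front of the pixel columns.  The geometry is described
by the source-to-detector length and the object-to-detector distance
z_od; the cone magnification M = sdd / (sdd - z_od) maps sample-plane
lengths onto the detector.  A *skipped* mask layout illuminates only
every ``skip_factor``-th pixel column, which suppresses inter-column
cross-talk (e.g. scintillator light spread) at the cost of flux.

All transverse lengths are in µm; the two long distances are entered in
cm.  The canonical transverse frame is the sample-mask plane; detector
plane quantities map by ×M.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .units import CM_TO_UM

#: tolerance (µm, sample plane) on the mask pitch matching condition
PITCH_ALIGNMENT_TOL_UM = 1.0 + 1e-9


class ConfigurationError(ValueError):
    """Raised when a scanner description violates a design invariant."""


@dataclass(frozen=True)
class SourceSpec:
    """Focal spot model: an incoherent Gaussian spot of given FWHM."""

    focal_spot_fwhm: float = 70.0  # µm
    profile_shape: str = "gaussian"
    effective_energy: float = 19.0  # keV

    def __post_init__(self):
        if self.focal_spot_fwhm < 0:
            raise ConfigurationError("focal_spot_fwhm must be >= 0 (0 = point source)")
        if self.effective_energy <= 0:
            raise ConfigurationError("effective_energy must be positive")
        if self.profile_shape != "gaussian":
            raise ConfigurationError(f"unsupported source profile {self.profile_shape!r}")


@dataclass(frozen=True)
class MaskSpec:
    """Absorption grating. ``pitch`` is the physical aperture-to-aperture period.

    For a skipped layout the printed pitch already spans the skipped
    columns; ``skip_factor`` records how many detector columns each
    aperture period covers (1 = every column illuminated).
    """

    pitch: float  # µm
    aperture: float  # µm
    skip_factor: int = 1
    septa_transmission: float = 0.0
    plane: str = "sample"

    def __post_init__(self):
        if not 0 < self.aperture < self.pitch:
            raise ConfigurationError(
                f"aperture must satisfy 0 < aperture < pitch, got "
                f"aperture={self.aperture}, pitch={self.pitch}"
            )
        if self.skip_factor < 1:
            raise ConfigurationError("skip_factor must be >= 1")
        if not 0 <= self.septa_transmission < 1:
            raise ConfigurationError("septa_transmission must be in [0, 1)")
        if self.plane not in ("sample", "detector"):
            raise ConfigurationError(f"unknown mask plane {self.plane!r}")

    @property
    def duty_cycle(self) -> float:
        return self.aperture / self.pitch


@dataclass(frozen=True)
class DetectorSpec:
    """Pixel grid and column cross-talk model.

    ``crosstalk_fwhm`` is the FWHM (µm) of the bare-detector line spread
    function *as reported at the sample plane* by a slanted-edge scan with
    the masks removed; the physical detector-plane kernel is this value
    times the system magnification.  0 disables cross-talk.
    """

    pixel_pitch: float = 50.0  # µm
    crosstalk_fwhm: float = 0.0  # µm, sample-referred bare LSF FWHM
    crosstalk_shape: str = "gaussian_lorentzian"
    crosstalk_tail_fraction: float = 0.2  # Lorentzian weight in the mixture
    dark_level: float = 0.0  # counts
    i0_rate: float = 1.0e4  # open-beam counts per second per used pixel

    def __post_init__(self):
        if self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be positive")
        if self.crosstalk_fwhm < 0:
            raise ConfigurationError("crosstalk_fwhm must be >= 0")
        if self.crosstalk_shape not in ("gaussian", "gaussian_lorentzian"):
            raise ConfigurationError(f"unknown crosstalk_shape {self.crosstalk_shape!r}")
        if not 0 <= self.crosstalk_tail_fraction < 1:
            raise ConfigurationError("crosstalk_tail_fraction must be in [0, 1)")
        if self.dark_level < 0 or self.i0_rate <= 0:
            raise ConfigurationError("dark_level >= 0 and i0_rate > 0 required")


@dataclass(frozen=True)
class Geometry:
    source_to_detector: float  # cm
    object_to_detector: float  # cm (z_od)

    def __post_init__(self):
        if not 0 < self.object_to_detector < self.source_to_detector:
            raise ConfigurationError(
                f"need 0 < z_od < source_to_detector, got z_od="
                f"{self.object_to_detector} cm, sdd={self.source_to_detector} cm"
            )

    @property
    def magnification(self) -> float:
        return magnification(self)

    @property
    def z_od_um(self) -> float:
        return self.object_to_detector * CM_TO_UM

    @property
    def sdd_um(self) -> float:
        return self.source_to_detector * CM_TO_UM


@dataclass(frozen=True)
class Acquisition:
    """Acquisition protocol: dithering, working point, exposure, rotation."""

    n_dither_steps: int = 1
    dither_step: float = 0.0  # µm, sample-plane sample translation per step
    mask_offset_si: float = -9.0  # µm, signed working-point offset from the IC apex
    exposure_time: float = 1.0  # s
    n_angles: int = 1
    angular_range: float = 360.0  # deg
    jitter_enabled: bool = False

    def __post_init__(self):
        if self.n_dither_steps < 1:
            raise ConfigurationError("n_dither_steps must be >= 1")
        if self.n_dither_steps > 1 and self.dither_step <= 0:
            raise ConfigurationError("dither_step must be > 0 when dithering")
        if self.exposure_time <= 0 or self.n_angles < 1:
            raise ConfigurationError("exposure_time > 0 and n_angles >= 1 required")


@dataclass(frozen=True)
class ScannerConfig:
    source: SourceSpec
    sample_mask: MaskSpec
    detector_mask: MaskSpec
    detector: DetectorSpec
    geometry: Geometry
    acquisition: Acquisition = field(default_factory=Acquisition)

    def __post_init__(self):
        M = self.geometry.magnification
        projected = self.detector_mask.pitch / M
        if abs(projected - self.sample_mask.pitch) > PITCH_ALIGNMENT_TOL_UM:
            raise ConfigurationError(
                "mask pitches inconsistent with magnification: detector pitch "
                f"{self.detector_mask.pitch} µm projects to {projected:.3f} µm at the "
                f"sample plane (M={M:.4f}) but the sample mask pitch is "
                f"{self.sample_mask.pitch} µm (tolerance {PITCH_ALIGNMENT_TOL_UM:.1f} µm)"
            )
        if self.sample_mask.skip_factor != self.detector_mask.skip_factor:
            raise ConfigurationError("sample and detector masks must share skip_factor")
        if self.acquisition.n_dither_steps > 1:
            coverage = self.acquisition.n_dither_steps * self.acquisition.dither_step
            period = self.beamlet_period
            if abs(coverage - period) > 0.05 * period:
                raise ConfigurationError(
                    f"dither coverage {coverage:.2f} µm deviates more than 5% from the "
                    f"sample-plane beamlet period {period:.2f} µm"
                )

    # -- derived quantities -------------------------------------------------
    @property
    def magnification(self) -> float:
        return self.geometry.magnification

    @property
    def beamlet_period(self) -> float:
        """Sample-plane beamlet spacing (= physical sample-mask pitch), µm."""
        return self.sample_mask.pitch

    @property
    def skip_factor(self) -> int:
        return self.sample_mask.skip_factor

    @property
    def row_pitch_sample(self) -> float:
        """Detector row pitch referred to the sample plane, µm."""
        return self.detector.pixel_pitch / self.magnification

    @property
    def working_shift(self) -> float:
        """Absolute mask displacement of the working point (apex assumed at 0
        for a symmetric illumination curve); see illumination.compute_ic."""
        return self.acquisition.mask_offset_si

    def config_hash(self) -> str:
        payload = json.dumps(config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def magnification(geometry: Geometry) -> float:
    """Cone magnification M = sdd / (sdd - z_od) of the sample plane."""
    sdd = geometry.source_to_detector
    z_od = geometry.object_to_detector
    if z_od >= sdd:
        raise ConfigurationError("z_od must be smaller than the system length")
    return sdd / (sdd - z_od)


def build_config(raw: dict) -> ScannerConfig:
    """Build and validate a :class:`ScannerConfig` from nested plain dicts.

    Raises :class:`ConfigurationError` when any invariant is violated,
    naming the offending values.
    """
    try:
        return ScannerConfig(
            source=SourceSpec(**raw.get("source", {})),
            sample_mask=MaskSpec(**{"plane": "sample", **raw["sample_mask"]}),
            detector_mask=MaskSpec(**{"plane": "detector", **raw["detector_mask"]}),
            detector=DetectorSpec(**raw.get("detector", {})),
            geometry=Geometry(**raw["geometry"]),
            acquisition=Acquisition(**raw.get("acquisition", {})),
        )
    except KeyError as exc:  # missing mandatory section
        raise ConfigurationError(f"missing configuration section: {exc}") from exc
    except TypeError as exc:  # unknown/missing key inside a section
        raise ConfigurationError(str(exc)) from exc


def mask_transmission_profile(mask: MaskSpec, sampling_step: float):
    """Tabulate one period of the binary mask transmission profile.

    Returns ``(x, t)`` with ``x`` in [0, pitch) and ``t`` = 1 inside the
    aperture (centred at pitch/2), ``septa_transmission`` elsewhere.
    """
    if sampling_step > mask.aperture / 4:
        raise ValueError(
            f"sampling_step {sampling_step} µm too coarse; need <= aperture/4 = "
            f"{mask.aperture / 4} µm"
        )
    n = int(round(mask.pitch / sampling_step))
    x = (np.arange(n) + 0.5) * (mask.pitch / n)
    t = np.full(n, mask.septa_transmission, dtype=float)
    half = mask.aperture / 2
    centre = mask.pitch / 2
    inside = np.abs(x - centre) < half
    t[inside] = 1.0
    # fractional end bins keep the integral right to quadrature tolerance
    return x, t


def dither_sampling(config: ScannerConfig, nominal_magnification: float | None = None):
    """Sampling arithmetic of a dithered acquisition.

    Returns ``(detector_pitch, sample_step)``: the recombined sampling
    pitch at the detector plane (skip_factor × pixel_pitch / n_steps) and
    the sample-plane dither step that realises it.  ``nominal_magnification``
    overrides the distance-derived M (mask sets are laid out for a rounded
    design magnification).
    """
    n = config.acquisition.n_dither_steps
    det_pitch = config.skip_factor * config.detector.pixel_pitch / n
    M = nominal_magnification if nominal_magnification is not None else config.magnification
    return det_pitch, det_pitch / M


# ---------------------------------------------------------------------------
# config file I/O (TOML)
# ---------------------------------------------------------------------------

_SECTIONS = ("source", "sample_mask", "detector_mask", "detector", "geometry", "acquisition")


def config_to_dict(config: ScannerConfig) -> dict:
    return {name: dataclasses.asdict(getattr(config, name)) for name in _SECTIONS}


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return json.dumps(value)


def save_config(config: ScannerConfig, path) -> None:
    lines = []
    for section, payload in config_to_dict(config).items():
        lines.append(f"[{section}]")
        for key, value in payload.items():
            lines.append(f"{key} = {_toml_scalar(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def load_config(path) -> ScannerConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return build_config(raw)


# ---------------------------------------------------------------------------
# reference configurations (the two mask sets of the scanner this toolkit
# emulates: a 70 µm FWHM Mo source at 19 keV effective energy, 50 µm pixels,
# 70 cm length, 15 cm object-to-detector)
# ---------------------------------------------------------------------------

def lowres_preset(**overrides) -> ScannerConfig:
    """Non-skipped mask set (48/38 µm pitches, 20/12 µm apertures): the
    intra-operative, detector-resolution-limited mode; single frame."""
    raw = {
        "source": {"focal_spot_fwhm": 70.0, "effective_energy": 19.0},
        "sample_mask": {"pitch": 38.0, "aperture": 12.0, "skip_factor": 1},
        "detector_mask": {"pitch": 48.0, "aperture": 20.0, "skip_factor": 1},
        "detector": {"pixel_pitch": 50.0, "crosstalk_fwhm": 100.0},
        "geometry": {"source_to_detector": 70.0, "object_to_detector": 15.0},
        "acquisition": {"n_dither_steps": 1, "dither_step": 0.0, "mask_offset_si": -9.0},
    }
    _merge(raw, overrides)
    return build_config(raw)


def highres_preset(**overrides) -> ScannerConfig:
    """Skipped mask set (98/78 µm pitches, 20/12 µm apertures, every other
    column illuminated) with 8 dithering steps of 10 µm: the aperture-
    limited virtual-histology mode."""
    raw = {
        "source": {"focal_spot_fwhm": 70.0, "effective_energy": 19.0},
        "sample_mask": {"pitch": 78.0, "aperture": 12.0, "skip_factor": 2},
        "detector_mask": {"pitch": 98.0, "aperture": 20.0, "skip_factor": 2},
        "detector": {"pixel_pitch": 50.0, "crosstalk_fwhm": 100.0},
        "geometry": {"source_to_detector": 70.0, "object_to_detector": 15.0},
        "acquisition": {"n_dither_steps": 8, "dither_step": 10.0, "mask_offset_si": -9.0},
    }
    _merge(raw, overrides)
    return build_config(raw)


def _merge(base: dict, overrides: dict) -> None:
    for section, payload in overrides.items():
        if section not in base:
            raise ConfigurationError(f"unknown config section {section!r}")
        base[section].update(payload)
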