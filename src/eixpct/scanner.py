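"""Forward simulation of edge-illumination frames.

Each illuminated pixel column sees one beamlet.  A frame is built by
sampling the projected object (transmission T and refraction shift Δx)
across the sample-mask aperture with several sub-rays and evaluating

    I = I0 · ⟨ T · IC(s − Δx) ⟩_aperture

per beamlet, then mixing columns with the detector cross-talk kernel,
adding the dark level and (optionally) drawing Poisson counts.  Dithering
translates the *sample* (never the masks) in sub-period steps; jitter
adds per-angle integer-period sample translations which are undone later
in the sinogram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .illumination import IlluminationCurve, compute_ic
from .phantom import PhantomVolume, ProjectedSample, project_sample
from .system_model import ScannerConfig
from .units import sigma_from_fwhm

DEFAULT_SUBRAYS = 7


@dataclass
class Frame:
    """Raw detector frame: counts over all columns, with the used mask."""

    counts: np.ndarray  # (ny, n_columns)
    used: np.ndarray  # (n_columns,) bool — columns behind open detector apertures
    beamlet_x: np.ndarray  # sample-plane centre of each used column's beamlet, µm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def used_counts(self) -> np.ndarray:
        return self.counts[:, self.used]


@dataclass
class FrameSet:
    frames: list
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self):
        d = [f.meta.get("dither_offset", 0.0) for f in self.frames]
        steps = np.diff(sorted(set(np.round(d, 9))))
        if len(steps) > 1 and not np.allclose(steps, steps[0]):
            raise ValueError("dither offsets must form a uniform grid")

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def crosstalk_kernel(config: ScannerConfig, n_sigma: float = 6.0) -> np.ndarray:
    """Normalised symmetric cross-talk weights at detector column offsets.

    The detector-plane kernel FWHM is the sample-referred bare-LSF FWHM
    times the magnification (a bare slanted-edge measurement demagnifies
    by exactly M).  Built-in shapes: pure Gaussian, or a Gaussian core
    plus Lorentzian tail of the same FWHM (tail weight
    ``crosstalk_tail_fraction``), emulating scintillator long tails.
    """
    det = config.detector
    if det.crosstalk_fwhm == 0:
        return np.array([1.0])
    w_det = det.crosstalk_fwhm * config.magnification  # physical FWHM, µm
    sigma = sigma_from_fwhm(w_det)
    half = int(np.ceil(n_sigma * sigma / det.pixel_pitch))
    x = np.arange(-half, half + 1) * det.pixel_pitch
    core = np.exp(-0.5 * (x / sigma) ** 2)
    if det.crosstalk_shape == "gaussian":
        k = core
    else:
        tail = 1.0 / (1.0 + (2 * x / w_det) ** 2)
        eta = det.crosstalk_tail_fraction
        k = (1 - eta) * core + eta * tail
    return k / k.sum()


def _beamlet_grid(config: ScannerConfig, x_min: float, x_max: float):
    """Sample-plane beamlet centres (k + 1/2)·period covering [x_min, x_max]."""
    p = config.beamlet_period
    k_lo = int(np.floor(x_min / p - 0.5))
    k_hi = int(np.ceil(x_max / p - 0.5))
    k = np.arange(k_lo, k_hi + 1)
    return (k + 0.5) * p


def simulate_frame(
    config: ScannerConfig,
    projected: ProjectedSample | None,
    s: float,
    dither_offset: float = 0.0,
    jitter_offset: float = 0.0,
    ic: IlluminationCurve | None = None,
    noise: str | None = None,
    rng: np.random.Generator | None = None,
    exposure: float | None = None,
    n_subrays: int = DEFAULT_SUBRAYS,
    angle: float = 0.0,
    like: "Frame | None" = None,
    beamlets: np.ndarray | None = None,
) -> Frame:
    """Simulate one detector frame at mask displacement ``s`` (absolute
    shift, µm).  ``projected=None`` means vacuum (flat field).

    The sample is translated by ``dither_offset + jitter_offset`` along
    +x, so sub-rays at sample-plane position x probe the object at
    x − (dither_offset + jitter_offset).
    """
    if ic is None:
        ic = compute_ic(config)
    if not ic.shift[0] <= s <= ic.shift[-1]:
        raise ValueError(
            f"working point s={s} outside the tabulated IC range "
            f"[{ic.shift[0]}, {ic.shift[-1]}] µm")
    if n_subrays < 3:
        raise ValueError("need at least 3 sub-rays per aperture")
    shift = dither_offset + jitter_offset
    if projected is not None:
        ny = projected.transmission.shape[0]
        x_min = projected.x[0] - abs(shift)
        x_max = projected.x[-1] + abs(shift)
    else:
        ny = 1
        x_min, x_max = -config.beamlet_period * 4, config.beamlet_period * 4

    if beamlets is None:
        beamlets = (like.beamlet_x.copy() if like is not None
                    else _beamlet_grid(config, x_min, x_max))
    kernel = crosstalk_kernel(config)
    # extend the simulated region by the kernel support so convolution
    # boundaries fall outside the reported columns (the physical detector
    # is wider than the region of interest); off-phantom rays see vacuum
    skip = config.skip_factor
    n_margin = int(np.ceil((len(kernel) // 2) / skip))
    p = config.beamlet_period
    if n_margin:
        left = beamlets[0] - p * np.arange(n_margin, 0, -1)
        right = beamlets[-1] + p * np.arange(1, n_margin + 1)
        beamlets_ext = np.concatenate([left, beamlets, right])
    else:
        beamlets_ext = beamlets
    n_report = len(beamlets)
    beamlets, report_slice = beamlets_ext, slice(n_margin, n_margin + n_report)
    a = config.sample_mask.aperture
    offsets = (np.arange(n_subrays) + 0.5) / n_subrays * a - a / 2
    sub_x = beamlets[:, None] + offsets[None, :]  # (n_beamlets, n_subrays)

    i0 = config.detector.i0_rate * (exposure if exposure is not None
                                    else config.acquisition.exposure_time)
    signal = np.empty((ny, len(beamlets)))
    flat_q = (sub_x - shift).ravel()
    for r in range(ny):
        if projected is None:
            signal[r] = i0 * float(ic.value(s))
        else:
            t, dx = projected.sample(r, flat_q)
            vals = t * ic.value(s - dx)
            signal[r] = i0 * vals.reshape(sub_x.shape).mean(axis=1)

    # place beamlets on the full column grid and apply cross-talk
    n_cols = len(beamlets) * skip
    counts = np.zeros((ny, n_cols))
    used = np.zeros(n_cols, dtype=bool)
    used[::skip] = True
    counts[:, ::skip] = signal
    if len(kernel) > 1:
        counts = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="same"), 1, counts)
    # crop the margin columns added for the convolution
    col_slice = slice(report_slice.start * skip, report_slice.stop * skip)
    counts = counts[:, col_slice]
    used = used[col_slice]
    beamlets = beamlets[report_slice]
    counts += config.detector.dark_level
    if noise == "poisson":
        if rng is None:
            raise ValueError("poisson noise requires an rng (seed mandatory)")
        counts = rng.poisson(counts).astype(float)
    elif noise not in (None, "none"):
        raise ValueError(f"unknown noise model {noise!r}")

    return Frame(
        counts=counts, used=used, beamlet_x=beamlets,
        meta={"s": s, "dither_offset": dither_offset, "jitter_offset": jitter_offset,
              "exposure": exposure if exposure is not None
              else config.acquisition.exposure_time,
              "angle": angle, "is_flat": projected is None},
    )


def simulate_dithered_projection(
    config: ScannerConfig,
    phantom: PhantomVolume | ProjectedSample,
    s: float | None = None,
    n_steps: int | None = None,
    step: float | None = None,
    ic: IlluminationCurve | None = None,
    noise: str | None = None,
    rng: np.random.Generator | None = None,
    jitter_offset: float = 0.0,
    angle: float = 0.0,
) -> FrameSet:
    """n_steps frames with the sample translated by k·step (k = 0..n−1)."""
    acq = config.acquisition
    if ic is None:
        ic = compute_ic(config)
    if s is None:
        s = ic.apex + acq.mask_offset_si
    n_steps = acq.n_dither_steps if n_steps is None else n_steps
    step = (acq.dither_step if acq.n_dither_steps > 1 else 0.0) if step is None else step
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps > 1:
        coverage = n_steps * step
        period = config.beamlet_period
        if abs(coverage - period) > 0.05 * period:
            warnings.warn(
                f"dither coverage {coverage:.2f} µm deviates >5% from the beamlet "
                f"period {period:.2f} µm (incomplete or overlapping sampling)",
                stacklevel=2,
            )
    projected = (phantom if isinstance(phantom, ProjectedSample)
                 else project_sample(phantom, config.geometry))
    # one common beamlet grid for all dither steps (and any jitter offset)
    max_shift = (n_steps - 1) * step + abs(jitter_offset)
    beamlets = _beamlet_grid(config, projected.x[0] - max_shift,
                             projected.x[-1] + max_shift)
    frames = [
        simulate_frame(config, projected, s, dither_offset=k * step,
                       jitter_offset=jitter_offset, ic=ic, noise=noise, rng=rng,
                       angle=angle, beamlets=beamlets)
        for k in range(n_steps)
    ]
    return FrameSet(frames, descriptor={"kind": "dithered_projection", "s": s,
                                        "n_steps": n_steps, "step": step,
                                        "angle": angle})


def simulate_ct(
    config: ScannerConfig,
    phantom: PhantomVolume,
    n_angles: int | None = None,
    angular_range: float | None = None,
    jitter: str | None = None,
    jitter_seed: int | None = None,
    noise: str | None = None,
    seed: int | None = None,
    n_steps: int | None = None,
    step: float | None = None,
) -> FrameSet:
    """Full CT acquisition: rotate the phantom about the row axis, emit a
    dithered frame set per angle.  Jitter (``jitter='period'``) translates
    the sample by a random integer number of sample-mask periods per
    angle, recorded in frame metadata for later compensation."""
    acq = config.acquisition
    n_angles = acq.n_angles if n_angles is None else n_angles
    angular_range = acq.angular_range if angular_range is None else angular_range
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    ic = compute_ic(config)
    s = ic.apex + acq.mask_offset_si
    rng = np.random.default_rng(seed) if noise == "poisson" else None
    jit_rng = np.random.default_rng(jitter_seed)
    angles = np.arange(n_angles) * (angular_range / n_angles)
    period = config.beamlet_period
    frames = []
    for ang in angles:
        j_off = 0.0
        if jitter == "period":
            j_off = float(jit_rng.integers(-3, 4)) * period
        rotated = phantom.rotated(ang)
        projected = project_sample(rotated, config.geometry)
        fs = simulate_dithered_projection(
            config, projected, s=s, n_steps=n_steps, step=step, ic=ic,
            noise=noise, rng=rng, jitter_offset=j_off, angle=ang)
        frames.extend(fs.frames)
    return FrameSet(frames, descriptor={"kind": "ct", "n_angles": n_angles,
                                        "angular_range": angular_range, "s": s,
                                        "jitter": jitter or "none"})


def simulate_flat_dark(
    config: ScannerConfig,
    n_frames: int = 1,
    noise: str | None = None,
    seed: int | None = None,
    ic: IlluminationCurve | None = None,
    like: Frame | None = None,
) -> tuple:
    """Vacuum (flat) frames at the working point and dark frames.

    ``like`` copies the column layout of an existing frame so flats can
    normalise a sample acquisition; flats are single-row (the vacuum
    signal has no row structure) and broadcast in correction.
    """
    if ic is None:
        ic = compute_ic(config)
    s = ic.apex + config.acquisition.mask_offset_si
    rng = np.random.default_rng(seed) if noise == "poisson" else None
    flats, darks = [], []
    for _ in range(n_frames):
        flats.append(simulate_frame(config, None, s, ic=ic, noise=noise, rng=rng,
                                    like=like))
        f = flats[-1]
        dark_counts = np.full_like(f.counts, config.detector.dark_level)
        if noise == "poisson":
            dark_counts = rng.poisson(dark_counts).astype(float)
        darks.append(Frame(dark_counts, f.used.copy(), f.beamlet_x.copy(),
                           meta={**f.meta, "is_dark": True}))
    return (FrameSet(flats, {"kind": "flat", "s": s}),
            FrameSet(darks, {"kind": "dark"}))


# ---------------------------------------------------------------------------
# I/O: TIFF stack + JSON sidecar
# ---------------------------------------------------------------------------

def save_frameset(frameset: FrameSet, stem) -> None:
    import tifffile

    stem = Path(stem)
    stack = np.stack([f.counts for f in frameset.frames]).astype(np.float32)
    tifffile.imwrite(stem.with_suffix(".tiff"), stack)
    sidecar = {
        "descriptor": frameset.descriptor,
        "frames": [
            {"meta": f.meta, "used": f.used.tolist(), "beamlet_x": f.beamlet_x.tolist()}
            for f in frameset.frames
        ],
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_frameset(stem) -> FrameSet:
    import tifffile

    stem = Path(stem)
    stack = tifffile.imread(stem.with_suffix(".tiff")).astype(float)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    frames = [
        Frame(stack[i], np.asarray(fr["used"], dtype=bool),
              np.asarray(fr["beamlet_x"], dtype=float), meta=fr["meta"])
        for i, fr in enumerate(sidecar["frames"])
    ]
    return FrameSet(frames, sidecar["descriptor"])
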