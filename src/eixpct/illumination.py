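"""Illumination curve IC(x): detected open-beam intensity vs mask displacement.

The IC is the (periodic) convolution of the sample-mask aperture profile,
the projected source profile, and the detector-mask aperture profile, all
expressed in the sample-mask plane.  It is computed purely geometrically
(no Fresnel propagation): the beam model underlying the forward and
retrieval operators is incoherent-geometric.

Conventions
-----------
* ``x`` (shift) is the sample-mask-plane displacement between the two
  mask patterns, in µm.  The aligned position (apex of a symmetric IC)
  is at x = 0.
* IC is normalised so that fully overlapping apertures with a point
  source give IC = 1.
* The source focal spot (FWHM ``f``) enters as a penumbra Gaussian of
  FWHM f·z_od/sdd at the sample plane (detector-plane penumbra
  f·z_od/(sdd−z_od), demagnified by M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .system_model import ScannerConfig
from .units import sigma_from_fwhm

#: default tabulation step for the IC shift grid, µm
DEFAULT_SHIFT_STEP = 0.1
#: internal fine integration step, µm
FINE_STEP = 0.02


def source_penumbra_fwhm(config: ScannerConfig) -> float:
    """Sample-plane FWHM of the projected focal spot, µm."""
    g = config.geometry
    return config.source.focal_spot_fwhm * g.object_to_detector / g.source_to_detector


def _rect_train(u: np.ndarray, period: float, aperture: float, septa: float) -> np.ndarray:
    """Periodic aperture train: 1 inside apertures (centred on integer
    multiples of ``period``), ``septa`` outside."""
    phase = np.abs(((u + period / 2) % period) - period / 2)
    return np.where(phase < aperture / 2, 1.0, septa)


@dataclass
class IlluminationCurve:
    """Tabulated IC over one period with a C2 periodic interpolant."""

    shift: np.ndarray  # µm, spans exactly one period, endpoint inclusive
    values: np.ndarray  # dimensionless, in [0, 1]
    period: float  # µm
    working_offset: float = 0.0  # signed s_i relative to the apex, µm
    _spline: CubicSpline = field(init=False, repr=False)
    _apex: float = field(init=False, repr=False)

    def __post_init__(self):
        self.shift = np.asarray(self.shift, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        v = self.values.copy()
        v[-1] = v[0]  # enforce exact periodicity for the spline
        self._spline = CubicSpline(self.shift, v, bc_type="periodic")
        self._apex = self._find_apex()

    # -- lookups ------------------------------------------------------------
    def _wrap(self, s):
        lo = self.shift[0]
        return (np.asarray(s, dtype=float) - lo) % self.period + lo

    def value(self, s):
        return self._spline(self._wrap(s))

    def slope(self, s):
        return self._spline(self._wrap(s), 1)

    @property
    def apex(self) -> float:
        """Shift of the IC maximum, µm."""
        return self._apex

    def _find_apex(self) -> float:
        dense = np.linspace(self.shift[0], self.shift[-1], 4001)
        i = int(np.argmax(self._spline(dense)))
        from scipy.optimize import minimize_scalar

        lo = dense[max(i - 1, 0)]
        hi = dense[min(i + 1, len(dense) - 1)]
        if hi <= lo:
            return dense[i]
        res = minimize_scalar(lambda s: -self._spline(s), bounds=(lo, hi), method="bounded")
        return float(res.x)

    @property
    def working_shift(self) -> float:
        return self.apex + self.working_offset

    @property
    def ic_at_si(self) -> float:
        return float(self.value(self.working_shift))

    @property
    def slope_at_si(self) -> float:
        return float(self.slope(self.working_shift))

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"shift_um": self.shift, "ic": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, working_offset: float = 0.0) -> "IlluminationCurve":
        df = pd.read_csv(path)
        shift = df["shift_um"].to_numpy()
        return cls(shift, df["ic"].to_numpy(), period=float(shift[-1] - shift[0]),
                   working_offset=working_offset)


def compute_ic(
    config: ScannerConfig,
    shift_grid: np.ndarray | None = None,
    fine_step: float = FINE_STEP,
) -> IlluminationCurve:
    """Compute the illumination curve of a scanner configuration.

    The triple convolution is evaluated on a fine grid by FFT
    cross-correlation of the sample-mask train with the source-blurred
    detector-mask train.  ``shift_grid`` must span at least one full
    period with a step ≤ 0.5 µm; default: one period at 0.1 µm.
    """
    period = config.beamlet_period
    if shift_grid is None:
        n = int(np.ceil(period / DEFAULT_SHIFT_STEP))
        shift_grid = np.linspace(-period / 2, period / 2, n + 1)
    else:
        shift_grid = np.asarray(shift_grid, dtype=float)
        if shift_grid[-1] - shift_grid[0] < period * (1 - 1e-9):
            raise ValueError("shift_grid must span at least one full period")
        if np.max(np.diff(shift_grid)) > 0.5 + 1e-12:
            raise ValueError("shift_grid step too coarse; need <= 0.5 µm")

    M = config.magnification
    a1 = config.sample_mask.aperture
    a2 = config.detector_mask.aperture / M
    septa1 = config.sample_mask.septa_transmission
    septa2 = config.detector_mask.septa_transmission
    src_fwhm = source_penumbra_fwhm(config)

    values = _ic_fft(shift_grid, period, a1, a2, septa1, septa2, src_fwhm, fine_step)
    ic = IlluminationCurve(shift_grid, values, period=period,
                           working_offset=config.acquisition.mask_offset_si)
    return ic


def _ic_fft(shifts, period, a1, a2, septa1, septa2, src_fwhm, du) -> np.ndarray:
    """FFT-correlation evaluation of IC(x) = (1/a_min) ∫ A1(u) B(u−x) du
    with B = S * A2, averaged per sample-mask aperture."""
    half_span = max(abs(shifts[0]), abs(shifts[-1]))
    n_pad = int(np.ceil((half_span + 4 * max(src_fwhm, 1.0) + a1 + a2) / period)) + 1
    n_central = 3
    half = (n_central / 2 + n_pad) * period
    m = int(np.ceil(2 * half / du))
    u = (np.arange(m) - m / 2 + 0.5) * du

    a1_train = _rect_train(u, period, a1, septa1)
    b = _rect_train(u, period, a2, septa2)
    if src_fwhm > 0:
        sigma = sigma_from_fwhm(src_fwhm)
        k_half = int(np.ceil(5 * sigma / du))
        k = np.arange(-k_half, k_half + 1) * du
        kernel = np.exp(-0.5 * (k / sigma) ** 2)
        kernel /= kernel.sum()
        b = signal.fftconvolve(b, kernel, mode="same")

    central = np.abs(u) < n_central * period / 2
    a1_central = np.where(central, a1_train, 0.0)

    corr = signal.correlate(b, a1_central, mode="same", method="fft") * du
    # correlate(b, a)[lag] = Σ_u a(u) b(u + lag); IC(x) = ∫ A1(u) B(u − x) du
    # → evaluate at lag = −x
    lags = signal.correlation_lags(len(b), len(a1_central), mode="same") * du
    a_min = min(a1, a2)
    norm = n_central * a_min
    return np.interp(-np.asarray(shifts), lags, corr) / norm


def ic_lookup(ic: IlluminationCurve, s) -> tuple:
    """Interpolated ``(IC(s), IC'(s))`` with periodic wrapping."""
    return ic.value(s), ic.slope(s)


def find_max_slope_point(ic: IlluminationCurve) -> float:
    """Signed offset from the apex that maximises |IC'|.

    The slope is evaluated as finite differences of the tabulated curve
    (a cubic interpolant overshoots at the kinks of piecewise-linear ICs,
    which would break the plateau tie-break).  Tie-break for slope
    plateaus (e.g. the linear flanks of a triangular IC): the midpoint of
    the plateau, preferring the smallest |offset| and the negative-shift
    flank.
    """
    dense = 0.5 * (ic.shift[1:] + ic.shift[:-1])
    d = np.abs(np.diff(ic.values) / np.diff(ic.shift))
    peak = float(d.max())
    if peak < 1e-9:
        raise ValueError("illumination curve is constant; no slope maximum")
    plateau = d >= (1 - 1e-3) * peak
    # contiguous plateau segments of consistent slope sign (the two flanks
    # of a symmetric IC meet at the apex but are distinct extrema)
    idx = np.flatnonzero(plateau)
    sign = np.sign(np.diff(ic.values))[idx]
    breaks = np.flatnonzero((np.diff(idx) > 1) | (np.diff(sign) != 0)) + 1
    segments = np.split(idx, breaks)
    offsets = []
    for seg in segments:
        mid = dense[seg].mean() - ic.apex
        offsets.append(mid)
    # smallest magnitude wins; ties go to the negative side
    offsets.sort(key=lambda o: (round(abs(o), 6), o))
    return float(offsets[0])
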