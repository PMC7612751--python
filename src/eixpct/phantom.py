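"""Digital phantoms: voxelised δ/β volumes and their projections.

δ and β are the refractive-index decrement and absorption index
(n = 1 − δ + iβ); the linear attenuation coefficient is µ = 4πβ/λ.
The Beer–Lambert transmission therefore uses µ, not β directly — β is
dimensionless and only enters attenuation through µ.

Volumes are stored as ``(ny, nx, nz)`` arrays: ``y`` runs along detector
rows (mask lines), ``x`` along the mask modulation direction and ``z``
along the beam.  The ray model is parallel within the slice (the cone
angle of a desk-scale object at tens of cm is negligible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .system_model import Geometry
from .units import wavelength_um


@dataclass(frozen=True)
class MaterialProperties:
    """Optical constants of a homogeneous material at one energy."""

    delta: float
    beta: float
    energy: float = 19.0  # keV
    name: str = ""

    def __post_init__(self):
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")

    @property
    def wavelength(self) -> float:
        return wavelength_um(self.energy)

    @property
    def mu(self) -> float:
        """Linear attenuation coefficient 4πβ/λ, 1/µm."""
        return 4 * np.pi * self.beta / self.wavelength

    @property
    def gamma(self) -> float:
        """δ/β ratio (dimensionless homogeneity parameter)."""
        if self.beta == 0:
            return np.inf
        return self.delta / self.beta

    @property
    def phase_per_attenuation(self) -> float:
        """c = δ/µ in µm: phase thickness per unit optical depth."""
        if self.beta == 0:
            return np.inf
        return self.delta / self.mu


# Configurable reference materials at 19 keV.  Soft-tissue values are
# water-like defaults from standard optical-constant tabulations; they are
# deliberately plain config values, not physical constants of the toolkit.
SOFT_TISSUE = MaterialProperties(delta=7.0e-7, beta=3.0e-10, energy=19.0, name="soft_tissue")
ADIPOSE = MaterialProperties(delta=6.3e-7, beta=2.0e-10, energy=19.0, name="adipose")
FIBROGLANDULAR = MaterialProperties(delta=7.6e-7, beta=3.6e-10, energy=19.0, name="fibroglandular")
TUNGSTEN = MaterialProperties(delta=1.5e-5, beta=1.1e-6, energy=19.0, name="tungsten")
#: ideal test-edge material: fully absorbing, no refraction term (a sharp
#: opaque interface in the geometric model would otherwise produce an
#: unphysical single-voxel refraction spike)
ABSORBER = MaterialProperties(delta=0.0, beta=1.1e-6, energy=19.0, name="absorber")


@dataclass
class PhantomVolume:
    """Voxelised δ/β maps with (possibly anisotropic) voxel spacing."""

    delta: np.ndarray  # (ny, nx, nz)
    beta: np.ndarray
    spacing: tuple  # (dy, dx, dz) µm
    energy: float = 19.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.delta.shape != self.beta.shape or self.delta.ndim != 3:
            raise ValueError("delta and beta must be 3-D arrays of equal shape")
        if np.any(self.delta < 0) or np.any(self.beta < 0):
            raise ValueError("negative refractive decrement or absorption index")
        if not (np.all(np.isfinite(self.delta)) and np.all(np.isfinite(self.beta))):
            raise ValueError("non-finite phantom values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (dy, dx, dz)")

    @property
    def shape(self):
        return self.delta.shape

    @property
    def x_coords(self) -> np.ndarray:
        """Sample-plane x coordinate of voxel centres, centred on 0, µm."""
        nx = self.shape[1]
        dx = self.spacing[1]
        return (np.arange(nx) - (nx - 1) / 2) * dx

    def rotated(self, angle_deg: float, order: int = 1) -> "PhantomVolume":
        """Volume rotated about the y (row) axis, same grid (x–z plane)."""
        from scipy import ndimage

        if angle_deg % 360.0 == 0.0:
            return self
        d = ndimage.rotate(self.delta, angle_deg, axes=(1, 2), reshape=False,
                           order=order, mode="constant", cval=0.0)
        b = ndimage.rotate(self.beta, angle_deg, axes=(1, 2), reshape=False,
                           order=order, mode="constant", cval=0.0)
        return PhantomVolume(np.clip(d, 0, None), np.clip(b, 0, None), self.spacing,
                             self.energy, {**self.provenance, "rotated_deg": angle_deg})


@dataclass
class ProjectedSample:
    """Line-integral maps of a phantom: transmission, phase, refraction."""

    transmission: np.ndarray  # T(y, x), in (0, 1]
    phase_thickness: np.ndarray  # ∫δ dz (y, x), µm·(dimensionless δ)
    refraction_angle: np.ndarray  # Δθ(y, x), rad
    beamlet_shift: np.ndarray  # Δx(y, x) = z_od·Δθ, µm
    x: np.ndarray  # sample-plane x of columns, µm
    row_pitch: float  # µm
    fill: str = "vacuum"  # off-grid rays: "vacuum" (T=1, Δθ=0) or "extend"
    meta: dict = field(default_factory=dict)

    def sample(self, row: int, x_query: np.ndarray):
        """(T, Δx) linearly interpolated along a row.

        Rays missing the grid see vacuum by default; ``fill='extend'``
        continues the boundary values (appropriate for half-plane objects
        such as a resolution test edge)."""
        if self.fill == "extend":
            t = np.interp(x_query, self.x, self.transmission[row])
            dx = np.interp(x_query, self.x, self.beamlet_shift[row])
        else:
            t = np.interp(x_query, self.x, self.transmission[row], left=1.0, right=1.0)
            dx = np.interp(x_query, self.x, self.beamlet_shift[row], left=0.0, right=0.0)
        return t, dx


def project_sample(
    phantom: PhantomVolume,
    geometry: Geometry,
    row_pitch: float | None = None,
    fill: str | None = None,
) -> ProjectedSample:
    """Parallel-ray projection along z: T = exp(−∫µ dz), Δθ = ∂x ∫δ dz.

    ``row_pitch`` is recorded metadata (defaults to the phantom's dy).
    ``fill`` defaults to 'extend' for half-plane edge phantoms and
    'vacuum' otherwise.
    """
    lam = wavelength_um(phantom.energy)
    dz = phantom.spacing[2]
    dx = phantom.spacing[1]
    beta_int = phantom.beta.sum(axis=2) * dz
    phase = phantom.delta.sum(axis=2) * dz
    mu_int = 4 * np.pi * beta_int / lam
    transmission = np.exp(-mu_int)
    dtheta = np.gradient(phase, dx, axis=1)
    z_od = geometry.z_od_um
    if fill is None:
        fill = ("extend" if phantom.provenance.get("builder") == "make_slanted_edge"
                else "vacuum")
    return ProjectedSample(
        transmission=transmission,
        phase_thickness=phase,
        refraction_angle=dtheta,
        beamlet_shift=z_od * dtheta,
        x=phantom.x_coords,
        row_pitch=row_pitch if row_pitch is not None else phantom.spacing[0],
        fill=fill,
        meta={"energy": phantom.energy, "z_od_um": z_od,
              "provenance": dict(phantom.provenance)},
    )


def check_linearity(projected: ProjectedSample, working_offset: float) -> bool:
    """Warn when beamlet shifts leave the linear range of the IC flank.

    The single-shot retrieval linearises IC about the working point; the
    usable range is of order the apex distance |s_i|.  Returns True when
    the linearisation is safe.
    """
    max_shift = float(np.max(np.abs(projected.beamlet_shift)))
    limit = abs(working_offset) / 2
    if max_shift >= limit:
        warnings.warn(
            f"max |Δx| = {max_shift:.3f} µm exceeds half the working-point "
            f"offset ({limit:.3f} µm); the linearised retrieval model may break",
            stacklevel=2,
        )
        return False
    return True


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def make_slanted_edge(
    angle: float,
    material: MaterialProperties = ABSORBER,
    thickness: float = 200.0,
    fov_x: float = 1000.0,
    n_rows: int = 48,
    row_pitch: float = 39.2857,
    voxel_x: float = 1.0,
) -> PhantomVolume:
    """Half-plane of ``material`` with a straight edge tilted by ``angle``
    degrees from the detector column direction.

    The material covers x < x_e(y) with x_e(y) = tan(angle)·(y − y_mid);
    edge voxels carry partial-volume coverage.  The analytic edge line is
    recorded in ``provenance['edge']`` for oracle checks.  The slanted-edge
    method is only valid for small tilts: 1° ≤ angle ≤ 10° enforced.
    """
    if not 1.0 <= angle <= 10.0:
        raise ValueError(f"edge angle must be in [1, 10] degrees, got {angle}")
    nx = int(round(fov_x / voxel_x))
    x_edges = (np.arange(nx + 1) - nx / 2) * voxel_x  # voxel boundaries
    y = (np.arange(n_rows) - (n_rows - 1) / 2) * row_pitch
    slope = np.tan(np.radians(angle))
    x_e = slope * y  # per-row analytic crossing
    # coverage of voxel [x0, x1) by material occupying x < x_e
    cov = np.clip((x_e[:, None] - x_edges[None, :-1]) / voxel_x, 0.0, 1.0)
    delta = material.delta * cov[:, :, None]
    beta = material.beta * cov[:, :, None]
    return PhantomVolume(
        delta, beta, spacing=(row_pitch, voxel_x, thickness),
        energy=material.energy,
        provenance={
            "builder": "make_slanted_edge",
            "angle_deg": angle,
            "material": material.name,
            "thickness_um": thickness,
            "edge": {"slope": slope, "intercept": 0.0, "y_um": y.tolist()},
        },
    )


def make_strand_phantom(
    strand_width: float = 30.0,
    strand_contrast: float = 1.0,
    background: MaterialProperties = SOFT_TISSUE,
    background_radius: float = 500.0,
    strand_offsets: tuple = ((0.0, 0.0),),
    fov: float = 1400.0,
    voxel_size: float = 2.0,
) -> PhantomVolume:
    """Soft-tissue disk with embedded strand(s) of elevated δ/β.

    A strand is a parallel rod (circle in the x–z slice) of diameter
    ``strand_width`` whose optical constants are the background's scaled
    by (1 + strand_contrast); γ = δ/β is preserved so the quasi-
    homogeneity assumption of the single-shot retrieval holds.
    """
    if strand_width < 2 * voxel_size:
        raise ValueError("strand_width must be at least two voxels")
    n = int(round(fov / voxel_size))
    c = (np.arange(n) - (n - 1) / 2) * voxel_size
    xx, zz = np.meshgrid(c, c, indexing="ij")
    disk = (xx**2 + zz**2) <= background_radius**2
    scale = np.where(disk, 1.0, 0.0)
    for (ox, oz) in strand_offsets:
        strand = ((xx - ox) ** 2 + (zz - oz) ** 2) <= (strand_width / 2) ** 2
        scale = np.where(strand, 1.0 + strand_contrast, scale)
    delta = background.delta * scale[None, :, :]
    beta = background.beta * scale[None, :, :]
    return PhantomVolume(
        delta, beta, spacing=(voxel_size, voxel_size, voxel_size),
        energy=background.energy,
        provenance={
            "builder": "make_strand_phantom",
            "strand_width_um": strand_width,
            "strand_contrast": strand_contrast,
            "strand_offsets": [list(o) for o in strand_offsets],
            "background": background.name,
            "background_radius_um": background_radius,
            "mu_background": background.mu,
        },
    )


def make_texture_phantom(
    seed: int,
    feature_scale: float = 100.0,
    materials: tuple = (ADIPOSE, FIBROGLANDULAR),
    fractions: tuple = (0.5, 0.5),
    fov: float = 1000.0,
    voxel_size: float = 4.0,
    radius: float | None = None,
) -> PhantomVolume:
    """Reproducible clustered two-material texture (adipose/fibrous-like).

    A Gaussian random field smoothed at ``feature_scale`` (µm) is
    thresholded at the quantile giving the requested material fractions;
    the result is masked to a disk so it can serve as a CT object.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    n = int(round(fov / voxel_size))
    fieldv = rng.standard_normal((n, n))
    fieldv = ndimage.gaussian_filter(fieldv, sigma=feature_scale / voxel_size, mode="wrap")
    thr = np.quantile(fieldv, fractions[0])
    m0, m1 = materials
    delta = np.where(fieldv < thr, m0.delta, m1.delta)
    beta = np.where(fieldv < thr, m0.beta, m1.beta)
    if radius is None:
        radius = fov / 2 - 2 * voxel_size
    c = (np.arange(n) - (n - 1) / 2) * voxel_size
    xx, zz = np.meshgrid(c, c, indexing="ij")
    disk = (xx**2 + zz**2) <= radius**2
    delta = np.where(disk, delta, 0.0)
    beta = np.where(disk, beta, 0.0)
    return PhantomVolume(
        delta[None, :, :], beta[None, :, :],
        spacing=(voxel_size, voxel_size, voxel_size), energy=m0.energy,
        provenance={"builder": "make_texture_phantom", "seed": seed,
                    "feature_scale_um": feature_scale,
                    "materials": [m0.name, m1.name], "fractions": list(fractions)},
    )


def save_phantom(phantom: PhantomVolume, stem) -> None:
    """Write ``<stem>_delta.tiff``, ``<stem>_beta.tiff`` and ``<stem>.json``."""
    import json
    from pathlib import Path

    import tifffile

    stem = Path(stem)
    tifffile.imwrite(stem.with_name(stem.name + "_delta.tiff"),
                     phantom.delta.astype(np.float32))
    tifffile.imwrite(stem.with_name(stem.name + "_beta.tiff"),
                     phantom.beta.astype(np.float32))
    meta = {"spacing_um": list(phantom.spacing), "energy_kev": phantom.energy,
            "provenance": phantom.provenance}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_phantom(stem) -> PhantomVolume:
    import json
    from pathlib import Path

    import tifffile

    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    delta = tifffile.imread(stem.with_name(stem.name + "_delta.tiff")).astype(float)
    beta = tifffile.imread(stem.with_name(stem.name + "_beta.tiff")).astype(float)
    return PhantomVolume(delta, beta, tuple(meta["spacing_um"]), meta["energy_kev"],
                         meta.get("provenance", {}))


def shifted(phantom: PhantomVolume, shift_um: float) -> PhantomVolume:
    """Phantom translated along +x by an integer number of voxels."""
    dx = phantom.spacing[1]
    n = shift_um / dx
    if abs(n - round(n)) > 1e-9:
        raise ValueError("shift must be an integer number of voxels")
    n = int(round(n))
    d = np.roll(phantom.delta, n, axis=1)
    b = np.roll(phantom.beta, n, axis=1)
    return PhantomVolume(d, b, phantom.spacing, phantom.energy,
                         {**phantom.provenance, "shifted_um": shift_um})
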