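"""Synthetic cryo-EM-like density generation for helical tail sheaths.

Volumes are cubic voxel grids indexed ``[z, y, x]`` with the helical axis along
z through the box center.  Subunits are rendered as isotropic Gaussian
pseudo-atoms placed on the lattice from :mod:`sheathkit.geometry`; the tail
tube is a uniform annular cylinder; the outer coil is a single large-pitch
helix of blobs outside the sheath.  Projections are side-view line integrals
with optional additive white Gaussian noise.  The defaults mirror the
processing scale of the phage G study: 3.484 A/pixel sampling in a 224-voxel
box, and a blob sigma of 8 A giving map features at roughly the 7-8 A
resolution of the experimental reconstructions.  No CTF, dose weighting or
motion blur is simulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from . import geometry as geo
from .errors import MapFormatError, MeasurementError

__all__ = [
    "DensityVolume",
    "BlobModel",
    "CoilSpec",
    "ProjectionImage",
    "render_volume",
    "add_tube",
    "add_coil",
    "project",
    "add_noise",
    "add_map_noise",
    "noise_sigma_for_snr",
    "measure_coil_pitch",
    "read_mrc",
    "write_mrc",
    "simulate_sheath_map",
    "simulate_projection",
]

DEFAULT_VOXEL_SIZE_ANG = 3.484
DEFAULT_BOX_VOXELS = 224
DEFAULT_BLOB_SIGMA_ANG = 8.0
COIL_PITCH_ANG = 210.0
COIL_DIAMETER_ANG = {"non_contracted": 390.0, "contracted": 490.0}


@dataclass
class DensityVolume:
    """Cubic scalar density grid.

    ``grid`` is float32, indexed ``[z, y, x]``; the helical axis is the grid
    z-axis through the box center ``(n-1)/2``.
    """

    grid: np.ndarray
    voxel_size_ang: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise MapFormatError(f"volume must be a cubic 3D grid, got shape {self.grid.shape}")
        if self.voxel_size_ang <= 0:
            raise MapFormatError("voxel_size_ang must be > 0")
        if not np.all(np.isfinite(self.grid)):
            raise MapFormatError("volume contains non-finite values")

    @property
    def box_voxels(self) -> int:
        return self.grid.shape[0]

    @property
    def center_voxel(self) -> float:
        return (self.box_voxels - 1) / 2.0

    @property
    def box_size_ang(self) -> float:
        return self.box_voxels * self.voxel_size_ang

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel_size_ang)


@dataclass(frozen=True)
class BlobModel:
    """Isotropic Gaussian pseudo-atom standing in for one sheath subunit."""

    sigma_ang: float = DEFAULT_BLOB_SIGMA_ANG
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_ang <= 0:
            raise ValueError("sigma_ang must be > 0")

    @property
    def mass(self) -> float:
        """Analytic integral of the 3D Gaussian (density units x A^3)."""
        return self.amplitude * (2.0 * math.pi) ** 1.5 * self.sigma_ang**3


@dataclass(frozen=True)
class CoilSpec:
    """Outer coil: a fixed-axial-pitch helix outside the sheath.

    Phage G's outer coil keeps a 210 A axial pitch in both sheath states while
    its diameter changes from 390 A (non-contracted) to 490 A (contracted).
    Strand count and handedness are not established experimentally; defaults
    are one right-handed strand.
    """

    axial_pitch_ang: float = COIL_PITCH_ANG
    diameter_ang: float = COIL_DIAMETER_ANG["non_contracted"]
    handedness: str = "right"
    n_coil_strands: int = 1

    def __post_init__(self) -> None:
        if self.axial_pitch_ang <= 0 or self.diameter_ang <= 0:
            raise ValueError("pitch and diameter must be > 0")
        if self.n_coil_strands < 1:
            raise ValueError("n_coil_strands must be >= 1")


@dataclass
class ProjectionImage:
    """2D side-view projection, indexed ``[z, lateral]``."""

    data: np.ndarray
    pixel_size_ang: float
    noise_sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("projection must be 2D")
        if self.pixel_size_ang <= 0:
            raise ValueError("pixel_size_ang must be > 0")


def _pose_xyz(pose: geo.SubunitPose) -> Tuple[float, float, float]:
    phi = math.radians(pose.azimuth_deg)
    return (
        pose.radius_ang * math.cos(phi),
        pose.radius_ang * math.sin(phi),
        pose.z_ang,
    )


def _splat_blobs(
    grid: np.ndarray,
    centers_xyz_ang: np.ndarray,
    blob: BlobModel,
    voxel: float,
    warn_outside: bool = True,
) -> None:
    """Accumulate Gaussian blobs (in place) at physical centers (x, y, z in A).

    Physical (0, 0, 0) maps to the box center.  Blobs are evaluated on a
    +-4 sigma patch, clipped at box edges; a blob whose center falls outside
    the box is still rendered where its tail overlaps, with a warning.
    """
    n = grid.shape[0]
    c = (n - 1) / 2.0
    r_vox = max(1, int(math.ceil(4.0 * blob.sigma_ang / voxel)))
    two_s2 = 2.0 * (blob.sigma_ang / voxel) ** 2
    outside = 0
    for x, y, z in centers_xyz_ang:
        iz, iy, ix = z / voxel + c, y / voxel + c, x / voxel + c
        if not (0 <= iz < n and 0 <= iy < n and 0 <= ix < n):
            outside += 1
        zlo, zhi = int(math.floor(iz - r_vox)), int(math.ceil(iz + r_vox)) + 1
        ylo, yhi = int(math.floor(iy - r_vox)), int(math.ceil(iy + r_vox)) + 1
        xlo, xhi = int(math.floor(ix - r_vox)), int(math.ceil(ix + r_vox)) + 1
        zlo, ylo, xlo = max(zlo, 0), max(ylo, 0), max(xlo, 0)
        zhi, yhi, xhi = min(zhi, n), min(yhi, n), min(xhi, n)
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        zz = np.arange(zlo, zhi, dtype=np.float64) - iz
        yy = np.arange(ylo, yhi, dtype=np.float64) - iy
        xx = np.arange(xlo, xhi, dtype=np.float64) - ix
        g = (
            np.exp(-(zz**2) / two_s2)[:, None, None]
            * np.exp(-(yy**2) / two_s2)[None, :, None]
            * np.exp(-(xx**2) / two_s2)[None, None, :]
        )
        grid[zlo:zhi, ylo:yhi, xlo:xhi] += blob.amplitude * g
    if outside and warn_outside:
        warnings.warn(
            f"{outside} blob center(s) fell outside the box and were clipped",
            stacklevel=3,
        )


def render_volume(
    lattice: Sequence[geo.SubunitPose],
    blob: BlobModel,
    box_voxels: int = DEFAULT_BOX_VOXELS,
    voxel_size_ang: float = DEFAULT_VOXEL_SIZE_ANG,
    center_z: bool = True,
) -> DensityVolume:
    """Render a subunit lattice as a sum of Gaussian blobs.

    With ``center_z`` the axial mid-point of the lattice is placed at the box
    center; laterally the helical axis always passes through the box center.
    """
    if box_voxels < 32:
        raise ValueError("box_voxels must be >= 32")
    grid = np.zeros((box_voxels,) * 3, dtype=np.float64)
    if lattice:
        centers = np.array([_pose_xyz(p) for p in lattice], dtype=np.float64)
        if center_z:
            centers[:, 2] -= (centers[:, 2].min() + centers[:, 2].max()) / 2.0
        _splat_blobs(grid, centers, blob, voxel_size_ang)
    return DensityVolume(grid.astype(np.float32), voxel_size_ang)


def add_tube(
    vol: DensityVolume,
    outer_diam_ang: float,
    inner_diam_ang: float,
    amplitude: float = 0.5,
    edge_sigma_ang: Optional[float] = None,
) -> DensityVolume:
    """Add a z-uniform annular cylinder along z (the tail tube).

    The radial edges are softened with an error-function profile of width
    ``edge_sigma_ang`` (default: one voxel) so the density stays band-limited
    on the grid, as a real map at finite resolution would be.
    """
    if not outer_diam_ang > inner_diam_ang >= 0:
        raise ValueError("need outer_diam > inner_diam >= 0")
    from scipy.special import erf

    s = edge_sigma_ang if edge_sigma_ang is not None else vol.voxel_size_ang
    n = vol.box_voxels
    c = vol.center_voxel
    ax = (np.arange(n) - c) * vol.voxel_size_ang
    rr = np.sqrt(ax[None, :] ** 2 + ax[:, None] ** 2)  # [y, x]
    w = 0.5 * (1.0 + erf((outer_diam_ang / 2.0 - rr) / (s * math.sqrt(2.0))))
    if inner_diam_ang > 0:
        w *= 0.5 * (1.0 + erf((rr - inner_diam_ang / 2.0) / (s * math.sqrt(2.0))))
    out = vol.copy()
    out.grid += (amplitude * w).astype(np.float32)[None, :, :]
    return out


def _coil_centers(
    coil: CoilSpec, z_min_ang: float, z_max_ang: float, step_ang: float
) -> np.ndarray:
    """Blob centers along the coil helix at ~uniform arc spacing ``step_ang``."""
    radius = coil.diameter_ang / 2.0
    hand = +1.0 if coil.handedness == "right" else -1.0
    dphi_dz = hand * 2.0 * math.pi / coil.axial_pitch_ang
    arc_per_z = math.sqrt(1.0 + (radius * dphi_dz) ** 2)
    dz = step_ang / arc_per_z
    zs = np.arange(z_min_ang, z_max_ang + dz, dz)
    centers = []
    for s in range(coil.n_coil_strands):
        phase = 2.0 * math.pi * s / coil.n_coil_strands
        phi = phase + dphi_dz * zs
        centers.append(np.stack([radius * np.cos(phi), radius * np.sin(phi), zs], axis=1))
    return np.concatenate(centers, axis=0)


def add_coil(vol: DensityVolume, coil: CoilSpec, blob: BlobModel) -> DensityVolume:
    """Add blob density along the outer-coil helix spanning the full box in z."""
    half_box = vol.box_size_ang / 2.0
    if coil.diameter_ang / 2.0 + 3.0 * blob.sigma_ang > half_box:
        raise ValueError(
            f"coil diameter {coil.diameter_ang} A does not fit in a "
            f"{vol.box_size_ang:.0f} A box"
        )
    out = vol.copy()
    grid = out.grid.astype(np.float64)
    centers = _coil_centers(coil, -half_box, half_box, step_ang=blob.sigma_ang / 2.0)
    _splat_blobs(grid, centers, blob, vol.voxel_size_ang, warn_outside=False)
    out.grid = grid.astype(np.float32)
    return out


def project(vol: DensityVolume, axis: str = "y") -> ProjectionImage:
    """Side-view projection: line-integral sum along a transverse axis.

    ``axis="y"`` gives an image indexed ``[z, x]``; ``axis="x"`` gives
    ``[z, y]``.  Projection along z is unsupported (tails are viewed side-on).
    """
    if axis == "y":
        data = vol.grid.sum(axis=1, dtype=np.float64)
    elif axis == "x":
        data = vol.grid.sum(axis=2, dtype=np.float64)
    elif axis == "z":
        raise ValueError("projection along the helical axis (z) is unsupported")
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    return ProjectionImage(data * vol.voxel_size_ang, vol.voxel_size_ang)


def add_noise(img: ProjectionImage, sigma: float, seed: int) -> ProjectionImage:
    """Add white Gaussian noise with standard deviation ``sigma`` (seeded)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return replace(img, noise_sigma=0.0, seed=seed, data=img.data.copy())
    rng = np.random.default_rng(seed)
    noisy = img.data + rng.normal(0.0, sigma, size=img.data.shape)
    return ProjectionImage(noisy, img.pixel_size_ang, noise_sigma=sigma, seed=seed)


def add_map_noise(vol: DensityVolume, sigma: float, seed: int) -> DensityVolume:
    """Add white Gaussian noise to a 3D volume (seeded, reproducible)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = vol.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out.grid = (
            out.grid.astype(np.float64) + rng.normal(0.0, sigma, size=out.grid.shape)
        ).astype(np.float32)
    return out


def noise_sigma_for_snr(
    vol: DensityVolume, snr: float, mask: Optional[np.ndarray] = None
) -> float:
    """Noise sigma giving signal-variance / noise-variance = ``snr`` in ``mask``."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    values = vol.grid[mask] if mask is not None else vol.grid
    return float(np.sqrt(values.var() / snr))


def _flank_profiles(img: ProjectionImage, band: int = 3) -> List[np.ndarray]:
    """Axial intensity profiles at the two outermost significant columns."""
    data = img.data
    col_amp = data.max(axis=0) - np.median(data, axis=0)
    baseline = np.median(col_amp)
    threshold = baseline + 0.1 * (col_amp.max() - baseline)
    significant = np.flatnonzero(col_amp > threshold)
    if significant.size < 2:
        raise MeasurementError("no significant lateral extent found in projection")
    left, right = significant[0], significant[-1]
    profiles = []
    for lo, hi in ((left, left + band), (right + 1 - band, right + 1)):
        lo, hi = max(lo, 0), min(hi, data.shape[1])
        profiles.append(data[:, lo:hi].mean(axis=1))
    return profiles


def measure_coil_pitch(img: ProjectionImage) -> float:
    """Measure the outer-coil axial pitch from a side-view projection.

    The coil crosses each lateral flank of the tail once per axial period, so
    the density profile along the two outermost image columns shows peaks
    spaced by the pitch.  Returns the median axial peak spacing (both flanks
    pooled) times the pixel size, in Angstrom.
    """
    spacings: List[float] = []
    for profile in _flank_profiles(img):
        prominence = 0.25 * float(profile.max() - profile.min())
        peaks, _ = signal.find_peaks(profile, prominence=prominence, distance=3)
        if peaks.size >= 2:
            spacings.extend(np.diff(peaks).tolist())
    if not spacings:
        raise MeasurementError("fewer than 2 coil density peaks detected on both flanks")
    return float(np.median(spacings) * img.pixel_size_ang)


def write_mrc(path, vol: DensityVolume) -> None:
    """Write a volume as an MRC2014 mode-2 (float32) map with cubic voxels."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.grid.T))  # (x, y, z) order
    a = vol.box_voxels * vol.voxel_size_ang
    grid.unit_cell = gemmi.UnitCell(a, a, a, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_mrc(path) -> DensityVolume:
    """Read an MRC/CCP4 map into a DensityVolume (cubic voxels required)."""
    import gemmi

    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
        ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC map {path}: {exc}") from exc
    g = ccp4.grid
    arr = np.array(g, copy=True)  # (x, y, z)
    if not np.all(np.isfinite(arr)):
        raise MapFormatError(f"map {path} has unset/non-finite voxels")
    voxels = np.array([g.unit_cell.a / g.nu, g.unit_cell.b / g.nv, g.unit_cell.c / g.nw])
    if not np.allclose(voxels, voxels[0], rtol=1e-3):
        raise MapFormatError(f"map {path} has anisotropic voxels {voxels}")
    return DensityVolume(arr.T, float(voxels.mean()))


def _default_voxel_size(geometry: geo.SheathGeometry, box_voxels: int) -> float:
    """Smallest sampling >= the study's 3.484 A/px such that the symmetry-search
    mask (1.1 x outer radius, plus rotation margin) fits in the box."""
    needed = 2.6 * geometry.outer_diameter_ang / 2.0 / box_voxels
    return max(DEFAULT_VOXEL_SIZE_ANG, needed)


def simulate_sheath_map(
    state: str = "non_contracted",
    box_voxels: int = DEFAULT_BOX_VOXELS,
    voxel_size_ang: Optional[float] = None,
    blob: Optional[BlobModel] = None,
    include_tube: bool = True,
    snr: Optional[float] = None,
    seed: int = 0,
) -> DensityVolume:
    """Build a synthetic phage G sheath map in one state.

    The sheath lattice is extended past the box in z so the density inside the
    box is exactly helical; the tube is added as a uniform annulus.  If ``snr``
    is given, white Gaussian noise is added so that signal variance / noise
    variance equals ``snr`` inside the cylindrical region of radius
    1.1 x outer radius.
    """
    g = geo.phage_g_geometry(state)
    voxel = voxel_size_ang if voxel_size_ang is not None else _default_voxel_size(g, box_voxels)
    blob = blob or BlobModel()
    # enough layers to overfill the box in z, so edge blobs lie outside
    span = box_voxels * voxel + 8.0 * blob.sigma_ang + 2.0 * g.symmetry.rise_ang
    lattice_geom = geo.SheathGeometry(
        state=g.state,
        outer_diameter_ang=g.outer_diameter_ang,
        inner_diameter_ang=g.inner_diameter_ang,
        tail_length_ang=span,
        symmetry=g.symmetry,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # out-of-box blobs are intentional here
        vol = render_volume(geo.build_lattice(lattice_geom), blob, box_voxels, voxel)
    if include_tube:
        vol = add_tube(vol, g.inner_diameter_ang, g.inner_diameter_ang / 2.0)
    if snr is not None:
        n = vol.box_voxels
        ax = (np.arange(n) - vol.center_voxel) * voxel
        rr2 = ax[None, :] ** 2 + ax[:, None] ** 2
        mask3 = np.broadcast_to(
            rr2 <= (1.1 * g.outer_diameter_ang / 2.0) ** 2, vol.grid.shape
        )
        sigma = noise_sigma_for_snr(vol, snr, mask3)
        vol = add_map_noise(vol, sigma, seed)
    return vol


def simulate_projection(
    state: str = "non_contracted",
    coil: bool = True,
    box_voxels: int = DEFAULT_BOX_VOXELS,
    voxel_size_ang: float = DEFAULT_VOXEL_SIZE_ANG,
    blob: Optional[BlobModel] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ProjectionImage:
    """Side-view projection of a synthetic tail, optionally with the outer coil.

    The coil uses the fixed 210 A axial pitch with the state-dependent
    diameter (390 A non-contracted, 490 A contracted).
    """
    vol = simulate_sheath_map(
        state, box_voxels=box_voxels, voxel_size_ang=voxel_size_ang, blob=blob
    )
    if coil:
        spec = CoilSpec(diameter_ang=COIL_DIAMETER_ANG[state])
        vol = add_coil(vol, spec, blob or BlobModel())
    img = project(vol, axis="y")
    if noise_sigma > 0:
        img = add_noise(img, noise_sigma, seed)
    return img
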