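"""Digital carotid-like vessel phantoms.

A phantom is a bifurcating vessel rendered on a 3-D Cartesian grid: a parent
(common carotid, CCA-analog) cylinder below the bifurcation splitting into
two straight daughter cylinders (ICA/ECA-analogs) above it.  The vessel axis
runs along the slice-encode axis (axis 2), so cross-sections live in the
(readout, phase) plane where the acquired in-plane resolution is isotropic.

Black-blood contrast is emulated by the intensity ordering
``lumen < background < wall``: flowing blood is suppressed (dark lumen), the
wall is bright, surrounding tissue intermediate.  Rendering uses exact
analytic disk-coverage per voxel (partial-volume anti-aliasing), so half-max
contour extraction and sub-voxel repositioning behave continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .contours import LUMEN, OUTER_WALL, Contour, ContourSet

__all__ = [
    "PhantomSpec",
    "PlaqueBump",
    "GroundTruthGeometry",
    "CoilSensitivities",
    "build_phantom",
    "ground_truth_geometry",
    "make_coil_sensitivities",
    "jitter_geometry",
    "observer_contours",
    "disk_coverage",
    "DEFAULT_INTENSITIES",
]

# Per-contrast (lumen, wall, background) signal triples.  Black-blood
# ordering lumen < background < wall; absolute levels are free parameters.
DEFAULT_INTENSITIES: dict[str, tuple[float, float, float]] = {
    "t1w": (0.05, 1.00, 0.30),
    "pdw": (0.08, 0.90, 0.35),
    "t2w": (0.05, 0.80, 0.28),
}

FOV_MARGIN_VOXELS = 5


@dataclass(frozen=True)
class PlaqueBump:
    """Focal wall thickening: a Gaussian bump in wall thickness along z.

    ``amplitude_mm`` is added to the wall thickness at ``z_mm`` with axial
    spread ``sigma_mm``.  A bump of amplitude >= 0.5 mm on a 1 mm wall is a
    volunteer-with-thick-wall analog; patient analogs use a >= 2 mm base wall.
    """

    amplitude_mm: float = 0.0
    z_mm: float = 0.0
    sigma_mm: float = 3.0

    def thickness_add(self, z: np.ndarray | float) -> np.ndarray | float:
        if self.amplitude_mm == 0.0:
            return np.zeros_like(np.asarray(z, dtype=float))
        z = np.asarray(z, dtype=float)
        return self.amplitude_mm * np.exp(-0.5 * ((z - self.z_mm) / self.sigma_mm) ** 2)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one subject's vessel and acquisition grid.

    Axes are (readout, phase, slice); the vessel axis is the slice axis.
    All coordinates are in a centred mm frame (0 at the grid centre).
    """

    grid_shape: tuple[int, int, int] = (48, 96, 40)
    voxel_mm: tuple[float, float, float] = (0.625, 0.625, 1.4)
    lumen_radius_mm: float = 3.0
    wall_thickness_mm: float = 1.0
    bifurcation_z_mm: float = 7.0
    branch_separation_mm: float = 9.0
    branch_radius_frac: tuple[float, float] = (0.85, 0.70)  # ICA, ECA
    center_xy_mm: tuple[float, float] = (0.0, 0.0)
    plaque: PlaqueBump = field(default_factory=PlaqueBump)
    intensities: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    n_coils: int = 4
    noise_sd: float = 0.05

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_mm))

    def outer_radius_mm(self, z: float = 0.0, segment: str = "CCA") -> float:
        frac = {"CCA": 1.0, "ICA": self.branch_radius_frac[0], "ECA": self.branch_radius_frac[1]}[segment]
        t = self.wall_thickness_mm + float(self.plaque.thickness_add(z))
        return frac * self.lumen_radius_mm + t

    def validate(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be strictly positive")
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen_radius_mm must be > 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be > 0 everywhere")
        if self.plaque.amplitude_mm < -self.wall_thickness_mm:
            raise ValueError("plaque bump cannot make the wall thickness non-positive")
        for contrast, (lum, wall, bg) in self.intensities.items():
            if min(lum, wall, bg) < 0:
                raise ValueError(f"{contrast}: intensities must be nonnegative")
            if not (lum < bg < wall):
                raise ValueError(
                    f"{contrast}: black-blood ordering requires lumen < background < wall, "
                    f"got ({lum}, {wall}, {bg})"
                )
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self._check_fov_margin()

    def _check_fov_margin(self) -> None:
        """The vessel (wall included) must fit with >= 5 voxels of margin.

        Extents are evaluated per slice, so a focal plaque bump below the
        bifurcation does not inflate the branch extents above it.
        """
        fx, fy, _ = self.fov_mm
        dx, dy, _ = self.voxel_mm
        extents_x, extents_y = [0.0], [0.0]
        for z in self.axis_coords(2):
            for seg, cx, cy, rl, ro in _slice_annuli(self, z):
                extents_x.append(abs(cx) + ro)
                extents_y.append(abs(cy) + ro)
        margin_x = fx / 2.0 - max(extents_x)
        margin_y = fy / 2.0 - max(extents_y)
        if margin_x < FOV_MARGIN_VOXELS * dx:
            raise ValueError(
                f"vessel exceeds FOV margin along readout: margin {margin_x:.2f} mm "
                f"< required {FOV_MARGIN_VOXELS * dx:.2f} mm ({FOV_MARGIN_VOXELS} voxels)"
            )
        if margin_y < FOV_MARGIN_VOXELS * dy:
            raise ValueError(
                f"vessel exceeds FOV margin along phase: margin {margin_y:.2f} mm "
                f"< required {FOV_MARGIN_VOXELS * dy:.2f} mm ({FOV_MARGIN_VOXELS} voxels)"
            )

    def axis_coords(self, axis: int) -> np.ndarray:
        """Centred mm coordinates of voxel centres along one axis."""
        n = self.grid_shape[axis]
        d = self.voxel_mm[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d


@dataclass
class GroundTruthGeometry:
    """Per-slice true geometry of the rendered vessel.

    ``per_slice`` has one row per (acquired slice, segment) with true centre,
    lumen/outer radii and wall thickness in mm.  Outer radius equals lumen
    radius plus wall thickness on every row by construction.
    """

    per_slice: pd.DataFrame
    bifurcation_index: int
    bifurcation_z_mm: float
    voxel_mm: tuple[float, float, float]

    def segments_at(self, slice_index: int) -> pd.DataFrame:
        return self.per_slice[self.per_slice["slice"] == slice_index]

    def segment_rows(self, segment: str) -> pd.DataFrame:
        return self.per_slice[self.per_slice["segment"] == segment]


@dataclass
class CoilSensitivities:
    """Smooth complex coil maps: one Gaussian lobe per coil on the FOV rim."""

    maps: np.ndarray  # (n_coils, nx, ny, nz) complex
    sigma_mm: float

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def sos(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


# ---------------------------------------------------------------------------
# exact disk coverage
# ---------------------------------------------------------------------------

def _g_integral(x: np.ndarray, r: float) -> np.ndarray:
    """Signed integral of sqrt(r^2 - t^2) from 0 to x, saturating at |x| >= r."""
    xc = np.clip(x, -r, r)
    return 0.5 * (xc * np.sqrt(np.maximum(r * r - xc * xc, 0.0)) + r * r * np.arcsin(xc / r))


def _corner_area(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    """Area of {X <= x, Y <= y} intersected with a disk of radius r at the origin.

    Closed form via integration of the chord length; vectorised over broadcast
    x, y.  Used with inclusion-exclusion to get exact pixel coverage.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = np.broadcast_arrays(x, y)
    out = np.zeros(x.shape, dtype=float)
    quarter = 0.25 * np.pi * r * r

    xc = np.clip(x, -r, r)
    yc = np.clip(y, -r, r)
    s = np.sqrt(np.maximum(r * r - yc * yc, 0.0))

    # y >= r: full vertical extent -> area below x
    hi = y >= r
    out[hi] = (2.0 * _g_integral(xc, r) + 2.0 * quarter)[hi]

    # 0 <= y < r
    mid = (y >= 0) & (y < r)
    if np.any(mid):
        a1 = np.minimum(xc, -s)
        a2 = np.clip(xc, -s, s)
        a3 = np.clip(xc, s, r)
        part1 = _g_integral(xc, r) + quarter
        part2 = (_g_integral(a1, r) + quarter) + yc * (a2 + s) + (_g_integral(a3, r) - _g_integral(s, r))
        out[mid] = (part1 + part2)[mid]

    # -r < y < 0: only the cap where the chord exceeds |y|
    lo = (y > -r) & (y < 0)
    if np.any(lo):
        u2 = np.clip(xc, -s, s)
        val = yc * (u2 + s) + _g_integral(u2, r) + _g_integral(s, r)
        out[lo] = np.maximum(val, 0.0)[lo]

    return out


def disk_coverage(
    center_xy: tuple[float, float],
    radius: float,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
) -> np.ndarray:
    """Exact fraction of each pixel covered by a disk.

    Parameters
    ----------
    center_xy : disk centre (x, y) in mm.
    radius : disk radius in mm.
    x_edges, y_edges : pixel edge coordinates (len nx+1 / ny+1) in mm.

    Returns
    -------
    (nx, ny) array of coverage fractions in [0, 1].
    """
    if radius <= 0:
        return np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    xr = np.asarray(x_edges, dtype=float) - center_xy[0]
    yr = np.asarray(y_edges, dtype=float) - center_xy[1]
    H = _corner_area(xr[:, None], yr[None, :], radius)
    area = H[1:, 1:] - H[:-1, 1:] - H[1:, :-1] + H[:-1, :-1]
    px = np.diff(xr)[:, None] * np.diff(yr)[None, :]
    return np.clip(area / px, 0.0, 1.0)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _slice_annuli(spec: PhantomSpec, z: float) -> list[tuple[str, float, float, float, float]]:
    """(segment, cx, cy, lumen_r, outer_r) for every vessel segment at height z."""
    cx, cy = spec.center_xy_mm
    bump = float(spec.plaque.thickness_add(z))
    t = spec.wall_thickness_mm + bump
    if z <= spec.bifurcation_z_mm:
        rl = spec.lumen_radius_mm
        return [("CCA", cx, cy, rl, rl + t)]
    half = spec.branch_separation_mm / 2.0
    rl_ica = spec.branch_radius_frac[0] * spec.lumen_radius_mm
    rl_eca = spec.branch_radius_frac[1] * spec.lumen_radius_mm
    return [
        ("ICA", cx - half, cy, rl_ica, rl_ica + t),
        ("ECA", cx + half, cy, rl_eca, rl_eca + t),
    ]


# 3-point Gauss-Legendre nodes/weights on [-1/2, 1/2], used to average the
# coverage through the slice thickness when the wall profile varies with z.
_GL3_NODES = np.array([-0.5, 0.0, 0.5]) * np.sqrt(3.0 / 5.0)
_GL3_WEIGHTS = np.array([5.0, 8.0, 5.0]) / 18.0


def ground_truth_geometry(spec: PhantomSpec) -> GroundTruthGeometry:
    """Per-slice true geometry implied by a spec, without rasterising."""
    spec.validate()
    nz = spec.grid_shape[2]
    z_centers = spec.axis_coords(2)
    rows = []
    for k, z in enumerate(z_centers):
        for seg, cx, cy, rl, ro in _slice_annuli(spec, z):
            rows.append(
                {
                    "slice": k,
                    "z_mm": z,
                    "segment": seg,
                    "cx_mm": cx,
                    "cy_mm": cy,
                    "lumen_radius_mm": rl,
                    "outer_radius_mm": ro,
                    "wall_thickness_mm": ro - rl,
                }
            )
    bif_index = int(np.searchsorted(z_centers, spec.bifurcation_z_mm, side="right") - 1)
    bif_index = int(np.clip(bif_index, 0, nz - 1))
    return GroundTruthGeometry(
        per_slice=pd.DataFrame(rows),
        bifurcation_index=bif_index,
        bifurcation_z_mm=spec.bifurcation_z_mm,
        voxel_mm=spec.voxel_mm,
    )


def build_phantom(
    spec: PhantomSpec,
    contrasts: tuple[str, ...] | None = None,
) -> tuple[dict[str, np.ndarray], GroundTruthGeometry, CoilSensitivities]:
    """Rasterise a phantom: one noiseless complex image per contrast.

    Parameters
    ----------
    contrasts : subset of ``spec.intensities`` keys to rasterise (all by
        default); the geometry computation is shared.

    Returns
    -------
    images : contrast -> complex (nx, ny, nz) volume (zero phase; coil phase
        enters through the sensitivities).
    geometry : per-slice ground truth.
    sens : smooth complex coil sensitivity maps.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_mm
    x_edges = (np.arange(nx + 1) - nx / 2.0) * dx
    y_edges = (np.arange(ny + 1) - ny / 2.0) * dy
    z_centers = spec.axis_coords(2)

    # coverage of (outer disk, lumen disk) per segment per slice
    cov_wall = np.zeros((nx, ny, nz))
    cov_lumen = np.zeros((nx, ny, nz))
    varying_wall = spec.plaque.amplitude_mm != 0.0
    for k, z in enumerate(z_centers):
        if varying_wall:
            z_samples = z + _GL3_NODES * dz
            weights = _GL3_WEIGHTS
        else:
            z_samples = np.array([z])
            weights = np.array([1.0])
        for zs, w in zip(z_samples, weights):
            for seg, cx, cy, rl, ro in _slice_annuli(spec, zs):
                cov_wall[:, :, k] += w * disk_coverage((cx, cy), ro, x_edges, y_edges)
                cov_lumen[:, :, k] += w * disk_coverage((cx, cy), rl, x_edges, y_edges)

    images: dict[str, np.ndarray] = {}
    for contrast, (lum, wall, bg) in spec.intensities.items():
        if contrasts is not None and contrast not in contrasts:
            continue
        vol = bg + (wall - bg) * cov_wall + (lum - wall) * cov_lumen
        images[contrast] = vol.astype(np.complex128)

    geometry = ground_truth_geometry(spec)
    sens = make_coil_sensitivities(spec)
    return images, geometry, sens


def make_coil_sensitivities(spec: PhantomSpec) -> CoilSensitivities:
    """Gaussian-lobe complex coil maps around the FOV rim (neck-coil-like).

    Each coil has a smooth amplitude lobe and a mild linear phase ramp.
    The maps are normalised so their sum-of-squares is exactly 1 at every
    voxel: the combined image then carries no coil shading (as after a
    bias-field correction), while the coil-to-coil relative structure that
    autocalibrated parallel imaging exploits is preserved.
    """
    nx, ny, nz = spec.grid_shape
    fx, fy, _ = spec.fov_mm
    x = spec.axis_coords(0)[:, None]
    y = spec.axis_coords(1)[None, :]
    sigma = 0.6 * max(fx, fy)
    n = spec.n_coils
    angles = 2.0 * np.pi * (np.arange(n) + 0.5) / n
    maps = np.empty((n, nx, ny, nz), dtype=np.complex128)
    for c, th in enumerate(angles):
        cx = 0.5 * fx * np.cos(th)
        cy = 0.5 * fy * np.sin(th)
        amp = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2))
        phase = 2.0 * np.pi * 0.15 * (np.cos(th) * x / fx + np.sin(th) * y / fy)
        maps[c] = (amp * np.exp(1j * phase))[:, :, None]
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0, keepdims=True))
    maps /= sos
    return CoilSensitivities(maps=maps, sigma_mm=sigma)


# ---------------------------------------------------------------------------
# scan-rescan and observer models
# ---------------------------------------------------------------------------

def jitter_geometry(
    spec: PhantomSpec,
    session_seed: int,
    translation_sd_mm: float = 0.5,
    radius_sd_mm: float = 0.05,
) -> PhantomSpec:
    """Scan-rescan variant: rigid in-plane repositioning plus a small true
    geometry change, deterministic in ``session_seed``.

    Translation emulates repositioning of the subject between sessions;
    the radius/thickness perturbation emulates small physiological change.
    Zero standard deviations return a field-for-field identical spec.
    """
    if translation_sd_mm < 0 or radius_sd_mm < 0:
        raise ValueError("jitter standard deviations must be >= 0")
    rng = np.random.default_rng(session_seed)
    shift = translation_sd_mm * rng.standard_normal(2)
    d_lumen, d_wall = radius_sd_mm * rng.standard_normal(2)
    out = replace(
        spec,
        center_xy_mm=(spec.center_xy_mm[0] + shift[0], spec.center_xy_mm[1] + shift[1]),
        lumen_radius_mm=spec.lumen_radius_mm + d_lumen,
        wall_thickness_mm=spec.wall_thickness_mm + d_wall,
    )
    try:
        out.validate()
    except ValueError as err:
        raise ValueError(f"jittered spec violates phantom invariants: {err}") from err
    return out


def observer_contours(
    truth: GroundTruthGeometry,
    reader_bias_mm: float,
    vertex_noise_sd_mm: float,
    seed: int,
    n_vertices: int = 64,
    reader_id: str = "reader",
    session_id: str = "",
    slice_indices: list[int] | None = None,
    max_retries: int = 8,
) -> tuple[ContourSet, ContourSet]:
    """Simulated manual contouring of the true geometry.

    Each contour is a circular polygon at the true radius plus a per-reader
    constant radial bias (common to lumen and outer wall, so it cancels in
    wall thickness to first order) plus i.i.d. radial vertex noise.
    Deterministic given ``seed``.
    """
    if vertex_noise_sd_mm < 0:
        raise ValueError("vertex_noise_sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    angles = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    ca, sa = np.cos(angles), np.sin(angles)
    lumen_set = ContourSet(role=LUMEN, reader_id=reader_id, session_id=session_id)
    outer_set = ContourSet(role=OUTER_WALL, reader_id=reader_id, session_id=session_id)

    df = truth.per_slice
    if slice_indices is not None:
        df = df[df["slice"].isin(slice_indices)]
    for _, row in df.iterrows():
        for attempt in range(max_retries + 1):
            r_lum = row.lumen_radius_mm + reader_bias_mm + vertex_noise_sd_mm * rng.standard_normal(n_vertices)
            r_out = row.outer_radius_mm + reader_bias_mm + vertex_noise_sd_mm * rng.standard_normal(n_vertices)
            if np.all(r_out > r_lum) and np.all(r_lum > 0):
                break
        else:
            raise RuntimeError(
                f"observer noise too large: lumen crosses outer wall on slice "
                f"{int(row['slice'])} after {max_retries} retries"
            )
        for radii, cset, role in ((r_lum, lumen_set, LUMEN), (r_out, outer_set, OUTER_WALL)):
            verts = np.stack([row.cx_mm + radii * ca, row.cy_mm + radii * sa], axis=1)
            cset.add(
                Contour(
                    slice_index=int(row["slice"]),
                    segment=row["segment"],
                    vertices=verts,
                    role=role,
                    reader_id=reader_id,
                    session_id=session_id,
                )
            )
    return lumen_set, outer_set
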