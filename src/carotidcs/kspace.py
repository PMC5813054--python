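"""Fourier encoding and k-space sampling patterns.

3-D Cartesian acquisition: the readout axis (axis 0 of the image grid) is
always fully sampled; undersampling lives in the two phase-encode dimensions
(phase x slice).  The compressed-sensing pattern draws an exact budget of
``round(N / R)`` points with probability proportional to a centred 2-D
Gaussian, keeping a fully sampled calibration block (default 32 x 32) at the
k-space centre.  All DFTs are orthonormal and centred (DC at the grid
centre), so Parseval's identity holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "make_cs_mask",
    "make_pi_mask",
    "combine_masks",
    "encode",
    "apply_mask",
    "fft3c",
    "ifft3c",
]

_AXES = (-3, -2, -1)


def fft3c(x: np.ndarray) -> np.ndarray:
    """Centred orthonormal 3-D DFT over the last three axes."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"), axes=_AXES)


def ifft3c(x: np.ndarray) -> np.ndarray:
    """Centred orthonormal 3-D inverse DFT over the last three axes."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"), axes=_AXES)


def _center_block(shape: tuple[int, int], center: tuple[int, int]) -> tuple[slice, slice]:
    ny, nz = shape
    cy, cz = center
    if cy > ny or cz > nz:
        raise ValueError(f"centre block {center} does not fit in phase grid {shape}")
    y0 = (ny - cy) // 2
    z0 = (nz - cz) // 2
    return slice(y0, y0 + cy), slice(z0, z0 + cz)


@dataclass
class SamplingMask:
    """Boolean phase-encode sampling pattern (phase x slice).

    The mask is shared by every readout position.  ``kind`` is one of
    ``"cs"`` (variable-density pseudo-random), ``"uniform_pi"`` (regular
    comb for autocalibrated parallel imaging) or ``"combined"``.
    """

    mask: np.ndarray
    R: float
    center_size: tuple[int, int]
    kind: str
    seed: int | None = None
    pi_factors: tuple[int, int] | None = None
    components: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (phase x slice)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_total(self) -> int:
        return self.mask.size

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    @property
    def sampled_fraction(self) -> float:
        return self.n_sampled / self.n_total

    @property
    def effective_R(self) -> float:
        return self.n_total / self.n_sampled

    @property
    def is_full(self) -> bool:
        return bool(self.mask.all())

    def center_slices(self) -> tuple[slice, slice]:
        return _center_block(self.shape, self.center_size)

    def save(self, path: str | Path) -> None:
        """Compressed boolean array plus a JSON header."""
        path = Path(path)
        header = {
            "shape": list(self.shape),
            "R": self.R,
            "center_size": list(self.center_size),
            "kind": self.kind,
            "seed": self.seed,
            "pi_factors": list(self.pi_factors) if self.pi_factors else None,
        }
        np.savez_compressed(path, mask=np.packbits(self.mask), header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "SamplingMask":
        with np.load(path) as f:
            header = json.loads(bytes(f["header"]).decode())
            shape = tuple(header["shape"])
            mask = np.unpackbits(f["mask"])[: shape[0] * shape[1]].reshape(shape).astype(bool)
        return cls(
            mask=mask,
            R=header["R"],
            center_size=tuple(header["center_size"]),
            kind=header["kind"],
            seed=header["seed"],
            pi_factors=tuple(header["pi_factors"]) if header["pi_factors"] else None,
        )


@dataclass
class KSpaceData:
    """Per-coil complex Cartesian k-space samples.

    ``data`` has shape (n_coils, nx, ny, nz) with the mask broadcast over
    the readout axis.  Unsampled locations are exactly zero; ``mask=None``
    means fully sampled.
    """

    data: np.ndarray
    mask: SamplingMask | None = None
    noise_sd: float = 0.0
    voxel_mm: tuple[float, float, float] = (0.625, 0.625, 1.4)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("k-space data must be (n_coils, nx, ny, nz)")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def make_cs_mask(
    phase_shape: tuple[int, int],
    R: float,
    center: tuple[int, int] = (32, 32),
    density_sd_frac: float = 0.25,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density Gaussian pseudo-random undersampling pattern.

    Exactly ``round(N / R)`` points are sampled: the fully sampled centre
    block plus points drawn without replacement with probability
    proportional to a centred 2-D Gaussian of sd ``density_sd_frac`` times
    the grid extent per dimension.
    """
    ny, nz = phase_shape
    if R < 1:
        raise ValueError("acceleration R must be >= 1")
    n_total = ny * nz
    budget = int(round(n_total / R))
    ys, zs = _center_block(phase_shape, center)
    center_area = center[0] * center[1]
    if budget < center_area:
        min_R = n_total / center_area
        raise ValueError(
            f"R={R} leaves a budget of {budget} samples, below the {center_area}-point "
            f"fully sampled centre; minimum feasible R is {min_R:.3f}"
        )
    mask = np.zeros(phase_shape, dtype=bool)
    mask[ys, zs] = True
    n_free = budget - center_area
    if n_free > 0:
        yy = (np.arange(ny) - (ny - 1) / 2.0) / (density_sd_frac * ny)
        zz = (np.arange(nz) - (nz - 1) / 2.0) / (density_sd_frac * nz)
        p = np.exp(-0.5 * (yy[:, None] ** 2 + zz[None, :] ** 2))
        p[mask] = 0.0
        flat = p.ravel()
        candidates = np.flatnonzero(flat > 0)
        if len(candidates) < n_free:
            # Gaussian tail underflow: admit every remaining point uniformly
            candidates = np.flatnonzero(~mask.ravel())
            flat = np.ones(mask.size)
        rng = np.random.default_rng(seed)
        probs = flat[candidates] / flat[candidates].sum()
        chosen = rng.choice(candidates, size=n_free, replace=False, p=probs)
        mask.ravel()[chosen] = True
    return SamplingMask(mask=mask, R=R, center_size=center, kind="cs", seed=seed)


def make_pi_mask(
    phase_shape: tuple[int, int],
    factors: tuple[int, int] = (2, 1),
    calib: tuple[int, int] = (32, 32),
) -> SamplingMask:
    """Uniform comb for autocalibrated parallel imaging plus a fully sampled
    calibration block."""
    fy, fz = factors
    if fy < 1 or fz < 1:
        raise ValueError("parallel-imaging factors must be >= 1")
    mask = np.zeros(phase_shape, dtype=bool)
    mask[::fy, ::fz] = True
    ys, zs = _center_block(phase_shape, calib)
    mask[ys, zs] = True
    R = mask.size / mask.sum()
    return SamplingMask(mask=mask, R=R, center_size=calib, kind="uniform_pi", pi_factors=(fy, fz))


def combine_masks(cs: SamplingMask, pi: SamplingMask) -> SamplingMask:
    """Elementwise AND of a CS and a parallel-imaging mask (sequential
    acquisition); effective acceleration is reported from the sampled count."""
    if cs.shape != pi.shape:
        raise ValueError(f"mask shapes differ: {cs.shape} vs {pi.shape}")
    mask = cs.mask & pi.mask
    return SamplingMask(
        mask=mask,
        R=mask.size / mask.sum(),
        center_size=cs.center_size,
        kind="combined",
        seed=cs.seed,
        pi_factors=pi.pi_factors,
        components={"cs": cs, "pi": pi},
    )


def encode(
    image: np.ndarray,
    sens,
    noise_sd: float = 0.0,
    seed: int = 0,
    voxel_mm: tuple[float, float, float] = (0.625, 0.625, 1.4),
) -> KSpaceData:
    """Fully sampled multi-coil encoding of a complex image volume.

    Per coil: orthonormal 3-D DFT of (sensitivity x image) plus i.i.d.
    complex Gaussian noise with standard deviation ``noise_sd`` per real and
    imaginary component of every k-space sample.
    """
    image = np.asarray(image)
    maps = sens.maps if hasattr(sens, "maps") else np.asarray(sens)
    if maps.ndim == 3:
        maps = maps[None]
    if maps.shape[1:] != image.shape:
        raise ValueError(f"sensitivity grid {maps.shape[1:]} != image grid {image.shape}")
    k = fft3c(maps * image[None])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k + noise_sd * (rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape))
    return KSpaceData(data=k, mask=None, noise_sd=noise_sd, voxel_mm=voxel_mm)


def apply_mask(k: KSpaceData, mask: SamplingMask) -> KSpaceData:
    """Zero the unsampled phase-encode points and record the mask.

    Sampled values are carried over bit-identically; applying a mask twice
    is the same as applying it once.
    """
    if mask.shape != k.grid_shape[1:]:
        raise ValueError(f"mask shape {mask.shape} != phase grid {k.grid_shape[1:]}")
    data = np.where(mask.mask[None, None, :, :], k.data, 0.0 + 0.0j)
    return KSpaceData(data=data, mask=mask, noise_sd=k.noise_sd, voxel_mm=k.voxel_mm)
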