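"""Render occupancy trajectories into TIRF-like image stacks.

Bound fluorophores sit at fixed positions along a straight DNA line in the
image.  Each unbleached dye contributes ``photons_per_dye`` expected
photons per frame, attenuated exponentially with distance along the DNA
(the DNA is tilted away from the coverslip, so evanescent-field excitation
decays toward the bead end).  Expected photons are blurred with a Gaussian
PSF, sampled from a Poisson distribution, multiplied by the camera gain,
and corrupted with Gaussian read noise plus a constant offset.  Output is
an unsigned 16-bit multi-page-TIFF-compatible stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .simulate import OccupancyTrajectory

__all__ = ["Optics", "render_stack", "write_stack", "read_stack"]


@dataclass(frozen=True)
class Optics:
    """Camera and illumination model for stack rendering.

    Parameters
    ----------
    shape
        Frame shape ``(ny, nx)`` in pixels.
    dna_start, dna_end
        ``(x, y)`` pixel coordinates of the DNA line's anchored end and
        bead end.  Binding sites are spread uniformly between them.
    psf_sigma_px
        Gaussian PSF standard deviation in pixels.
    penetration_decay_px
        Excitation attenuation length along the DNA, in pixels of distance
        from the anchored end (``inf`` disables attenuation).
    photons_per_dye
        Expected photons per unbleached dye per frame at the anchored end.
    background
        Constant camera offset, in counts.
    read_noise
        Gaussian read noise standard deviation, in counts.
    gain
        Multiplicative camera gain (counts per photon).
    """

    shape: tuple[int, int] = (48, 80)
    dna_start: tuple[float, float] = (8.0, 24.0)
    dna_end: tuple[float, float] = (72.0, 24.0)
    psf_sigma_px: float = 1.2
    penetration_decay_px: float = math.inf
    photons_per_dye: float = 20.0
    background: float = 100.0
    read_noise: float = 2.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        ny, nx = self.shape
        for x, y in (self.dna_start, self.dna_end):
            if not (0 <= x < nx and 0 <= y < ny):
                raise ValueError("DNA coordinates must lie inside the frame")
        if min(self.psf_sigma_px, self.photons_per_dye, self.gain) <= 0:
            raise ValueError("psf_sigma_px, photons_per_dye and gain must be positive")
        if self.penetration_decay_px <= 0:
            raise ValueError("penetration_decay_px must be positive")
        if self.read_noise < 0 or self.background < 0:
            raise ValueError("read_noise and background must be non-negative")


def site_positions(optics: Optics, n_sites: int) -> np.ndarray:
    """``(n_sites, 2)`` array of site ``(x, y)`` coordinates along the DNA line."""
    f = (np.arange(n_sites) + 0.5) / n_sites
    x0, y0 = optics.dna_start
    x1, y1 = optics.dna_end
    return np.column_stack([x0 + f * (x1 - x0), y0 + f * (y1 - y0)])


def excitation_weights(optics: Optics, n_sites: int) -> np.ndarray:
    """Excitation attenuation factor per site (1 at the anchored end)."""
    pos = site_positions(optics, n_sites)
    d = np.hypot(pos[:, 0] - optics.dna_start[0], pos[:, 1] - optics.dna_start[1])
    return np.exp(-d / optics.penetration_decay_px)


def _psf_matrix(optics: Optics, n_sites: int) -> np.ndarray:
    """(n_sites, ny*nx) matrix of unit-integral Gaussian PSFs at the site positions."""
    ny, nx = optics.shape
    pos = site_positions(optics, n_sites)
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    s2 = 2.0 * optics.psf_sigma_px ** 2
    mats = np.empty((n_sites, ny * nx))
    norm = 1.0 / (math.pi * s2)
    for i, (x, y) in enumerate(pos):
        g = norm * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / s2)
        mats[i] = g.ravel()
    return mats


def render_stack(traj: OccupancyTrajectory, optics: Optics,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None) -> np.ndarray:
    """Render a trajectory into a ``(n_frames, ny, nx)`` uint16 stack.

    Only TIRF-visible sites (``traj.visible``) emit.  Pixel values are
    ``Poisson(expected photons) * gain + N(0, read_noise) + background``,
    rounded and clipped to the 16-bit range.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ny, nx = optics.shape
    n_frames, n_sites = traj.dye_counts.shape

    psf = _psf_matrix(optics, n_sites)
    exc = excitation_weights(optics, n_sites) * traj.visible

    # expected photons per pixel: (frames, sites) @ (sites, pixels)
    weights = traj.dye_counts.astype(float) * exc[None, :] * optics.photons_per_dye
    expected = weights @ psf
    counts = rng.poisson(expected).astype(float) * optics.gain
    counts += rng.normal(0.0, optics.read_noise, size=counts.shape)
    counts += optics.background
    stack = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return stack.reshape(n_frames, ny, nx)


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a stack as a grayscale 16-bit multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as ``(n_frames, ny, nx)``."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack
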