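"""Synthetic HR-pQCT-like volumes of a porous cortical annulus.

A pore population is rasterized into an annular cortex cross-section
(values in mg HA/cm^3: matrix vBMD inside bone, ~0 in pores, marrow and
background), replicated along the scanner axis (pores are cylinders along
the bone axis), blurred with a Gaussian PSF and degraded with additive
noise.  The default isotropic voxel size of 60.7 um matches
second-generation HR-pQCT; at that resolution ~30 um Haversian canals are
unresolved (partial volume only) while pores larger than ~90 um appear as
segmentable voids.

Rasterization is done at sub-voxel resolution (supersampling) so that voxel
values carry the correct partial-volume fractions and the rasterized
porosity matches the analytic areal porosity of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pores import PorePopulation

__all__ = ["CTParams", "MicroCTVolume", "synthesize_microct"]


@dataclass(frozen=True)
class CTParams:
    """Scanner and phantom geometry for the synthetic volume."""

    voxel_um: float = 60.7
    outer_radius_mm: float = 6.0
    cortical_thickness_mm: float = 3.0
    n_slices: int = 24
    psf_sigma_um: float = 45.0  # in-plane Gaussian PSF (1 sigma)
    noise_sd: float = 25.0  # additive noise, mg HA/cm^3
    supersample: int = 4
    margin_mm: float = 0.5

    def __post_init__(self):
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        if self.psf_sigma_um < 0:
            raise ValueError("PSF width must be non-negative")


@dataclass
class MicroCTVolume:
    """Calibrated vBMD voxel grid (slice, y, x) with ground-truth bookkeeping."""

    data: np.ndarray  # (n_z, n_y, n_x), mg HA/cm^3
    voxel_um: float
    calibration: dict
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def synthesize_microct(
    pop: PorePopulation,
    ct_params: CTParams = CTParams(),
    seed: int | np.random.Generator = 0,
) -> MicroCTVolume:
    """Rasterize a pore population into an annular cortical volume.

    The population's slab (lateral x, depth z) is wrapped onto the annulus:
    x maps to arc length along the mid-cortical circumference, z to radial
    depth below the periosteal (outer) surface.  Pores deeper than the
    cortical thickness are dropped (and recorded in ``truth``).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = ct_params
    vox_mm = p.voxel_um * 1e-3
    half = p.outer_radius_mm + p.margin_mm
    n_xy = int(np.ceil(2 * half / vox_mm))
    if p.outer_radius_mm < vox_mm or p.cortical_thickness_mm < vox_mm:
        raise ValueError("phantom smaller than one voxel")

    ss = max(1, int(p.supersample))
    n_fine = n_xy * ss
    fine_mm = vox_mm / ss
    coords = (np.arange(n_fine) + 0.5) * fine_mm - half
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    rr = np.hypot(xx, yy)
    r_out = p.outer_radius_mm
    r_in = r_out - p.cortical_thickness_mm
    cortex = (rr <= r_out) & (rr >= r_in)

    # wrap slab onto the annulus: x -> arc angle at mid radius, z -> radial depth
    r_mid = (r_out + r_in) / 2.0
    keep = pop.centers[:, 1] <= p.cortical_thickness_mm
    theta = pop.centers[keep, 0] / r_mid
    rad = r_out - pop.centers[keep, 1]
    cx = rad * np.cos(theta)
    cy = rad * np.sin(theta)
    radii = pop.diameters_um[keep] * 1e-6 * 1e3 / 2.0  # mm

    pore_fine = np.zeros_like(cortex)
    for x0, y0, r0 in zip(cx, cy, radii):
        i0 = max(0, int((x0 - r0 + half) / fine_mm) - 1)
        i1 = min(n_fine, int((x0 + r0 + half) / fine_mm) + 2)
        j0 = max(0, int((y0 - r0 + half) / fine_mm) - 1)
        j1 = min(n_fine, int((y0 + r0 + half) / fine_mm) + 2)
        sub = (xx[j0:j1, i0:i1] - x0) ** 2 + (yy[j0:j1, i0:i1] - y0) ** 2 <= r0**2
        pore_fine[j0:j1, i0:i1] |= sub
    pore_fine &= cortex

    vbmd = pop.matrix.vbmd
    fine_img = np.where(cortex & ~pore_fine, vbmd, 0.0)
    # block-average the supersampled image -> partial-volume gray levels
    img = fine_img.reshape(n_xy, ss, n_xy, ss).mean(axis=(1, 3))
    cortex_frac = cortex.reshape(n_xy, ss, n_xy, ss).mean(axis=(1, 3))
    pore_frac = pore_fine.reshape(n_xy, ss, n_xy, ss).mean(axis=(1, 3))

    if p.psf_sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=p.psf_sigma_um / p.voxel_um)

    vol = np.repeat(img[None, :, :], p.n_slices, axis=0)
    if p.noise_sd > 0:
        vol = vol + rng.normal(0.0, p.noise_sd, size=vol.shape)

    cortex_area = float(cortex_frac.sum())
    raster_porosity = 100.0 * float(pore_frac.sum()) / cortex_area if cortex_area else 0.0
    resolved = pop.diameters_um[keep] >= 1.5 * p.voxel_um
    truth = {
        "matrix_vbmd": vbmd,
        "cortex_mask": cortex_frac > 0.5,
        "pore_mask": pore_frac > 0.5,
        "raster_porosity_pct": raster_porosity,
        "analytic_porosity_pct": _analytic_annulus_porosity(radii, r_in, r_out),
        "diameters_um": pop.diameters_um[keep].copy(),
        "resolved_mask": resolved,
        "inner_radius_mm": r_in,
        "outer_radius_mm": r_out,
    }
    calibration = {
        "units": "mg HA/cm^3",
        "matrix_vbmd": vbmd,
        "voxel_um": p.voxel_um,
        "psf_sigma_um": p.psf_sigma_um,
        "noise_sd": p.noise_sd,
    }
    return MicroCTVolume(data=vol, voxel_um=p.voxel_um, calibration=calibration, truth=truth)


def _analytic_annulus_porosity(radii_mm, r_in, r_out) -> float:
    area = np.pi * (r_out**2 - r_in**2)
    return 100.0 * float(np.sum(np.pi * np.asarray(radii_mm) ** 2)) / area
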