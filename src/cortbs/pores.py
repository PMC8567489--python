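"""Ground-truth cortical pore microstructures.

Pores are modelled as straight circular cylinders along the bone long axis
(2.5-D geometry): the morphometric quantity of interest is the pore diameter,
so out-of-plane tortuosity is ignored.  Cylinder cross-sections are placed in
the scan plane (lateral x, depth z) by dart throwing with a hard-core
rejection rule, and diameters are drawn from an asymmetric two-component
lognormal mixture: a Haversian baseline (median ~30 um) plus an optional
pathological tail of merged remodeling cavities reaching "giant" pore sizes
(>385 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DiameterMixtureParams",
    "MatrixProperties",
    "PoreFluidProperties",
    "PorePopulation",
    "sample_pore_population",
]


@dataclass(frozen=True)
class MatrixProperties:
    """Acoustic and densitometric properties of the mineralized matrix.

    Conventional values for human cortical bone; configurable because they
    are site- and subject-dependent.
    """

    sound_speed: float = 3800.0  # m/s
    density: float = 1.9  # g/cm^3
    vbmd: float = 1100.0  # mg HA/cm^3

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance in MRayl."""
        return self.sound_speed * self.density * 1e-3


@dataclass(frozen=True)
class PoreFluidProperties:
    """Properties of the fluid filling the pore space (marrow/soft tissue)."""

    sound_speed: float = 1500.0  # m/s
    density: float = 1.0  # g/cm^3

    @property
    def impedance(self) -> float:
        return self.sound_speed * self.density * 1e-3


@dataclass(frozen=True)
class DiameterMixtureParams:
    """Two-component lognormal mixture over pore diameters (um).

    ``tail_weight = 0`` degenerates to a single lognormal.  The baseline
    component represents normal Haversian canals; the tail component the
    enlarged, partially refilled remodeling cavities whose clustering
    produces giant pores.

    Parameters are on the natural-log scale of the diameter in micrometers,
    so ``exp(baseline_log_mean)`` is the baseline median diameter.
    """

    baseline_log_mean: float = float(np.log(30.0))
    baseline_log_sd: float = 0.35
    tail_weight: float = 0.0
    tail_log_mean: float = float(np.log(150.0))
    tail_log_sd: float = 0.45
    areal_density: float = 12.0  # pores / mm^2 of cross-section
    hard_core_um: float = 10.0  # minimum extra center spacing, um

    def __post_init__(self) -> None:
        if not 0.0 <= self.tail_weight <= 1.0:
            raise ValueError(f"tail_weight must be in [0, 1], got {self.tail_weight}")
        if self.baseline_log_sd <= 0 or self.tail_log_sd <= 0:
            raise ValueError("log-sd parameters must be positive")
        if self.areal_density <= 0:
            raise ValueError("areal_density must be positive")

    # -- distribution functions -------------------------------------------

    def _components(self):
        base = stats.lognorm(s=self.baseline_log_sd, scale=np.exp(self.baseline_log_mean))
        tail = stats.lognorm(s=self.tail_log_sd, scale=np.exp(self.tail_log_mean))
        return base, tail

    def pdf(self, d):
        base, tail = self._components()
        w = self.tail_weight
        return (1.0 - w) * base.pdf(d) + w * tail.pdf(d)

    def cdf(self, d):
        base, tail = self._components()
        w = self.tail_weight
        return (1.0 - w) * base.cdf(d) + w * tail.cdf(d)

    def ppf(self, q):
        """Mixture quantile by numerical inversion of the CDF."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        base, tail = self._components()
        lo = min(base.ppf(1e-12), tail.ppf(1e-12))
        hi = max(base.ppf(1.0 - 1e-12), tail.ppf(1.0 - 1e-12))
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            out[i] = optimize.brentq(lambda d: self.cdf(d) - qi, lo, hi)
        return out if out.size > 1 else float(out[0])

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        base, tail = self._components()
        pick_tail = rng.random(n) < self.tail_weight
        d = np.where(
            pick_tail,
            tail.rvs(size=n, random_state=rng),
            base.rvs(size=n, random_state=rng),
        )
        return d


@dataclass
class PorePopulation:
    """Cylindrical pores in a rectangular cortical slab.

    ``centers`` holds (x, z) positions in mm in the scan plane; the cylinder
    axis is perpendicular to that plane (the bone long axis).  ``slab_extent``
    is (x, y, z) in mm where y is the out-of-plane length.
    """

    slab_extent: tuple[float, float, float]
    centers: np.ndarray  # (n, 2) mm
    diameters_um: np.ndarray  # (n,)
    pore_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    matrix: MatrixProperties = field(default_factory=MatrixProperties)
    pore_fluid: PoreFluidProperties = field(default_factory=PoreFluidProperties)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float).reshape(-1, 2))
        self.diameters_um = np.asarray(self.diameters_um, dtype=float).ravel()
        if np.any(self.diameters_um <= 0):
            raise ValueError("all pore diameters must be positive")

    @property
    def n_pores(self) -> int:
        return int(self.diameters_um.size)

    @property
    def cross_section_area_mm2(self) -> float:
        return self.slab_extent[0] * self.slab_extent[2]

    def areal_porosity(self) -> float:
        """Analytic area fraction of pore cross-sections, in percent."""
        r_mm = self.diameters_um * 1e-3 / 2.0
        return 100.0 * float(np.sum(np.pi * r_mm**2)) / self.cross_section_area_mm2

    def areal_pore_density(self) -> float:
        """Pores per mm^2 of cross-section."""
        return self.n_pores / self.cross_section_area_mm2


class HardCoreError(RuntimeError):
    """Dart throwing could not satisfy the hard-core constraint."""


def sample_pore_population(
    params: DiameterMixtureParams,
    slab_extent: tuple[float, float, float] = (10.0, 5.0, 4.0),
    seed: int | np.random.Generator = 0,
    matrix: MatrixProperties | None = None,
    pore_fluid: PoreFluidProperties | None = None,
    max_attempts_per_pore: int = 10_000,
) -> PorePopulation:
    """Draw a pore population by dart throwing with hard-core rejection.

    The number of pores is ``areal_density * slab_x * slab_z`` (rounded).
    A candidate center is rejected when its distance to any accepted center
    is below ``max(hard_core, (d_i + d_j)/2)`` — the second term prevents
    geometric overlap so that the analytic areal porosity is additive.

    Raises
    ------
    HardCoreError
        if a pore cannot be placed within ``max_attempts_per_pore``
        rejections; the message names the areal density achieved so far.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sx, sy, sz = (float(v) for v in slab_extent)
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ValueError("slab extents must be positive")
    area = sx * sz
    n = int(round(params.areal_density * area))
    diam = np.sort(params.rvs(n, rng))[::-1]  # place big pores first
    rad_mm = diam * 1e-3 / 2.0
    hc_mm = params.hard_core_um * 1e-3

    centers = np.empty((n, 2))
    for i in range(n):
        for _ in range(max_attempts_per_pore):
            cand = rng.random(2) * (sx, sz)
            if i == 0:
                break
            dist = np.hypot(*(centers[:i] - cand).T)
            min_sep = np.maximum(hc_mm, rad_mm[:i] + rad_mm[i])
            if np.all(dist >= min_sep):
                break
        else:
            achieved = i / area
            raise HardCoreError(
                f"could not place pore {i + 1}/{n} after {max_attempts_per_pore} "
                f"attempts; achieved areal density {achieved:.2f}/mm^2"
            )
        centers[i] = cand

    # restore random order so diameters are not depth-sorted downstream
    perm = rng.permutation(n)
    return PorePopulation(
        slab_extent=(sx, sy, sz),
        centers=centers[perm],
        diameters_um=diam[perm],
        matrix=matrix or MatrixProperties(),
        pore_fluid=pore_fluid or PoreFluidProperties(),
    )


def baseline_only(median_um: float = 30.0, log_sd: float = 0.35, **kw) -> DiameterMixtureParams:
    """Convenience constructor for a single-lognormal (healthy) mixture."""
    return DiameterMixtureParams(
        baseline_log_mean=float(np.log(median_um)),
        baseline_log_sd=log_sd,
        tail_weight=0.0,
        **kw,
    )


def pathological(
    median_um: float = 30.0,
    log_sd: float = 0.35,
    tail_weight: float = 0.10,
    tail_median_um: float = 200.0,
    tail_log_sd: float = 0.45,
    **kw,
) -> DiameterMixtureParams:
    """Mixture with a giant-pore tail, emulating clustered BMU merging."""
    return DiameterMixtureParams(
        baseline_log_mean=float(np.log(median_um)),
        baseline_log_sd=log_sd,
        tail_weight=tail_weight,
        tail_log_mean=float(np.log(tail_median_um)),
        tail_log_sd=tail_log_sd,
        **kw,
    )
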