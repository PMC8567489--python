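"""Synthetic clinical cohorts of postmenopausal women with and without
fragility fractures.

Generates per-subject tables with the variable blocks of the study design:
anthropometrics and age, DXA aBMD/T-scores, cortical-backscatter parameters
(attenuation intercept/slope and six pore-size-distribution descriptors) and
custom HR-pQCT cortical parameters.  Group means and SDs default to the
fractured (Fx) / non-fractured (nFx) values of the clinical cohort tables;
variables are drawn from per-group multivariate normals with a configurable
block correlation (default 0.3 within a modality, 0 across).

BMI is computed from the drawn height and weight (never drawn
independently); a configurable fraction of spine T-scores is set missing,
mirroring degenerative lumbar changes that preclude a valid spine scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GroupSpec", "CohortSpec", "generate_cohort", "VARIABLE_BLOCKS"]

#: variable -> modality block (correlation structure is block diagonal)
VARIABLE_BLOCKS = {
    "Age": "anthropometric",
    "Height": "anthropometric",
    "Weight": "anthropometric",
    "aBMD_Femur_Total": "dxa",
    "aBMD_Femur_Neck": "dxa",
    "aBMD_Spine": "dxa",
    "T_score_Femur": "dxa",
    "T_score_Spine": "dxa",
    "T_score_Total": "dxa",
    "Ct.alpha0": "cortbs",
    "Ct.alphaf": "cortbs",
    "Ct.Po.Dm.D_Peak": "cortbs",
    "Ct.Po.Dm.D_Q10": "cortbs",
    "Ct.Po.Dm.D_Q90": "cortbs",
    "Ct.Po.Dm.D_FWHM": "cortbs",
    "Ct.Po.Dm.D_FWHM_min": "cortbs",
    "Ct.Po.Dm.D_FWHM_max": "cortbs",
    "Ct.Th_ROI": "hrpqct",
    "Ct.Po_BH_ROI": "hrpqct",
    "Ct.Po.D_SD_ROI": "hrpqct",
    "Ct.Po.D_skewness_Full": "hrpqct",
    "Ct.Po.D_kurtosis_Full": "hrpqct",
    "Ct.Po.Dm.D_Mean_ROI": "hrpqct",
    "Ct.Po.Dm.D_Q90_ROI": "hrpqct",
}

# (Fx mean, Fx SD, nFx mean, nFx SD) per variable — clinical cohort defaults
_DEFAULTS = {
    "Age": (69.2, 7.5, 70.2, 6.3),
    "Height": (165.0, 8.1, 163.1, 7.2),
    "Weight": (62.4, 9.1, 61.0, 6.7),
    "aBMD_Femur_Total": (0.786, 0.072, 0.808, 0.076),
    "aBMD_Femur_Neck": (0.793, 0.081, 0.805, 0.072),
    "aBMD_Spine": (0.904, 0.130, 0.950, 0.110),
    "T_score_Femur": (-1.93, 0.86, -1.83, 0.55),
    "T_score_Spine": (-2.28, 1.04, -1.90, 0.90),
    "T_score_Total": (-2.41, 0.72, -2.14, 0.66),
    "Ct.alpha0": (2.34, 0.40, 1.96, 0.48),
    "Ct.alphaf": (0.11, 0.06, 0.16, 0.06),
    "Ct.Po.Dm.D_Peak": (38.6, 5.6, 36.6, 7.1),
    "Ct.Po.Dm.D_Q10": (29.9, 4.7, 28.8, 5.8),
    "Ct.Po.Dm.D_Q90": (48.7, 7.1, 45.3, 8.8),
    "Ct.Po.Dm.D_FWHM": (16.5, 3.5, 14.9, 2.9),
    "Ct.Po.Dm.D_FWHM_min": (31.1, 5.0, 29.5, 5.8),
    "Ct.Po.Dm.D_FWHM_max": (47.6, 6.8, 44.4, 8.6),
    "Ct.Th_ROI": (2.7, 0.8, 2.7, 0.6),
    "Ct.Po_BH_ROI": (5.4, 2.3, 4.5, 2.2),
    "Ct.Po.D_SD_ROI": (6.0, 1.2, 5.4, 1.1),
    "Ct.Po.D_skewness_Full": (0.98, 0.37, 1.35, 0.51),
    "Ct.Po.D_kurtosis_Full": (5.1, 1.5, 7.3, 3.4),
    "Ct.Po.Dm.D_Mean_ROI": (128.0, 20.0, 120.0, 15.0),
    "Ct.Po.Dm.D_Q90_ROI": (230.0, 54.0, 205.0, 35.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """Mean/SD per variable for one group."""

    means: dict
    sds: dict

    @classmethod
    def default(cls, group: str) -> "GroupSpec":
        if group not in ("Fx", "nFx"):
            raise ValueError("group must be 'Fx' or 'nFx'")
        i = 0 if group == "Fx" else 2
        return cls(
            means={k: v[i] for k, v in _DEFAULTS.items()},
            sds={k: v[i + 1] for k, v in _DEFAULTS.items()},
        )

    @classmethod
    def null(cls) -> "GroupSpec":
        """Group-average spec (no group effect) for null-calibration runs."""
        return cls(
            means={k: (v[0] + v[2]) / 2 for k, v in _DEFAULTS.items()},
            sds={k: (v[1] + v[3]) / 2 for k, v in _DEFAULTS.items()},
        )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and correlation structure."""

    fx: GroupSpec = field(default_factory=lambda: GroupSpec.default("Fx"))
    nfx: GroupSpec = field(default_factory=lambda: GroupSpec.default("nFx"))
    n_fx: int = 29
    n_nfx: int = 26
    n_vertebral: int = 18
    n_other: int = 21
    within_block_corr: float = 0.3
    spine_missing_frac: float = 0.15


def _block_correlation(variables, rho) -> np.ndarray:
    blocks = [VARIABLE_BLOCKS.get(v, "other") for v in variables]
    n = len(variables)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if blocks[i] == blocks[j]:
                corr[i, j] = corr[j, i] = rho
    return corr


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a cohort table with Fx/nFx groups and fracture-subtype flags.

    Returns a DataFrame with one row per subject: ``id``, ``group``
    (Fx/nFx), ``fracture_vertebral``/``fracture_other`` flags, BMI computed
    from height and weight, and every configured clinical variable.  Spine
    T-scores are set missing (NaN, flagged in ``T_score_Spine_missing``) at
    the configured rate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    variables = list(_DEFAULTS)
    corr = _block_correlation(variables, spec.within_block_corr)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"correlation block (rho={spec.within_block_corr}) is not positive definite"
        ) from err

    frames = []
    for group, gs, n in (("Fx", spec.fx, spec.n_fx), ("nFx", spec.nfx, spec.n_nfx)):
        missing = [v for v in variables if v not in gs.means or v not in gs.sds]
        if missing:
            raise ValueError(f"group {group} spec missing variables: {missing}")
        z = rng.standard_normal((n, len(variables))) @ chol.T
        mu = np.array([gs.means[v] for v in variables])
        sd = np.array([gs.sds[v] for v in variables])
        df = pd.DataFrame(z * sd + mu, columns=variables)
        df.insert(0, "group", group)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"S{i + 1:03d}" for i in range(len(out))])

    out["BMI"] = out["Weight"] / (out["Height"] / 100.0) ** 2

    # fracture subtype flags among the Fx group; overlap = n_v + n_o - n_fx
    n_v, n_o, n_fx = spec.n_vertebral, spec.n_other, spec.n_fx
    if not (0 <= n_v <= n_fx and 0 <= n_o <= n_fx and n_v + n_o >= n_fx):
        raise ValueError("subtype counts incompatible with the Fx group size")
    vert = np.zeros(len(out), dtype=bool)
    other = np.zeros(len(out), dtype=bool)
    fx_idx = np.flatnonzero((out["group"] == "Fx").to_numpy())
    perm = rng.permutation(fx_idx)
    n_both = n_v + n_o - n_fx
    vert[perm[: n_v]] = True
    other[perm[n_v - n_both : n_v - n_both + n_o]] = True
    out["fracture_vertebral"] = vert
    out["fracture_other"] = other

    miss = rng.random(len(out)) < spec.spine_missing_frac
    out["T_score_Spine_missing"] = miss
    out.loc[miss, "T_score_Spine"] = np.nan
    return out
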