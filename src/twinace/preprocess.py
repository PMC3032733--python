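"""Phenotype preprocessing: standardization, age/sex correction, composites,
and residualized ("covariate-free") achievement scores.

All regressions are ordinary least squares over individual twin observations
pooled across zygosity groups; within-pair dependence is deliberately ignored
at this stage, as is conventional when preparing twin phenotypes.  Residual
traits are re-standardized so downstream variance components are proportions
of the corrected trait's variance.

Standardization uses the population SD convention (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateScaleError, InsufficientDataError, RankDeficiencyError
from .sim import TwinDataset

__all__ = [
    "CorrectionSpec",
    "standardize",
    "correct_age_sex",
    "make_composite",
    "residualize",
]


@dataclass(frozen=True)
class CorrectionSpec:
    """Residualize ``outcome`` on ``covariates``; store result as ``label``."""

    outcome: str
    covariates: tuple[str, ...]
    label: str

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.covariates:
            raise ConfigError("at least one covariate is required")
        if self.outcome in self.covariates:
            raise ConfigError(f"outcome {self.outcome!r} cannot be its own covariate")

    def validate(self, data: TwinDataset) -> None:
        for name in (self.outcome, *self.covariates):
            if name not in data.traits:
                raise ConfigError(f"trait {name!r} not present in dataset")


def _pair_values(data: TwinDataset, trait: str) -> tuple[np.ndarray, np.ndarray]:
    return (
        data.df[f"{trait}_t1"].to_numpy(dtype=float),
        data.df[f"{trait}_t2"].to_numpy(dtype=float),
    )


def _zscore(v1: np.ndarray, v2: np.ndarray, trait: str) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.concatenate([v1, v2])
    obs = pooled[~np.isnan(pooled)]
    if obs.size < 2:
        raise InsufficientDataError(f"trait {trait!r} has fewer than 2 observations")
    mu = obs.mean()
    sd = obs.std()  # population convention
    if sd < 1e-12:
        raise DegenerateScaleError(f"trait {trait!r} has (numerically) zero variance")
    return (v1 - mu) / sd, (v2 - mu) / sd


def standardize(data: TwinDataset, traits=None) -> TwinDataset:
    """Scale each trait to mean 0, SD 1 over all non-missing twin observations."""
    traits = data.traits if traits is None else tuple(traits)
    out = data
    for t in traits:
        v1, v2 = _pair_values(out, t)
        z1, z2 = _zscore(v1, v2, t)
        out = out.with_trait(t, z1, z2)
    return out


def _ols_residuals(y: np.ndarray, x: np.ndarray, context: str) -> np.ndarray:
    """Residuals of y on [1, x] over rows where everything is observed;
    NaN where y or any covariate is missing."""
    design = np.column_stack([np.ones(len(y)), x])
    ok = ~np.isnan(y) & ~np.isnan(design).any(axis=1)
    n_ok = int(ok.sum())
    if n_ok < design.shape[1] + 1:
        raise InsufficientDataError(
            f"{context}: only {n_ok} complete observations for {design.shape[1]} coefficients"
        )
    beta, _, rank, _ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
    if rank < design.shape[1]:
        raise RankDeficiencyError(f"{context}: collinear covariates (rank {rank})")
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - design[ok] @ beta
    return resid


def correct_age_sex(data: TwinDataset, traits=None) -> TwinDataset:
    """Replace each trait by the standardized residual of its regression on
    age and sex (coded 0/1) over individual twin observations."""
    traits = data.traits if traits is None else tuple(traits)
    age = data.df["age"].to_numpy(dtype=float)
    sex = {
        1: (data.df["sex_t1"] == "M").to_numpy(dtype=float),
        2: (data.df["sex_t2"] == "M").to_numpy(dtype=float),
    }
    out = data
    for t in traits:
        v1, v2 = _pair_values(out, t)
        n = len(v1)
        y = np.concatenate([v1, v2])
        x = np.column_stack(
            [np.concatenate([age, age]), np.concatenate([sex[1], sex[2]])]
        )
        resid = _ols_residuals(y, x, f"age/sex correction of {t!r}")
        z1, z2 = _zscore(resid[:n], resid[n:], t)
        out = out.with_trait(t, z1, z2)
    return out


def make_composite(data: TwinDataset, subscale_names, label: str) -> TwinDataset:
    """New trait = mean of the non-missing subscales per twin, standardized.

    A twin missing every subscale is missing the composite; otherwise the mean
    of the observed subscales is used (maximizing N rather than complete-case).
    """
    subscale_names = tuple(subscale_names)
    if not subscale_names:
        raise ConfigError("no subscales listed for composite")
    for s in subscale_names:
        if s not in data.traits:
            raise ConfigError(f"subscale {s!r} not present in dataset")
    parts = []
    for twin in (1, 2):
        block = data.df[[f"{s}_t{twin}" for s in subscale_names]].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            parts.append(np.nanmean(block, axis=1))
    z1, z2 = _zscore(parts[0], parts[1], label)
    return data.with_trait(label, z1, z2)


def residualize(data: TwinDataset, spec: CorrectionSpec) -> TwinDataset:
    """Create ``spec.label`` = standardized residual of the outcome regressed
    on the covariates (complete cases); missing wherever any input is missing."""
    spec.validate(data)
    v1, v2 = _pair_values(data, spec.outcome)
    n = len(v1)
    y = np.concatenate([v1, v2])
    x = np.column_stack(
        [
            np.concatenate([data.df[f"{c}_t1"].to_numpy(dtype=float),
                            data.df[f"{c}_t2"].to_numpy(dtype=float)])
            for c in spec.covariates
        ]
    )
    resid = _ols_residuals(y, x, f"residualization of {spec.outcome!r}")
    try:
        z1, z2 = _zscore(resid[:n], resid[n:], spec.label)
    except DegenerateScaleError:
        raise DegenerateScaleError(
            f"residual of {spec.outcome!r} on {list(spec.covariates)} has zero "
            "variance: outcome is fully explained by the covariates"
        )
    return data.with_trait(spec.label, z1, z2)
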