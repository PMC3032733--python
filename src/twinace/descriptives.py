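"""Descriptive twin statistics: intraclass correlations, Falconer ACE
estimates, and the sex-by-zygosity ANOVA on one randomly selected twin.

The Falconer estimators are the classical moment formulas: heritability is
twice the MZ-DZ correlation difference, shared environment is the MZ
correlation net of heritability, and non-shared environment is whatever MZ
co-twins do not share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import InsufficientDataError
from .sim import TwinDataset

__all__ = [
    "ICCResult",
    "FalconerEstimate",
    "intraclass_correlation",
    "double_entry_correlation",
    "falconer",
    "anova_sex_zygosity",
]


@dataclass(frozen=True)
class ICCResult:
    trait: str
    zygosity: str
    icc: float
    n_pairs: int

    def __post_init__(self):
        if not -1.0 <= self.icc <= 1.0 + 1e-12:
            raise ValueError(f"ICC out of range: {self.icc}")


@dataclass(frozen=True)
class FalconerEstimate:
    """Raw Falconer arithmetic; components may fall outside [0, 1]."""

    trait: str
    A: float
    C: float
    E: float

    @property
    def out_of_bounds(self) -> bool:
        return any(v < 0 or v > 1 for v in (self.A, self.C, self.E))


def _complete_pairs(data: TwinDataset, trait: str, zygosity: str) -> np.ndarray:
    x = data.pairs(trait, zygosity)
    return x[~np.isnan(x).any(axis=1)]


def intraclass_correlation(data: TwinDataset, trait: str, zygosity: str) -> ICCResult:
    """One-way random-effects ICC over unordered complete twin pairs.

    With pairs as groups of size 2: ICC = (MSB - MSW) / (MSB + MSW).
    """
    x = _complete_pairs(data, trait, zygosity)
    k = len(x)
    if k < 2:
        raise InsufficientDataError(
            f"trait {trait!r} has {k} complete {zygosity} pairs (need >= 2)"
        )
    pair_means = x.mean(axis=1)
    grand = x.mean()
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (k - 1)
    msw = np.sum((x[:, 0] - x[:, 1]) ** 2) / (2.0 * k)
    denom = msb + msw
    icc = 0.0 if denom == 0 else (msb - msw) / denom
    return ICCResult(trait=trait, zygosity=zygosity, icc=float(icc), n_pairs=k)


def double_entry_correlation(data: TwinDataset, trait: str, zygosity: str) -> float:
    """Pearson correlation over double-entered pairs (cross-check estimator)."""
    x = _complete_pairs(data, trait, zygosity)
    if len(x) < 2:
        raise InsufficientDataError(f"too few complete {zygosity} pairs for {trait!r}")
    a = np.concatenate([x[:, 0], x[:, 1]])
    b = np.concatenate([x[:, 1], x[:, 0]])
    return float(np.corrcoef(a, b)[0, 1])


def falconer(rmz: float, rdz: float, trait: str = "") -> FalconerEstimate:
    """Moment ACE estimates from MZ/DZ twin correlations.

    A = 2(rMZ - rDZ); C = rMZ - A; E = 1 - rMZ.  No truncation is applied:
    negative components are reported as-is (``out_of_bounds`` flags them).
    """
    for name, r in (("rmz", rmz), ("rdz", rdz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
    a = 2.0 * (rmz - rdz)
    return FalconerEstimate(trait=trait, A=a, C=rmz - a, E=1.0 - rmz)


def select_one_twin(data: TwinDataset, trait: str, seed: int) -> pd.DataFrame:
    """One randomly selected member of each pair (seeded), long format."""
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=data.n_pairs)
    df = data.df
    value = np.where(
        pick == 1,
        df[f"{trait}_t1"].to_numpy(dtype=float),
        df[f"{trait}_t2"].to_numpy(dtype=float),
    )
    sex = np.where(pick == 1, df["sex_t1"], df["sex_t2"])
    return pd.DataFrame(
        {"zygosity": df["zygosity"].to_numpy(), "sex": sex, "value": value}
    ).dropna(subset=["value"])


def anova_sex_zygosity(data: TwinDataset, trait: str, seed: int = 0) -> pd.DataFrame:
    """2x2 fixed-effects ANOVA (sex x zygosity) on one random twin per pair.

    Returns a table with p-values and eta-squared (effect SS / total SS) for
    the two main effects and the interaction.  Meant to be run on standardized
    values before age/sex correction.
    """
    long = select_one_twin(data, trait, seed)
    cells = long.groupby(["sex", "zygosity"], observed=True).size()
    for sex in ("F", "M"):
        for zyg in ("MZ", "DZ"):
            if cells.get((sex, zyg), 0) == 0:
                raise InsufficientDataError(f"empty design cell: sex={sex}, zygosity={zyg}")
    model = smf.ols("value ~ C(sex) * C(zygosity)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_total = float(np.sum((long["value"] - long["value"].mean()) ** 2))
    rows = []
    for label, term in (
        ("sex", "C(sex)"),
        ("zygosity", "C(zygosity)"),
        ("sex_x_zygosity", "C(sex):C(zygosity)"),
    ):
        rows.append(
            {
                "effect": label,
                "p": float(table.loc[term, "PR(>F)"]),
                "eta2": float(table.loc[term, "sum_sq"] / ss_total),
            }
        )
    out = pd.DataFrame(rows).set_index("effect")
    out.attrs["n"] = len(long)
    out.attrs["seed"] = seed
    return out


def icc_table(data: TwinDataset, traits) -> pd.DataFrame:
    """Per-trait MZ/DZ intraclass correlations with Falconer estimates."""
    rows = []
    for t in traits:
        rmz = intraclass_correlation(data, t, "MZ")
        rdz = intraclass_correlation(data, t, "DZ")
        est = falconer(rmz.icc, rdz.icc, trait=t)
        rows.append(
            {
                "trait": t,
                "rMZ": rmz.icc,
                "n_MZ": rmz.n_pairs,
                "rDZ": rdz.icc,
                "n_DZ": rdz.n_pairs,
                "falconer_A": est.A,
                "falconer_C": est.C,
                "falconer_E": est.E,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
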