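"""Bivariate and trivariate Cholesky ACE decompositions by FIML.

The Cholesky twin model assigns each trait, in a user-chosen causal order, a
triangular set of A/C/E factors: the first factor triple loads on every trait,
the second on every trait but the first, and so on.  The final factor triple
therefore captures genetic and environmental influences on the last trait that
are *independent* of all earlier traits — the model-based analogue of a
regression-residualized ("covariate-free") score.  Dividing those independent
components by their sum re-standardizes them to the covariate-free portion of
variance.

Estimation mirrors :mod:`twinace.ace_ml`: Gaussian FIML over the stacked
2n-trait twin-pair vector, grouped by missingness pattern, with per-trait free
means shared across co-twins and zygosity groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._likelihood import fiml_nll, multistart_minimize, pattern_stats
from .errors import (
    ConfigError,
    DegenerateScaleError,
    InsufficientDataError,
    ProfileError,
    UndefinedCorrelationError,
)
from .sim import CholeskyParams, TwinDataset

__all__ = ["CholeskyFit", "fit_cholesky", "restandardize", "genetic_correlation",
           "independent_ci"]

_CHI2_95_DF1 = 3.841458820694124
_COMPONENTS = ("A", "C", "E")


@dataclass
class CholeskyFit:
    """Fitted multivariate Cholesky ACE model.

    ``standardized`` holds squared standardized paths: for each trait (row),
    the share of its total variance contributed by each (component, factor)
    column; rows sum to 1.
    """

    traits: tuple[str, ...]
    params: CholeskyParams
    standardized: pd.DataFrame
    loglik: float
    n_pairs_mz: int
    n_pairs_dz: int
    means: np.ndarray
    multistart_spread: float = 0.0
    ci_independent: dict = field(default_factory=dict)
    ns_flags: dict = field(default_factory=dict)
    _stats: dict = field(default_factory=dict, repr=False)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def independent(self) -> tuple[float, float, float]:
        """Final factor's standardized contributions (A, C, E) to the final trait."""
        last = self.traits[-1]
        k = self.n_traits
        return tuple(
            float(self.standardized.loc[last, (comp, f"{comp}{k}")]) for comp in _COMPONENTS
        )

    @property
    def restandardized(self) -> tuple[float, float, float]:
        """Independent components re-standardized to the covariate-free variance."""
        return restandardize(self.independent)


def _tril_size(n: int) -> int:
    return n * (n + 1) // 2


def _unpack(x: np.ndarray, n: int):
    m = _tril_size(n)
    idx = np.tril_indices(n)
    mats = []
    for j in range(3):
        mat = np.zeros((n, n))
        mat[idx] = x[j * m : (j + 1) * m]
        mats.append(mat)
    means = x[3 * m : 3 * m + n]
    return mats[0], mats[1], mats[2], means


def _pack(la, lc, le, means) -> np.ndarray:
    idx = np.tril_indices(len(means))
    return np.concatenate([la[idx], lc[idx], le[idx], means])


def _implied_pair_cov(la, lc, le, zygosity: str) -> np.ndarray:
    sa, sc, se = la @ la.T, lc @ lc.T, le @ le.T
    within = sa + sc + se
    cross = sa + sc if zygosity == "MZ" else 0.5 * sa + sc
    return np.block([[within, cross], [cross.T, within]])


def _psd_clip(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    return (v * np.clip(w, floor, None)) @ v.T


def _moment_start(data: TwinDataset, traits) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments A/C/E covariance components (PSD-projected)."""
    k = len(traits)
    cross = {}
    within_blocks = []
    for zyg in ("MZ", "DZ"):
        x = data.stacked(traits, zyg)
        df = pd.DataFrame(x)
        # double entry symmetrizes the cross-twin block
        swapped = df[list(range(k, 2 * k)) + list(range(k))]
        swapped.columns = df.columns
        big = pd.concat([df, swapped], ignore_index=True).cov().to_numpy()
        within_blocks.append(big[:k, :k])
        cross[zyg] = (big[:k, k:] + big[k:, :k].T) / 2.0
    within = (within_blocks[0] + within_blocks[1]) / 2.0
    sa = _psd_clip(2.0 * (cross["MZ"] - cross["DZ"]))
    sc = _psd_clip(2.0 * cross["DZ"] - cross["MZ"])
    se = _psd_clip(within - cross["MZ"], floor=1e-4)
    return sa, sc, se


def _chol_start(sigma: np.ndarray, ridge: float) -> np.ndarray:
    return np.linalg.cholesky(_psd_clip(sigma) + ridge * np.eye(len(sigma)))


def _canonicalize(mat: np.ndarray) -> np.ndarray:
    """Flip column signs so diagonals are non-negative (leaves M M^T unchanged)."""
    out = mat.copy()
    for j in range(out.shape[1]):
        if out[j, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _group_stats(data: TwinDataset, traits, complete_pairs_only: bool):
    stats, counts = {}, {}
    for zyg in ("MZ", "DZ"):
        x = data.stacked(traits, zyg)
        if complete_pairs_only:
            x = x[~np.isnan(x).any(axis=1)]
        n_any = int((~np.isnan(x)).any(axis=1).sum())
        if n_any < 10:
            raise InsufficientDataError(
                f"{n_any} informative {zyg} pairs for {tuple(traits)} (need >= 10)"
            )
        stats[zyg] = pattern_stats(x)
        counts[zyg] = n_any
    return stats, counts


def _nll_from_stats(stats, n: int):
    from ._likelihood import PatternBundle

    bundles = {z: PatternBundle(stats[z]) for z in ("MZ", "DZ")}

    def nll(x):
        la, lc, le, means = _unpack(x, n)
        mu = np.concatenate([means, means])
        return fiml_nll(_implied_pair_cov(la, lc, le, "MZ"), mu, bundles["MZ"]) + fiml_nll(
            _implied_pair_cov(la, lc, le, "DZ"), mu, bundles["DZ"]
        )

    return nll


def _standardized_table(params: CholeskyParams) -> pd.DataFrame:
    n = params.n_traits
    total = np.diag(params.total_covariance)
    cols = [(comp, f"{comp}{k + 1}") for comp in _COMPONENTS for k in range(n)]
    table = np.zeros((n, 3 * n))
    for ci_, (comp, _) in enumerate(cols):
        k = ci_ % n
        lam = {"A": params.lambda_a, "C": params.lambda_c, "E": params.lambda_e}[comp]
        table[:, ci_] = lam[:, k] ** 2 / total
    return pd.DataFrame(
        table, index=list(params.trait_names), columns=pd.MultiIndex.from_tuples(cols)
    )


def fit_cholesky(
    data: TwinDataset,
    traits,
    ci: bool = False,
    complete_pairs_only: bool = False,
) -> CholeskyFit:
    """FIML Cholesky decomposition in the given causal trait order.

    Trait order matters for the path estimates (covariates first, outcome
    last) but not for the implied covariance matrix.  With ``ci=True``,
    profile-likelihood intervals are computed for the three independent
    (final-factor, final-trait) components and NS flags set where the lower
    bound is 0.
    """
    traits = tuple(traits)
    if len(traits) < 2:
        raise ConfigError("fit_cholesky needs at least 2 traits")
    for t in traits:
        if t not in data.traits:
            raise ConfigError(f"trait {t!r} not present in dataset")
    n = len(traits)
    stats, counts = _group_stats(data, traits, complete_pairs_only)
    nll = _nll_from_stats(stats, n)

    sa, sc, se = _moment_start(data, traits)
    means0 = np.array(
        [np.nanmean(data.pairs(t)) for t in traits]
    )
    la0, lc0, le0 = _chol_start(sa, 1e-3), _chol_start(sc, 1e-3), _chol_start(se, 1e-3)
    within = sa + sc + se
    generic = _chol_start(within / 3.0, 1e-3)
    starts = [
        _pack(la0, lc0, le0, means0),
        _pack(generic, generic, generic, means0),
        _pack(1.1 * la0, 0.8 * lc0, le0, means0),
    ]
    best, spread = multistart_minimize(nll, starts)
    la, lc, le, means = _unpack(best.x, n)
    la, lc, le = _canonicalize(la), _canonicalize(lc), _canonicalize(le)
    # guard the E diagonal so CholeskyParams validation passes
    for j in range(n):
        if le[j, j] <= 0:
            le[j, j] = 1e-8
    params = CholeskyParams(lambda_a=la, lambda_c=lc, lambda_e=le, trait_names=traits)
    fit = CholeskyFit(
        traits=traits,
        params=params,
        standardized=_standardized_table(params),
        loglik=-best.fun,
        n_pairs_mz=counts["MZ"],
        n_pairs_dz=counts["DZ"],
        means=means,
        multistart_spread=float(spread),
        _stats={"patterns": stats},
    )
    if ci:
        for comp in _COMPONENTS:
            lo, hi = independent_ci(fit, comp)
            fit.ci_independent[comp] = (lo, hi)
            fit.ns_flags[comp] = lo <= 1e-9
    return fit


def restandardize(independent) -> tuple[float, float, float]:
    """Divide the final-factor components by their sum (output sums to 1)."""
    a, c, e = (float(v) for v in independent)
    for v in (a, c, e):
        if v < -1e-9:
            raise ValueError(f"independent components must be non-negative, got {independent}")
    total = a + c + e
    if total <= 1e-12:
        raise DegenerateScaleError(
            "independent variance is zero: the outcome is fully explained by the covariates"
        )
    return (a / total, c / total, e / total)


def genetic_correlation(fit, trait_i: str, trait_j: str) -> float:
    """Genetic correlation r_g between two traits of a fitted (or specified) model.

    r_g = Sigma_A[i,j] / sqrt(Sigma_A[i,i] * Sigma_A[j,j]).
    """
    params = fit.params if isinstance(fit, CholeskyFit) else fit
    names = list(params.trait_names)
    i, j = names.index(trait_i), names.index(trait_j)
    sa = params.sigma_a
    if sa[i, i] <= 1e-12 or sa[j, j] <= 1e-12:
        raise UndefinedCorrelationError(
            f"zero genetic variance in {trait_i if sa[i, i] <= 1e-12 else trait_j!r}"
        )
    return float(sa[i, j] / np.sqrt(sa[i, i] * sa[j, j]))


def _constrained_profile_nll(fit: CholeskyFit, component: str, t: float) -> float:
    """Min negative log-likelihood subject to the independent component == t."""
    n = fit.n_traits
    stats = fit._stats["patterns"]
    nll = _nll_from_stats(stats, n)
    attr = {"A": "lambda_a", "C": "lambda_c", "E": "lambda_e"}[component]

    def constraint(x):
        la, lc, le, _ = _unpack(x, n)
        total = (la @ la.T + lc @ lc.T + le @ le.T)[n - 1, n - 1]
        lam = {"lambda_a": la, "lambda_c": lc, "lambda_e": le}[attr]
        return lam[n - 1, n - 1] ** 2 / total - t

    x0 = _pack(fit.params.lambda_a, fit.params.lambda_c, fit.params.lambda_e, fit.means)
    res = optimize.minimize(
        nll,
        x0,
        method="SLSQP",
        constraints=[{"type": "eq", "fun": constraint}],
        options={"maxiter": 500, "ftol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise ProfileError(f"constrained profile failed at {component}={t}")
    return float(res.fun)


def independent_ci(fit: CholeskyFit, component: str, level: float = 0.95):
    """Profile-likelihood CI for one independent (final-factor) component."""
    from scipy.stats import chi2

    crit = chi2.ppf(level, 1) if level != 0.95 else _CHI2_95_DF1
    t_hat = dict(zip(_COMPONENTS, fit.independent))[component]
    nll_hat = -fit.loglik

    def lr(t):
        return 2.0 * (_constrained_profile_nll(fit, component, t) - nll_hat)

    def solve(edge: float) -> float:
        t_in = t_hat
        for frac in (0.5, 0.8, 0.95, 1.0):
            t_out = t_hat + (edge - t_hat) * frac
            val = lr(t_out)
            if val >= crit:
                return float(
                    optimize.brentq(
                        lambda u: lr(u) - crit, min(t_in, t_out), max(t_in, t_out), xtol=1e-4
                    )
                )
            t_in = t_out
        return edge

    lo, hi = solve(0.0), solve(1.0)
    return (max(0.0, min(lo, t_hat)), min(1.0, max(hi, t_hat)))
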