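"""Univariate ACE variance decomposition by full-information maximum likelihood.

The model is the standard biometric twin model: phenotype pairs are bivariate
normal with expected covariance

    MZ: [[a^2+c^2+e^2, a^2+c^2  ], [a^2+c^2,   a^2+c^2+e^2]]
    DZ: [[a^2+c^2+e^2, a^2/2+c^2], [a^2/2+c^2, a^2+c^2+e^2]]

estimated in path-coefficient form (a, c, e), which keeps the implied variance
components non-negative.  A single free mean is shared by co-twins and
zygosity groups (the data are pre-standardized residuals).  Pairs with one
missing twin contribute their marginal (univariate) likelihood.

Confidence intervals are profile-likelihood intervals on the standardized
proportions A = a^2/V etc., using the chi-square(1) 95% cutoff 3.841.
A lower bound at exactly 0 marks the component non-significant (NS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._likelihood import fiml_nll, multistart_minimize, pattern_stats
from .errors import InsufficientDataError, ProfileError
from .sim import TwinDataset

__all__ = ["VarianceComponents", "fit_ace", "profile_ci", "compare_submodels"]

_CHI2_95_DF1 = 3.841458820694124  # scipy.stats.chi2.ppf(0.95, 1)

_STARTS = (
    (0.6, 0.4, 0.5, 0.0),
    (0.3, 0.3, 0.8, 0.0),
    (0.75, 0.1, 0.55, 0.0),
    (0.1, 0.6, 0.7, 0.0),
)


@dataclass
class VarianceComponents:
    """Standardized ACE proportions for one trait, with optional profile CIs."""

    trait: str
    A: float
    C: float
    E: float
    loglik: float
    n_pairs_mz: int
    n_pairs_dz: int
    ci_A: tuple[float, float] | None = None
    ci_C: tuple[float, float] | None = None
    ci_E: tuple[float, float] | None = None
    ns_flags: dict = field(default_factory=dict)
    mean: float = 0.0
    total_variance: float = 1.0
    multistart_spread: float = 0.0
    _stats: dict = field(default_factory=dict, repr=False)

    def proportions(self) -> tuple[float, float, float]:
        return (self.A, self.C, self.E)


def _group_stats(data: TwinDataset, trait: str, complete_pairs_only: bool):
    stats = {}
    counts = {}
    for zyg in ("MZ", "DZ"):
        x = data.pairs(trait, zyg)
        if complete_pairs_only:
            x = x[~np.isnan(x).any(axis=1)]
        n_any = int((~np.isnan(x)).any(axis=1).sum())
        if n_any < 10:
            raise InsufficientDataError(
                f"trait {trait!r}: {n_any} informative {zyg} pairs (need >= 10)"
            )
        stats[zyg] = pattern_stats(x)
        counts[zyg] = n_any
    return stats, counts


def _implied(a: float, c: float, e: float):
    v = a * a + c * c + e * e
    mz = np.array([[v, a * a + c * c], [a * a + c * c, v]])
    dz = np.array([[v, 0.5 * a * a + c * c], [0.5 * a * a + c * c, v]])
    return mz, dz


def _nll_from_stats(stats) -> callable:
    from ._likelihood import PatternBundle

    bundles = {z: PatternBundle(stats[z]) for z in ("MZ", "DZ")}

    def nll(x):
        a, c, e, mu = x
        mz, dz = _implied(a, c, e)
        m = np.array([mu, mu])
        return fiml_nll(mz, m, bundles["MZ"]) + fiml_nll(dz, m, bundles["DZ"])

    return nll


def fit_ace(
    data: TwinDataset,
    trait: str,
    ci: bool = True,
    complete_pairs_only: bool = False,
    fixed: dict | None = None,
) -> VarianceComponents:
    """FIML fit of the univariate ACE model; proportions sum to 1.

    ``fixed`` may pin paths at zero, e.g. ``{"c": 0.0}`` for the AE submodel.
    Deterministic: the optimizer runs from a fixed set of starting points.
    """
    stats, counts = _group_stats(data, trait, complete_pairs_only)
    fixed = dict(fixed or {})
    free = [p for p in ("a", "c", "e") if p not in fixed]
    base_nll = _nll_from_stats(stats)

    def expand(x):
        vals = dict(zip(free, x[: len(free)]))
        vals.update(fixed)
        return np.array([vals["a"], vals["c"], vals["e"], x[-1]])

    starts = [
        tuple(s[("a", "c", "e").index(p)] for p in free) + (s[3],) for s in _STARTS
    ]
    best, spread = multistart_minimize(lambda x: base_nll(expand(x)), starts)
    a, c, e, mu = expand(best.x)
    a, c, e = abs(a), abs(c), abs(e)
    v = a * a + c * c + e * e
    result = VarianceComponents(
        trait=trait,
        A=a * a / v,
        C=c * c / v,
        E=e * e / v,
        loglik=-best.fun,
        n_pairs_mz=counts["MZ"],
        n_pairs_dz=counts["DZ"],
        mean=float(mu),
        total_variance=float(v),
        multistart_spread=float(spread),
        _stats={"patterns": stats, "fixed": fixed},
    )
    if ci:
        for comp in ("A", "C", "E"):
            if ("a", "c", "e")[("A", "C", "E").index(comp)] in fixed:
                continue
            lo, hi = profile_ci(result, comp)
            setattr(result, f"ci_{comp}", (lo, hi))
            result.ns_flags[comp] = lo <= 1e-9
    return result


def _profile_nll(fit: VarianceComponents, component: str, t: float) -> float:
    """Minimized negative log-likelihood with the named proportion fixed at t.

    Parameterization: total variance V > 0 and the share s of one remaining
    component, so the three variance components are (t*V, s*V, (1-t-s)*V)
    arranged by component.
    """
    stats = fit._stats["patterns"]
    nll4 = _nll_from_stats(stats)
    order = {"A": (0, 1, 2), "C": (1, 0, 2), "E": (2, 0, 1)}[component]

    def nll(x):
        v, s, mu = x
        props = np.empty(3)
        props[order[0]] = t
        props[order[1]] = s * (1.0 - t)
        props[order[2]] = (1.0 - s) * (1.0 - t)
        a2, c2, e2 = props * v
        if e2 <= 0 and component != "E":
            e2 = max(e2, 1e-12)
        return nll4(np.array([np.sqrt(a2), np.sqrt(c2), np.sqrt(max(e2, 0.0)), mu]))

    v0 = fit.total_variance
    props = {"A": fit.A, "C": fit.C, "E": fit.E}
    rest = [p for p in ("A", "C", "E") if p != component]
    denom = props[rest[0]] + props[rest[1]]
    s0 = 0.5 if denom <= 0 else props[rest[0]] / denom
    starts = [(v0, min(max(s0, 0.02), 0.98), fit.mean), (v0, 0.5, fit.mean)]
    bounds = [(1e-8, None), (0.0, 1.0), (None, None)]
    best, _ = multistart_minimize(nll, starts, bounds=bounds)
    return float(best.fun)


def profile_ci(fit: VarianceComponents, component: str, level: float = 0.95):
    """Profile-likelihood interval for one standardized proportion.

    Bounds solve 2*(loglik_max - loglik_profile(t)) = chi2_{1,level}, clipped
    to [0, 1].  A lower bound of exactly 0 means the component could be dropped
    (NS at the complementary alpha).
    """
    if component not in ("A", "C", "E"):
        raise ValueError("component must be 'A', 'C' or 'E'")
    from scipy.stats import chi2

    crit = chi2.ppf(level, 1) if level != 0.95 else _CHI2_95_DF1
    nll_hat = -fit.loglik
    t_hat = {"A": fit.A, "C": fit.C, "E": fit.E}[component]

    def lr(t):
        return 2.0 * (_profile_nll(fit, component, t) - nll_hat)

    def solve(side: str) -> float:
        edge = 0.0 if side == "lower" else 1.0
        # walk from the estimate toward the edge until the LR crosses crit
        t_in = t_hat
        for frac in (0.5, 0.8, 0.95, 1.0):
            t_out = t_hat + (edge - t_hat) * frac
            val = lr(t_out)
            if val >= crit:
                try:
                    return float(
                        optimize.brentq(lambda u: lr(u) - crit, min(t_in, t_out),
                                        max(t_in, t_out), xtol=1e-5)
                    )
                except ValueError as exc:  # bracket lost to numeric noise
                    raise ProfileError(
                        f"profile bracket failed for {component} ({side}): {exc}; "
                        f"widest bracket [{min(t_in, t_out):.4f}, {max(t_in, t_out):.4f}] "
                        f"with LR {val:.3f} vs cutoff {crit:.3f}"
                    )
            t_in = t_out
        return edge  # LR never reaches the cutoff before the boundary

    lo = solve("lower")
    hi = solve("upper")
    lo, hi = max(0.0, min(lo, t_hat)), min(1.0, max(hi, t_hat))
    return (lo, hi)


def compare_submodels(data: TwinDataset, trait: str, complete_pairs_only: bool = False):
    """Fit ACE plus the nested AE / CE / E submodels; likelihood-ratio table.

    Returns a list of dicts with the submodel estimates, the LR statistic
    versus the full ACE model, and its degrees of freedom (number of dropped
    paths).  Boundary caveat: under a true zero component the LR statistic is
    a chi-square mixture, so nominal chi-square p-values are conservative.
    """
    full = fit_ace(data, trait, ci=False, complete_pairs_only=complete_pairs_only)
    rows = [
        {"model": "ACE", "A": full.A, "C": full.C, "E": full.E,
         "loglik": full.loglik, "lr": 0.0, "df": 0}
    ]
    for name, fixed in (("AE", {"c": 0.0}), ("CE", {"a": 0.0}),
                        ("E", {"a": 0.0, "c": 0.0})):
        sub = fit_ace(data, trait, ci=False, complete_pairs_only=complete_pairs_only,
                      fixed=fixed)
        rows.append(
            {"model": name, "A": sub.A, "C": sub.C, "E": sub.E,
             "loglik": sub.loglik,
             "lr": max(0.0, 2.0 * (full.loglik - sub.loglik)),
             "df": len(fixed)}
        )
    return rows
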