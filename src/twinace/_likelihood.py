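"""Shared full-information maximum likelihood (FIML) machinery.

Twin-pair phenotype vectors are Gaussian with a zygosity-specific expected
covariance.  Missing entries (a twin who skipped a measure) are handled by
marginalization: observations are grouped by missingness pattern and each
pattern contributes the likelihood of its observed sub-vector.  Because the
Gaussian log-likelihood depends on the data only through per-pattern counts,
sums and cross-product matrices, the negative log-likelihood is O(#patterns)
per evaluation regardless of sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConvergenceError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PatternStats:
    """Sufficient statistics for one missingness pattern.

    mask : boolean array over the stacked observation vector (observed entries)
    n    : number of rows with this pattern
    s1   : sum of observed sub-vectors, shape (d,)
    s2   : sum of outer products of observed sub-vectors, shape (d, d)
    """

    mask: np.ndarray
    n: int
    s1: np.ndarray
    s2: np.ndarray

    @property
    def idx(self) -> np.ndarray:
        if not hasattr(self, "_idx"):
            object.__setattr__(self, "_idx", np.flatnonzero(self.mask))
        return self._idx


def pattern_stats(x: np.ndarray) -> list[PatternStats]:
    """Group rows of ``x`` (NaN = missing) by missingness pattern.

    Rows with no observed entries are dropped (they carry no information).
    """
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    keep = obs.any(axis=1)
    x, obs = x[keep], obs[keep]
    out: list[PatternStats] = []
    if x.size == 0:
        return out
    # encode each pattern as bytes for grouping
    codes = np.packbits(obs, axis=1)
    order = np.lexsort(codes.T[::-1])
    codes, x, obs = codes[order], x[order], obs[order]
    boundaries = np.flatnonzero(np.any(codes[1:] != codes[:-1], axis=1)) + 1
    for block in np.split(np.arange(len(x)), boundaries):
        mask = obs[block[0]]
        sub = x[np.ix_(block, np.flatnonzero(mask))]
        out.append(
            PatternStats(mask=mask, n=len(block), s1=sub.sum(axis=0), s2=sub.T @ sub)
        )
    return out


class PatternBundle:
    """Pattern statistics regrouped by observed dimension for batched FIML.

    Patterns with the same number of observed entries are stacked so the
    log-determinants, solves and traces run as single batched linalg calls.
    """

    def __init__(self, stats: list[PatternStats]):
        self.groups = []
        by_dim: dict[int, list[PatternStats]] = {}
        for p in stats:
            by_dim.setdefault(len(p.idx), []).append(p)
        for d, plist in sorted(by_dim.items()):
            idx = np.stack([p.idx for p in plist])  # (k, d)
            self.groups.append(
                (
                    idx,
                    np.array([p.n for p in plist], dtype=float),
                    np.stack([p.s1 for p in plist]),
                    np.stack([p.s2 for p in plist]),
                )
            )

    def nll(self, sigma: np.ndarray, mu: np.ndarray) -> float:
        total = 0.0
        for idx, n, s1, s2 in self.groups:
            d = idx.shape[1]
            sig = sigma[idx[:, :, None], idx[:, None, :]]  # (k, d, d)
            m = mu[idx]  # (k, d)
            sign, logdet = np.linalg.slogdet(sig)
            if np.any(sign <= 0):
                return np.inf
            scatter = (
                s2
                - m[:, :, None] * s1[:, None, :]
                - s1[:, :, None] * m[:, None, :]
                + n[:, None, None] * (m[:, :, None] * m[:, None, :])
            )
            try:
                solved = np.linalg.solve(sig, scatter)
            except np.linalg.LinAlgError:
                return np.inf
            trace = np.einsum("kii->k", solved)
            total += 0.5 * float(np.sum(n * (logdet + d * _LOG_2PI) + trace))
        return total


def fiml_nll(sigma: np.ndarray, mu: np.ndarray, stats) -> float:
    """Negative Gaussian log-likelihood from pattern sufficient statistics.

    ``stats`` may be a list of :class:`PatternStats` or a prebuilt
    :class:`PatternBundle` (preferred inside optimization loops).
    """
    if not isinstance(stats, PatternBundle):
        stats = PatternBundle(stats)
    return stats.nll(sigma, mu)


def multistart_minimize(
    fun,
    starts,
    bounds=None,
    agreement_tol: float = 1e-6,
    ftol: float = 1e-12,
    gtol: float = 1e-9,
    maxiter: int = 2000,
):
    """Run L-BFGS-B from several fixed starting points; return the best result.

    Raises :class:`ConvergenceError` if no start converges.  The spread of the
    converged optima is returned so callers can enforce a multi-start
    agreement contract.
    """
    results = []
    for x0 in starts:
        res = optimize.minimize(
            fun,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter},
        )
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise ConvergenceError("no start point produced a finite optimum")
    results.sort(key=lambda r: r.fun)
    best = results[0]
    converged = [r for r in results if r.success]
    if not converged:
        g = getattr(best, "jac", None)
        raise ConvergenceError(
            "optimizer failed to converge from any start",
            loglik=-best.fun,
            grad_norm=None if g is None else float(np.linalg.norm(g)),
        )
    spread = max(r.fun for r in converged) - best.fun if len(converged) > 1 else 0.0
    return best, spread
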