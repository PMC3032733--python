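"""Synthetic twin-cohort generation from multivariate ACE Cholesky models.

The generative model is the classical twin design: each standardized
phenotype vector y for one twin is

    y = Lambda_A @ A + Lambda_C @ C + Lambda_E @ E  (+ sex and age mean shifts)

where A, C and E are vectors of independent standard-normal latent factors
(additive genetic, shared environmental and non-shared environmental) and the
Lambdas are lower-triangular path matrices.  Co-twins share C exactly; MZ
co-twins share A exactly while DZ co-twins correlate 0.5 on each A factor;
E is independent between co-twins.  The implied cross-twin covariance is
therefore Sigma_A + Sigma_C for MZ pairs and 0.5*Sigma_A + Sigma_C for DZ
pairs, with Sigma_X = Lambda_X @ Lambda_X.T.

Random streams are keyed by (group, role, factor index) through
``numpy.random.SeedSequence`` spawn keys, so adding a trait or changing the
missingness of one measure never perturbs the draws of another.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidModelError, ParseError

__all__ = [
    "CholeskyParams",
    "SimConfig",
    "SubscaleSpec",
    "TwinDataset",
    "expected_covariances",
    "simulate_cohort",
    "moment_matched_cohort",
    "write_cohort",
    "read_cohort",
]

_META_COLS = ["family_id", "zygosity", "sex_t1", "sex_t2", "age"]


def _is_lower_triangular(m: np.ndarray) -> bool:
    return bool(np.all(np.triu(m, k=1) == 0.0))


def _safe_cholesky(sigma: np.ndarray, name: str) -> np.ndarray:
    """Lower Cholesky factor, tolerating tiny negative eigenvalues."""
    sigma = np.asarray(sigma, dtype=float)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((sigma + sigma.T) / 2.0)
        if w.min() < -1e-8:
            raise InvalidModelError(
                f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})"
            )
        w = np.clip(w, 0.0, None)
        # re-factor the PSD projection; add a whisper of ridge for rank deficiency
        fixed = (v * w) @ v.T + 1e-12 * np.eye(len(w))
        return np.linalg.cholesky(fixed)


@dataclass(frozen=True)
class CholeskyParams:
    """Lower-triangular A/C/E path matrices of a multivariate twin model."""

    lambda_a: np.ndarray
    lambda_c: np.ndarray
    lambda_e: np.ndarray
    trait_names: tuple[str, ...]

    def __post_init__(self):
        la = np.atleast_2d(np.asarray(self.lambda_a, dtype=float))
        lc = np.atleast_2d(np.asarray(self.lambda_c, dtype=float))
        le = np.atleast_2d(np.asarray(self.lambda_e, dtype=float))
        object.__setattr__(self, "lambda_a", la)
        object.__setattr__(self, "lambda_c", lc)
        object.__setattr__(self, "lambda_e", le)
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        n = len(self.trait_names)
        for name, m in (("lambda_a", la), ("lambda_c", lc), ("lambda_e", le)):
            if m.shape != (n, n):
                raise InvalidModelError(f"{name} must be {n}x{n}, got {m.shape}")
            if not _is_lower_triangular(m):
                raise InvalidModelError(f"{name} must be lower triangular")
        if np.any(np.diag(le) <= 0):
            raise InvalidModelError(
                "lambda_e must have a strictly positive diagonal "
                "(every trait needs unique residual variance)"
            )
        total = self.sigma_a + self.sigma_c + self.sigma_e
        w = np.linalg.eigvalsh(total)
        if w.min() <= 0:
            raise InvalidModelError(
                f"implied total covariance is not positive definite "
                f"(min eigenvalue {w.min():.3g})"
            )

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def sigma_a(self) -> np.ndarray:
        return self.lambda_a @ self.lambda_a.T

    @property
    def sigma_c(self) -> np.ndarray:
        return self.lambda_c @ self.lambda_c.T

    @property
    def sigma_e(self) -> np.ndarray:
        return self.lambda_e @ self.lambda_e.T

    @property
    def total_covariance(self) -> np.ndarray:
        return self.sigma_a + self.sigma_c + self.sigma_e

    @classmethod
    def from_components(cls, sigma_a, sigma_c, sigma_e, trait_names) -> "CholeskyParams":
        """Build path matrices from A/C/E covariance components (PSD each)."""
        return cls(
            lambda_a=_safe_cholesky(sigma_a, "sigma_a"),
            lambda_c=_safe_cholesky(sigma_c, "sigma_c"),
            lambda_e=_safe_cholesky(sigma_e, "sigma_e"),
            trait_names=trait_names,
        )

    @classmethod
    def univariate(cls, a2: float, c2: float, e2: float, trait: str = "y") -> "CholeskyParams":
        """One-trait model from variance components (a^2, c^2, e^2)."""
        return cls(
            lambda_a=np.array([[np.sqrt(a2)]]),
            lambda_c=np.array([[np.sqrt(c2)]]),
            lambda_e=np.array([[np.sqrt(e2)]]),
            trait_names=(trait,),
        )


def expected_covariances(params: CholeskyParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied (2n x 2n) twin-pair covariance matrices (MZ, DZ).

    The stacked order is (twin1 traits..., twin2 traits...).  The within-twin
    block is Sigma_A + Sigma_C + Sigma_E for both zygosities; the cross-twin
    block is Sigma_A + Sigma_C for MZ and 0.5*Sigma_A + Sigma_C for DZ.
    """
    sa, sc, se = params.sigma_a, params.sigma_c, params.sigma_e
    within = sa + sc + se
    out = []
    for zyg, cross in (("MZ", sa + sc), ("DZ", 0.5 * sa + sc)):
        full = np.block([[within, cross], [cross.T, within]])
        w = np.linalg.eigvalsh(full)
        if w.min() < -1e-10:
            raise InvalidModelError(
                f"implied {zyg} pair covariance is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )
        out.append(full)
    return out[0], out[1]


@dataclass(frozen=True)
class SubscaleSpec:
    """Emit ``n_subscales`` noisy indicators of a trait with the given reliability.

    Each subscale is sqrt(reliability)*trait + sqrt(1-reliability)*noise, so
    subscale intercorrelations equal ``reliability`` when the trait has unit
    variance.
    """

    n_subscales: int
    reliability: float

    def __post_init__(self):
        if self.n_subscales < 1:
            raise ConfigError("n_subscales must be >= 1")
        if not 0.0 < self.reliability <= 1.0:
            raise ConfigError("reliability must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated twin cohort."""

    n_mz_pairs: int
    n_dz_pairs: int
    cholesky: CholeskyParams
    sex_effect: np.ndarray | float = 0.0
    age_effect: np.ndarray | float = 0.0
    age_range: tuple[float, float] = (10.4, 12.7)
    missing_rate: np.ndarray | float = 0.0
    seed: int = 0
    subscale_spec: dict[str, SubscaleSpec] = field(default_factory=dict)

    def __post_init__(self):
        n = self.cholesky.n_traits
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ConfigError("pair counts must be >= 0")
        for name in ("sex_effect", "age_effect", "missing_rate"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,)).copy()
            if v.shape != (n,):
                raise ConfigError(f"{name} must broadcast to n_traits={n}")
            object.__setattr__(self, name, v)
        if np.any(self.missing_rate < 0) or np.any(self.missing_rate >= 1):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not self.age_range[1] >= self.age_range[0]:
            raise ConfigError("age_range must be (low, high) with high >= low")
        for trait in self.subscale_spec:
            if trait not in self.cholesky.trait_names:
                raise ConfigError(f"subscale_spec names unknown trait {trait!r}")


@dataclass
class TwinDataset:
    """Wide per-pair twin data: one row per family, two columns per trait.

    ``df`` columns: family_id, zygosity (MZ/DZ), sex_t1, sex_t2 (F/M), age,
    then ``<trait>_t1`` and ``<trait>_t2`` per trait (NaN = missing).
    """

    df: pd.DataFrame
    traits: tuple[str, ...]

    def __post_init__(self):
        self.traits = tuple(self.traits)
        missing = [c for c in _META_COLS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"dataset missing metadata columns {missing}")
        for t in self.traits:
            for c in (f"{t}_t1", f"{t}_t2"):
                if c not in self.df.columns:
                    raise ConfigError(f"dataset missing trait column {c}")
        if self.df["family_id"].duplicated().any():
            dup = self.df.loc[self.df["family_id"].duplicated(), "family_id"].iloc[0]
            raise ConfigError(f"duplicate family_id {dup!r}")
        mz = self.df["zygosity"] == "MZ"
        if (self.df.loc[mz, "sex_t1"] != self.df.loc[mz, "sex_t2"]).any():
            raise ConfigError("MZ pairs must be same-sex")

    def __eq__(self, other):
        return (
            isinstance(other, TwinDataset)
            and self.traits == other.traits
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.df.copy(), self.traits)

    def with_trait(self, name: str, t1: np.ndarray, t2: np.ndarray) -> "TwinDataset":
        """Return a copy with one additional (or replaced) trait."""
        df = self.df.copy()
        df[f"{name}_t1"] = np.asarray(t1, dtype=float)
        df[f"{name}_t2"] = np.asarray(t2, dtype=float)
        traits = self.traits if name in self.traits else self.traits + (name,)
        return TwinDataset(df, traits)

    def pairs(self, trait: str, zygosity: str | None = None) -> np.ndarray:
        """(n, 2) array of co-twin values (NaN preserved) for one trait."""
        df = self.df if zygosity is None else self.df[self.df["zygosity"] == zygosity]
        return df[[f"{trait}_t1", f"{trait}_t2"]].to_numpy(dtype=float)

    def stacked(self, traits, zygosity: str) -> np.ndarray:
        """(n, 2k) array stacking twin1 traits then twin2 traits."""
        df = self.df[self.df["zygosity"] == zygosity]
        cols = [f"{t}_t1" for t in traits] + [f"{t}_t2" for t in traits]
        return df[cols].to_numpy(dtype=float)

    def long(self, traits=None) -> pd.DataFrame:
        """Per-individual long format (one row per twin)."""
        traits = self.traits if traits is None else tuple(traits)
        frames = []
        for twin in (1, 2):
            cols = {f"{t}_t{twin}": t for t in traits}
            sub = self.df[_META_COLS + list(cols)].rename(columns=cols)
            sub["sex"] = sub[f"sex_t{twin}"]
            sub["twin"] = twin
            frames.append(sub.drop(columns=["sex_t1", "sex_t2"]))
        out = pd.concat(frames, ignore_index=True)
        return out[["family_id", "zygosity", "twin", "sex", "age"] + list(traits)]


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic child stream keyed by integers (stable under reordering)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _simulate_group(config: SimConfig, zygosity: str, gi: int, n: int):
    params = config.cholesky
    k = params.n_traits
    a1 = np.empty((k, n))
    a2 = np.empty((k, n))
    c = np.empty((k, n))
    e1 = np.empty((k, n))
    e2 = np.empty((k, n))
    for j in range(k):
        fa = _rng(config.seed, gi, 0, j).standard_normal(n)
        a1[j] = fa
        if zygosity == "MZ":
            a2[j] = fa
        else:
            a2[j] = 0.5 * fa + np.sqrt(0.75) * _rng(config.seed, gi, 1, j).standard_normal(n)
        c[j] = _rng(config.seed, gi, 2, j).standard_normal(n)
        e1[j] = _rng(config.seed, gi, 3, j).standard_normal(n)
        e2[j] = _rng(config.seed, gi, 4, j).standard_normal(n)
    y1 = params.lambda_a @ a1 + params.lambda_c @ c + params.lambda_e @ e1
    y2 = params.lambda_a @ a2 + params.lambda_c @ c + params.lambda_e @ e2

    lo, hi = config.age_range
    age = _rng(config.seed, gi, 5).uniform(lo, hi, size=n)
    age_c = age - (lo + hi) / 2.0

    sex_rng = _rng(config.seed, gi, 6)
    if zygosity == "MZ":
        s = sex_rng.integers(0, 2, size=n)
        sex1, sex2 = s, s.copy()
    else:
        # half same-sex, half opposite-sex in expectation
        sex1 = sex_rng.integers(0, 2, size=n)
        opposite = sex_rng.integers(0, 2, size=n).astype(bool)
        sex2 = np.where(opposite, 1 - sex1, sex1)

    for j in range(k):
        y1[j] += config.sex_effect[j] * sex1 + config.age_effect[j] * age_c
        y2[j] += config.sex_effect[j] * sex2 + config.age_effect[j] * age_c

    miss1 = np.zeros((k, n), dtype=bool)
    miss2 = np.zeros((k, n), dtype=bool)
    for j in range(k):
        if config.missing_rate[j] > 0:
            miss1[j] = _rng(config.seed, gi, 7, j).random(n) < config.missing_rate[j]
            miss2[j] = _rng(config.seed, gi, 8, j).random(n) < config.missing_rate[j]

    cols = {}
    for j, t in enumerate(params.trait_names):
        v1, v2 = y1[j].copy(), y2[j].copy()
        v1[miss1[j]] = np.nan
        v2[miss2[j]] = np.nan
        cols[f"{t}_t1"] = v1
        cols[f"{t}_t2"] = v2
        spec = config.subscale_spec.get(t)
        if spec is not None:
            w = np.sqrt(spec.reliability)
            noise_sd = np.sqrt(1.0 - spec.reliability)
            for s in range(spec.n_subscales):
                for twin, (y, miss) in enumerate(((y1[j], miss1[j]), (y2[j], miss2[j])), 1):
                    sub = w * y + noise_sd * _rng(config.seed, gi, 9, j, s, twin).standard_normal(n)
                    sub[miss] = np.nan
                    cols[f"{t}_sub{s + 1}_t{twin}"] = sub

    meta = {
        "zygosity": np.repeat(zygosity, n),
        "sex_t1": np.where(sex1 == 1, "M", "F"),
        "sex_t2": np.where(sex2 == 1, "M", "F"),
        "age": age,
    }
    return meta, cols


def simulate_cohort(config: SimConfig) -> TwinDataset:
    """Draw a twin cohort from the configured multivariate ACE model.

    Deterministic under ``config.seed``.  Subscale columns (if requested) are
    named ``<trait>_sub<i>_t<1|2>`` and inherit the parent trait's missingness.
    """
    frames = []
    offset = 0
    for gi, (zyg, n) in enumerate((("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs))):
        if n == 0:
            continue
        meta, cols = _simulate_group(config, zyg, gi, n)
        df = pd.DataFrame(
            {"family_id": [f"fam{fid:06d}" for fid in range(offset, offset + n)], **meta, **cols}
        )
        offset += n
        frames.append(df)
    if not frames:
        raise ConfigError("cannot simulate an empty cohort (no pairs requested)")
    df = pd.concat(frames, ignore_index=True)
    traits = list(config.cholesky.trait_names)
    for t in config.cholesky.trait_names:
        spec = config.subscale_spec.get(t)
        if spec is not None:
            traits.extend(f"{t}_sub{s + 1}" for s in range(spec.n_subscales))
    return TwinDataset(df, tuple(traits))


def moment_matched_cohort(
    params: CholeskyParams, n_mz_pairs: int, n_dz_pairs: int, seed: int = 0
) -> TwinDataset:
    """Cohort whose per-zygosity sample moments EXACTLY equal the model's.

    Each group's stacked (2n-trait) data matrix is affinely transformed so its
    population-convention sample covariance equals the implied pair covariance
    and its sample mean is exactly zero.  Useful for calibration: the FIML
    optimum on such data sits exactly at the generating parameters.
    """
    cov_mz, cov_dz = expected_covariances(params)
    k = params.n_traits
    frames = []
    offset = 0
    for zyg, n, target in (("MZ", n_mz_pairs, cov_mz), ("DZ", n_dz_pairs, cov_dz)):
        if n <= 2 * k:
            raise ConfigError("need more pairs than stacked dimension for moment matching")
        rng = _rng(seed, 0 if zyg == "MZ" else 1, 99)
        x = rng.standard_normal((n, 2 * k))
        x -= x.mean(axis=0)
        samp = x.T @ x / n
        l_target = _safe_cholesky(target + 1e-12 * np.eye(2 * k), "target covariance")
        l_samp = np.linalg.cholesky(samp)
        x = x @ np.linalg.solve(l_samp.T, l_target.T)
        cols = {"family_id": [f"fam{fid:06d}" for fid in range(offset, offset + n)]}
        offset += n
        cols["zygosity"] = np.repeat(zyg, n)
        cols["sex_t1"] = np.repeat("F", n)
        cols["sex_t2"] = np.repeat("F", n)
        cols["age"] = np.repeat(11.5, n)
        for j, t in enumerate(params.trait_names):
            cols[f"{t}_t1"] = x[:, j]
            cols[f"{t}_t2"] = x[:, k + j]
        frames.append(pd.DataFrame(cols))
    return TwinDataset(pd.concat(frames, ignore_index=True), params.trait_names)


def _canonical_columns(data: TwinDataset) -> list[str]:
    return _META_COLS + [f"{t}_t{i}" for t in data.traits for i in (1, 2)]


def write_cohort(data: TwinDataset, path) -> None:
    """Write a cohort CSV (canonical column order, missing as empty field)."""
    cols = _canonical_columns(data)
    data.df[cols].to_csv(path, index=False, na_rep="", float_format="%.17g")


def read_cohort(path) -> TwinDataset:
    """Read a cohort CSV written by :func:`write_cohort` (lossless round trip).

    Raises :class:`ParseError` naming the offending row for unknown zygosity
    codes, duplicate family ids, or ragged rows.
    """
    if hasattr(path, "read"):
        handle, close = path, False
    else:
        handle, close = open(path, newline="", encoding="utf-8"), True
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file: no header row")
        for col in _META_COLS:
            if col not in header:
                raise ParseError(f"header missing required column {col!r}")
        idx = {name: i for i, name in enumerate(header)}
        trait_cols = [c for c in header if c not in _META_COLS]
        bad = [c for c in trait_cols if not (c.endswith("_t1") or c.endswith("_t2"))]
        if bad:
            raise ParseError(f"unrecognized column(s) {bad}")
        traits = []
        for c in trait_cols:
            base = c[:-3]
            if base not in traits:
                traits.append(base)
        for t in traits:
            if f"{t}_t1" not in header or f"{t}_t2" not in header:
                raise ParseError(f"trait {t!r} lacks both twin columns")
        rows = []
        seen = set()
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"row {rownum}: expected {len(header)} fields, got {len(row)}"
                )
            fid = row[idx["family_id"]]
            if fid in seen:
                raise ParseError(f"row {rownum}: duplicate family_id {fid!r}")
            seen.add(fid)
            zyg = row[idx["zygosity"]]
            if zyg not in ("MZ", "DZ"):
                raise ParseError(f"row {rownum}: unknown zygosity code {zyg!r}")
            rec = {
                "family_id": fid,
                "zygosity": zyg,
                "sex_t1": row[idx["sex_t1"]],
                "sex_t2": row[idx["sex_t2"]],
            }
            for c in ("sex_t1", "sex_t2"):
                if rec[c] not in ("F", "M"):
                    raise ParseError(f"row {rownum}: unknown sex code {rec[c]!r}")
            try:
                rec["age"] = float(row[idx["age"]])
            except ValueError:
                raise ParseError(f"row {rownum}: unparsable age {row[idx['age']]!r}")
            for c in trait_cols:
                raw = row[idx[c]]
                if raw == "":
                    rec[c] = np.nan
                else:
                    try:
                        rec[c] = float(raw)
                    except ValueError:
                        raise ParseError(f"row {rownum}: unparsable value {raw!r} in {c}")
            rows.append(rec)
    finally:
        if close:
            handle.close()
    if not rows:
        raise ParseError("no data rows")
    df = pd.DataFrame(rows)
    return TwinDataset(df, tuple(traits))
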