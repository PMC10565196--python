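"""Spatial autocorrelation diagnostics: Moran's I and the Mantel test.

Moran's I measures whether a variable (or a vector of model residuals) is
more spatially clustered (I above its null expectation of -1/(n-1), z > 0)
or more dispersed (z < 0) than random assignment of the observed values to
the observed locations would produce.  Inference uses the classical
Cliff-Ord moments under the randomization (kurtosis-corrected, default) or
normality assumption, or a Monte-Carlo permutation null.  The Mantel test
correlates the lower triangles of two pairwise-distance matrices and
assesses it by jointly permuting rows and columns of one matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .geo import DistanceMatrix, ValidationError

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "MantelResult",
    "build_weights",
    "morans_i",
    "residual_moran",
    "mantel_test",
]

WeightScheme = Literal["inverse_distance", "k_nearest", "kernel"]
MoranMethod = Literal["randomization", "normality", "permutation"]


@dataclass
class SpatialWeights:
    """Non-negative spatial weights with zero diagonal and the Cliff-Ord sums."""

    values: np.ndarray
    ids: list[str]
    scheme: str
    row_standardized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.values, dtype=float)
        if np.any(np.diag(w) != 0):
            raise ValidationError("weights diagonal must be zero")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if w.sum() <= 0:
            raise ValidationError("all-zero weights matrix")
        self.values = w

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def s0(self) -> float:
        return float(self.values.sum())

    @property
    def s1(self) -> float:
        return float(0.5 * ((self.values + self.values.T) ** 2).sum())

    @property
    def s2(self) -> float:
        return float(((self.values.sum(axis=1) + self.values.sum(axis=0)) ** 2).sum())


def build_weights(
    D: DistanceMatrix,
    scheme: WeightScheme = "inverse_distance",
    d_floor: float = 1.0,
    k: int = 5,
    rho_w: float = 1000.0,
    row_standardize: bool = False,
) -> SpatialWeights:
    """Spatial weights from a distance matrix.

    ``inverse_distance``: w_ij = 1 / max(d_ij, d_floor), the package default
    for residual diagnostics (d_floor guards coincident points).
    ``k_nearest``: binary membership of j among i's k nearest neighbours
    (asymmetric in general).  ``kernel``: w_ij = exp(-d_ij / rho_w).
    """
    d = D.values
    n = D.n
    if scheme == "inverse_distance":
        if d_floor <= 0:
            raise ValidationError("d_floor must be > 0")
        w = 1.0 / np.maximum(d, d_floor)
    elif scheme == "k_nearest":
        if not 1 <= k <= n - 1:
            raise ValidationError(f"k must be in [1, n-1] (got {k})")
        w = np.zeros((n, n))
        for i in range(n):
            order = np.argsort(np.where(np.arange(n) == i, np.inf, d[i]), kind="stable")
            w[i, order[:k]] = 1.0
    elif scheme == "kernel":
        if rho_w <= 0:
            raise ValidationError("rho_w must be > 0")
        w = np.exp(-d / rho_w)
    else:
        raise ValidationError(f"unknown weights scheme '{scheme}'")
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        sums = w.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValidationError("row standardization impossible: zero-weight row")
        w = w / sums
    return SpatialWeights(w, list(D.ids), scheme=scheme, row_standardized=row_standardize)


@dataclass
class MoranResult:
    statistic: float
    expected: float
    sd: float
    z: float
    p: float
    n: int
    method: str
    scheme: str
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _moran_statistic(z: np.ndarray, w: np.ndarray, s0: float) -> float:
    return float(len(z) / s0 * (z @ w @ z) / (z @ z))


def morans_i(
    x,
    W: SpatialWeights,
    method: MoranMethod = "randomization",
    permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> MoranResult:
    """Global Moran's I with analytic (Cliff-Ord) or permutation inference.

    The analytic null expectation is E[I] = -1/(n-1); the variance follows
    the randomization formula (using the sample kurtosis b2) or the
    normality formula.  Analytic p-values are two-sided from the normal
    approximation; the permutation p is two-sided around E[I] with the
    +1 correction, p = (1 + #{|I* - E| >= |I - E|}) / (B + 1).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n != W.n:
        raise ValidationError(f"length of x ({n}) does not match weights ({W.n})")
    if n < 4:
        raise ValidationError("Moran's I requires n >= 4 (randomization variance undefined below)")
    z = x - x.mean()
    sz2 = float(z @ z)
    if sz2 == 0:
        raise ValidationError("zero variance: x is constant")

    w = W.values
    s0, s1, s2 = W.s0, W.s1, W.s2
    stat = _moran_statistic(z, w, s0)
    e_i = -1.0 / (n - 1)

    if method in ("randomization", "normality"):
        if method == "normality":
            var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i**2
        else:
            b2 = n * float((z**4).sum()) / sz2**2
            num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
                (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
            )
            var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i**2
        if var <= 0:
            raise ValidationError("null variance of Moran's I is not positive")
        sd = float(np.sqrt(var))
        zscore = (stat - e_i) / sd
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(zscore)))
        return MoranResult(stat, e_i, sd, float(zscore), p, n, method, W.scheme, seed)

    if method == "permutation":
        ref = abs(stat - e_i)
        if exact:
            # full enumeration of all n! relabelings (feasible for tiny n)
            from itertools import permutations as iperm

            sims = np.array([_moran_statistic(z[list(pm)], w, s0) for pm in iperm(range(n))])
            p = float(np.mean(np.abs(sims - e_i) >= ref - 1e-12))
        else:
            rng = np.random.default_rng(seed)
            count = 0
            sims = np.empty(permutations)
            for b in range(permutations):
                zp = z[rng.permutation(n)]
                sims[b] = _moran_statistic(zp, w, s0)
                if abs(sims[b] - e_i) >= ref - 1e-12:
                    count += 1
            p = (1 + count) / (permutations + 1)
        sd = float(sims.std(ddof=1))
        zscore = (stat - sims.mean()) / sd if sd > 0 else np.inf
        return MoranResult(stat, e_i, sd, float(zscore), float(p), n, method, W.scheme, seed)

    raise ValidationError(f"unknown Moran method '{method}'")


def residual_moran(fit, W: SpatialWeights, method: MoranMethod = "randomization", **kwargs) -> MoranResult:
    """Moran's I on a model fit's Pearson residuals.

    The fit must carry ``pearson_resid`` and ``ids`` aligned with the
    weights' id order; a near-constant residual vector (saturated model) is
    reported as degenerate via the zero-variance error.
    """
    ids = getattr(fit, "ids", None)
    if ids is not None and list(ids) != list(W.ids):
        raise ValidationError("id order mismatch between fit residuals and weights")
    resid = np.asarray(fit.pearson_resid, dtype=float)
    scale = getattr(fit, "scale", None)
    outcome_var = float(np.var(np.asarray(fit.fitted, dtype=float))) + 1e-300
    if float(np.var(resid)) < 1e-12 or (scale is not None and scale < 1e-12 * outcome_var):
        raise ValidationError("degenerate residuals (perfect fit): Moran's I undefined")
    return morans_i(resid, W, method=method, **kwargs)


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    alternative: str
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices_from(m, k=-1)]


def mantel_test(
    A,
    B,
    permutations: int = 999,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of strictly-lower-triangle entries; the
    null distribution comes from jointly permuting rows and columns of A.
    One-sided 'greater' by default (positive association of the two
    dissimilarity structures).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"matrix shape mismatch: {A.shape} vs {B.shape}")
    for name, m in (("A", A), ("B", B)):
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValidationError(f"matrix {name} is not symmetric")
    n = A.shape[0]
    if n < 3:
        raise ValidationError("Mantel test requires n >= 3")

    a = _lower_triangle(A)
    b = _lower_triangle(B)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])

    def _hit(r_sim: float) -> bool:
        if alternative == "greater":
            return r_sim >= r_obs - 1e-12
        if alternative == "less":
            return r_sim <= r_obs + 1e-12
        return abs(r_sim) >= abs(r_obs) - 1e-12

    if exact:
        from itertools import permutations as iperm

        hits = total = 0
        for perm in iperm(range(n)):
            hits += _hit(float(np.corrcoef(_lower_triangle(A[np.ix_(perm, perm)]), b)[0, 1]))
            total += 1
        return MantelResult(r_obs, hits / total, total, alternative, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        count += _hit(float(np.corrcoef(_lower_triangle(A[np.ix_(perm, perm)]), b)[0, 1]))
    p = (1 + count) / (permutations + 1)
    return MantelResult(r_obs, float(p), permutations, alternative, seed)
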