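"""Positive-semidefinite covariance matrices from space and from ancestry.

Spatial covariances decay with great-circle distance through an exponential
or half-integer Matérn kernel (variance sigma2, range rho in km, nugget
tau2).  Phylogenetic covariances come either from a rooted tree with branch
lengths (Brownian-motion shared-path covariance) or from a hierarchical
classification table (shared nested levels, equal per-level increments).
Both can be combined, after rescaling to unit diagonal, into a phylospatial
covariance sigma2_s * K_s + sigma2_p * K_p + tau2 * I whose components are
comparable variance shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from .geo import DistanceMatrix, ValidationError

__all__ = [
    "KernelSpec",
    "CovarianceMatrix",
    "kernel_correlation",
    "spatial_covariance",
    "phylo_covariance",
    "tree_covariance",
    "classification_covariance",
    "combine_covariances",
    "read_newick",
    "read_classification",
]

KernelFamily = Literal["exponential", "matern"]


@dataclass(frozen=True)
class KernelSpec:
    """Distance-decay kernel: family, smoothness, variance, range, nugget.

    ``exponential`` is identical to Matérn with nu = 0.5.  Matérn smoothness
    is restricted to the half-integer values {0.5, 1.5, 2.5} that have
    closed forms.  ``rho`` is the range in km; ``sigma2`` the marginal
    spatial variance; ``tau2`` the nugget (variance at zero distance not
    carried by the field, and the numerical stabilizer for coincident
    points).
    """

    family: KernelFamily = "exponential"
    nu: float = 0.5
    sigma2: float = 1.0
    rho: float = 1000.0
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "matern"):
            raise ValidationError(f"unknown kernel family '{self.family}'")
        if self.family == "matern" and self.nu not in (0.5, 1.5, 2.5):
            raise ValidationError(f"matern smoothness must be one of 0.5, 1.5, 2.5 (got {self.nu})")
        if self.rho <= 0:
            raise ValidationError(f"range rho must be > 0 (got {self.rho})")
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValidationError("variances sigma2 and tau2 must be >= 0")


def kernel_correlation(d, family: KernelFamily = "exponential", nu: float = 0.5, rho: float = 1.0):
    """Correlation k(d) in [0, 1]; k(0) = 1, monotone non-increasing in d."""
    d = np.asarray(d, dtype=float)
    if rho <= 0:
        raise ValidationError("rho must be > 0")
    s = d / rho
    if family == "exponential" or (family == "matern" and nu == 0.5):
        return np.exp(-s)
    if family == "matern" and nu == 1.5:
        t = math.sqrt(3.0) * s
        return (1.0 + t) * np.exp(-t)
    if family == "matern" and nu == 2.5:
        t = math.sqrt(5.0) * s
        return (1.0 + t + t * t / 3.0) * np.exp(-t)
    raise ValidationError(f"unsupported kernel family/smoothness ({family}, nu={nu})")


@dataclass
class CovarianceMatrix:
    """Realized covariance with its id order and a provenance tag."""

    values: np.ndarray
    ids: list[str]
    kind: Literal["spatial", "phylogenetic", "combined"] = "spatial"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"covariance shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("covariance matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def check_psd(self, rel_tol: float = 1e-8) -> None:
        tr = float(np.trace(self.values))
        if self.min_eigenvalue() < -rel_tol * max(tr / self.n, 1.0):
            raise ValidationError("covariance matrix is not positive semidefinite")

    def correlation_scaled(self) -> np.ndarray:
        """Rescale to unit diagonal (zero-variance rows left untouched)."""
        d = np.sqrt(np.clip(np.diag(self.values), 0.0, None))
        d = np.where(d > 0, d, 1.0)
        return self.values / np.outer(d, d)


def spatial_covariance(D: DistanceMatrix, spec: KernelSpec) -> CovarianceMatrix:
    """Sigma[i, j] = sigma2 * k(d_ij / rho) + tau2 * 1[i == j]."""
    k = kernel_correlation(D.values, spec.family, spec.nu, spec.rho)
    sigma = spec.sigma2 * k + spec.tau2 * np.eye(D.n)
    return CovarianceMatrix(sigma, list(D.ids), kind="spatial")


# ---------------------------------------------------------------------------
# Phylogenetic covariance


def read_newick(path_or_string) -> dendropy.Tree:
    """Parse a rooted Newick tree (from a path or a literal string)."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def tree_covariance(tree: dendropy.Tree, ids: list[str]) -> CovarianceMatrix:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair.

    Var(i) is the root-to-tip distance of i; Cov(i, j) = (t_i + t_j -
    d_ij) / 2 with d_ij the patristic distance, which equals the length of
    the path shared by the two root-to-tip walks.
    """
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [i for i in ids if i not in taxa]
    if missing:
        raise ValidationError(f"ids not found as tree tips: {missing}")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(ids)
    cov = np.zeros((n, n))
    for i, a in enumerate(ids):
        cov[i, i] = depth[a]
        for j in range(i + 1, n):
            b = ids[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            cov[i, j] = cov[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return CovarianceMatrix(cov, list(ids), kind="phylogenetic")


def read_classification(path_or_df, taxon_col: str = "taxon") -> pd.DataFrame:
    """Classification table: one row per taxon, group columns coarsest first."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if taxon_col not in df.columns:
        raise ValidationError(f"classification table lacks '{taxon_col}' column")
    return df.set_index(df[taxon_col].astype(str)).drop(columns=[taxon_col])


def classification_covariance(classification: pd.DataFrame, ids: list[str]) -> CovarianceMatrix:
    """Relatedness from a nested classification, equal per-level increments.

    Cov(i, j) = (number of shared nested levels, counted from the coarsest
    until the first mismatch) / (total levels); the diagonal is 1.  This is
    the simplest monotone map from a hierarchical classification to a valid
    correlation matrix.
    """
    missing = [i for i in ids if i not in classification.index]
    if missing:
        raise ValidationError(f"ids not found in classification: {missing}")
    levels = classification.loc[ids].to_numpy(dtype=object)
    n, L = levels.shape
    if L == 0:
        raise ValidationError("classification has no grouping levels")
    cov = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            for k in range(L):
                if (
                    pd.notna(levels[i, k])
                    and pd.notna(levels[j, k])
                    and levels[i, k] == levels[j, k]
                ):
                    shared += 1
                else:
                    break
            cov[i, j] = cov[j, i] = shared / L
    return CovarianceMatrix(cov, list(ids), kind="phylogenetic")


def phylo_covariance(source, ids: list[str]) -> CovarianceMatrix:
    """Dispatch: a dendropy Tree / Newick gives Brownian covariance, a
    classification table gives shared-level covariance."""
    if isinstance(source, dendropy.Tree):
        return tree_covariance(source, ids)
    if isinstance(source, pd.DataFrame):
        if "taxon" in source.columns:
            source = read_classification(source)
        return classification_covariance(source, ids)
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        s = str(source)
        if s.lstrip().startswith("(") or s.endswith((".nwk", ".newick", ".tre", ".tree")):
            return tree_covariance(read_newick(s), ids)
        return classification_covariance(read_classification(s), ids)
    raise ValidationError(f"cannot interpret phylogenetic source of type {type(source).__name__}")


def combine_covariances(
    spatial: CovarianceMatrix,
    phylo: CovarianceMatrix,
    sigma2_s: float,
    sigma2_p: float,
    tau2: float,
) -> CovarianceMatrix:
    """Phylospatial covariance sigma2_s*K_s + sigma2_p*K_p + tau2*I.

    Both inputs are correlation-scaled first so the weights are marginal
    variance components on a common scale.  With both weights zero the
    result is pure independent noise, the no-autocorrelation limit.
    """
    if min(sigma2_s, sigma2_p, tau2) < 0:
        raise ValidationError("variance weights must be non-negative")
    if list(spatial.ids) != list(phylo.ids):
        raise ValidationError("id order mismatch between spatial and phylogenetic covariances")
    n = spatial.n
    sigma = (
        sigma2_s * spatial.correlation_scaled()
        + sigma2_p * phylo.correlation_scaled()
        + tau2 * np.eye(n)
    )
    return CovarianceMatrix(sigma, list(spatial.ids), kind="combined")
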