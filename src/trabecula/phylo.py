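"""Phylogenetic comparative statistics.

Brownian trait covariance from a time-scaled tree, phylogenetic
generalized least squares (PGLS), Blomberg's K with a tip-permutation
test, and averaging of per-vertebral-position fits.

Under Brownian motion the expected covariance of a trait between two
tips is proportional to the length of their shared root-to-MRCA path,
so the species covariance matrix C has C[i, j] = depth(MRCA(i, j)) and
C[i, i] = the root-to-tip depth. PGLS estimates
(X' C^-1 X)^-1 X' C^-1 y with CIs from the GLS variance; one row per
species (species means are computed upstream, since a species cannot
appear twice against one tree tip).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .allometry import RegressionResult

__all__ = [
    "Phylogeny",
    "PhyloSignalResult",
    "PGLSResult",
    "brownian_cov",
    "pgls",
    "blomberg_k",
    "simulate_brownian",
    "average_over_positions",
]


class Phylogeny:
    """Rooted tree with branch lengths, wrapping a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        self.tip_labels = labels

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def prune_to(self, taxa: list[str]) -> "Phylogeny":
        """Prune to the given tips (underscores and spaces both accepted)."""
        wanted = {t.replace(" ", "_") for t in taxa}
        tree = self._tree.clone(depth=1)
        keep = [
            leaf.taxon
            for leaf in tree.leaf_node_iter()
            if leaf.taxon.label.replace(" ", "_") in wanted
        ]
        if len(keep) != len(wanted):
            have = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
            raise KeyError(f"taxa missing from tree: {sorted(wanted - have)}")
        tree.retain_taxa(keep)
        return Phylogeny(tree)

    def brownian_covariance(self, taxa: list[str] | None = None) -> np.ndarray:
        """Brownian covariance matrix C[i, j] = shared root-to-MRCA path length."""
        return brownian_cov(self, taxa)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def brownian_cov(tree: Phylogeny, taxa: list[str] | None = None) -> np.ndarray:
    """Species covariance under Brownian motion, rows ordered like ``taxa``.

    C[i, j] is the root-to-MRCA path length of tips i and j; diagonal
    entries are root-to-tip depths. Symmetric positive semi-definite by
    construction. Raises on a zero-depth tree.
    """
    t = tree._tree
    if taxa is None:
        taxa = tree.tip_labels
    order = {label.replace(" ", "_"): i for i, label in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))

    # accumulate each internal edge's length onto all tip pairs below it
    for node in t.preorder_node_iter():
        node.depth_from_root = (
            0.0
            if node.parent_node is None
            else node.parent_node.depth_from_root + (node.edge.length or 0.0)
        )
    for node in t.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            node.tips_below = [order[label]] if label in order else []
        else:
            node.tips_below = [i for ch in node.child_nodes() for i in ch.tips_below]
            for a_child in node.child_nodes():
                for b_child in node.child_nodes():
                    if a_child is b_child:
                        continue
                    for i in a_child.tips_below:
                        for j in b_child.tips_below:
                            C[i, j] = node.depth_from_root
    for node in t.leaf_node_iter():
        label = node.taxon.label.replace(" ", "_")
        if label in order:
            C[order[label], order[label]] = node.depth_from_root
    if np.max(np.diag(C)) <= 0:
        raise ValueError("zero-depth tree: branch lengths are required")
    return C


@dataclass(frozen=True)
class PGLSResult(RegressionResult):
    covariance_model: str = "Brownian"


def pgls(
    x: np.ndarray, y: np.ndarray, C: np.ndarray, ci_level: float = 0.95
) -> PGLSResult:
    """Generalized least squares slope of y on x with error covariance C.

    Expects one row per species with C aligned to the rows; x and y are
    used as given (log-transform upstream if fitting power laws). CIs
    come from the t distribution with n-2 df on the GLS standard error.
    With C = I this reduces exactly to OLS.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = np.asarray(C, float)
    n = len(x)
    if C.shape != (n, n):
        raise ValueError("C must be n x n aligned to the observations")
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance matrix: jitter the diagonal or rescale lambda"
        ) from exc
    X = np.column_stack([np.ones(n), x])
    XtCi = X.T @ Ci
    cov_unscaled = np.linalg.inv(XtCi @ X)
    beta = cov_unscaled @ (XtCi @ y)
    resid = y - X @ beta
    df = n - 2
    sigma2 = float(resid @ Ci @ resid) / df
    se = float(np.sqrt(sigma2 * cov_unscaled[1, 1]))
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
    tval = beta[1] / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else 0.0
    # GLS R^2 relative to the GLS-weighted mean
    one = np.ones(n)
    mu = float((one @ Ci @ y) / (one @ Ci @ one))
    ss_tot = float((y - mu) @ Ci @ (y - mu))
    r2 = 1.0 - float(resid @ Ci @ resid) / ss_tot if ss_tot > 0 else 1.0
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        ci_low=float(beta[1] - tcrit * se),
        ci_high=float(beta[1] + tcrit * se),
        p_value=float(p),
        r_squared=float(r2),
        n=n,
    )


@dataclass(frozen=True)
class PhyloSignalResult:
    K: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")


def _k_ratio(y: np.ndarray, Ci: np.ndarray, ones: np.ndarray) -> float:
    """Observed MSE0/MSE with the phylogenetically corrected mean."""
    a = float((ones @ Ci @ y) / (ones @ Ci @ ones))
    d = y - a
    mse0 = float(d @ d)
    mse = float(d @ Ci @ d)
    return mse0 / mse


def blomberg_k(
    trait: np.ndarray,
    C: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PhyloSignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K is the observed MSE0/MSE ratio (trait variance about the
    phylogenetically corrected mean over its Brownian-weighted
    counterpart) divided by its expectation under Brownian motion on
    this tree; K = 1 is the Brownian expectation, K << 1 means less
    signal than Brownian. The p-value is the proportion of tip-label
    permutations with a ratio at least as large as observed, with the
    (r+1)/(n+1) correction. Scale- and shift-invariant in the trait.
    """
    y = np.asarray(trait, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("constant trait: K is undefined")
    C = np.asarray(C, float)
    Ci = np.linalg.inv(C)
    ones = np.ones(n)
    expected = (np.trace(C) - n / float(ones @ Ci @ ones)) / (n - 1)
    observed = _k_ratio(y, Ci, ones)
    K = observed / expected

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _k_ratio(y[perm], Ci, ones) >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PhyloSignalResult(K=float(K), p_value=float(p), n_permutations=n_perm, seed=seed)


def simulate_brownian(
    C: np.ndarray, sigma2: float = 1.0, n_traits: int = 1, seed: int = 0
) -> np.ndarray:
    """Draw traits from MVN(0, sigma2 * C); shape (n_tips, n_traits)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.asarray(C, float) + 1e-12 * np.eye(len(C)))
    z = rng.standard_normal((len(C), n_traits))
    return np.sqrt(sigma2) * (L @ z)


def average_over_positions(results: dict[str, RegressionResult]) -> dict:
    """Average per-position fits, with the per-position slope range.

    Arithmetic means of slopes, CI bounds, and p-values across the
    fitted positions, in the "average (range)" style used for reporting
    along the vertebral column.
    """
    if not results:
        raise ValueError("no per-position results to average")
    slopes = np.array([r.slope for r in results.values()])
    return {
        "slope": float(slopes.mean()),
        "slope_range": (float(slopes.min()), float(slopes.max())),
        "ci_low": float(np.mean([r.ci_low for r in results.values()])),
        "ci_high": float(np.mean([r.ci_high for r in results.values()])),
        "p_value": float(np.mean([r.p_value for r in results.values()])),
        "n_positions": len(results),
        "formatted": f"{slopes.mean():.2f} ({slopes.min():.2f}–{slopes.max():.2f})",
    }
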