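"""Phylogenetic signal in a continuous trait: Blomberg's K and Pagel's lambda.

The trait here is the population-level preferred temperature, but the
machinery is generic.  Trees are consumed as newick (via dendropy); branch
lengths can be assigned by Grafen's method (node height = descendant tip
count - 1, rescaled to unit root depth), matching the usual treatment of a
topology-only tree.  Under Brownian motion on the tree, tip values are
multivariate normal with covariance C[i, j] equal to the shared root-to-MRCA
path length.  Blomberg's K compares the observed ratio of the ordinary to
the phylogenetically-corrected mean squared error with its Brownian
expectation (K = 1 under pure BM); its p-value comes from permuting trait
values across tips.  Pagel's lambda multiplies the off-diagonal covariances
and is estimated by maximum likelihood with the mean and rate profiled out;
the upper search bound is the largest lambda keeping the covariance positive
definite, which for shallow internal nodes can exceed 1.  Significance of
lambda is a likelihood-ratio test against lambda = 0 (chi-square, 1 df).

With very few tips (the five-population case) both tests have little power;
simulation-based checks use larger trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

from .errors import DegenerateTraitError, InvalidTreeError

__all__ = [
    "SignalResult",
    "read_tree",
    "grafen_lengths",
    "phylo_covariance",
    "blomberg_k",
    "blomberg_k_test",
    "pagel_lambda_ml",
    "lambda_lr_test",
    "simulate_bm",
    "balanced_tree",
    "phylo_signal_tests",
]


def balanced_tree(n_tips: int, branch_length: float = 1.0) -> dendropy.Tree:
    """Fully balanced binary tree (n_tips a power of two) with equal branch lengths.

    A convenient fixed topology for simulation studies.
    """
    if n_tips < 2 or (n_tips & (n_tips - 1)) != 0:
        raise InvalidTreeError("n_tips must be a power of two >= 2")

    def build(labels):
        if len(labels) == 1:
            return f"{labels[0]}:{branch_length}"
        half = len(labels) // 2
        return f"({build(labels[:half])},{build(labels[half:])}):{branch_length}"

    labels = [f"t{i + 1:03d}" for i in range(n_tips)]
    half = n_tips // 2
    nwk = f"({build(labels[:half])},{build(labels[half:])});"
    return read_tree(nwk)


@dataclass(frozen=True)
class SignalResult:
    k_stat: float
    p_k: float
    lambda_hat: float
    loglik_at_hat: float
    p_lambda: float


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string (or file path ending in .nwk/.tre/.newick)."""
    if newick.strip().startswith("(") or newick.strip().startswith(";"):
        return dendropy.Tree.get(data=newick, schema="newick")
    return dendropy.Tree.get(path=newick, schema="newick")


def grafen_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign Grafen branch lengths: node height = #descendant tips - 1, unit depth.

    Returns a new ultrametric tree with root-to-tip depth exactly 1.
    """
    tree = tree.clone(depth=1)
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise InvalidTreeError("need at least 2 tips")
    n = len(leaves)
    heights = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            ntips = sum(1 for _ in node.leaf_iter())
            heights[node] = (ntips - 1) / (n - 1)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
        else:
            node.edge.length = None
    return tree


def phylo_covariance(tree: dendropy.Tree):
    """Brownian-motion covariance of the tips: shared root-to-MRCA path lengths.

    Returns (labels, C) with tips in sorted-label order; C is symmetric PSD
    with tip depths on the diagonal.
    """
    leaves = tree.leaf_nodes()
    labels = sorted(lf.taxon.label for lf in leaves)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[parent] + (node.edge.length or 0.0)
    C = np.zeros((n, n))
    tip_sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            tip_sets[node] = [i]
            C[i, i] = depth[node]
        else:
            child_sets = [tip_sets.pop(c) for c in node.child_nodes()]
            # tips in different child subtrees coalesce exactly here
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = depth[node]
            tip_sets[node] = [i for s in child_sets for i in s]
    return labels, C


def _as_vector(trait, labels):
    if isinstance(trait, dict):
        missing = [l for l in labels if l not in trait]
        if missing:
            raise InvalidTreeError(f"trait missing for tips {missing}")
        return np.array([float(trait[l]) for l in labels])
    x = np.asarray(trait, dtype=float)
    if x.size != len(labels):
        raise InvalidTreeError("trait length does not match tip count")
    return x


def blomberg_k(trait, tree: dendropy.Tree) -> float:
    """Blomberg's K for a continuous trait on a tree with branch lengths.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected, where MSE0 uses the
    ordinary deviations from the phylogenetic (GLS) mean, MSE the
    phylogenetically corrected ones, and the Brownian expectation of the
    ratio is [tr(C) - n / sum(C^-1)] / (n - 1).
    """
    labels, C = phylo_covariance(tree)
    x = _as_vector(trait, labels)
    return _blomberg_k_from_cov(x, C)


def _blomberg_k_from_cov(x: np.ndarray, C: np.ndarray) -> float:
    n = x.size
    if n < 3:
        raise InvalidTreeError("need n >= 3 tips")
    if np.ptp(x) == 0:
        raise DegenerateTraitError("constant trait")
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Cinv @ one
    a = (one @ Cinv @ x) / denom  # phylogenetic GLS mean
    r = x - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Cinv @ r) / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k_test(trait, tree: dendropy.Tree, n_perm: int = 999, seed: int = 0):
    """Permutation test of K: trait values shuffled across tips.

    Returns (k_observed, p) with p = (1 + #{K_perm >= K_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, C = phylo_covariance(tree)
    x = _as_vector(trait, labels)
    k_obs = _blomberg_k_from_cov(x, C)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        k = _blomberg_k_from_cov(rng.permutation(x), C)
        if k >= k_obs:
            count += 1
    return k_obs, (1 + count) / (n_perm + 1)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _profile_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Gaussian log-likelihood at lambda with mean and rate profiled out."""
    n = x.size
    V = _lambda_cov(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Vinv_x = np.linalg.solve(V, x)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    a = (np.ones(n) @ Vinv_x) / (np.ones(n) @ Vinv_1)
    r = x - a
    sig2 = (r @ np.linalg.solve(V, r)) / n
    if sig2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n))


def lambda_upper_bound(C: np.ndarray) -> float:
    """Largest lambda keeping the transformed covariance positive definite.

    For an ultrametric tree this is the tip depth over the deepest internal
    node height (max off-diagonal), and can exceed 1.
    """
    off = C - np.diag(np.diag(C))
    m = off.max()
    if m <= 0:
        return 1.0  # star tree: any lambda is equivalent
    return float(np.max(np.diag(C)) / m)


def pagel_lambda_ml(trait, tree: dendropy.Tree, lambda_bounds=None):
    """ML estimate of Pagel's lambda; returns (lambda_hat, loglik_at_hat).

    Coarse grid over the admissible range followed by bounded refinement.
    """
    labels, C = phylo_covariance(tree)
    x = _as_vector(trait, labels)
    if np.ptp(x) == 0:
        raise DegenerateTraitError("constant trait")
    if lambda_bounds is None:
        lambda_bounds = (0.0, lambda_upper_bound(C) * (1 - 1e-9))
    lo, hi = lambda_bounds
    grid = np.linspace(lo, hi, 51)
    ll = np.array([_profile_loglik(x, C, g) for g in grid])
    best = int(np.argmax(ll))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid.size - 1)]
    if a == b:
        lam_hat = float(grid[best])
    else:
        res = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(x, C, lam),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-7},
        )
        lam_hat = float(res.x)
        # keep whichever of the refined point and grid best is higher
        if _profile_loglik(x, C, lam_hat) < ll[best]:
            lam_hat = float(grid[best])
    return lam_hat, _profile_loglik(x, C, lam_hat)


def lambda_lr_test(trait, tree: dendropy.Tree):
    """LR test of lambda-hat against lambda = 0; returns (lambda_hat, LR, p).

    p is the chi-square (1 df) upper tail of twice the log-likelihood gap;
    a boundary estimate lambda-hat = 0 gives p = 1.
    """
    labels, C = phylo_covariance(tree)
    x = _as_vector(trait, labels)
    lam_hat, ll_hat = pagel_lambda_ml(trait, tree)
    ll0 = _profile_loglik(x, C, 0.0)
    lr = max(2.0 * (ll_hat - ll0), 0.0)
    p = 1.0 if lr == 0.0 else float(stats.chi2.sf(lr, df=1))
    return lam_hat, lr, p


def simulate_bm(tree: dendropy.Tree, rng, sigma2: float = 1.0, mean: float = 0.0):
    """Draw tip values under Brownian motion; returns (labels, values)."""
    labels, C = phylo_covariance(tree)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
    z = rng.standard_normal(len(labels))
    return labels, mean + np.sqrt(sigma2) * (L @ z)


def phylo_signal_tests(
    trait, tree: dendropy.Tree, n_perm: int = 999, seed: int = 0
) -> SignalResult:
    """Both signal tests in one call, as reported for the population trait."""
    k_obs, p_k = blomberg_k_test(trait, tree, n_perm=n_perm, seed=seed)
    lam_hat, _, p_lam = lambda_lr_test(trait, tree)
    labels, C = phylo_covariance(tree)
    x = _as_vector(trait, labels)
    return SignalResult(
        k_stat=k_obs,
        p_k=p_k,
        lambda_hat=lam_hat,
        loglik_at_hat=_profile_loglik(x, C, lam_hat),
        p_lambda=p_lam,
    )
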