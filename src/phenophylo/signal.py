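"""Blomberg's K and its permutation test.

K compares the observed ratio of trait variance among tips (MSE0) to the
variance remaining after accounting for phylogeny through the GLS fit of a
single phylogenetic mean (MSE), scaled by the same ratio's expectation
under Brownian motion on the given tree:

    a_hat  = (1' C^-1 1)^-1 1' C^-1 x            (GLS grand mean)
    MSE0   = (x - a_hat 1)'        (x - a_hat 1) / (n - 1)
    MSE    = (x - a_hat 1)' C^-1   (x - a_hat 1) / (n - 1)
    E[MSE0/MSE] = (tr(C) - n / (1' C^-1 1)) / (n - 1)
    K      = (MSE0 / MSE) / E[MSE0/MSE]

K = 1 matches Brownian motion, K < 1 weaker phylogenetic structure, K > 1
stronger.  Significance comes from shuffling trait values across tips: the
GLS MSE is recomputed for each permutation and the one-tailed P-value is
the smoothed fraction of permutations whose MSE is at least as small as
observed (phylogenetic signal depresses MSE).

All linear solves use a Cholesky factorization of C; C is never inverted
explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .treeio import PhyloCovariance, Tree, phylo_covariance

__all__ = ["SignalResult", "blomberg_k", "permutation_pvalue", "align_trait"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalResult:
    """Blomberg's K with its variance ratios and (optional) permutation P."""

    K: float
    observed_ratio: float
    expected_ratio: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    n: int = 0


class ConstantTraitError(ValueError):
    """The trait has zero variance; K is undefined."""


def align_trait(trait, taxa, *, min_common: int = 3) -> np.ndarray:
    """Align a {species: value} mapping / Series to a taxa ordering.

    Requires the trait to cover every taxon; extra trait species are
    dropped with a warning.  Fewer than ``min_common`` shared species is an
    error.  Callers that tolerate tree-only tips prune the tree first (see
    :func:`_common_cov`).
    """
    trait = dict(trait)
    common = [t for t in taxa if t in trait]
    only_tree = [t for t in taxa if t not in trait]
    only_trait = sorted(set(map(str, trait)) - set(taxa))
    if only_trait:
        logger.warning(
            "dropping %d trait-only species %s", len(only_trait), only_trait[:5]
        )
    if len(common) < min_common:
        raise ValueError(
            f"only {len(common)} species shared between tree and trait "
            f"(need >= {min_common}); tree-only={only_tree} trait-only={only_trait}"
        )
    if only_tree:
        raise ValueError(
            f"trait not defined for all tree tips (missing: {only_tree})"
        )
    return np.array([float(trait[t]) for t in taxa])


def _common_cov(tree: Tree, trait, cov: PhyloCovariance | None) -> PhyloCovariance:
    """Covariance restricted to tree/trait shared species.

    Tips without a trait value are dropped (with a warning) by pruning the
    tree; a hard error only if fewer than 3 species remain.
    """
    from .treeio import prune_to

    if cov is None:
        cov = phylo_covariance(tree)
    trait = dict(trait)
    only_tree = [t for t in cov.taxa if t not in trait]
    if not only_tree:
        return cov
    common = [t for t in cov.taxa if t in trait]
    logger.warning(
        "dropping %d tree-only species %s", len(only_tree), only_tree[:5]
    )
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} species shared between tree and trait (need >= 3)"
        )
    return phylo_covariance(prune_to(tree, common))


def _chol(C: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "phylogenetic covariance is singular (duplicate tips or "
            "zero-length terminal branches?); prune duplicates or add a ridge"
        ) from exc


def _gls_mse(L: np.ndarray, x: np.ndarray) -> float:
    """(x - a 1)' C^-1 (x - a 1) / (n-1) with a the GLS mean, via L = chol(C)."""
    n = x.shape[0]
    z = linalg.solve_triangular(L, x, lower=True)
    o = linalg.solve_triangular(L, np.ones(n), lower=True)
    a = (o @ z) / (o @ o)
    r = z - a * o
    return float(r @ r) / (n - 1)


def _k_parts(C: np.ndarray, x: np.ndarray):
    n = x.shape[0]
    L = _chol(C)
    o = linalg.solve_triangular(L, np.ones(n), lower=True)
    ones_quad = float(o @ o)  # 1' C^-1 1
    z = linalg.solve_triangular(L, x, lower=True)
    a = (o @ z) / ones_quad
    mse0 = float(np.sum((x - a) ** 2)) / (n - 1)
    r = z - a * o
    mse = float(r @ r) / (n - 1)
    expected = (float(np.trace(C)) - n / ones_quad) / (n - 1)
    return L, mse0, mse, expected


def blomberg_k(tree: Tree, trait, *, cov: PhyloCovariance | None = None) -> SignalResult:
    """Blomberg's K for one continuous trait on a tree (no P-value).

    ``trait`` maps species to values (dict or pandas Series) covering all
    tips.  A precomputed covariance can be passed to amortize the tree
    traversal across traits.
    """
    cov = _common_cov(tree, trait, cov)
    x = align_trait(trait, cov.taxa)
    if np.ptp(x) == 0:
        raise ConstantTraitError("trait is constant; K is undefined")
    _, mse0, mse, expected = _k_parts(cov.matrix, x)
    return SignalResult(
        K=(mse0 / mse) / expected,
        observed_ratio=mse0 / mse,
        expected_ratio=expected,
        n=x.shape[0],
    )


def permutation_pvalue(
    tree: Tree,
    trait,
    n_permutations: int = 1000,
    seed: int | None = None,
    *,
    cov: PhyloCovariance | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation P-value.

    Trait values are permuted across tips ``n_permutations`` times; for
    each permutation the GLS MSE is recomputed against the fixed tree.
    P = (1 + #{MSE_perm <= MSE_obs}) / (n_permutations + 1), one-tailed,
    so P is never exactly 0 and P >= 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cov = _common_cov(tree, trait, cov)
    x = align_trait(trait, cov.taxa)
    if np.ptp(x) == 0:
        raise ConstantTraitError("trait is constant; K is undefined")
    L, mse0, mse, expected = _k_parts(cov.matrix, x)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_permutations):
        if _gls_mse(L, rng.permutation(x)) <= mse:
            n_le += 1
    return SignalResult(
        K=(mse0 / mse) / expected,
        observed_ratio=mse0 / mse,
        expected_ratio=expected,
        p_value=(1 + n_le) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
        n=x.shape[0],
    )
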