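"""Phylogenetic eigenvector regression (PVR) and PSR curves.

The patristic distance matrix is turned into an orthogonal eigenvector
basis by classical principal-coordinates analysis (Gower double-centering
of the squared distances, by default):

    B = -1/2 * J (D o D) J,   J = I - 11'/n

Eigenpairs with eigenvalue > tol * lambda_max are retained, sorted
descending.  The PSR (phylogenetic signal-representation) curve regresses
the trait on the first k eigenvectors for k = 1..m and plots the R^2
against the cumulative eigenvalue fraction; its shape diagnoses the tempo
of trait evolution (a Brownian trait tracks the 45-degree line, a
phylogeny-free trait rises like k/m).  Monte-Carlo envelopes under BM and
WN simulation give pointwise null bands (the red/yellow bands of the
published figure style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import align_trait
from .treeio import PatristicDistances, Tree, patristic_distances, phylo_covariance

__all__ = [
    "Eigenbasis",
    "PSRCurve",
    "NullEnvelope",
    "pvr_eigenbasis",
    "psr_curve",
    "psr_envelopes",
]


@dataclass(frozen=True)
class Eigenbasis:
    """Positive eigenpairs of the double-centered (squared) distance matrix."""

    taxa: tuple[str, ...]
    eigenvalues: np.ndarray  # (m,), descending, all > 0
    eigenvectors: np.ndarray  # (n, m), orthonormal columns

    @property
    def m(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.eigenvalues) / np.sum(self.eigenvalues)


@dataclass(frozen=True)
class PSRCurve:
    """R^2 of successive PVR models vs cumulative eigenvalue fraction."""

    x: np.ndarray  # cumulative eigenvalue fraction, (m,)
    y: np.ndarray  # R^2 of trait ~ first k eigenvectors, (m,)

    @property
    def area(self) -> float:
        """Signed trapezoid area between the curve and the identity line.

        The origin (0, 0) is prepended so the comparison with the
        45-degree reference is defined on the whole [0, 1] interval.
        Positive area = curve above the line (trait variance concentrates
        in the leading, deep-phylogeny eigenvectors).
        """
        x = np.concatenate([[0.0], self.x])
        y = np.concatenate([[0.0], self.y])
        return float(np.trapezoid(y - x, x))


@dataclass(frozen=True)
class NullEnvelope:
    """Pointwise quantile bands of the PSR curve under BM and WN nulls."""

    x: np.ndarray
    bm_lo: np.ndarray
    bm_hi: np.ndarray
    wn_lo: np.ndarray
    wn_hi: np.ndarray
    bm_mean: np.ndarray
    wn_mean: np.ndarray
    level: float
    n_sim: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cum_eigenvalue_fraction": self.x,
                "bm_lo": self.bm_lo,
                "bm_hi": self.bm_hi,
                "wn_lo": self.wn_lo,
                "wn_hi": self.wn_hi,
            }
        )


def pvr_eigenbasis(
    distances: PatristicDistances,
    *,
    squared: bool = True,
    tol: float = 1e-10,
) -> Eigenbasis:
    """PCoA eigenbasis of the patristic distance matrix.

    ``squared=True`` (default) double-centers the elementwise-squared
    distances (Gower), the standard PVR construction; ``squared=False``
    centers the raw distances.  Tree metrics need not be Euclidean, so
    eigenpairs with lambda <= tol * lambda_max are discarded.
    """
    D = distances.matrix
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    A = -0.5 * (D * D if squared else D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(vals.max(), np.finfo(float).tiny)
    if keep.sum() < 2:
        raise ValueError(
            "degenerate geometry: fewer than 2 positive eigenvalues in PCoA"
        )
    return Eigenbasis(distances.taxa, vals[keep], vecs[:, keep])


def psr_curve(basis: Eigenbasis, trait) -> PSRCurve:
    """Sequential-OLS R^2 curve of a trait on the first k eigenvectors.

    The eigenvectors are orthonormal and centered, so the R^2 of the model
    with the first k of them is the cumulative sum of squared projections
    of the centered trait on each eigenvector, divided by the trait's
    total sum of squares (identical to refitting OLS for each k).
    """
    x = align_trait(trait, basis.taxa)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: R^2 undefined")
    xc = x - x.mean()
    tss = float(xc @ xc)
    proj = basis.eigenvectors.T @ xc  # (m,)
    y = np.minimum(np.cumsum(proj**2) / tss, 1.0)
    return PSRCurve(basis.cumulative_fraction, y)


def psr_envelopes(
    tree: Tree,
    basis: Eigenbasis,
    n_sim: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> NullEnvelope:
    """Monte-Carlo PSR bands under BM and WN traits simulated on the tree."""
    from .synthetic_data import simulate_trait

    if n_sim < 20:
        raise ValueError("n_sim must be >= 20 for meaningful quantiles")
    rng = np.random.default_rng(seed)
    curves = {"BM": [], "WN": []}
    for model in ("BM", "WN"):
        for _ in range(n_sim):
            tr = simulate_trait(
                tree, model, mu=0.0, sigma2=1.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            curves[model].append(psr_curve(basis, tr).y)
    bm = np.array(curves["BM"])
    wn = np.array(curves["WN"])
    qlo, qhi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    return NullEnvelope(
        x=basis.cumulative_fraction,
        bm_lo=np.quantile(bm, qlo, axis=0),
        bm_hi=np.quantile(bm, qhi, axis=0),
        wn_lo=np.quantile(wn, qlo, axis=0),
        wn_hi=np.quantile(wn, qhi, axis=0),
        bm_mean=bm.mean(axis=0),
        wn_mean=wn.mean(axis=0),
        level=level,
        n_sim=n_sim,
        seed=seed,
    )
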