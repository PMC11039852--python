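"""Phylogenetic generalized least squares (PGLS).

Regresses a phenological trait on a plant functional trait while modeling
the error covariance as the Brownian phylogenetic covariance C (optionally
Pagel-lambda scaled: off-diagonal entries multiplied by lambda).  With
V the error structure:

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y
    sigma2_hat = (y - X beta_hat)' V^-1 (y - X beta_hat) / (n - p)
    SE = sqrt(diag(sigma2_hat (X' V^-1 X)^-1))

t statistics use n - p degrees of freedom.  With V = I the fit is exactly
ordinary least squares.

Functional traits are binary categories with fixed reference levels
(shrub, biotic, deciduous), so the indicator is 1 for tree / abiotic /
evergreen and the coefficient sign is deterministic: e.g. later leaf-out
in trees gives a positive life-form coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .signal import align_trait
from .treeio import PhyloCovariance

__all__ = [
    "FunctionalTraits",
    "PGLSFit",
    "FUNCTIONAL_TRAITS",
    "REFERENCE_LEVELS",
    "encode_design",
    "pgls_fit",
    "read_functional_traits_csv",
]

# column -> (reference level, indicator level); indicator = 1 for the second
FUNCTIONAL_TRAITS = {
    "life_form": ("shrub", "tree"),
    "pollination": ("biotic", "abiotic"),
    "leaf_habit": ("deciduous", "evergreen"),
}
REFERENCE_LEVELS = {k: v[0] for k, v in FUNCTIONAL_TRAITS.items()}


@dataclass
class FunctionalTraits:
    """Per-species categorical traits: life form, pollination, leaf habit."""

    data: pd.DataFrame  # index = species

    def __post_init__(self) -> None:
        df = self.data
        for col, levels in FUNCTIONAL_TRAITS.items():
            if col not in df.columns:
                raise ValueError(f"functional-trait table lacks column {col!r}")
            bad = set(df[col].dropna()) - set(levels)
            if bad:
                raise ValueError(f"unknown {col} categories: {sorted(bad)}")
            if df[col].isna().any():
                missing = list(df.index[df[col].isna()])
                raise ValueError(f"missing {col} for species {missing[:5]}")
        self.data = df.sort_index()

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.index)


@dataclass(frozen=True)
class PGLSFit:
    predictors: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    df_resid: int
    lam: float  # Pagel's lambda applied to the correlation structure
    n: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.t, "p": self.p},
            index=list(self.predictors),
        )


def encode_design(
    traits: FunctionalTraits, predictor: str, taxa=None
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Intercept + one 0/1 indicator design for a functional trait.

    Returns ``(X, column_names, taxa)`` in canonical (sorted) species
    order, restricted to ``taxa`` when given.  The indicator is 1 for the
    non-reference level (tree / abiotic / evergreen).
    """
    if predictor not in FUNCTIONAL_TRAITS:
        raise KeyError(
            f"unknown functional trait {predictor!r}; "
            f"choose from {sorted(FUNCTIONAL_TRAITS)}"
        )
    df = traits.data
    if taxa is not None:
        missing = sorted(set(taxa) - set(df.index))
        if missing:
            raise KeyError(f"species lacking functional traits: {missing[:5]}")
        df = df.loc[list(taxa)]
    ref, ind = FUNCTIONAL_TRAITS[predictor]
    z = (df[predictor] == ind).to_numpy(dtype=float)
    if z.min() == z.max():
        raise ValueError(
            f"all species share one {predictor} level; design is rank deficient"
        )
    X = np.column_stack([np.ones(len(df)), z])
    return X, ("intercept", f"{predictor}[{ind}]"), tuple(df.index)


def _lambda_scale(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimates plus the profile ML log-likelihood (for lambda search)."""
    n, p = X.shape
    L = linalg.cholesky(V, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    Xt = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    xtvx_inv = np.linalg.inv(Xt.T @ Xt)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    s2_ml = rss / n if rss > 0 else 0.0
    if s2_ml > 0:
        logL = -0.5 * n * np.log(2 * np.pi * s2_ml) - 0.5 * logdet - 0.5 * n
    else:
        logL = np.inf
    return beta, rss, xtvx_inv, logL


def pgls_fit(
    y,
    X: np.ndarray,
    C: PhyloCovariance,
    *,
    predictors: tuple[str, ...] | None = None,
    lambda_mode: str = "fixed",
    lam: float = 1.0,
) -> PGLSFit:
    """Fit a PGLS regression.

    Parameters
    ----------
    y
        Response: {species: value} mapping aligned to ``C.taxa``, or an
        array already in that order.
    X
        Design matrix in the same species order (see :func:`encode_design`).
    C
        Phylogenetic covariance.
    lambda_mode
        "fixed" uses ``lam`` as given (default 1.0 = pure Brownian
        structure, 0.0 = OLS); "ML" profiles lambda over [0, 1] by a
        likelihood grid plus golden-section refinement.
    """
    yv = align_trait(y, C.taxa) if hasattr(y, "keys") else np.asarray(y, dtype=float)
    n, p = X.shape
    if yv.shape[0] != n or C.matrix.shape[0] != n:
        raise ValueError(
            f"taxa misaligned: y has {yv.shape[0]}, X has {n}, C has "
            f"{C.matrix.shape[0]} rows"
        )
    if lambda_mode == "ML":
        from scipy import optimize

        grid = np.linspace(0.0, 1.0, 21)
        lls = [
            _gls_core(yv, X, _lambda_scale(C.matrix, g))[3] for g in grid
        ]
        g0 = grid[int(np.argmax(lls))]
        res = optimize.minimize_scalar(
            lambda g: -_gls_core(yv, X, _lambda_scale(C.matrix, g))[3],
            bounds=(max(0.0, g0 - 0.05), min(1.0, g0 + 0.05)),
            method="bounded",
        )
        lam = float(res.x) if -res.fun >= max(lls) else float(g0)
    elif lambda_mode != "fixed":
        raise ValueError("lambda_mode must be 'fixed' or 'ML'")
    V = _lambda_scale(C.matrix, lam)
    beta, rss, xtvx_inv, _ = _gls_core(yv, X, V)
    df_resid = n - p
    sigma2 = rss / df_resid
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtvx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return PGLSFit(
        predictors=predictors or tuple(f"x{i}" for i in range(p)),
        coef=beta,
        se=se,
        t=t,
        p=pvals,
        sigma2=float(sigma2),
        df_resid=df_resid,
        lam=float(lam),
        n=n,
    )


def read_functional_traits_csv(path) -> FunctionalTraits:
    """Functional-trait CSV: species, life_form, pollination, leaf_habit."""
    df = pd.read_csv(path).set_index("species")
    df.index = df.index.astype(str)
    return FunctionalTraits(df)
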