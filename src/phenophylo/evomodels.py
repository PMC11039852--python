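"""Maximum-likelihood WN / BM / OU trait-model fits and AIC comparison.

Three Gaussian models for a continuous trait x on n species:

* WN (white noise): x ~ N(mu 1, sigma2 I) — phylogenetically independent
  variation.  MLEs are the sample mean and the (1/n) variance.
* BM (Brownian motion): x ~ N(mu 1, sigma2 C) with C the phylogenetic
  covariance — progressive random drift along the tree.
* OU (Ornstein-Uhlenbeck): drift with pull (strength alpha) toward an
  optimum.  Non-stationary, root fixed at the optimum, on an ultrametric
  tree:

      V_ij = (sigma2 / (2 alpha)) * exp(-alpha D_ij) * (1 - exp(-2 alpha C_ij))

  which converges entrywise to sigma2 * C as alpha -> 0, so BM nests
  exactly in OU at the alpha = 0 boundary.

mu and sigma2 are profiled in closed form (GLS mean; ML, not REML, so the
AIC magnitudes follow the k = {2, 2, 3} parameter counts).  alpha is
maximized by bounded 1-D search on the log scale with multistart, because
the likelihood is flat in alpha near 0.

Models are compared by AIC = -2 logL + 2k and Akaike weights
w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2); the selected model is
the one with the lowest AIC (equivalently the highest weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .signal import align_trait
from .treeio import PhyloCovariance, Tree, check_ultrametric, phylo_covariance

__all__ = [
    "ModelFit",
    "ModelComparison",
    "fit_wn",
    "fit_bm",
    "fit_ou",
    "fit_all",
    "compare_models",
]


@dataclass(frozen=True)
class ModelFit:
    model: str  # "WN" | "BM" | "OU"
    mu: float
    sigma2: float
    logL: float
    k: int
    n: int
    alpha: float | None = None
    at_bound: bool = False  # OU optimizer stopped on an alpha bound

    @property
    def AIC(self) -> float:
        return -2.0 * self.logL + 2.0 * self.k

    def aicc(self) -> float:
        n, k = self.n, self.k
        if n - k - 1 <= 0:
            return math.inf
        return self.AIC + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelComparison:
    fits: dict[str, ModelFit]
    delta_aic: dict[str, float] = field(init=False)
    akaike_weights: dict[str, float] = field(init=False)
    selected: str = field(init=False)

    def __post_init__(self):
        aics = {m: f.AIC for m, f in self.fits.items()}
        amin = min(aics.values())
        delta = {m: a - amin for m, a in aics.items()}
        raw = {m: math.exp(-d / 2.0) for m, d in delta.items()}
        tot = sum(raw.values())
        object.__setattr__(self, "delta_aic", delta)
        object.__setattr__(self, "akaike_weights", {m: r / tot for m, r in raw.items()})
        object.__setattr__(self, "selected", min(aics, key=aics.get))


def _as_vector(trait, taxa=None) -> np.ndarray:
    if taxa is not None:
        return align_trait(trait, taxa)
    x = np.asarray(
        [trait[k] for k in sorted(trait)] if isinstance(trait, dict) else trait,
        dtype=float,
    )
    return x


def _check_nonconstant(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 species, got {x.shape[0]}")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: degenerate (zero) variance")


def fit_wn(trait) -> ModelFit:
    """White-noise (non-phylogenetic i.i.d. normal) ML fit."""
    x = _as_vector(trait)
    _check_nonconstant(x)
    n = x.shape[0]
    mu = float(x.mean())
    sigma2 = float(np.sum((x - mu) ** 2)) / n
    logL = -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * n
    return ModelFit("WN", mu, sigma2, logL, k=2, n=n)


def _gls_profile(S: np.ndarray, x: np.ndarray):
    """Profile (mu, sigma2, logL) for x ~ N(mu 1, sigma2 S), S a fixed structure.

    Returns (mu_hat, sigma2_hat, logL, logdet_S).
    """
    n = x.shape[0]
    L = linalg.cholesky(S, lower=True)
    z = linalg.solve_triangular(L, x, lower=True)
    o = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(o @ z) / float(o @ o)
    r = z - mu * o
    sigma2 = float(r @ r) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    logL = -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return mu, sigma2, logL, logdet


def fit_bm(tree: Tree, trait, *, cov: PhyloCovariance | None = None) -> ModelFit:
    """Brownian-motion ML fit: x ~ N(mu 1, sigma2 C)."""
    if cov is None:
        cov = phylo_covariance(tree)
    x = align_trait(trait, cov.taxa)
    _check_nonconstant(x)
    try:
        mu, sigma2, logL, _ = _gls_profile(cov.matrix, x)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular phylogenetic covariance; prune duplicate/zero-length tips"
        ) from exc
    return ModelFit("BM", mu, sigma2, logL, k=2, n=x.shape[0])


def _ou_structure(C: np.ndarray, D: np.ndarray, alpha: float) -> np.ndarray:
    """OU covariance divided by sigma2: (1/(2a)) e^{-a D} (1 - e^{-2a C})."""
    W = np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)
    return W


def fit_ou(
    tree: Tree,
    trait,
    alpha_bounds: tuple[float, float] | None = None,
    *,
    cov: PhyloCovariance | None = None,
    fixed_alpha: float | None = None,
    n_starts: int = 8,
) -> ModelFit:
    """Ornstein-Uhlenbeck ML fit on an ultrametric tree.

    alpha is profiled by bounded scalar maximization of the log-likelihood
    on the log-alpha scale, restarted from ``n_starts`` points spread over
    ``alpha_bounds`` (default [1e-8, 50/T] with T the tree height) to avoid
    the flat ridge at small alpha.  ``fixed_alpha`` skips optimization
    (used for nesting checks).
    """
    ok, T = check_ultrametric(tree, rel_tol=1e-6)
    if not ok:
        depths = tree._root_to_node_depths()
        tips = sorted(
            ((leaf.taxon.label, depths[leaf]) for leaf in tree._dtree.leaf_node_iter()),
            key=lambda p: p[1],
        )
        raise ValueError(
            "OU fit needs an ultrametric tree; extreme tip depths: "
            f"{tips[0]} vs {tips[-1]}"
        )
    if cov is None:
        cov = phylo_covariance(tree)
    x = align_trait(trait, cov.taxa)
    _check_nonconstant(x)
    C = cov.matrix
    diag = np.diag(C)
    D = diag[:, None] + diag[None, :] - 2.0 * C

    def negloglik_logalpha(la: float) -> float:
        W = _ou_structure(C, D, math.exp(la))
        try:
            return -_gls_profile(W, x)[2]
        except linalg.LinAlgError:
            return math.inf

    if fixed_alpha is not None:
        alpha = fixed_alpha
        at_bound = False
    else:
        lo, hi = alpha_bounds if alpha_bounds is not None else (1e-8, 50.0 / T)
        llo, lhi = math.log(lo), math.log(hi)
        best_la, best_nll = llo, negloglik_logalpha(llo)
        for la0 in np.linspace(llo, lhi, n_starts):
            res = optimize.minimize_scalar(
                negloglik_logalpha,
                bounds=(llo, lhi),
                method="bounded",
                options={"xatol": 1e-10},
            ) if la0 == llo else optimize.minimize_scalar(
                negloglik_logalpha,
                bounds=(max(llo, la0 - 3.0), min(lhi, la0 + 3.0)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun < best_nll:
                best_nll, best_la = res.fun, float(res.x)
        alpha = math.exp(best_la)
        at_bound = bool(
            alpha <= lo * (1 + 1e-6) or alpha >= hi * (1 - 1e-6)
        )
    W = _ou_structure(C, D, alpha)
    mu, sigma2, logL, _ = _gls_profile(W, x)
    return ModelFit(
        "OU", mu, sigma2, logL, k=3, n=x.shape[0], alpha=alpha, at_bound=at_bound
    )


def fit_all(tree: Tree, trait, *, cov: PhyloCovariance | None = None) -> ModelComparison:
    """Fit WN, BM and OU to one trait and compare by AIC."""
    if cov is None:
        cov = phylo_covariance(tree)
    x = align_trait(trait, cov.taxa)
    wn = fit_wn(dict(zip(cov.taxa, x)))
    bm = fit_bm(tree, trait, cov=cov)
    ou = fit_ou(tree, trait, cov=cov)
    return compare_models(wn, bm, ou)


def compare_models(*fits: ModelFit) -> ModelComparison:
    """AIC ranking and Akaike weights for fits of the same trait."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different taxa sets (n = {sorted(ns)})")
    return ModelComparison({f.model: f for f in fits})
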