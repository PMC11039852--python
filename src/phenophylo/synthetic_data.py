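"""Synthetic study-system generator with known ground truth.

Emulates every input the pipeline consumes — a dated phylogeny, species
trait tables, daily station climate, long-format phenology observations
and functional traits — so every stage is testable end to end without any
external data.  The generators mirror the structure of multi-decade
station phenology programs: ~50-year daily weather with seasonal cycle,
interannual anomalies and AR(1) noise, and integer day-of-year phenophase
records produced by a known preseason window and known sensitivity slope,
through the SAME window-mean operator the estimator uses (so noiseless
recovery is exact by construction).

All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .evomodels import _ou_structure
from .sensitivity import DailyClimate, PhenoSeries, window_mean
from .treeio import Tree, check_ultrametric, phylo_covariance

__all__ = [
    "SyntheticConfig",
    "simulate_yule_tree",
    "simulate_trait",
    "simulate_climate",
    "simulate_phenology",
    "simulate_station",
    "StationFixture",
]


@dataclass
class SyntheticConfig:
    """Parameters of a full synthetic station.

    Defaults emulate a temperate deciduous station with a 50-year record
    (the analysis requires >= 50 years per species): spring leaf-out near
    DOY 100 driven by a 30-day preseason at -3 days/degC and a weak
    precipitation response, with phenophase baselines carrying a Brownian
    phylogenetic component plus functional-trait offsets.
    """

    seed: int = 0
    n_species: int = 40
    birth_rate: float = 1.0
    # trait simulation defaults (used by simulate_station's baseline traits)
    trait_model: str = "BM"
    trait_mu: float = 0.0
    trait_sigma2: float = 1.0
    trait_alpha: float = 1.0
    # climate
    years: tuple[int, int] = (1968, 2018)  # inclusive range
    annual_mean_c: float = 12.0
    seasonal_amplitude_c: float = 12.0
    peak_doy: float = 200.0
    ar1_coef: float = 0.7
    daily_noise_sd_c: float = 2.0
    year_effect_sd_c: float = 0.8
    prcp_gamma_shape: float = 0.6
    prcp_gamma_scale_mm: float = 4.0
    # phenology
    base_fld_doy: float = 100.0
    base_ffd_doy: float = 130.0
    preseason_days: int = 30
    slope_t: float = -3.0  # days/degC
    slope_p: float = 0.0  # days/mm
    pheno_noise_sd: float = 2.0
    # species-level structure
    base_doy_sigma2: float = 64.0  # phylogenetic variance of baseline DOY
    slope_sigma2: float = 0.25  # phylogenetic variance of slopes
    tree_effect_days: float = 10.0  # later leaf-out of trees vs shrubs
    noise_frac: float = 0.1  # independent (non-phylogenetic) variance share

    def __post_init__(self) -> None:
        if not 1 <= self.preseason_days <= 120:
            raise ValueError("preseason_days must lie in [1, 120]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        for name in ("trait_sigma2", "daily_noise_sd_c", "year_effect_sd_c",
                     "pheno_noise_sd", "base_doy_sigma2", "slope_sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def simulate_yule_tree(n_species: int, birth_rate: float = 1.0,
                       seed: int | None = None) -> Tree:
    """Pure-birth (Yule) ultrametric tree with tips sp001..spN.

    Standard forward construction: starting from two lineages, wait an
    Exp(k * birth_rate) time with k lineages alive, then split a uniformly
    chosen lineage; tips are extended to the final time, so the tree is
    exactly ultrametric.  E[height] = sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - node.birth_time
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    # final waiting time so tips do not end exactly at the last split
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    width = len(str(n_species))
    for i, node in enumerate(sorted(active, key=_preorder_key(tree))):
        node.edge.length = t - node.birth_time
        node.taxon = taxa.new_taxon(label=f"sp{i + 1:0{width}d}")
    return Tree(tree)


def _preorder_key(tree):
    order = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}
    return lambda nd: order[nd]


def trait_covariance(tree: Tree, model: str, sigma2: float,
                     alpha: float | None = None) -> tuple[tuple[str, ...], np.ndarray]:
    """Model covariance matrix: sigma2*I (WN), sigma2*C (BM), or OU V."""
    cov = phylo_covariance(tree)
    n = len(cov.taxa)
    if model == "WN":
        return cov.taxa, sigma2 * np.eye(n)
    if model == "BM":
        return cov.taxa, sigma2 * cov.matrix
    if model == "OU":
        if alpha is None or alpha <= 0:
            raise ValueError("OU simulation needs alpha > 0")
        ok, _ = check_ultrametric(tree)
        if not ok:
            raise ValueError("OU simulation needs an ultrametric tree")
        C = cov.matrix
        diag = np.diag(C)
        D = diag[:, None] + diag[None, :] - 2.0 * C
        return cov.taxa, sigma2 * _ou_structure(C, D, alpha)
    raise ValueError(f"unknown trait model {model!r}")


def simulate_trait(
    tree: Tree,
    model: str,
    mu: float = 0.0,
    sigma2: float = 1.0,
    alpha: float | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """One trait drawn from N(mu 1, Sigma) under WN, BM or OU."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    taxa, Sigma = trait_covariance(tree, model, max(sigma2, 0.0), alpha)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        x = np.full(len(taxa), mu)
    else:
        L = np.linalg.cholesky(Sigma + 1e-12 * np.trace(Sigma) / len(taxa) * np.eye(len(taxa)))
        x = mu + L @ rng.standard_normal(len(taxa))
    return dict(zip(taxa, x))


def simulate_climate(years: tuple[int, int], config: SyntheticConfig | None = None,
                     seed: int | None = None) -> tuple[DailyClimate, dict[int, float]]:
    """Daily temperature and precipitation over an inclusive year range.

    tmean(d) = annual_mean + amplitude * cos(2 pi (DOY - peak)/365.25)
               + year_effect(year) + AR(1) noise;
    prcp(d) ~ Gamma(shape, scale) >= 0, independent across days.

    Returns the climate and the injected per-year temperature anomalies
    (for recovery tests).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    y0, y1 = years
    if y1 < y0 + 1:
        raise ValueError("need at least 2 years of climate")
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    season = cfg.annual_mean_c + cfg.seasonal_amplitude_c * np.cos(
        2 * math.pi * (doy - cfg.peak_doy) / 365.25
    )
    year_effects = {
        int(y): float(e)
        for y, e in zip(
            range(y0, y1 + 1),
            rng.normal(0.0, cfg.year_effect_sd_c, y1 - y0 + 1),
        )
    }
    yeff = np.array([year_effects[int(y)] for y in dates.year])
    eps = np.empty(len(dates))
    innov_sd = cfg.daily_noise_sd_c * math.sqrt(max(1.0 - cfg.ar1_coef**2, 0.0))
    innov = rng.normal(0.0, 1.0, len(dates))
    eps[0] = cfg.daily_noise_sd_c * innov[0]
    for i in range(1, len(dates)):
        eps[i] = cfg.ar1_coef * eps[i - 1] + innov_sd * innov[i]
    tmean = season + yeff + eps
    prcp = rng.gamma(cfg.prcp_gamma_shape, cfg.prcp_gamma_scale_mm, len(dates))
    clim = DailyClimate(
        pd.DataFrame({"tmean_c": tmean, "prcp_mm": prcp}, index=dates)
    )
    return clim, year_effects


def simulate_phenology(
    climate: DailyClimate,
    species: str,
    phenophase: str,
    base_doy: float,
    preseason_days: int,
    slope_t: float,
    noise_sd: float,
    seed: int | None = None,
    *,
    slope_p: float = 0.0,
    years: tuple[int, int] | None = None,
) -> PhenoSeries:
    """Yearly phenophase dates generated from the preseason climate.

    DOY_y = base + slope_t * (Tbar_y - mean_y Tbar_y)
                 + slope_p * (Pbar_y - mean_y Pbar_y) + N(0, noise_sd),
    rounded to integer days and clipped to [1, 366], where Tbar_y / Pbar_y
    are the window means over the ``preseason_days`` days ending the day
    before the anchor DOY (= round(base)).  Uses the same window operator
    as the estimator, so with noise_sd = 0 the construction is exactly
    invertible up to DOY rounding.
    """
    rng = np.random.default_rng(seed)
    anchor = int(round(base_doy))
    y0 = climate.start.year if climate.start.dayofyear == 1 else climate.start.year + 1
    y1 = climate.end.year
    if years is not None:
        y0, y1 = max(y0, years[0]), min(y1, years[1])
    # require the full 120-day scan window so estimation can use every year
    usable = [
        y for y in range(y0, y1 + 1)
        if pd.Timestamp(year=y, month=1, day=1)
        + pd.Timedelta(days=anchor - 1 - max(120, preseason_days)) >= climate.start
    ]
    if len(usable) < 2:
        raise ValueError("climate record too short for the requested window")
    tbar = np.array([
        window_mean(climate, y, anchor, preseason_days, "temperature")
        for y in usable
    ])
    pbar = np.array([
        window_mean(climate, y, anchor, preseason_days, "precipitation")
        for y in usable
    ])
    doy = (
        base_doy
        + slope_t * (tbar - tbar.mean())
        + slope_p * (pbar - pbar.mean())
        + rng.normal(0.0, noise_sd, len(usable))
    )
    doy = np.clip(np.rint(doy), 1, 366).astype(int)
    return PhenoSeries(species, phenophase, dict(zip(usable, doy)))


@dataclass
class StationFixture:
    """Everything one station analysis consumes, plus its ground truth."""

    tree: Tree
    climate: DailyClimate
    phenology: dict[str, dict[str, PhenoSeries]]  # species -> phenophase -> series
    functional_traits: pd.DataFrame  # index species
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        """Write the fixture in the pipeline's input dialects."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "climate": outdir / "climate.csv",
            "phenology": outdir / "phenology.csv",
            "functional_traits": outdir / "functional_traits.csv",
        }
        paths["tree"].write_text(self.tree.write_newick() + "\n")
        self.climate.data.round(4).to_csv(paths["climate"], index_label="date")
        rows = [
            {"species": sp, "phenophase": ph, "year": y, "doy": d}
            for sp in sorted(self.phenology)
            for ph in sorted(self.phenology[sp])
            for y, d in sorted(self.phenology[sp][ph].doy_by_year.items())
        ]
        pd.DataFrame(rows).to_csv(paths["phenology"], index=False)
        self.functional_traits.to_csv(
            paths["functional_traits"], index_label="species"
        )
        return paths


def simulate_station(config: SyntheticConfig) -> StationFixture:
    """Coherent full fixture: tree, climate, phenology, functional traits.

    Species baseline phenophase dates carry a functional-trait offset
    (trees leaf out ``tree_effect_days`` later than shrubs), a
    phylogenetic component drawn under ``trait_model``, and an independent
    noise share; climate sensitivities likewise vary phylogenetically
    around the configured true slopes.  Yearly records then follow from
    the climate through the preseason window operator.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    tree = simulate_yule_tree(cfg.n_species, cfg.birth_rate, seed=child())
    taxa = tree.taxa
    climate, year_effects = simulate_climate(cfg.years, cfg, seed=child())

    # functional traits: balanced independent coin flips at the tips
    ft = pd.DataFrame(
        {
            "life_form": rng.choice(["tree", "shrub"], len(taxa)),
            "pollination": rng.choice(["biotic", "abiotic"], len(taxa)),
            "leaf_habit": rng.choice(["deciduous", "evergreen"], len(taxa)),
        },
        index=list(taxa),
    )

    phylo_var = cfg.base_doy_sigma2 * (1.0 - cfg.noise_frac)
    noise_var = cfg.base_doy_sigma2 * cfg.noise_frac
    alpha = cfg.trait_alpha if cfg.trait_model == "OU" else None

    def species_field(mu: float, s2_phylo: float, s2_noise: float) -> np.ndarray:
        g = simulate_trait(
            tree, cfg.trait_model, 0.0, s2_phylo, alpha, seed=child()
        )
        vals = np.array([g[t] for t in taxa])
        return mu + vals + rng.normal(0.0, math.sqrt(s2_noise), len(taxa))

    life_offset = (ft["life_form"] == "tree").to_numpy(float) * cfg.tree_effect_days
    base = {
        "FLD": cfg.base_fld_doy + life_offset
        + species_field(0.0, phylo_var, noise_var),
        "FFD": cfg.base_ffd_doy + life_offset
        + species_field(0.0, phylo_var, noise_var),
    }
    s_phylo = cfg.slope_sigma2 * (1.0 - cfg.noise_frac)
    s_noise = cfg.slope_sigma2 * cfg.noise_frac
    slopes_t = {
        ph: species_field(cfg.slope_t, s_phylo, s_noise) for ph in ("FLD", "FFD")
    }
    slopes_p = {
        ph: species_field(cfg.slope_p, 0.25 * s_phylo, 0.25 * s_noise)
        for ph in ("FLD", "FFD")
    }

    phenology: dict[str, dict[str, PhenoSeries]] = {}
    for i, sp in enumerate(taxa):
        phenology[sp] = {}
        for ph in ("FLD", "FFD"):
            phenology[sp][ph] = simulate_phenology(
                climate,
                sp,
                ph,
                base_doy=float(np.clip(base[ph][i], 30, 330)),
                preseason_days=cfg.preseason_days,
                slope_t=float(slopes_t[ph][i]),
                slope_p=float(slopes_p[ph][i]),
                noise_sd=cfg.pheno_noise_sd,
                seed=child(),
            )

    truth = {
        "preseason_days": cfg.preseason_days,
        "slope_t": {ph: dict(zip(taxa, slopes_t[ph])) for ph in ("FLD", "FFD")},
        "slope_p": {ph: dict(zip(taxa, slopes_p[ph])) for ph in ("FLD", "FFD")},
        "base_doy": {ph: dict(zip(taxa, base[ph])) for ph in ("FLD", "FFD")},
        "year_effects": year_effects,
        "trait_model": cfg.trait_model,
    }
    return StationFixture(tree, climate, phenology, ft, truth)
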