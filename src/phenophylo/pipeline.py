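"""Full station analysis: filter -> sensitivities -> signal -> models ->
PSR -> PGLS -> group summaries.

``run_station`` consumes the four station inputs (Newick tree, long
phenology CSV, daily climate CSV, functional-trait CSV), applies the
minimum-record-length species filter, estimates per-species preseason
sensitivities, assembles the six station-level trait vectors

    FLD, FFD, FLD-S_T, FFD-S_T, FLD-S_Prc, FFD-S_Prc

(mean phenophase dates plus their temperature and precipitation
sensitivities), and runs the comparative analyses on each: Blomberg's K
with a permutation P, WN/BM/OU fits with AIC and Akaike weights, and the
PSR curve with BM/WN envelopes; PGLS regressions relate each trait vector
to each functional trait.  Outputs are plain CSV/JSON artifacts shaped
like the published summary tables, plus a structured run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evomodels, pgls, psr, sensitivity, signal, treeio

__all__ = [
    "StationConfig",
    "StationReport",
    "run_station",
    "summarize_groups",
    "frequency_table",
    "TRAIT_NAMES",
]

logger = logging.getLogger(__name__)

TRAIT_NAMES = ("FLD", "FFD", "FLD-S_T", "FFD-S_T", "FLD-S_Prc", "FFD-S_Prc")


@dataclass
class StationConfig:
    """Single source of truth for one station run."""

    station: str
    tree: str
    phenology: str
    climate: str
    functional_traits: str
    min_years: int = 50
    max_preseason_days: int = 120
    n_permutations: int = 1000
    psr_n_sim: int = 100
    psr_level: float = 0.95
    seed: int = 0
    lambda_mode: str = "fixed"  # PGLS correlation: "fixed" (lambda=1) or "ML"
    use_abs_r: bool = True

    @classmethod
    def from_file(cls, path) -> "StationConfig":
        """Load from a flat JSON config file (keys = field names)."""
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**raw)
        for attr in ("tree", "phenology", "climate", "functional_traits"):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                setattr(cfg, attr, str(base / p))
        return cfg


@dataclass
class StationReport:
    station: str
    table1: pd.DataFrame  # per-trait K/P/AIC/weights/selected/psr_area
    table2: pd.DataFrame  # PGLS rows
    sensitivities: pd.DataFrame  # per-species preseason + slope rows
    psr_curves: pd.DataFrame  # long per-trait-per-k PSR + envelope rows
    summaries: pd.DataFrame  # group mean/median/range per phenophase
    retained_species: tuple[str, ...] = ()
    config: StationConfig | None = None
    extras: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1.csv", index=False)
        self.table2.to_csv(outdir / "table2.csv", index=False)
        self.sensitivities.to_csv(outdir / "sensitivities.csv", index=False)
        self.psr_curves.to_csv(outdir / "psr_curves.csv", index=False)
        self.summaries.to_csv(outdir / "summaries.csv", index=False)
        report = {
            "station": self.station,
            "retained_species": list(self.retained_species),
            "config": dataclasses.asdict(self.config) if self.config else None,
            "extras": self.extras,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        if self.config is not None:
            (outdir / "config.echo.json").write_text(
                json.dumps(dataclasses.asdict(self.config), indent=2) + "\n"
            )


def _species_sensitivities(
    series: dict, climate, cfg: StationConfig
) -> pd.DataFrame:
    rows = []
    for sp in sorted(series):
        for ph in sensitivity.PHENOPHASES:
            pheno = series[sp][ph]
            for var in sensitivity.VARIABLES:
                try:
                    pre = sensitivity.find_preseason(
                        pheno, climate, var, cfg.max_preseason_days,
                        use_abs_r=cfg.use_abs_r,
                    )
                    res = sensitivity.sensitivity_slope(pheno, climate, pre)
                except ValueError as exc:
                    logger.warning("failed sensitivity %s %s %s: %s", sp, ph, var, exc)
                    continue
                rows.append(
                    {
                        "species": sp,
                        "phenophase": ph,
                        "variable": var,
                        "preseason_days": pre.length,
                        "anchor_doy": pre.anchor_doy,
                        "r": res.pearson_r,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "n_years": pre.n_years,
                    }
                )
    return pd.DataFrame(rows)


def _trait_vectors(series: dict, sens: pd.DataFrame) -> dict[str, dict[str, float]]:
    """The six station-level trait vectors keyed by trait name."""
    vectors: dict[str, dict[str, float]] = {name: {} for name in TRAIT_NAMES}
    for sp in sorted(series):
        for ph in sensitivity.PHENOPHASES:
            vectors[ph][sp] = series[sp][ph].mean_doy()
    tag = {"temperature": "S_T", "precipitation": "S_Prc"}
    for _, row in sens.iterrows():
        vectors[f"{row['phenophase']}-{tag[row['variable']]}"][row["species"]] = row[
            "slope"
        ]
    return vectors


def run_station(cfg: StationConfig) -> StationReport:
    """Run the complete comparative analysis for one station."""
    logger.info("station %s: seed %d", cfg.station, cfg.seed)
    tree = treeio.parse_newick(Path(cfg.tree).read_text())
    climate = sensitivity.read_climate_csv(cfg.climate)
    series = sensitivity.read_phenology_csv(cfg.phenology)
    ftraits = pgls.read_functional_traits_csv(cfg.functional_traits)

    off_tree = sorted(set(series) - set(tree.taxa))
    if off_tree:
        logger.warning("dropping %d species absent from the tree: %s",
                       len(off_tree), off_tree[:5])
        series = {sp: d for sp, d in series.items() if sp in set(tree.taxa)}
    series = sensitivity.filter_min_years(series, cfg.min_years)
    keep = sorted(set(series) & set(tree.taxa))
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} species survive the {cfg.min_years}-year filter "
            "and tree matching; need >= 3"
        )
    series = {sp: series[sp] for sp in keep}
    tree = treeio.prune_to(tree, keep)
    cov = treeio.phylo_covariance(tree)
    dist = treeio.patristic_distances(tree)
    basis = psr.pvr_eigenbasis(dist)

    sens = _species_sensitivities(series, climate, cfg)
    vectors = _trait_vectors(series, sens)

    rng = np.random.default_rng(cfg.seed)
    t1_rows, psr_rows = [], []
    for name in TRAIT_NAMES:
        vec = vectors[name]
        if len(vec) < len(keep):
            logger.warning(
                "trait %s defined for %d/%d species", name, len(vec), len(keep)
            )
        sig = signal.permutation_pvalue(
            tree, vec, cfg.n_permutations, seed=int(rng.integers(2**31 - 1)), cov=cov
        )
        comp = evomodels.fit_all(tree, vec, cov=cov)
        curve = psr.psr_curve(basis, vec)
        env = psr.psr_envelopes(
            tree, basis, cfg.psr_n_sim, cfg.psr_level,
            seed=int(rng.integers(2**31 - 1)),
        )
        t1_rows.append(
            {
                "trait": name,
                "n": sig.n,
                "K": sig.K,
                "P": sig.p_value,
                "AIC_BM": comp.fits["BM"].AIC,
                "AIC_OU": comp.fits["OU"].AIC,
                "AIC_WN": comp.fits["WN"].AIC,
                "weight_BM": comp.akaike_weights["BM"],
                "weight_OU": comp.akaike_weights["OU"],
                "weight_WN": comp.akaike_weights["WN"],
                "selected": comp.selected,
                "psr_area": curve.area,
            }
        )
        for k in range(curve.x.shape[0]):
            psr_rows.append(
                {
                    "trait": name,
                    "k": k + 1,
                    "cum_eigenvalue_fraction": curve.x[k],
                    "R2": curve.y[k],
                    "bm_lo": env.bm_lo[k],
                    "bm_hi": env.bm_hi[k],
                    "wn_lo": env.wn_lo[k],
                    "wn_hi": env.wn_hi[k],
                }
            )

    t2_rows = []
    for pred in pgls.FUNCTIONAL_TRAITS:
        X, names, taxa = pgls.encode_design(ftraits, pred, taxa=cov.taxa)
        for name in TRAIT_NAMES:
            vec = vectors[name]
            try:
                fit = pgls.pgls_fit(
                    vec, X, cov, predictors=names, lambda_mode=cfg.lambda_mode
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("PGLS failed for %s ~ %s: %s", name, pred, exc)
                continue
            t2_rows.append(
                {
                    "station": cfg.station,
                    "functional_trait": pred,
                    "phenological_trait": name,
                    "coefficient": fit.coef[1],
                    "p_value": fit.p[1],
                    "n": fit.n,
                    "lambda": fit.lam,
                    "reference_level": pgls.REFERENCE_LEVELS[pred],
                }
            )

    summaries = summarize_groups(vectors, ftraits)

    return StationReport(
        station=cfg.station,
        table1=pd.DataFrame(t1_rows),
        table2=pd.DataFrame(t2_rows),
        sensitivities=sens,
        psr_curves=pd.DataFrame(psr_rows),
        summaries=summaries,
        retained_species=tuple(keep),
        config=cfg,
    )


def summarize_groups(vectors: dict, ftraits: pgls.FunctionalTraits) -> pd.DataFrame:
    """Mean / median / range of each trait per functional-trait level."""
    rows = []
    df = ftraits.data
    for trait_name, vec in vectors.items():
        s = pd.Series(vec)
        for ftrait, levels in pgls.FUNCTIONAL_TRAITS.items():
            for level in levels:
                members = [sp for sp in s.index
                           if sp in df.index and df.loc[sp, ftrait] == level]
                if not members:
                    logger.warning("empty group %s=%s for %s", ftrait, level,
                                   trait_name)
                    continue
                v = s.loc[members]
                rows.append(
                    {
                        "phenological_trait": trait_name,
                        "functional_trait": ftrait,
                        "level": level,
                        "n": len(v),
                        "mean": float(v.mean()),
                        "median": float(v.median()),
                        "min": float(v.min()),
                        "max": float(v.max()),
                    }
                )
    return pd.DataFrame(rows)


def frequency_table(values, bin_width: float, origin: float | None = None) -> pd.DataFrame:
    """Histogram counts over half-open bins [lo, lo + w) covering the data.

    The final bin is closed on the right so the maximum is counted; counts
    always sum to the number of values.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = float(origin) if origin is not None else float(v.min())
    n_bins = max(1, int(np.ceil((v.max() - lo) / bin_width)))
    if lo + n_bins * bin_width <= v.max():
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )
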