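"""End-to-end comparative pipeline: data preparation through reports.

Stages, in order: specimen records are averaged into a species table (per
specimen the left/right eye and cornea measurements are averaged first, then
specimens are averaged per species; body size enters as the cube root of
species-mean wet mass, RM, so isometry with length traits sits at slope 1);
the tree is matched to the data (prune / substitute / graft / resolve); six
pairwise allometric models (ED~RM, ED~SVL, CD~ED, CD~RM, CD~SVL, SVL~RM) are
fit by PGLS with ML lambda, OLS and SMA; PGLS residuals become investment
tables; each ecological trait is tested by Kruskal-Wallis and phylogenetic
ANCOVA; and the Studentized-residual outlier sensitivity check reruns the
focal PGLS. Every stage logs species counts, and all outputs are plain CSV /
JSON / Newick so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import allometry, ecology, pgls, phylo
from .synthetic import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARISONS",
    "PipelineConfig",
    "prepare_species_table",
    "match_tree",
    "fit_allometries",
    "run_pipeline",
]

#: The six pairwise scaling models, as (response, predictor) log10 columns.
COMPARISONS: tuple[tuple[str, str], ...] = (
    ("ED_log", "RM_log"),
    ("ED_log", "SVL_log"),
    ("CD_log", "ED_log"),
    ("CD_log", "RM_log"),
    ("CD_log", "SVL_log"),
    ("SVL_log", "RM_log"),
)

#: Default specimen CSV column mapping (input name -> canonical name).
DEFAULT_COLUMNS: dict[str, str] = {
    "species": "species",
    "condition": "condition",
    "SVL_mm": "SVL_mm",
    "mass_g": "mass_g",
    "ED_left_mm": "ED_left_mm",
    "ED_right_mm": "ED_right_mm",
    "CD_left_mm": "CD_left_mm",
    "CD_right_mm": "CD_right_mm",
    "AL_mm": "AL_mm",
}


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Either ``sim`` (synthetic mode) or the three input paths must be set.
    ``rm_from_mean_mass`` selects whether RM is the cube root of the species
    mean mass (default) or the mean of per-specimen cube roots.
    """

    out_dir: Path = Path("frogeye_out")
    seed: int = 0
    sim: Optional[SimConfig] = None
    traits_csv: Optional[Path] = None
    tree_newick: Optional[Path] = None
    ecology_csv: Optional[Path] = None
    substitutions_csv: Optional[Path] = None  # two columns: old,new
    grafts_csv: Optional[Path] = None         # two columns: new_taxon,sister
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    condition_filter: Optional[str] = "preserved"
    outlier_threshold: float = 3.0
    robust_sma: bool = False
    investment_model: tuple[str, str] = ("ED_log", "RM_log")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        kwargs = {}
        for key in ("out_dir", "traits_csv", "tree_newick", "ecology_csv",
                    "substitutions_csv", "grafts_csv"):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw.pop(key))
        for key in ("seed", "columns", "condition_filter", "outlier_threshold",
                    "robust_sma"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "investment_model" in raw:
            kwargs["investment_model"] = tuple(raw.pop("investment_model"))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        if sim is not None:
            kwargs["sim"] = SimConfig(**sim)
        return cls(**kwargs)


def prepare_species_table(
    records: pd.DataFrame,
    columns: Optional[Mapping[str, str]] = None,
    condition: Optional[str] = None,
    rm_from_mean_mass: bool = True,
) -> pd.DataFrame:
    """Collapse specimen records to a species table with log10 trait columns.

    Per specimen, ED = mean(left, right) (one side is enough, with a
    warning), likewise CD; species values are arithmetic means over
    specimens; RM = (species mean mass)^(1/3). Records with a non-positive
    measurement are rejected and logged; species left with no valid record
    are dropped with a warning.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    inv = {v: k for k, v in colmap.items()}
    df = records.rename(columns=inv).copy()
    if "species" not in df.columns:
        raise KeyError("no species column after mapping")
    if condition is not None and "condition" in df.columns:
        df = df[df["condition"] == condition]

    measure_cols = [c for c in ("SVL_mm", "mass_g", "ED_left_mm", "ED_right_mm",
                                "CD_left_mm", "CD_right_mm", "AL_mm")
                    if c in df.columns]
    bad = pd.Series(False, index=df.index)
    for c in measure_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        df[c] = vals
        bad |= vals <= 0
    if bad.any():
        logger.warning(
            "prepare_species_table: rejected %d records with non-positive "
            "measurements", int(bad.sum()),
        )
        df = df[~bad]

    def side_mean(row, left, right):
        lv, rv = row.get(left), row.get(right)
        if pd.isna(lv) and pd.isna(rv):
            return np.nan
        if pd.isna(lv) or pd.isna(rv):
            return lv if pd.isna(rv) else rv
        return 0.5 * (lv + rv)

    one_sided = (
        df[["ED_left_mm", "ED_right_mm"]].isna().sum(axis=1) == 1
    ).sum() if {"ED_left_mm", "ED_right_mm"} <= set(df.columns) else 0
    if one_sided:
        logger.warning(
            "prepare_species_table: %d specimens with a single eye "
            "measurement", int(one_sided),
        )
    df["ED_mm"] = df.apply(lambda r: side_mean(r, "ED_left_mm", "ED_right_mm"), axis=1)
    df["CD_mm"] = df.apply(lambda r: side_mean(r, "CD_left_mm", "CD_right_mm"), axis=1)
    no_eye = df["ED_mm"].isna() & df["CD_mm"].isna()
    if no_eye.any():
        logger.warning(
            "prepare_species_table: rejected %d records without any eye "
            "measurement", int(no_eye.sum()),
        )
        df = df[~no_eye]

    agg_cols = [c for c in ("ED_mm", "CD_mm", "SVL_mm", "mass_g", "AL_mm")
                if c in df.columns]
    grouped = df.groupby("species")
    species = grouped[agg_cols].mean()
    species["n_specimens"] = grouped.size()
    empty = species[agg_cols].isna().all(axis=1)
    if empty.any():
        logger.warning(
            "prepare_species_table: dropped species with no valid records: %s",
            sorted(species.index[empty]),
        )
        species = species[~empty]
    if rm_from_mean_mass:
        species["RM"] = np.cbrt(species["mass_g"])
    else:
        species["RM"] = grouped["mass_g"].apply(lambda v: np.cbrt(v).mean())
    for raw, log in (("ED_mm", "ED_log"), ("CD_mm", "CD_log"),
                     ("SVL_mm", "SVL_log"), ("RM", "RM_log"),
                     ("AL_mm", "AL_log")):
        if raw in species.columns:
            with np.errstate(divide="ignore", invalid="ignore"):
                species[log] = np.where(
                    species[raw] > 0, np.log10(species[raw]), np.nan
                )
    species.index = species.index.map(lambda s: str(s).replace(" ", "_"))
    species.index.name = "species"
    logger.info(
        "prepare_species_table: %d records -> %d species", len(records), len(species)
    )
    return species.sort_index()


def match_tree(
    tree: phylo.Phylogeny,
    species: pd.DataFrame,
    substitutions: Optional[Mapping[str, str]] = None,
    grafts: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> tuple[phylo.Phylogeny, pd.DataFrame]:
    """Match tree and species table: substitute, graft, prune, resolve.

    Species absent from the (edited) tree and tips absent from the data are
    dropped and logged; an empty intersection aborts. Returns the binary
    analysis tree and the matched species table in tree-tip order.
    """
    t = tree
    if substitutions:
        t = phylo.substitute_tips(t, substitutions)
    if grafts:
        for new_taxon, sister in grafts.items():
            t = phylo.graft_polytomy_tip(t, new_taxon, sister)
    tips = set(t.tips)
    data_species = set(species.index)
    common = sorted(tips & data_species)
    if not common:
        raise ValueError("no overlap between tree tips and species table")
    dropped_data = sorted(data_species - tips)
    dropped_tips = sorted(tips - data_species)
    if dropped_data:
        logger.info("match_tree: %d species not in tree: %s",
                    len(dropped_data), dropped_data[:10])
    if dropped_tips:
        logger.info("match_tree: %d tips without data pruned", len(dropped_tips))
    t = phylo.prune_to_taxa(t, common)
    t = phylo.resolve_polytomies(t, seed=seed)
    matched = species.loc[t.tips]
    return t, matched


def fit_allometries(
    species: pd.DataFrame,
    tree: phylo.Phylogeny,
    robust_sma: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pgls.PGLSFit]]:
    """Fit the six scaling models by PGLS (ML lambda), OLS and SMA.

    Per model, species missing either variable are dropped (the per-model n
    is recorded), mirroring per-model listwise deletion.
    """
    cov_all = phylo.phylo_covariance(tree)
    rows = []
    pgls_fits: dict[tuple[str, str], pgls.PGLSFit] = {}
    for response, predictor in COMPARISONS:
        sub = species[[response, predictor]].dropna()
        taxa = [tp for tp in cov_all.taxa if tp in sub.index]
        sub = sub.loc[taxa]
        cov = cov_all.subset(taxa)
        X = pgls.design_matrix(sub, [predictor])
        pfit = pgls.profile_lambda(X, sub[response], cov)
        pgls_fits[(response, predictor)] = pfit
        ofit = allometry.ols_fit(sub[predictor], sub[response])
        sfit = allometry.sma_fit(sub[predictor], sub[response], robust=robust_sma)
        common = {"response": response, "predictor": predictor, "n": len(sub)}
        rows.append({**common, "method": "PGLS", "slope": pfit.slope,
                     "intercept": pfit.intercept, "slope_se": float(pfit.bse[predictor]),
                     "r_squared": pfit.r_squared, "lambda": pfit.lambda_,
                     "t": float(pfit.tvalues[predictor]), "df_resid": pfit.df_resid,
                     "p": float(pfit.pvalues[predictor])})
        rows.append({**common, "method": "OLS", "slope": ofit.slope,
                     "intercept": ofit.intercept, "slope_se": ofit.slope_se,
                     "r_squared": ofit.r_squared, "lambda": np.nan,
                     "t": ofit.t, "df_resid": ofit.df, "p": ofit.p})
        rows.append({**common, "method": "SMA", "slope": sfit.slope,
                     "intercept": sfit.intercept, "slope_se": np.nan,
                     "r_squared": sfit.r**2, "lambda": np.nan,
                     "t": np.nan, "df_resid": sfit.n - 2, "p": sfit.isometry_p})
        logger.info(
            "fit_allometries: %s ~ %s n=%d PGLS slope %.3f lambda %.3f",
            response, predictor, len(sub), pfit.slope, pfit.lambda_,
        )
    table = pd.DataFrame(rows)
    return table, pgls_fits


def _two_column_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and serialize reports to ``config.out_dir``.

    Returns a result bundle with the species table, analysis tree, allometry
    fit table, PGLS fits, investment table, ecology test table and outlier
    report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    substitutions = grafts = None
    if config.sim is not None:
        ds = generate_dataset(config.sim)
        raw_dir = out / "synthetic_inputs"
        ds.write(raw_dir)
        records = ds.specimens
        tree = ds.tree
        eco = ds.ecology
    else:
        if not (config.traits_csv and config.tree_newick):
            raise ValueError("config needs traits_csv and tree_newick (or sim)")
        records = pd.read_csv(config.traits_csv)
        tree = phylo.read_newick(config.tree_newick)
        eco = (
            pd.read_csv(config.ecology_csv, index_col=0)
            if config.ecology_csv else None
        )
        if config.substitutions_csv:
            substitutions = _two_column_map(config.substitutions_csv)
        if config.grafts_csv:
            grafts = _two_column_map(config.grafts_csv)

    species = prepare_species_table(
        records, columns=config.columns, condition=config.condition_filter
    )
    tree, species = match_tree(
        tree, species, substitutions=substitutions, grafts=grafts,
        seed=config.seed,
    )
    if eco is not None:
        eco = eco.copy()
        eco.index = eco.index.map(lambda s: str(s).replace(" ", "_"))
        eco = ecology.validate_ecology(eco.reindex(species.index))

    fits_table, pgls_fits = fit_allometries(
        species, tree, robust_sma=config.robust_sma
    )

    # investment relative to the configured focal model (default ED ~ RM)
    focal = pgls_fits[tuple(config.investment_model)]
    investment = ecology.investment_scores(
        focal, ecology=eco, raw_size=species["ED_mm"]
    )
    cornea_key = ("CD_log", "ED_log")
    cornea_investment = ecology.investment_scores(pgls_fits[cornea_key], ecology=eco)

    eco_rows = []
    summaries = {}
    cov_all = phylo.phylo_covariance(tree)
    if eco is not None:
        for trait in ecology.ECOLOGICAL_TRAITS:
            if trait not in eco.columns:
                continue
            mask = investment[trait].notna()
            if investment.loc[mask, trait].nunique() < 2:
                continue
            for label, vals in (
                ("ED", investment.loc[mask, "raw_size"]),
                ("eye_investment", investment.loc[mask, "investment_factor"]),
                ("cornea_investment",
                 cornea_investment["investment_factor"].reindex(investment.index)[mask]),
            ):
                kw = ecology.kruskal_wallis(vals, investment.loc[mask, trait])
                eco_rows.append({"trait": trait, "test": f"KW_{label}",
                                 "statistic": kw.H, "df": f"{kw.df}",
                                 "p": kw.p})
            data = species.join(eco[[trait]])
            try:
                anc, anc_fit = ecology.phylo_ancova(
                    data, cov_all, response="ED_log", covariate="RM_log",
                    factor=trait,
                )
                for term in (trait, f"RM_log:{trait}"):
                    r = anc.loc[term]
                    eco_rows.append({
                        "trait": trait, "test": f"ANCOVA_{term}",
                        "statistic": float(r["F"]),
                        "df": f"{int(r['df'])}, {int(anc.loc['Residual', 'df'])}",
                        "p": float(r["p"]),
                    })
            except ValueError as err:
                logger.warning("phylo_ancova failed for %s: %s", trait, err)
                eco_rows.append({"trait": trait, "test": "ANCOVA", "statistic": np.nan,
                                 "df": "", "p": np.nan})
            summaries[trait] = ecology.group_summary(investment, trait)
    eco_table = pd.DataFrame(
        eco_rows, columns=["trait", "test", "statistic", "df", "p"]
    )

    # outlier sensitivity on the focal model
    resp, pred = config.investment_model
    sub = species[[resp, pred]].dropna()
    taxa = [t for t in cov_all.taxa if t in sub.index]
    cov = cov_all.subset(taxa)
    X = pgls.design_matrix(sub.loc[taxa], [pred])
    report = pgls.iterative_outlier_refit(
        X, sub.loc[taxa, resp], cov, threshold=config.outlier_threshold
    )

    # serialize
    species.to_csv(out / "species_table.csv", float_format="%.10g")
    phylo.write_newick(tree, out / "analysis_tree.nwk")
    fits_table.to_csv(out / "allometry_fits.csv", index=False, float_format="%.10g")
    investment.to_csv(out / "investment.csv", float_format="%.10g")
    cornea_investment.to_csv(out / "cornea_investment.csv", float_format="%.10g")
    eco_table.to_csv(out / "ecology_tests.csv", index=False, float_format="%.10g")
    for trait, summ in summaries.items():
        summ.to_csv(out / f"summary_{trait}.csv", float_format="%.10g")
    with open(out / "outlier_report.json", "w") as fh:
        json.dump(
            {
                "removed": report.iterations,
                "parameter_drift": report.parameter_drift.to_dict(),
                "initial": {"slope": report.initial_fit.slope,
                            "lambda": report.initial_fit.lambda_},
                "final": {"slope": report.final_fit.slope,
                          "lambda": report.final_fit.lambda_},
            },
            fh, indent=1, default=float,
        )
    with open(out / "pgls_fits.json", "w") as fh:
        json.dump(
            {f"{r}~{p}": f.to_dict() for (r, p), f in pgls_fits.items()},
            fh, indent=1, default=float,
        )
    logger.info("run_pipeline: wrote reports to %s", out)
    return {
        "species": species,
        "tree": tree,
        "allometry": fits_table,
        "pgls_fits": pgls_fits,
        "investment": investment,
        "cornea_investment": cornea_investment,
        "ecology_tests": eco_table,
        "summaries": summaries,
        "outlier_report": report,
    }
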