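"""Orchestration of the four-step trait-climate spatial analysis.

For every (group, grouping feature, trait):

1. Global Moran's I of the cell-aggregated abundance-weighted trait (AWT),
   under great-circle-distance weights between occupied cell centres;
2. zero-or-one-inflated beta regression of the cell AWT on all principal
   component scores of the climate layers — 100 x adjusted R2 is the
   *explained variance* by climate;
3. Moran's I of the model's response residuals, subtracted from step 1's
   value and expressed as a percentage — the *explained spatial
   autocorrelation*;
4. optional single-layer refits with each climate layer's original values
   as the only covariate, ranking the layers by explanatory power.

Results come back as flat DataFrames with machine-readable flag columns
(``trait_absent``, ``zero_variability``, ``not_significant``) mirroring the
footnote conventions of order-by-trait summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beinf, climate as climate_mod, composition, spatial
from .grid import ClimateStack

__all__ = ["run_combined_analysis", "run_single_bi_analysis", "summarize",
           "membership_summary", "PreparedData", "prepare"]

logger = logging.getLogger(__name__)


@dataclass
class PreparedData:
    """Cell-level data shared by the combined and single-layer analyses."""

    awt_cells: pd.DataFrame          # cell_id, feature, trait, awt, n_sites
    cell_ids: np.ndarray             # occupied cells with complete climate
    weights: spatial.SpatialWeights
    scores: np.ndarray               # cells x components (PCA of layers)
    layer_values: pd.DataFrame       # per-layer original values per cell
    pca: climate_mod.PCAResult
    single_trait_features: set = field(default_factory=set)


def prepare(abund: pd.DataFrame, traits: pd.DataFrame, stack: ClimateStack,
            genus_threshold: float = 0.01, absent_policy: str = "zero",
            weight_scheme: str = "inverse_distance",
            harmonize: bool = True) -> PreparedData:
    """Run the data-processing stages up to the cell-level tables."""
    if harmonize:
        abund = composition.harmonize_taxonomy(abund, threshold=genus_threshold)
    if "membership_pct" not in traits.columns:
        traits = composition.normalize_membership(traits)
    if "genus_id" in traits.columns:
        traits = composition.genus_trait_median(traits)
    site_awt = composition.compute_site_awt(abund, traits)
    awt_cells = composition.aggregate_to_cells(site_awt, stack.geometry,
                                               absent_policy=absent_policy)
    occupied = np.sort(awt_cells["cell_id"].unique())
    pca = climate_mod.pca_scores(stack, occupied)
    cell_ids = pca.cell_ids  # occupied cells with complete climate data
    awt_cells = awt_cells[awt_cells["cell_id"].isin(cell_ids)]
    lon, lat = stack.geometry.cell_center(cell_ids)
    weights = spatial.build_weights(lon, lat, scheme=weight_scheme)
    layer_values = pd.DataFrame(
        {name: stack.values_at_cells(name, cell_ids)
         for name in stack.layer_names})
    counts = traits.groupby("grouping_feature")["trait"].nunique()
    single = set(counts[counts < 2].index)
    return PreparedData(awt_cells=awt_cells, cell_ids=cell_ids,
                        weights=weights, scores=pca.scores,
                        layer_values=layer_values, pca=pca,
                        single_trait_features=single)


def _trait_vector(prep: PreparedData, feature: str, trait: str) -> np.ndarray:
    sub = prep.awt_cells[(prep.awt_cells["grouping_feature"] == feature)
                         & (prep.awt_cells["trait"] == trait)]
    y = (sub.set_index("cell_id")["awt"]
            .reindex(prep.cell_ids))
    if y.isna().any():
        # a cell with sites but no row for this trait means the trait table
        # never listed it for the cell's taxa; treat as absent
        y = y.fillna(0.0)
    return y.to_numpy()


def _analyze_one(y: np.ndarray, X: np.ndarray, weights, alpha: float) -> dict:
    """Steps 1-3 for one response vector; returns a flat result record."""
    rec = {"n_cells": y.size, "trait_absent": False, "zero_variability": False,
           "not_significant": False, "reason": "",
           "explained_variance_pct": np.nan,
           "explained_autocorrelation_pct": np.nan,
           "i_total": np.nan, "i_total_p": np.nan,
           "i_residual": np.nan, "i_residual_p": np.nan}
    if np.all(y == 0.0):
        rec.update(trait_absent=True, reason="trait not occurring")
        return rec
    if np.ptp(y) == 0.0:
        rec.update(zero_variability=True, reason="zero variability")
        return rec
    i_total = spatial.morans_i(y, weights)
    rec.update(i_total=i_total.I, i_total_p=i_total.p_value)
    try:
        fit = beinf.fit_beinf(y, X)
    except ValueError as exc:
        rec.update(reason=f"model fit failed: {exc}")
        return rec
    rec["explained_variance_pct"] = 100.0 * fit.r2_adj
    resid = fit.response_residuals
    i_res = spatial.morans_i(resid, weights)
    rec.update(i_residual=i_res.I, i_residual_p=i_res.p_value)
    part = spatial.partition_autocorrelation(i_total, i_res, alpha=alpha)
    if part.valid:
        rec["explained_autocorrelation_pct"] = part.explained_autocorrelation_pct
        rec["reason"] = part.reason
    else:
        rec.update(not_significant=True, reason=part.reason)
    return rec


def _groups_of(abund: pd.DataFrame, groups):
    if groups is None:
        if "group" in abund.columns:
            groups = sorted(abund["group"].dropna().unique())
        else:
            return {"full": abund}
    out = {g: abund[abund["group"] == g] for g in groups}
    out["full"] = abund
    return out


def run_combined_analysis(abund: pd.DataFrame, traits: pd.DataFrame,
                          stack: ClimateStack, *, groups=None,
                          genus_threshold: float = 0.01,
                          weight_scheme: str = "inverse_distance",
                          absent_policy: str = "zero",
                          alpha: float = 0.05,
                          min_cells: int = 3) -> pd.DataFrame:
    """Steps 1-3 for every group x grouping feature x trait.

    ``groups`` selects subsets of the abundance table via its ``group``
    column (e.g. insect orders); a pooled ``"full"`` run is always added.
    Without a group column there is a single full run.
    """
    abund = composition.harmonize_taxonomy(abund, threshold=genus_threshold)
    rows = []
    for group, sub in _groups_of(abund, groups).items():
        if sub.empty:
            logger.warning("group %s has no records; skipped", group)
            continue
        prep = prepare(sub, traits, stack, absent_policy=absent_policy,
                       weight_scheme=weight_scheme, harmonize=False)
        if prep.cell_ids.size < min_cells:
            logger.warning("group %s occupies %d cells (< %d); skipped",
                           group, prep.cell_ids.size, min_cells)
            continue
        X = np.column_stack([np.ones(prep.cell_ids.size), prep.scores])
        pairs = (prep.awt_cells[["grouping_feature", "trait"]]
                 .drop_duplicates().sort_values(["grouping_feature", "trait"]))
        for feature, trait in pairs.itertuples(index=False):
            if group != "full" and feature in prep.single_trait_features:
                continue  # single-trait feature skipped per group
            y = _trait_vector(prep, feature, trait)
            rec = _analyze_one(y, X, prep.weights, alpha)
            rec.update(group=group, grouping_feature=feature, trait=trait)
            rows.append(rec)
    cols = ["group", "grouping_feature", "trait", "explained_variance_pct",
            "explained_autocorrelation_pct", "i_total", "i_total_p",
            "i_residual", "i_residual_p", "n_cells", "trait_absent",
            "zero_variability", "not_significant", "reason"]
    return pd.DataFrame(rows, columns=cols)


def run_single_bi_analysis(abund: pd.DataFrame, traits: pd.DataFrame,
                           stack: ClimateStack, targets, *,
                           genus_threshold: float = 0.01,
                           weight_scheme: str = "inverse_distance",
                           absent_policy: str = "zero",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Step 4: refit each target trait with one climate layer at a time.

    ``targets`` is an iterable of (group, grouping_feature, trait).  The
    best layer per target (highest explained variance) is flagged.
    """
    abund = composition.harmonize_taxonomy(abund, threshold=genus_threshold)
    grouped = _groups_of(abund, None)
    rows = []
    preps: dict[str, PreparedData] = {}
    for group, feature, trait in targets:
        if group not in preps:
            sub = grouped.get(group, abund if group == "full" else None)
            if sub is None:
                sub = abund[abund["group"] == group]
            preps[group] = prepare(sub, traits, stack,
                                   absent_policy=absent_policy,
                                   weight_scheme=weight_scheme,
                                   harmonize=False)
        prep = preps[group]
        y = _trait_vector(prep, feature, trait)
        for name in prep.layer_values.columns:
            X = np.column_stack([np.ones(y.size),
                                 prep.layer_values[name].to_numpy()])
            rec = _analyze_one(y, X, prep.weights, alpha)
            rec.update(group=group, grouping_feature=feature, trait=trait,
                       bi=name)
            rows.append(rec)
    out = pd.DataFrame(rows)
    out["best"] = False
    for key, sub in out.groupby(["group", "grouping_feature", "trait"]):
        ev = sub["explained_variance_pct"]
        if ev.notna().any():
            out.loc[ev.idxmax(), "best"] = True
    cols = ["group", "grouping_feature", "trait", "bi",
            "explained_variance_pct", "explained_autocorrelation_pct",
            "i_total", "i_total_p", "i_residual", "i_residual_p", "n_cells",
            "trait_absent", "zero_variability", "not_significant", "reason",
            "best"]
    return out[cols]


def summarize(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Simple means over unflagged rows, per group and per grouping feature."""
    if results.empty:
        logger.warning("empty results table; nothing to summarize")
        return {"by_group": pd.DataFrame(), "by_feature": pd.DataFrame()}
    ok = results[~(results["trait_absent"] | results["zero_variability"])]
    if ok.empty:
        logger.warning("all rows flagged; empty report")
        return {"by_group": pd.DataFrame(), "by_feature": pd.DataFrame()}
    metrics = ["explained_variance_pct", "explained_autocorrelation_pct"]
    by_group = ok.groupby("group")[metrics].mean().reset_index()
    by_feature = ok.groupby("grouping_feature")[metrics].mean().reset_index()
    overall = ok[metrics].mean().to_frame().T
    overall.insert(0, "group", "average")
    return {"by_group": pd.concat([by_group, overall], ignore_index=True),
            "by_feature": by_feature}


def membership_summary(traits: pd.DataFrame,
                       group_col: str = "group") -> pd.DataFrame:
    """Median membership states per group, rescaled to 100% per feature.

    A convenience report: for each group of taxa (e.g. an insect order),
    the membership state of a trait is the median over the group's taxa,
    then scaled so each grouping feature sums to 100%.
    """
    if group_col not in traits.columns:
        traits = traits.assign(**{group_col: "all"})
    med = (traits.groupby([group_col, "grouping_feature", "trait"],
                          as_index=False)["membership_state"].median())
    totals = med.groupby([group_col, "grouping_feature"])[
        "membership_state"].transform("sum")
    med["membership_pct"] = np.where(totals > 0,
                                     100.0 * med["membership_state"] / totals,
                                     0.0)
    return med
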