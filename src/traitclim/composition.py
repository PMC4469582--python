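"""From abundance classes and fuzzy trait codes to abundance-weighted traits.

Stream macroinvertebrate monitoring reports semi-quantitative abundance
classes (integers 0-7 approximating log abundance; 0 = absent), and trait
databases describe each taxon's affinity for the categories ("traits") of a
grouping feature (e.g. temperature preference: cold / warm / eurytherm) as
membership states on a 0-10 fuzzy-coding scale.  This module turns the two
into the community-level response analysed downstream:

1. membership states are normalized to percentages per (taxon, feature);
2. taxonomy is harmonized — any genus identified at genus level at more
   than a threshold share of sites has all its species collapsed to the
   genus, merging duplicate records by the maximum class;
3. genera lacking trait data inherit the trait-wise median of their
   species' percentages, renormalized per feature;
4. the abundance-weighted trait (AWT) of a site is the abundance-class-
   weighted mean of percent memberships, averaged over the site's sampling
   events within the study window ("annual averaged"), giving a proportion
   in [0, 1] with exact zeros (trait absent) and ones possible;
5. site AWTs are averaged within each climate-raster cell so that a cell is
   one observation, avoiding pseudo-replication.

Tables are plain pandas DataFrames with documented columns (see
``ABUNDANCE_COLUMNS`` / ``TRAIT_COLUMNS``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grid import GridGeometry

__all__ = ["normalize_membership", "harmonize_taxonomy", "genus_trait_median",
           "compute_site_awt", "aggregate_to_cells",
           "ABUNDANCE_COLUMNS", "TRAIT_COLUMNS"]

logger = logging.getLogger(__name__)

ABUNDANCE_COLUMNS = ["site_id", "event_id", "lon", "lat", "taxon_id", "rank",
                     "genus_id", "abundance_class"]
TRAIT_COLUMNS = ["taxon_id", "rank", "grouping_feature", "trait",
                 "membership_state"]


def validate_abundance(abund: pd.DataFrame) -> None:
    missing = set(ABUNDANCE_COLUMNS) - set(abund.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    cls = abund["abundance_class"]
    if not np.isin(cls, np.arange(8)).all():
        raise ValueError("abundance_class outside {0,...,7}")
    species = abund[abund["rank"] == "species"]
    if species["genus_id"].isna().any():
        raise ValueError("species records without genus_id")
    if abund.duplicated(["site_id", "event_id", "taxon_id"]).any():
        raise ValueError("duplicate (site_id, event_id, taxon_id) records")


def normalize_membership(traits: pd.DataFrame) -> pd.DataFrame:
    """Convert raw 0-10 membership states to percentages per feature.

    Per (taxon, grouping feature) the states are rescaled to sum to 100.
    All-zero features are left at zero with a warning — such rows carry no
    trait information but record that the taxon was scored.
    """
    missing = set(TRAIT_COLUMNS) - set(traits.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    states = traits["membership_state"].to_numpy(float)
    if np.any(states < 0.0) or np.any(states > 10.0):
        raise ValueError("membership_state outside the raw 0-10 scale")
    out = traits.copy()
    totals = out.groupby(["taxon_id", "grouping_feature"])[
        "membership_state"].transform("sum")
    zero = totals == 0.0
    if zero.any():
        rows = out.loc[zero, ["taxon_id", "grouping_feature"]].drop_duplicates()
        logger.warning("all-zero membership for %d (taxon, feature) pairs; "
                       "left as zeros", len(rows))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(zero, 0.0, 100.0 * states / totals.to_numpy(float))
    out["membership_pct"] = pct
    return out


def harmonize_taxonomy(abund: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Collapse species to genus where genus-level records are common.

    A genus identified at genus level at more than ``threshold`` of all
    sites has every species record of that genus relabelled to the genus;
    records that become duplicates within a (site, event) merge into one
    genus record carrying the *maximum* abundance class (classes are
    log-like, so summing them is not meaningful, and the maximum is
    independent of merge order).  Idempotent.
    """
    validate_abundance(abund)
    n_sites = abund["site_id"].nunique()
    # only detections count as genus-level identifications
    present = abund[abund["abundance_class"] > 0]
    genus_records = present[present["rank"] == "genus"]
    sites_per_genus = genus_records.groupby("taxon_id")["site_id"].nunique()
    collapse = set(sites_per_genus[sites_per_genus / n_sites > threshold].index)
    if not collapse:
        return abund.copy()
    out = abund.copy()
    hit = (out["rank"] == "species") & out["genus_id"].isin(collapse)
    out.loc[hit, "taxon_id"] = out.loc[hit, "genus_id"]
    out.loc[hit, "rank"] = "genus"
    # extra columns (e.g. an order/group label) ride along with "first"
    agg = {c: "first" for c in out.columns
           if c not in {"site_id", "event_id", "taxon_id", "abundance_class"}}
    agg["abundance_class"] = "max"
    out = (out.groupby(["site_id", "event_id", "taxon_id"], as_index=False)
              .agg(agg))
    extras = [c for c in abund.columns if c not in ABUNDANCE_COLUMNS]
    return out[ABUNDANCE_COLUMNS + extras]


def genus_trait_median(traits: pd.DataFrame,
                       genus_map: dict | None = None) -> pd.DataFrame:
    """Impute genus-level trait percentages as species medians.

    For each genus not already present in the (normalized) trait table, the
    genus percentage for a trait is the median across its species'
    percentages, renormalized per grouping feature to sum to 100.  Genera
    whose species all lack trait data are flagged and excluded.

    ``genus_map`` maps species taxon_id to genus_id; if omitted the trait
    table must carry a ``genus_id`` column.
    """
    if "membership_pct" not in traits.columns:
        raise ValueError("traits must be normalized first (membership_pct)")
    if genus_map is None:
        if "genus_id" not in traits.columns:
            raise ValueError("need genus_map or a genus_id column")
        species = traits[traits["rank"] == "species"]
        genus_map = dict(zip(species["taxon_id"], species["genus_id"]))

    species_rows = traits[(traits["rank"] == "species")
                          & traits["taxon_id"].isin(genus_map)].copy()
    species_rows["genus_id"] = species_rows["taxon_id"].map(genus_map)
    existing = set(traits.loc[traits["rank"] == "genus", "taxon_id"])
    todo = species_rows[~species_rows["genus_id"].isin(existing)]
    if todo.empty:
        return traits.copy()

    med = (todo.groupby(["genus_id", "grouping_feature", "trait"],
                        as_index=False)["membership_pct"].median())
    totals = med.groupby(["genus_id", "grouping_feature"])[
        "membership_pct"].transform("sum")
    degenerate = totals == 0.0
    if degenerate.any():
        bad = med.loc[degenerate, ["genus_id", "grouping_feature"]].drop_duplicates()
        logger.warning("genus medians all zero for %d (genus, feature) pairs; "
                       "excluded", len(bad))
        med = med[~degenerate]
        totals = totals[~degenerate]
    med["membership_pct"] = 100.0 * med["membership_pct"] / totals.to_numpy(float)
    med = med.rename(columns={"genus_id": "taxon_id"})
    med["rank"] = "genus"
    med["membership_state"] = np.nan  # imputed rows have no raw state
    return pd.concat([traits, med], ignore_index=True)


def compute_site_awt(abund: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted trait proportions per site.

    Per (site, event, feature, trait):

        AWT = sum_taxa(class_i * pct_i,trait) / sum_taxa(class_i * 100)

    over the taxa joined to trait data for that feature; the site value is
    the mean over the site's sampling events that have any presence.  Sites
    where no feature-bearing taxon is present get ``absent=True`` and
    ``awt=0``.  Taxa absent from the trait table are logged and dropped.

    Returns columns: site_id, lon, lat, grouping_feature, trait, awt, absent.
    """
    validate_abundance(abund)
    if "membership_pct" not in traits.columns:
        raise ValueError("traits must be normalized first (membership_pct)")

    trait_cols = traits[["taxon_id", "grouping_feature", "trait",
                         "membership_pct"]]
    unmatched = set(abund["taxon_id"]) - set(trait_cols["taxon_id"])
    if unmatched:
        logger.warning("%d taxa lack trait data and are dropped: %s",
                       len(unmatched), sorted(unmatched)[:10])
    joined = abund.merge(trait_cols, on="taxon_id", how="inner")

    sites = abund[["site_id", "lon", "lat"]].drop_duplicates("site_id")
    all_traits = (trait_cols[["grouping_feature", "trait"]]
                  .drop_duplicates().sort_values(["grouping_feature", "trait"]))

    if joined.empty:
        grid = sites.merge(all_traits, how="cross")
        grid["awt"] = 0.0
        grid["absent"] = True
        return grid

    joined["num"] = joined["abundance_class"] * joined["membership_pct"]
    joined["den"] = joined["abundance_class"] * 100.0
    ev = (joined.groupby(["site_id", "event_id", "grouping_feature", "trait"],
                         as_index=False)
                .agg(num=("num", "sum"), den=("den", "sum")))
    present = ev[ev["den"] > 0.0].copy()
    present["awt_event"] = present["num"] / present["den"]
    site_awt = (present.groupby(["site_id", "grouping_feature", "trait"],
                                as_index=False)["awt_event"].mean()
                       .rename(columns={"awt_event": "awt"}))

    grid = sites.merge(all_traits, how="cross")
    out = grid.merge(site_awt, on=["site_id", "grouping_feature", "trait"],
                     how="left")
    out["absent"] = out["awt"].isna()
    out["awt"] = out["awt"].fillna(0.0)
    return out


def aggregate_to_cells(site_awt: pd.DataFrame, geometry: GridGeometry,
                       absent_policy: str = "zero") -> pd.DataFrame:
    """Average site AWTs within each raster cell.

    ``absent_policy='zero'`` (default) keeps trait-absent sites as AWT 0 —
    they are genuine observations of trait absence and supply the zero
    inflation the regression models; ``'drop'`` excludes them (sensitivity
    switch).  Cells without any contributing site are omitted.

    Returns columns: cell_id, cell_center_lon, cell_center_lat,
    grouping_feature, trait, awt, n_sites.
    """
    if absent_policy not in {"zero", "drop"}:
        raise ValueError("absent_policy must be 'zero' or 'drop'")
    df = site_awt.copy()
    sites = df[["site_id", "lon", "lat"]].drop_duplicates("site_id")
    inside = geometry.contains(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    if not inside.all():
        bad = sites.loc[~inside, "site_id"].tolist()
        raise ValueError(f"sites outside raster extent: {bad}")
    sites = sites.assign(cell_id=geometry.cell_id(sites["lon"].to_numpy(),
                                                  sites["lat"].to_numpy()))
    df = df.merge(sites[["site_id", "cell_id"]], on="site_id")
    if absent_policy == "drop":
        df = df[~df["absent"]]
    agg = (df.groupby(["cell_id", "grouping_feature", "trait"], as_index=False)
             .agg(awt=("awt", "mean"), n_sites=("site_id", "nunique")))
    lon, lat = geometry.cell_center(agg["cell_id"].to_numpy())
    agg.insert(1, "cell_center_lon", lon)
    agg.insert(2, "cell_center_lat", lat)
    return agg
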