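"""From abundance classes to cell-level abundance-weighted traits.

Reads the synthetic dataset written by 01_simulate_dataset.py, harmonizes
taxonomy (species collapse to genus where genus-level records exceed 1% of
sites), normalizes trait membership states to percentages, computes the
annual-averaged abundance-weighted trait (AWT) per site, and averages sites
within each climate-raster cell.  Writes site_awt.csv and cell_awt.csv.
"""

from pathlib import Path

import pandas as pd

from traitclim import composition
from traitclim.grid import ClimateStack

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    abund = pd.read_csv(BASE / "synthetic" / "abundance.csv")
    traits = pd.read_csv(BASE / "synthetic" / "traits.csv")
    stack = ClimateStack.read(BASE / "synthetic" / "climate")

    harmonized = composition.harmonize_taxonomy(abund, threshold=0.01)
    collapsed = abund["taxon_id"].nunique() - harmonized["taxon_id"].nunique()
    print(f"taxonomic harmonization removed {collapsed} species "
          f"(collapsed into genera)")

    norm = composition.normalize_membership(traits)
    norm = composition.genus_trait_median(norm)
    site_awt = composition.compute_site_awt(harmonized, norm)
    cell_awt = composition.aggregate_to_cells(site_awt, stack.geometry)

    site_awt.to_csv(BASE / "site_awt.csv", index=False)
    cell_awt.to_csv(BASE / "cell_awt.csv", index=False)

    occupied = cell_awt["cell_id"].nunique()
    zeros = (cell_awt["awt"] == 0.0).mean()
    print(f"{site_awt['site_id'].nunique()} sites -> {occupied} occupied "
          f"cells ({100 * occupied / stack.geometry.n_cells:.0f}% of grid)")
    print(f"{100 * zeros:.1f}% of cell x trait values are exact zeros")
    for (feat, trait), g in cell_awt.groupby(["grouping_feature", "trait"]):
        print(f"  {feat}/{trait}: mean AWT {g['awt'].mean():.3f}")


if __name__ == "__main__":
    main()
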