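"""Synthetic inputs with known trait-climate coupling.

The generator emulates the three inputs of the trait-climate analysis —
a semi-quantitative site-by-taxon abundance table, a fuzzy-coded trait
table, and a stack of spatially autocorrelated, mutually correlated
climate layers — with a *known* ground truth: one trait ("cold" preference
within temperature preference) is coupled to one climate layer with a
tunable strength, and one trait ("low" dispersal capacity) is neutral.
Every downstream stage can therefore be checked against what was planted.

Construction:

* Climate layers are Gaussian-kernel-smoothed white-noise fields on the
  cell grid (kernel length scale = ``spatial_range`` in degrees), each a
  mixture of a shared and a layer-own field so the layers are mutually
  correlated and exercise the PCA stage.  ``spatial_range = 0`` degenerates
  to white noise (Moran's I at its null expectation).
* Each taxon gets a dominant trait per grouping feature (state 6-10) and
  small memberships elsewhere (0-3), yielding sparse fuzzy codes with some
  pure-trait taxa, hence exact ones in the trait proportions.
* Site-by-taxon latent log-abundance = taxon baseline (N(-0.2, 1.5^2),
  spreading prevalence across taxa) + coupling_strength *
  (cold membership / 10) * standardized local climate + N(0, 1.5^2) noise,
  discretized to classes 0-7 at fixed equally spaced quantiles of the
  latent pool (class 0 mass ~ 0.3); a Bernoulli ``inflation_rate`` share of
  sites is forced entirely to class 0, producing the all-absent sites that
  feed the zero-inflated regression.

All randomness flows from ``numpy.random.default_rng`` seeded from
``config.seed`` (one stream per stage), so identical config implies
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ClimateStack, GridGeometry

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_climate_stack",
           "generate_trait_table", "generate_abundance_table",
           "generate_dataset"]

COUPLED_FEATURE = "temperature_preference"
COUPLED_TRAIT = "cold"
NEUTRAL_FEATURE = "dispersal_capacity"
NEUTRAL_TRAIT = "low"

FEATURES = {
    "temperature_preference": ["cold", "warm", "eurytherm"],
    "dispersal_capacity": ["low", "high"],
}

# cumulative probability below class 1; classes 1-7 share the rest equally
_P_ABSENT = 0.30

# latent log-abundance: taxon baselines and per-observation noise
_BASELINE_MEAN = -0.2
_BASELINE_SD = 1.5
_NOISE_SD = 1.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a desk-scale version of a national biomonitoring
    campaign on a 10-arc-minute climate grid: a 20 x 20 cell grid
    (cell size 1/6 degree), 800 sites, 150 taxa, 5 climate layers with a
    smoothing range of 5 cells, and a 10% rate of all-absent sites.
    """

    n_cells_x: int = 20
    n_cells_y: int = 20
    cell_size_deg: float = 1.0 / 6.0
    origin_lon: float = 6.0
    origin_lat: float = 47.0
    n_sites: int = 800
    n_taxa: int = 150
    n_climate_layers: int = 5
    spatial_range: float = 5.0 / 6.0   # degrees; 5 cells at the default size
    coupling_strength: float = 1.0
    inflation_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_x <= 0 or self.n_cells_y <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_sites <= 0 or self.n_taxa < 2:
            raise ValueError("need n_sites >= 1 and n_taxa >= 2")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if not 0.0 <= self.inflation_rate <= 1.0:
            raise ValueError("inflation_rate must be in [0, 1]")
        if self.spatial_range < 0:
            raise ValueError("spatial_range must be >= 0")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(origin_lon=self.origin_lon,
                            origin_lat=self.origin_lat,
                            cell_size_deg=self.cell_size_deg,
                            n_x=self.n_cells_x, n_y=self.n_cells_y)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


def _smoothed_field(noise: np.ndarray, kernel: np.ndarray | None) -> np.ndarray:
    f = noise if kernel is None else kernel @ noise
    return (f - f.mean()) / f.std()


def generate_climate_stack(config: SyntheticConfig) -> ClimateStack:
    """Smooth, mutually correlated climate layers on the config grid.

    Each layer mixes one shared and one layer-own smoothed field
    (correlation share drawn from U(0.35, 0.7)) and receives its own offset
    and scale, imitating incommensurable bioclimatic-index units.
    """
    if config.n_climate_layers < 2:
        raise ValueError("need at least 2 climate layers")
    geo = config.geometry
    rng = config.rng(1)
    lon, lat = geo.center_arrays()
    pts = np.column_stack([lon.ravel(), lat.ravel()])
    kernel = None
    if config.spatial_range > 0.0:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        kernel = np.exp(-d2 / (2.0 * config.spatial_range ** 2))
    n = geo.n_cells
    shared = _smoothed_field(rng.standard_normal(n), kernel)
    layers = {}
    for j in range(config.n_climate_layers):
        own = _smoothed_field(rng.standard_normal(n), kernel)
        alpha = rng.uniform(0.35, 0.7)
        field = alpha * shared + np.sqrt(1.0 - alpha ** 2) * own
        offset = rng.uniform(-5.0, 20.0)
        scale = rng.uniform(0.5, 5.0)
        layers[f"bio{j + 1:02d}"] = (offset + scale * field).reshape(geo.n_y,
                                                                     geo.n_x)
    # altitude: another smooth field on the same grid, in metres
    alt = _smoothed_field(rng.standard_normal(n), kernel)
    altitude = (400.0 + 300.0 * alt).reshape(geo.n_y, geo.n_x)
    return ClimateStack(geo, layers, altitude=altitude)


def generate_trait_table(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Fuzzy-coded trait table plus ground-truth metadata.

    Returns ``(traits, metadata)``: the table has columns taxon_id, rank,
    genus_id, grouping_feature, trait, membership_state (integers 0-10, one
    dominant trait per feature); metadata records which trait is
    climate-coupled, which is neutral, and each taxon's coupled-membership
    weight used by the abundance generator.
    """
    if config.n_taxa < 2:
        raise ValueError("need n_taxa >= 2")
    rng = config.rng(2)
    # a minority of genera carry genus-rank records (and two congeneric
    # species each) to exercise taxonomic harmonization; the remaining taxa
    # are standalone species in their own genera
    n_shared = min(max(config.n_taxa // 12, 1 if config.n_taxa >= 3 else 0),
                   config.n_taxa // 3)
    taxa = []
    for g in range(n_shared):
        genus = f"genus{g + 1:02d}"
        taxa.append((genus, "genus", genus))
        taxa.append((f"{genus}_sp1", "species", genus))
        taxa.append((f"{genus}_sp2", "species", genus))
    for i in range(len(taxa), config.n_taxa):
        genus = f"genus{n_shared + i + 1:02d}"
        taxa.append((f"{genus}_sp1", "species", genus))
    taxa = taxa[:config.n_taxa]
    rows = []
    for taxon_id, rank, genus in taxa:
        for feature, trait_names in FEATURES.items():
            dominant = rng.integers(len(trait_names))
            states = rng.integers(0, 4, size=len(trait_names))
            states[dominant] = rng.integers(6, 11)
            for t, s in zip(trait_names, states):
                rows.append({"taxon_id": taxon_id, "rank": rank,
                             "genus_id": genus, "grouping_feature": feature,
                             "trait": t, "membership_state": int(s)})
    traits = pd.DataFrame(rows)

    coupled = traits[(traits["grouping_feature"] == COUPLED_FEATURE)
                     & (traits["trait"] == COUPLED_TRAIT)]
    weights = dict(zip(coupled["taxon_id"],
                       coupled["membership_state"].astype(float) / 10.0))
    metadata = {
        "coupled_feature": COUPLED_FEATURE,
        "coupled_trait": COUPLED_TRAIT,
        "neutral_feature": NEUTRAL_FEATURE,
        "neutral_trait": NEUTRAL_TRAIT,
        "coupled_layer": "bio01",
        "coupling_strength": config.coupling_strength,
        "coupled_membership": weights,
    }
    return traits, metadata


def generate_abundance_table(config: SyntheticConfig, climate: ClimateStack,
                             traits: pd.DataFrame,
                             metadata: dict | None = None) -> pd.DataFrame:
    """Site-by-taxon abundance classes driven by the planted coupling.

    Sites are uniform over the grid; each has one or two sampling events.
    Absences are kept as explicit class-0 records so that all-absent sites
    remain visible to the trait-composition stage.
    """
    geo = config.geometry
    if metadata is None:
        _, metadata = generate_trait_table(config)
    rng = config.rng(3)
    lons = rng.uniform(geo.origin_lon, geo.east, size=config.n_sites)
    lats = rng.uniform(geo.origin_lat, geo.north, size=config.n_sites)
    if not np.all(geo.contains(lons, lats)):
        raise ValueError("generated site outside raster extent")
    cell_ids = geo.cell_id(lons, lats)
    layer = climate.layers[metadata["coupled_layer"]].ravel()
    z_cells = (layer - layer.mean()) / layer.std()
    z_site = z_cells[cell_ids]

    taxa = traits[["taxon_id", "rank", "genus_id"]].drop_duplicates("taxon_id")
    taxon_ids = taxa["taxon_id"].to_numpy()
    n_taxa = len(taxon_ids)
    weights = np.array([metadata["coupled_membership"].get(t, 0.0)
                        for t in taxon_ids])
    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n_taxa)

    n_events = rng.integers(1, 3, size=config.n_sites)
    rows_site, rows_event = [], []
    for s in range(config.n_sites):
        for e in range(n_events[s]):
            rows_site.append(s)
            rows_event.append(e + 1)
    rows_site = np.asarray(rows_site)
    rows_event = np.asarray(rows_event)
    n_rows = rows_site.size

    latent = (baseline[None, :]
              + config.coupling_strength * weights[None, :]
              * z_site[rows_site, None]
              + _NOISE_SD * rng.standard_normal((n_rows, n_taxa)))
    # fixed cut points: equally spaced quantiles of the latent pool above
    # the absence mass
    probs = _P_ABSENT + (1.0 - _P_ABSENT) * np.arange(1, 8) / 7.0
    cuts = np.quantile(latent, np.concatenate([[_P_ABSENT], probs[:-1]]))
    classes = np.searchsorted(cuts, latent, side="right")

    zero_site = rng.uniform(size=config.n_sites) < config.inflation_rate
    classes[zero_site[rows_site], :] = 0

    site_ids = np.array([f"site{s + 1:04d}" for s in range(config.n_sites)])
    out = pd.DataFrame({
        "site_id": np.repeat(site_ids[rows_site], n_taxa),
        "event_id": np.repeat(rows_event, n_taxa),
        "lon": np.repeat(lons[rows_site], n_taxa),
        "lat": np.repeat(lats[rows_site], n_taxa),
        "taxon_id": np.tile(taxon_ids, n_rows),
        "rank": np.tile(taxa["rank"].to_numpy(), n_rows),
        "genus_id": np.tile(taxa["genus_id"].to_numpy(), n_rows),
        "abundance_class": classes.ravel().astype(int),
    })
    return out


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    climate: ClimateStack
    traits: pd.DataFrame
    abundance: pd.DataFrame
    metadata: dict

    def write(self, directory) -> None:
        """CSV tables, ASCII-grid climate stack and a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(directory / "abundance.csv", index=False)
        self.traits.to_csv(directory / "traits.csv", index=False)
        self.climate.write(directory / "climate")
        sidecar = {"config": dataclasses.asdict(self.config),
                   "metadata": self.metadata}
        (directory / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate climate, traits and abundance from one config."""
    climate = generate_climate_stack(config)
    traits, metadata = generate_trait_table(config)
    abundance = generate_abundance_table(config, climate, traits, metadata)
    return SyntheticDataset(config=config, climate=climate, traits=traits,
                            abundance=abundance, metadata=metadata)
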