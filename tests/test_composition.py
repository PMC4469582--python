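"""Trait normalization, taxonomy harmonization and abundance-weighted traits."""

import numpy as np
import pandas as pd
import pytest

from traitclim import composition
from traitclim.grid import GridGeometry


def trait_rows(taxon, states, feature="thermal", rank="species", genus=None):
    return [{"taxon_id": taxon, "rank": rank, "genus_id": genus or taxon,
             "grouping_feature": feature, "trait": t, "membership_state": s}
            for t, s in states.items()]


def abundance_rows(records):
    """records: (site, event, lon, lat, taxon, rank, genus, cls)."""
    return pd.DataFrame(records, columns=composition.ABUNDANCE_COLUMNS)


class TestNormalizeMembership:
    def test_states_become_percentages(self):
        traits = pd.DataFrame(trait_rows("t1", {"cold": 6, "warm": 2,
                                                "eurytherm": 2}))
        out = composition.normalize_membership(traits)
        assert out["membership_pct"].tolist() == [60.0, 20.0, 20.0]

    def test_single_full_membership(self):
        traits = pd.DataFrame(trait_rows("t1", {"cold": 10}))
        out = composition.normalize_membership(traits)
        assert out["membership_pct"].tolist() == [100.0]

    def test_all_zero_feature_left_as_zero_with_warning(self, caplog):
        traits = pd.DataFrame(trait_rows("t1", {"a": 0, "b": 0}))
        with caplog.at_level("WARNING"):
            out = composition.normalize_membership(traits)
        assert out["membership_pct"].tolist() == [0.0, 0.0]
        assert "all-zero" in caplog.text

    @pytest.mark.parametrize("bad", [-1, 11])
    def test_out_of_scale_state_rejected(self, bad):
        traits = pd.DataFrame(trait_rows("t1", {"a": bad, "b": 3}))
        with pytest.raises(ValueError, match="0-10"):
            composition.normalize_membership(traits)

    def test_percentages_sum_to_hundred_per_feature(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(20):
            states = {f"tr{j}": int(rng.integers(0, 11)) for j in range(4)}
            if all(v == 0 for v in states.values()):
                states["tr0"] = 1
            rows += trait_rows(f"t{i}", states)
        out = composition.normalize_membership(pd.DataFrame(rows))
        sums = out.groupby(["taxon_id", "grouping_feature"])["membership_pct"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestHarmonizeTaxonomy:
    def _table(self, genus_site_count, n_sites=100):
        rows = []
        for s in range(n_sites):
            site = f"s{s:03d}"
            if s < genus_site_count:
                rows.append((site, 1, 0.5, 50.5, "G", "genus", "G", 2))
            rows.append((site, 1, 0.5, 50.5, "G_a", "species", "G", 3))
            rows.append((site, 1, 0.5, 50.5, "H_a", "species", "H", 1))
        return abundance_rows(rows)

    def test_common_genus_collapses_species(self):
        out = composition.harmonize_taxonomy(self._table(2), threshold=0.01)
        assert "G_a" not in set(out["taxon_id"])
        assert (out[out["taxon_id"] == "G"]["rank"] == "genus").all()
        # untouched genus keeps its species
        assert "H_a" in set(out["taxon_id"])

    def test_rare_genus_leaves_table_unchanged(self):
        table = self._table(0)
        out = composition.harmonize_taxonomy(table, threshold=0.01)
        pd.testing.assert_frame_equal(
            out.sort_values(["site_id", "taxon_id"]).reset_index(drop=True),
            table.sort_values(["site_id", "taxon_id"]).reset_index(drop=True))

    def test_merge_takes_maximum_class(self):
        out = composition.harmonize_taxonomy(self._table(2), threshold=0.01)
        merged = out[(out["site_id"] == "s000") & (out["taxon_id"] == "G")]
        assert len(merged) == 1
        assert merged["abundance_class"].iloc[0] == 3  # max(2, 3)

    def test_merge_is_order_independent(self):
        table = self._table(5)
        base = composition.harmonize_taxonomy(table).sort_values(
            ["site_id", "taxon_id"]).reset_index(drop=True)
        for seed in range(4):
            shuffled = table.sample(frac=1.0, random_state=seed)
            out = composition.harmonize_taxonomy(shuffled).sort_values(
                ["site_id", "taxon_id"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(out, base)

    def test_idempotent(self):
        once = composition.harmonize_taxonomy(self._table(10))
        twice = composition.harmonize_taxonomy(once)
        pd.testing.assert_frame_equal(
            once.sort_values(["site_id", "taxon_id"]).reset_index(drop=True),
            twice.sort_values(["site_id", "taxon_id"]).reset_index(drop=True))


class TestGenusTraitMedian:
    def _normalized(self, rows):
        return composition.normalize_membership(pd.DataFrame(rows))

    def test_median_of_species_percentages(self):
        rows = (trait_rows("sp1", {"a": 2, "b": 8}, genus="G")
                + trait_rows("sp2", {"a": 4, "b": 6}, genus="G")
                + trait_rows("sp3", {"a": 6, "b": 4}, genus="G"))
        out = composition.genus_trait_median(self._normalized(rows))
        g = out[(out["taxon_id"] == "G") & (out["trait"] == "a")]
        assert g["membership_pct"].iloc[0] == pytest.approx(40.0)

    def test_opposite_specialists_average_to_even_split(self):
        rows = (trait_rows("sp1", {"a": 0, "b": 10}, genus="G")
                + trait_rows("sp2", {"a": 10, "b": 0}, genus="G"))
        out = composition.genus_trait_median(self._normalized(rows))
        g = out[out["taxon_id"] == "G"].set_index("trait")["membership_pct"]
        assert g["a"] == pytest.approx(50.0)
        assert g["b"] == pytest.approx(50.0)

    def test_medians_renormalized_per_feature(self):
        # hand oracle: percentages {80,20},{60,40},{10,90} -> medians {60,40}
        rows = (trait_rows("sp1", {"a": 8, "b": 2}, genus="G")
                + trait_rows("sp2", {"a": 6, "b": 4}, genus="G")
                + trait_rows("sp3", {"a": 1, "b": 9}, genus="G"))
        out = composition.genus_trait_median(self._normalized(rows))
        g = out[out["taxon_id"] == "G"].set_index("trait")["membership_pct"]
        assert g["a"] == pytest.approx(60.0)
        assert g["b"] == pytest.approx(40.0)

    def test_existing_genus_rows_not_overwritten(self):
        rows = (trait_rows("G", {"a": 10, "b": 0}, rank="genus", genus="G")
                + trait_rows("sp1", {"a": 0, "b": 10}, genus="G"))
        out = composition.genus_trait_median(self._normalized(rows))
        g = out[(out["taxon_id"] == "G") & (out["trait"] == "a")]
        assert len(g) == 1 and g["membership_pct"].iloc[0] == 100.0


def awt_oracle(abund, traits_pct):
    """Naive loop-based abundance-weighted trait computation.

    Independent of the vectorized implementation: dictionaries and explicit
    loops over sites, events, features and traits.
    """
    pct = {}
    features = {}
    for row in traits_pct.itertuples():
        pct[(row.taxon_id, row.grouping_feature, row.trait)] = row.membership_pct
        features.setdefault(row.grouping_feature, set()).add(row.trait)
    out = {}
    for site in sorted(abund["site_id"].unique()):
        srows = abund[abund["site_id"] == site]
        for feature, traits_ in features.items():
            for trait in sorted(traits_):
                vals = []
                for event in sorted(srows["event_id"].unique()):
                    erows = srows[srows["event_id"] == event]
                    num = den = 0.0
                    for r in erows.itertuples():
                        key = (r.taxon_id, feature, trait)
                        if key not in pct:
                            continue
                        num += r.abundance_class * pct[key]
                        den += r.abundance_class * 100.0
                    if den > 0:
                        vals.append(num / den)
                out[(site, feature, trait)] = (sum(vals) / len(vals), False) \
                    if vals else (0.0, True)
    return out


def random_awt_instance(seed, n_sites=6, n_taxa=5, n_events=2):
    rng = np.random.default_rng(seed)
    trows = []
    for i in range(n_taxa):
        states = {f"tr{j}": int(rng.integers(0, 11)) for j in range(3)}
        if all(v == 0 for v in states.values()):
            states["tr0"] = 5
        trows += trait_rows(f"tax{i}", states)
    traits = composition.normalize_membership(pd.DataFrame(trows))
    arows = []
    for s in range(n_sites):
        lon, lat = rng.uniform(0, 5), rng.uniform(45, 50)
        for e in range(1, 1 + int(rng.integers(1, n_events + 1))):
            for i in range(n_taxa):
                arows.append((f"s{s}", e, lon, lat, f"tax{i}", "species",
                              f"tax{i}", int(rng.integers(0, 8))))
    return abundance_rows(arows), traits


class TestComputeSiteAwt:
    def test_weighted_mean_example(self):
        traits = composition.normalize_membership(pd.DataFrame(
            trait_rows("A", {"t": 10, "u": 0}) + trait_rows("B", {"t": 0, "u": 10})))
        abund = abundance_rows([("s1", 1, 0.0, 50.0, "A", "species", "A", 3),
                                ("s1", 1, 0.0, 50.0, "B", "species", "B", 1)])
        out = composition.compute_site_awt(abund, traits).set_index("trait")
        assert out.loc["t", "awt"] == pytest.approx(0.75)
        assert out.loc["u", "awt"] == pytest.approx(0.25)

    def test_single_pure_taxon_gives_one(self):
        traits = composition.normalize_membership(
            pd.DataFrame(trait_rows("A", {"t": 10, "u": 0})))
        abund = abundance_rows([("s1", 1, 0.0, 50.0, "A", "species", "A", 4)])
        out = composition.compute_site_awt(abund, traits).set_index("trait")
        assert out.loc["t", "awt"] == 1.0

    def test_absent_site_flagged(self):
        traits = composition.normalize_membership(
            pd.DataFrame(trait_rows("A", {"t": 10, "u": 0})))
        abund = abundance_rows([("s1", 1, 0.0, 50.0, "A", "species", "A", 0)])
        out = composition.compute_site_awt(abund, traits)
        assert out["absent"].all() and (out["awt"] == 0.0).all()

    def test_annual_average_over_events(self):
        traits = composition.normalize_membership(pd.DataFrame(
            trait_rows("A", {"t": 10, "u": 0}) + trait_rows("B", {"t": 0, "u": 10})))
        abund = abundance_rows([
            ("s1", 1, 0.0, 50.0, "A", "species", "A", 1),   # event 1: AWT_t = 1
            ("s1", 2, 0.0, 50.0, "A", "species", "A", 1),   # event 2: AWT_t = .5
            ("s1", 2, 0.0, 50.0, "B", "species", "B", 1),
        ])
        out = composition.compute_site_awt(abund, traits).set_index("trait")
        assert out.loc["t", "awt"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_loop_oracle(self, seed):
        abund, traits = random_awt_instance(seed)
        out = composition.compute_site_awt(abund, traits)
        oracle = awt_oracle(abund, traits)
        for row in out.itertuples():
            exp_awt, exp_absent = oracle[(row.site_id, row.grouping_feature,
                                          row.trait)]
            assert row.awt == pytest.approx(exp_awt, abs=1e-12)
            assert row.absent == exp_absent

    def test_compositional_closure(self):
        abund, traits = random_awt_instance(99, n_sites=12)
        out = composition.compute_site_awt(abund, traits)
        sums = (out[~out["absent"]]
                .groupby(["site_id", "grouping_feature"])["awt"].sum())
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_taxon_row_order_irrelevant(self):
        abund, traits = random_awt_instance(3)
        base = composition.compute_site_awt(abund, traits)
        shuffled = composition.compute_site_awt(
            abund.sample(frac=1.0, random_state=0), traits)
        merged = base.merge(shuffled, on=["site_id", "grouping_feature",
                                          "trait"], suffixes=("", "_s"))
        assert np.allclose(merged["awt"], merged["awt_s"], atol=1e-12)

    def test_scale_equivariance_of_membership(self):
        """Scaling raw states before normalization leaves AWT unchanged."""
        abund, _ = random_awt_instance(5)
        rng = np.random.default_rng(5)
        rows = []
        for i in range(5):
            states = {f"tr{j}": int(rng.integers(0, 6)) * 2 for j in range(3)}
            if all(v == 0 for v in states.values()):
                states["tr0"] = 4
            rows += trait_rows(f"tax{i}", states)
        raw = pd.DataFrame(rows)
        halved = raw.assign(membership_state=raw["membership_state"] / 2)
        a = composition.compute_site_awt(abund,
                                         composition.normalize_membership(raw))
        b = composition.compute_site_awt(abund,
                                         composition.normalize_membership(halved))
        assert np.allclose(a["awt"], b["awt"], atol=1e-12)


class TestAggregateToCells:
    geometry = GridGeometry(origin_lon=0.0, origin_lat=45.0,
                            cell_size_deg=0.5, n_x=10, n_y=10)

    def _site_awt(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "lon", "lat",
                                           "grouping_feature", "trait", "awt",
                                           "absent"])

    def test_two_sites_average(self):
        sa = self._site_awt([("s1", 0.1, 45.1, "f", "t", 0.2, False),
                             ("s2", 0.2, 45.2, "f", "t", 0.4, False)])
        out = composition.aggregate_to_cells(sa, self.geometry)
        assert len(out) == 1
        assert out["awt"].iloc[0] == pytest.approx(0.3)
        assert out["n_sites"].iloc[0] == 2

    def test_single_site_identity(self):
        sa = self._site_awt([("s1", 3.3, 47.7, "f", "t", 0.77, False)])
        out = composition.aggregate_to_cells(sa, self.geometry)
        assert out["awt"].iloc[0] == pytest.approx(0.77)

    def test_matches_groupby_oracle_on_random_sites(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(100):
            lon, lat = rng.uniform(0, 5), rng.uniform(45, 50)
            rows.append((f"s{i}", lon, lat, "f", "t", rng.uniform(), False))
        sa = self._site_awt(rows)
        out = composition.aggregate_to_cells(sa, self.geometry)
        # exhaustive assignment: which cell interval contains each site
        cells = {}
        for _, r in sa.iterrows():
            ix = int((r["lon"] - 0.0) // 0.5)
            iy = int((r["lat"] - 45.0) // 0.5)
            cells.setdefault(iy * 10 + ix, []).append(r["awt"])
        assert set(out["cell_id"]) == set(cells)
        for cid, vals in cells.items():
            got = out.loc[out["cell_id"] == cid, "awt"].iloc[0]
            assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_absent_policy(self):
        sa = self._site_awt([("s1", 0.1, 45.1, "f", "t", 0.4, False),
                             ("s2", 0.2, 45.2, "f", "t", 0.0, True)])
        zero = composition.aggregate_to_cells(sa, self.geometry, "zero")
        drop = composition.aggregate_to_cells(sa, self.geometry, "drop")
        assert zero["awt"].iloc[0] == pytest.approx(0.2)
        assert drop["awt"].iloc[0] == pytest.approx(0.4)

    def test_site_outside_extent_is_an_error(self):
        sa = self._site_awt([("far", 30.0, 45.1, "f", "t", 0.4, False)])
        with pytest.raises(ValueError, match="far"):
            composition.aggregate_to_cells(sa, self.geometry)
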