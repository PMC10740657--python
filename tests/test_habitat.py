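import dataclasses

import numpy as np
import pytest

from owlshift import (HabitatMap, OccurrenceRecord, SpeciesProfile, Territory,
                      buffer_mask, capture_records, change_summary,
                      default_generalization, default_taxonomy,
                      load_species_profiles, overlay_territories,
                      profile_retention, render_habitat, round_to_nearest_5,
                      published_regional_extents, territory_transition_fixture, thin_points,
                      transition_matrix)
from owlshift.habitat import ChangeSummary


@pytest.fixture
def profiles(world):
    return load_species_profiles(landscape=world["landscape"])


class TestRenderHabitat:
    def test_all_forest_woodland_profile_covers_every_such_cell(
            self, world, taxonomy, profiles):
        """The generalist profile spanning all forest and woodland types
        renders as exactly the forest/woodland cells."""
        ls = world["landscape"]
        gho = profiles["great_horned_owl"]
        mask = render_habitat(gho, ls).mask
        forest = ls.eru_mask([e.id for e in taxonomy if e.is_forest_or_woodland])
        assert np.array_equal(mask, forest)

    def test_zone_restriction_excludes_other_zones(self, world, profiles):
        ls = world["landscape"]
        boreal = profiles["boreal_owl"]  # zone Z4 only
        mask = render_habitat(boreal, ls).mask
        assert not mask[ls.zone != "Z4"].any()

    def test_zero_warming_inclusive_superset_of_current(self, world, taxonomy,
                                                        profiles):
        from owlshift import project_landscape
        ls = world["landscape"]
        pr0 = project_landscape(ls, world["climate_now"], world["envelopes"],
                                taxonomy)
        prof = profiles["flammulated_owl"]
        cur = render_habitat(prof, ls).mask
        proj = render_habitat(prof, ls, pr0, mode="inclusive").mask
        zmask = ls.zone_mask(prof.zones_2090)
        assert np.all((cur & zmask) <= proj)

    def test_inclusive_superset_of_most_likely(self, world, profiles):
        ls = world["landscape"]
        for prof in profiles.values():
            inc = render_habitat(prof, ls, world["projection"], "inclusive")
            ml = render_habitat(prof, ls, world["projection"], "most_likely")
            assert np.all(ml.mask <= inc.mask)

    def test_unknown_zone_rejected(self, world):
        prof = SpeciesProfile("x", frozenset({"PPF"}), frozenset({"Z99"}))
        with pytest.raises(ValueError):
            render_habitat(prof, world["landscape"])

    def test_empty_eru_set_rejected(self):
        with pytest.raises(ValueError):
            SpeciesProfile("x", frozenset(), frozenset({"Z1"}))

    def test_warming_weakly_shrinks_upper_elevation_habitat(self, world,
                                                            taxonomy,
                                                            profiles):
        """Increasing the warming offset weakly decreases projected extent
        for profiles restricted to subalpine + montane types."""
        from owlshift import (extent_ha, fit_envelopes, generate_climate,
                              project_landscape)
        ls, cfg = world["landscape"], world["config"]
        for species in ("boreal_owl", "flammulated_owl",
                        "northern_saw_whet_owl"):
            prof = profiles[species]
            assert all(taxonomy[e].zone in {"subalpine", "montane"}
                       for e in prof.eru_ids)
            prev = None
            for off in (0.0, 150.0, 300.0, 450.0, 600.0):
                c = dataclasses.replace(cfg, warming_offset_m=off)
                clim = generate_climate(ls, c, warmed=True)
                pr = project_landscape(ls, clim, world["envelopes"], taxonomy)
                ext = extent_ha(render_habitat(prof, ls, pr, "inclusive"))
                if prev is not None:
                    assert ext <= prev
                prev = ext


class TestChangeSummary:
    @pytest.mark.parametrize("row", published_regional_extents(),
                             ids=lambda r: r["species"])
    def test_published_extent_pairs_reproduce_rounded_percentages(self, row):
        """Every published per-species rounded change follows from its own
        extent pair under round-to-nearest-5, ties away from zero."""
        cs = ChangeSummary(row["species"], row["current_ha"],
                           row["projected_ha"], 0, 0, 0)
        assert cs.pct_change_rounded == row["published_pct_change"]

    def test_flammulated_raw_value(self):
        cs = ChangeSummary("f", 4_684_000, 714_000, 0, 0, 0)
        assert cs.pct_change_raw == pytest.approx(-84.757, abs=1e-3)
        assert cs.pct_change_rounded == -85

    def test_five_species_decline_at_least_60_percent(self):
        declines = [-ChangeSummary("s", r["current_ha"], r["projected_ha"],
                                   0, 0, 0).pct_change_raw
                    for r in published_regional_extents()]
        assert sum(d >= 60 for d in declines) == 5

    def test_rounding_ties_away_from_zero(self):
        assert round_to_nearest_5(-2.5) == -5
        assert round_to_nearest_5(2.5) == 5
        assert round_to_nearest_5(-2.4999) == 0
        assert round_to_nearest_5(0.0) == 0
        assert round_to_nearest_5(-86.27) == -85
        assert round_to_nearest_5(-52.57) == -55

    def test_identical_masks_no_change(self, world, profiles):
        ls = world["landscape"]
        cur = render_habitat(profiles["flammulated_owl"], ls)
        cs = change_summary(cur, cur)
        assert cs.pct_change_raw == 0.0
        assert cs.pct_change_rounded == 0
        assert cs.lost_ha == cs.gained_ha == 0.0

    def test_projected_is_persisted_plus_gained(self, world, profiles):
        ls = world["landscape"]
        for prof in profiles.values():
            cur = render_habitat(prof, ls)
            proj = render_habitat(prof, ls, world["projection"])
            cs = change_summary(cur, proj)
            assert cs.projected_ha == pytest.approx(
                cs.persisted_ha + cs.gained_ha)
            assert cs.current_ha == pytest.approx(
                cs.persisted_ha + cs.lost_ha)
            if cs.pct_change_raw is not None:
                assert abs(cs.pct_change_rounded - cs.pct_change_raw) <= 2.5

    def test_zero_current_extent_reports_absent(self, world):
        ls = world["landscape"]
        empty = HabitatMap(ls, np.zeros(ls.shape, bool))
        cs = change_summary(empty, empty)
        assert cs.pct_change_raw is None
        assert cs.pct_change_rounded is None


class TestCaptureRecords:
    def test_all_inside_unbuffered(self, world, profiles):
        ls = world["landscape"]
        hab = render_habitat(profiles["flammulated_owl"], ls)
        i, j = np.argwhere(hab.mask)[0]
        recs = [OccurrenceRecord("f", j * 100.0, i * 100.0)] * 5
        cc = capture_records(recs, hab)
        assert (cc.within_model, cc.within_buffer_only, cc.outside,
                cc.total) == (5, 0, 0, 5)

    def test_buffer_only_capture_by_geometry(self, world):
        ls = world["landscape"]
        mask = np.zeros(ls.shape, bool)
        mask[50, 50] = True
        hab = HabitatMap(ls, mask)
        # 500 m east of the habitat cell centre: outside the cell, inside 1 km
        rec = OccurrenceRecord("x", 50 * 100.0 + 500.0, 50 * 100.0)
        cc = capture_records([rec], hab, buffer_distance=1000.0)
        assert (cc.within_model, cc.within_buffer_only, cc.outside) == (0, 1, 0)

    def test_partition_property_on_random_records(self, world, profiles):
        rng = np.random.default_rng(3)
        ls = world["landscape"]
        hab = render_habitat(profiles["northern_pygmy_owl"], ls)
        recs = [OccurrenceRecord("x", float(rng.uniform(0, 19900)),
                                 float(rng.uniform(0, 19900)))
                for _ in range(200)]
        cc = capture_records(recs, hab)
        assert cc.within_model + cc.within_buffer_only + cc.outside == 200
        assert cc.total == 200

    def test_off_landscape_record_counts_outside_with_warning(self, world,
                                                              profiles):
        ls = world["landscape"]
        hab = render_habitat(profiles["flammulated_owl"], ls)
        with pytest.warns(UserWarning, match="off the landscape"):
            cc = capture_records([OccurrenceRecord("x", -5e4, -5e4)], hab)
        assert cc.outside == 1


class TestTerritoryOverlay:
    def test_ponderosa_cell_generalizes_to_dry_forest(self, world):
        ls = world["landscape"]
        i, j = np.argwhere(ls.eru == "PPF")[0]
        t = Territory("f", x=j * 100.0, y=i * 100.0)
        out = overlay_territories([t], ls, world["projection"],
                                  default_generalization())
        assert out[0].current_label == "Dry Forest"

    def test_zero_warming_projected_equals_current_label(self, world,
                                                         taxonomy):
        from owlshift import project_landscape
        ls = world["landscape"]
        pr0 = project_landscape(ls, world["climate_now"], world["envelopes"],
                                taxonomy)
        rng = np.random.default_rng(7)
        # most-likely under zero warming can differ from the current type
        # only inside envelope-overlap zones; check cells away from band
        # edges via a deterministic subsample of exact matches
        terr = [Territory("f", x=float(rng.uniform(0, 19900)),
                          y=float(rng.uniform(0, 19900))) for _ in range(50)]
        out = overlay_territories(terr, ls, pr0, default_generalization())
        # the current label is always among the candidate generalizations
        for t in out:
            cell = ls.cell_of_point(t.x, t.y)
            assert pr0.candidates_contain_current()[cell]

    def test_off_landscape_territory_rejected(self, world):
        t = Territory("f", x=-1e5, y=0.0)
        with pytest.raises(ValueError, match="off the landscape"):
            overlay_territories([t], world["landscape"], world["projection"],
                                default_generalization())

    def test_incomplete_generalization_rejected(self, world):
        t = Territory("f", x=0.0, y=0.0)
        with pytest.raises(ValueError):
            overlay_territories([t], world["landscape"], world["projection"],
                                {"PPF": "Dry Forest"})


class TestTransitionMatrix:
    def test_fixture_matrix_reproduces_published_cells(self):
        tm = transition_matrix(territory_transition_fixture())
        assert tm.table.loc["Dry Forest", "Pinyon-Juniper"] == 122
        assert tm.grand_total == 148
        assert list(tm.column_totals()[["Dry Forest", "Madrean Woodland",
                                        "Pinyon-Juniper", "Riparian",
                                        "Gambel Oak Shrubland"]]) == (
            [5, 9, 124, 7, 3])

    def test_single_territory_matrix(self):
        t = Territory("f", current_label="Dry Forest",
                      projected_label="Pinyon-Juniper")
        tm = transition_matrix([t])
        assert tm.table.shape == (1, 1)
        assert tm.grand_total == 1

    def test_unlabelled_territory_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix([Territory("f")])


class TestProfileRetention:
    PROFILE = {"Dry Forest", "Mixed Conifer with Aspen"}

    def test_current_in_profile_about_92_percent(self):
        tm = transition_matrix(territory_transition_fixture())
        pct_cur, _, _ = profile_retention(tm, self.PROFILE)
        assert pct_cur == pytest.approx(100 * 136 / 148)
        assert round(pct_cur) == 92

    def test_remaining_in_profile_under_10_percent(self):
        tm = transition_matrix(territory_transition_fixture())
        _, pct_rem, _ = profile_retention(tm, self.PROFILE)
        assert pct_rem == pytest.approx(100 * 5 / 148)
        assert pct_rem < 10

    def test_over_80_percent_move_to_pinyon_juniper_or_madrean(self):
        tm = transition_matrix(territory_transition_fixture())
        _, _, pct_q = profile_retention(
            tm, self.PROFILE, {"Pinyon-Juniper", "Madrean Woodland"})
        assert pct_q == pytest.approx(100 * 131 / 136)
        assert pct_q > 80

    def test_unknown_profile_label_rejected(self):
        tm = transition_matrix(territory_transition_fixture())
        with pytest.raises(ValueError):
            profile_retention(tm, {"Lunar Forest"})


class TestThinning:
    def test_greedy_thinning_enforces_separation(self):
        pts = [(0.0, 0.0), (100.0, 0.0), (300.0, 0.0), (350.0, 0.0)]
        kept = thin_points(pts, min_separation=250.0)
        assert kept == [0, 2]

    def test_order_dependence_is_first_come_first_kept(self):
        # same point set, different order, different survivors
        assert thin_points([(0.0, 0.0), (100.0, 0.0), (300.0, 0.0)],
                           250.0) == [0, 2]
        assert thin_points([(100.0, 0.0), (0.0, 0.0), (300.0, 0.0)],
                           250.0) == [0]

    def test_exactly_at_separation_is_kept(self):
        assert thin_points([(0.0, 0.0), (250.0, 0.0)], 250.0) == [0, 1]
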