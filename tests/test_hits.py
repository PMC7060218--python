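import itertools

import numpy as np
import pandas as pd
import pytest

from pkdscreen.hits import (aggregate_human_hits, call_cyst_active,
                            call_differential_human_pair,
                            call_differential_mouse, call_mouse_screen,
                            categorize_hits)


def profile_row(compound="C1", cell_line="embryonic_null", channel="CTG",
                curve_class=-1.1, auc=-300.0, zero=0.0):
    return pd.Series({"compound_id": compound, "cell_line": cell_line,
                      "channel": channel, "curve_class": curve_class,
                      "auc": auc, "zero": zero})


class TestMouseDifferential:
    def test_strong_differential_is_primary_hit(self):
        null = profile_row(curve_class=-1.1, auc=-300.0)
        wt = profile_row(cell_line="embryonic_wt", curve_class=4.0, auc=-20.0)
        call = call_differential_mouse(null, wt, "primary")
        assert call.delta_auc == pytest.approx(-280.0)
        assert call.is_hit

    def test_identical_profiles_not_a_hit(self):
        null = profile_row(auc=-150.0)
        wt = profile_row(cell_line="embryonic_wt", auc=-150.0)
        call = call_differential_mouse(null, wt, "primary")
        assert call.delta_auc == 0.0 and not call.is_hit

    def test_phase_cutoffs_minus10_vs_minus20(self):
        null = profile_row(curve_class=-2.1, auc=-115.0)
        wt = profile_row(cell_line="embryonic_wt", curve_class=-2.1, auc=-100.0)
        assert call_differential_mouse(null, wt, "primary").is_hit
        assert not call_differential_mouse(null, wt, "validation").is_hit

    def test_low_quality_null_curve_blocks_hit(self):
        null = profile_row(curve_class=5.0, auc=-400.0)
        wt = profile_row(cell_line="embryonic_wt", curve_class=4.0, auc=0.0)
        assert not call_differential_mouse(null, wt, "primary").is_hit

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ValueError, match="match"):
            call_differential_mouse(profile_row(compound="A"),
                                    profile_row(compound="B"), "primary")

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            call_differential_mouse(profile_row(),
                                    profile_row(cell_line="embryonic_wt"),
                                    "tertiary")


class TestCystActivity:
    @pytest.mark.parametrize("cls", [-1.1, -1.2, -2.1, -2.2, -3.0, 4.0, 5.0])
    @pytest.mark.parametrize("auc", [-400.0, -150.0, -100.0, -50.0, 0.0])
    def test_matches_rule_truth_table(self, cls, auc):
        """Active iff non-class-4 and AUC strictly below -100."""
        expected = (cls != 4.0) and (auc < -100.0)
        call = call_cyst_active(profile_row(channel="CTG-3D",
                                            curve_class=cls, auc=auc))
        assert call.is_active == expected

    def test_swelling_flag_unknown_by_default(self):
        call = call_cyst_active(profile_row(channel="CTG-3D"))
        assert call.swelling_reduced is None


class TestHumanPair:
    def adpkd(self, **kw):
        return profile_row(cell_line="ADPKD-1", **kw)

    def nhk(self, **kw):
        return profile_row(cell_line="NHK-1", **kw)

    def test_qualified_pair_is_hit(self):
        call = call_differential_human_pair(
            self.adpkd(curve_class=-1.2, auc=-200.0, zero=2.0),
            self.nhk(curve_class=4.0, auc=-120.0, zero=-3.0))
        assert call.delta_auc == pytest.approx(-80.0)
        assert call.delta_abs_zero == pytest.approx(1.0)
        assert call.is_hit

    def test_baseline_disagreement_blocks_hit(self):
        call = call_differential_human_pair(
            self.adpkd(auc=-200.0, zero=20.0),
            self.nhk(auc=-120.0, zero=5.0))
        assert call.delta_abs_zero == pytest.approx(15.0)
        assert not call.is_hit

    def test_insufficient_delta_auc_blocks_hit(self):
        call = call_differential_human_pair(
            self.adpkd(auc=-170.0, zero=0.0),
            self.nhk(auc=-120.0, zero=0.0))
        assert call.delta_auc == pytest.approx(-50.0)
        assert not call.is_hit


class TestAggregateHumanHits:
    def make_calls(self, hit_pairs):
        adpkd = [f"A{i}" for i in range(5)]
        nhk = [f"N{i}" for i in range(6)]
        rows = []
        for a, n in itertools.product(adpkd, nhk):
            rows.append({"compound_id": "C", "adpkd": a, "nhk": n,
                         "channel": "CTG", "is_hit": (a, n) in hit_pairs})
        return pd.DataFrame(rows)

    def test_six_pairs_spanning_2x3_flagged(self):
        pairs = {(f"A{i}", f"N{j}") for i in range(2) for j in range(3)}
        agg = aggregate_human_hits(self.make_calls(pairs))
        assert agg.flagged.all() and agg.n_hit_pairs.iloc[0] == 6

    def test_six_pairs_single_adpkd_not_flagged(self):
        pairs = {("A0", f"N{j}") for j in range(6)}
        agg = aggregate_human_hits(self.make_calls(pairs))
        assert not agg.flagged.any()

    def test_five_pairs_not_flagged(self):
        pairs = {("A0", "N0"), ("A1", "N1"), ("A2", "N2"),
                 ("A0", "N3"), ("A1", "N4")}
        assert not aggregate_human_hits(self.make_calls(pairs)).flagged.any()

    def test_agrees_with_bruteforce_over_random_subsets(self, rng):
        all_pairs = list(itertools.product([f"A{i}" for i in range(5)],
                                           [f"N{j}" for j in range(6)]))
        for _ in range(50):
            k = int(rng.integers(0, 31))
            idx = rng.choice(30, size=k, replace=False)
            subset = {all_pairs[i] for i in idx}
            flagged = bool(aggregate_human_hits(
                self.make_calls(subset)).flagged.iloc[0])
            expected = (len(subset) >= 6
                        and len({a for a, _ in subset}) >= 2
                        and len({n for _, n in subset}) >= 3)
            assert flagged == expected

    def test_pair_counts_if_either_channel_hits(self):
        rows = [
            {"compound_id": "C", "adpkd": "A0", "nhk": "N0",
             "channel": "CTG", "is_hit": False},
            {"compound_id": "C", "adpkd": "A0", "nhk": "N0",
             "channel": "GF-AFC", "is_hit": True},
        ]
        agg = aggregate_human_hits(pd.DataFrame(rows))
        assert agg.n_hit_pairs.iloc[0] == 1


class TestCategorizeHits:
    def make_calls(self, spec_map):
        rows = []
        for cid, combos in spec_map.items():
            for pair, ch in itertools.product(["embryonic", "postnatal"],
                                              ["GF-AFC", "CTG"]):
                rows.append({"compound_id": cid, "pair_id": pair,
                             "channel": ch, "delta_auc": -50.0,
                             "is_hit": (pair, ch) in combos,
                             "phase": "validation"})
        return pd.DataFrame(rows)

    def test_single_combo_assignment(self):
        cats = categorize_hits(self.make_calls(
            {"C1": {("embryonic", "GF-AFC")}}))
        assert cats.iloc[0].pair_category == "embryonic_only"
        assert cats.iloc[0].channel_category == "GF-AFC"

    def test_all_combo_assignment(self):
        cats = categorize_hits(self.make_calls(
            {"C1": set(itertools.product(["embryonic", "postnatal"],
                                         ["GF-AFC", "CTG"]))}))
        assert cats.iloc[0].pair_category == "both"
        assert cats.iloc[0].channel_category == "both"

    def test_partition_is_disjoint_and_complete(self, rng):
        combos = list(itertools.product(["embryonic", "postnatal"],
                                        ["GF-AFC", "CTG"]))
        spec_map = {}
        for i in range(20):
            k = int(rng.integers(1, 5))
            picks = rng.choice(4, size=k, replace=False)
            spec_map[f"C{i}"] = {combos[j] for j in picks}
        calls = self.make_calls(spec_map)
        cats = categorize_hits(calls)
        assert set(cats.compound_id) == set(spec_map)
        assert cats.compound_id.is_unique
        assert set(cats.pair_category) <= {"embryonic_only", "postnatal_only",
                                           "both"}


def test_missing_wt_profile_inconclusive(caplog):
    profiles = pd.DataFrame([
        {"compound_id": "C1", "cell_line": "embryonic_null", "channel": "CTG",
         "curve_class": -1.1, "auc": -300.0, "zero": 0.0},
    ])
    calls = call_mouse_screen(profiles, "primary")
    assert calls.is_hit.isna().all()
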