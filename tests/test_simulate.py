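import numpy as np
import pandas as pd
import pytest

from pkdscreen.simulate import (CHANNEL_BASELINES, ConfigurationError,
                                CystObject, ScreenConfig, cyst_titration,
                                default_titration, make_truth_table,
                                render_cyst_image, simulate_cyst_plate,
                                simulate_monolayer_screen,
                                simulate_panel_screen)


def custom_truth(categories, ac50=1.0, hill=1.0, efficacy=-100.0):
    """Hand-built truth table with one compound per requested category."""
    rows, eff = [], []
    lines = ["embryonic_null", "embryonic_wt", "postnatal_null", "postnatal_wt"]
    for i, cat in enumerate(categories):
        cid = f"X{i}"
        rows.append({"compound_id": cid, "category": cat, "target_gene": "G1",
                     "ac50_um": ac50, "hill": hill,
                     "active_efficacy": efficacy,
                     "swell_efficacy": -80.0 if cat == "cyst_swelling_only" else 0.0})
        for ln in lines:
            pair, geno = ln.rsplit("_", 1)
            if cat == "pan_active":
                e = efficacy
            elif cat in (f"differential_{pair}", "differential_both") and geno == "null":
                e = efficacy
            else:
                e = 0.0
            eff.append({"compound_id": cid, "cell_line": ln, "efficacy": e})
    from pkdscreen.simulate import TruthTable
    return TruthTable(pd.DataFrame(rows), pd.DataFrame(eff))


class TestTitrations:
    def test_default_11_point_series_spans_nanomolar_to_57um(self):
        t = default_titration()
        assert t.size == 11
        assert t[-1] == pytest.approx(57.0)
        assert t[0] == pytest.approx(57.0 / 3 ** 10)  # ~0.96 nM
        assert np.allclose(t[1:] / t[:-1], 3.0)

    def test_cyst_series_8_point_1_to_2(self):
        t = cyst_titration()
        assert t.size == 8
        assert t[-1] == pytest.approx(100.0)
        assert t[0] == pytest.approx(100.0 / 128)


class TestTruthTable:
    def test_unique_ids_and_efficacy_bounds(self, small_truth):
        assert small_truth.compounds.compound_id.is_unique
        assert small_truth.effects.efficacy.between(-100, 0).all()

    def test_differential_gap_at_least_margin(self, small_truth):
        eff = small_truth.effects.pivot(index="compound_id",
                                        columns="cell_line", values="efficacy")
        for pair in ("embryonic", "postnatal"):
            for cid in small_truth.differential_compounds(pair):
                gap = abs(eff.loc[cid, f"{pair}_null"] - eff.loc[cid, f"{pair}_wt"])
                assert gap >= 60.0

    def test_annotations_one_row_per_annotated_compound(self, small_truth):
        ann = small_truth.annotations()
        assert ann.compound_id.is_unique
        assert len(ann) <= len(small_truth)


class TestMonolayerScreen:
    def test_inactive_compound_reads_at_neutral_baseline(self):
        truth = custom_truth(["inactive"])
        cfg = ScreenConfig(n_compounds=1, noise_cv=0.0, plate_effect_cv=0.0,
                           seed=0)
        wells = simulate_monolayer_screen(cfg, truth)
        cmp = wells[wells.role == "compound"]
        for ch, (neu, _) in CHANNEL_BASELINES.items():
            if ch == "CTG-3D":
                continue
            assert np.allclose(cmp.loc[cmp.channel == ch, "signal"], neu)

    def test_hill_midpoint_halfway_between_baselines(self):
        truth = custom_truth(["pan_active"], ac50=1.0, hill=1.0, efficacy=-100.0)
        titr = np.array([0.1, 0.5, 1.0, 2.0, 10.0])
        cfg = ScreenConfig(n_compounds=1, titration=titr, noise_cv=0.0,
                           plate_effect_cv=0.0, seed=0)
        wells = simulate_monolayer_screen(cfg, truth)
        mid = wells[(wells.role == "compound") & (wells.conc_um == 1.0)
                    & (wells.channel == "CTG")]
        neu, pos = CHANNEL_BASELINES["CTG"]
        assert np.allclose(mid.signal, (neu + pos) / 2.0)

    def test_seeded_determinism_byte_identical(self, small_truth):
        cfg = ScreenConfig(n_compounds=60, noise_cv=0.1, seed=7)
        a = simulate_monolayer_screen(cfg, small_truth).to_csv(index=False)
        b = simulate_monolayer_screen(cfg, small_truth).to_csv(index=False)
        assert a == b

    def test_every_compound_at_every_dose_both_channels(self, clean_screen,
                                                        small_truth):
        _, wells, _ = clean_screen
        counts = wells[wells.role == "compound"].groupby(
            ["compound_id", "cell_line", "channel"])["conc_um"].nunique()
        assert (counts == 11).all()
        assert set(wells.channel) == {"GF-AFC", "CTG"}

    def test_truth_config_mismatch_raises(self, small_truth):
        cfg = ScreenConfig(n_compounds=10, seed=0)
        with pytest.raises(ConfigurationError, match="compounds"):
            simulate_monolayer_screen(cfg, small_truth)

    def test_decreasing_titration_rejected(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            ScreenConfig(n_compounds=5, titration=[10.0, 1.0, 0.1])


class TestCystPlate:
    @pytest.fixture()
    def cyst(self):
        truth = custom_truth(["inactive", "pan_active", "cyst_swelling_only"])
        cfg = ScreenConfig(n_compounds=3, plate_format=384,
                           titration=cyst_titration(), noise_cv=0.0,
                           plate_effect_cv=0.0, seed=2)
        return truth, *simulate_cyst_plate(cfg, truth)

    def test_positive_control_killed_and_cystless(self, cyst):
        _, wells, truth_wells = cyst
        pos = wells[wells.role == "positive"]
        _, kill = CHANNEL_BASELINES["CTG-3D"]
        assert np.allclose(pos.signal, kill)
        assert (truth_wells.loc[truth_wells.role == "positive", "n_swelled"] == 0).all()

    def test_swelling_only_compound_spares_viability(self, cyst):
        truth, wells, truth_wells = cyst
        top = truth_wells[(truth_wells.compound_id == "X2")
                          & (truth_wells.conc_um == 100.0)]
        dmso = truth_wells.loc[truth_wells.role == "neutral", "n_swelled"].median()
        assert (top.n_swelled <= 0.5 * dmso).all()
        sig = wells[(wells.compound_id == "X2") & (wells.conc_um == 100.0)]
        neu, _ = CHANNEL_BASELINES["CTG-3D"]
        assert np.allclose(sig.signal, neu)  # ATP readout untouched

    def test_active_compound_monotone_true_viability(self, cyst):
        _, wells, _ = cyst
        curve = (wells[wells.compound_id == "X1"]
                 .groupby("conc_um")["signal"].median().sort_index())
        assert np.all(np.diff(curve.to_numpy()) <= 1e-9)

    def test_wrong_format_raises_and_titration_warns(self):
        truth = custom_truth(["inactive"])
        with pytest.raises(ConfigurationError, match="384"):
            simulate_cyst_plate(ScreenConfig(n_compounds=1, plate_format=1536,
                                             titration=cyst_titration()), truth)
        cfg = ScreenConfig(n_compounds=1, plate_format=384,
                           titration=[1.0, 10.0, 100.0])
        with pytest.warns(UserWarning, match="8 expected"):
            simulate_cyst_plate(cfg, truth)


class TestPanelScreen:
    def test_selective_compound_active_in_configured_isolates_only(self):
        truth = custom_truth(["differential_both", "inactive"])
        cfg = ScreenConfig(n_compounds=2, noise_cv=0.0, seed=3)
        _, ptruth = simulate_panel_screen(cfg, truth,
                                          adpkd_sensitive={"ADPKD-1", "ADPKD-2"})
        eff = ptruth.effects.set_index(["compound_id", "cell_line"]).efficacy
        active = {ln for (cid, ln) in eff.index if cid == "X0" and eff[(cid, ln)] < 0}
        assert active == {"ADPKD-1", "ADPKD-2"}

    def test_unit_multiplier_null_panel_has_no_selective_signal(self):
        truth = custom_truth(["inactive", "inactive"])
        cfg = ScreenConfig(n_compounds=2, noise_cv=0.0, seed=3)
        _, ptruth = simulate_panel_screen(cfg, truth)
        assert (ptruth.effects.efficacy == 0).all()

    def test_two_seeds_differ_in_noise_share_truth(self, small_truth):
        cfg1 = ScreenConfig(n_compounds=60, noise_cv=0.1, seed=1)
        cfg2 = ScreenConfig(n_compounds=60, noise_cv=0.1, seed=2)
        w1, t1 = simulate_panel_screen(cfg1, small_truth)
        w2, t2 = simulate_panel_screen(cfg2, small_truth)
        assert not np.allclose(w1.signal, w2.signal)
        pd.testing.assert_frame_equal(t1.effects, t2.effects)


class TestRenderCystImage:
    def test_disk_area_within_five_percent(self):
        stack = render_cyst_image([CystObject(200, 200, 40.0, focus_plane=0)],
                                  pixel_size=1.0, n_planes=1)
        area = (stack[0] > 100.0 * 1.05).sum()
        assert area == pytest.approx(np.pi * 40 ** 2, rel=0.05)

    def test_empty_truth_pure_background(self):
        stack = render_cyst_image([], n_planes=3, background=50.0)
        assert np.all(stack == 50.0)

    def test_stack_depth_matches_z_sections(self):
        stack = render_cyst_image([], n_planes=30, shape=(32, 32))
        assert stack.shape[0] == 30

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            CystObject(0, 0, -1.0)

    def test_object_sharpest_at_assigned_plane(self):
        obj = CystObject(100, 100, 30.0, focus_plane=3, contrast=1.0)
        stack = render_cyst_image([obj], n_planes=6, shape=(200, 200))
        grad = [np.abs(np.diff(p, axis=0)).max() for p in stack]
        assert int(np.argmax(grad)) == 3
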