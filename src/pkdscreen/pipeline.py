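"""End-to-end reproducible pipeline: simulate -> normalize -> fit -> call.

A :class:`RunConfig` holds every cutoff of the triage with its default
value (dAUC below -10 / -20 / -60 for primary, validation and human
screens; AUC < -100 with a non-class-4 curve for 3D activity; Zero-activity
agreement within 10; 6-pair / 2-ADPKD / 3-NHK panel aggregation; 3500 µm²
and 0.4 SBR for imaging; alpha 0.05), so sensitivity analyses are
one-field changes.  :func:`run_pipeline` executes the stages in order,
writes versioned CSV artifacts plus a machine-readable ``summary.json``
and is idempotent for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrich, hillfit, hits, imaging, normalize, panel, simulate

__all__ = ["Thresholds", "RunConfig", "run_pipeline", "run_mouse_triage",
           "KNOWN_STAGES"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "normalize", "fit", "call-mouse", "call-cyst",
                "call-human", "panel", "enrich", "imaging")


@dataclass
class Thresholds:
    """Every decision cutoff of the triage, with its default."""

    delta_auc_primary: float = -10.0
    delta_auc_validation: float = -20.0
    delta_auc_human: float = -60.0
    delta_zero: float = 10.0
    cyst_auc: float = -100.0
    alpha: float = 0.05
    min_area_um2: float = 3500.0
    min_sbr: float = 0.4
    min_pairs: int = 6
    min_adpkd: int = 2
    min_nhk: int = 3


@dataclass
class RunConfig:
    """Configuration of one pipeline run (round-trips through YAML)."""

    n_compounds: int = 200
    noise_cv: float = 0.05
    n_replicates: int = 3
    phase: str = "validation"
    seed: int = 0
    stages: tuple = KNOWN_STAGES[:-1]  # imaging opt-in (renders stacks)
    outdir: str = "pkdscreen_run"
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_imaging_wells: int = 4

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise simulate.ConfigurationError(
                f"unknown stage(s): {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _screen_profiles(truth, n_compounds, noise_cv, n_replicates, seed,
                     compound_ids=None):
    cfg = simulate.ScreenConfig(n_compounds=n_compounds, noise_cv=noise_cv,
                                n_replicates=n_replicates, seed=seed)
    wells = simulate.simulate_monolayer_screen(cfg, truth)
    if compound_ids is not None:
        wells = wells[wells["compound_id"].isin(compound_ids)
                      | wells["compound_id"].isna()]
    normed = normalize.normalize_wells(wells)
    return hillfit.profile_titrations(normalize.assemble_titrations(normed))


def run_mouse_triage(n_compounds: int, noise_cv: float, seed: int,
                     truth: simulate.TruthTable | None = None,
                     thresholds: Thresholds | None = None):
    """Two-stage murine triage: primary screen, then validation of its hits.

    Mirrors the screening campaign's design: a single-replicate primary
    screen calls differential activity at dAUC < -10; its hits are
    re-screened in triplicate (fresh plates, fresh noise) and confirmed at
    dAUC < -20.  Confirmation must reproduce the specific finding — the
    same cell pair and readout that hit in the primary screen must hit
    again in validation.

    Returns ``(validated_ids, primary_ids, truth, validation_calls)``
    where validation_calls keeps only the confirmed (pair, readout)
    observations.
    """
    th = thresholds or Thresholds()
    if truth is None:
        truth = simulate.make_truth_table(n_compounds, seed=seed)
    prof1 = _screen_profiles(truth, n_compounds, noise_cv, 1, seed)
    calls1 = hits.call_mouse_screen(prof1, "primary",
                                    cutoff=th.delta_auc_primary)
    hit1 = calls1[calls1["is_hit"] == True]  # noqa: E712
    primary_ids = set(hit1["compound_id"])
    if not primary_ids:
        return set(), set(), truth, calls1.iloc[0:0]
    prof2 = _screen_profiles(truth, n_compounds, noise_cv, 3,
                             seed + 10_000, compound_ids=primary_ids)
    calls2 = hits.call_mouse_screen(prof2, "validation",
                                    cutoff=th.delta_auc_validation)
    hit2 = calls2[calls2["is_hit"] == True]  # noqa: E712
    key = ["compound_id", "pair_id", "channel"]
    confirmed = hit2.merge(hit1[key], on=key)
    return (set(confirmed["compound_id"]), primary_ids, truth, confirmed)


def _stage(name, summary, t0):
    summary.setdefault("stage_seconds", {})[name] = round(time.time() - t0, 3)
    logger.info("stage %s done in %.2fs", name, summary["stage_seconds"][name])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a report bundle.

    Returns the summary dict (also written as ``summary.json``).  A stage
    failure raises with the failing stage named; artifacts written by
    earlier stages are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    th = config.thresholds
    summary: dict = {"seed": config.seed, "n_compounds": config.n_compounds}
    state: dict = {}

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                truth = simulate.make_truth_table(config.n_compounds,
                                                  seed=config.seed)
                mono_cfg = simulate.ScreenConfig(
                    n_compounds=config.n_compounds,
                    noise_cv=config.noise_cv,
                    n_replicates=config.n_replicates, seed=config.seed)
                wells = simulate.simulate_monolayer_screen(mono_cfg, truth)
                cyst_cfg = simulate.ScreenConfig(
                    n_compounds=config.n_compounds, plate_format=384,
                    titration=simulate.cyst_titration(),
                    noise_cv=config.noise_cv, n_replicates=3,
                    seed=config.seed + 1)
                cwells, ctruth = simulate.simulate_cyst_plate(cyst_cfg, truth)
                pan_cfg = simulate.ScreenConfig(
                    n_compounds=config.n_compounds, noise_cv=config.noise_cv,
                    n_replicates=3, seed=config.seed + 2)
                pwells, ptruth = simulate.simulate_panel_screen(pan_cfg, truth)
                state.update(truth=truth, wells=wells, cyst_wells=cwells,
                             cyst_truth=ctruth, panel_wells=pwells,
                             panel_truth=ptruth)
                normalize.write_well_table(wells, out / "wells_monolayer.csv")
                truth.compounds.to_csv(out / "truth_compounds.csv", index=False)
                truth.effects.to_csv(out / "truth_effects.csv", index=False)
                summary["n_wells_monolayer"] = len(wells)
            elif stage == "normalize":
                for key in ("wells", "cyst_wells", "panel_wells"):
                    state[key] = normalize.normalize_wells(state[key])
                qc = pd.DataFrame([asdict(q) for q in
                                   normalize.plate_qc(state["wells"])])
                qc.to_csv(out / "plate_qc.csv", index=False)
                summary["median_zprime"] = float(qc["zprime"].median())
                summary["n_flagged_plates"] = int(qc["flagged"].sum())
            elif stage == "fit":
                for key, dst in (("wells", "profiles"),
                                 ("cyst_wells", "cyst_profiles"),
                                 ("panel_wells", "panel_profiles")):
                    titr = normalize.assemble_titrations(state[key])
                    state[dst] = hillfit.profile_titrations(titr)
                state["profiles"].to_csv(out / "profiles_monolayer.csv", index=False)
                state["cyst_profiles"].to_csv(out / "profiles_cyst.csv", index=False)
                state["panel_profiles"].to_csv(out / "profiles_panel.csv", index=False)
                summary["n_profiles"] = int(sum(len(state[k]) for k in
                                               ("profiles", "cyst_profiles",
                                                "panel_profiles")))
            elif stage == "call-mouse":
                cutoff = (th.delta_auc_primary if config.phase == "primary"
                          else th.delta_auc_validation)
                calls = hits.call_mouse_screen(state["profiles"], config.phase,
                                               cutoff=cutoff)
                cats = hits.categorize_hits(calls)
                calls.to_csv(out / "calls_mouse.csv", index=False)
                cats.to_csv(out / "hit_categories.csv", index=False)
                state["mouse_calls"], state["mouse_categories"] = calls, cats
                hit_ids = set(calls.loc[calls["is_hit"] == True, "compound_id"])  # noqa: E712
                state["mouse_hits"] = hit_ids
                summary["n_mouse_hits"] = len(hit_ids)
                summary["hit_categories"] = {
                    f"{r.pair_category}/{r.channel_category}": 1
                    for r in cats.itertuples()}
                counts: dict = {}
                for r in cats.itertuples():
                    key = f"{r.pair_category}/{r.channel_category}"
                    counts[key] = counts.get(key, 0) + 1
                summary["hit_categories"] = counts
            elif stage == "call-cyst":
                ccalls = hits.call_cyst_screen(state["cyst_profiles"],
                                               auc_cutoff=th.cyst_auc)
                ccalls.to_csv(out / "calls_cyst.csv", index=False)
                state["cyst_calls"] = ccalls
                summary["n_cyst_active"] = int(ccalls["is_active"].sum())
            elif stage == "call-human":
                adpkd = [n for n, g in simulate.DEFAULT_ISOLATES if g == "ADPKD"]
                nhk = [n for n, g in simulate.DEFAULT_ISOLATES if g == "NHK"]
                hcalls = hits.call_human_screen(
                    state["panel_profiles"], adpkd, nhk,
                    cutoff=th.delta_auc_human, zero_cutoff=th.delta_zero)
                agg = hits.aggregate_human_hits(
                    hcalls, th.min_pairs, th.min_adpkd, th.min_nhk)
                hcalls.to_csv(out / "calls_human.csv", index=False)
                agg.to_csv(out / "hits_human.csv", index=False)
                state["human_calls"], state["human_hits"] = hcalls, agg
                summary["n_human_flagged"] = int(agg["flagged"].sum())
            elif stage == "panel":
                prof = state["panel_profiles"]
                for ch in ("CTG", "GF-AFC"):
                    mat = prof[prof["channel"] == ch].pivot(
                        index="compound_id", columns="cell_line", values="auc")
                    pvals, cat = panel.similarity_matrix(mat, alpha=th.alpha)
                    pvals.to_csv(out / f"panel_pvalues_{ch}.csv")
                    cat.to_csv(out / f"panel_categories_{ch}.csv")
                    summary[f"n_different_pairs_{ch}"] = int(
                        (cat == "different").to_numpy().sum() // 2)
            elif stage == "enrich":
                ann = state["truth"].annotations()
                screened = set(state["truth"].compounds["compound_id"])
                table = enrich.enrich_targets(
                    state.get("mouse_hits", set()), screened, ann,
                    alpha=th.alpha)
                table.to_csv(out / "enrichment.csv", index=False)
                state["enrichment"] = table
                summary["n_enriched_genes"] = int(table["significant"].sum())
            elif stage == "imaging":
                # demonstrate the imaging path on a handful of wells
                rng_truth = state["cyst_truth"]
                demo = rng_truth[rng_truth["role"].isin(["neutral", "compound"])]
                demo = demo.head(config.n_imaging_wells)
                rows = []
                import numpy as np
                rng = np.random.default_rng(config.seed + 3)
                for w in demo.itertuples():
                    objs = []
                    for _ in range(min(int(w.n_swelled), 8)):
                        objs.append(simulate.CystObject(
                            x_um=float(rng.uniform(60, 340)),
                            y_um=float(rng.uniform(60, 340)),
                            radius_um=float(rng.uniform(35, 60)),
                            lumen=True, focus_plane=int(rng.integers(0, 5)),
                            contrast=0.8))
                    stack = simulate.render_cyst_image(objs, n_planes=5)
                    z, regions = imaging.analyze_stack(
                        stack, 1.0, th.min_area_um2, th.min_sbr)
                    n, area = imaging.summarize_well(regions)
                    rows.append({"plate_id": w.plate_id, "row": w.row,
                                 "col": w.col, "focus_plane": z,
                                 "n_regions": n, "total_area_um2": area})
                pd.DataFrame(rows).to_csv(out / "imaging_summary.csv", index=False)
                summary["n_imaged_wells"] = len(rows)
            else:  # pragma: no cover - guarded in RunConfig
                raise simulate.ConfigurationError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _stage(stage, summary, t0)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
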