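"""Synthetic screening campaigns with planted ground truth.

Every downstream stage of the triage pipeline (normalization, Hill
fitting, differential and 3D hit calling, panel statistics, enrichment,
imaging) is exercised against campaigns generated here, where the true
category of every compound is known:

``differential_embryonic`` / ``differential_postnatal`` /
``differential_both``
    suppress viability of the cystic (Pkd1-null) line(s) of the named
    pair(s) while sparing the matched wild-type line — the signal the
    screen exists to find;
``pan_active``
    equally cytotoxic to every line (no therapeutic window);
``inactive``
    no viability effect anywhere;
``cyst_swelling_only``
    no viability effect, but reduces the fraction of 3D structures that
    swell into lumen-bearing cysts (visible only to the imaging readout).

The emulated campaign mirrors a murine qHTS design: 1,536-well plates with
a positive-control (full-kill) column and a neutral (DMSO) column, 11-point
1:3 titrations from 57 µM down to ~0.96 nM, two viability channels
(GF-AFC protease fluorescence and CTG ATP luminescence), four cell lines in
two null/wild-type pairs, an 11-isolate human panel (5 ADPKD + 6 NHK), and
384-well 3D cyst plates with 8-point 1:2 dilutions from 100 µM.

Noise is multiplicative log-normal per well (plate readers show
signal-proportional noise); replicates are realized as separate plates.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ConfigurationError",
    "ScreenConfig",
    "TruthTable",
    "CystObject",
    "MOUSE_CELL_LINES",
    "DEFAULT_ISOLATES",
    "CATEGORIES",
    "default_titration",
    "cyst_titration",
    "make_truth_table",
    "simulate_monolayer_screen",
    "simulate_cyst_plate",
    "simulate_panel_screen",
    "render_cyst_image",
]

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Inconsistent screen configuration or truth/config mismatch."""


#: mouse lines as (pair_id, genotype); joined with '_' for the cell_line key
MOUSE_CELL_LINES = [("embryonic", "null"), ("embryonic", "wt"),
                    ("postnatal", "null"), ("postnatal", "wt")]

#: synthetic human panel: 5 ADPKD cystic + 6 normal human kidney isolates
DEFAULT_ISOLATES = [(f"ADPKD-{i}", "ADPKD") for i in range(1, 6)] + \
                   [(f"NHK-{i}", "NHK") for i in range(1, 7)]

CATEGORIES = ("differential_embryonic", "differential_postnatal",
              "differential_both", "pan_active", "inactive",
              "cyst_swelling_only")

#: default planted category mix (fractions of the library)
DEFAULT_CATEGORY_FRACTIONS = {
    "differential_embryonic": 0.05,
    "differential_postnatal": 0.05,
    "differential_both": 0.05,
    "pan_active": 0.10,
    "cyst_swelling_only": 0.05,
    "inactive": 0.70,
}

#: genes over-represented among planted differential compounds, plus a
#: generic target pool for everything else
_DIFFERENTIAL_GENES = ["XPO1", "HDAC1", "TOP2A", "TUBB", "MTOR"]
_GENERIC_GENES = [
    "EGFR", "BRAF", "ABL1", "SRC", "KDR", "MET", "ALK", "JAK2", "BTK",
    "PIK3CA", "AKT1", "MAPK1", "CDK4", "CDK9", "AURKA", "PLK1", "CHEK1",
    "PARP1", "BCL2", "MDM2", "EZH2", "BRD4", "DNMT1", "PTGS2", "HMGCR",
    "ADRB2", "HTR2A", "DRD2", "SLC6A4", "CFTR",
]

# neutral / positive control baselines per channel (arbitrary units)
CHANNEL_BASELINES = {
    "GF-AFC": (5000.0, 100.0),
    "CTG": (200000.0, 4000.0),
    "CTG-3D": (500000.0, 10000.0),
}

PLATE_DIMS = {1536: (32, 48), 384: (16, 24)}


def default_titration(n_points: int = 11, top_um: float = 57.0,
                      ratio: float = 3.0) -> np.ndarray:
    """Ascending titration: 1:`ratio` serial dilution from ``top_um``.

    The default reproduces the 11-point 1:3 series from 57 µM whose lowest
    dose is ~0.96 nM.
    """
    return top_um / ratio ** np.arange(n_points - 1, -1, -1, dtype=float)


def cyst_titration() -> np.ndarray:
    """8-point 1:2 series from 100 µM down to ~0.78 µM (3D cyst plates)."""
    return default_titration(8, 100.0, 2.0)


@dataclass
class ScreenConfig:
    """Layout and noise parameters of one simulated screen.

    ``control_layout`` maps 0-based plate column -> control role; the
    default dedicates column 0 to the positive and column 1 to the neutral
    control, with all remaining wells available for compounds.
    ``noise_cv`` is the per-well multiplicative coefficient of variation;
    ``plate_effect_cv`` scales whole plates (what plate-wise normalization
    removes).
    """

    n_compounds: int
    plate_format: int = 1536
    titration: np.ndarray = field(default_factory=default_titration)
    n_replicates: int = 1
    noise_cv: float = 0.0
    plate_effect_cv: float = 0.05
    control_layout: dict = field(
        default_factory=lambda: {0: "positive", 1: "neutral"})
    seed: int = 0

    def __post_init__(self) -> None:
        self.titration = np.asarray(self.titration, dtype=float)
        if np.any(np.diff(self.titration) <= 0):
            raise ConfigurationError("titration must be strictly increasing")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.plate_format not in PLATE_DIMS:
            raise ConfigurationError(f"unsupported plate format {self.plate_format}")

    @property
    def plate_capacity(self) -> int:
        rows, cols = PLATE_DIMS[self.plate_format]
        return rows * (cols - len(self.control_layout))


@dataclass
class TruthTable:
    """Planted ground truth for a compound library.

    ``compounds`` has one row per compound: compound_id, category,
    target_gene (or NaN), ac50_um, hill, active_efficacy (percent at
    saturation when the compound is active, in [-100, 0]) and
    swell_efficacy (effect on cyst swelling for cyst_swelling_only
    compounds).  ``effects`` is tidy per compound x cell line:
    compound_id, cell_line, efficacy.
    """

    compounds: pd.DataFrame
    effects: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.compounds["compound_id"]
        if ids.duplicated().any():
            raise ValueError("compound ids must be unique")
        eff = self.effects["efficacy"].to_numpy(float)
        if np.any(eff < -100) or np.any(eff > 0):
            raise ValueError("efficacies must lie in [-100, 0]")

    def __len__(self) -> int:
        return len(self.compounds)

    def category_map(self) -> dict[str, str]:
        return dict(zip(self.compounds["compound_id"], self.compounds["category"]))

    def efficacy_map(self) -> dict[tuple[str, str], float]:
        return {(r.compound_id, r.cell_line): r.efficacy
                for r in self.effects.itertuples()}

    def differential_compounds(self, pair: str | None = None) -> set[str]:
        """Planted differential set, optionally restricted to one pair."""
        cat = self.compounds["category"]
        if pair is None:
            keep = cat.str.startswith("differential")
        else:
            keep = cat.isin([f"differential_{pair}", "differential_both"])
        return set(self.compounds.loc[keep, "compound_id"])

    def annotations(self) -> pd.DataFrame:
        """Compound -> primary-target annotation table for enrichment."""
        ann = self.compounds.dropna(subset=["target_gene"])
        return pd.DataFrame({
            "compound_id": ann["compound_id"],
            "gene": ann["target_gene"],
            "moa": "synthetic",
            "indication": "synthetic",
        }).reset_index(drop=True)


def make_truth_table(n_compounds: int,
                     seed: int = 0,
                     fractions: dict[str, float] | None = None,
                     min_gap: float = 60.0,
                     cell_lines: list[tuple[str, str]] | None = None,
                     annotated_fraction: float = 0.95) -> TruthTable:
    """Plant a compound library with known categories and potencies.

    Active compounds get a log-uniform AC50 in 0.05–5 µM (well inside the
    57 µM titration) and a Hill slope in 1–2.  Differential compounds
    suppress the null line to -100..-(65) percent while the wild-type line
    stays within -5..0, enforcing an efficacy gap of at least ``min_gap``.
    Differential compounds draw their primary target from a small
    disease-associated gene set (so enrichment has signal to find); a few
    compounds are left unannotated.
    """
    rng = np.random.default_rng(seed)
    fractions = dict(DEFAULT_CATEGORY_FRACTIONS if fractions is None else fractions)
    cell_lines = MOUSE_CELL_LINES if cell_lines is None else cell_lines
    line_keys = [f"{p}_{g}" for p, g in cell_lines]

    cats = list(fractions)
    counts = {c: int(round(fractions[c] * n_compounds)) for c in cats}
    # absorb rounding drift into the most abundant category
    bulk = max(counts, key=counts.get)
    counts[bulk] += n_compounds - sum(counts.values())
    categories = np.repeat(cats, [counts[c] for c in cats])
    rng.shuffle(categories)

    rows, eff_rows = [], []
    for i, cat in enumerate(categories):
        cid = f"C{i:05d}"
        ac50 = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
        h = float(rng.uniform(1.0, 2.0))
        active_eff = float(rng.uniform(-100.0, -(min_gap + 5.0)))
        weak_eff = float(rng.uniform(-5.0, 0.0))
        swell_eff = float(rng.uniform(-90.0, -60.0)) if cat == "cyst_swelling_only" else 0.0
        if cat.startswith("differential"):
            gene = str(rng.choice(_DIFFERENTIAL_GENES))
        else:
            gene = str(rng.choice(_GENERIC_GENES))
        if rng.uniform() > annotated_fraction:
            gene = None
        rows.append({"compound_id": cid, "category": cat, "target_gene": gene,
                     "ac50_um": ac50, "hill": h,
                     "active_efficacy": active_eff, "swell_efficacy": swell_eff})
        for key in line_keys:
            pair, genotype = key.rsplit("_", 1)
            if cat == "pan_active":
                eff = active_eff
            elif cat == f"differential_{pair}" or cat == "differential_both":
                eff = active_eff if genotype == "null" else weak_eff
            elif cat.startswith("differential"):
                eff = weak_eff if genotype == "null" else weak_eff
            else:  # inactive, cyst_swelling_only
                eff = 0.0
            eff_rows.append({"compound_id": cid, "cell_line": key, "efficacy": eff})
    return TruthTable(pd.DataFrame(rows), pd.DataFrame(eff_rows))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _hill_fraction(conc: np.ndarray, ac50: float, h: float) -> np.ndarray:
    return 1.0 / (1.0 + (ac50 / conc) ** h)


def _simulate_screen(config: ScreenConfig, truth: TruthTable,
                     cell_lines: list[str],
                     efficacy: dict[tuple[str, str], float],
                     channels: tuple[str, ...],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Shared plate-layout engine for the monolayer and panel screens.

    Plates follow the qHTS inter-plate dilution-series design: the whole
    library is arrayed at ONE concentration per plate (compounds keep a
    fixed well position across the series), so a titration's dose points
    come from different plates and plate-level artifacts are independent
    across doses.  Each replicate is a separate plate series.
    """
    if config.n_compounds != len(truth):
        raise ConfigurationError(
            f"config expects {config.n_compounds} compounds, truth has {len(truth)}")
    rows_n, cols_n = PLATE_DIMS[config.plate_format]
    ctrl_cols = config.control_layout
    open_cols = [c for c in range(cols_n) if c not in ctrl_cols]
    cap = config.plate_capacity
    concs = config.titration
    comp_ids = truth.compounds["compound_id"].to_numpy()
    n_cmp = len(comp_ids)

    # static per-plate geometry: control wells first, then compound wells
    ctrl_rows = np.concatenate([np.arange(rows_n) for _ in sorted(ctrl_cols)])
    ctrl_colv = np.concatenate([np.full(rows_n, cc) for cc in sorted(ctrl_cols)])
    ctrl_role = np.concatenate([np.full(rows_n, ctrl_cols[cc], dtype=object)
                                for cc in sorted(ctrl_cols)])
    ctrl_act = np.where(ctrl_role == "neutral", 0.0, -100.0)

    frames = []
    for line in cell_lines:
        # (n_compounds, n_doses) true percent activity
        act = np.empty((n_cmp, concs.size))
        for i, r in enumerate(truth.compounds.itertuples()):
            eff = efficacy.get((r.compound_id, line), 0.0)
            act[i] = eff * _hill_fraction(concs, r.ac50_um, r.hill)
        for rep in range(config.n_replicates):
            for j, conc in enumerate(concs):
                for p0 in range(0, n_cmp, cap):
                    sel = slice(p0, min(p0 + cap, n_cmp))
                    ids = comp_ids[sel]
                    k = np.arange(ids.size)
                    rr = k // len(open_cols)
                    cc = np.take(open_cols, k % len(open_cols))
                    plate_id = f"{line}-r{rep + 1}-d{j + 1}-p{p0 // cap + 1}"
                    n_wells = ctrl_rows.size + ids.size
                    a_vec = np.concatenate([ctrl_act, act[sel, j]])
                    for ch in channels:
                        neu, pos = CHANNEL_BASELINES[ch]
                        pf = float(_lognormal_factors(
                            rng, config.plate_effect_cv, ()))
                        clean = neu + (a_vec / 100.0) * (neu - pos)
                        sig = pf * clean * _lognormal_factors(
                            rng, config.noise_cv, n_wells)
                        frames.append(pd.DataFrame({
                            "plate_id": plate_id,
                            "row": np.concatenate([ctrl_rows, rr]),
                            "col": np.concatenate([ctrl_colv, cc]),
                            "role": np.concatenate(
                                [ctrl_role, np.full(ids.size, "compound",
                                                    dtype=object)]),
                            "compound_id": np.concatenate(
                                [np.full(ctrl_rows.size, None, dtype=object),
                                 ids]),
                            "conc_um": np.concatenate(
                                [np.full(ctrl_rows.size, np.nan),
                                 np.full(ids.size, conc)]),
                            "channel": ch,
                            "cell_line": line,
                            "signal": sig,
                        }))
    return pd.concat(frames, ignore_index=True)


def simulate_monolayer_screen(config: ScreenConfig, truth: TruthTable,
                              cell_lines: list[tuple[str, str]] | None = None
                              ) -> pd.DataFrame:
    """Simulate the two-channel monolayer viability screen.

    Every compound appears at every titration point in both channels for
    all cell lines; each replicate is a separate set of plates.  Raw
    signals are ``baseline x (1 + Hill-shaped suppression) x noise``, so a
    zero-noise inactive compound reads exactly at the neutral baseline and
    a zero-noise full-efficacy compound reads at the positive baseline at
    saturation.
    """
    cell_lines = MOUSE_CELL_LINES if cell_lines is None else cell_lines
    keys = [f"{p}_{g}" for p, g in cell_lines]
    missing = set(keys) - set(truth.effects["cell_line"])
    if missing:
        raise ConfigurationError(f"truth table lacks cell lines: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    return _simulate_screen(config, truth, keys, truth.efficacy_map(),
                            ("GF-AFC", "CTG"), rng)


def simulate_panel_screen(config: ScreenConfig, truth: TruthTable,
                          isolates: list[tuple[str, str]] | None = None,
                          sensitivity: dict[str, float] | None = None,
                          adpkd_sensitive: set[str] | None = None
                          ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the human-isolate panel screen (ADPKD vs NHK).

    Compounds planted as differential suppress viability only in the
    sensitive ADPKD isolates (default: all of them); ``sensitivity`` maps
    isolate -> multiplier on efficacy to emulate inter-patient variability.
    Returns the well table plus a TruthTable whose effects are per isolate.
    """
    isolates = DEFAULT_ISOLATES if isolates is None else isolates
    groups = {g for _, g in isolates}
    if not groups <= {"ADPKD", "NHK"}:
        raise ConfigurationError("isolate groups must be ADPKD or NHK")
    if len(isolates) != 11:
        logger.warning("panel has %d isolates (11 expected)", len(isolates))
    sensitivity = sensitivity or {}
    adpkd_names = {n for n, g in isolates if g == "ADPKD"}
    sensitive = adpkd_names if adpkd_sensitive is None else set(adpkd_sensitive)

    eff_rows = []
    for r in truth.compounds.itertuples():
        for name, group in isolates:
            mult = sensitivity.get(name, 1.0)
            if r.category == "pan_active":
                eff = r.active_efficacy * mult
            elif r.category.startswith("differential") and name in sensitive:
                eff = r.active_efficacy * mult
            else:
                eff = 0.0
            eff_rows.append({"compound_id": r.compound_id, "cell_line": name,
                             "efficacy": float(np.clip(eff, -100.0, 0.0))})
    effects = pd.DataFrame(eff_rows)
    panel_truth = TruthTable(truth.compounds.copy(), effects)
    rng = np.random.default_rng(config.seed)
    wells = _simulate_screen(config, panel_truth, [n for n, _ in isolates],
                             panel_truth.efficacy_map(), ("GF-AFC", "CTG"), rng)
    return wells, panel_truth


#: DMSO-well baseline for the 3D assay: expected swelled-cyst count and
#: mean area per swelled cyst (µm^2)
CYST_BASELINE_COUNT = 30
CYST_MEAN_AREA_UM2 = 8000.0


def simulate_cyst_plate(config: ScreenConfig, truth: TruthTable,
                        viability_line: str = "postnatal_null"
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate 384-well 3D cyst plates: CTG-3D viability + cyst truth.

    The 3D assay grows postnatal Pkd1-null cells in matrix, so viability
    follows the compound's efficacy in that line.  ``cyst_swelling_only``
    compounds reduce the swelled-cyst count with their own dose response
    while leaving the ATP (CTG-3D) signal at the DMSO level; cytotoxic
    compounds reduce both.  The positive control is a full-kill agent
    (leptomycin-B-like): CTG-3D at the kill baseline and zero cysts.

    Returns ``(wells, cyst_truth)`` where cyst_truth has per well the true
    swelled-cyst count and total cyst area.
    """
    if config.plate_format != 384:
        raise ConfigurationError("3D cyst plates use the 384-well format")
    if config.titration.size != 8:
        warnings.warn(f"cyst titration has {config.titration.size} points "
                      "(8 expected)", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    eff = {(c, ln): e for (c, ln), e in truth.efficacy_map().items()
           if ln == viability_line}
    if not eff:
        raise ConfigurationError(f"truth table lacks cell line {viability_line}")

    wells = _simulate_screen(
        config, truth, [viability_line],
        truth.efficacy_map(), ("CTG-3D",), rng)

    swell_eff = dict(zip(truth.compounds["compound_id"],
                         truth.compounds["swell_efficacy"]))
    cat = truth.category_map()
    prm = {r.compound_id: (r.ac50_um, r.hill) for r in truth.compounds.itertuples()}
    truth_rows = []
    for w in wells.itertuples():
        if w.role == "neutral":
            frac = 1.0
        elif w.role == "positive":
            frac = 0.0
        else:
            ac50, h = prm[w.compound_id]
            if cat[w.compound_id] == "cyst_swelling_only":
                f = float(_hill_fraction(np.array([w.conc_um]), ac50, h)[0])
                frac = 1.0 + (swell_eff[w.compound_id] / 100.0) * f
            else:
                viab = eff.get((w.compound_id, viability_line), 0.0)
                f = float(_hill_fraction(np.array([w.conc_um]), ac50, h)[0])
                frac = 1.0 + (viab / 100.0) * f
        noise = float(_lognormal_factors(rng, config.noise_cv, ()))
        count = int(round(CYST_BASELINE_COUNT * max(frac, 0.0) * noise))
        area = count * CYST_MEAN_AREA_UM2
        truth_rows.append((w.plate_id, w.row, w.col, w.role, w.compound_id,
                           w.conc_um, count, area))
    cyst_truth = pd.DataFrame(truth_rows, columns=[
        "plate_id", "row", "col", "role", "compound_id", "conc_um",
        "n_swelled", "total_area_um2"])
    return wells, cyst_truth


@dataclass
class CystObject:
    """One rendered 3D structure: a swelled cyst (annulus) or aggregate (disc).

    Coordinates and radius in µm; ``focus_plane`` is the z index at which
    the object is sharpest; ``contrast`` is the rim/disc intensity relative
    to background.
    """

    x_um: float
    y_um: float
    radius_um: float
    lumen: bool = False
    focus_plane: int = 0
    contrast: float = 0.6

    def __post_init__(self) -> None:
        if self.radius_um < 0:
            raise ValueError("radius must be non-negative")


#: lumen interior starts below this fraction of the radius (annulus rim width)
LUMEN_RADIUS_FRACTION = 0.75
#: lumen intensity deficit relative to the rim excess
LUMEN_DIM_FRACTION = 0.35


def render_cyst_image(objects: list[CystObject],
                      pixel_size: float = 1.0,
                      n_planes: int = 30,
                      shape: tuple[int, int] = (400, 400),
                      background: float = 100.0,
                      defocus_sigma_per_plane: float = 1.2,
                      noise_sd: float = 0.0,
                      seed: int | None = None) -> np.ndarray:
    """Render a bright-field-like z-stack of cysts and aggregates.

    Swelled cysts (``lumen=True``) are a bright annulus around a dim lumen;
    aggregates are filled bright discs.  An object is sharp at its
    ``focus_plane`` and blurred elsewhere with a Gaussian whose sigma grows
    by ``defocus_sigma_per_plane`` pixels per plane of defocus.  Returns a
    float32 array of shape (n_planes, H, W).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    h, w = shape
    stack = np.full((n_planes, h, w), float(background), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for obj in objects:
        r_px = obj.radius_um / pixel_size
        cx, cy = obj.x_um / pixel_size, obj.y_um / pixel_size
        margin = int(np.ceil(r_px + 4 * defocus_sigma_per_plane * n_planes / 6 + 3))
        x0, x1 = max(0, int(cx) - margin), min(w, int(cx) + margin + 1)
        y0, y1 = max(0, int(cy) - margin), min(h, int(cy) + margin + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        d = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
        delta = np.zeros_like(d)
        amp = background * obj.contrast
        if obj.lumen:
            rim = (d <= r_px) & (d >= LUMEN_RADIUS_FRACTION * r_px)
            interior = d < LUMEN_RADIUS_FRACTION * r_px
            delta[rim] = amp
            delta[interior] = -LUMEN_DIM_FRACTION * amp
        else:
            delta[d <= r_px] = amp
        for z in range(n_planes):
            sigma = defocus_sigma_per_plane * abs(z - obj.focus_plane)
            blurred = gaussian_filter(delta, sigma) if sigma > 0 else delta
            stack[z, y0:y1, x0:x1] += blurred
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    return stack.astype(np.float32)
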