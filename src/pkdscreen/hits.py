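"""Phase-specific decision rules turning curve profiles into hit lists.

All rules operate on the interchange profile table produced by
:func:`pkdscreen.hillfit.profile_titrations` (one row per compound x
cell line x channel with curve class and AUC) and use the signed AUC
convention in which viability loss is negative.

Decision rules (all cutoffs configurable, defaults below):

* murine differential (primary / validation screens): the null-line curve
  must be a high-quality CRC (class -1.x or -2.x) and
  dAUC = AUC_null - AUC_wt must fall below -10 (primary) or -20
  (validation);
* 3D cyst activity (CTG-3D readout): curve class -1, -2 or 5 (anything
  but class 4) and AUC < -100;
* human ADPKD vs NHK pair: ADPKD curve class -1.x/-2.x, dAUC < -60 and
  difference of |Zero activity| below 10 percentage points; a compound is
  flagged panel-wide when at least 6 of the 30 isolate pairs are hits and
  those pairs span at least 2 distinct ADPKD and 3 distinct NHK isolates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hillfit import ACTIVE_CLASSES

__all__ = [
    "DifferentialCall",
    "CystCall",
    "DELTA_AUC_CUTOFFS",
    "CYST_AUC_CUTOFF",
    "DELTA_ZERO_CUTOFF",
    "call_differential_mouse",
    "call_cyst_active",
    "call_differential_human_pair",
    "call_mouse_screen",
    "call_cyst_screen",
    "call_human_screen",
    "aggregate_human_hits",
    "categorize_hits",
]

logger = logging.getLogger(__name__)

#: dAUC cutoffs by screening phase
DELTA_AUC_CUTOFFS = {"primary": -10.0, "validation": -20.0, "human": -60.0}
#: 3D activity requires AUC below this
CYST_AUC_CUTOFF = -100.0
#: human pairs additionally require | |zero_ADPKD| - |zero_NHK| | below this
DELTA_ZERO_CUTOFF = 10.0


@dataclass
class DifferentialCall:
    compound_id: str
    pair_id: str
    channel: str
    delta_auc: float
    is_hit: bool
    phase: str
    delta_abs_zero: float = np.nan
    disease_class: float = np.nan


@dataclass
class CystCall:
    compound_id: str
    curve_class: float
    auc: float
    is_active: bool
    swelling_reduced: bool | None = None


def _is_quality_class(curve_class: float) -> bool:
    return any(np.isclose(curve_class, c) for c in ACTIVE_CLASSES)


def call_differential_mouse(profile_null: pd.Series, profile_wt: pd.Series,
                            phase: str = "primary",
                            cutoff: float | None = None) -> DifferentialCall:
    """Differential-activity call for one compound/channel in a null/wt pair.

    ``profile_null`` / ``profile_wt`` are profile-table rows for the same
    compound and channel.  A hit requires a high-quality CRC in the
    Pkd1-null line and dAUC = AUC_null - AUC_wt below the phase cutoff.
    """
    if phase not in ("primary", "validation"):
        raise ValueError(f"unknown mouse screening phase {phase!r}")
    if profile_null["compound_id"] != profile_wt["compound_id"] or \
            profile_null["channel"] != profile_wt["channel"]:
        raise ValueError("null and wt profiles must match compound and channel")
    cutoff = DELTA_AUC_CUTOFFS[phase] if cutoff is None else cutoff
    delta = float(profile_null["auc"] - profile_wt["auc"])
    hit = _is_quality_class(profile_null["curve_class"]) and delta < cutoff
    pair = str(profile_null["cell_line"]).rsplit("_", 1)[0]
    return DifferentialCall(str(profile_null["compound_id"]), pair,
                            str(profile_null["channel"]), delta, bool(hit),
                            phase, disease_class=float(profile_null["curve_class"]))


def call_cyst_active(profile_3d: pd.Series,
                     auc_cutoff: float = CYST_AUC_CUTOFF) -> CystCall:
    """3D cyst-assay activity call from the CTG-3D profile.

    Active iff the curve class is not 4 (i.e. -1, -2, -3 or 5) and the AUC
    is below the cutoff (-100 by default).
    """
    cls = float(profile_3d["curve_class"])
    auc = float(profile_3d["auc"])
    active = (not np.isclose(cls, 4.0)) and auc < auc_cutoff
    return CystCall(str(profile_3d["compound_id"]), cls, auc, bool(active))


def call_differential_human_pair(profile_adpkd: pd.Series, profile_nhk: pd.Series,
                                 cutoff: float | None = None,
                                 zero_cutoff: float = DELTA_ZERO_CUTOFF
                                 ) -> DifferentialCall:
    """Differential call for one ADPKD x NHK isolate pair and channel.

    A hit requires a high-quality CRC in the ADPKD isolate, dAUC < -60 and
    agreement of the low-concentration asymptotes: the difference of the
    absolute Zero-activity values must stay below 10 percentage points
    (curves starting from comparable baselines).
    """
    if profile_adpkd["compound_id"] != profile_nhk["compound_id"] or \
            profile_adpkd["channel"] != profile_nhk["channel"]:
        raise ValueError("profiles must match compound and channel")
    cutoff = DELTA_AUC_CUTOFFS["human"] if cutoff is None else cutoff
    delta = float(profile_adpkd["auc"] - profile_nhk["auc"])
    dzero = abs(abs(float(profile_adpkd["zero"])) - abs(float(profile_nhk["zero"])))
    hit = (_is_quality_class(profile_adpkd["curve_class"])
           and delta < cutoff and dzero < zero_cutoff)
    pair = f"{profile_adpkd['cell_line']}x{profile_nhk['cell_line']}"
    return DifferentialCall(str(profile_adpkd["compound_id"]), pair,
                            str(profile_adpkd["channel"]), delta, bool(hit),
                            "human", delta_abs_zero=dzero,
                            disease_class=float(profile_adpkd["curve_class"]))


def _profile_lookup(profiles: pd.DataFrame) -> dict:
    return {(r["compound_id"], r["cell_line"], r["channel"]): r
            for _, r in profiles.iterrows()}


def call_mouse_screen(profiles: pd.DataFrame, phase: str = "primary",
                      pairs: list[str] | None = None,
                      cutoff: float | None = None) -> pd.DataFrame:
    """Differential calls for every compound x pair x channel in a screen.

    ``profiles`` must contain cell lines named ``<pair>_null`` and
    ``<pair>_wt``.  Compounds missing the wild-type profile are logged and
    reported as inconclusive (is_hit NA, excluded from hit lists).
    """
    lines = set(profiles["cell_line"])
    if pairs is None:
        pairs = sorted({ln.rsplit("_", 1)[0] for ln in lines
                        if ln.endswith("_null")})
    lut = _profile_lookup(profiles)
    channels = sorted(set(profiles["channel"]))
    rows = []
    for cid in profiles["compound_id"].unique():
        for pair, ch in itertools.product(pairs, channels):
            pn = lut.get((cid, f"{pair}_null", ch))
            pw = lut.get((cid, f"{pair}_wt", ch))
            if pn is None or pw is None:
                logger.info("inconclusive: %s %s %s (missing profile)", cid, pair, ch)
                rows.append({"compound_id": cid, "pair_id": pair, "channel": ch,
                             "delta_auc": np.nan, "is_hit": pd.NA, "phase": phase})
                continue
            c = call_differential_mouse(pn, pw, phase, cutoff)
            rows.append({"compound_id": c.compound_id, "pair_id": c.pair_id,
                         "channel": c.channel, "delta_auc": c.delta_auc,
                         "is_hit": c.is_hit, "phase": c.phase,
                         "disease_class": c.disease_class})
    return pd.DataFrame(rows)


def call_cyst_screen(profiles: pd.DataFrame,
                     auc_cutoff: float = CYST_AUC_CUTOFF,
                     swelling: pd.DataFrame | None = None) -> pd.DataFrame:
    """3D activity calls for every compound in the CTG-3D channel.

    ``swelling``, when provided by the imaging module, maps compound_id to
    a boolean ``swelling_reduced``; otherwise the flag is left unknown.
    """
    p3 = profiles[profiles["channel"] == "CTG-3D"]
    sw = {} if swelling is None else dict(
        zip(swelling["compound_id"], swelling["swelling_reduced"]))
    rows = []
    for _, r in p3.iterrows():
        c = call_cyst_active(r, auc_cutoff)
        rows.append({"compound_id": c.compound_id, "curve_class": c.curve_class,
                     "auc": c.auc, "is_active": c.is_active,
                     "swelling_reduced": sw.get(c.compound_id, pd.NA)})
    return pd.DataFrame(rows)


def call_human_screen(profiles: pd.DataFrame,
                      adpkd: list[str], nhk: list[str],
                      cutoff: float | None = None,
                      zero_cutoff: float = DELTA_ZERO_CUTOFF) -> pd.DataFrame:
    """Pairwise ADPKD x NHK differential calls over all isolate pairs."""
    lut = _profile_lookup(profiles)
    channels = sorted(set(profiles["channel"]))
    rows = []
    for cid in profiles["compound_id"].unique():
        for a, n, ch in itertools.product(adpkd, nhk, channels):
            pa, pn = lut.get((cid, a, ch)), lut.get((cid, n, ch))
            if pa is None or pn is None:
                logger.info("inconclusive: %s %sx%s %s", cid, a, n, ch)
                continue
            c = call_differential_human_pair(pa, pn, cutoff, zero_cutoff)
            rows.append({"compound_id": c.compound_id, "adpkd": a, "nhk": n,
                         "channel": ch, "delta_auc": c.delta_auc,
                         "delta_abs_zero": c.delta_abs_zero,
                         "is_hit": c.is_hit})
    return pd.DataFrame(rows)


def aggregate_human_hits(calls: pd.DataFrame, min_pairs: int = 6,
                         min_adpkd: int = 2, min_nhk: int = 3) -> pd.DataFrame:
    """Panel-wide flag per compound from per-pair human calls.

    A pair counts as a hit if it passes in either channel.  A compound is
    flagged when at least ``min_pairs`` pairs hit and those pairs span at
    least ``min_adpkd`` distinct ADPKD and ``min_nhk`` distinct NHK
    isolates.
    """
    pair_hits = (calls.groupby(["compound_id", "adpkd", "nhk"])["is_hit"]
                 .any().reset_index())
    rows = []
    for cid, grp in pair_hits.groupby("compound_id"):
        hit = grp[grp["is_hit"]]
        n_pairs = len(hit)
        n_a, n_n = hit["adpkd"].nunique(), hit["nhk"].nunique()
        rows.append({"compound_id": cid, "n_hit_pairs": n_pairs,
                     "n_adpkd": n_a, "n_nhk": n_n,
                     "flagged": n_pairs >= min_pairs and n_a >= min_adpkd
                     and n_n >= min_nhk})
    return pd.DataFrame(rows)


def categorize_hits(calls: pd.DataFrame) -> pd.DataFrame:
    """Partition mouse hits by cell pair and readout.

    From per-pair/channel differential calls (typically validation phase),
    each hit compound gets a ``pair_category`` in {embryonic_only,
    postnatal_only, both} and a ``channel_category`` in {GF-AFC, CTG,
    both}.  Categories on the pair axis are pairwise disjoint and their
    union is the full hit list.
    """
    hits = calls[calls["is_hit"] == True]  # noqa: E712 - may hold pd.NA
    rows = []
    for cid, grp in hits.groupby("compound_id"):
        pairs = set(grp["pair_id"])
        chans = set(grp["channel"])
        if pairs >= {"embryonic", "postnatal"}:
            pcat = "both"
        else:
            pcat = f"{next(iter(pairs))}_only"
        ccat = "both" if len(chans) > 1 else next(iter(chans))
        rows.append({"compound_id": cid, "pair_category": pcat,
                     "channel_category": ccat})
    out = pd.DataFrame(rows, columns=["compound_id", "pair_category",
                                      "channel_category"])
    return out
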