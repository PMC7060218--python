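"""Plate-wise normalization to intra-plate controls and plate quality control.

Raw well signals are converted to percent activity anchored on the two
control columns of each plate: the neutral control (DMSO) maps to 0% and
the positive control (a full-kill cytotoxin such as digitonin, or
leptomycin B in the 3D assay) maps to -100%, so viability loss is negative.
Control centers use the median (robust to occasional dead control wells);
control spread uses the standard deviation, the convention of the Z'
factor.

The well table is a tidy pandas DataFrame with columns::

    plate_id, row, col, role, compound_id, conc_um, channel, cell_line, signal

``role`` is one of ``neutral``, ``positive``, ``compound``, ``empty``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hillfit import Titration

__all__ = [
    "WELL_COLUMNS",
    "PlateQC",
    "percent_activity",
    "zprime",
    "plate_qc",
    "normalize_wells",
    "assemble_titrations",
    "read_well_table",
    "write_well_table",
]

logger = logging.getLogger(__name__)

WELL_COLUMNS = ["plate_id", "row", "col", "role", "compound_id",
                "conc_um", "channel", "cell_line", "signal"]


@dataclass
class PlateQC:
    """Per plate x channel assay-quality metrics.

    ``zprime`` is 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| (1 is ideal,
    <= 0 unusable); ``s_to_b`` is the neutral/positive mean ratio.
    A plate with coincident control centers gets ``zprime = -inf`` and is
    flagged so its wells can be excluded.
    """

    plate_id: str
    channel: str
    zprime: float
    s_to_b: float
    n_pos: int
    n_neg: int
    flagged: bool = False


def percent_activity(signal, neutral_center: float, positive_center: float):
    """Affine map of raw signal to percent activity.

    The neutral-control center maps to 0, the positive-control center to
    -100; the map is linear in the signal so it is exactly invertible.
    """
    if neutral_center == positive_center:
        raise ValueError("degenerate controls: neutral and positive centers coincide")
    return 100.0 * (np.asarray(signal, dtype=float) - neutral_center) / (
        neutral_center - positive_center)


def zprime(pos: np.ndarray, neg: np.ndarray) -> float:
    """Z' factor of one plate's control wells.

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|.  Zero variance in
    both groups gives the noiseless limit 1; zero mean separation returns
    -inf as a flag sentinel.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    sep = abs(pos.mean() - neg.mean())
    if sep == 0.0:
        return -np.inf
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def plate_qc(wells: pd.DataFrame) -> list[PlateQC]:
    """Compute Z' and S:B for every plate x channel in a well table."""
    out: list[PlateQC] = []
    for (plate, channel), grp in wells.groupby(["plate_id", "channel"], sort=True):
        pos = grp.loc[grp["role"] == "positive", "signal"].to_numpy(float)
        neg = grp.loc[grp["role"] == "neutral", "signal"].to_numpy(float)
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError(
                f"plate {plate}/{channel}: need >= 2 wells per control group")
        z = zprime(pos, neg)
        sb = neg.mean() / pos.mean() if pos.mean() != 0 else np.inf
        out.append(PlateQC(str(plate), str(channel), z, float(sb),
                           len(pos), len(neg), flagged=not np.isfinite(z)))
    return out


def normalize_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Add an ``activity`` column: plate-wise percent activity per channel.

    Control centers are intra-plate medians.  Plates whose control centers
    coincide are flagged: their activities are set to NaN and a warning is
    logged.
    """
    wells = wells.copy()
    wells["activity"] = np.nan
    for (plate, channel), idx in wells.groupby(["plate_id", "channel"]).groups.items():
        grp = wells.loc[idx]
        neu = grp.loc[grp["role"] == "neutral", "signal"].median()
        pos = grp.loc[grp["role"] == "positive", "signal"].median()
        if not np.isfinite(neu) or not np.isfinite(pos) or neu == pos:
            logger.warning("plate %s/%s flagged: degenerate controls", plate, channel)
            continue
        wells.loc[idx, "activity"] = percent_activity(
            grp["signal"].to_numpy(float), neu, pos)
    return wells


def assemble_titrations(wells: pd.DataFrame) -> list[Titration]:
    """Group normalized compound wells into per-curve titrations.

    One :class:`Titration` per compound x cell line x channel with
    concentrations ascending.  Wells at the same concentration (replicate
    plates or duplicate wells) are kept individually in ``replicates`` and
    aggregated by median into ``activities``.  Missing dose points are
    retained as NaN gaps and logged.
    """
    if "activity" not in wells.columns:
        raise ValueError("wells must be normalized first (no 'activity' column)")
    cmp = wells[wells["role"] == "compound"]
    out: list[Titration] = []
    for (compound, line, channel), grp in cmp.groupby(
            ["compound_id", "cell_line", "channel"], sort=True):
        conc = grp["conc_um"].to_numpy(float)
        act = grp["activity"].to_numpy(float)
        order = np.argsort(conc, kind="stable")
        conc_s, act_s = conc[order], act[order]
        concs, starts = np.unique(conc_s, return_index=True)
        counts = np.diff(np.append(starts, conc_s.size))
        reps = np.full((int(counts.max()), concs.size), np.nan)
        within = np.arange(conc_s.size) - np.repeat(starts, counts)
        cols = np.repeat(np.arange(concs.size), counts)
        reps[within, cols] = act_s
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(reps, axis=0)
        if np.any(~np.isfinite(med)):
            logger.info("titration %s/%s/%s has missing dose points",
                        compound, line, channel)
        out.append(Titration(str(compound), str(line), str(channel),
                             concs, med, replicates=reps))
    return out


def read_well_table(path) -> pd.DataFrame:
    """Read the CSV well-table dialect (shared with the simulators)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "compound_id": str})
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    return df


def write_well_table(wells: pd.DataFrame, path) -> None:
    cols = [c for c in WELL_COLUMNS if c in wells.columns]
    extra = [c for c in wells.columns if c not in cols]
    wells[cols + extra].to_csv(path, index=False)
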