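"""Western-blot ratio statistics with internal-standard cross-gel normalization.

Lanes carry raw densitometry intensities for LRRK2, pS935-LRRK2, Rab10,
pT73-Rab10 and tubulin (arbitrary units from multiplexed near-infrared
imaging). Within-lane ratios remove loading differences; dividing by the same
ratio measured in the gel's internal-standard lane (the same control sample
run on every gel) makes values comparable across gels. The LLOMe response is
the percent increase in the internally-controlled pT73-Rab10/Rab10 ratio over
basal, computed from within-gel ratios since the ratio needs no cross-gel
anchor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError, UndefinedResponseError

logger = logging.getLogger(__name__)

BANDS = ("LRRK2", "pS935", "Rab10", "pT73_Rab10", "tubulin")
OPTIONAL_BANDS = ("pS106_Rab12", "Rab12")

#: (numerator, denominator) pairs quantified per lane.
RATIOS = (
    ("LRRK2", "tubulin"),
    ("pS935", "tubulin"),
    ("pS935", "LRRK2"),
    ("Rab10", "tubulin"),
    ("pT73_Rab10", "tubulin"),
    ("pT73_Rab10", "Rab10"),
)

CONDITIONS = ("basal", "MLi2", "LLOMe", "LLOMe_MLi2")


def ratio_column(numerator: str, denominator: str) -> str:
    return f"{numerator}_over_{denominator}"


def normalize_lanes(lanes: pd.DataFrame, standard_sample_id: str
                    ) -> pd.DataFrame:
    """Compute within-lane ratios and internal-standard-relative values.

    ``lanes`` needs columns sample_id, gel_id, condition, replicate plus the
    raw band intensities in :data:`BANDS`. Every gel must contain at least one
    lane of ``standard_sample_id``; its (replicate-averaged) within-lane
    ratios define the per-gel anchor, so each ratio also gains a
    ``rel_``-prefixed cross-gel-comparable column. Lanes with a zero
    denominator band are dropped with a warning. One output row per input
    lane; replicate averaging is a separate step (:func:`average_replicates`).
    """
    missing = [c for c in ("sample_id", "gel_id", "condition", *BANDS)
               if c not in lanes.columns]
    if missing:
        raise InputError(f"lane table missing columns: {missing}")

    df = lanes.copy()
    denominators = {den for _, den in RATIOS}
    bad = pd.Series(False, index=df.index)
    for den in denominators:
        bad |= df[den] <= 0
    if bad.any():
        logger.warning("dropping %d lane(s) with a zero denominator band",
                       int(bad.sum()))
        df = df[~bad].copy()

    for num, den in RATIOS:
        df[ratio_column(num, den)] = df[num] / df[den]

    for gel, gel_rows in df.groupby("gel_id"):
        std = gel_rows[gel_rows["sample_id"] == standard_sample_id]
        if std.empty:
            raise NormalizationError(
                f"gel {gel!r} lacks internal-standard lane "
                f"{standard_sample_id!r}")
        for num, den in RATIOS:
            col = ratio_column(num, den)
            anchor = std[col].mean()
            df.loc[gel_rows.index, f"rel_{col}"] = gel_rows[col] / anchor
    return df


def average_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Average normalized ratios over replicate lanes per sample × condition."""
    value_cols = [c for c in normalized.columns
                  if "_over_" in c]
    return (normalized
            .groupby(["sample_id", "condition"], as_index=False)[value_cols]
            .mean())


def llome_response(normalized: pd.DataFrame) -> pd.DataFrame:
    """Percent LLOMe-triggered increase in pT73-Rab10/Rab10 per sample.

    percent increase = 100 × (ratio[LLOMe] − ratio[basal]) / ratio[basal],
    and analogously with MLi2 present (LLOMe_MLi2 vs basal). Samples whose
    increase is ≤ 0 are flagged non-responders. Requires basal and LLOMe
    conditions per sample; the MLi2 column is NaN when LLOMe_MLi2 is absent.
    """
    col = ratio_column("pT73_Rab10", "Rab10")
    if col not in normalized.columns:
        raise InputError(f"normalized table lacks {col!r}; run normalize_lanes")
    averaged = average_replicates(normalized)
    wide = averaged.pivot(index="sample_id", columns="condition", values=col)

    rows = []
    for sample_id, r in wide.iterrows():
        basal = r.get("basal", np.nan)
        llome = r.get("LLOMe", np.nan)
        llome_mli2 = r.get("LLOMe_MLi2", np.nan)
        if np.isnan(llome):
            continue  # sample not part of the LLOMe arm (e.g. the standard)
        if np.isnan(basal):
            raise InputError(f"sample {sample_id!r} lacks a basal condition")
        if basal == 0:
            raise UndefinedResponseError(
                f"sample {sample_id!r}: basal pT73-Rab10/Rab10 ratio is zero")
        pct = 100.0 * (llome - basal) / basal
        pct_mli2 = (100.0 * (llome_mli2 - basal) / basal
                    if not np.isnan(llome_mli2) else np.nan)
        rows.append({
            "sample_id": sample_id,
            "pct_increase": pct,
            "pct_increase_mli2": pct_mli2,
            "non_responder": pct <= 0,
        })
    return pd.DataFrame(rows, columns=["sample_id", "pct_increase",
                                       "pct_increase_mli2", "non_responder"])
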