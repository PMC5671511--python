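"""Dual-reporter plate normalization: blanks, GFP/mCherry ratios, summaries.

A plate holds well-level two-channel readings with roles ``sample``,
``blank`` and ``background``.  Processing is: subtract the per-channel blank
aggregate, form the per-well GFP/mCherry ratio (cancelling the per-well
transfection-efficiency factor shared by both channels), exclude wells whose
mCherry does not rise above the non-transfected background, average wells
within each transfection (the biological replicate), and report per-construct
mean / sd / c.v. plus a reference-scaled relative value with a two-sample
equal-variance t-test against the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "ROLES",
    "Plate",
    "RatioTable",
    "blank_correct",
    "normalized_ratios",
    "summarize_constructs",
    "median_cv",
]

CHANNELS = ("GFP", "mCherry")
ROLES = ("sample", "blank", "background")

PLATE_COLUMNS = ["well", "construct", "role", "channel", "value"]


@dataclass(frozen=True)
class Plate:
    """Well-level readings; one row per well x channel.

    ``data`` columns: well, construct, role, channel, value and optionally
    ``transfection`` (the biological-replicate label; defaults to the well
    id).  After :func:`blank_correct`, ``blank_corrected`` is True and a
    boolean ``negative`` flag marks values that went below zero.
    """

    data: pd.DataFrame
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = set(PLATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"plate is missing columns {sorted(missing)}")
        if "transfection" not in df.columns:
            df["transfection"] = df["well"]
        bad_roles = set(df["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")
        bad_channels = set(df["channel"]) - set(CHANNELS)
        if bad_channels:
            raise ValueError(f"unknown channels {sorted(bad_channels)}")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("plate values must be finite")
        samples = df[df["role"] == "sample"]
        per_well = samples.groupby("well")["channel"].agg(lambda s: frozenset(s))
        incomplete = per_well[per_well != frozenset(CHANNELS)]
        if len(incomplete):
            raise ValueError(
                f"sample wells missing a channel: {sorted(incomplete.index)}"
            )
        object.__setattr__(self, "data", df)

    def channel_values(self, role: str, channel: str) -> pd.Series:
        df = self.data
        return df.loc[(df["role"] == role) & (df["channel"] == channel), "value"]


def blank_correct(plate: Plate, aggregate: str = "mean") -> Plate:
    """Subtract the per-channel blank aggregate from every well.

    Negative corrected values are kept but flagged in a ``negative`` column.
    """
    if plate.blank_corrected:
        raise ValueError("plate is already blank-corrected")
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown blank aggregate {aggregate!r}")
    blanks = {}
    for channel in CHANNELS:
        vals = plate.channel_values("blank", channel)
        if vals.empty:
            raise ValueError(f"no blank wells for channel {channel}")
        blanks[channel] = vals.mean() if aggregate == "mean" else vals.median()
    df = plate.data.copy()
    df["value"] = df["value"] - df["channel"].map(blanks)
    df["negative"] = df["value"] < 0
    n_neg = int(df["negative"].sum())
    if n_neg:
        logger.warning("blank correction left %d negative readings (flagged)", n_neg)
    return Plate(data=df, blank_corrected=True)


@dataclass(frozen=True)
class RatioTable:
    """Per-well corrected channels and their ratio, with exclusion flags.

    ``data`` columns: well, construct, transfection, gfp_corrected,
    mcherry_corrected, ratio, excluded, reason.
    """

    data: pd.DataFrame

    def included(self) -> pd.DataFrame:
        return self.data[~self.data["excluded"]]


def normalized_ratios(
    plate: Plate, background_rule: str | None = "mean"
) -> RatioTable:
    """Form the per-well GFP/mCherry ratio on a blank-corrected plate.

    Wells whose corrected mCherry does not exceed the background-well mCherry
    aggregate are excluded with reason ``"mCherry at background"``.
    ``background_rule`` is ``mean`` (default), ``median`` or None to skip the
    exclusion.
    """
    if not plate.blank_corrected:
        raise ValueError("normalized_ratios requires a blank-corrected plate")
    threshold = -np.inf
    if background_rule is not None:
        if background_rule not in ("mean", "median"):
            raise ValueError(f"unknown background rule {background_rule!r}")
        bg = plate.channel_values("background", "mCherry")
        if bg.empty:
            raise ValueError(
                "background rule requires background wells but none are present"
            )
        threshold = bg.mean() if background_rule == "mean" else bg.median()
    samples = plate.data[plate.data["role"] == "sample"]
    wide = samples.pivot_table(
        index=["well", "construct", "transfection"],
        columns="channel",
        values="value",
        aggfunc="first",
    ).reset_index()
    rows = pd.DataFrame(
        {
            "well": wide["well"],
            "construct": wide["construct"],
            "transfection": wide["transfection"],
            "gfp_corrected": wide["GFP"].astype(float),
            "mcherry_corrected": wide["mCherry"].astype(float),
        }
    )
    excluded = rows["mcherry_corrected"] <= threshold
    rows["ratio"] = np.where(
        excluded, np.nan, rows["gfp_corrected"] / rows["mcherry_corrected"]
    )
    rows["excluded"] = excluded
    rows["reason"] = np.where(excluded, "mCherry at background", "")
    n_excl = int(excluded.sum())
    if n_excl:
        logger.info("excluded %d wells with mCherry at background", n_excl)
    return RatioTable(data=rows.sort_values("well", kind="mergesort").reset_index(drop=True))


def _replicate_values(ratios: RatioTable, value: str) -> pd.DataFrame:
    col = {"ratio": "ratio", "gfp": "gfp_corrected"}[value]
    inc = ratios.included()
    reps = (
        inc.groupby(["construct", "transfection"], sort=True)[col]
        .mean()
        .rename("value")
        .reset_index()
    )
    return reps


def summarize_constructs(
    ratios: RatioTable,
    reference_id: str,
    scale: float = 1.0,
    value: str = "ratio",
) -> pd.DataFrame:
    """Aggregate replicates per construct and scale to a reference.

    The replicate unit is the transfection: wells of one transfection are
    averaged first.  Returns a frame with columns construct, n, mean_ratio,
    sd, cv, relative, p_vs_reference.  ``relative`` is mean / reference mean
    x scale (the reference row is exactly ``scale``); p is a two-sided
    equal-variance Student's t-test against the reference replicates
    (NaN and a logged flag for constructs with < 2 replicates).
    ``value="gfp"`` summarizes raw corrected GFP instead of the ratio.
    """
    reps = _replicate_values(ratios, value)
    if reference_id not in set(reps["construct"]):
        raise ValueError(f"reference construct {reference_id!r} not present")
    ref_values = reps.loc[reps["construct"] == reference_id, "value"].to_numpy()
    if len(ref_values) < 2:
        raise ValueError("reference construct needs at least 2 replicates")
    ref_mean = ref_values.mean()
    out = []
    for construct, sub in reps.groupby("construct", sort=True):
        vals = sub["value"].to_numpy()
        n = len(vals)
        mean = vals.mean()
        sd = vals.std(ddof=1) if n >= 2 else np.nan
        cv = sd / mean if n >= 2 and mean != 0 else np.nan
        if construct == reference_id:
            relative = float(scale)
        else:
            relative = mean / ref_mean * scale
        if n < 2:
            logger.warning("%s: fewer than 2 replicates; p undefined", construct)
            p = np.nan
        else:
            pooled_sd = np.sqrt(
                ((n - 1) * np.var(vals, ddof=1) + (len(ref_values) - 1) * np.var(ref_values, ddof=1))
                / (n + len(ref_values) - 2)
            )
            if pooled_sd == 0:
                p = 1.0 if mean == ref_mean else 0.0
            else:
                p = float(_sps.ttest_ind(vals, ref_values, equal_var=True).pvalue)
        out.append(
            {
                "construct": construct,
                "n": n,
                "mean_ratio": mean,
                "sd": sd,
                "cv": cv,
                "relative": relative,
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(out)


def median_cv(summary: pd.DataFrame) -> float:
    """Median of the per-construct coefficients of variation."""
    cvs = summary["cv"].dropna()
    if cvs.empty:
        raise ValueError("no construct has a defined c.v.")
    return float(cvs.median())
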