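"""Time-in-score exposure statistics.

Converts per-frame RULA scores into the summary layer used for reporting:

* the relative time spent in each integer score value;
* the *relative average risk score over time* (rel. av. RST), i.e. the
  time-weighted mean score, sum over v of (fraction of frames at v) * v;
* the *ergonomic risk potential* (ERP), the rel. av. RST expressed as a
  percentage of the outcome's maximum possible score;
* median and interquartile distance (IQD, Q3 - Q1 with linearly
  interpolated quantiles).

Aggregation is per-subject first: every subject contributes one summary per
outcome, and group cells take the median/IQD of subject medians and the mean
of subject rel. av. RSTs.  Rounding (two decimals, half-up) happens only at
the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "OUTCOME_COLUMNS",
    "ScoreTimeDistribution",
    "RiskSummary",
    "RiskStatsError",
    "time_distribution",
    "rel_av_rst",
    "erp",
    "median_iqd",
    "round_half_up",
    "summarize_frames",
    "summarize_subject",
    "cohort_summaries",
    "group_table",
    "distribution_table",
]


class RiskStatsError(ValueError):
    pass


#: Reported outcomes and their maximum possible scores.
OUTCOMES: dict[str, int] = {
    "final": 7,
    "trunk": 6,
    "neck": 6,
    "wrist_r": 6,
    "wrist_l": 6,
    "lower_arm_r": 3,
    "lower_arm_l": 3,
    "upper_arm_r": 6,
    "upper_arm_l": 6,
}

#: Outcome -> column of the per-frame score table (wrist uses the combined score).
OUTCOME_COLUMNS: dict[str, str] = {
    "final": "final",
    "trunk": "trunk",
    "neck": "neck",
    "wrist_r": "wrist_combined_r",
    "wrist_l": "wrist_combined_l",
    "lower_arm_r": "lower_arm_r",
    "lower_arm_l": "lower_arm_l",
    "upper_arm_r": "upper_arm_r",
    "upper_arm_l": "upper_arm_l",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoreTimeDistribution:
    """Relative time spent in each integer score value for one outcome."""

    outcome: str
    max_score: int
    rel_time: dict[int, float]

    def __post_init__(self):
        total = 0.0
        for v, frac in self.rel_time.items():
            if not (1 <= v <= self.max_score):
                raise RiskStatsError(
                    f"score value {v} outside 1..{self.max_score} for {self.outcome}"
                )
            if frac < 0:
                raise RiskStatsError("relative times must be non-negative")
            total += frac
        if abs(total - 1.0) > 1e-12:
            raise RiskStatsError(f"relative times sum to {total!r}, expected 1")


@dataclass(frozen=True)
class RiskSummary:
    """Median, IQD, rel. av. RST and ERP for one (subject, outcome) cell."""

    outcome: str
    max_score: int
    median: float
    iqd: float
    rel_av_rst: float
    erp_pct: float


def time_distribution(scores, max_score: int, outcome: str = "final") -> ScoreTimeDistribution:
    """Relative time per score value: rel_time[v] = count(v) / n."""
    arr = np.asarray(scores)
    if arr.size == 0:
        raise RiskStatsError("empty score sequence")
    if not np.all(arr == arr.astype(np.int64)):
        raise RiskStatsError("scores must be integers")
    arr = arr.astype(np.int64)
    if arr.min() < 1 or arr.max() > max_score:
        raise RiskStatsError(
            f"score outside 1..{max_score} in sequence (min {arr.min()}, max {arr.max()})"
        )
    values, counts = np.unique(arr, return_counts=True)
    rel = {int(v): c / arr.size for v, c in zip(values, counts)}
    return ScoreTimeDistribution(outcome=outcome, max_score=max_score, rel_time=rel)


def rel_av_rst(dist: ScoreTimeDistribution) -> float:
    """Time-weighted mean score: sum of rel_time[v] * v."""
    return float(sum(frac * v for v, frac in dist.rel_time.items()))


def erp(rel_av_rst_value: float, max_score: int) -> float:
    """Ergonomic risk potential: rel. av. RST as percent of the maximum score."""
    if rel_av_rst_value > max_score:
        raise RiskStatsError(
            f"rel. av. RST {rel_av_rst_value} exceeds maximum score {max_score}"
        )
    if rel_av_rst_value < 0:
        raise RiskStatsError("rel. av. RST must be non-negative")
    return rel_av_rst_value / max_score * 100.0


def median_iqd(values) -> tuple[float, float]:
    """Median (standard even/odd rule) and IQD = Q3 - Q1, linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise RiskStatsError("empty sequence")
    q1, q3 = np.percentile(arr, [25, 75])
    return float(np.median(arr)), float(q3 - q1)


def summarize_frames(scores_df: pd.DataFrame) -> dict[str, RiskSummary]:
    """Per-outcome :class:`RiskSummary` for one subject's per-frame scores."""
    out: dict[str, RiskSummary] = {}
    for outcome, max_score in OUTCOMES.items():
        col = scores_df[OUTCOME_COLUMNS[outcome]].to_numpy()
        dist = time_distribution(col, max_score, outcome)
        rst = rel_av_rst(dist)
        med, iqd = median_iqd(col)
        out[outcome] = RiskSummary(
            outcome=outcome,
            max_score=max_score,
            median=med,
            iqd=iqd,
            rel_av_rst=rst,
            erp_pct=erp(rst, max_score),
        )
    return out


def summarize_subject(scores_df: pd.DataFrame, metadata: dict) -> pd.DataFrame:
    """Tidy one-subject summary: one row per outcome plus subject descriptors."""
    rows = []
    for outcome, s in summarize_frames(scores_df).items():
        rows.append(
            {
                **{k: metadata[k] for k in ("subject_id", "occupation", "pair_id", "dwc")},
                "outcome": outcome,
                "max_score": s.max_score,
                "median": s.median,
                "iqd": s.iqd,
                "rel_av_rst": s.rel_av_rst,
                "erp_pct": s.erp_pct,
            }
        )
    return pd.DataFrame(rows)


def cohort_summaries(scored: list[tuple[pd.DataFrame, dict]]) -> pd.DataFrame:
    """Concatenate per-subject summaries for a scored cohort."""
    if not scored:
        raise RiskStatsError("no scored recordings")
    return pd.concat(
        [summarize_subject(df, meta) for df, meta in scored], ignore_index=True
    )


def group_table(summaries: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Group-level report: one row per (outcome, occupation), columns per DWC.

    Cells aggregate subject-level values: median and IQD of the subject
    medians, mean of the subject rel. av. RSTs, and the ERP recomputed from
    that group rel. av. RST.  Values are rounded half-up at ``ndigits``.
    """
    rows = []
    for (outcome, occupation), grp in summaries.groupby(["outcome", "occupation"], sort=False):
        row: dict = {
            "outcome": outcome,
            "occupation": occupation,
            "max_score": int(grp["max_score"].iloc[0]),
        }
        for dwc, sub in grp.groupby("dwc"):
            med, iqd = median_iqd(sub["median"].to_numpy())
            rst = float(sub["rel_av_rst"].mean())
            row[f"dwc{dwc}_median"] = round_half_up(med, ndigits)
            row[f"dwc{dwc}_iqd"] = round_half_up(iqd, ndigits)
            row[f"dwc{dwc}_rel_av_rst"] = round_half_up(rst, ndigits)
            row[f"dwc{dwc}_erp_pct"] = round_half_up(erp(rst, row["max_score"]), ndigits)
        rows.append(row)
    return pd.DataFrame(rows)


def distribution_table(scored: list[tuple[pd.DataFrame, dict]]) -> pd.DataFrame:
    """Long-format time-in-score table (outcome, occupation, dwc, score, rel time).

    Relative times are averaged across the subjects of each cell.
    """
    rows = []
    for scores_df, meta in scored:
        for outcome, max_score in OUTCOMES.items():
            dist = time_distribution(
                scores_df[OUTCOME_COLUMNS[outcome]].to_numpy(), max_score, outcome
            )
            for v in range(1, max_score + 1):
                rows.append(
                    {
                        "occupation": meta["occupation"],
                        "dwc": meta["dwc"],
                        "outcome": outcome,
                        "score": v,
                        "rel_time": dist.rel_time.get(v, 0.0),
                    }
                )
    long = pd.DataFrame(rows)
    return (
        long.groupby(["occupation", "dwc", "outcome", "score"], as_index=False)["rel_time"]
        .mean()
    )
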