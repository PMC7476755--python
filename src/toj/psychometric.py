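"""Probit-line psychometrics: PSS, JND, accuracy, and 'visual first' bias.

Per participant and condition, response proportions at each SOA are probit-
transformed (after clamping to keep the transform finite) and an unweighted
ordinary-least-squares line is fitted over SOA. The point of subjective
simultaneity (PSS) is the zero crossing of that line, bounded to ±150 ms;
the just noticeable difference (JND) is the SOA at which the line predicts
75% correct order judgments, z(0.75)/slope.

Asymptote rule: if performance (proportion correct, pooled over both signs)
at the longest |SOA| has reached that at the second-longest |SOA|, the
longest-SOA points are dropped before fitting, because saturated proportions
carry no slope information after clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "ParticipantSummary",
    "probit_points",
    "fit_probit_line",
    "fit_condition",
    "summarize_participant",
    "fit_all_participants",
]

Z75 = float(norm.ppf(0.75))  # ≈ 0.6745
PSS_BOUND_MS = 150.0


class InsufficientDataError(ValueError):
    pass


def probit_points(trials: pd.DataFrame, coding: str = "visual_first") -> pd.DataFrame:
    """Per-SOA response proportions and their probit transforms.

    ``coding`` selects the response variable and its SOA axis:
    ``visual_first`` (bimodal rows, over ``soa_visual``) or ``right_first``
    (over ``soa_side``). Proportions are clamped to
    [1/(2n), 1 - 1/(2n)] with n the trial count at that SOA, so every probit
    is finite.
    """
    if coding == "visual_first":
        soa_col, resp_col = "soa_visual", "visual_first"
        df = trials[trials[resp_col].notna()]
    elif coding == "right_first":
        soa_col, resp_col = "soa_side", "right_first"
        df = trials
    else:
        raise ValueError(f"unknown coding {coding!r}")

    g = df.groupby(soa_col)[resp_col].agg(["count", "sum"]).reset_index()
    g.columns = ["soa", "n_trials", "k_first"]
    if len(g) < 2:
        raise InsufficientDataError(
            f"need >= 2 SOA levels with data, got {len(g)}"
        )
    g["proportion"] = g["k_first"] / g["n_trials"]
    lo = 1.0 / (2.0 * g["n_trials"])
    g["prop_clamped"] = g["proportion"].clip(lower=lo, upper=1.0 - lo)
    g["probit"] = norm.ppf(g["prop_clamped"])
    return g


@dataclass
class PsychometricFit:
    """OLS probit line for one participant x condition."""

    slope: float  # probit units per ms
    intercept: float  # probit units
    soas_used: tuple[float, ...]
    dropped_longest: bool
    pss_raw: float
    pss: float  # bounded to ±PSS_BOUND_MS
    pss_bounded: bool
    jnd: float
    n_trials_used: int
    coding: str
    identifiable: bool = True
    note: str = ""

    def as_row(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pss_raw": self.pss_raw,
            "pss": self.pss,
            "pss_bounded": self.pss_bounded,
            "jnd": self.jnd,
            "dropped_longest": self.dropped_longest,
            "n_trials_used": self.n_trials_used,
            "coding": self.coding,
            "identifiable": self.identifiable,
        }


def _asymptote_reached(accuracy_by_abs_soa: pd.Series, rule: str) -> bool:
    """Has accuracy at the longest |SOA| reached the second longest?"""
    acc = accuracy_by_abs_soa.dropna().sort_index()
    if len(acc) < 2:
        return False
    longest, second = acc.iloc[-1], acc.iloc[-2]
    if rule == "le":
        return bool(longest <= second)
    if rule == "eq":
        return bool(np.isclose(longest, second))
    raise ValueError(f"unknown asymptote rule {rule!r}")


def fit_probit_line(
    points: pd.DataFrame,
    accuracy_by_abs_soa: pd.Series | None = None,
    *,
    coding: str = "visual_first",
    pss_bound: float = PSS_BOUND_MS,
    asymptote_rule: str = "le",
) -> PsychometricFit:
    """Fit the probit line and derive PSS and JND.

    ``accuracy_by_abs_soa`` (index |SOA|, values proportion correct) drives
    the asymptote rule; pass None to skip it. With a non-positive slope the
    fit is flagged non-identifiable and PSS/JND are NaN.
    """
    pts = points.copy()
    dropped = False
    if accuracy_by_abs_soa is not None and _asymptote_reached(
        accuracy_by_abs_soa, asymptote_rule
    ):
        longest = pts["soa"].abs().max()
        keep = pts["soa"].abs() < longest
        if keep.sum() >= 2:
            pts = pts[keep]
            dropped = True

    if len(pts) < 2:
        raise InsufficientDataError("need >= 2 SOA levels to fit a line")

    slope, intercept = np.polyfit(pts["soa"].to_numpy(), pts["probit"].to_numpy(), 1)
    n_used = int(pts["n_trials"].sum())
    soas_used = tuple(float(s) for s in pts["soa"])

    if slope <= 0:
        return PsychometricFit(
            slope=float(slope),
            intercept=float(intercept),
            soas_used=soas_used,
            dropped_longest=dropped,
            pss_raw=np.nan,
            pss=np.nan,
            pss_bounded=False,
            jnd=np.nan,
            n_trials_used=n_used,
            coding=coding,
            identifiable=False,
            note="non-positive slope; PSS/JND not identifiable",
        )

    pss_raw = float(-intercept / slope)
    pss = float(np.clip(pss_raw, -pss_bound, pss_bound))
    return PsychometricFit(
        slope=float(slope),
        intercept=float(intercept),
        soas_used=soas_used,
        dropped_longest=dropped,
        pss_raw=pss_raw,
        pss=pss,
        pss_bounded=pss != pss_raw,
        jnd=float(Z75 / slope),
        n_trials_used=n_used,
        coding=coding,
    )


def _accuracy_by_abs_soa(trials: pd.DataFrame) -> pd.Series:
    df = trials.copy()
    df["abs_soa"] = df["soa_side"].abs()
    return df.groupby("abs_soa")["correct"].mean()


def fit_condition(
    trials: pd.DataFrame,
    condition: str,
    *,
    pss_bound: float = PSS_BOUND_MS,
    asymptote_rule: str = "le",
) -> PsychometricFit:
    """Probit-line fit for one condition of one participant's coded trials.

    Bimodal conditions are fitted on the 'visual first' coding over
    ``soa_visual``; unimodal conditions on the 'right first' coding over
    ``soa_side``.
    """
    sub = trials[trials["condition"] == condition]
    if len(sub) == 0:
        raise InsufficientDataError(f"no trials in condition {condition!r}")
    coding = "visual_first" if condition == "bimodal" else "right_first"
    pts = probit_points(sub, coding)
    return fit_probit_line(
        pts,
        _accuracy_by_abs_soa(sub),
        coding=coding,
        pss_bound=pss_bound,
        asymptote_rule=asymptote_rule,
    )


@dataclass
class ParticipantSummary:
    """Model-free per-participant measures."""

    participant_id: str
    proportion_correct: dict = field(default_factory=dict)  # per condition
    p_visual_first: float = np.nan  # across all bimodal SOAs
    bias: float = np.nan  # |p_visual_first - 0.5|

    def as_row(self) -> dict:
        row = {"participant_id": self.participant_id}
        for cond, acc in self.proportion_correct.items():
            row[f"accuracy_{cond}"] = acc
        row["p_visual_first"] = self.p_visual_first
        row["bias"] = self.bias
        return row


def summarize_participant(trials: pd.DataFrame) -> ParticipantSummary:
    """Accuracy per condition plus the SOA-independent 'visual first' bias."""
    pid = str(trials["participant_id"].iloc[0]) if len(trials) else ""
    summary = ParticipantSummary(participant_id=pid)
    for cond, sub in trials.groupby("condition"):
        summary.proportion_correct[cond] = float(sub["correct"].mean())
    bim = trials[trials["visual_first"].notna()]
    if len(bim):
        summary.p_visual_first = float(bim["visual_first"].mean())
        summary.bias = abs(summary.p_visual_first - 0.5)
    return summary


def fit_all_participants(
    trials: pd.DataFrame,
    *,
    pss_bound: float = PSS_BOUND_MS,
    asymptote_rule: str = "le",
) -> pd.DataFrame:
    """One row per participant x condition: probit fit plus summaries."""
    rows = []
    for (pid, expt), sub in trials.groupby(["participant_id", "experiment"]):
        summary = summarize_participant(sub)
        for cond in sorted(sub["condition"].unique()):
            try:
                fit = fit_condition(
                    sub, cond, pss_bound=pss_bound, asymptote_rule=asymptote_rule
                )
            except InsufficientDataError:
                continue
            row = {
                "participant_id": pid,
                "experiment": expt,
                "group": sub["group"].iloc[0],
                "condition": cond,
            }
            row.update(fit.as_row())
            row["accuracy"] = summary.proportion_correct.get(cond, np.nan)
            if cond == "bimodal":
                row["p_visual_first"] = summary.p_visual_first
                row["bias"] = summary.bias
            rows.append(row)
    return pd.DataFrame(rows)
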