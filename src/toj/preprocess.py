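"""Trial-table I/O, RT-based trial exclusion, and response recoding.

The canonical trial CSV is tidy: one row per trial, UTF-8, comma-separated,
header required, with exactly the columns in :data:`REQUIRED_COLUMNS`.

Exclusion rule (applied per participant, per experiment, to rows not entered
by the experimenter): drop trials with RT < 100 ms, then drop trials with RT
more than 2.5 sample standard deviations above that participant's mean RT,
where mean and SD are computed over the participant's remaining trials
pooled across conditions. Experimenter-entered responses are never filtered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "TrialValidationError",
    "FilterResult",
    "load_trials",
    "validate_trials",
    "recode",
    "filter_trials",
]

REQUIRED_COLUMNS = (
    "participant_id",
    "group",
    "experiment",
    "modality_left",
    "modality_right",
    "soa_side",
    "response_side",
    "rt",
    "experimenter_entered",
    "block",
)

MODALITIES = ("visual", "auditory", "tactile")
DEFAULT_SOA_SET = frozenset({30.0, 90.0, 135.0, 400.0})

_EXPERIMENT_MODALITIES = {
    "visual-auditory": {"visual", "auditory"},
    "visual-tactile": {"visual", "tactile"},
}


class TrialValidationError(ValueError):
    """Schema violation in a trial table; message lists offending rows."""


def validate_trials(trials: pd.DataFrame, soa_set=DEFAULT_SOA_SET) -> pd.DataFrame:
    """Validate a trial table against the canonical schema.

    Returns the table with normalised dtypes. Raises
    :class:`TrialValidationError` naming offending columns/rows (0-based
    data-row indices).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing required column(s): {missing}")
    if len(trials) == 0:
        raise TrialValidationError("trial table is empty")

    df = trials.copy()
    df["soa_side"] = pd.to_numeric(df["soa_side"], errors="coerce")
    df["rt"] = pd.to_numeric(df["rt"], errors="coerce")
    df["experimenter_entered"] = df["experimenter_entered"].astype(bool)
    df["block"] = pd.to_numeric(df["block"], errors="coerce").astype("Int64")

    problems = []

    bad = df.index[df["soa_side"].isna() | ~df["soa_side"].abs().isin(soa_set)]
    if len(bad):
        problems.append(
            f"soa_side not in ±{sorted(soa_set)} at rows {list(bad[:10])}"
            + ("..." if len(bad) > 10 else "")
        )
    for col in ("modality_left", "modality_right"):
        bad = df.index[~df[col].isin(MODALITIES)]
        if len(bad):
            problems.append(f"unknown {col} label at rows {list(bad[:10])}")
    bad = df.index[~df["response_side"].isin(("left", "right"))]
    if len(bad):
        problems.append(f"response_side must be left/right at rows {list(bad[:10])}")
    for expt, allowed in _EXPERIMENT_MODALITIES.items():
        sub = df[df["experiment"] == expt]
        bad = sub.index[
            ~sub["modality_left"].isin(allowed) | ~sub["modality_right"].isin(allowed)
        ]
        if len(bad):
            problems.append(f"modality labels inconsistent with {expt} at rows {list(bad[:10])}")
    bad = df.index[df["rt"].isna() & ~df["experimenter_entered"]]
    if len(bad):
        # Tolerated (the filter excludes them with a logged reason) but noted.
        logger.warning("missing rt on %d non-experimenter rows", len(bad))

    if problems:
        raise TrialValidationError("; ".join(problems))
    return df


def load_trials(path, soa_set=DEFAULT_SOA_SET) -> pd.DataFrame:
    """Read and validate a trial CSV in the canonical schema."""
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise TrialValidationError(f"{path} contains no trials")
    return validate_trials(df, soa_set=soa_set)


def recode(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the derived response codes the analysis works on.

    New columns:

    condition
        ``visual-visual`` / ``auditory-auditory`` / ``tactile-tactile`` for
        unimodal pairs, ``bimodal`` otherwise.
    right_first
        1 iff the response was 'right side first'.
    soa_visual, visual_first
        Bimodal rows only (NaN elsewhere): the SOA re-signed so positive
        means the visual stimulus led, and 1 iff the response side carried
        the visual stimulus.
    correct
        1 iff the chosen side matches the sign of ``soa_side``.
    """
    df = trials.copy()
    left = df["modality_left"]
    right = df["modality_right"]
    bimodal = (left != right).to_numpy()

    df["condition"] = np.where(bimodal, "bimodal", left + "-" + right)
    df["right_first"] = (df["response_side"] == "right").astype(int)
    df["correct"] = (
        (df["right_first"] == 1) == (df["soa_side"] > 0)
    ).astype(int)

    right_visual = (right == "visual").to_numpy()
    left_visual = (left == "visual").to_numpy()
    soa_visual = np.where(right_visual, df["soa_side"], -df["soa_side"])
    responded_visual = np.where(
        right_visual, df["right_first"] == 1, df["right_first"] == 0
    )
    df["soa_visual"] = np.where(bimodal, soa_visual, np.nan)
    df["visual_first"] = np.where(bimodal, responded_visual.astype(float), np.nan)

    # A bimodal row must have exactly one visual side in these experiments.
    bad = bimodal & ~(left_visual ^ right_visual)
    if bad.any():
        raise TrialValidationError(
            f"bimodal rows without a unique visual side at rows {list(df.index[bad][:10])}"
        )
    return df


@dataclass
class FilterResult:
    """Partition of a coded trial table into retained and excluded rows."""

    retained: pd.DataFrame
    excluded: pd.DataFrame  # carries a 'reason' column
    exclusion_fraction: float
    n_input: int
    n_excluded_fast: int
    n_excluded_outlier: int
    n_excluded_missing_rt: int

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_fast": self.n_excluded_fast,
            "n_excluded_outlier": self.n_excluded_outlier,
            "n_excluded_missing_rt": self.n_excluded_missing_rt,
            "exclusion_fraction": self.exclusion_fraction,
        }

    def write(self, outdir, stem: str = "trials") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.retained.to_csv(outdir / f"{stem}_retained.csv", index=False)
        self.excluded.to_csv(outdir / f"{stem}_excluded.csv", index=False)
        (outdir / f"{stem}_filter_summary.json").write_text(
            json.dumps(self.summary(), indent=2)
        )


def filter_trials(
    trials: pd.DataFrame,
    fast_ms: float = 100.0,
    outlier_sd: float = 2.5,
) -> FilterResult:
    """Apply the RT-based trial exclusions.

    Thresholds are computed once on the raw data, per participant and per
    experiment; filtering an already-filtered table therefore never removes
    further rows in a pipeline that keeps the retained table. Rows entered by
    the experimenter are always retained and never contribute to thresholds.
    The exclusion fraction is reported over non-experimenter rows.
    """
    df = trials if "right_first" in trials.columns else recode(trials)
    df = df.reset_index(drop=True)

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    own = ~df["experimenter_entered"].to_numpy(dtype=bool)

    missing = own & df["rt"].isna().to_numpy()
    reason[missing] = "rt_missing"
    fast = own & ~missing & (df["rt"].to_numpy() < fast_ms)
    reason[fast.astype(bool)] = "rt_too_fast"

    usable = own & ~missing & ~fast
    for (_pid, _expt), idx in df[usable].groupby(
        ["participant_id", "experiment"], sort=False
    ).groups.items():
        rts = df.loc[idx, "rt"].to_numpy(dtype=float)
        if len(rts) < 2:
            logger.warning(
                "participant %s (%s): <2 usable RTs, outlier rule skipped", _pid, _expt
            )
            continue
        cutoff = rts.mean() + outlier_sd * rts.std(ddof=1)
        out = idx[rts > cutoff]
        reason[out] = "rt_outlier"

    excluded_mask = reason.notna().to_numpy()
    retained = df[~excluded_mask].reset_index(drop=True)
    excluded = df[excluded_mask].copy()
    excluded["reason"] = reason[excluded_mask]
    excluded = excluded.reset_index(drop=True)

    n_own = int(own.sum())
    counts = excluded["reason"].value_counts()
    return FilterResult(
        retained=retained,
        excluded=excluded,
        exclusion_fraction=float(excluded_mask.sum() / n_own) if n_own else 0.0,
        n_input=len(df),
        n_excluded_fast=int(counts.get("rt_too_fast", 0)),
        n_excluded_outlier=int(counts.get("rt_outlier", 0)),
        n_excluded_missing_rt=int(counts.get("rt_missing", 0)),
    )
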