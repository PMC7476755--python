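"""End-to-end analysis: filter -> recode -> fits -> group tests -> RT -> correlation.

The test plan is data-driven from group labels. Clinical groups are compared
only with their age-matched controls (CC vs MCC, DC vs MDC); groups are
never pooled or compared across experiments. Planned, directional
comparisons (PSS against zero, clinical group vs control) default to
one-tailed permutation p-values; everything else is two-tailed. Every
stochastic stage records its seed and permutation count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, preprocess, psychometric, rt_peak
from .observer import StudySpec, default_study, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "analyze_trials"]

PLANNED_PAIRS = (("CC", "MCC"), ("DC", "MDC"))


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    mode: str = "simulate"  # 'simulate' or 'load'
    data_paths: tuple[str, ...] = ()
    study: StudySpec | None = None
    fast_ms: float = 100.0
    outlier_sd: float = 2.5
    pss_bound_ms: float = 150.0
    asymptote_rule: str = "le"
    n_perm: int = 10_000
    seed: int = 0
    tails_planned: str = "one"
    tails_other: str = "two"
    glmm_link: str = "logit"
    glmm_n_quad: int = 15
    corr_exclude_sd: float = 2.5

    def __post_init__(self) -> None:
        for name in ("fast_ms", "outlier_sd", "pss_bound_ms", "corr_exclude_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = raw.pop("study", None)
        cfg = cls(**raw)
        if study is not None:
            from .observer import DesignSpec, GroupSpec

            groups = tuple(GroupSpec(**g) for g in study.pop("groups"))
            design = DesignSpec(**study.pop("design")) if "design" in study else None
            kwargs = dict(study)
            if design is not None:
                kwargs["design"] = design
            cfg.study = StudySpec(groups=groups, **kwargs)
        return cfg

    def digest(self) -> str:
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k != "study"
        }
        if self.study is not None:
            payload["study"] = dataclasses.asdict(self.study)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables of one analysis run plus provenance."""

    participant_fits: pd.DataFrame
    group_summary: pd.DataFrame
    tests: pd.DataFrame
    rt_peaks: pd.DataFrame
    correlation_points: pd.DataFrame
    filter_summary: dict
    provenance: dict
    truth: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participant_fits.to_csv(outdir / "participant_fits.csv", index=False)
        self.group_summary.to_csv(outdir / "group_summary.csv", index=False)
        self.tests.to_csv(outdir / "tests.csv", index=False)
        self.rt_peaks.to_csv(outdir / "rt_peaks.csv", index=False)
        self.correlation_points.to_csv(outdir / "correlation_points.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(outdir / "true_parameters.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(
                {"filter_summary": self.filter_summary, **self.provenance},
                indent=2,
                default=str,
            )
        )


def _seed_stream(seed: int):
    """Deterministic per-test seeds below 2^31."""
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, 2**31 - 1))


def _group_summary(fits: pd.DataFrame) -> pd.DataFrame:
    bim = fits[fits["condition"] == "bimodal"]
    rows = []
    for (expt, grp), sub in fits.groupby(["experiment", "group"]):
        row = {"experiment": expt, "group": grp, "n": sub["participant_id"].nunique()}
        b = bim[(bim["experiment"] == expt) & (bim["group"] == grp)]
        row["pss_mean"] = b["pss"].mean()
        row["pss_sd"] = b["pss"].std(ddof=1)
        row["jnd_mean"] = b["jnd"].mean()
        row["p_visual_first_mean"] = b["p_visual_first"].mean()
        for cond, csub in sub.groupby("condition"):
            row[f"accuracy_{cond}"] = csub["accuracy"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_trials(
    trials: pd.DataFrame, config: AnalysisConfig, truth: pd.DataFrame | None = None
) -> ReportBundle:
    """Run the full analysis on a validated trial table."""
    seeds = _seed_stream(config.seed)
    trials = preprocess.validate_trials(trials)
    coded = preprocess.recode(trials)
    filt = preprocess.filter_trials(
        coded, fast_ms=config.fast_ms, outlier_sd=config.outlier_sd
    )
    retained = filt.retained

    fits = psychometric.fit_all_participants(
        retained,
        pss_bound=config.pss_bound_ms,
        asymptote_rule=config.asymptote_rule,
    )
    group_summary = _group_summary(fits)

    tests: list[dict] = []
    corr_tables: list[pd.DataFrame] = []

    def record(res: inference.TestResult, test_id: str, **extra):
        row = {"id": test_id, **extra, **res.as_row()}
        tests.append(row)
        return res

    for expt, efits in fits.groupby("experiment"):
        bim = efits[(efits["condition"] == "bimodal") & efits["identifiable"]]
        groups_here = sorted(bim["group"].unique())
        pss_by_group = {
            g: bim.loc[bim["group"] == g, "pss"].dropna().to_numpy()
            for g in groups_here
        }

        # PSS of each group against zero
        for g, vals in pss_by_group.items():
            if len(vals) >= 3:
                record(
                    inference.perm_t_one_sample(
                        vals, 0.0, tails=config.tails_planned,
                        n_perm=config.n_perm, seed=next(seeds),
                    ),
                    f"{expt}:pss_vs_zero:{g}", experiment=expt, groups=g,
                )

        # omnibus group effect on PSS
        usable = [v for v in pss_by_group.values() if len(v) >= 2]
        if len(usable) >= 2:
            record(
                inference.perm_anova_oneway(
                    usable, n_perm=config.n_perm, seed=next(seeds)
                ),
                f"{expt}:pss_anova", experiment=expt, groups=",".join(groups_here),
            )

        etrials = retained[retained["experiment"] == expt]
        for a, b in PLANNED_PAIRS:
            if a not in pss_by_group or b not in pss_by_group:
                continue
            # planned PSS comparison
            record(
                inference.perm_t_two_sample(
                    pss_by_group[a], pss_by_group[b], tails=config.tails_planned,
                    n_perm=config.n_perm, seed=next(seeds),
                ),
                f"{expt}:pss:{a}_vs_{b}", experiment=expt, groups=f"{a},{b}",
            )

            pair_bim = etrials[
                etrials["group"].isin((a, b)) & (etrials["condition"] == "bimodal")
            ]
            n_pair = pair_bim["participant_id"].nunique()
            try:
                full = inference.fit_binomial_glmm(
                    pair_bim, "visual_first", ["group"],
                    link=config.glmm_link, n_quad=config.glmm_n_quad,
                )
                null = inference.fit_binomial_glmm(
                    pair_bim, "visual_first", [],
                    link=config.glmm_link, n_quad=config.glmm_n_quad,
                )
                record(
                    inference.lrt(full, null, r_equiv_df=n_pair - 2),
                    f"{expt}:visual_first_glmm:{a}_vs_{b}",
                    experiment=expt, groups=f"{a},{b}",
                )
            except inference.GLMMError as err:
                logger.warning("GLMM %s vs %s failed: %s", a, b, err)

            # accuracy model: group x modality condition
            pair_all = etrials[etrials["group"].isin((a, b))]
            try:
                full_acc = inference.fit_binomial_glmm(
                    pair_all, "correct", ["group", "condition"],
                    link=config.glmm_link, n_quad=config.glmm_n_quad,
                )
                null_acc = inference.fit_binomial_glmm(
                    pair_all, "correct", ["condition"],
                    link=config.glmm_link, n_quad=config.glmm_n_quad,
                )
                record(
                    inference.lrt(full_acc, null_acc, r_equiv_df=n_pair - 2),
                    f"{expt}:accuracy_glmm:{a}_vs_{b}",
                    experiment=expt, groups=f"{a},{b}",
                )
            except inference.GLMMError as err:
                logger.warning("accuracy GLMM %s vs %s failed: %s", a, b, err)

        # per-group 'visual first' probability against chance
        chance = 0.0 if config.glmm_link == "logit" else float(np.log(0.5))
        for g in groups_here:
            gb = etrials[
                (etrials["group"] == g) & (etrials["condition"] == "bimodal")
            ]
            n_g = gb["participant_id"].nunique()
            if n_g < 2:
                continue
            try:
                fit_g = inference.fit_binomial_glmm(
                    gb, "visual_first", [],
                    link=config.glmm_link, n_quad=config.glmm_n_quad,
                )
                record(
                    inference.wald_contrast(
                        fit_g, {"Intercept": 1.0}, value=chance,
                        r_equiv_df=n_g - 1,
                    ),
                    f"{expt}:visual_first_vs_chance:{g}", experiment=expt, groups=g,
                )
            except inference.GLMMError as err:
                logger.warning("chance-contrast GLMM for %s failed: %s", g, err)

        # bias-accuracy correlation across all groups of this experiment
        corr_in = bim[["participant_id", "group", "bias", "accuracy"]].dropna()
        if len(corr_in) >= 4:
            try:
                res, corr_points = inference.bias_accuracy_correlation(
                    corr_in,
                    exclude_sd=config.corr_exclude_sd,
                    tails=config.tails_other,
                    n_perm=config.n_perm,
                    seed=next(seeds),
                )
                record(res, f"{expt}:bias_accuracy_corr", experiment=expt,
                       groups=",".join(groups_here))
                corr_tables.append(corr_points.assign(experiment=expt))
            except ValueError as err:
                logger.warning("correlation skipped: %s", err)

    # RT peaks per participant, compared within planned pairs
    normalized = rt_peak.normalize_rt(retained)
    peaks = rt_peak.fit_rt_peaks(normalized) if len(normalized) else pd.DataFrame()
    if len(peaks):
        for expt, ep in peaks.groupby("experiment"):
            ok = ep[ep["reliable"]]
            for a, b in PLANNED_PAIRS:
                pa = ok.loc[ok["group"] == a, "peak_soa"].to_numpy()
                pb = ok.loc[ok["group"] == b, "peak_soa"].to_numpy()
                if len(pa) >= 2 and len(pb) >= 2:
                    record(
                        rt_peak.compare_rt_peaks(
                            pa, pb, tails=config.tails_other,
                            n_perm=config.n_perm, seed=next(seeds),
                        ),
                        f"{expt}:rt_peak:{a}_vs_{b}", experiment=expt,
                        groups=f"{a},{b}",
                    )

    from . import __version__

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_perm": config.n_perm,
        "software_version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "study"
        },
    }
    return ReportBundle(
        participant_fits=fits,
        group_summary=group_summary,
        tests=pd.DataFrame(tests),
        rt_peaks=peaks,
        correlation_points=(
            pd.concat(corr_tables, ignore_index=True) if corr_tables else pd.DataFrame()
        ),
        filter_summary=filt.summary(),
        provenance=provenance,
        truth=truth,
    )


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Simulate or load trial data per the config, then analyze it."""
    if config.mode == "simulate":
        spec = config.study or default_study()
        trials, truth = simulate_study(spec, config.seed)
        return analyze_trials(trials, config, truth=truth)
    if not config.data_paths:
        raise ValueError("load mode requires data_paths")
    tables = [preprocess.load_trials(p) for p in config.data_paths]
    trials = pd.concat(tables, ignore_index=True)
    return analyze_trials(trials, config)
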