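"""Synthetic observers for spatial temporal-order-judgment (TOJ) experiments.

The generator reproduces the statistical structure the downstream analysis
assumes: a two-alternative "which side came first?" task with unimodal and
bimodal (cross-modal) stimulus pairs, signed stimulus onset asynchronies
(SOAs), cumulative-Gaussian observers with a lapse rate, between-participant
variability in bias (PSS) and precision (sigma), reaction times that peak
near each observer's point of subjective simultaneity, occasional
experimenter-entered responses (no usable RT), and incomplete sessions.

Sign conventions
----------------
``soa_side``   : negative = left-side stimulus first.
``soa_visual`` : positive = visual stimulus first (bimodal trials only).
``pss``        : positive = the visual stimulus must lead to be perceived
                 as simultaneous with the non-visual stimulus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "ObserverParams",
    "GroupSpec",
    "StudySpec",
    "default_design",
    "default_study",
    "p_first",
    "simulate_participant",
    "simulate_study",
]

DEFAULT_SOAS = (-400.0, -135.0, -90.0, -30.0, 30.0, 90.0, 135.0, 400.0)

_EXPERIMENT_MODALITIES = {
    "visual-auditory": ("visual", "auditory"),
    "visual-tactile": ("visual", "tactile"),
}


class ParameterError(ValueError):
    """Raised when observer or design parameters are invalid."""


@dataclass(frozen=True)
class DesignSpec:
    """One session's factorial design.

    ``modality_pairs`` lists (left, right) modality labels; the default
    factory functions include every pair in both side assignments, giving
    2 modalities x 2 sides x len(soas) SOA cells.
    """

    soas: tuple[float, ...] = DEFAULT_SOAS
    reps_per_cell: int = 10
    modality_pairs: tuple[tuple[str, str], ...] = (
        ("visual", "visual"),
        ("auditory", "auditory"),
        ("visual", "auditory"),
        ("auditory", "visual"),
    )
    n_blocks: int = 10

    def __post_init__(self) -> None:
        soas = np.asarray(self.soas, dtype=float)
        if soas.size == 0 or not np.allclose(np.sort(soas), np.sort(-soas)):
            raise ParameterError("soas must be symmetric about 0")
        if np.any(soas == 0):
            raise ParameterError("soa = 0 is not a valid order-judgment trial")
        if self.reps_per_cell < 1:
            raise ParameterError("reps_per_cell must be >= 1")
        if self.n_blocks < 1:
            raise ParameterError("n_blocks must be >= 1")
        pairs = set(self.modality_pairs)
        for left, right in self.modality_pairs:
            if (right, left) not in pairs:
                raise ParameterError(
                    f"modality pair {(left, right)} lacks its mirrored side assignment"
                )

    @property
    def n_cells(self) -> int:
        return len(self.modality_pairs) * len(self.soas)

    @property
    def n_trials(self) -> int:
        return self.n_cells * self.reps_per_cell


def default_design(experiment: str = "visual-auditory") -> DesignSpec:
    """The canonical 32-cell design: 2 modalities x 2 sides x 8 SOAs, 10 reps."""
    try:
        visual, other = _EXPERIMENT_MODALITIES[experiment]
    except KeyError:
        raise ParameterError(f"unknown experiment {experiment!r}") from None
    return DesignSpec(
        modality_pairs=(
            (visual, visual),
            (other, other),
            (visual, other),
            (other, visual),
        )
    )


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    The psychometric model for bimodal trials is a cumulative Gaussian with
    symmetric lapses,

        P(visual first) = lapse/2 + (1 - lapse) * Phi((soa_v - pss) / sigma),

    where ``soa_v`` is the SOA signed positive for visual-first stimulation.
    Unimodal trials use the same form over ``soa_side`` with pss fixed at 0
    and their own sigma. Mean RT on bimodal trials is a Gaussian bump centred
    on the observer's PSS (longest RTs where the order is most uncertain):

        E[rt] = rt_baseline + rt_amplitude * exp(-(soa_v - pss)^2 / (2 rt_width^2)).
    """

    pss: float = 0.0
    sigma: float = 90.0
    lapse: float = 0.02
    rt_baseline: float = 500.0
    rt_amplitude: float = 150.0
    rt_width: float = 120.0
    rt_noise_sd: float = 150.0
    unimodal_sigma: float = 60.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError("sigma must be > 0")
        if not 0 <= self.lapse <= 1:
            raise ParameterError("lapse must be in [0, 1]")
        if not self.rt_width > 0:
            raise ParameterError("rt_width must be > 0")
        if self.rt_noise_sd < 0:
            raise ParameterError("rt_noise_sd must be >= 0")
        if not self.unimodal_sigma > 0:
            raise ParameterError("unimodal_sigma must be > 0")
        if self.rt_baseline + self.rt_amplitude < 100:
            raise ParameterError(
                "rt_baseline + rt_amplitude must be >= 100 ms, otherwise "
                "nearly all trials fall below the fast-RT exclusion"
            )


def p_first(soa, params: ObserverParams):
    """Probability of a 'visual first' response at a signed SOA.

    ``soa`` is signed positive for visual-first stimulation. Scalar or
    array-like; returns the same shape.
    """
    if not isinstance(params, ObserverParams):
        raise TypeError("params must be ObserverParams")
    soa = np.asarray(soa, dtype=float)
    p = params.lapse / 2 + (1 - params.lapse) * norm.cdf(
        (soa - params.pss) / params.sigma
    )
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class GroupSpec:
    """Distribution of observer parameters within one participant group.

    Each ``*_mean``/``*_sd`` pair describes a normal distribution across
    participants; draws are clipped to the valid parameter range.
    """

    label: str
    n_participants: int
    pss_mean: float = 0.0
    pss_sd: float = 40.0
    sigma_mean: float = 90.0
    sigma_sd: float = 20.0
    lapse_mean: float = 0.02
    lapse_sd: float = 0.02
    rt_baseline_mean: float = 500.0
    rt_baseline_sd: float = 80.0
    rt_amplitude_mean: float = 150.0
    rt_amplitude_sd: float = 40.0
    rt_width_mean: float = 120.0
    rt_width_sd: float = 20.0
    rt_noise_sd: float = 150.0
    unimodal_sigma_mean: float = 60.0
    unimodal_sigma_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ParameterError(
                f"group {self.label!r} needs >= 2 participants, got {self.n_participants}"
            )
        for f in dataclasses.fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ParameterError(f"{f.name} must be >= 0")

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        def trunc(mean, sd, lo, hi=np.inf):
            return float(np.clip(rng.normal(mean, sd), lo, hi))

        return ObserverParams(
            pss=float(rng.normal(self.pss_mean, self.pss_sd)),
            sigma=trunc(self.sigma_mean, self.sigma_sd, 10.0),
            lapse=trunc(self.lapse_mean, self.lapse_sd, 0.0, 0.3),
            rt_baseline=trunc(self.rt_baseline_mean, self.rt_baseline_sd, 150.0),
            rt_amplitude=trunc(self.rt_amplitude_mean, self.rt_amplitude_sd, 0.0),
            rt_width=trunc(self.rt_width_mean, self.rt_width_sd, 20.0),
            rt_noise_sd=self.rt_noise_sd,
            unimodal_sigma=trunc(self.unimodal_sigma_mean, self.unimodal_sigma_sd, 10.0),
        )


@dataclass(frozen=True)
class StudySpec:
    """A whole multi-group study: groups, design, and data-quality nuisances."""

    groups: tuple[GroupSpec, ...]
    design: DesignSpec = field(default_factory=default_design)
    experiment: str = "visual-auditory"
    fraction_experimenter_entered: float = 0.0
    completion_rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ParameterError("study needs at least one group")
        if not 0 <= self.fraction_experimenter_entered <= 1:
            raise ParameterError("fraction_experimenter_entered must be in [0, 1]")
        if not 0 < self.completion_rate <= 1:
            raise ParameterError("completion_rate must be in (0, 1]")


def default_study(experiment: str = "visual-auditory") -> StudySpec:
    """A four-group study mirroring the sensory-deprivation design.

    Two clinical groups (CC: congenital-cataract reversal, biased toward
    perceiving vision as early; DC: developmental-cataract reversal, typical
    direction of bias) and their matched sighted controls (MCC, MDC), with the
    typical-control bias direction opposite to CC. Sample sizes follow a
    10/10/9/9 layout typical of sight-recovery designs.
    """
    return StudySpec(
        groups=(
            GroupSpec("CC", 10, pss_mean=-40.0, sigma_mean=140.0, lapse_mean=0.05),
            GroupSpec("MCC", 10, pss_mean=40.0, sigma_mean=80.0),
            GroupSpec("DC", 9, pss_mean=60.0, sigma_mean=140.0, lapse_mean=0.05),
            GroupSpec("MDC", 9, pss_mean=30.0, sigma_mean=80.0),
        ),
        design=default_design(experiment),
        experiment=experiment,
        fraction_experimenter_entered=0.02,
        completion_rate=0.97,
    )


def _is_visual(modality: str) -> bool:
    return modality == "visual"


def simulate_participant(
    params: ObserverParams,
    design: DesignSpec,
    seed,
    *,
    participant_id: str = "P01",
    group: str = "other",
    experiment: str = "visual-auditory",
    fraction_experimenter_entered: float = 0.0,
) -> pd.DataFrame:
    """Simulate one participant's full session as a tidy trial table.

    Returns one row per design cell x repetition with the columns of the
    canonical trial CSV schema. Trials are assigned round-robin to blocks
    (repetition r of every cell lands in block ``r % n_blocks``).
    Experimenter-entered trials keep the model's response but have no RT.
    """
    rng = np.random.default_rng(seed)

    rows = []
    for left, right in design.modality_pairs:
        for soa in design.soas:
            for rep in range(design.reps_per_cell):
                rows.append((left, right, float(soa), rep % design.n_blocks))
    df = pd.DataFrame(rows, columns=["modality_left", "modality_right", "soa_side", "block"])

    left_visual = df["modality_left"].map(_is_visual).to_numpy()
    right_visual = df["modality_right"].map(_is_visual).to_numpy()
    bimodal = df["modality_left"].to_numpy() != df["modality_right"].to_numpy()
    soa_side = df["soa_side"].to_numpy()

    # Bimodal rows: respond through the visual-first psychometric function.
    # soa_visual is the side SOA re-signed so positive means visual led.
    soa_visual = np.where(right_visual, soa_side, -soa_side)
    p_vf = p_first(soa_visual, params)
    # Unimodal rows: 'right side first' model with pss = 0 and its own sigma.
    p_right_uni = params.lapse / 2 + (1 - params.lapse) * norm.cdf(
        soa_side / params.unimodal_sigma
    )

    u = rng.random(len(df))
    visual_first = u < p_vf
    right_resp_bimodal = np.where(right_visual, visual_first, ~visual_first)
    right_resp = np.where(bimodal, right_resp_bimodal, u < p_right_uni)
    df["response_side"] = np.where(right_resp, "right", "left")

    rt_mean = np.where(
        bimodal,
        params.rt_baseline
        + params.rt_amplitude
        * np.exp(-((soa_visual - params.pss) ** 2) / (2 * params.rt_width**2)),
        params.rt_baseline,
    )
    rt = rt_mean + rng.normal(0.0, params.rt_noise_sd, len(df))
    df["rt"] = np.maximum(rt, 1.0)

    df["experimenter_entered"] = rng.random(len(df)) < fraction_experimenter_entered
    df.loc[df["experimenter_entered"], "rt"] = np.nan

    df.insert(0, "participant_id", participant_id)
    df.insert(1, "group", group)
    df.insert(2, "experiment", experiment)
    order = [
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
    ]
    return df[order].reset_index(drop=True)


def simulate_study(spec: StudySpec, seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole study.

    Returns ``(trials, truth)``: the concatenated trial tables of every
    participant, and a sidecar table of each participant's true generative
    parameters (for parameter-recovery checks). Incomplete sessions are
    modelled by truncating each participant's session to
    ``ceil(completion_rate * n_blocks)`` blocks at the earliest; each
    participant's completed-block count is drawn uniformly between that
    floor and the full session.
    """
    master = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    n_total = sum(g.n_participants for g in spec.groups)
    child_seeds = master.spawn(n_total)

    tables = []
    truth_rows = []
    i = 0
    for g in spec.groups:
        for k in range(g.n_participants):
            pid = f"{g.label}{k + 1:02d}"
            params = g.draw(param_rng)
            table = simulate_participant(
                params,
                spec.design,
                child_seeds[i],
                participant_id=pid,
                group=g.label,
                experiment=spec.experiment,
                fraction_experimenter_entered=spec.fraction_experimenter_entered,
            )
            if spec.completion_rate < 1.0:
                floor = int(np.ceil(spec.completion_rate * spec.design.n_blocks))
                n_done = int(param_rng.integers(floor, spec.design.n_blocks + 1))
                table = table[table["block"] < n_done].reset_index(drop=True)
            tables.append(table)
            truth_rows.append(
                {"participant_id": pid, "group": g.label, "experiment": spec.experiment}
                | dataclasses.asdict(params)
            )
            i += 1

    trials = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
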