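"""Synthetic behavioral data: experimental designs and generative agents.

The hidden-target task hides a target angle on a ring and reveals, on every
trial, a visual hint drawn from a von Mises distribution centred on the
target.  An agent reports its current estimate with a pro-saccade (look at
the estimate) or an anti-saccade (look diametrically opposite).  Blocks of 20
trials switch response modality after trial 10; task difficulty is set by
the hint concentration kappa.

Agents form their estimate as a lag-weighted linear combination of their own
previous guesses and the hints seen so far, operating on signed angular
errors relative to the target (the small-angle linear regime: at the
concentrations used here responses stay localized, so plain rather than
circular statistics apply).  Motor noise is zero-mean Gaussian on the
reported angle with a modality-specific SD.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from priorlearn.angles import signed_angle_diff, wrap_angle

__all__ = [
    "DesignSpec",
    "AgentParams",
    "BlockDesign",
    "generate_design",
    "sample_hints",
    "simulate_agent_block",
    "simulate_calibration",
    "simulate_confidence",
    "simulate_cohort",
    "simulate_from_model",
    "kappa_to_sd_deg",
    "TRIAL_COLUMNS",
    "CALIBRATION_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "block_id",
    "trial_index",
    "difficulty",
    "response_type",
    "order",
    "target_angle",
    "hint_angle",
    "endpoint_angle",
    "estimate_angle",
    "confidence",
    "failed",
    "failure_reason",
]

CALIBRATION_COLUMNS = [
    "participant_id",
    "block_id",
    "trial_index",
    "response_type",
    "target_angle",
    "endpoint_angle",
    "estimate_angle",
]


def kappa_to_sd_deg(kappa: float) -> float:
    """Dispersion of a von Mises with concentration kappa, in degrees.

    Uses the high-concentration approximation sigma^2 = 1/kappa (radians^2),
    which is the standard reading at the concentrations used here
    (kappa >= 5) rather than the exact circular SD.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    return math.degrees(math.sqrt(1.0 / kappa))


@dataclass
class DesignSpec:
    """Design of one participant's session.

    Defaults reproduce the study conditions: 40 blocks of 20 trials, the
    response modality switching after trial 10, targets drawn without
    replacement from 20 evenly spaced ring locations (each used twice),
    difficulty and modality order counterbalanced (10 blocks per cell), and
    4 calibration blocks of 10 pro- followed by 10 anti-saccade trials.
    """

    n_participants: int = 20
    n_blocks: int = 40
    trials_per_block: int = 20
    switch_trial: int = 10
    location_set: tuple = tuple(np.arange(20) * 18.0)
    kappa_easy: float = 30.0
    kappa_hard: float = 5.0
    kappa_training: float = 80.0
    ring_radius: float = 7.5  # dva; metadata only
    n_calibration_blocks: int = 4
    calibration_locations: tuple = tuple(np.arange(10) * 36.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks % 4 != 0:
            raise ValueError(
                f"n_blocks={self.n_blocks} must be divisible by 4 to "
                "counterbalance difficulty x order"
            )
        if self.n_blocks % len(self.location_set) != 0:
            raise ValueError(
                f"n_blocks={self.n_blocks} not divisible by "
                f"{len(self.location_set)} target locations"
            )
        for k in (self.kappa_easy, self.kappa_hard, self.kappa_training):
            if k <= 0:
                raise ValueError("von Mises concentrations must be positive")

    @property
    def sigma_easy_deg(self) -> float:
        return kappa_to_sd_deg(self.kappa_easy)

    @property
    def sigma_hard_deg(self) -> float:
        return kappa_to_sd_deg(self.kappa_hard)

    @property
    def sigma_training_deg(self) -> float:
        return kappa_to_sd_deg(self.kappa_training)

    def kappa_for(self, difficulty: str) -> float:
        return {"easy": self.kappa_easy, "hard": self.kappa_hard}[difficulty]


@dataclass
class AgentParams:
    """Generative parameters of a simulated participant.

    The agent's internal estimate on trial t (as signed error to the target)
    is

        e_t = intercept + sum_i w_guess[i-1] * g_{t-i}
                        + sum_j w_hint[j] * h_{t-j},   i in 1..3, j in 0..3,

    with g the agent's own previous reported guesses and h the hint errors.
    The reported guess adds Gaussian motor noise with the SD of the modality
    in use.  Lags that reach before the first trial of the block (or, for a
    reset_on_switch agent, before the response switch) are dropped and the
    remaining weights rescaled to the full weight total, so trial 1 — and
    trial 11 for a resetting agent — follows the current hint.

    ``reset_on_switch`` embodies the no-transfer hypothesis: knowledge tied
    to one visuo-motor mapping is discarded when the mapping changes.
    """

    w_guess: tuple = (0.3, 0.2, 0.1)
    w_hint: tuple = (0.4, 0.0, 0.0, 0.0)
    intercept: float = 0.0
    motor_sd_pro: float = 6.3
    motor_sd_anti: float = 9.5
    reset_on_switch: bool = True
    confidence_scale: float = 0.2
    confidence_offset: float = 6.5
    seed: int = 0

    def __post_init__(self):
        if len(self.w_guess) != 3 or len(self.w_hint) != 4:
            raise ValueError("w_guess must have 3 lags, w_hint 4 (current + 3)")
        if not (np.all(np.isfinite(self.w_guess)) and np.all(np.isfinite(self.w_hint))):
            raise ValueError("weights must be finite")
        if self.motor_sd_pro < 0 or self.motor_sd_anti < 0:
            raise ValueError("motor SDs must be non-negative")

    def motor_sd(self, response_type: str) -> float:
        return {"pro": self.motor_sd_pro, "anti": self.motor_sd_anti}[response_type]


@dataclass
class BlockDesign:
    """One block: condition cell, target, and the per-trial response types."""

    block_id: int
    difficulty: str  # easy | hard
    order: str  # pro_first | anti_first
    target_angle: float
    kappa: float
    response_types: tuple  # length trials_per_block
    switch_trial: int


def generate_design(spec: DesignSpec) -> list[BlockDesign]:
    """Build the counterbalanced block sequence for one session.

    Each of the four difficulty x order cells receives n_blocks/4 blocks and
    each target location serves exactly n_blocks/len(location_set) blocks;
    cell and location assignments are independently shuffled by the spec's
    seed, so the composition is deterministic given the seed but the
    ordering is random.
    """
    rng = np.random.default_rng(spec.seed)
    cells = [
        (diff, order)
        for diff in ("easy", "hard")
        for order in ("pro_first", "anti_first")
    ]
    per_cell = spec.n_blocks // 4
    cell_seq = [c for c in cells for _ in range(per_cell)]
    rng.shuffle(cell_seq)

    per_loc = spec.n_blocks // len(spec.location_set)
    loc_seq = [loc for loc in spec.location_set for _ in range(per_loc)]
    rng.shuffle(loc_seq)

    blocks = []
    for b, ((difficulty, order), target) in enumerate(zip(cell_seq, loc_seq)):
        first, second = ("pro", "anti") if order == "pro_first" else ("anti", "pro")
        rts = tuple(
            first if t <= spec.switch_trial else second
            for t in range(1, spec.trials_per_block + 1)
        )
        blocks.append(
            BlockDesign(
                block_id=b + 1,
                difficulty=difficulty,
                order=order,
                target_angle=float(target),
                kappa=spec.kappa_for(difficulty),
                response_types=rts,
                switch_trial=spec.switch_trial,
            )
        )
    return blocks


def sample_hints(target_angle: float, kappa: float, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. von Mises hint angles (degrees in [0, 360)) centred on
    the target.  ``seed`` may be an int or a ``numpy.random.Generator``."""
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = rng.vonmises(math.radians(target_angle), kappa, size=n)
    return wrap_angle(np.degrees(draws))


def simulate_confidence(internal_sd: float, params: AgentParams) -> int:
    """Map the agent's internal uncertainty (deg) to a 1..6 confidence rating.

    round(offset - scale * internal_sd), clipped to [1, 6]; monotone
    non-increasing in internal_sd.
    """
    if internal_sd < 0:
        raise ValueError("internal_sd must be non-negative")
    raw = round(params.confidence_offset - params.confidence_scale * internal_sd)
    return int(min(6, max(1, raw)))


def _scaled_weights(params: AgentParams, t: int, anchor: int):
    """Available lag weights at trial t, rescaled to the full weight total.

    ``anchor`` is the first trial index whose history the agent may use
    (block start, or switch_trial+1 after a reset).  Returns two lists of
    (lag, weight).
    """
    g_terms = [
        (i, params.w_guess[i - 1]) for i in (1, 2, 3) if t - i >= anchor
    ]
    h_terms = [(j, params.w_hint[j]) for j in (0, 1, 2, 3) if t - j >= anchor]
    total = float(np.sum(params.w_guess) + np.sum(params.w_hint))
    avail = sum(w for _, w in g_terms) + sum(w for _, w in h_terms)
    if avail != 0.0:
        scale = total / avail
        g_terms = [(i, w * scale) for i, w in g_terms]
        h_terms = [(j, w * scale) for j, w in h_terms]
    return g_terms, h_terms


def simulate_agent_block(
    block: BlockDesign,
    params: AgentParams,
    seed,
    participant_id: int = 1,
) -> pd.DataFrame:
    """Simulate one block of the hidden-target task for one agent.

    Returns a trial table (one row per trial) with target, hint, endpoint and
    estimate angles, plus confidence.  The recurrence runs on signed errors
    relative to the target; see :class:`AgentParams` for the update rule.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_trials = len(block.response_types)
    sigma_dist = kappa_to_sd_deg(block.kappa)

    hints = sample_hints(block.target_angle, block.kappa, n_trials, rng)
    hint_err = signed_angle_diff(hints, block.target_angle)

    rows = []
    guess_err = np.zeros(n_trials)
    for t in range(1, n_trials + 1):
        rt = block.response_types[t - 1]
        anchor = 1
        if params.reset_on_switch and t > block.switch_trial:
            anchor = block.switch_trial + 1
        g_terms, h_terms = _scaled_weights(params, t, anchor)
        est = params.intercept
        est += sum(w * guess_err[t - 1 - i] for i, w in g_terms)
        est += sum(w * hint_err[t - 1 - j] for j, w in h_terms)
        noise = rng.normal(0.0, params.motor_sd(rt))
        guess_err[t - 1] = est + noise

        estimate_angle = wrap_angle(block.target_angle + guess_err[t - 1])
        endpoint_angle = (
            estimate_angle if rt == "pro" else wrap_angle(estimate_angle + 180.0)
        )
        internal_sd = sigma_dist / math.sqrt(t - anchor + 1)
        rows.append(
            {
                "participant_id": participant_id,
                "block_id": block.block_id,
                "trial_index": t,
                "difficulty": block.difficulty,
                "response_type": rt,
                "order": block.order,
                "target_angle": block.target_angle,
                "hint_angle": hints[t - 1],
                "endpoint_angle": endpoint_angle,
                "estimate_angle": estimate_angle,
                "confidence": simulate_confidence(internal_sd, params),
                "failed": False,
                "failure_reason": "none",
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_calibration(
    spec: DesignSpec,
    motor_sd_pro: float,
    motor_sd_anti: float,
    seed,
    participant_id: int = 1,
) -> pd.DataFrame:
    """Simulate the calibration task: visually guided saccades to a shown
    line, 10 pro then 10 anti trials per block.

    Each 10-trial half visits every calibration location once in shuffled
    order.  The endpoint is the instructed direction (the line for pro, its
    antipode for anti) plus Gaussian motor noise of the modality's SD.
    """
    if motor_sd_pro < 0 or motor_sd_anti < 0:
        raise ValueError("motor SDs must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    locs = np.asarray(spec.calibration_locations, dtype=float)
    rows = []
    for b in range(1, spec.n_calibration_blocks + 1):
        for rt, sd in (("pro", motor_sd_pro), ("anti", motor_sd_anti)):
            targets = rng.permutation(locs)
            noise = rng.normal(0.0, sd, size=len(targets))
            aimed = targets if rt == "pro" else wrap_angle(targets + 180.0)
            endpoints = wrap_angle(aimed + noise)
            estimates = (
                endpoints if rt == "pro" else wrap_angle(endpoints + 180.0)
            )
            t0 = 0 if rt == "pro" else len(targets)
            for k in range(len(targets)):
                rows.append(
                    {
                        "participant_id": participant_id,
                        "block_id": b,
                        "trial_index": t0 + k + 1,
                        "response_type": rt,
                        "target_angle": targets[k],
                        "endpoint_angle": endpoints[k],
                        "estimate_angle": estimates[k],
                    }
                )
    return pd.DataFrame(rows, columns=CALIBRATION_COLUMNS)


def simulate_cohort(
    spec: DesignSpec,
    params: AgentParams | list[AgentParams],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: hidden-target trials and calibration trials.

    ``params`` is either one AgentParams shared by all participants or a
    per-participant list.  Per-participant RNG streams are spawned from the
    top-level seed (``seed`` or ``spec.seed``), so any cohort is reproducible
    from the spec alone.
    """
    if isinstance(params, AgentParams):
        params = [params] * spec.n_participants
    if len(params) != spec.n_participants:
        raise ValueError(
            f"need {spec.n_participants} AgentParams, got {len(params)}"
        )
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    trial_frames, calib_frames = [], []
    for pid, (p, ss) in enumerate(
        zip(params, root.spawn(spec.n_participants)), start=1
    ):
        rng = np.random.default_rng(ss)
        design_spec = dataclasses.replace(
            spec, seed=int(rng.integers(2**31))
        )
        for block in generate_design(design_spec):
            trial_frames.append(
                simulate_agent_block(block, p, rng, participant_id=pid)
            )
        calib_frames.append(
            simulate_calibration(
                spec, p.motor_sd_pro, p.motor_sd_anti, rng, participant_id=pid
            )
        )
    trials = pd.concat(trial_frames, ignore_index=True)
    calib = pd.concat(calib_frames, ignore_index=True)
    return trials, calib


def simulate_ideal_observer(
    kappa: float,
    motor_sd: float,
    n_blocks: int,
    n_trials: int = 10,
    seed=None,
    hint_distribution: str = "vonmises",
) -> pd.DataFrame:
    """Simulate the optimal agent: its estimate on trial t is the cumulative
    mean of hint errors 1..t, reported with Gaussian motor noise.

    This agent attains the theoretical bound: its mean absolute error at
    trial t is sqrt(2/pi) * sqrt(motor_sd^2 + sigma_dist^2 / t).
    ``hint_distribution`` selects von Mises hint errors (the task's
    generative law) or their normal approximation N(0, 1/kappa) (the law the
    bound itself assumes; at kappa >= 30 the two differ by well under a
    tenth of a degree in mean absolute error).  Returns a long table
    (block_id, trial_index, error) of signed guess errors.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if motor_sd < 0:
        raise ValueError("motor_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if hint_distribution == "vonmises":
        h = np.degrees(rng.vonmises(0.0, kappa, size=(n_blocks, n_trials)))
    elif hint_distribution == "normal":
        h = rng.normal(0.0, kappa_to_sd_deg(kappa), size=(n_blocks, n_trials))
    else:
        raise ValueError(f"unknown hint_distribution {hint_distribution!r}")
    cummean = np.cumsum(h, axis=1) / np.arange(1, n_trials + 1)
    err = cummean + rng.normal(0.0, motor_sd, size=h.shape)
    return pd.DataFrame(
        {
            "block_id": np.repeat(np.arange(1, n_blocks + 1), n_trials),
            "trial_index": np.tile(np.arange(1, n_trials + 1), n_blocks),
            "error": err.ravel(),
        }
    )


def simulate_from_model(
    betas: dict,
    noise_sd: float,
    kappa: float,
    n_blocks: int,
    n_trials: int = 10,
    seed=None,
) -> pd.DataFrame:
    """Simulate guess-error sequences whose generative law is one of the
    lagged-regression models (for model and parameter recovery).

    ``betas`` maps predictor names (``hint_t``, ``hint_t1..t3``,
    ``guess_t1..t3``, ``cumavg_hint``, ``cumavg_guess``, ``intercept``) to
    generative coefficients.  Trials whose predictors are not yet defined
    anchor on the current hint.  Vectorized across blocks; returns a long
    table with columns block_id, trial_index, guess_error, hint_error.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma = 1.0 / math.sqrt(kappa)
    h = np.degrees(rng.vonmises(0.0, kappa, size=(n_blocks, n_trials)))
    g = np.zeros((n_blocks, n_trials))
    b0 = betas.get("intercept", 0.0)
    for t in range(1, n_trials + 1):
        i = t - 1
        pred = np.full(n_blocks, b0)
        defined = True
        for name, beta in betas.items():
            if name == "intercept" or beta == 0.0:
                continue
            if name == "hint_t":
                pred += beta * h[:, i]
            elif name.startswith("hint_t"):
                lag = int(name[-1])
                if t - lag < 1:
                    defined = False
                    break
                pred += beta * h[:, i - lag]
            elif name == "cumavg_hint":
                pred += beta * h[:, : i + 1].mean(axis=1)
            elif name == "cumavg_guess":
                if t == 1:
                    defined = False
                    break
                pred += beta * g[:, :i].mean(axis=1)
            elif name.startswith("guess_t"):
                lag = int(name[-1])
                if t - lag < 1:
                    defined = False
                    break
                pred += beta * g[:, i - lag]
            else:
                raise ValueError(f"unknown predictor {name!r}")
        if not defined:
            pred = h[:, i].copy()
        g[:, i] = pred + rng.normal(0.0, noise_sd, size=n_blocks)
    out = pd.DataFrame(
        {
            "block_id": np.repeat(np.arange(1, n_blocks + 1), n_trials),
            "trial_index": np.tile(np.arange(1, n_trials + 1), n_blocks),
            "guess_error": g.ravel(),
            "hint_error": h.ravel(),
        }
    )
    out.attrs["sigma_dist_deg"] = math.degrees(sigma)
    return out
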