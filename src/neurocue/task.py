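"""Cued near-threshold detection task: session generation and simulated observers.

The task is a Posner-style exogenous cueing paradigm: a brief non-predictive
peripheral cue is followed, 300 ms later, by a near-threshold tilted Gabor
target on the cued side (valid), the opposite side (invalid), or no target at
all (catch).  Participants first discriminate the tilt direction (2AFC) and
then report the perceived presence or absence of the target.  This module
generates balanced randomized sessions of that task and simulates behavioral
observers with a logistic psychometric function, an additive criterion shift
under valid cueing, a false-alarm rate on catch trials, and lognormal
response times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger("neurocue")

# Timing constants of the task (milliseconds).
SOA_MS = 300.0
CUE_DUR_MS = 50.0
TARGET_DUR_MS = 16.0
RESP_DELAY_MS = 484.0

#: 12 equally spaced Gabor orientations in (0, 180), offset to exclude the
#: vertical and horizontal axes.  The two discrimination alternatives differ
#: by 30 degrees.
TILT_GRID = tuple(7.5 + 15.0 * i for i in range(12))
TILT_ALTERNATIVE_SEP = 30.0

N_PRESENT_PER_BLOCK = 88
N_CATCH_PER_BLOCK = 22
N_TRIALS_PER_BLOCK = N_PRESENT_PER_BLOCK + N_CATCH_PER_BLOCK


class ConfigurationError(ValueError):
    """Raised for invalid task/session configuration."""


@dataclass(frozen=True)
class TrialSpec:
    """Condition labels, timings and contrast for one trial.

    ``validity`` is 'valid' iff the cue and a present target share a side,
    'invalid' iff they differ, and 'catch' iff the target is absent.
    """

    cue_side: str                # {'left', 'right'}
    target_side: str             # {'left', 'right', 'absent'}
    validity: str                # {'valid', 'invalid', 'catch'}
    target_contrast: float       # fraction of max Michelson contrast, [0, 1]
    tilt: float                  # degrees in (0, 180) excluding 0/90
    fixation_ms: float = 1250.0
    cue_on_ms: float = 0.0
    cue_dur_ms: float = CUE_DUR_MS
    soa_ms: float = SOA_MS
    target_dur_ms: float = TARGET_DUR_MS
    resp_delay_ms: float = RESP_DELAY_MS

    def __post_init__(self) -> None:
        present = self.target_side in ("left", "right")
        if self.validity == "catch":
            if present:
                raise ConfigurationError("catch trials must have target_side='absent'")
        elif self.validity == "valid":
            if not present or self.cue_side != self.target_side:
                raise ConfigurationError("valid trials require cue_side == target_side")
        elif self.validity == "invalid":
            if not present or self.cue_side == self.target_side:
                raise ConfigurationError("invalid trials require cue_side != target_side")
        else:
            raise ConfigurationError(f"unknown validity {self.validity!r}")
        if not 0.0 <= self.target_contrast <= 1.0:
            raise ConfigurationError("target_contrast must lie in [0, 1]")


@dataclass(frozen=True)
class BehavioralRecord:
    """One trial's simulated responses."""

    trial: TrialSpec
    discrimination_correct: bool
    report: str                  # {'seen_left', 'seen_right', 'absent'}
    rt_discrim_ms: float
    rt_report_ms: float

    @property
    def seen(self) -> bool:
        return self.report != "absent"


@dataclass
class RTModel:
    """Lognormal RT model: exp(N(mu, sigma)) milliseconds, per task."""

    discrim_mu: float = 6.55     # median ~700 ms
    discrim_sigma: float = 0.35
    report_mu: float = 6.40      # median ~600 ms
    report_sigma: float = 0.35


@dataclass
class ObserverParams:
    """Synthetic logistic-psychometric observer with a cue-induced criterion shift.

    Detection probability on target-present trials is
    ``1 / (1 + exp(-slope * (contrast - threshold_contrast)))`` plus
    ``criterion_shift_valid`` on validly cued trials (a liberal shift: valid
    cues raise the detection rate).  Catch-trial "seen" probability is
    ``fa_rate``; false alarms are reported on the cued side with probability
    ``fa_cue_bias``.
    """

    threshold_contrast: float = 0.15
    slope: float = 30.0
    criterion_shift_valid: float = 0.05
    fa_rate: float = 0.10
    discrim_acc_seen: float = 0.85
    discrim_acc_unseen: float = 0.55
    fa_cue_bias: float = 0.75
    rt_model: RTModel = field(default_factory=RTModel)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError("slope must be > 0")
        for name in ("threshold_contrast", "criterion_shift_valid", "fa_rate",
                     "discrim_acc_seen", "discrim_acc_unseen", "fa_cue_bias"):
            v = getattr(self, name)
            if name != "criterion_shift_valid" and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    def p_seen(self, contrast, valid: bool = False):
        """Detection probability at ``contrast`` (vectorized), clamped to [0, 1]."""
        contrast = np.asarray(contrast, dtype=float)
        p = 1.0 / (1.0 + np.exp(-self.slope * (contrast - self.threshold_contrast)))
        if valid:
            p = p + self.criterion_shift_valid
        if np.any(p > 1.0) or np.any(p < 0.0):
            warnings.warn("detection probability clamped to [0, 1] after criterion shift")
        return np.clip(p, 0.0, 1.0)


@dataclass
class SessionConfig:
    """Session-level configuration: number of blocks and the fixed target contrast."""

    blocks: int = 1
    contrast: float = 0.15

    def __post_init__(self) -> None:
        if self.blocks < 1:
            raise ConfigurationError("blocks must be >= 1")
        if not 0.0 <= self.contrast <= 1.0:
            raise ConfigurationError("contrast must lie in [0, 1]")


def generate_session(config: SessionConfig | None = None, seed: int = 0) -> list[TrialSpec]:
    """Generate a randomized session of the cueing task.

    Each block holds exactly 88 target-present trials (44 valid, 44 invalid,
    left/right counterbalanced exactly within validity) and 22 catch trials
    (cue side counterbalanced), shuffled by ``seed``.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for _ in range(config.blocks):
        block: list[TrialSpec] = []
        for side in ("left", "right"):
            other = "right" if side == "left" else "left"
            for _ in range(22):
                block.append(_make_trial(rng, side, side, "valid", config.contrast))
            for _ in range(22):
                block.append(_make_trial(rng, other, side, "invalid", config.contrast))
        for cue_side in ("left", "right"):
            for _ in range(11):
                block.append(_make_trial(rng, cue_side, "absent", "catch", 0.0))
        order = rng.permutation(len(block))
        trials.extend(block[i] for i in order)
    return trials


def _make_trial(rng, cue_side, target_side, validity, contrast) -> TrialSpec:
    return TrialSpec(
        cue_side=cue_side,
        target_side=target_side,
        validity=validity,
        target_contrast=contrast,
        tilt=float(rng.choice(TILT_GRID)),
        fixation_ms=float(rng.uniform(1000.0, 1500.0)),
    )


def simulate_observer(trials: list[TrialSpec], obs: ObserverParams,
                      seed: int = 0) -> list[BehavioralRecord]:
    """Simulate an observer's detection report, 2AFC discrimination and RTs."""
    if not trials:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[BehavioralRecord] = []
    for t in trials:
        if t.validity == "catch":
            seen = rng.random() < obs.fa_rate
            if seen:
                fa_side = t.cue_side if rng.random() < obs.fa_cue_bias else (
                    "right" if t.cue_side == "left" else "left")
                report = f"seen_{fa_side}"
            else:
                report = "absent"
        else:
            p = float(obs.p_seen(t.target_contrast, valid=(t.validity == "valid")))
            seen = rng.random() < p
            report = f"seen_{t.target_side}" if seen else "absent"
        acc = obs.discrim_acc_seen if seen else obs.discrim_acc_unseen
        correct = rng.random() < acc
        m = obs.rt_model
        rt_d = float(np.exp(rng.normal(m.discrim_mu, m.discrim_sigma)))
        rt_r = float(np.exp(rng.normal(m.report_mu, m.report_sigma)))
        records.append(BehavioralRecord(t, bool(correct), report, rt_d, rt_r))
    return records


def simulate_random_discrimination(n_trials: int, seed: int = 0) -> float:
    """Discrimination accuracy of a responder choosing uniformly between the
    two forced-choice alternatives on ``n_trials`` target-present trials."""
    rng = np.random.default_rng(seed)
    sides = rng.integers(0, 2, size=n_trials)       # true target side
    responses = rng.integers(0, 2, size=n_trials)   # uniform random choice
    return float(np.mean(sides == responses))


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """One row per trial, columns as in :class:`TrialSpec`."""
    return pd.DataFrame([asdict(t) for t in trials])


def records_to_frame(records: list[BehavioralRecord]) -> pd.DataFrame:
    """Tidy behavioral table (trial condition columns + responses)."""
    rows = []
    for r in records:
        row = asdict(r.trial)
        row.update(
            discrimination_correct=r.discrimination_correct,
            report=r.report,
            seen=r.seen,
            rt_discrim_ms=r.rt_discrim_ms,
            rt_report_ms=r.rt_report_ms,
        )
        rows.append(row)
    return pd.DataFrame(rows)
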