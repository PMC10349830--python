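"""Synthetic condition-labelled contact time series.

This generator emulates the statistical structure that the trajectory
clustering and time-resolved statistics assume: contacts belong to one of
five temporal-profile families (or a null family), each defined by the time
windows in which consciously reported ("seen") targets evoke more
high-frequency-broadband power than unreported ones, plus — for three
profiles — a cue-validity x report interaction (valid-seen boosted) and —
for the reorienting profile — the reversed interaction (invalid-seen
boosted).  Activity is the profile mean in z-units plus i.i.d. Gaussian
noise and a per-contact lognormal gain jitter; trials carry a complete
2 x 2 x 2 condition labelling (target side x cue validity x seen/unseen).

Profile shapes are boxcars with raised-cosine edges for transient/sustained
windows, a linear ramp for the late-accumulation profile, and a Gaussian
bump (sigma 15 ms) at 180 ms for the reorienting profile.

A separate helper synthesizes raw broadband traces (pink-noise background
with injected amplitude-modulated 70-140 Hz bursts at known times) as a
ground-truth fixture for the spectral pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import ConfigurationError

DEFAULT_TIMES_MS = np.arange(-300.0, 501.0, 10.0)   # target-locked, 100 Hz

#: patient-scale cluster proportions (Visual 42, Sustained 148,
#: Late accumulation 67, Reorienting 19, Conscious report 38, remainder
#: null, out of 727 contacts) for full-scale synthetic runs.
PATIENT_SCALE_CLUSTER_SIZES = {
    "visual": 42, "sustained": 148, "late_accumulation": 67,
    "reorienting": 19, "conscious_report": 38, "null": 413,
}

SIDE_LEVELS = ("left", "right")
VALIDITY_LEVELS = ("invalid", "valid")
REPORT_LEVELS = ("unseen", "seen")


# ---------------------------------------------------------------------------
# window primitives
# ---------------------------------------------------------------------------

def smooth_boxcar(t: np.ndarray, lo: float, hi: float, edge: float = 10.0) -> np.ndarray:
    """Boxcar on [lo, hi] with raised-cosine edges of width ``edge`` inside
    the window; exactly zero outside [lo, hi]."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = (t >= lo) & (t <= hi)
    out[inside] = 1.0
    rise = inside & (t < lo + edge)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - lo) / edge))
    fall = inside & (t > hi - edge)
    out[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t[fall]) / edge))
    return out


def linear_ramp(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linear 0 -> 1 ramp over [lo, hi], zero outside."""
    t = np.asarray(t, dtype=float)
    out = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
    out[(t < lo) | (t > hi)] = 0.0
    return out


def gaussian_bump(t: np.ndarray, center: float, sigma: float,
                  lo: float, hi: float) -> np.ndarray:
    """Gaussian bump truncated to [lo, hi] (zero outside)."""
    t = np.asarray(t, dtype=float)
    out = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    out[(t < lo) | (t > hi)] = 0.0
    return out


# ---------------------------------------------------------------------------
# profile templates
# ---------------------------------------------------------------------------

@dataclass
class ProfileTemplate:
    """Mean z-power profile as a function of time and condition.

    ``seen_fn(t)`` is the seen-minus-unseen difference (added to seen trials
    only); the interaction term adds ``+/- 0.5 * interaction_amplitude *
    interaction_fn(t)`` to seen trials depending on validity (positive sign
    boosts valid-seen; ``interaction_sign=-1`` boosts invalid-seen), so the
    marginal seen-unseen difference stays exactly ``seen_fn``.
    """

    name: str
    amplitude: float
    seen_windows: list[tuple[float, float]]
    shape: str = "boxcar"                      # boxcar | ramp | bump
    interaction_window: tuple[float, float] | None = None
    interaction_amplitude: float = 0.0
    interaction_sign: int = +1
    cue_period_effect: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        for lo, hi in self.seen_windows:
            if hi <= lo:
                raise ConfigurationError(
                    f"{self.name}: contradictory window ({lo}, {hi})")
        if self.interaction_window is not None:
            lo, hi = self.interaction_window
            if hi <= lo:
                raise ConfigurationError(
                    f"{self.name}: contradictory interaction window ({lo}, {hi})")

    def seen_fn(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for lo, hi in self.seen_windows:
            if self.shape == "ramp":
                out += linear_ramp(t, lo, hi)
            elif self.shape == "bump":
                out += gaussian_bump(t, (lo + hi) / 2.0, 15.0, lo, hi)
            else:
                out += smooth_boxcar(t, lo, hi)
        return self.amplitude * out

    def interaction_fn(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.interaction_window is None or self.interaction_amplitude == 0:
            return np.zeros_like(t)
        lo, hi = self.interaction_window
        return self.interaction_amplitude * smooth_boxcar(t, lo, hi)

    def mean(self, t: np.ndarray, validity: str, report: str) -> np.ndarray:
        """Condition mean at times ``t`` (target side is profile-neutral)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if report == "seen":
            out = out + self.seen_fn(t)
            v = 1.0 if validity == "valid" else -1.0
            out = out + 0.5 * self.interaction_sign * v * self.interaction_fn(t)
        return out


def make_profile_templates(amplitude: float = 1.0,
                           interaction_amplitude: float = 0.5) -> dict[str, ProfileTemplate]:
    """The six-profile template bank (five effect profiles + null).

    Window boundaries (ms, target-locked) follow the reported cluster
    significance windows; amplitudes are free parameters in z-units.
    """
    a, ia = amplitude, interaction_amplitude
    bank = {
        "visual": ProfileTemplate(
            "visual", a, [(90, 350), (380, 430)],
            interaction_window=(190, 220), interaction_amplitude=ia),
        "sustained": ProfileTemplate(
            "sustained", a,
            [(-140, -90), (160, 200), (240, 300), (340, 430), (450, 500)],
            interaction_window=(270, 330), interaction_amplitude=ia,
            cue_period_effect=True),
        "late_accumulation": ProfileTemplate(
            "late_accumulation", a, [(300, 500)], shape="ramp",
            interaction_window=(360, 430), interaction_amplitude=ia),
        "reorienting": ProfileTemplate(
            "reorienting", a, [(160, 190)], shape="bump",
            interaction_window=(160, 190), interaction_amplitude=ia,
            interaction_sign=-1, cue_period_effect=True),
        "conscious_report": ProfileTemplate(
            "conscious_report", a, [(310, 450)]),
        "null": ProfileTemplate("null", 0.0, []),
    }
    return bank


# ---------------------------------------------------------------------------
# contact dataset
# ---------------------------------------------------------------------------

@dataclass
class ContactDataset:
    """Per-contact, per-trial, per-timepoint normalized band power with a
    complete 2 x 2 x 2 condition labelling and ground-truth cluster labels."""

    contact_ids: list[str]
    true_labels: list[str]
    trials: pd.DataFrame            # columns: target_side, validity, report
    times_ms: np.ndarray            # 10 ms sampling, -300..+500 target-locked
    power: np.ndarray               # (n_contacts, n_trials, n_times), z-units
    rt_discrim_ms: np.ndarray | None = None

    @property
    def n_contacts(self) -> int:
        return self.power.shape[0]

    def condition_means(self) -> np.ndarray:
        """Trial-averaged power per condition cell:
        (n_contacts, 2 side, 2 validity, 2 report, n_times)."""
        out = np.empty((self.n_contacts, 2, 2, 2, len(self.times_ms)))
        for i_s, s in enumerate(SIDE_LEVELS):
            for i_v, v in enumerate(VALIDITY_LEVELS):
                for i_r, r in enumerate(REPORT_LEVELS):
                    sel = ((self.trials.target_side == s)
                           & (self.trials.validity == v)
                           & (self.trials.report == r)).to_numpy()
                    if not sel.any():
                        raise ValueError(f"empty condition cell ({s}, {v}, {r})")
                    out[:, i_s, i_v, i_r] = self.power[:, sel].mean(axis=1)
        return out

    def validity_report_means(self) -> np.ndarray:
        """(n_contacts, 2 validity, 2 report, n_times), pooled over side."""
        m = self.condition_means()
        return m.mean(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (contact, trial, condition columns, time, power)."""
        n_c, n_t, n_time = self.power.shape
        idx = pd.MultiIndex.from_product(
            [self.contact_ids, range(n_t), self.times_ms],
            names=["contact", "trial", "time_ms"])
        frame = pd.DataFrame({"power": self.power.reshape(-1)}, index=idx).reset_index()
        trial_cols = self.trials.reset_index(drop=True)
        for col in ("target_side", "validity", "report"):
            frame[col] = trial_cols[col].to_numpy()[frame["trial"].to_numpy()]
        return frame

    def save(self, csv_path, labels_json_path) -> None:
        self.to_long_frame().to_csv(csv_path, index=False)
        with open(labels_json_path, "w") as fh:
            json.dump(dict(zip(self.contact_ids, self.true_labels)), fh, indent=1)


def balanced_condition_trials(n_trials: int, seed: int = 0) -> pd.DataFrame:
    """A shuffled trial table with (near-)equal counts in all 8 condition cells."""
    cells = [(s, v, r) for s in SIDE_LEVELS for v in VALIDITY_LEVELS
             for r in REPORT_LEVELS]
    reps = [cells[i % 8] for i in range(n_trials)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    rows = [reps[i] for i in order]
    return pd.DataFrame(rows, columns=["target_side", "validity", "report"])


def generate_contacts(templates: dict[str, ProfileTemplate] | None = None,
                      n_per_cluster: dict[str, int] | None = None,
                      n_trials: int = 200, noise_sd: float = 1.0,
                      seed: int = 0, gain_jitter_sd: float = 0.2,
                      times_ms: np.ndarray = DEFAULT_TIMES_MS) -> ContactDataset:
    """Generate a synthetic contact dataset with known cluster membership.

    power = gain * template_mean(condition, t) + N(0, noise_sd), with a
    per-contact lognormal(0, ``gain_jitter_sd``) gain emulating electrode
    heterogeneity.  Defaults: 300 contacts (5 x 40 effect + 100 null),
    200 trials, noise_sd 1.0 z.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0")
    templates = templates or make_profile_templates()
    n_per_cluster = n_per_cluster or {
        "visual": 40, "sustained": 40, "late_accumulation": 40,
        "reorienting": 40, "conscious_report": 40, "null": 100,
    }
    if n_trials < 16:
        raise ConfigurationError("need >= 2 trials per condition cell")
    rng = np.random.default_rng(seed)
    trials = balanced_condition_trials(n_trials, seed=int(rng.integers(2**31)))
    times_ms = np.asarray(times_ms, dtype=float)

    contact_ids, labels, rows = [], [], []
    # precompute per-template condition means (side-neutral)
    cond_mean = {
        name: {(v, r): tpl.mean(times_ms, v, r)
               for v in VALIDITY_LEVELS for r in REPORT_LEVELS}
        for name, tpl in templates.items()
    }
    v_arr = trials.validity.to_numpy()
    r_arr = trials.report.to_numpy()
    for name, count in n_per_cluster.items():
        tpl_means = cond_mean[name]
        trial_means = np.stack([tpl_means[(v, r)] for v, r in zip(v_arr, r_arr)])
        for j in range(count):
            gain = float(np.exp(rng.normal(0.0, gain_jitter_sd)))
            noise = rng.normal(0.0, noise_sd, size=(n_trials, len(times_ms)))
            rows.append(gain * trial_means + noise)
            contact_ids.append(f"{name}_{j:03d}")
            labels.append(name)
    power = np.stack(rows)
    return ContactDataset(contact_ids, labels, trials, times_ms, power)


def rt_coupled_activity(n_trials: int = 200, times_ms: np.ndarray = None,
                        coupling: float = 1.0, noise_sd: float = 1.0,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-trial activity whose sustained duration tracks the trial RT.

    Activity ramps up from 300 ms and stays high until the trial's
    (lognormal) discrimination RT, emulating accumulation-to-report
    dynamics.  Returns (activity [n_trials x T], rts_ms, times_ms).  With
    ``coupling=0`` the activity is RT-independent noise.
    """
    if times_ms is None:
        times_ms = np.arange(0.0, 1001.0, 10.0)
    rng = np.random.default_rng(seed)
    rts = np.exp(rng.normal(6.55, 0.35, size=n_trials))
    times_ms = np.asarray(times_ms, dtype=float)
    act = rng.normal(0.0, noise_sd, size=(n_trials, len(times_ms)))
    rise = np.clip((times_ms - 300.0) / 100.0, 0.0, 1.0)   # ramp then sustain
    for i, rt in enumerate(rts):
        act[i] += coupling * rise * (times_ms <= rt + 300.0)
    return act, rts, times_ms


# ---------------------------------------------------------------------------
# raw broadband fixture for the spectral pipeline
# ---------------------------------------------------------------------------

@dataclass
class RawBurstTrace:
    """Pink-noise trace with injected high-gamma bursts and their ground truth."""

    signal: np.ndarray
    sample_rate: float
    burst_envelope: np.ndarray
    burst_times_s: list[float]
    carrier_hz: float


@dataclass
class BurstConfig:
    sample_rate: float = 512.0
    duration_s: float = 4.0
    carrier_hz: float = 100.0
    burst_times_s: tuple[float, ...] = (2.0,)
    burst_amplitude: float = 5.0
    burst_sigma_s: float = 0.03
    background_sd: float = 1.0


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec = spec / np.sqrt(freqs)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def generate_raw_contact(cfg: BurstConfig | None = None, seed: int = 0) -> RawBurstTrace:
    """Raw broadband trace: pink-noise background plus amplitude-modulated
    bursts at ``cfg.carrier_hz`` centered on ``cfg.burst_times_s``."""
    cfg = cfg or BurstConfig()
    if cfg.sample_rate < 512:
        raise ConfigurationError("sample_rate must be >= 512 Hz")
    if cfg.carrier_hz >= cfg.sample_rate / 2:
        raise ConfigurationError("burst carrier above Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    signal = cfg.background_sd * pink_noise(n, rng)
    envelope = np.zeros(n)
    for t0 in cfg.burst_times_s:
        envelope += np.exp(-0.5 * ((t - t0) / cfg.burst_sigma_s) ** 2)
    carrier = np.sin(2 * np.pi * cfg.carrier_hz * t + rng.uniform(0, 2 * np.pi))
    signal = signal + cfg.burst_amplitude * envelope * carrier
    return RawBurstTrace(signal, cfg.sample_rate, envelope,
                         list(cfg.burst_times_s), cfg.carrier_hz)
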