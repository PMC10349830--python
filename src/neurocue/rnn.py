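"""Dale-constrained recurrent network model of the cued detection task.

The network is a single recurrent layer of N=50 rectified-linear units, 80%
excitatory and 20% inhibitory (Dale's principle: all outgoing weights of a
unit share its sign), driven by two noisy input channels (left/right visual
field).  Before discretization the dynamics are

    tau dx/dt = -x + f(W_rec r + b_rec + W_in u + sqrt(2 tau sigma_rec^2) xi)
    r = f(x),        z = W_out r + b_out

with f = ReLU, tau = 100 ms and sigma_rec = 0.05.  The Euler step at
resolution dt is x <- (1 - dt/tau) x + (dt/tau) f(drive).  The two readouts
are squashed by a logistic so the reported outputs lie in [0, 1]; training
minimizes the mean squared error between the squashed outputs and the
target traces inside the response window, by backpropagation through time
with Adam, re-projecting the Dale sign constraints after every update.

A trial mirrors the human task: 200 ms fixation, a 50 ms cue pulse
(amplitude 0.30) on one input channel, the target pulse (amplitude equal to
the trial's contrast, drawn from 0-0.13) 300 ms after cue onset on the
cued (valid) or opposite (invalid) channel — or absent in 20% of catch
trials — and a response window opening 150 ms after target offset.

Matrix conventions: W_in is (N, 2) (column = input channel), W_rec is
(N, N) with W_rec[i, j] the weight from unit j to unit i (so a unit's
outgoing weights form a column; the diagonal is held at zero), W_out is
(2, N).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize as spopt
from scipy.special import expit
from scipy import stats as sps

from .stats import holm_bonferroni, holm_sidak

logger = logging.getLogger("neurocue")

CUE_AMPLITUDE = 0.30
INPUT_NOISE_SD = 0.05
MAX_CONTRAST = 0.13
N_CONTRAST_LEVELS = 12


class InstabilityError(RuntimeError):
    pass


@dataclass
class TaskTiming:
    """Trial phase durations in milliseconds."""

    fixation_ms: float = 200.0
    cue_ms: float = 50.0
    cue_target_soa_ms: float = 300.0       # cue onset -> target onset
    target_ms: float = 20.0
    resp_delay_ms: float = 150.0           # target offset -> window onset
    resp_window_ms: float = 300.0

    def steps(self, dt_ms: float):
        cue_on = int(round(self.fixation_ms / dt_ms))
        cue_off = cue_on + int(round(self.cue_ms / dt_ms))
        tgt_on = cue_on + int(round(self.cue_target_soa_ms / dt_ms))
        tgt_off = tgt_on + int(round(self.target_ms / dt_ms))
        win_on = tgt_off + int(round(self.resp_delay_ms / dt_ms))
        win_off = win_on + int(round(self.resp_window_ms / dt_ms))
        return cue_on, cue_off, tgt_on, tgt_off, win_on, win_off

    def n_steps(self, dt_ms: float) -> int:
        return self.steps(dt_ms)[-1] + int(round(50.0 / dt_ms))


@dataclass
class RNNParams:
    """Network weights with excitatory/inhibitory sign structure."""

    W_in: np.ndarray                      # (N, 2)
    W_rec: np.ndarray                     # (N, N), zero diagonal
    W_out: np.ndarray                     # (2, N)
    b_rec: np.ndarray                     # (N,)
    b_out: np.ndarray                     # (2,)
    sign_vector: np.ndarray               # (N,) +1 excitatory / -1 inhibitory
    tau_ms: float = 100.0
    dt_ms: float = 10.0
    sigma_rec: float = 0.05
    timing: TaskTiming = field(default_factory=TaskTiming)

    @property
    def n_units(self) -> int:
        return self.W_rec.shape[0]

    @property
    def n_excitatory(self) -> int:
        return int((self.sign_vector > 0).sum())

    def copy(self) -> "RNNParams":
        return copy.deepcopy(self)

    def dale_violation(self) -> float:
        """Largest sign-constraint violation across W_rec and W_out columns
        (0 when Dale's principle holds exactly and the diagonal is zero)."""
        s = self.sign_vector[None, :]
        v = float(np.maximum(0.0, -self.W_rec * s).max())
        v = max(v, float(np.maximum(0.0, -self.W_out * s).max()))
        v = max(v, float(np.abs(np.diag(self.W_rec)).max()))
        return v


def project_dale(params: RNNParams) -> None:
    """Project W_rec and W_out onto the Dale constraint set in place:
    outgoing weights of excitatory units clipped to >= 0, inhibitory to <= 0,
    and the recurrent diagonal zeroed."""
    e = params.sign_vector > 0
    params.W_rec[:, e] = np.maximum(params.W_rec[:, e], 0.0)
    params.W_rec[:, ~e] = np.minimum(params.W_rec[:, ~e], 0.0)
    params.W_out[:, e] = np.maximum(params.W_out[:, e], 0.0)
    params.W_out[:, ~e] = np.minimum(params.W_out[:, ~e], 0.0)
    np.fill_diagonal(params.W_rec, 0.0)


def _glorot_trunc(rng, shape) -> np.ndarray:
    std = np.sqrt(2.0 / (shape[0] + shape[1]))
    return np.clip(rng.normal(0.0, std, size=shape), -1.0, 1.0)


def init_network(n_units: int = 50, frac_excitatory: float = 0.8,
                 seed: int = 0, dt_ms: float = 10.0,
                 timing: TaskTiming | None = None) -> RNNParams:
    """Glorot-Gaussian initialization truncated to [-1, 1], with the first
    80% of units excitatory, balanced E/I input (inhibitory columns scaled
    by the E/I ratio) and sigma_rec = 0.05, tau = 100 ms."""
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    if n_units < 16:
        warnings.warn("networks below 16 units fail to reach human-level "
                      "performance on this task")
    rng = np.random.default_rng(seed)
    n_e = int(round(frac_excitatory * n_units))
    sign = np.ones(n_units)
    sign[n_e:] = -1.0
    W_in = _glorot_trunc(rng, (n_units, 2))
    W_rec = np.abs(_glorot_trunc(rng, (n_units, n_units))) * sign[None, :]
    if n_units > n_e:  # balance total excitatory and inhibitory drive
        W_rec[:, n_e:] *= n_e / (n_units - n_e)
    W_out = np.abs(_glorot_trunc(rng, (2, n_units))) * sign[None, :]
    params = RNNParams(W_in, W_rec, W_out,
                       b_rec=np.zeros(n_units), b_out=np.zeros(2),
                       sign_vector=sign, dt_ms=dt_ms,
                       timing=timing or TaskTiming())
    project_dale(params)
    return params


# ---------------------------------------------------------------------------
# trial batches, inputs and targets
# ---------------------------------------------------------------------------

@dataclass
class TrialBatch:
    """Condition arrays for a batch of model trials."""

    cue_side: np.ndarray          # (B,) 0 = left, 1 = right
    target_side: np.ndarray       # (B,) 0/1, or -1 when absent
    contrast: np.ndarray          # (B,)

    @property
    def n(self) -> int:
        return len(self.cue_side)

    @property
    def present(self) -> np.ndarray:
        return self.target_side >= 0

    @property
    def valid(self) -> np.ndarray:
        return self.present & (self.cue_side == self.target_side)


def contrast_levels(n_levels: int = N_CONTRAST_LEVELS,
                    max_contrast: float = MAX_CONTRAST) -> np.ndarray:
    return np.linspace(0.0, max_contrast, n_levels)


def make_trial_batch(rng: np.random.Generator, batch: int = 50,
                     contrasts: np.ndarray | None = None,
                     catch_frac: float = 0.2,
                     fixed_contrast: float | None = None) -> TrialBatch:
    """Random batch: cue side uniform, 20% catch trials, valid/invalid with
    equal probability, contrast drawn from ``contrasts`` (or fixed)."""
    if contrasts is None:
        contrasts = contrast_levels()
    cue = rng.integers(0, 2, size=batch)
    catch = rng.random(batch) < catch_frac
    valid = rng.random(batch) < 0.5
    tgt = np.where(valid, cue, 1 - cue)
    tgt = np.where(catch, -1, tgt)
    if fixed_contrast is not None:
        c = np.full(batch, fixed_contrast)
    else:
        c = rng.choice(contrasts, size=batch)
    c = np.where(catch, 0.0, c)
    return TrialBatch(cue.astype(np.int64), tgt.astype(np.int64), c)


def make_inputs(params: RNNParams, batch: TrialBatch,
                rng: np.random.Generator | None = None,
                noise_on: bool = True, dtype=np.float64) -> np.ndarray:
    """Input traces u (T, 2, B): Gaussian background noise (SD 0.05) plus a
    cue pulse (amplitude 0.30) and a target pulse (amplitude = contrast)."""
    T = params.timing.n_steps(params.dt_ms)
    cue_on, cue_off, tgt_on, tgt_off, _, _ = params.timing.steps(params.dt_ms)
    B = batch.n
    u = np.zeros((T, 2, B), dtype=dtype)
    if noise_on:
        if rng is None:
            raise ValueError("rng required when noise_on")
        u += INPUT_NOISE_SD * rng.standard_normal((T, 2, B), dtype=dtype)
    cols = np.arange(B)
    u[cue_on:cue_off, batch.cue_side, cols] += CUE_AMPLITUDE
    present = batch.present
    u[tgt_on:tgt_off, batch.target_side[present], cols[present]] += \
        batch.contrast[present]
    return u


def make_training_targets(params: RNNParams,
                          batch: TrialBatch) -> tuple[np.ndarray, np.ndarray]:
    """Desired squashed-output traces and loss mask, both (T, 2, B):
    the target-side output is 1 inside the response window on target-present
    trials, everything else is 0; the loss is masked to the window."""
    T = params.timing.n_steps(params.dt_ms)
    _, _, _, _, win_on, win_off = params.timing.steps(params.dt_ms)
    B = batch.n
    target = np.zeros((T, 2, B))
    mask = np.zeros((T, 2, B))
    mask[win_on:win_off] = 1.0
    present = batch.present
    cols = np.arange(B)
    target[win_on:win_off, batch.target_side[present], cols[present]] = 1.0
    return target, mask


def recurrent_noise(params: RNNParams, batch_size: int, T: int,
                    rng: np.random.Generator | None,
                    noise_on: bool = True, dtype=np.float64) -> np.ndarray:
    """The recurrent-noise term entering the drive, (T, N, B).

    The dynamics carry continuous-time white noise sqrt(2 tau sigma_rec^2)
    xi(t); its Euler-Maruyama realization at step dt is
    sqrt(2 tau sigma_rec^2 / dt) N(0, 1) per step (equivalently a state
    noise of sqrt(2 dt/tau) sigma_rec after the dt/tau factor).
    """
    if not noise_on:
        return np.zeros((T, params.n_units, batch_size), dtype=dtype)
    if rng is None:
        raise ValueError("rng required when noise_on")
    scale = float(np.sqrt(2.0 * params.tau_ms / params.dt_ms
                          * params.sigma_rec ** 2))
    return scale * rng.standard_normal((T, params.n_units, batch_size),
                                       dtype=dtype)


# ---------------------------------------------------------------------------
# jitted dynamics: forward simulation and BPTT
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_loop(W_rec, alpha, pre):
    """Sequential part of the forward pass.

    ``pre`` (T, N, B) is the precomputed non-recurrent drive
    W_in u + b_rec + noise; the recurrent matmul is the only per-step work.
    Returns state X, rates R and the ReLU mask of the drive DP.
    """
    T, N, B = pre.shape
    X = np.zeros((T, N, B), dtype=pre.dtype)
    R = np.zeros((T, N, B), dtype=pre.dtype)
    DP = np.zeros((T, N, B), dtype=pre.dtype)
    x = np.zeros((N, B), dtype=pre.dtype)
    r = np.zeros((N, B), dtype=pre.dtype)
    one_m_a = 1.0 - alpha
    for t in range(T):
        rec = np.dot(W_rec, r)
        for i in range(N):
            for j in range(B):
                d = rec[i, j] + pre[t, i, j]
                xv = one_m_a * x[i, j]
                if d > 0.0:
                    xv += alpha * d
                    DP[t, i, j] = 1.0
                x[i, j] = xv
                rv = xv if xv > 0.0 else 0.0
                r[i, j] = rv
                X[t, i, j] = xv
                R[t, i, j] = rv
    return X, R, DP


@njit(cache=True)
def _backward_loop(W_rec_T, alpha, X, DP, DRT):
    """Sequential part of BPTT: accumulate the drive gradients GA (T, N, B).

    ``DRT`` (T, N, B) is the precomputed readout contribution W_out^T dz.
    """
    T, N, B = X.shape
    GA = np.zeros((T, N, B), dtype=X.dtype)
    gx = np.zeros((N, B), dtype=X.dtype)
    ga = np.zeros((N, B), dtype=X.dtype)
    one_m_a = 1.0 - alpha
    for t in range(T - 1, -1, -1):
        rec = np.dot(W_rec_T, ga)
        for i in range(N):
            for j in range(B):
                g = one_m_a * gx[i, j]
                if X[t, i, j] > 0.0:
                    g += rec[i, j] + DRT[t, i, j]
                gx[i, j] = g
                gav = alpha * g * DP[t, i, j]
                ga[i, j] = gav
                GA[t, i, j] = gav
    return GA


def _weights(params: RNNParams, dtype):
    return tuple(np.ascontiguousarray(getattr(params, n), dtype=dtype)
                 for n in ("W_in", "W_rec", "b_rec", "W_out", "b_out"))


def _forward_full(params: RNNParams, u: np.ndarray, noise: np.ndarray):
    """Full forward pass at the dtype of ``u`` (float64 for simulation,
    float32 inside training)."""
    dtype = u.dtype
    W_in, W_rec, b_rec, W_out, b_out = _weights(params, dtype)
    alpha = params.dt_ms / params.tau_ms
    T, _, B = u.shape
    N = params.n_units
    pre = (W_in @ u.transpose(1, 0, 2).reshape(2, -1)).reshape(N, T, B)
    pre = np.ascontiguousarray(pre.transpose(1, 0, 2)) + noise \
        + b_rec[None, :, None]
    X, R, DP = _forward_loop(W_rec, alpha, pre)
    Z = (W_out @ R.transpose(1, 0, 2).reshape(N, -1)).reshape(2, T, B)
    Z = Z.transpose(1, 0, 2) + b_out[None, :, None]
    return X, R, DP, Z


def _forward_backward(params: RNNParams, u, noise, target, mask):
    """Loss and parameter gradients for one mini-batch (BPTT)."""
    dtype = u.dtype
    W_in, W_rec, b_rec, W_out, b_out = _weights(params, dtype)
    alpha = params.dt_ms / params.tau_ms
    X, R, DP, Z = _forward_full(params, u, noise)
    Y = expit(Z)
    norm = mask.sum()
    loss = float((mask * (Y - target) ** 2).sum() / norm)

    DZ = mask * (2.0 / norm) * (Y - target) * Y * (1.0 - Y)      # (T, 2, B)
    T, N, B = R.shape
    R2 = R.transpose(1, 0, 2).reshape(N, -1)                     # (N, T*B)
    DZ2 = np.ascontiguousarray(DZ.transpose(1, 0, 2).reshape(2, -1))
    gW_out = DZ2 @ R2.T
    gb_out = DZ2.sum(axis=1)
    DRT = (W_out.T @ DZ2).reshape(N, T, B).transpose(1, 0, 2)
    GA = _backward_loop(np.ascontiguousarray(W_rec.T), alpha,
                        X, DP, np.ascontiguousarray(DRT))
    GA2 = GA.transpose(1, 0, 2).reshape(N, -1)
    # ga_t pairs with r_{t-1}; r_{-1} = 0
    GAs = GA[1:].transpose(1, 0, 2).reshape(N, -1)
    Rp = R[:-1].transpose(1, 0, 2).reshape(N, -1)
    gW_rec = GAs @ Rp.T
    U2 = u.transpose(1, 0, 2).reshape(2, -1)
    gW_in = GA2 @ U2.T
    gb_rec = GA2.sum(axis=1)
    return loss, gW_in, gW_rec, gb_rec, gW_out, gb_out


def simulate_batch(params: RNNParams, batch: TrialBatch, seed: int = 0,
                   noise_on: bool = True):
    """Simulate a batch of trials.

    Returns (u, X, R, Y) with u (T, 2, B) inputs, X/R (T, N, B) states and
    rates, and Y (T, 2, B) squashed outputs in [0, 1].
    """
    rng = np.random.default_rng(seed)
    T = params.timing.n_steps(params.dt_ms)
    u = make_inputs(params, batch, rng, noise_on=noise_on)
    noise = recurrent_noise(params, batch.n, T, rng, noise_on=noise_on)
    X, R, _, Z = _forward_full(params, u, noise)
    if np.abs(X).max() > 1e6:
        raise InstabilityError("network state diverged (|x| > 1e6)")
    Y = expit(Z)
    return u, X, R, Y


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: RNNParams
    loss_curve: np.ndarray         # (n_recorded, 2): iteration, loss
    n_iterations: int
    dale_audited: bool = False


def train_network(params: RNNParams, n_iterations: int = 20000,
                  batch: int = 50, lr: float = 1e-2, seed: int = 0,
                  grad_clip: float = 1.0, record_every: int = 100,
                  audit_dale: bool = False, lr_decay: str | None = "cosine",
                  contrasts: np.ndarray | None = None) -> TrainResult:
    """Mini-batch gradient training by backpropagation through time.

    Adam with gradient clipping and (by default) cosine learning-rate decay
    to 10% of ``lr`` over the run; the Dale sign constraints are re-imposed
    by projection after every update (optionally audited every step).
    Target contrasts are drawn from 12 levels spanning 0-0.13.
    """
    params = params.copy()
    rng = np.random.default_rng(seed)
    T = params.timing.n_steps(params.dt_ms)
    names = ("W_in", "W_rec", "b_rec", "W_out", "b_out")
    m = {n: np.zeros_like(getattr(params, n)) for n in names}
    v = {n: np.zeros_like(getattr(params, n)) for n in names}
    b1, b2, eps = 0.9, 0.999, 1e-8
    curve = []
    dtype = np.float32   # training runs in single precision for speed
    for it in range(1, n_iterations + 1):
        tb = make_trial_batch(rng, batch, contrasts=contrasts)
        u = make_inputs(params, tb, rng, dtype=dtype)
        noise = recurrent_noise(params, batch, T, rng, dtype=dtype)
        target, mask = make_training_targets(params, tb)
        loss, *grads = _forward_backward(params, u, noise,
                                         target.astype(dtype),
                                         mask.astype(dtype))
        if not np.isfinite(loss):
            raise InstabilityError(f"NaN/inf loss at iteration {it}")
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
        scale = min(1.0, grad_clip / (gnorm + 1e-12))
        if lr_decay == "cosine":
            lr_t = lr * (0.55 + 0.45 * np.cos(np.pi * it / n_iterations))
        else:
            lr_t = lr
        if lr > 0:
            for name, g in zip(names, grads):
                g = g * scale
                m[name] = b1 * m[name] + (1 - b1) * g
                v[name] = b2 * v[name] + (1 - b2) * g * g
                mhat = m[name] / (1 - b1 ** it)
                vhat = v[name] / (1 - b2 ** it)
                arr = getattr(params, name)
                arr -= lr_t * mhat / (np.sqrt(vhat) + eps)
            project_dale(params)
        if audit_dale and params.dale_violation() > 0:
            raise AssertionError(f"Dale constraint violated at iteration {it}")
        if it == 1 or it % record_every == 0 or it == n_iterations:
            curve.append((it, float(loss)))
    return TrainResult(params, np.array(curve), n_iterations,
                       dale_audited=audit_dale)


# ---------------------------------------------------------------------------
# behavioral readout and evaluation
# ---------------------------------------------------------------------------

def decode_batch(params: RNNParams, batch: TrialBatch, Y: np.ndarray,
                 seen_threshold: float = 0.5) -> pd.DataFrame:
    """Per-trial behavioral readout from squashed outputs Y (T, 2, B).

    Discrimination response = argmax of the two window-averaged outputs
    (target-present trials); "seen" = windowed max of the target-side output
    exceeds ``seen_threshold`` (for catch trials, of either output — a false
    alarm); detection correct = present & seen, or absent & not seen.
    """
    _, _, _, _, win_on, win_off = params.timing.steps(params.dt_ms)
    win = Y[win_on:win_off]                     # (W, 2, B)
    win_mean = win.mean(axis=0)                 # (2, B)
    win_max = win.max(axis=0)                   # (2, B)
    B = batch.n
    cols = np.arange(B)
    choice = win_mean.argmax(axis=0)
    present = batch.present
    seen = np.where(present,
                    win_max[np.clip(batch.target_side, 0, 1), cols] > seen_threshold,
                    win_max.max(axis=0) > seen_threshold)
    disc_correct = np.where(present, choice == batch.target_side, False)
    detect_correct = np.where(present, seen, ~seen)
    return pd.DataFrame({
        "cue_side": batch.cue_side, "target_side": batch.target_side,
        "contrast": batch.contrast, "present": present,
        "valid": batch.valid, "seen": seen,
        "discrimination_correct": disc_correct,
        "detection_correct": detect_correct,
    })


def evaluate_performance(params: RNNParams, contrasts: np.ndarray | None = None,
                         n_batches: int = 50, batch: int = 50,
                         seed: int = 0, catch_frac: float = 0.2) -> pd.DataFrame:
    """Per-contrast detection rate and discrimination accuracy, split by cue
    validity, evaluated on ``n_batches`` batches of ``batch`` trials each."""
    if contrasts is None:
        contrasts = contrast_levels()
    rng = np.random.default_rng(seed)
    frames = []
    for b in range(n_batches):
        tb = make_trial_batch(rng, batch, contrasts=np.asarray(contrasts),
                              catch_frac=catch_frac)
        _, _, _, Y = simulate_batch(params, tb,
                                    seed=int(rng.integers(2**31)))
        df = decode_batch(params, tb, Y)
        df["batch"] = b
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def performance_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-trial decisions into per-contrast (x validity) rates."""
    present = trials[trials.present]
    rows = []
    for (c, valid), g in present.groupby(["contrast", "valid"]):
        rows.append({"contrast": c, "validity": "valid" if valid else "invalid",
                     "detection_rate": g.seen.mean(),
                     "discrimination_accuracy": g.discrimination_correct.mean(),
                     "n": len(g)})
    catch = trials[~trials.present]
    if len(catch):
        rows.append({"contrast": 0.0, "validity": "catch",
                     "detection_rate": catch.seen.mean(),   # false-alarm rate
                     "discrimination_accuracy": np.nan, "n": len(catch)})
    return pd.DataFrame(rows)


@dataclass
class PsychometricFit:
    midpoint: float
    slope: float
    floor: float
    ceiling: float
    residuals: np.ndarray
    degenerate: bool = False

    def predict(self, contrast) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-self.slope * (c - self.midpoint)))


def fit_psychometric(contrasts: np.ndarray, rates: np.ndarray) -> PsychometricFit:
    """Least-squares logistic fit (with floor/ceiling asymptotes) of
    per-contrast rates.  Degenerate (flat or non-monotone) data is flagged
    but parameters are still returned."""
    c = np.asarray(contrasts, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(c) < 4:
        raise ValueError("need >= 4 contrast levels")
    span = c.max() - c.min()

    def model(x, mid, slope, floor, ceil):
        return floor + (ceil - floor) / (1.0 + np.exp(-slope * (x - mid)))

    p0 = (float(np.median(c)), 4.0 / max(span, 1e-6), float(r.min()),
          float(r.max()))
    try:
        popt, _ = spopt.curve_fit(
            model, c, r, p0=p0,
            bounds=([c.min(), 0.0, 0.0, 0.0], [c.max(), np.inf, 1.0, 1.0]),
            maxfev=20000)
        degenerate = False
    except RuntimeError:
        popt, degenerate = p0, True
    resid = r - model(c, *popt)
    if popt[1] * (popt[3] - popt[2]) * span < 0.05:  # nearly flat curve
        degenerate = True
    if degenerate:
        warnings.warn("psychometric fit is degenerate (flat or non-monotone)")
    return PsychometricFit(float(popt[0]), float(popt[1]), float(popt[2]),
                           float(popt[3]), resid, degenerate)


# ---------------------------------------------------------------------------
# unit clustering in the 3-condition trajectory space
# ---------------------------------------------------------------------------

@dataclass
class UnitClusterResult:
    solution: "ClusterSolution"
    select: "SelectKResult"
    cond_means: np.ndarray          # (N, 3, T) valid-seen / invalid-seen / catch
    condition_labels: list[str]
    times_ms: np.ndarray            # relative to target onset
    seen_unseen_masks: dict[int, np.ndarray]
    labels: dict[int, str]


def collect_unit_activity(params: RNNParams, contrast: float = 0.10,
                          n_batches: int = 20, batch: int = 50,
                          seed: int = 0):
    """Simulate n_batches x batch trials at a fixed contrast and return the
    per-trial unit rates, decisions and times (relative to target onset)."""
    rng = np.random.default_rng(seed)
    rates, frames = [], []
    for b in range(n_batches):
        tb = make_trial_batch(rng, batch, fixed_contrast=contrast)
        _, _, R, Y = simulate_batch(params, tb, seed=int(rng.integers(2**31)))
        rates.append(R)
        df = decode_batch(params, tb, Y)
        df["batch"] = b
        frames.append(df)
    R = np.concatenate(rates, axis=2)           # (T, N, n_trials)
    trials = pd.concat(frames, ignore_index=True)
    tgt_on = params.timing.steps(params.dt_ms)[2]
    T = R.shape[0]
    times_ms = (np.arange(T) - tgt_on) * params.dt_ms
    return R, trials, times_ms


def cluster_units(params: RNNParams, contrast: float = 0.10,
                  n_batches: int = 20, batch: int = 50, seed: int = 0,
                  k_range=range(2, 11), n_restarts: int = 20,
                  alpha: float = 0.05) -> UnitClusterResult:
    """Trajectory k-means over units in the three-condition space
    (validly cued seen / invalidly cued seen / no target), with
    silhouette-based k selection and per-cluster seen-vs-unseen
    time-resolved t-tests (Holm-corrected)."""
    from .trajclust import build_trajectories, select_k

    R, trials, times_ms = collect_unit_activity(params, contrast, n_batches,
                                                batch, seed)
    conds = {
        "valid_seen": (trials.present & trials.valid & trials.seen).to_numpy(),
        "invalid_seen": (trials.present & ~trials.valid & trials.seen).to_numpy(),
        "no_target": (~trials.present).to_numpy(),
    }
    for name, sel in conds.items():
        if not sel.any():
            raise ValueError(
                f"condition {name!r} has zero trials at contrast {contrast}; "
                "adjust the contrast")
    N = R.shape[1]
    cond_means = np.stack([R[:, :, sel].mean(axis=2).T for sel in conds.values()],
                          axis=1)               # (N, 3, T)
    trajs = build_trajectories(cond_means, [f"u{i:02d}" for i in range(N)],
                               list(conds), times_ms)
    sel_res = select_k(trajs, k_range=k_range, n_restarts=n_restarts, seed=seed)
    sol = sel_res.solutions[sel_res.best_k]

    # per-cluster seen vs unseen (target-present trials), t-test per timepoint
    seen = (trials.present & trials.seen).to_numpy()
    unseen = (trials.present & ~trials.seen).to_numpy()
    masks = {}
    post = times_ms >= 0
    for c in range(sol.k):
        units = sol.members(c)
        act = R[:, units].mean(axis=1)          # (T, n_trials) cluster mean
        if seen.any() and unseen.any():
            t, p = sps.ttest_ind(act[np.ix_(post, seen)].T,
                                 act[np.ix_(post, unseen)].T, axis=0)
            masks[c], _ = holm_bonferroni(p, alpha=alpha)
        else:
            masks[c] = np.zeros(int(post.sum()), dtype=bool)
    labels = label_unit_clusters(sol, cond_means, times_ms)
    return UnitClusterResult(sol, sel_res, cond_means, list(conds), times_ms,
                             masks, labels)


def label_unit_clusters(solution, cond_means: np.ndarray,
                        times_ms: np.ndarray) -> dict[int, str]:
    """Heuristic functional labels for unit clusters.

    Reorienting = largest early (0-400 ms post-target) invalid-seen minus
    valid-seen activity; among the rest, Visual / Sustained / Late
    accumulation are ordered by the center-of-mass latency of their
    (baseline-subtracted) valid-seen activity; remaining clusters are
    labelled other_<i>.
    """
    post = (times_ms >= 0) & (times_ms <= 400)
    late = times_ms >= 0
    k = solution.k
    reorient_score, latency, activity = {}, {}, {}
    for c in range(k):
        units = solution.members(c)
        vs = cond_means[units, 0].mean(axis=0)
        ivs = cond_means[units, 1].mean(axis=0)
        reorient_score[c] = float((ivs - vs)[post].mean())
        a = vs[late] - vs[late][0]
        a = np.maximum(a - a.min(), 0.0)
        w = a.sum()
        latency[c] = float((a * times_ms[late]).sum() / w) if w > 0 else np.inf
        activity[c] = float(vs[late].mean())
    labels: dict[int, str] = {}
    reor = max(reorient_score, key=reorient_score.get)
    labels[reor] = "reorienting"
    rest = sorted((c for c in range(k) if c != reor), key=lambda c: latency[c])
    names = ["visual", "sustained", "late_accumulation"]
    for i, c in enumerate(rest):
        labels[c] = names[i] if i < len(names) else f"other_{i - len(names)}"
    return labels


# ---------------------------------------------------------------------------
# directed connection-weight graph
# ---------------------------------------------------------------------------

@dataclass
class ConnectionGraph:
    edges: pd.DataFrame            # pre, post, mean_weight, n, t, p, p_corrected, significant
    input_gain: pd.DataFrame       # group, mean input weight
    output_gain: pd.DataFrame      # group, mean output weight


def connection_graph(params: RNNParams,
                     groups: dict[str, np.ndarray],
                     alpha: float = 0.05) -> ConnectionGraph:
    """Directed cluster connection graph: mean unit-to-unit weight from each
    (pre-synaptic) group to each other group, a one-sample t-test of the
    individual weights against zero per ordered pair, Holm-Sidak corrected
    across edges, plus mean input and output weights per group."""
    rows = []
    for pre_name, pre in groups.items():
        for post_name, post in groups.items():
            block = params.W_rec[np.ix_(post, pre)]
            if pre_name == post_name:  # exclude the (zero) self-connections
                w = block[~np.eye(len(pre), dtype=bool)]
            else:
                w = block.ravel()
            row = {"pre": pre_name, "post": post_name,
                   "mean_weight": float(w.mean()) if w.size else np.nan,
                   "n": int(w.size)}
            if w.size >= 2 and w.std() > 0:
                t, p = sps.ttest_1samp(w, 0.0)
                row.update(t=float(t), p=float(p))
            else:
                row.update(t=np.nan, p=np.nan, flagged=True)
            rows.append(row)
    edges = pd.DataFrame(rows)
    valid = edges.p.notna()
    p_corr = np.full(len(edges), np.nan)
    sig = np.zeros(len(edges), dtype=bool)
    if valid.any():
        rej, pc = holm_sidak(edges.p[valid].to_numpy(), alpha=alpha)
        p_corr[valid.to_numpy()] = pc
        sig[valid.to_numpy()] = rej
    edges["p_corrected"] = p_corr
    edges["significant"] = sig
    input_gain = pd.DataFrame(
        [{"group": g, "mean_input_weight": float(params.W_in[idx].mean())}
         for g, idx in groups.items()])
    output_gain = pd.DataFrame(
        [{"group": g, "mean_output_weight": float(params.W_out[:, idx].mean())}
         for g, idx in groups.items()])
    return ConnectionGraph(edges, input_gain, output_gain)


def ei_groups(params: RNNParams, solution, labels: dict[int, str],
              include: tuple[str, ...] = ("sustained", "late_accumulation",
                                          "reorienting")) -> dict[str, np.ndarray]:
    """Split each named cluster into excitatory/inhibitory unit groups."""
    out = {}
    for c, name in labels.items():
        if name not in include:
            continue
        units = solution.members(c)
        e = units[params.sign_vector[units] > 0]
        i = units[params.sign_vector[units] < 0]
        if len(e):
            out[f"{name}_E"] = e
        if len(i):
            out[f"{name}_I"] = i
    return out


# ---------------------------------------------------------------------------
# lesion experiments
# ---------------------------------------------------------------------------

def lesion_params(params: RNNParams, units: np.ndarray) -> RNNParams:
    """Disable ``units``: zero their input, recurrent (both directions) and
    output weights."""
    p = params.copy()
    units = np.asarray(units, dtype=int)
    if units.size:
        p.W_in[units, :] = 0.0
        p.W_rec[units, :] = 0.0
        p.W_rec[:, units] = 0.0
        p.W_out[:, units] = 0.0
    return p


def lesion_experiment(params: RNNParams, groups: dict[str, np.ndarray],
                      contrasts: np.ndarray | None = None,
                      n_batches: int = 50, batch: int = 50,
                      seed: int = 0) -> pd.DataFrame:
    """Lesion each group in turn (plus an intact control) and re-evaluate
    detection and discrimination per validity x contrast; valid vs invalid
    compared per contrast by a t-test across batches.

    The same ``seed`` is used for every lesion so performance differences
    are attributable to the lesion alone.
    """
    if contrasts is None:
        contrasts = contrast_levels()
    all_groups = {"intact": np.array([], dtype=int), **groups}
    frames = []
    intact = None
    for name, units in all_groups.items():
        p = lesion_params(params, units)
        trials = evaluate_performance(p, contrasts, n_batches, batch, seed=seed)
        present = trials[trials.present]
        for (c, valid), g in present.groupby(["contrast", "valid"]):
            frames.append({
                "lesion": name, "contrast": float(c),
                "validity": "valid" if valid else "invalid",
                "detection_rate": g.seen.mean(),
                "discrimination_accuracy": g.discrimination_correct.mean(),
                "n": len(g),
            })
        # valid vs invalid detection per contrast, t-test across batches
        rates = present.groupby(["contrast", "valid", "batch"]).seen.mean()
        for c in np.unique(present.contrast):
            try:
                v = rates.loc[c, True].to_numpy()
                iv = rates.loc[c, False].to_numpy()
            except KeyError:
                continue
            t, pv = sps.ttest_ind(v, iv)
            frames.append({"lesion": name, "contrast": float(c),
                           "validity": "valid_vs_invalid",
                           "detection_rate": np.nan,
                           "discrimination_accuracy": np.nan,
                           "t": float(t), "p": float(pv), "n": len(v) + len(iv)})
    table = pd.DataFrame(frames)
    # deltas vs intact
    base = table[(table.lesion == "intact")
                 & (table.validity != "valid_vs_invalid")]
    base = base.set_index(["contrast", "validity"])
    deltas = []
    for _, row in table[table.validity != "valid_vs_invalid"].iterrows():
        b = base.loc[(row.contrast, row.validity)]
        deltas.append(row.detection_rate - b.detection_rate)
    table.loc[table.validity != "valid_vs_invalid", "detection_delta"] = deltas
    return table


# ---------------------------------------------------------------------------
# similarity between model unit clusters and neural clusters
# ---------------------------------------------------------------------------

def permutation_pvalue_greater(a: np.ndarray, b: np.ndarray,
                               n_perm: int = 1000,
                               rng: np.random.Generator | None = None) -> float:
    """One-sided permutation p-value for mean(a) > mean(b), by label
    shuffling, with the add-one correction p = (1 + #{perm >= obs})/(1 + n)."""
    rng = rng or np.random.default_rng(0)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = len(a)
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    return float((1 + (diffs >= obs).sum()) / (1 + n_perm))


def similarity_test(trained: RNNParams, untrained: RNNParams,
                    rnn_cluster_units: dict[str, np.ndarray],
                    neural_trajectories: dict[str, np.ndarray],
                    neural_times_ms: np.ndarray,
                    contrast: float = 0.10, n_samples: int = 500,
                    batch: int = 50, n_perm: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Correlation of model cluster trajectories with neural cluster ones.

    ``neural_trajectories`` maps cluster name -> (2, n_times) seen/unseen
    mean activity on ``neural_times_ms`` (target-locked, cue onset to 500 ms
    post-target).  For each of ``n_samples`` batches, the model cluster's
    seen/unseen mean unit activity is resampled onto the neural time base
    and the Pearson r (averaged over the two conditions) is recorded, for
    the trained and untrained model alike; a one-sided permutation test asks
    whether the trained distribution exceeds the untrained one.
    """
    rng = np.random.default_rng(seed)
    results = {name: {"trained": [], "untrained": []}
               for name in rnn_cluster_units}
    for model_name, params in (("trained", trained), ("untrained", untrained)):
        tgt_on = params.timing.steps(params.dt_ms)[2]
        T = params.timing.n_steps(params.dt_ms)
        model_times = (np.arange(T) - tgt_on) * params.dt_ms
        for _ in range(n_samples):
            tb = make_trial_batch(rng, batch, fixed_contrast=contrast)
            _, _, R, Y = simulate_batch(params, tb,
                                        seed=int(rng.integers(2**31)))
            dec = decode_batch(params, tb, Y)
            seen = (dec.present & dec.seen).to_numpy()
            unseen = (dec.present & ~dec.seen).to_numpy()
            if not seen.any() or not unseen.any():
                continue
            for name, units in rnn_cluster_units.items():
                ref = neural_trajectories[name]
                rs = []
                for cond_sel, ref_row in zip((seen, unseen), ref):
                    traj = R[:, units][:, :, cond_sel].mean(axis=(1, 2))
                    traj = np.interp(neural_times_ms, model_times, traj)
                    if traj.std() == 0 or np.std(ref_row) == 0:
                        warnings.warn("zero-variance trajectory; sample skipped")
                        break
                    rs.append(np.corrcoef(traj, ref_row)[0, 1])
                else:
                    results[name][model_name].append(float(np.mean(rs)))
    rows = []
    for name, d in results.items():
        a = np.array(d["trained"])
        b = np.array(d["untrained"])
        p = permutation_pvalue_greater(a, b, n_perm=n_perm, rng=rng) \
            if len(a) and len(b) else np.nan
        rows.append({"cluster": name,
                     "r_trained_mean": a.mean() if len(a) else np.nan,
                     "r_untrained_mean": b.mean() if len(b) else np.nan,
                     "n_trained": len(a), "n_untrained": len(b),
                     "p_permutation": p})
    return pd.DataFrame(rows)
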