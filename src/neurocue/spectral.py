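"""Spectral preprocessing: bipolar montage, Morlet high-frequency-broadband
power, baseline normalization, downsampling and artifact rejection.

High-frequency broadband (HFBB, 70-140 Hz) power is a proxy for local
population spiking.  It is estimated with complex Morlet wavelets (7 cycles)
at 14 equally spaced center frequencies spanning the band inclusively; each
band's power is z-scored per trial against a pre-cue baseline window before
averaging across bands (which flattens the 1/f slope across the band), then
low-pass filtered and decimated onto an exact 10-ms grid aligned to target
onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps

from .task import ConfigurationError


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# raw recordings and bipolar montage
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Multichannel raw recording with electrode geometry and event markers.

    ``electrode_map`` maps contact name -> (electrode id, position index);
    contacts on one electrode have consecutive position indices.
    """

    signals: np.ndarray                      # (n_contacts, n_samples)
    sample_rate: float
    contact_names: list[str]
    electrode_map: dict[str, tuple[str, int]]
    event_times: dict[str, np.ndarray] = field(default_factory=dict)  # samples

    def __post_init__(self) -> None:
        if self.sample_rate < 512:
            raise ConfigurationError("sample_rate must be >= 512 Hz")
        if self.signals.shape[0] != len(self.contact_names):
            raise ConfigurationError("signals/contact_names length mismatch")


def bipolar_rereference(rec: RawRecording) -> RawRecording:
    """Difference adjacent contacts on each electrode (bipolar montage).

    Output contact i = input contact i - input contact i+1 within electrode;
    an electrode with n contacts yields n-1 bipoles.  Single-contact
    electrodes are skipped with a warning.
    """
    by_electrode: dict[str, list[tuple[int, str, int]]] = {}
    for idx, name in enumerate(rec.contact_names):
        elec, pos = rec.electrode_map[name]
        by_electrode.setdefault(elec, []).append((pos, name, idx))
    signals, names, emap = [], [], {}
    for elec, contacts in by_electrode.items():
        contacts.sort()
        if len(contacts) < 2:
            warnings.warn(f"electrode {elec!r} has a single contact; skipped")
            continue
        for (p0, n0, i0), (p1, n1, i1) in zip(contacts[:-1], contacts[1:]):
            signals.append(rec.signals[i0] - rec.signals[i1])
            name = f"{n0}-{n1}"
            names.append(name)
            emap[name] = (elec, p0)   # bipole indexed by the leading contact
    if not signals:
        raise PipelineError("no electrode had >= 2 contacts")
    return RawRecording(np.stack(signals), rec.sample_rate, names, emap,
                        rec.event_times)


# ---------------------------------------------------------------------------
# Morlet wavelet power
# ---------------------------------------------------------------------------

def morlet_wavelet(freq_hz: float, sample_rate: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet (Gaussian-windowed exponential), L2-normalized."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    wave = np.exp(2j * np.pi * freq_hz * t) * np.exp(-t**2 / (2 * sigma_t**2))
    return wave / np.sqrt(np.sum(np.abs(wave) ** 2))


def morlet_power(x: np.ndarray, sample_rate: float, freqs_hz: np.ndarray,
                 n_cycles: float = 7.0) -> np.ndarray:
    """Time-resolved wavelet power of ``x`` (..., n_samples) at each frequency.

    Returns an array shaped (n_freqs, ..., n_samples).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty((len(freqs_hz),) + x.shape)
    for i, f in enumerate(freqs_hz):
        w = morlet_wavelet(f, sample_rate, n_cycles)
        conv = spsig.fftconvolve(x, w.reshape((1,) * (x.ndim - 1) + (-1,)),
                                 mode="same", axes=-1)
        out[i] = np.abs(conv) ** 2
    return out


def band_center_frequencies(band: tuple[float, float] = (70.0, 140.0),
                            n_bands: int = 14) -> np.ndarray:
    """Equally spaced center frequencies spanning ``band`` inclusively."""
    return np.linspace(band[0], band[1], n_bands)


def hfbb_power(epochs: np.ndarray, sample_rate: float, epoch_start_s: float,
               band: tuple[float, float] = (70.0, 140.0), n_bands: int = 14,
               n_cycles: float = 7.0,
               baseline_s: tuple[float, float] = (-0.5, -0.3),
               out_rate: float = 100.0,
               out_window_s: tuple[float, float] = (-0.3, 0.5)) -> tuple[np.ndarray, np.ndarray]:
    """High-frequency broadband power of target-locked epochs.

    ``epochs`` is (n_trials, n_samples) for one contact (or (n_samples,));
    times are relative to target onset with the first sample at
    ``epoch_start_s``.  Per band, power is z-scored per trial against the
    baseline window (the 200 ms before cue onset by default), averaged
    across the 14 bands, low-pass filtered and sampled on an exact
    1/out_rate grid over ``out_window_s``.

    Returns ``(times_ms, power)`` with power shaped (n_trials, n_out_times).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_samples = epochs.shape[-1]
    if band[1] >= sample_rate / 2:
        raise ConfigurationError("band extends above Nyquist frequency")
    t = epoch_start_s + np.arange(n_samples) / sample_rate
    base = (t >= baseline_s[0]) & (t < baseline_s[1])
    if not base.any() or baseline_s[0] < t[0] or baseline_s[1] > t[-1]:
        raise ConfigurationError("baseline window outside epoch")

    freqs = band_center_frequencies(band, n_bands)
    power = morlet_power(epochs, sample_rate, freqs, n_cycles)  # (F, trials, S)
    mu = power[..., base].mean(axis=-1, keepdims=True)
    sd = power[..., base].std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (power - mu) / sd
    hfbb = z.mean(axis=0)                                       # (trials, S)

    # anti-alias filter then sample on the exact out_rate grid
    sos = spsig.butter(4, 0.4 * out_rate, btype="low", fs=sample_rate, output="sos")
    smooth = spsig.sosfiltfilt(sos, hfbb, axis=-1)
    out_times = np.arange(round(out_window_s[0] * out_rate),
                          round(out_window_s[1] * out_rate) + 1) / out_rate
    if out_times[0] < t[0] or out_times[-1] > t[-1]:
        raise ConfigurationError("output window outside epoch")
    out = np.stack([np.interp(out_times, t, row) for row in smooth])
    return out_times * 1000.0, out


# ---------------------------------------------------------------------------
# threshold-based artifact rejection
# ---------------------------------------------------------------------------

@dataclass
class ArtifactThresholds:
    """Robust-deviation thresholds (in SDs above the per-contact median of the
    per-trial metric) for the four rejection criteria."""

    max_abs: float = 8.0
    z: float = 8.0
    variance: float = 5.0
    kurtosis: float = 5.0

    def __post_init__(self) -> None:
        if min(self.max_abs, self.z, self.variance, self.kurtosis) <= 0:
            raise ConfigurationError("thresholds must be positive")


def artifact_reject(epochs: np.ndarray,
                    thresholds: ArtifactThresholds | None = None,
                    contact_reject_frac: float = 0.3
                    ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Reject trials/contacts with excessive maximal signal, z value,
    variance or kurtosis of the signal distribution.

    ``epochs`` is (n_contacts, n_trials, n_samples).  A trial is rejected
    when any per-trial metric deviates from the contact's median metric by
    more than the threshold (in units of the metric's SD across trials); a
    contact is rejected when more than ``contact_reject_frac`` of its trials
    are.  Returns (trial_keep_mask [contacts x trials], contact_keep_mask,
    rejection log).
    """
    thresholds = thresholds or ArtifactThresholds()
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[None]
    n_c, n_t, _ = epochs.shape
    mu = epochs.mean(axis=(1, 2), keepdims=True)
    sd = epochs.std(axis=(1, 2), keepdims=True)
    metrics = {
        "max_abs": np.abs(epochs).max(axis=-1),
        "z": np.abs((epochs - mu) / sd).max(axis=-1),
        "variance": epochs.var(axis=-1),
        "kurtosis": sps.kurtosis(epochs, axis=-1),
    }
    keep = np.ones((n_c, n_t), dtype=bool)
    log_rows = []
    for name, m in metrics.items():
        thr = getattr(thresholds, name)
        med = np.median(m, axis=1, keepdims=True)
        # robust spread (scaled MAD) so an outlier cannot mask itself
        spread = 1.4826 * np.median(np.abs(m - med), axis=1, keepdims=True)
        spread[spread == 0] = np.inf
        bad = (m - med) / spread > thr
        for c, tr in zip(*np.nonzero(bad)):
            log_rows.append({"contact": int(c), "trial": int(tr),
                             "reason": name, "value": float(m[c, tr])})
        keep &= ~bad
    contact_keep = keep.mean(axis=1) >= (1.0 - contact_reject_frac)
    if not keep.any():
        raise PipelineError(
            "all trials rejected; check thresholds "
            f"(metrics medians: { {k: float(np.median(v)) for k, v in metrics.items()} })")
    return keep, contact_keep, pd.DataFrame(log_rows)
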