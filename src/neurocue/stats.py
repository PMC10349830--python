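"""Time-resolved factorial statistics on cluster activity.

The observational unit for cluster-level tests is the contact (or RNN unit):
trials are first averaged within contact x condition, and the factorial
ANOVA is computed across contacts at every timepoint.  Designs are balanced
full factorials (every contact contributes one value per condition cell), so
sums of squares are computed from marginal means by Moebius inversion; they
partition exactly (SS_total = sum of effect SS + SS_error) and are vectorized
over the time axis.  Familywise error over timepoints is controlled with the
step-down Holm-Bonferroni procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps



class DegenerateDesignError(ValueError):
    """A factor has fewer than two levels or a cell is empty."""


# ---------------------------------------------------------------------------
# Balanced N-way ANOVA, vectorized over trailing axes
# ---------------------------------------------------------------------------

def _anova_decompose(data: np.ndarray, n_factors: int):
    """Sums of squares per effect term for a balanced full factorial.

    ``data`` has shape (n_obs, l_1, ..., l_k, *extra); replicates vary along
    axis 0 and any trailing axes are carried through (e.g. time).  Returns
    (terms, SS, df, SS_error, df_error) where each SS has the extra shape.
    """
    if np.isnan(data).any():
        raise DegenerateDesignError("design contains empty cells (NaN)")
    n_obs = data.shape[0]
    levels = data.shape[1:1 + n_factors]
    if any(l < 2 for l in levels):
        bad = [i for i, l in enumerate(levels) if l < 2]
        raise DegenerateDesignError(f"factor(s) {bad} have fewer than two levels")
    extra_shape = data.shape[1 + n_factors:]
    cell_mean = data.mean(axis=0)                       # (levels..., extra)
    grand = cell_mean.mean(axis=tuple(range(n_factors)), keepdims=True)

    # marginal means over every subset of factors (keepdims for broadcasting)
    factor_axes = tuple(range(n_factors))
    marg: dict[frozenset, np.ndarray] = {}
    for r in range(n_factors + 1):
        for subset in itertools.combinations(factor_axes, r):
            s = frozenset(subset)
            collapse = tuple(a for a in factor_axes if a not in s)
            marg[s] = (cell_mean.mean(axis=collapse, keepdims=True)
                       if collapse else cell_mean)

    terms, SS, df = [], [], []
    for r in range(1, n_factors + 1):
        for subset in itertools.combinations(factor_axes, r):
            s = frozenset(subset)
            effect = sum(((-1) ** (len(s) - len(t))) * marg[t] for t in _subsets(s))
            full = np.broadcast_to(effect, cell_mean.shape)
            SS.append(n_obs * (full ** 2).sum(axis=factor_axes))
            terms.append(tuple(subset))
            df.append(int(np.prod([levels[a] - 1 for a in subset])))

    SS_err = ((data - cell_mean) ** 2).sum(axis=(0, *[a + 1 for a in factor_axes]))
    df_err = (n_obs - 1) * int(np.prod(levels))
    if df_err <= 0:
        raise DegenerateDesignError("no residual degrees of freedom (n_obs < 2)")
    assert SS_err.shape == extra_shape
    return terms, SS, df, SS_err, df_err


def _subsets(s: frozenset):
    items = sorted(s)
    for r in range(len(items) + 1):
        for c in itertools.combinations(items, r):
            yield frozenset(c)


def _term_label(term: tuple[int, ...], names: tuple[str, ...]) -> str:
    return ":".join(names[a] for a in term)


def factorial_anova(data: np.ndarray,
                    factor_names: tuple[str, ...]) -> pd.DataFrame:
    """Balanced N-way ANOVA; ``data`` shaped (n_obs, levels_1, ..., levels_k).

    Returns a tidy table with one row per effect term: F, p, partial eta
    squared, and degrees of freedom.
    """
    data = np.asarray(data, dtype=float)
    k = len(factor_names)
    terms, SS, df, SS_err, df_err = _anova_decompose(data, k)
    rows = []
    for term, ss, d in zip(terms, SS, df):
        F = (ss / d) / (SS_err / df_err)
        p = sps.f.sf(F, d, df_err)
        rows.append({
            "term": _term_label(term, tuple(factor_names)),
            "df": d, "df_error": df_err,
            "F": float(F), "p": float(p),
            "partial_eta2": float(ss / (ss + SS_err)),
        })
    return pd.DataFrame(rows)


@dataclass
class TimeResolvedStats:
    """Per-timepoint F/p/effect-size per term with a corrected significance mask."""

    times_ms: np.ndarray
    terms: list[str]
    F: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    p_corrected: dict[str, np.ndarray]
    partial_eta2: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]
    alpha: float = 0.05
    correction: str = "holm"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term in self.terms:
            for i, t in enumerate(self.times_ms):
                rows.append({
                    "term": term, "time_ms": float(t),
                    "F": float(self.F[term][i]), "p": float(self.p[term][i]),
                    "p_corrected": float(self.p_corrected[term][i]),
                    "eta2": float(self.partial_eta2[term][i]),
                    "significant": bool(self.significant[term][i]),
                })
        return pd.DataFrame(rows)


def factorial_anova_timecourse(data: np.ndarray, times_ms: np.ndarray,
                               factor_names: tuple[str, ...],
                               alpha: float = 0.05) -> TimeResolvedStats:
    """Time-resolved balanced N-way ANOVA across contacts.

    ``data`` has shape (n_contacts, levels_1, ..., levels_k, n_times): one
    trial-averaged value per contact x condition cell x timepoint.  The Holm
    correction is applied per term across all timepoints.
    """
    data = np.asarray(data, dtype=float)
    k = len(factor_names)
    if data.ndim != k + 2:
        raise ValueError("data must be (n_obs, *levels, n_times)")
    terms, SS, df, SS_err, df_err = _anova_decompose(data, k)
    out_F, out_p, out_pc, out_eta, out_sig = {}, {}, {}, {}, {}
    labels = []
    for term, ss, d in zip(terms, SS, df):
        label = _term_label(term, tuple(factor_names))
        labels.append(label)
        F = (ss / d) / (SS_err / df_err)
        p = sps.f.sf(F, d, df_err)
        sig, p_corr = holm_bonferroni(p, alpha=alpha)
        out_F[label], out_p[label], out_pc[label] = F, p, p_corr
        out_eta[label] = ss / (ss + SS_err)
        out_sig[label] = sig
    return TimeResolvedStats(np.asarray(times_ms, dtype=float), labels,
                             out_F, out_p, out_pc, out_eta, out_sig, alpha)


# ---------------------------------------------------------------------------
# Multiple-comparison corrections
# ---------------------------------------------------------------------------

def _stepdown(p_values, alpha, adjust):
    # direct step-down implementation (statsmodels' multipletests forces a
    # gc.collect per call, which dominates time-resolved loops)
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(m)
    adj_sorted = np.minimum(np.maximum.accumulate(adjust(p[order], m, ranks)),
                            1.0)
    p_corr = np.empty(m)
    p_corr[order] = adj_sorted
    return p_corr < alpha, p_corr


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Step-down Holm-Bonferroni procedure.

    Returns ``(reject_mask, corrected_p)``; the mask is true only where the
    corrected p-value is below ``alpha``.  Empty input yields empty arrays.
    """
    return _stepdown(p_values, alpha, lambda p, m, i: (m - i) * p)


def holm_sidak(p_values, alpha: float = 0.05):
    """Step-down Holm-Sidak procedure (slightly less conservative than Holm)."""
    return _stepdown(p_values, alpha,
                     lambda p, m, i: 1.0 - (1.0 - p) ** (m - i))


# ---------------------------------------------------------------------------
# Interaction effect-size gradient across ordered clusters
# ---------------------------------------------------------------------------

@dataclass
class EffectGradient:
    """Cohen's d of the attention x report interaction per cluster, ordered,
    with a one-way ANOVA and a linear polynomial contrast across clusters."""

    cluster_names: list[str]
    d_timecourse: dict[str, np.ndarray]
    window_d: dict[str, float]
    per_contact_window_contrast: dict[str, np.ndarray] = field(repr=False, default=None)
    anova_F: float = np.nan
    anova_p: float = np.nan
    linear_t: float = np.nan
    linear_p: float = np.nan


def interaction_contrast(cond_means: np.ndarray) -> np.ndarray:
    """Per-contact interaction contrast (seen valid - unseen valid) -
    (seen invalid - unseen invalid).

    ``cond_means`` has shape (n_contacts, 2 validity [invalid, valid],
    2 report [unseen, seen], n_times).
    """
    sv = cond_means[:, 1, 1]
    uv = cond_means[:, 1, 0]
    si = cond_means[:, 0, 1]
    ui = cond_means[:, 0, 0]
    return (sv - uv) - (si - ui)


def cohens_d_1samp(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """One-sample Cohen's d: mean / SD (ddof=1) along ``axis``."""
    v = np.asarray(values, dtype=float)
    return v.mean(axis=axis) / v.std(axis=axis, ddof=1)


def interaction_effectsize_gradient(
        clusters: dict[str, np.ndarray], windows_ms: dict[str, tuple[float, float]],
        times_ms: np.ndarray, order: list[str] | None = None) -> EffectGradient:
    """Effect-size gradient of the validity x report interaction across an
    ordered list of clusters.

    ``clusters`` maps cluster name -> condition means (n_contacts, 2, 2,
    n_times) with axes (contact, validity [invalid, valid], report [unseen,
    seen], time).  Each cluster's interaction contrast is averaged over its
    significance window; a one-way ANOVA plus a linear polynomial contrast
    (equally spaced weights, e.g. -1/0/+1 for three clusters) tests for a
    monotone gradient across the stated order.
    """
    order = order or list(clusters)
    if len(order) < 3:
        raise ValueError("need >= 3 clusters for a gradient")
    times_ms = np.asarray(times_ms, dtype=float)
    d_tc, window_d, groups = {}, {}, {}
    kept = []
    for name in order:
        data = clusters[name]
        if data.shape[0] < 2:
            import warnings
            warnings.warn(f"cluster {name!r} has <2 contacts; excluded")
            continue
        contrast = interaction_contrast(data)            # (n_contacts, T)
        d_tc[name] = cohens_d_1samp(contrast, axis=0)
        lo, hi = windows_ms[name]
        sel = (times_ms >= lo) & (times_ms <= hi)
        vals = contrast[:, sel].mean(axis=1)             # per-contact window mean
        groups[name] = vals
        window_d[name] = float(cohens_d_1samp(vals))
        kept.append(name)

    arrays = [groups[n] for n in kept]
    F, p = sps.f_oneway(*arrays)
    # linear polynomial contrast with equally spaced centered weights
    w = np.arange(len(kept), dtype=float)
    w -= w.mean()
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_err = int(ns.sum() - len(kept))
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err
    est = float(np.dot(w, means))
    se = float(np.sqrt(mse * np.sum(w ** 2 / ns)))
    t = est / se
    p_lin = float(sps.t.sf(np.abs(t), df_err) * 2)
    return EffectGradient(kept, d_tc, window_d, groups,
                          float(F), float(p), float(t), p_lin)


# ---------------------------------------------------------------------------
# RT-quantile bin analysis
# ---------------------------------------------------------------------------

@dataclass
class RTBinResult:
    times_ms: np.ndarray
    bin_means: np.ndarray            # (n_bins, n_times)
    bin_mean_rt: np.ndarray          # (n_bins,)
    anova_F: np.ndarray              # per timepoint, across bins
    anova_p: np.ndarray
    anova_significant: np.ndarray    # Holm-corrected mask
    fastslow_t: np.ndarray           # slow half minus fast half, per timepoint
    fastslow_p: np.ndarray
    fastslow_significant: np.ndarray


def rt_quantile_bins(rts_ms: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Assign trials to ``n_bins`` equal-count quantile bins by RT.

    Ties are broken by a stable sort on trial index; bin edges are by rank so
    counts differ by at most one.
    """
    rts = np.asarray(rts_ms, dtype=float)
    if len(rts) < n_bins:
        raise ValueError(f"need >= {n_bins} trials for {n_bins} bins")
    order = np.argsort(rts, kind="stable")
    ranks = np.empty(len(rts), dtype=int)
    ranks[order] = np.arange(len(rts))
    return (ranks * n_bins) // len(rts)


def rt_bin_analysis(activity: np.ndarray, rts_ms: np.ndarray,
                    times_ms: np.ndarray, n_bins: int = 20,
                    window_ms: tuple[float, float] = (0.0, 1000.0),
                    alpha: float = 0.05) -> RTBinResult:
    """Relate single-trial activity (trials x times, trials pooled across
    conditions and contacts) to discrimination RT.

    Trials are binned into ``n_bins`` RT quantiles; a one-way ANOVA across
    bins is run per timepoint inside ``window_ms``, and the slowest half of
    bins is compared with the fastest half by a two-sample t-test, both
    Holm-corrected over timepoints.
    """
    activity = np.asarray(activity, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    times = times_ms[sel]
    act = activity[:, sel]
    bins = rt_quantile_bins(rts_ms, n_bins)
    bin_means = np.stack([act[bins == b].mean(axis=0) for b in range(n_bins)])
    bin_rt = np.array([np.mean(np.asarray(rts_ms)[bins == b]) for b in range(n_bins)])

    groups = [act[bins == b] for b in range(n_bins)]
    F, p = sps.f_oneway(*groups, axis=0)
    sig, _ = holm_bonferroni(p, alpha=alpha)

    fast = act[bins < n_bins // 2]
    slow = act[bins >= n_bins // 2]
    t, pt = sps.ttest_ind(slow, fast, axis=0)
    sig_t, _ = holm_bonferroni(pt, alpha=alpha)
    return RTBinResult(times, bin_means, bin_rt, F, p, sig,
                       t, pt, sig_t)
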