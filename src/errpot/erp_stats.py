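"""Condition-wise ERP summaries and nonparametric statistics.

Grand averages of correct vs incorrect feedback trials, their difference
wave, a per-timepoint Kruskal-Wallis p-value series (trials pooled
across subjects), and an exact two-tailed Wilcoxon signed-rank test for
paired pipeline comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import RawEpochSet

__all__ = [
    "ERPStatsResult",
    "grand_average",
    "kruskal_wallis_series",
    "wilcoxon_signed_rank",
    "erp_contrast",
    "plot_erp_contrast",
]


@dataclass
class ERPStatsResult:
    """ERP contrast at one channel: averages, difference wave, p-series."""

    channel: str
    times: np.ndarray
    grand_avg_correct: np.ndarray
    grand_avg_incorrect: np.ndarray
    difference_wave: np.ndarray
    p_series: np.ndarray
    alpha: float = 0.05
    n_correct: int = 0
    n_incorrect: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time": self.times,
            "mean_correct": self.grand_avg_correct,
            "mean_incorrect": self.grand_avg_incorrect,
            "difference": self.difference_wave,
            "p": self.p_series,
        })


def _collect(epoch_sets: list[RawEpochSet], channel: str,
             condition: str) -> np.ndarray:
    """Stack all trials of one condition at one channel (trials x samples)."""
    if condition not in ("correct", "incorrect"):
        raise ValueError(f"unknown condition {condition!r}")
    chunks = []
    for es in epoch_sets:
        ci = list(es.channel_names).index(channel) \
            if channel in es.channel_names else None
        if ci is None:
            raise ValueError(f"channel {channel!r} absent from {es.subject_id}")
        mask = np.asarray(es.correctness) == condition
        if mask.any():
            chunks.append(es.data[mask, ci, :])
    if not chunks:
        raise ValueError(f"no {condition!r} trials found")
    return np.vstack(chunks)


def grand_average(epoch_sets: list[RawEpochSet] | RawEpochSet, channel: str,
                  condition: str) -> tuple[np.ndarray, int]:
    """Mean over all matching trials of all subjects; returns (series, n)."""
    if isinstance(epoch_sets, RawEpochSet):
        epoch_sets = [epoch_sets]
    trials = _collect(epoch_sets, channel, condition)
    return trials.mean(axis=0), trials.shape[0]


def kruskal_wallis_series(correct: np.ndarray,
                          incorrect: np.ndarray) -> np.ndarray:
    """Per-timepoint two-group Kruskal-Wallis p-values (tie-corrected).

    Inputs are trials x samples arrays for each condition. Timepoints
    where every value is tied are degenerate and reported as p = 1.
    """
    correct = np.atleast_2d(correct)
    incorrect = np.atleast_2d(incorrect)
    if correct.shape[1] != incorrect.shape[1]:
        raise ValueError("conditions must share the time axis")
    if correct.shape[0] < 2 or incorrect.shape[0] < 2:
        raise ValueError("need >= 2 trials per condition")
    p = np.empty(correct.shape[1])
    for t in range(correct.shape[1]):
        a, b = correct[:, t], incorrect[:, t]
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"all values tied at timepoint {t}; p set to 1",
                          stacklevel=2)
            p[t] = 1.0
        else:
            p[t] = stats.kruskal(a, b).pvalue
    return p


def _exact_signed_rank_p(w_stat: float, scaled_ranks: np.ndarray) -> float:
    """Two-tailed exact p by dynamic programming over sign assignments.

    ``scaled_ranks`` are integer (midranks doubled to clear .5 ties).
    Enumerates the distribution of W+ = sum of positively signed ranks
    under the null that each sign is +/- with probability 1/2.
    """
    total = int(scaled_ranks.sum())
    # counts[s] = number of sign assignments with W+ == s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        counts[r:] = counts[r:] + counts[:-r or None]
    counts /= counts.sum()
    mean = total / 2.0
    dev = abs(w_stat - mean)
    lo = mean - dev + 1e-9
    hi = mean + dev - 1e-9
    s = np.arange(total + 1)
    p = counts[(s <= lo) | (s >= hi)].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is enumerated for n <= 25 remaining pairs (midranks for
    tied magnitudes), with a normal approximation beyond. All-zero
    differences are degenerate and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= 25:
        scaled = np.round(2 * ranks).astype(int)  # midranks -> integers
        return _exact_signed_rank_p(2 * w_plus, scaled)
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    tie_term = sum((cnt**3 - cnt) for cnt in
                   np.unique(ranks, return_counts=True)[1])
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """FDR-adjusted p-values (optional; the default display is raw p)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p), method="fdr_bh")[1]


def erp_contrast(epoch_sets: list[RawEpochSet], channel: str,
                 alpha: float = 0.05,
                 per_subject: bool = False) -> ERPStatsResult:
    """Grand averages, difference wave and KW p-series at one channel.

    With ``per_subject`` the statistical unit is the subject mean per
    condition rather than the pooled single trials.
    """
    if per_subject:
        correct = np.vstack([_collect([es], channel, "correct").mean(0)
                             for es in epoch_sets])
        incorrect = np.vstack([_collect([es], channel, "incorrect").mean(0)
                               for es in epoch_sets])
    else:
        correct = _collect(epoch_sets, channel, "correct")
        incorrect = _collect(epoch_sets, channel, "incorrect")
    times = epoch_sets[0].times
    ga_c = correct.mean(axis=0)
    ga_i = incorrect.mean(axis=0)
    return ERPStatsResult(
        channel=channel, times=times,
        grand_avg_correct=ga_c, grand_avg_incorrect=ga_i,
        difference_wave=ga_i - ga_c,
        p_series=kruskal_wallis_series(correct, incorrect),
        alpha=alpha, n_correct=correct.shape[0], n_incorrect=incorrect.shape[0],
    )


def plot_erp_contrast(result: ERPStatsResult, display_onset: float = 0.5,
                      ax=None):
    """Averages + difference + p trace with the significance line marked."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(result.times, result.grand_avg_correct, color="tab:blue",
            label="correct")
    ax.plot(result.times, result.grand_avg_incorrect, color="tab:red",
            label="incorrect")
    ax.plot(result.times, result.difference_wave, color="black",
            label="incorrect - correct")
    ax.axvline(display_onset, linestyle=":", color="gray",
               label="feedback display")
    ax.set_xlabel("time from feedback-period onset (s)")
    ax.set_ylabel("amplitude (uV)")
    ax2 = ax.twinx()
    ax2.plot(result.times, result.p_series, color="0.6", alpha=0.7)
    ax2.axhline(result.alpha, linestyle="--", color="black", linewidth=0.8)
    ax2.set_ylabel("Kruskal-Wallis p")
    ax.set_title(f"{result.channel}")
    ax.legend(loc="upper left", fontsize=8)
    return ax
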