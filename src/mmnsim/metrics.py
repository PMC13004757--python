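"""Quantification of network activity.

Deviance index, the model-acceptance test, Gaussian-smoothed rate
curves, interspike-interval burst detection, entrainment scoring and
rank-sum group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .core.record import SpikeRecord
from .stimuli import StimulusProtocol

__all__ = [
    "DevianceResult",
    "Burst",
    "deviance_index",
    "acceptance_test",
    "rate_curve",
    "detect_bursts",
    "score_entrainment",
    "group_compare",
    "INDEX_WINDOW",
    "RESPONSE_WINDOW",
]

#: peristimulus window (relative to the expected onset) used for the
#: deviance index: 150 ms before to 350 ms after the expected onset.
INDEX_WINDOW = (-150.0, 350.0)
#: alternative 0.5-s window used for response totals: 50 ms before to
#: 450 ms after the expected onset.
RESPONSE_WINDOW = (-50.0, 450.0)


@dataclass
class DevianceResult:
    f_deviant: float           # spikes/s (population total over the window)
    f_standard: float
    f_dd: float
    n_deviant_trials: int
    n_standard_trials: int
    per_trial: Dict = field(default_factory=dict)


def _trial_classes(
    protocol: StimulusProtocol, skip_warmup: bool
) -> Tuple[List[float], List[float]]:
    start = protocol.n_warmup_trials if skip_warmup else 0
    deviants, standards = [], []
    for ev in protocol.events[start:]:
        (deviants if ev.is_deviant_trial else standards).append(ev.slot_onset)
    return deviants, standards


def _window_counts(
    times: np.ndarray, onsets: Sequence[float], window: Tuple[float, float]
) -> List[float]:
    counts = []
    for onset in onsets:
        lo, hi = onset + window[0], onset + window[1]
        if lo < 0:
            warnings.warn(
                f"trial at {onset} ms excluded: window extends before t=0",
                stacklevel=3,
            )
            continue
        counts.append(float(np.count_nonzero((times >= lo) & (times < hi))))
    return counts


def deviance_index(
    record: SpikeRecord,
    protocol: StimulusProtocol,
    population: str = "EO",
    window: Tuple[float, float] = INDEX_WINDOW,
    skip_warmup: bool = True,
) -> DevianceResult:
    """Deviant-minus-standard rate difference of the output population.

    Per trial class, spikes of ``population`` in the half-open window
    ``[onset + window[0], onset + window[1])`` are counted, divided by
    the window length, and averaged over trials; the index is the
    difference of the two class rates.
    """
    times = record.pop_spike_times(population)
    span_s = (window[1] - window[0]) / 1000.0
    dev_onsets, std_onsets = _trial_classes(protocol, skip_warmup)
    dev_counts = _window_counts(times, dev_onsets, window)
    std_counts = _window_counts(times, std_onsets, window)
    f_dev = float(np.mean(dev_counts)) / span_s if dev_counts else 0.0
    f_std = float(np.mean(std_counts)) / span_s if std_counts else 0.0
    return DevianceResult(
        f_deviant=f_dev,
        f_standard=f_std,
        f_dd=f_dev - f_std,
        n_deviant_trials=len(dev_counts),
        n_standard_trials=len(std_counts),
        per_trial={"deviant": dev_counts, "standard": std_counts},
    )


def acceptance_test(
    record: SpikeRecord,
    protocol: StimulusProtocol,
    n_output_neurons: int,
    population: str = "EO",
    window: Tuple[float, float] = INDEX_WINDOW,
    skip_warmup: bool = True,
    frac_threshold: float = 0.8,
    ratio_threshold: float = 6.0,
) -> Tuple[bool, Dict]:
    """Model-acceptance criterion.

    Accepted iff (a) at least 80% of the output neurons fire one or more
    spikes in the deviant window (averaged across scored deviant trials)
    and (b) deviant-evoked spikes are at least six times the average
    standard-evoked spike count.  Both thresholds are inclusive.
    """
    times, neurons = record.population(population)
    dev_onsets, std_onsets = _trial_classes(protocol, skip_warmup)

    fracs = []
    dev_counts = []
    for onset in dev_onsets:
        lo, hi = onset + window[0], onset + window[1]
        if lo < 0:
            continue
        sel = (times >= lo) & (times < hi)
        fracs.append(len(np.unique(neurons[sel])) / n_output_neurons)
        dev_counts.append(float(np.count_nonzero(sel)))
    std_counts = _window_counts(times, std_onsets, window)

    frac = float(np.mean(fracs)) if fracs else 0.0
    mean_dev = float(np.mean(dev_counts)) if dev_counts else 0.0
    mean_std = float(np.mean(std_counts)) if std_counts else 0.0
    if mean_dev == 0.0:
        ratio = 0.0
    elif mean_std == 0.0:
        ratio = np.inf
    else:
        ratio = mean_dev / mean_std
    accepted = (frac >= frac_threshold) and (ratio >= ratio_threshold)
    return accepted, {
        "fraction_firing": frac,
        "deviant_spikes": mean_dev,
        "standard_spikes": mean_std,
        "ratio": ratio,
    }


def rate_curve(
    spike_times: Union[SpikeRecord, np.ndarray],
    sigma: float = 25.0,
    t_start: float = 0.0,
    t_end: Optional[float] = None,
    dt: float = 1.0,
    population: str = "EO",
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed firing-rate curve.

    Each spike contributes a normal kernel with SD ``sigma`` (ms) whose
    integral is one spike; the returned curve is in spikes/s, so that
    ``trapz(y, t) / 1000 == n_spikes`` up to edge truncation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if isinstance(spike_times, SpikeRecord):
        t_end = spike_times.t_end if t_end is None else t_end
        spike_times = spike_times.pop_spike_times(population)
    spike_times = np.asarray(spike_times, dtype=float)
    if t_end is None:
        t_end = float(spike_times.max()) + 5 * sigma if spike_times.size else 1000.0
    t = np.arange(t_start, t_end + dt / 2, dt)
    y = np.zeros_like(t)
    norm = 1000.0 / (sigma * np.sqrt(2.0 * np.pi))
    for ts in spike_times:
        lo = np.searchsorted(t, ts - 6 * sigma)
        hi = np.searchsorted(t, ts + 6 * sigma)
        y[lo:hi] += norm * np.exp(-0.5 * ((t[lo:hi] - ts) / sigma) ** 2)
    return t, y


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_bursts(spike_times: Sequence[float], max_isi: float = 50.0) -> List[Burst]:
    """Split a sorted spike train into maximal runs whose consecutive
    interspike intervals are all <= ``max_isi`` (boundary inclusive)."""
    times = np.asarray(spike_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    bursts: List[Burst] = []
    if times.size == 0:
        return bursts
    start = 0
    for i in range(1, len(times)):
        if times[i] - times[i - 1] > max_isi:
            bursts.append(Burst(times[start], times[i - 1], i - start))
            start = i
    bursts.append(Burst(times[start], times[-1], len(times) - start))
    return bursts


def score_entrainment(
    spike_times: Union[SpikeRecord, np.ndarray],
    cessation_time: float,
    rate: float = 2.0,
    mode: str = "relative",
    max_isi: float = 50.0,
    max_burst_ms: float = 75.0,
    min_cycle: float = 450.0,
    max_cycle: float = 550.0,
    n_cycles: int = 4,
    expected_half_width: float = 60.0,
    unexpected_end: float = 440.0,
    min_spikes: int = 5,
    population: str = "base",
) -> Dict:
    """Score post-cessation rhythmicity of the base population.

    ``relative`` mode counts, starting from the last pre-cessation
    burst, post-cessation bursts whose first spike falls no earlier than
    ``min_cycle`` ms and whose last spike falls no later than
    ``max_cycle`` ms after the previous burst's last spike.  Each burst
    is judged against its immediate predecessor, so one ill-timed cycle
    does not invalidate later well-timed ones; any burst longer than
    ``max_burst_ms`` aborts the count.

    ``absolute`` mode checks fixed windows anchored at the cessation
    time: for each cycle i in 0..n_cycles-1, the "expected" window is
    ``cessation + i*T +- expected_half_width`` and the "unexpected"
    region is ``(cessation + i*T + expected_half_width,
    cessation + i*T + unexpected_end]``; a window is hit when at least
    ``min_spikes`` spikes fall inside.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    if isinstance(spike_times, SpikeRecord):
        spike_times = spike_times.pop_spike_times(population)
    times = np.sort(np.asarray(spike_times, dtype=float))
    T = 1000.0 / rate

    if mode == "absolute":
        expected, unexpected = [], []
        for i in range(n_cycles):
            c = cessation_time + i * T
            n_exp = np.count_nonzero(
                (times > c - expected_half_width) & (times <= c + expected_half_width)
            )
            n_unexp = np.count_nonzero(
                (times > c + expected_half_width) & (times <= c + unexpected_end)
            )
            expected.append(n_exp >= min_spikes)
            unexpected.append(n_unexp >= min_spikes)
        return {
            "expected": expected,
            "unexpected": unexpected,
            "n_expected_hits": int(np.sum(expected)),
            "n_unexpected_hits": int(np.sum(unexpected)),
        }

    bursts = detect_bursts(times, max_isi=max_isi)
    # reference burst: the last one starting at least half a period
    # before the cessation time (i.e. the final stimulus-evoked cycle)
    ref_idx = None
    for i, b in enumerate(bursts):
        if b.start <= cessation_time - T / 2:
            ref_idx = i
    n_good = 0
    cycle_lengths: List[float] = []
    if ref_idx is not None:
        prev_last = bursts[ref_idx].end
        for b in bursts[ref_idx + 1:]:
            if b.duration > max_burst_ms:
                break
            gap_first = b.start - prev_last
            gap_last = b.end - prev_last
            if gap_first >= min_cycle and gap_last <= max_cycle:
                n_good += 1
                cycle_lengths.append(gap_first)
            prev_last = b.end
    return {
        "n_good_cycles": n_good,
        "cycle_lengths": cycle_lengths,
        "n_bursts": len(bursts),
    }


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_tests: int = 4,
    alpha: float = 0.05,
) -> Tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum test (normal approximation with tie
    correction) with Bonferroni-corrected significance over ``n_tests``
    comparisons."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, False
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return p, p < alpha / n_tests
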