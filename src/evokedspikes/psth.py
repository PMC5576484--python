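"""Trial-aligned PSTHs and detection of evoked excitatory/inhibitory epochs.

The analysis follows the classic threshold-and-run convention for single-unit
stimulation experiments: spikes are binned at 5 ms relative to each stimulus,
summed over trials, and baseline statistics (mean and SD of counts per bin) are
taken over the 500-ms pre-stimulus epoch. An excitatory epoch begins at the
first of ``run_length`` (default 5) consecutive bins each exceeding
``mean + 2 SD`` and ends at the first subsequent run of bins back within that
bound; an inhibitory epoch uses the symmetric rule with a ``30% of baseline
mean`` floor. Response magnitude is the epoch spike count minus the
baseline-expected count for the same number of bins (reported as a positive
deficit for inhibition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .spike_data import SpikeTrain, StimulusProtocol

__all__ = [
    "PSTH",
    "BaselineStats",
    "EvokedResponse",
    "DetectionConfig",
    "build_psth",
    "baseline_stats",
    "detect_excitation",
    "detect_inhibition",
    "excitation_magnitude",
    "inhibition_magnitude",
    "classify_evoked",
]

log = logging.getLogger(__name__)

ResponseKind = Literal["excitation", "inhibition", "none"]
OnsetRule = Literal["each_bin", "window_mean"]


@dataclass(frozen=True)
class PSTH:
    """Peristimulus time histogram: per-bin spike counts summed over trials.

    ``window_ms`` is half-open relative to stimulus onset and must contain the
    full ``baseline_ms`` pre-stimulus epoch; bins are half-open ``[left,
    right)`` so an edge spike is counted once.
    """

    counts: np.ndarray
    n_trials: int
    bin_width_ms: float = 5.0
    window_ms: tuple[float, float] = (-500.0, 500.0)
    baseline_ms: float = 500.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))
        lo, hi = self.window_ms
        n_bins = (hi - lo) / self.bin_width_ms
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("window length is not a multiple of bin_width_ms")
        if len(self.counts) != round(n_bins):
            raise ValueError(
                f"counts length {len(self.counts)} != window bins {round(n_bins)}"
            )
        nb = self.baseline_ms / self.bin_width_ms
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError("baseline_ms is not a multiple of bin_width_ms")
        if lo > -self.baseline_ms or hi <= 0:
            raise ValueError("window must contain the pre-stimulus baseline epoch")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_lefts_ms(self) -> np.ndarray:
        return self.window_ms[0] + self.bin_width_ms * np.arange(self.n_bins)

    @property
    def baseline_slice(self) -> slice:
        """Index range of the baseline bins (the ``baseline_ms`` before 0)."""
        stop = round(-self.window_ms[0] / self.bin_width_ms)
        start = stop - round(self.baseline_ms / self.bin_width_ms)
        return slice(start, stop)

    @property
    def post_slice(self) -> slice:
        """Index range of the post-stimulus bins (time >= 0)."""
        return slice(round(-self.window_ms[0] / self.bin_width_ms), self.n_bins)


@dataclass(frozen=True)
class BaselineStats:
    """Mean and SD of counts per bin over the baseline epoch."""

    mean_per_bin: float
    sd_per_bin: float

    def __post_init__(self) -> None:
        if self.sd_per_bin < 0:
            raise ValueError("sd_per_bin must be >= 0")


@dataclass(frozen=True)
class EvokedResponse:
    """Detected evoked epoch for one unit.

    For ``kind='none'`` the epoch fields are ``None``. ``onset_ms``/
    ``offset_ms`` are bin left edges relative to stimulus onset;
    ``magnitude_counts`` is positive for both kinds (excess spikes for
    excitation, spike deficit for inhibition).
    """

    kind: ResponseKind
    onset_ms: float | None = None
    offset_ms: float | None = None
    magnitude_counts: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "none":
            if not (self.onset_ms is None and self.offset_ms is None
                    and self.magnitude_counts is None):
                raise ValueError("kind='none' admits no epoch fields")
        else:
            if self.onset_ms is None or self.offset_ms is None:
                raise ValueError("detected epoch requires onset and offset")
            if self.onset_ms < 0 or self.offset_ms <= self.onset_ms:
                raise ValueError("epoch must satisfy 0 <= onset < offset")

    @property
    def duration_ms(self) -> float | None:
        if self.kind == "none":
            return None
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the epoch detectors (field defaults = study rules)."""

    bin_width_ms: float = 5.0
    baseline_ms: float = 500.0
    window_ms: tuple[float, float] = (-500.0, 500.0)
    run_length: int = 5
    sd_multiplier: float = 2.0
    inhibition_fraction: float = 0.30
    sd_ddof: int = 0
    onset_rule: OnsetRule = "each_bin"


def build_psth(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    bin_width_ms: float = 5.0,
    window_ms: tuple[float, float] = (-500.0, 500.0),
    baseline_ms: float = 500.0,
    align: Literal["events", "trains"] = "events",
) -> PSTH:
    """Bin spikes relative to every stimulus event, summed over events.

    ``align='trains'`` aligns to train onsets instead of individual pulses
    (relevant for optical protocols only).
    """
    events = protocol.train_onsets if align == "trains" else protocol.event_times
    lo, hi = window_ms
    n_bins = (hi - lo) / bin_width_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window length is not a multiple of bin_width_ms")
    n_bins = round(n_bins)
    edges = lo / 1000.0 + (bin_width_ms / 1000.0) * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        idx = np.searchsorted(train.spike_times, ev + edges, side="left")
        counts += np.diff(idx)
    return PSTH(
        counts=counts,
        n_trials=len(events),
        bin_width_ms=bin_width_ms,
        window_ms=window_ms,
        baseline_ms=baseline_ms,
    )


def baseline_stats(psth: PSTH, ddof: int = 0) -> BaselineStats:
    """Mean and SD of counts per bin over the pre-stimulus baseline.

    The default is the population SD (``ddof=0``): the baseline bins are
    treated as the full reference population, not a sample.
    """
    base = psth.counts[psth.baseline_slice]
    if base.size == 0:
        raise ValueError("baseline epoch is empty")
    return BaselineStats(
        mean_per_bin=float(np.mean(base)),
        sd_per_bin=float(np.std(base, ddof=ddof)) if base.size > ddof else 0.0,
    )


def _find_run(above: np.ndarray, run_length: int, start: int = 0) -> int | None:
    """Index of the first position >= start opening ``run_length`` True's."""
    n = len(above)
    for i in range(start, n - run_length + 1):
        if above[i : i + run_length].all():
            return i
    return None


def _detect_epoch(
    psth: PSTH,
    onset_hit: np.ndarray,
    run_length: int,
    onset_rule: OnsetRule,
) -> tuple[int, int] | None:
    """Shared run-scan: returns (onset_bin, offset_bin) indices into the
    post-stimulus array, offset exclusive, or None."""
    if onset_rule == "window_mean":
        # mean of the run_length-bin window must cross, evaluated per start
        n = len(onset_hit)
        kernel_hits = onset_hit  # already averaged by caller
        start = _find_run(kernel_hits, 1)
        if start is None or start > n - 1:
            return None
        onset = start
        off = _find_run(~kernel_hits, 1, start + 1)
    else:
        onset = _find_run(onset_hit, run_length)
        if onset is None:
            return None
        off = _find_run(~onset_hit, run_length, onset + 1)
    offset = off if off is not None else len(onset_hit)
    return onset, offset


def detect_excitation(
    psth: PSTH,
    stats: BaselineStats | None = None,
    run_length: int = 5,
    sd_multiplier: float = 2.0,
    onset_rule: OnsetRule = "each_bin",
) -> EvokedResponse:
    """Detect an excitatory epoch in the post-stimulus window.

    Onset is the left edge of the first post-stimulus bin opening a run of
    ``run_length`` consecutive bins each with count strictly above
    ``mean + sd_multiplier * SD`` of baseline; offset is the left edge of the
    first subsequent bin opening a run of bins back at or below that
    threshold (window end if activity never settles). A zero-variance
    baseline degenerates gracefully: the threshold is the baseline mean and
    the strict inequality still applies.

    ``onset_rule='window_mean'`` instead requires the ``run_length``-bin
    moving average to cross the threshold.
    """
    if stats is None:
        stats = baseline_stats(psth)
    threshold = stats.mean_per_bin + sd_multiplier * stats.sd_per_bin
    post = psth.counts[psth.post_slice]
    if post.size == 0:
        return EvokedResponse("none")
    if onset_rule == "window_mean":
        hits = _window_means(post, run_length) > threshold
    else:
        hits = post > threshold
    found = _detect_epoch(psth, hits, run_length, onset_rule)
    if found is None:
        return EvokedResponse("none")
    onset_bin, offset_bin = found
    onset_ms = onset_bin * psth.bin_width_ms
    offset_ms = offset_bin * psth.bin_width_ms
    resp = EvokedResponse("excitation", onset_ms, offset_ms)
    magnitude = excitation_magnitude(psth, stats, resp)
    return EvokedResponse("excitation", onset_ms, offset_ms, magnitude)


def detect_inhibition(
    psth: PSTH,
    stats: BaselineStats | None = None,
    frac: float = 0.30,
    run_length: int = 5,
    onset_rule: OnsetRule = "each_bin",
) -> EvokedResponse:
    """Detect an inhibitory epoch: counts strictly below ``frac`` (default
    30%) of the baseline mean for ``run_length`` consecutive bins; offset at
    the first run of bins back at or above that floor. With a zero baseline
    mean inhibition is undetectable and ``kind='none'`` is returned."""
    if stats is None:
        stats = baseline_stats(psth)
    if stats.mean_per_bin == 0:
        log.info("zero baseline mean: inhibition undetectable")
        return EvokedResponse("none")
    threshold = frac * stats.mean_per_bin
    post = psth.counts[psth.post_slice]
    if post.size == 0:
        return EvokedResponse("none")
    if onset_rule == "window_mean":
        hits = _window_means(post, run_length) < threshold
    else:
        hits = post < threshold
    found = _detect_epoch(psth, hits, run_length, onset_rule)
    if found is None:
        return EvokedResponse("none")
    onset_bin, offset_bin = found
    onset_ms = onset_bin * psth.bin_width_ms
    offset_ms = offset_bin * psth.bin_width_ms
    resp = EvokedResponse("inhibition", onset_ms, offset_ms)
    magnitude = inhibition_magnitude(psth, stats, resp)
    return EvokedResponse("inhibition", onset_ms, offset_ms, magnitude)


def _window_means(post: np.ndarray, run_length: int) -> np.ndarray:
    """Forward ``run_length``-bin moving average, truncated at the edge."""
    out = np.empty(len(post))
    for i in range(len(post)):
        out[i] = post[i : i + run_length].mean()
    return out


def _epoch_bins(psth: PSTH, epoch: EvokedResponse) -> np.ndarray:
    post = psth.counts[psth.post_slice]
    i = epoch.onset_ms / psth.bin_width_ms
    j = epoch.offset_ms / psth.bin_width_ms
    if abs(i - round(i)) > 1e-9 or abs(j - round(j)) > 1e-9:
        raise ValueError("epoch edges are not aligned to bin edges")
    i, j = round(i), round(j)
    if i < 0 or j > post.size:
        raise ValueError("epoch lies outside the post-stimulus window")
    return post[i:j]


def excitation_magnitude(
    psth: PSTH, stats: BaselineStats, epoch: EvokedResponse
) -> float:
    """Excess spike count of an excitatory epoch:
    ``(counts in epoch) - (baseline mean per bin x number of epoch bins)``."""
    if epoch.kind != "excitation":
        raise ValueError("epoch is not an excitation")
    bins = _epoch_bins(psth, epoch)
    return float(bins.sum() - stats.mean_per_bin * bins.size)


def inhibition_magnitude(
    psth: PSTH, stats: BaselineStats, epoch: EvokedResponse
) -> float:
    """Spike deficit of an inhibitory epoch (positive number)."""
    if epoch.kind != "inhibition":
        raise ValueError("epoch is not an inhibition")
    bins = _epoch_bins(psth, epoch)
    return float(stats.mean_per_bin * bins.size - bins.sum())


def classify_evoked(
    psth: PSTH, config: DetectionConfig | None = None
) -> EvokedResponse:
    """Run both detectors and report a single response class per unit.

    If both an excitatory and an inhibitory epoch qualify, the one departing
    from baseline earlier wins; an exact onset tie resolves to excitation.
    """
    cfg = config or DetectionConfig()
    stats = baseline_stats(psth, ddof=cfg.sd_ddof)
    exc = detect_excitation(
        psth, stats, cfg.run_length, cfg.sd_multiplier, cfg.onset_rule
    )
    inh = detect_inhibition(
        psth, stats, cfg.inhibition_fraction, cfg.run_length, cfg.onset_rule
    )
    if exc.kind == "none":
        return inh
    if inh.kind == "none":
        return exc
    return exc if exc.onset_ms <= inh.onset_ms else inh
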