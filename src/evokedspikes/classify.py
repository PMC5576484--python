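"""Putative cell-type assignment for VTA single units.

Extracellular recordings cannot identify transmitter phenotype directly, so
units are divided into putative dopaminergic (pDAergic), putative GABAergic
(pGABAergic) and "other" groups from two waveform-agnostic observables:
mean firing rate and average-spike-waveform duration. The conventional
inequalities are strict — a slow (<10.0 Hz), broad (>1.5 ms) unit is pDAergic;
a fast (>10.0 Hz), thin (<1.5 ms) unit is pGABAergic; everything else,
including values exactly on a boundary, is "other". The "other" group likely
mixes both phenotypes; no reassignment is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .spike_data import UnitRecord

__all__ = [
    "UnitClassification",
    "classify_unit",
    "classify_population",
    "waveform_duration_from_template",
    "RATE_CUTOFF_HZ",
    "DURATION_CUTOFF_MS",
]

PutativeClass = Literal["pDAergic", "pGABAergic", "other"]

RATE_CUTOFF_HZ = 10.0
DURATION_CUTOFF_MS = 1.5


@dataclass(frozen=True)
class UnitClassification:
    unit_id: str
    putative_class: PutativeClass
    firing_rate_hz: float
    waveform_duration_ms: float | None


def classify_unit(
    firing_rate_hz: float,
    waveform_duration_ms: float | None,
    unit_id: str = "",
) -> UnitClassification:
    """Assign a putative class from firing rate and waveform duration.

    Deterministic partition of the (rate, duration) plane; boundary values
    (exactly 10.0 Hz or exactly 1.5 ms) fall in "other" because the defining
    inequalities are strict. A missing waveform duration yields "other" with
    a warning, since neither conjunction can be evaluated.
    """
    if firing_rate_hz < 0:
        raise ValueError("firing_rate_hz must be >= 0")
    if waveform_duration_ms is None:
        warnings.warn(
            f"unit {unit_id!r}: missing waveform duration; assigned 'other'",
            stacklevel=2,
        )
        return UnitClassification(unit_id, "other", firing_rate_hz, None)
    if not waveform_duration_ms > 0:
        raise ValueError("waveform_duration_ms must be > 0")
    if firing_rate_hz < RATE_CUTOFF_HZ and waveform_duration_ms > DURATION_CUTOFF_MS:
        cls: PutativeClass = "pDAergic"
    elif firing_rate_hz > RATE_CUTOFF_HZ and waveform_duration_ms < DURATION_CUTOFF_MS:
        cls = "pGABAergic"
    else:
        cls = "other"
    return UnitClassification(unit_id, cls, firing_rate_hz, waveform_duration_ms)


def classify_population(
    records: Sequence[UnitRecord],
    rate_window: Literal["whole", "baseline"] = "whole",
    baseline_window_s: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Classify every unit; returns a tidy table.

    ``rate_window='whole'`` uses the whole-recording mean rate (the default:
    no reference window is implied by the classification rule itself);
    ``'baseline'`` restricts the rate to ``baseline_window_s``, which is the
    right choice when stimulation occupies a large fraction of the recording
    and would bias the mean.
    """
    rows = []
    for rec in records:
        train = rec.spike_train
        if rate_window == "whole":
            rate = train.mean_rate_hz
        else:
            if baseline_window_s is None:
                raise ValueError("rate_window='baseline' requires baseline_window_s")
            rate = train.rate_in_window(*baseline_window_s)
        c = classify_unit(rate, train.waveform_duration_ms, train.unit_id)
        rows.append(
            {
                "unit_id": c.unit_id,
                "firing_rate_hz": c.firing_rate_hz,
                "waveform_duration_ms": c.waveform_duration_ms,
                "putative_class": c.putative_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "firing_rate_hz", "waveform_duration_ms", "putative_class"],
    )


def waveform_duration_from_template(
    samples: np.ndarray,
    sampling_rate_hz: float,
    estimator: Literal["trough_to_peak", "full_width"] = "trough_to_peak",
) -> float:
    """Waveform duration (ms) from an average-spike template.

    ``trough_to_peak`` (default): time from the global trough to the
    subsequent after-hyperpolarization peak — the common convention for
    separating broad dopaminergic from thin GABAergic extracellular spikes.
    ``full_width``: width of the trough at half its depth relative to the
    template median. Both are invariant to amplitude scaling and DC offset.
    """
    w = np.asarray(samples, dtype=float)
    if w.size < 8:
        raise ValueError("waveform template needs at least 8 samples")
    trough = int(np.argmin(w))
    dt_ms = 1000.0 / sampling_rate_hz
    baseline = float(np.median(w))
    if not w[trough] < baseline:
        raise ValueError("unmeasurable waveform: no dominant trough")
    if estimator == "trough_to_peak":
        after = w[trough + 1 :]
        if after.size == 0:
            raise ValueError("unmeasurable waveform: trough at template end")
        peak = trough + 1 + int(np.argmax(after))
        if not w[peak] > baseline:
            raise ValueError("unmeasurable waveform: no peak after trough")
        return (peak - trough) * dt_ms
    elif estimator == "full_width":
        half = (w[trough] + baseline) / 2.0
        below = w < half
        if not below[trough]:
            raise ValueError("unmeasurable waveform: trough shallower than half level")
        left = trough
        while left > 0 and below[left - 1]:
            left -= 1
        right = trough
        while right < w.size - 1 and below[right + 1]:
            right += 1
        return (right - left + 1) * dt_ms
    raise ValueError(f"unknown estimator {estimator!r}")
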