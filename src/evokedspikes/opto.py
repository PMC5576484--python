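"""Responsiveness of single units to optical train stimulation.

Firing rate is computed for three windows: a 60-s spontaneous baseline before
the first light pulse, the stimulation period (onset of the first pulse to
offset of the last, including inter-train gaps when trains repeat — rates are
averaged at the rate level, total spikes over total time), and a 60-s
post-stimulation window. A unit is responsive when its stimulation-period rate
departs from baseline by more than 20% in either direction; the post rate is
reported descriptively and plays no part in the criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .classify import UnitClassification
from .spike_data import SpikeTrain, StimulusProtocol

__all__ = [
    "OptoWindows",
    "OptoResponse",
    "window_rates",
    "opto_classify",
    "population_opto_table",
]

log = logging.getLogger(__name__)

OptoResponseKind = Literal["excited", "inhibited", "none"]


@dataclass(frozen=True)
class OptoWindows:
    """Baseline / stimulation / post analysis windows, in seconds.

    Windows are half-open, disjoint and ordered.
    """

    baseline: tuple[float, float]
    stim: tuple[float, float]
    post: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (a, b) in zip(
            ("baseline", "stim", "post"), (self.baseline, self.stim, self.post)
        ):
            if not b > a:
                raise ValueError(f"{name} window is empty")
        if not (self.baseline[1] <= self.stim[0] and self.stim[1] <= self.post[0]):
            raise ValueError("windows must be ordered baseline < stim < post")

    @classmethod
    def from_protocol(
        cls,
        protocol: StimulusProtocol,
        baseline_s: float = 60.0,
        post_s: float = 60.0,
    ) -> "OptoWindows":
        """60-s baseline before the first pulse, stim envelope, 60-s post."""
        start, end = protocol.stim_envelope
        return cls(
            baseline=(start - baseline_s, start),
            stim=(start, end),
            post=(end, end + post_s),
        )


@dataclass(frozen=True)
class OptoResponse:
    unit_id: str
    rate_baseline_hz: float
    rate_stim_hz: float
    rate_post_hz: float
    percent_change: float
    response: OptoResponseKind


def window_rates(
    train: SpikeTrain, windows: OptoWindows
) -> tuple[float, float, float]:
    """Firing rate (spike count / window length) in each analysis window."""
    span = train.recording_span
    if windows.baseline[0] < span[0] or windows.post[1] > span[1]:
        raise ValueError(
            f"unit {train.unit_id!r}: analysis windows exceed recording_span"
        )
    return (
        train.rate_in_window(*windows.baseline),
        train.rate_in_window(*windows.stim),
        train.rate_in_window(*windows.post),
    )


def opto_classify(
    rates: tuple[float, float, float],
    threshold_percent: float = 20.0,
    unit_id: str = "",
) -> OptoResponse:
    """Apply the percent-change responsiveness criterion.

    ``percent_change = 100 * (stim - baseline) / baseline``. Excited when the
    change exceeds ``+threshold``, inhibited below ``-threshold``, otherwise
    none. A silent baseline with any stimulation-period activity is an
    infinite relative increase and is classified excited (logged); a unit
    silent in both windows is unresponsive.
    """
    rb, rs, rp = rates
    if min(rb, rs, rp) < 0:
        raise ValueError("rates must be >= 0")
    if rb == 0:
        if rs > 0:
            log.info("unit %r: zero baseline with stim activity -> excited", unit_id)
            return OptoResponse(unit_id, rb, rs, rp, float("inf"), "excited")
        return OptoResponse(unit_id, rb, rs, rp, 0.0, "none")
    pct = 100.0 * (rs - rb) / rb
    if pct > threshold_percent:
        kind: OptoResponseKind = "excited"
    elif pct < -threshold_percent:
        kind = "inhibited"
    else:
        kind = "none"
    return OptoResponse(unit_id, rb, rs, rp, pct, kind)


def population_opto_table(
    responses: Sequence[OptoResponse],
    classes: Sequence[UnitClassification] | pd.DataFrame,
) -> pd.DataFrame:
    """Cross-tabulate opto responses with putative classes.

    Returns a long table with one row per (response, putative_class) cell:
    counts, percent of the whole population, percent within the response kind
    and percent within the class. Raises on unit_ids present on one side only.
    """
    resp = pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "response": r.response,
                "rate_baseline_hz": r.rate_baseline_hz,
                "rate_stim_hz": r.rate_stim_hz,
                "rate_post_hz": r.rate_post_hz,
                "percent_change": r.percent_change,
            }
            for r in responses
        ]
    )
    if isinstance(classes, pd.DataFrame):
        cls = classes[["unit_id", "putative_class"]].copy()
    else:
        cls = pd.DataFrame(
            [{"unit_id": c.unit_id, "putative_class": c.putative_class} for c in classes]
        )
    if resp.empty and cls.empty:
        return pd.DataFrame(
            columns=["response", "putative_class", "n", "pct_overall",
                     "pct_within_response", "pct_within_class"]
        )
    unmatched = set(resp["unit_id"]).symmetric_difference(set(cls["unit_id"]))
    if unmatched:
        raise ValueError(f"unmatched unit_ids: {sorted(unmatched)}")
    merged = resp.merge(cls, on="unit_id", validate="one_to_one")
    n_total = len(merged)
    cells = (
        merged.groupby(["response", "putative_class"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    cells["pct_overall"] = 100.0 * cells["n"] / n_total
    cells["pct_within_response"] = cells.groupby("response")["n"].transform(
        lambda s: 100.0 * s / s.sum()
    )
    cells["pct_within_class"] = cells.groupby("putative_class")["n"].transform(
        lambda s: 100.0 * s / s.sum()
    )
    return cells
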