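"""Operant and place-preference behavioral scores.

Progressive-ratio (PR) sessions escalate the lever-press requirement
geometrically: trial ``T`` requires ``floor(1.4**(T-1))`` presses, starting at
one press. The breakpoint is the requirement of the highest completed trial;
a session terminates once a trial clock reaches 15 min without the
requirement being met. Conditioned place preference (CPP) is scored as the
pre-to-post shift in time spent on the stimulation-paired (ON) side, and
real-time place preference (RTPP) as the percentage of session time on the
ON side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "PRTrial",
    "PRSession",
    "PlacePreference",
    "pr_requirement",
    "breakpoint",
    "cpp_scores",
    "rtpp_score",
    "read_session_log",
    "read_occupancy_log",
]

Interval = tuple[float, float]


def pr_requirement(T: int) -> int:
    """Lever-press requirement of PR trial ``T``: ``floor(1.4**(T-1))``.

    Computed with exact integer arithmetic (``7**(T-1) // 5**(T-1)``), so the
    floor is correct for arbitrarily large ``T``.
    """
    if not isinstance(T, int) or T < 1:
        raise ValueError("trial index T must be an integer >= 1")
    return 7 ** (T - 1) // 5 ** (T - 1)


@dataclass(frozen=True)
class PRTrial:
    T: int
    presses: int
    completed: bool
    trial_seconds: float

    @property
    def requirement(self) -> int:
        return pr_requirement(self.T)


@dataclass(frozen=True)
class PRSession:
    """An ordered progressive-ratio session log."""

    trials: tuple[PRTrial, ...]

    def __post_init__(self) -> None:
        for i, trial in enumerate(self.trials, start=1):
            if trial.T != i:
                raise ValueError(f"trial indices must run 1..n; got T={trial.T} at {i}")
            if trial.completed != (trial.presses >= trial.requirement):
                raise ValueError(
                    f"trial {trial.T}: completed flag inconsistent with "
                    f"{trial.presses} presses vs requirement {trial.requirement}"
                )

    @classmethod
    def from_table(cls, frame: pd.DataFrame) -> "PRSession":
        trials = tuple(
            PRTrial(
                T=int(r.trial), presses=int(r.presses),
                completed=bool(r.completed), trial_seconds=float(r.trial_seconds),
            )
            for r in frame.itertuples()
        )
        return cls(trials)


def breakpoint(session: PRSession, timeout_s: float = 900.0) -> int:
    """Breakpoint: requirement of the highest completed trial (0 if none).

    The 15-min termination clock is per trial (time since trial start); a
    completed trial following a timed-out one is an inconsistent log and
    raises.
    """
    bp = 0
    terminated = False
    for trial in session.trials:
        if trial.completed:
            if terminated:
                raise ValueError(
                    f"trial {trial.T} completed after session termination"
                )
            bp = trial.requirement
        elif trial.trial_seconds >= timeout_s:
            terminated = True
    return bp


def session_terminated(session: PRSession, timeout_s: float = 900.0) -> bool:
    return any(
        (not t.completed) and t.trial_seconds >= timeout_s for t in session.trials
    )


@dataclass(frozen=True)
class PlacePreference:
    """CPP/RTPP occupancy summary (times in seconds)."""

    pre_on_s: float
    pre_off_s: float
    post_on_s: float
    post_off_s: float

    @property
    def difference_score_s(self) -> float:
        """Post-minus-pre time on the stimulation-paired (ON) side."""
        return self.post_on_s - self.pre_on_s

    @property
    def percent_on(self) -> float:
        """Percentage of post-test two-chamber time spent on the ON side."""
        total = self.post_on_s + self.post_off_s
        if total == 0:
            raise ValueError("no post-test occupancy recorded")
        return 100.0 * self.post_on_s / total


def _occupancy_seconds(intervals: Mapping[str, Sequence[Interval]]) -> dict[str, float]:
    flat = [
        (a, b, chamber)
        for chamber, ivs in intervals.items()
        for a, b in ivs
    ]
    for a, b, chamber in flat:
        if not b > a:
            raise ValueError(f"empty or inverted interval {(a, b)} in {chamber!r}")
    flat.sort()
    for (a0, b0, c0), (a1, b1, c1) in zip(flat, flat[1:]):
        if a1 < b0:
            raise ValueError(
                f"overlapping occupancy: {(a0, b0)} in {c0!r} and {(a1, b1)} in {c1!r}"
            )
    out = {chamber: 0.0 for chamber in intervals}
    for a, b, chamber in flat:
        out[chamber] += b - a
    return out


def cpp_scores(
    pre: Mapping[str, Sequence[Interval]],
    post: Mapping[str, Sequence[Interval]],
) -> PlacePreference:
    """Score a CPP session from per-chamber occupancy intervals.

    ``pre`` and ``post`` map chamber names (``on``, ``off``, optionally
    ``center``) to disjoint ``(enter_s, exit_s)`` intervals. Center-chamber
    time, when declared, is excluded from the two-sided percentages.
    """
    pre_s = _occupancy_seconds(pre)
    post_s = _occupancy_seconds(post)
    for name, d in (("pre", pre_s), ("post", post_s)):
        unknown = set(d) - {"on", "off", "center"}
        if unknown:
            raise ValueError(f"{name}: unknown chambers {sorted(unknown)}")
    return PlacePreference(
        pre_on_s=pre_s.get("on", 0.0),
        pre_off_s=pre_s.get("off", 0.0),
        post_on_s=post_s.get("on", 0.0),
        post_off_s=post_s.get("off", 0.0),
    )


def rtpp_score(occupancy: Mapping[str, Sequence[Interval]]) -> tuple[float, float]:
    """RTPP summary: (percent time ON, ON-minus-OFF seconds)."""
    secs = _occupancy_seconds(occupancy)
    on, off = secs.get("on", 0.0), secs.get("off", 0.0)
    if on + off == 0:
        raise ValueError("no occupancy recorded")
    return 100.0 * on / (on + off), on - off


def read_session_log(path: str | Path) -> PRSession:
    """Read a PR session log: columns trial, presses, completed, trial_seconds."""
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = {"trial", "presses", "completed", "trial_seconds"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return PRSession.from_table(frame)


def read_occupancy_log(path: str | Path) -> dict[str, list[Interval]]:
    """Read an occupancy log: columns chamber, enter_s, exit_s."""
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = {"chamber", "enter_s", "exit_s"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[Interval]] = {}
    for r in frame.itertuples():
        out.setdefault(str(r.chamber), []).append((float(r.enter_s), float(r.exit_s)))
    return out
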