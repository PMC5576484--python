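"""Domain types and plain-text I/O for spike trains and stimulation protocols.

All event times are exchanged in seconds; durations that the field reports in
milliseconds (bin widths, pulse widths, waveform durations, latencies) carry an
explicit ``_ms`` suffix and are converted at this type boundary. Intervals are
half-open ``[start, end)`` throughout, so a spike sitting exactly on a bin or
window edge is counted once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "StimulusProtocol",
    "UnitRecord",
    "read_spikes",
    "read_events",
    "write_units",
    "read_units",
    "write_events",
    "write_responses",
    "read_responses",
]

GroupLabel = Literal["CTR", "iuGC", "unlabeled"]
Region = Literal["LDT", "VTA"]


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's spike times plus waveform metadata.

    Parameters
    ----------
    unit_id : str
        Identifier of the single unit.
    spike_times : array-like of float
        Strictly increasing event times in seconds, all inside
        ``recording_span``.
    recording_span : (float, float)
        Closed interval ``[start, end]`` of the recording, in seconds.
    waveform_duration_ms : float, optional
        Duration of the average spike waveform (trough-to-peak), in ms.
    """

    unit_id: str
    spike_times: np.ndarray
    recording_span: tuple[float, float]
    waveform_duration_ms: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        start, end = self.recording_span
        if not end > start:
            raise ValueError(
                f"unit {self.unit_id!r}: recording_span must have positive length"
            )
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"unit {self.unit_id!r}: spike_times are non-monotone"
                )
            if times[0] < start or times[-1] > end:
                raise ValueError(
                    f"unit {self.unit_id!r}: spike_times outside recording_span"
                )
        if self.waveform_duration_ms is not None and not self.waveform_duration_ms > 0:
            raise ValueError(
                f"unit {self.unit_id!r}: waveform_duration_ms must be > 0"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def span_length_s(self) -> float:
        return self.recording_span[1] - self.recording_span[0]

    @property
    def mean_rate_hz(self) -> float:
        """Whole-recording mean firing rate, recomputed on every access."""
        return self.n_spikes / self.span_length_s

    def rate_in_window(self, start_s: float, end_s: float) -> float:
        """Firing rate (Hz) over the half-open window ``[start_s, end_s)``."""
        if not end_s > start_s:
            raise ValueError("window must have positive length")
        lo, hi = np.searchsorted(self.spike_times, [start_s, end_s], side="left")
        return (hi - lo) / (end_s - start_s)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus pulse-onset times plus pulse parameters.

    ``kind`` distinguishes single-pulse electrical stimulation (default: 0.5 Hz,
    i.e. one 0.5-ms pulse every 2 s) from optical trains (default: trains of 30
    pulses of 15 ms at 20 Hz).
    """

    kind: Literal["electrical", "optical"]
    event_times: np.ndarray
    pulse_width_ms: float
    pulses_per_train: int | None = None
    train_rate_hz: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if times.size == 0:
            raise ValueError("protocol needs at least one event")
        if np.any(np.diff(times) <= 0):
            raise ValueError("event_times are non-monotone")
        if not self.pulse_width_ms > 0:
            raise ValueError("pulse_width_ms must be > 0")
        if self.kind == "optical":
            if not self.pulses_per_train or not self.train_rate_hz:
                raise ValueError(
                    "optical protocol requires pulses_per_train and train_rate_hz"
                )
            if times.size % self.pulses_per_train:
                raise ValueError("event count is not a whole number of trains")

    @classmethod
    def electrical(
        cls,
        n_pulses: int = 100,
        interval_s: float = 2.0,
        pulse_width_ms: float = 0.5,
        start_s: float = 1.0,
    ) -> "StimulusProtocol":
        """Single-pulse protocol: ``n_pulses`` onsets spaced ``interval_s``."""
        times = start_s + interval_s * np.arange(n_pulses)
        return cls("electrical", times, pulse_width_ms)

    @classmethod
    def optical(
        cls,
        n_trains: int = 1,
        pulses_per_train: int = 30,
        train_rate_hz: float = 20.0,
        pulse_width_ms: float = 15.0,
        inter_train_s: float = 3.0,
        start_s: float = 60.0,
    ) -> "StimulusProtocol":
        """Optical train protocol; ``inter_train_s`` is onset-to-onset."""
        within = np.arange(pulses_per_train) / train_rate_hz
        train_len = (pulses_per_train - 1) / train_rate_hz + pulse_width_ms / 1000.0
        if inter_train_s < train_len:
            raise ValueError("trains overlap: inter_train_s shorter than a train")
        onsets = start_s + inter_train_s * np.arange(n_trains)
        times = (onsets[:, None] + within[None, :]).ravel()
        return cls("optical", times, pulse_width_ms, pulses_per_train, train_rate_hz)

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def train_onsets(self) -> np.ndarray:
        """Onset time of each train (the events themselves for electrical)."""
        if self.kind == "electrical":
            return self.event_times
        return self.event_times[:: self.pulses_per_train]

    @property
    def train_offsets(self) -> np.ndarray:
        """Offset (last pulse onset + pulse width) of each train."""
        if self.kind == "electrical":
            return self.event_times + self.pulse_width_ms / 1000.0
        last = self.event_times[self.pulses_per_train - 1 :: self.pulses_per_train]
        return last + self.pulse_width_ms / 1000.0

    @property
    def stim_envelope(self) -> tuple[float, float]:
        """``[first pulse onset, last pulse offset)`` of the whole protocol."""
        return (float(self.event_times[0]), float(self.train_offsets[-1]))


@dataclass(frozen=True)
class UnitRecord:
    """A spike train with its experimental-group and region labels."""

    spike_train: SpikeTrain
    group_label: GroupLabel = "unlabeled"
    region: Region = "VTA"


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

_SPIKE_COLUMNS = ["unit_id", "time_s"]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def read_spikes(
    path: str | Path,
    dialect: Literal["long", "per_unit"] = "long",
    group_label: GroupLabel = "unlabeled",
    region: Region = "VTA",
    recording_span: tuple[float, float] | None = None,
) -> list[UnitRecord]:
    """Read spike times from a delimited file.

    Two dialects are supported: ``long`` — a two-column table
    ``unit_id,time_s`` (comma or tab, auto-detected, optional header) holding
    every unit; ``per_unit`` — a plain list of times, one per line, for a
    single unit named after the file stem.

    When ``recording_span`` is omitted it defaults to ``[0, ceil(max time)]``.
    A sidecar ``<path>.meta.json`` written by :func:`write_units` overrides
    spans, waveform durations and labels per unit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "per_unit":
        times: list[float] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw or raw.startswith("#"):
                    continue
                try:
                    times.append(float(raw))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed row {raw!r}") from None
        if not times:
            return []
        frame = pd.DataFrame({"unit_id": path.stem, "time_s": times})
    elif dialect == "long":
        try:
            frame = pd.read_csv(
                path, sep=_detect_sep(path), comment="#", header=None,
                names=_SPIKE_COLUMNS, dtype={"unit_id": str}, skip_blank_lines=True,
            )
        except pd.errors.EmptyDataError:
            return []
        if frame.empty:
            return []
        # tolerate a header row
        if frame.iloc[0].tolist() == _SPIKE_COLUMNS:
            frame = frame.iloc[1:].reset_index(drop=True)
        try:
            frame["time_s"] = frame["time_s"].astype(float)
        except (TypeError, ValueError):
            bad = frame[pd.to_numeric(frame["time_s"], errors="coerce").isna()]
            lineno = int(bad.index[0]) + 1
            raise ValueError(
                f"{path}:{lineno}: malformed row {bad.iloc[0].tolist()!r}"
            ) from None
        if frame.empty:
            return []
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    meta_path = path.with_name(path.name + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    default_span = recording_span or (0.0, float(np.ceil(frame["time_s"].max() + 1e-9)))
    records = []
    for unit_id, sub in frame.groupby("unit_id", sort=False):
        info = meta.get(str(unit_id), {})
        span = tuple(info.get("recording_span", default_span))
        train = SpikeTrain(
            unit_id=str(unit_id),
            spike_times=sub["time_s"].to_numpy(),
            recording_span=span,  # SpikeTrain re-raises naming the unit
            waveform_duration_ms=info.get("waveform_duration_ms"),
        )
        records.append(
            UnitRecord(
                spike_train=train,
                group_label=info.get("group_label", group_label),
                region=info.get("region", region),
            )
        )
    return records


def write_units(records: Sequence[UnitRecord], path: str | Path) -> Path:
    """Write units as a long-format table plus a JSON metadata sidecar.

    Round-trips exactly through :func:`read_units`: times are serialized at
    full double precision (17 significant digits).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("unit_id\ttime_s\n")
        for rec in records:
            for t in rec.spike_train.spike_times:
                fh.write(f"{rec.spike_train.unit_id}\t{t:.17g}\n")
    meta = {
        rec.spike_train.unit_id: {
            "recording_span": list(rec.spike_train.recording_span),
            "waveform_duration_ms": rec.spike_train.waveform_duration_ms,
            "group_label": rec.group_label,
            "region": rec.region,
        }
        for rec in records
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_units(path: str | Path) -> list[UnitRecord]:
    """Read a table written by :func:`write_units` (long dialect + sidecar)."""
    path = Path(path)
    records = read_spikes(path, dialect="long")
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        present = {r.spike_train.unit_id for r in records}
        for unit_id, info in meta.items():
            if unit_id not in present:  # unit with zero spikes
                records.append(
                    UnitRecord(
                        spike_train=SpikeTrain(
                            unit_id=unit_id,
                            spike_times=np.empty(0),
                            recording_span=tuple(info["recording_span"]),
                            waveform_duration_ms=info.get("waveform_duration_ms"),
                        ),
                        group_label=info.get("group_label", "unlabeled"),
                        region=info.get("region", "VTA"),
                    )
                )
    return records


def write_events(protocol: StimulusProtocol, path: str | Path) -> Path:
    """Write pulse onsets (one per line) with a ``# key=value`` header block."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind={protocol.kind}\n")
        fh.write(f"# pulse_width_ms={protocol.pulse_width_ms:.17g}\n")
        if protocol.kind == "optical":
            fh.write(f"# pulses_per_train={protocol.pulses_per_train}\n")
            fh.write(f"# train_rate_hz={protocol.train_rate_hz:.17g}\n")
        for t in protocol.event_times:
            fh.write(f"{t:.17g}\n")
    return path


def read_events(path: str | Path) -> StimulusProtocol:
    """Read a stimulus protocol from a file of onset times.

    Metadata (``kind``, ``pulse_width_ms`` and, for optical trains,
    ``pulses_per_train`` / ``train_rate_hz``) comes from ``# key=value`` header
    lines or from a ``<path>.json`` sidecar; ``kind`` is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta.update({k: str(v) for k, v in json.loads(sidecar.read_text()).items()})
    times: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            if raw.startswith("#"):
                if "=" in raw:
                    key, _, value = raw.lstrip("# ").partition("=")
                    meta[key.strip()] = value.strip()
                continue
            try:
                times.append(float(raw.split(",")[0].split("\t")[0]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed row {raw!r}") from None
    if "kind" not in meta:
        raise ValueError(f"{path}: missing 'kind' declaration (header or sidecar)")
    kind = meta["kind"]
    if kind not in ("electrical", "optical"):
        raise ValueError(f"{path}: unknown stimulus kind {kind!r}")
    default_width = 0.5 if kind == "electrical" else 15.0
    return StimulusProtocol(
        kind=kind,  # type: ignore[arg-type]
        event_times=np.asarray(times),
        pulse_width_ms=float(meta.get("pulse_width_ms", default_width)),
        pulses_per_train=(
            int(meta["pulses_per_train"]) if "pulses_per_train" in meta else None
        ),
        train_rate_hz=(
            float(meta["train_rate_hz"]) if "train_rate_hz" in meta else None
        ),
    )


_RESPONSE_COLUMNS = [
    "unit_id", "kind", "onset_ms", "offset_ms", "duration_ms",
    "magnitude_counts", "n_trials",
]


def write_responses(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> Path:
    """Write an evoked-response table (tab-separated, fixed column order)."""
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=_RESPONSE_COLUMNS)
    frame = frame.reindex(columns=_RESPONSE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return Path(path)


def read_responses(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"unit_id": str})
    missing = set(_RESPONSE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame
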