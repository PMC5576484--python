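"""Ground-truth spike-train, waveform and population simulators.

Units are modelled as piecewise-constant-rate (inhomogeneous) Poisson
processes: a class-specific baseline rate everywhere, multiplied inside
stimulus-locked modulation windows. For single-pulse electrical protocols the
modulation window follows every pulse at a fixed latency and duration
(additive excitation is realized by superposing an independent Poisson process
at ``(gain - 1) x baseline``; multiplicative inhibition by thinning baseline
spikes to probability ``depth``). For optical train protocols the modulation
is sustained over the whole stimulation period. Everything is a pure function
of its arguments including the seed.

Population scenarios allocate response kinds and putative classes by exact
largest-remainder rounding, so packaged fixtures realize their published
composition exactly and recovery error is attributable to the detectors alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import waveform_duration_from_template
from .spike_data import SpikeTrain, StimulusProtocol, UnitRecord

__all__ = [
    "ResponseSpec",
    "ScenarioConfig",
    "simulate_unit",
    "simulate_population",
    "make_waveform",
    "allocate_counts",
    "scenario_config",
    "simulate_scenario",
    "list_scenarios",
]

ResponseKind = Literal["excitation", "inhibition", "none"]


@dataclass(frozen=True)
class ResponseSpec:
    """Stimulus-locked rate modulation of one unit.

    ``gain`` is the rate multiplier inside the modulation window: > 1 for
    excitation (evoked rate = gain x baseline), in [0, 1) for inhibition
    (the inhibition depth; below 0.3 to be detectable by the 30% rule), and
    ignored for ``kind='none'``. ``latency_ms``/``duration_ms`` position the
    window after each pulse for electrical protocols; optical modulation
    spans the stimulation period and ignores them.
    """

    kind: ResponseKind
    latency_ms: float = 0.0
    duration_ms: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        if self.kind != "none":
            if not self.duration_ms > 0:
                raise ValueError("duration_ms must be > 0 for a response")
            if self.kind == "excitation" and not self.gain >= 1:
                raise ValueError("excitation requires gain >= 1")
            if self.kind == "inhibition" and not 0 <= self.gain < 1:
                raise ValueError("inhibition requires 0 <= depth < 1")

    @classmethod
    def none(cls) -> "ResponseSpec":
        return cls("none")


def _homogeneous(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _modulation_windows(
    spec: ResponseSpec, protocol: StimulusProtocol
) -> list[tuple[float, float]]:
    if spec.kind == "none":
        return []
    if protocol.kind == "electrical":
        lat, dur = spec.latency_ms / 1000.0, spec.duration_ms / 1000.0
        windows = [(float(e) + lat, float(e) + lat + dur) for e in protocol.event_times]
        for (a0, b0), (a1, b1) in zip(windows, windows[1:]):
            if b0 > a1:
                raise ValueError(
                    "evoked epochs overlap across events: protocol too dense"
                )
        return windows
    # optical: sustained modulation over the whole stimulation period
    return [protocol.stim_envelope]


def simulate_unit(
    baseline_rate_hz: float,
    spec: ResponseSpec,
    protocol: StimulusProtocol,
    span_s: tuple[float, float],
    seed: int | np.random.SeedSequence,
    unit_id: str = "sim",
    waveform_duration_ms: float | None = None,
) -> SpikeTrain:
    """Draw one unit's spike train from the piecewise-constant Poisson model."""
    if not baseline_rate_hz > 0:
        raise ValueError("baseline_rate_hz must be > 0")
    t0, t1 = span_s
    if protocol.event_times[0] < t0 or protocol.train_offsets[-1] > t1:
        raise ValueError("span_s does not cover the stimulation protocol")
    rng = np.random.default_rng(seed)
    spikes = _homogeneous(rng, baseline_rate_hz, t0, t1)
    windows = _modulation_windows(spec, protocol)
    if windows:
        if spec.kind == "excitation":
            extra_rate = (spec.gain - 1.0) * baseline_rate_hz
            extras = [_homogeneous(rng, extra_rate, a, b) for a, b in windows]
            spikes = np.concatenate([spikes, *extras])
            spikes.sort(kind="stable")
        else:  # inhibition: thin baseline spikes inside the windows
            keep = np.ones(spikes.size, dtype=bool)
            for a, b in windows:
                lo, hi = np.searchsorted(spikes, [a, b], side="left")
                keep[lo:hi] = rng.random(hi - lo) < spec.gain
            spikes = spikes[keep]
    spikes = np.unique(spikes)  # measure-zero ties would violate monotonicity
    return SpikeTrain(
        unit_id=unit_id,
        spike_times=spikes,
        recording_span=span_s,
        waveform_duration_ms=waveform_duration_ms,
    )


def make_waveform(
    putative_class: str,
    duration_ms: float,
    sampling_rate_hz: float = 40_000.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Synthesize a biphasic average-spike template.

    The template is a narrow negative Gaussian trough followed by a broader
    positive after-peak centred ``duration_ms`` later, plus faint seeded
    noise, so its measured trough-to-peak time equals ``duration_ms`` to
    within one sample.
    """
    if not duration_ms > 0:
        raise ValueError("duration_ms must be > 0")
    dt_ms = 1000.0 / sampling_rate_hz
    if duration_ms / dt_ms < 2:
        raise ValueError(
            f"duration {duration_ms} ms unresolvable at {sampling_rate_hz} Hz sampling"
        )
    rng = np.random.default_rng(seed)
    t_trough = 0.5
    total_ms = t_trough + duration_ms + 1.0
    t = np.arange(0.0, total_ms, dt_ms)
    trough = -1.0 * np.exp(-0.5 * ((t - t_trough) / 0.10) ** 2)
    peak = 0.45 * np.exp(-0.5 * ((t - (t_trough + duration_ms)) / 0.20) ** 2)
    noise = 0.001 * rng.standard_normal(t.size)
    return trough + peak + noise


def allocate_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to ``proportions``.

    Exact (sums to ``n``); remainder ties break toward the earlier entry so
    the allocation is deterministic.
    """
    props = np.asarray(proportions, dtype=float)
    if props.size == 0:
        raise ValueError("need at least one proportion")
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be non-negative and sum to 1")
    quotas = props / props.sum() * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # stable sort => ties go to the earlier entry
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts.tolist()


# ---------------------------------------------------------------------------
# population scenarios
# ---------------------------------------------------------------------------

_DEFAULT_RATE_RANGES: dict[str, tuple[float, float]] = {
    "pDAergic": (2.0, 8.0),
    "pGABAergic": (12.0, 25.0),
    "other_thin": (8.0, 8.4),
    "other_broad": (10.6, 12.0),
}
_DEFAULT_DURATION_RANGES: dict[str, tuple[float, float]] = {
    "pDAergic": (1.7, 2.5),
    "pGABAergic": (0.7, 1.3),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Population composition plus response/protocol parameters (ground truth).

    ``composition`` maps response kind -> ``{"proportion": p, "classes":
    {class: p}}``; proportions are turned into exact unit counts by
    largest-remainder allocation, kinds first, then classes within each kind.
    ``response`` maps the detectable kinds to their ResponseSpec parameters.
    """

    name: str
    n_units: int
    composition: Mapping[str, Mapping]
    response: Mapping[str, Mapping]
    protocol_params: Mapping[str, float | int | str]
    group_label: str = "unlabeled"
    seed: int = 1
    rate_ranges_hz: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RATE_RANGES)
    )
    duration_ranges_ms: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DURATION_RANGES)
    )
    sampling_rate_hz: float = 40_000.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        total = sum(c["proportion"] for c in self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("composition proportions must sum to 1")
        for kind, cell in self.composition.items():
            s = sum(cell["classes"].values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"class proportions for {kind!r} must sum to 1")
        for cls in ("pDAergic", "pGABAergic"):
            lo, hi = self.rate_ranges_hz[cls]
            bad = hi > 10.0 if cls == "pDAergic" else lo < 10.0
            if bad:
                raise ValueError(
                    f"{cls} rate range {self.rate_ranges_hz[cls]} is inconsistent "
                    "with the 10-Hz classification cutoff"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "ScenarioConfig":
        kwargs = dict(
            name=raw["name"],
            n_units=int(raw["n_units"]),
            composition=raw["composition"],
            response=raw["response"],
            protocol_params=raw["protocol"],
            group_label=raw.get("group_label", "unlabeled"),
            seed=int(raw.get("seed", 1)),
        )
        if "rate_ranges_hz" in raw:
            kwargs["rate_ranges_hz"] = {
                k: tuple(v) for k, v in raw["rate_ranges_hz"].items()
            }
        if "duration_ranges_ms" in raw:
            kwargs["duration_ranges_ms"] = {
                k: tuple(v) for k, v in raw["duration_ranges_ms"].items()
            }
        return cls(**kwargs)

    def build_protocol(self) -> StimulusProtocol:
        p = dict(self.protocol_params)
        kind = p.pop("kind")
        if kind == "electrical":
            return StimulusProtocol.electrical(**p)
        if kind == "optical":
            return StimulusProtocol.optical(**p)
        raise ValueError(f"unknown protocol kind {kind!r}")

    def allocation(self) -> pd.DataFrame:
        """Exact per-(kind, class) unit counts implied by the composition."""
        kinds = list(self.composition)
        kind_counts = allocate_counts(
            [self.composition[k]["proportion"] for k in kinds], self.n_units
        )
        rows = []
        for kind, n_kind in zip(kinds, kind_counts):
            classes = list(self.composition[kind]["classes"])
            class_counts = allocate_counts(
                [self.composition[kind]["classes"][c] for c in classes], n_kind
            )
            for cls_name, n_cell in zip(classes, class_counts):
                rows.append({"response_kind": kind, "putative_class": cls_name,
                             "n": n_cell})
        return pd.DataFrame(rows)


def _other_branch(kind: str) -> str:
    """Which side of the 10-Hz cutoff an 'other' unit sits on.

    Chosen so evoked-rate inflation (excitation) or deflation (inhibition)
    pushes the realized mean rate away from the cutoff, never across it.
    """
    return "other_broad" if kind == "excitation" else "other_thin"


def simulate_population(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[list[UnitRecord], pd.DataFrame]:
    """Simulate a whole scenario; returns unit records plus a ground-truth table.

    The ground-truth table has one row per unit: true response kind, true
    putative class, baseline rate, waveform duration, and the modulation
    parameters actually injected.
    """
    master_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master_seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    protocol = config.build_protocol()
    if protocol.kind == "electrical":
        first, last = protocol.event_times[0], protocol.event_times[-1]
        span = (min(0.0, first - 1.0), float(last) + 1.0)
    else:
        start, end = protocol.stim_envelope
        span = (start - 61.0, end + 61.0)

    alloc = config.allocation()
    n_total = int(alloc["n"].sum())
    unit_seeds = ss.spawn(n_total)
    records: list[UnitRecord] = []
    truth_rows: list[dict] = []
    idx = 0
    for _, cell in alloc.iterrows():
        kind, cls_name, n_cell = cell["response_kind"], cell["putative_class"], cell["n"]
        for _ in range(int(n_cell)):
            unit_id = f"u{idx:03d}"
            range_key = _other_branch(kind) if cls_name == "other" else cls_name
            lo, hi = config.rate_ranges_hz[range_key]
            rate = float(draw_rng.uniform(lo, hi))
            if cls_name == "other":
                dlo, dhi = (
                    config.duration_ranges_ms["pGABAergic"]
                    if range_key == "other_thin"
                    else config.duration_ranges_ms["pDAergic"]
                )
            else:
                dlo, dhi = config.duration_ranges_ms[cls_name]
            true_duration = float(draw_rng.uniform(dlo, dhi))
            template = make_waveform(
                cls_name, true_duration, config.sampling_rate_hz,
                seed=int(draw_rng.integers(2**31)),
            )
            measured_duration = waveform_duration_from_template(
                template, config.sampling_rate_hz
            )
            if kind == "none":
                spec = ResponseSpec.none()
            else:
                spec = ResponseSpec(kind=kind, **config.response[kind])
            train = simulate_unit(
                rate, spec, protocol, span, unit_seeds[idx],
                unit_id=unit_id, waveform_duration_ms=measured_duration,
            )
            records.append(
                UnitRecord(spike_train=train, group_label=config.group_label)  # type: ignore[arg-type]
            )
            truth_rows.append(
                {
                    "unit_id": unit_id,
                    "true_kind": kind,
                    "true_class": cls_name,
                    "baseline_rate_hz": rate,
                    "waveform_duration_ms": measured_duration,
                    "gain": spec.gain if kind != "none" else 1.0,
                    "latency_ms": spec.latency_ms,
                    "duration_ms": spec.duration_ms,
                }
            )
            idx += 1
    return records, pd.DataFrame(truth_rows)


def list_scenarios() -> list[str]:
    """Names of the packaged scenario fixtures."""
    root = resources.files("evokedspikes") / "scenarios"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def scenario_config(name: str) -> ScenarioConfig:
    """Load a packaged scenario fixture by name (see :func:`list_scenarios`)."""
    root = resources.files("evokedspikes") / "scenarios"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {list_scenarios()}"
        ) from None
    return ScenarioConfig._from_mapping(yaml.safe_load(text))


def simulate_scenario(
    name: str, seed: int | None = None
) -> tuple[list[UnitRecord], pd.DataFrame, ScenarioConfig]:
    """Convenience wrapper: load a packaged scenario and simulate it."""
    config = scenario_config(name)
    records, truth = simulate_population(config, seed=seed)
    return records, truth, config
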