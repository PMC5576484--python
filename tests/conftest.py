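import numpy as np
import pandas as pd
import pytest

from evokedspikes import (
    DetectionConfig,
    classify_population,
    detect_evoked_population,
    simulate_scenario,
)
from evokedspikes.opto import OptoWindows, opto_classify, window_rates
from evokedspikes.psth import PSTH


def make_psth(baseline_counts, post_counts, bin_width_ms=5.0, n_trials=100):
    """Construct a PSTH directly from baseline and post-stimulus count arrays."""
    baseline_counts = np.asarray(baseline_counts)
    post_counts = np.asarray(post_counts)
    window = (
        -bin_width_ms * len(baseline_counts),
        bin_width_ms * len(post_counts),
    )
    return PSTH(
        counts=np.concatenate([baseline_counts, post_counts]),
        n_trials=n_trials,
        bin_width_ms=bin_width_ms,
        window_ms=window,
        baseline_ms=bin_width_ms * len(baseline_counts),
    )


def brute_force_epoch(post_counts, threshold, run_length, mode):
    """Exhaustive scan over all candidate run starts (independent oracle).

    Returns (onset_bin, offset_bin_exclusive) or None. ``mode='exc'`` uses
    count > threshold for the epoch and <= threshold for recovery;
    ``mode='inh'`` uses count < threshold and >= threshold.
    """
    if mode == "exc":
        hits = [c > threshold for c in post_counts]
    else:
        hits = [c < threshold for c in post_counts]
    n = len(post_counts)
    onset = None
    for i in range(n - run_length + 1):
        if all(hits[i : i + run_length]):
            onset = i
            break
    if onset is None:
        return None
    for j in range(onset + 1, n - run_length + 1):
        if not any(hits[j : j + run_length]):
            return onset, j
    return onset, n


@pytest.fixture(scope="session")
def electrical_runs():
    """Both electrical scenarios run once through the full pipeline (seed 1)."""
    out = {}
    for name in ("ctr_electrical", "iugc_electrical"):
        records, truth, cfg = simulate_scenario(name, seed=1)
        protocol = cfg.build_protocol()
        responses = detect_evoked_population(records, protocol, DetectionConfig())
        classes = classify_population(records, rate_window="whole")
        out[name] = dict(
            records=records, truth=truth, config=cfg,
            responses=responses, classes=classes,
        )
    return out


@pytest.fixture(scope="session")
def opto_runs():
    """Both optogenetic scenarios run once through the opto pipeline (seed 1)."""
    out = {}
    for name in ("ctr_opto", "iugc_opto"):
        records, truth, cfg = simulate_scenario(name, seed=1)
        windows = OptoWindows.from_protocol(cfg.build_protocol())
        rows = []
        for rec in records:
            r = opto_classify(
                window_rates(rec.spike_train, windows),
                unit_id=rec.spike_train.unit_id,
            )
            rows.append(
                {"unit_id": r.unit_id, "response": r.response,
                 "percent_change": r.percent_change}
            )
        responses = pd.DataFrame(rows)
        classes = classify_population(
            records, rate_window="baseline", baseline_window_s=windows.baseline
        )
        out[name] = dict(
            records=records, truth=truth, config=cfg, windows=windows,
            responses=responses, classes=classes,
        )
    return out
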