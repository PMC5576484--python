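"""Population composition tables, group-comparison utilities and the
end-to-end pipeline.

``compose`` aggregates per-unit evoked responses and putative classes into
the two standard presentations: the share of each response kind in the
population, and the class mix within each response kind. ``group_compare``
wraps routine Welch/ANOVA + Bonferroni comparisons; it is a convenience for
users' own group data and is never applied to simulated fixtures as if they
were animal statistics. ``run_pipeline`` drives
simulate/read -> PSTH -> detect -> classify -> compose and writes
tab-separated tables; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import psth as _psth
from .classify import classify_population
from .opto import OptoWindows, opto_classify, population_opto_table, window_rates
from .simulate import ScenarioConfig, simulate_population, scenario_config
from .spike_data import (
    StimulusProtocol,
    UnitRecord,
    read_events,
    read_spikes,
    write_responses,
    write_units,
)

__all__ = [
    "CompositionTable",
    "compose",
    "StatsReport",
    "group_compare",
    "PipelineError",
    "run_pipeline",
    "detect_evoked_population",
]


@dataclass(frozen=True)
class CompositionTable:
    """Response-kind by putative-class counts with derived percentage views."""

    cells: pd.DataFrame  # columns: response_kind, putative_class, n

    @property
    def n_units(self) -> int:
        return int(self.cells["n"].sum())

    @property
    def kind_totals(self) -> pd.Series:
        return self.cells.groupby("response_kind")["n"].sum()

    @property
    def class_totals(self) -> pd.Series:
        return self.cells.groupby("putative_class")["n"].sum()

    @property
    def percent_by_kind(self) -> pd.Series:
        """Percent of all units in each response kind (the pie-plot view)."""
        return 100.0 * self.kind_totals / self.n_units

    @property
    def class_within_kind(self) -> pd.DataFrame:
        """Percent of each putative class among units of one response kind."""
        out = self.cells.copy()
        out["percent"] = out.groupby("response_kind")["n"].transform(
            lambda s: 100.0 * s / s.sum()
        )
        return out

    @property
    def kind_within_class(self) -> pd.DataFrame:
        """Percent of each response kind within one putative class."""
        out = self.cells.copy()
        out["percent"] = out.groupby("putative_class")["n"].transform(
            lambda s: 100.0 * s / s.sum()
        )
        return out

    def headline(self) -> pd.DataFrame:
        """Integer-percent summary matching the precision of published
        composition legends; full precision lives in the property views."""
        rows = [
            {"quantity": f"percent_{kind}", "value": int(round(value))}
            for kind, value in self.percent_by_kind.items()
        ]
        return pd.DataFrame(rows)


def compose(
    responses: pd.DataFrame, classifications: pd.DataFrame
) -> CompositionTable:
    """Cross-tabulate per-unit response kinds with putative classes.

    ``responses`` needs columns ``unit_id, kind``; ``classifications`` needs
    ``unit_id, putative_class``. Duplicate or unmatched unit_ids raise.
    """
    if responses.empty and classifications.empty:
        return CompositionTable(
            pd.DataFrame(columns=["response_kind", "putative_class", "n"])
        )
    for name, frame in (("responses", responses), ("classifications", classifications)):
        dup = frame["unit_id"][frame["unit_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"{name}: duplicate unit_ids {sorted(set(dup))}")
    unmatched = set(responses["unit_id"]).symmetric_difference(
        set(classifications["unit_id"])
    )
    if unmatched:
        raise ValueError(f"unmatched unit_ids: {sorted(unmatched)}")
    merged = responses[["unit_id", "kind"]].merge(
        classifications[["unit_id", "putative_class"]], on="unit_id",
        validate="one_to_one",
    )
    cells = (
        merged.groupby(["kind", "putative_class"], sort=True)
        .size()
        .rename("n")
        .reset_index()
        .rename(columns={"kind": "response_kind"})
    )
    return CompositionTable(cells)


@dataclass(frozen=True)
class StatsReport:
    test: str
    statistic: float
    dof: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, dof, p_raw, p_bonferroni
    anova_table: pd.DataFrame | None = None


def _validate_groups(groups: Mapping) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r}: need at least 2 values")
        if np.all(arr == arr[0]) and len(groups) == 2:
            pass  # zero variance is tolerable for one side of a Welch test
        clean[label] = arr
    if all(np.ptp(v) == 0 for v in clean.values()):
        raise ValueError("all groups are degenerate (zero variance)")
    return clean


def _pairwise_bonferroni(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append(
            {
                "group_a": str(a),
                "group_b": str(b),
                "statistic": float(res.statistic),
                "dof": float(res.df),
                "p_raw": float(res.pvalue),
                "p_bonferroni": min(1.0, m * float(res.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    groups: Mapping[str, Sequence[float]],
    test: str = "welch_t",
) -> StatsReport:
    """Routine group comparison with Bonferroni-adjusted pairwise tests.

    ``welch_t``: exactly two groups, unequal-variance t test.
    ``anova_bonferroni``: one-way ANOVA across the groups (two-way via
    statsmodels OLS when every group key is a ``(factor_a, factor_b)``
    tuple), followed by all pairwise Welch comparisons with Bonferroni
    adjustment ``p_adj = min(1, m * p_raw)``.
    """
    clean = _validate_groups(groups)
    if test == "welch_t":
        if len(clean) != 2:
            raise ValueError("welch_t requires exactly 2 groups")
        (a, xa), (b, xb) = clean.items()
        res = sps.ttest_ind(xa, xb, equal_var=False)
        pairwise = _pairwise_bonferroni(clean)
        return StatsReport(
            test="welch_t",
            statistic=float(res.statistic),
            dof=float(res.df),
            p_value=float(res.pvalue),
            pairwise=pairwise,
        )
    if test == "anova_bonferroni":
        two_way = all(isinstance(k, tuple) and len(k) == 2 for k in clean)
        pairwise = _pairwise_bonferroni(clean)
        if two_way:
            import statsmodels.api as sm
            import statsmodels.formula.api as smf

            frame = pd.DataFrame(
                [
                    {"a": str(k[0]), "b": str(k[1]), "y": v}
                    for k, arr in clean.items()
                    for v in arr
                ]
            )
            model = smf.ols("y ~ C(a) * C(b)", data=frame).fit()
            table = sm.stats.anova_lm(model, typ=2)
            main = table.iloc[0]
            return StatsReport(
                test="two_way_anova_bonferroni",
                statistic=float(main["F"]),
                dof=float(main["df"]),
                p_value=float(main["PR(>F)"]),
                pairwise=pairwise,
                anova_table=table,
            )
        res = sps.f_oneway(*clean.values())
        k = len(clean)
        n = sum(v.size for v in clean.values())
        return StatsReport(
            test="one_way_anova_bonferroni",
            statistic=float(res.statistic),
            dof=float(k - 1),
            p_value=float(res.pvalue),
            pairwise=pairwise,
        )
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and unit)."""


def detect_evoked_population(
    records: Sequence[UnitRecord],
    protocol: StimulusProtocol,
    config: _psth.DetectionConfig | None = None,
) -> pd.DataFrame:
    """Run PSTH construction and epoch detection for every unit."""
    cfg = config or _psth.DetectionConfig()
    rows = []
    for rec in records:
        train = rec.spike_train
        try:
            p = _psth.build_psth(
                train, protocol, cfg.bin_width_ms, cfg.window_ms, cfg.baseline_ms
            )
            resp = _psth.classify_evoked(p, cfg)
        except Exception as exc:
            raise PipelineError(
                f"stage detect: unit {train.unit_id!r}: {exc}"
            ) from exc
        rows.append(
            {
                "unit_id": train.unit_id,
                "kind": resp.kind,
                "onset_ms": resp.onset_ms,
                "offset_ms": resp.offset_ms,
                "duration_ms": resp.duration_ms,
                "magnitude_counts": resp.magnitude_counts,
                "n_trials": p.n_trials,
            }
        )
    return pd.DataFrame(rows)


def _opto_stage(
    records: Sequence[UnitRecord], protocol: StimulusProtocol, threshold: float
) -> tuple[pd.DataFrame, OptoWindows]:
    windows = OptoWindows.from_protocol(protocol)
    rows = []
    for rec in records:
        train = rec.spike_train
        try:
            rates = window_rates(train, windows)
            resp = opto_classify(rates, threshold, unit_id=train.unit_id)
        except Exception as exc:
            raise PipelineError(f"stage opto: unit {train.unit_id!r}: {exc}") from exc
        rows.append(
            {
                "unit_id": resp.unit_id,
                "rate_baseline_hz": resp.rate_baseline_hz,
                "rate_stim_hz": resp.rate_stim_hz,
                "rate_post_hz": resp.rate_post_hz,
                "percent_change": resp.percent_change,
                "response": resp.response,
                # evoked-kind vocabulary, for composition tables
                "kind": {"excited": "excitation", "inhibited": "inhibition",
                         "none": "none"}[resp.response],
            }
        )
    return pd.DataFrame(rows), windows


@dataclass(frozen=True)
class PipelineResult:
    out_dir: Path
    responses: pd.DataFrame
    classifications: pd.DataFrame
    composition: CompositionTable
    truth: pd.DataFrame | None
    opto: pd.DataFrame | None


def run_pipeline(config: Mapping | str | Path) -> PipelineResult:
    """Run the full analysis from a config mapping or YAML file.

    Config keys: either ``scenario`` (a packaged scenario name) with optional
    ``seed``, or ``spikes`` + ``events`` input paths; ``out_dir`` (required);
    optional ``detection`` overrides (run_length, sd_multiplier,
    inhibition_fraction, onset_rule, ...) and ``opto_threshold_percent``.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    truth: pd.DataFrame | None = None
    if "scenario" in cfg:
        try:
            scen = scenario_config(cfg["scenario"])
            records, truth = simulate_population(scen, seed=cfg.get("seed"))
            protocol = scen.build_protocol()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage simulate: {exc}") from exc
    else:
        try:
            records = read_spikes(cfg["spikes"])
            protocol = read_events(cfg["events"])
        except Exception as exc:
            raise PipelineError(f"stage read: {exc}") from exc

    det_cfg = _psth.DetectionConfig(**cfg.get("detection", {}))
    opto_table: pd.DataFrame | None = None
    if protocol.kind == "electrical":
        responses = detect_evoked_population(records, protocol, det_cfg)
        try:
            classifications = classify_population(records, rate_window="whole")
        except Exception as exc:
            raise PipelineError(f"stage classify: {exc}") from exc
    else:
        responses, windows = _opto_stage(
            records, protocol, float(cfg.get("opto_threshold_percent", 20.0))
        )
        try:
            classifications = classify_population(
                records, rate_window="baseline", baseline_window_s=windows.baseline
            )
        except Exception as exc:
            raise PipelineError(f"stage classify: {exc}") from exc
        opto_table = population_opto_table(
            [  # rebuild light objects for the cross-tab helper
                _row_to_opto(r) for r in responses.itertuples()
            ],
            classifications,
        )

    try:
        composition = compose(responses[["unit_id", "kind"]], classifications)
    except Exception as exc:
        raise PipelineError(f"stage compose: {exc}") from exc

    # ---- write the bundle (stable order, no timestamps => byte-identical) --
    write_units(records, out_dir / "units.tsv")
    if truth is not None:
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    if protocol.kind == "electrical":
        write_responses(responses, out_dir / "responses.tsv")
    else:
        responses.drop(columns=["kind"]).to_csv(
            out_dir / "opto_responses.tsv", sep="\t", index=False
        )
        opto_table.to_csv(out_dir / "opto_composition.tsv", sep="\t", index=False)
    classifications.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    composition.cells.to_csv(out_dir / "composition_counts.tsv", sep="\t", index=False)
    composition.class_within_kind.to_csv(
        out_dir / "composition_percent.tsv", sep="\t", index=False
    )
    composition.headline().to_csv(
        out_dir / "composition_headline.tsv", sep="\t", index=False
    )
    (out_dir / "run.log").write_text(
        "pipeline parameters\n" + json.dumps(
            {k: v for k, v in cfg.items() if k != "out_dir"},
            indent=1, sort_keys=True, default=str,
        ) + "\n"
    )
    return PipelineResult(
        out_dir=out_dir,
        responses=responses,
        classifications=classifications,
        composition=composition,
        truth=truth,
        opto=opto_table,
    )


def _row_to_opto(row):
    from .opto import OptoResponse

    return OptoResponse(
        unit_id=row.unit_id,
        rate_baseline_hz=row.rate_baseline_hz,
        rate_stim_hz=row.rate_stim_hz,
        rate_post_hz=row.rate_post_hz,
        percent_change=row.percent_change,
        response=row.response,
    )
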