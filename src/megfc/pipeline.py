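"""End-to-end orchestration: dataset -> segments -> FC networks -> graph
metrics -> pattern calls -> group statistics, with validated inputs, a
serializable configuration and a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import fc_matrix, threshold_network
from .errors import CollinearityError, DegenerateTestError
from .graphmetrics import graph_metrics
from .patterns import EDGE_CLASSES, LABEL_DISTRIBUTED, call_pattern
from .preprocess import (
    PERIOD_ICTAL,
    PERIOD_TERMINATION,
    PERIODS,
    SeizureEvent,
    band_by_name,
    default_bands,
    extract_segments,
    filter_segment,
    notch_array,
)
from .stats import (
    bh_fdr,
    bonferroni,
    encode_sex,
    fisher_exact_2x2,
    metric_t_test,
    partial_correlation,
    summarize_clinical,
)
from .synth import StudyDataset

log = logging.getLogger("megfc")

METRIC_NAMES = ("S", "D", "L", "C")


class ValidationError(ValueError):
    """Raised by run_study when the input dataset fails validation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("input validation failed:\n" + "\n".join(f"- {v}" for v in violations))


@dataclass
class PipelineConfig:
    """All analysis settings.  Defaults reproduce the stated study procedure:
    seven bands, 3-s ictal/termination and 30-s interictal segments with a
    10-s gap, per-pair alpha 0.05 on the nominal sample count, pattern
    dominance theta 0.5, paired t-tests, Bonferroni + FDR over the 28-test
    family with significance by the stricter of the two."""

    band_names: list[str] = field(default_factory=lambda: [b.name for b in default_bands()])
    alpha: float = 0.05
    sample_mode: str = "nominal"  # or "bandwidth"
    theta: float = 0.5
    ictal_len_s: float = 3.0
    interictal_len_s: float = 30.0
    interictal_gap_s: float = 10.0
    pad_s: float = 1.0
    notch_base: float | None = 50.0
    periods: tuple[str, ...] = PERIODS
    paired: bool = True
    correction: str = "stricter"  # "bonferroni" | "fdr" | "stricter"
    seed: int = 0

    def __post_init__(self) -> None:
        self.periods = tuple(self.periods)
        self.bands()  # validate band names
        if self.correction not in ("bonferroni", "fdr", "stricter"):
            raise ValueError(f"unknown correction {self.correction!r}")

    def bands(self):
        return [band_by_name(n) for n in self.band_names]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["periods"] = list(self.periods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def recovery_config(seed: int = 0, periods: tuple[str, ...] = (PERIOD_ICTAL, PERIOD_TERMINATION)) -> PipelineConfig:
    """Analysis settings frozen for the planted-coupling recovery experiment:
    bandwidth-corrected effective sample count and per-pair alpha 0.01, so the
    band-limited null edge rate is low enough for count-based pattern calls
    (see docs/methods.md on threshold calibration)."""
    return PipelineConfig(alpha=0.01, sample_mode="bandwidth", periods=periods, seed=seed)


@dataclass
class StudyResult:
    """Per-segment tables plus the group-level statistics of one run."""

    metrics: pd.DataFrame
    patterns: pd.DataFrame
    metric_tests: pd.DataFrame
    fisher_tests: pd.DataFrame
    clinical_correlations: pd.DataFrame
    clinical_summary: dict


# ---------------------------------------------------------------------------
# Per-seizure analysis
# ---------------------------------------------------------------------------


def analyze_seizure(
    rec_id: str,
    patient: int,
    recording,
    event: SeizureEvent,
    config: PipelineConfig,
    on_network=None,
):
    """FC networks, graph metrics and pattern calls for one seizure, all bands
    and periods.  ``on_network(rec_id, fc, net)`` is called per network (used
    by run_study to stream matrices to disk)."""
    windows = extract_segments(
        recording,
        event,
        interictal_gap_s=config.interictal_gap_s,
        ictal_len_s=config.ictal_len_s,
        interictal_len_s=config.interictal_len_s,
        pad_s=config.pad_s,
        periods=config.periods,
    )
    if config.notch_base is not None:
        # notch once per window; the per-band filtering then skips it
        for w in windows.values():
            w.data = notch_array(w.data, w.fs, config.notch_base)
    metric_rows, pattern_rows = [], []
    for band in config.bands():
        for period in config.periods:
            seg = filter_segment(windows[period], band, notch_base=None)
            fc = fc_matrix(seg)
            net = threshold_network(fc, alpha=config.alpha, sample_mode=config.sample_mode)
            gm = graph_metrics(net, fc)
            call = call_pattern(net, theta=config.theta)
            base = {
                "recording_id": rec_id,
                "patient": patient,
                "period": period,
                "band": band.name,
            }
            metric_rows.append(
                base
                | {
                    "S": gm.S,
                    "D": gm.D,
                    "L": gm.L,
                    "C": gm.C,
                    "n_edges": gm.n_edges,
                    "alpha": config.alpha,
                }
            )
            pattern_rows.append(
                base
                | {"label": call.label, "n_edges": call.n_edges}
                | {f"frac_{k}": call.fractions[k] for k in EDGE_CLASSES}
            )
            if on_network is not None:
                on_network(rec_id, fc, net)
    return metric_rows, pattern_rows


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def _apply_corrections(df: pd.DataFrame, correction: str, level: float = 0.05) -> pd.DataFrame:
    """Attach p_bonf, q_fdr and the significance flag to a table with p_raw;
    the family is the set of non-NaN p-values in the table."""
    if df.empty:
        return df.reindex(columns=list(df.columns) + ["p_bonf", "q_fdr", "significant"])
    p = df["p_raw"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    p_bonf = np.full_like(p, np.nan)
    q_fdr = np.full_like(p, np.nan)
    if ok.any():
        p_bonf[ok] = bonferroni(p[ok])
        q_fdr[ok] = bh_fdr(p[ok])
    df = df.copy()
    df["p_bonf"] = p_bonf
    df["q_fdr"] = q_fdr
    if correction == "bonferroni":
        sig = p_bonf < level
    elif correction == "fdr":
        sig = q_fdr < level
    else:  # stricter of the two
        sig = (p_bonf < level) & (q_fdr < level)
    df["significant"] = np.where(np.isfinite(p), sig, False)
    return df


def compare_metrics(
    metrics: pd.DataFrame,
    config: PipelineConfig,
    period_a: str = PERIOD_ICTAL,
    period_b: str = PERIOD_TERMINATION,
) -> pd.DataFrame:
    """Per band x metric t-tests between two periods, corrected as one family.

    ``t`` is oriented so that a positive statistic means larger values during
    ``period_b`` (termination) than ``period_a``.  Segments whose metric is
    undefined (NaN, e.g. L of an edgeless network) are dropped pairwise;
    degenerate tests report NaN p and are never flagged significant.
    """
    rows = []
    for band in config.band_names:
        sub = metrics[metrics["band"] == band]
        piv = sub.pivot_table(index="recording_id", columns="period", values=list(METRIC_NAMES))
        for m in METRIC_NAMES:
            try:
                pair = piv[m][[period_a, period_b]].dropna()
            except KeyError:
                continue
            row = {"band": band, "metric": m, "n": len(pair)}
            try:
                t, p = metric_t_test(
                    pair[period_b].to_numpy(), pair[period_a].to_numpy(), paired=config.paired
                )
                row |= {
                    "statistic": t,
                    "p_raw": p,
                    "mean_" + period_a: pair[period_a].mean(),
                    "mean_" + period_b: pair[period_b].mean(),
                }
            except (DegenerateTestError, ValueError) as exc:
                log.debug("degenerate t-test (%s, %s): %s", band, m, exc)
                row |= {
                    "statistic": np.nan,
                    "p_raw": np.nan,
                    "mean_" + period_a: pair[period_a].mean() if len(pair) else np.nan,
                    "mean_" + period_b: pair[period_b].mean() if len(pair) else np.nan,
                }
            rows.append(row)
    return _apply_corrections(pd.DataFrame(rows), config.correction)


def compare_patterns(
    patterns: pd.DataFrame,
    config: PipelineConfig,
    period_a: str = PERIOD_ICTAL,
    period_b: str = PERIOD_TERMINATION,
) -> pd.DataFrame:
    """Fisher's exact test per band on the modal ictal pattern label, the
    per-band family corrected together."""
    rows = []
    for band in config.band_names:
        sub = patterns[patterns["band"] == band]
        calls = {
            p: sub[sub["period"] == p]["label"].tolist() for p in (period_a, period_b)
        }
        if not calls[period_a] or not calls[period_b]:
            continue
        counts_a = pd.Series(calls[period_a]).value_counts()
        label = counts_a.index[0]
        if label == LABEL_DISTRIBUTED and len(counts_a) > 1:
            label = counts_a.index[1] if counts_a.iloc[1] == counts_a.iloc[0] else label
        a_with = int(sum(c == label for c in calls[period_a]))
        b_with = int(sum(c == label for c in calls[period_b]))
        table = [
            [a_with, len(calls[period_a]) - a_with],
            [b_with, len(calls[period_b]) - b_with],
        ]
        rows.append(
            {
                "band": band,
                "label": label,
                f"{period_a}_with": a_with,
                f"{period_a}_n": len(calls[period_a]),
                f"{period_b}_with": b_with,
                f"{period_b}_n": len(calls[period_b]),
                "p_raw": fisher_exact_2x2(table),
            }
        )
    return _apply_corrections(pd.DataFrame(rows), config.correction)


def clinical_metric_correlations(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig,
    period: str = PERIOD_ICTAL,
    target: str = "seizure_freq_per_day",
) -> pd.DataFrame:
    """Partial correlation (adjusted for age, sex, disease duration) between
    each band x metric (per-patient mean over the given period) and a clinical
    feature, corrected as one family."""
    clin = clinical.set_index("patient")
    covars = np.column_stack(
        [
            clin["age_years"].to_numpy(dtype=float),
            encode_sex(clin["sex"]),
            clin["duration_months"].to_numpy(dtype=float),
        ]
    )
    y = clin[target].to_numpy(dtype=float)
    rows = []
    per = metrics[metrics["period"] == period]
    for band in config.band_names:
        sub = per[per["band"] == band]
        by_patient = sub.groupby("patient")[list(METRIC_NAMES)].mean()
        for m in METRIC_NAMES:
            x = by_patient[m].reindex(clin.index)
            ok = x.notna().to_numpy()
            if ok.sum() <= covars.shape[1] + 2:
                continue
            try:
                r, p = partial_correlation(x.to_numpy()[ok], y[ok], covars[ok])
            except CollinearityError as exc:
                # a covariate can degenerate on the surviving patient subset
                log.debug("skipping partial correlation (%s, %s): %s", band, m, exc)
                continue
            rows.append({"band": band, "metric": m, "n": int(ok.sum()), "r": r, "p_raw": p})
    return _apply_corrections(pd.DataFrame(rows), config.correction)


def analyze_study(dataset: StudyDataset, config: PipelineConfig, on_network=None) -> StudyResult:
    """Run the full analysis on an in-memory study dataset."""
    metric_rows, pattern_rows = [], []
    t0 = time.perf_counter()
    for rec_id, patient, rec, event in dataset.records:
        if event is None:
            continue
        mr, pr = analyze_seizure(rec_id, patient, rec, event, config, on_network=on_network)
        metric_rows.extend(mr)
        pattern_rows.extend(pr)
    log.info("analyzed %d seizures in %.1f s", len(dataset.records), time.perf_counter() - t0)
    metrics = pd.DataFrame(metric_rows)
    patterns = pd.DataFrame(pattern_rows)
    return StudyResult(
        metrics=metrics,
        patterns=patterns,
        metric_tests=compare_metrics(metrics, config),
        fisher_tests=compare_patterns(patterns, config),
        clinical_correlations=clinical_metric_correlations(metrics, dataset.clinical, config),
        clinical_summary=summarize_clinical(dataset.clinical),
    )


# ---------------------------------------------------------------------------
# Disk-facing entry points
# ---------------------------------------------------------------------------


def validate_inputs(data_dir, config: PipelineConfig | None = None) -> list[str]:
    """Check a dataset directory; returns a list of violations (empty = valid)."""
    from . import io as _io

    config = config or PipelineConfig()
    data = Path(data_dir)
    violations: list[str] = []
    for name in ("events.tsv", "regions.tsv", "clinical.tsv"):
        if not (data / name).exists():
            violations.append(f"missing file: {name}")
    if not (data / "recordings").is_dir():
        violations.append("missing recordings/ directory")
        return violations
    if violations:
        return violations

    region_of = _io.read_regions(data / "regions.tsv")
    bad_regions = {c: r for c, r in region_of.items() if r not in
                   ("frontal", "central", "temporal", "parietal", "occipital")}
    for c, r in bad_regions.items():
        violations.append(f"channel {c}: unknown region {r!r}")
    events = _io.read_events(data / "events.tsv")
    min_dur = 2 * config.ictal_len_s
    for _, row in events.iterrows():
        dur = row["offset_s"] - row["onset_s"]
        if dur < min_dur:
            violations.append(
                f"event {row['recording_id']}: duration {dur:.2f} s < {min_dur:.0f} s"
            )
    f_hi = max(b.f_hi for b in config.bands())
    for path in sorted((data / "recordings").glob("*.h5")):
        try:
            rec = _io.read_recording(path, region_of)
        except Exception as exc:  # unreadable or channels missing regions
            violations.append(f"recording {path.name}: {exc}")
            continue
        if rec.fs <= 2 * f_hi:
            violations.append(
                f"recording {path.name}: fs {rec.fs} Hz cannot resolve bands up to {f_hi} Hz"
            )
    return violations


def run_study(data_dir, out_dir, config: PipelineConfig | None = None) -> StudyResult:
    """Validate, load, analyze and write one study.

    Outputs under ``out_dir``: fc/ and networks/ matrix TSVs (+ JSON
    sidecars), metrics.tsv, patterns.tsv, stats_metrics.tsv,
    stats_patterns.tsv, stats_clinical_correlations.tsv,
    clinical_summary.json and manifest.json.  Idempotent for fixed inputs,
    config and seed.
    """
    from . import io as _io

    config = config or PipelineConfig()
    violations = validate_inputs(data_dir, config)
    if violations:
        raise ValidationError(violations)

    out = Path(out_dir)
    (out / "fc").mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(parents=True, exist_ok=True)

    def on_network(rec_id, fc, net):
        stem = f"{rec_id}_{fc.period}_{fc.band.name.replace(' ', '_')}"
        _io.write_fc_matrix(fc, out / "fc" / f"{stem}.tsv")
        _io.write_network(net, out / "networks" / f"{stem}.tsv")

    dataset = _io.read_study(data_dir)
    result = analyze_study(dataset, config, on_network=on_network)

    result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    result.patterns.to_csv(out / "patterns.tsv", sep="\t", index=False)
    result.metric_tests.to_csv(out / "stats_metrics.tsv", sep="\t", index=False)
    result.fisher_tests.to_csv(out / "stats_patterns.tsv", sep="\t", index=False)
    result.clinical_correlations.to_csv(
        out / "stats_clinical_correlations.tsv", sep="\t", index=False
    )
    (out / "clinical_summary.json").write_text(json.dumps(result.clinical_summary, indent=1))
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "megfc_version": __version__,
        "numpy_version": np.__version__,
        "n_recordings": len(dataset.records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
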