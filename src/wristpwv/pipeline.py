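"""End-to-end orchestration: signals -> cycles -> fiducials -> WPD ->
features -> model -> evaluation, with a manifest for reproducible runs.

Every excluded cycle or measurement is logged with its reason (cycle SQI
failure, missing R pairing, WPD-SQI failure, no accepted cycles), and all
effective parameters are echoed into the run manifest so a run can be
reproduced bit-identically from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, fiducials, models, preprocessing, synth, wpd

__all__ = ["RunConfig", "RunResult", "extract_record", "extract_cohort", "run"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run over a synthetic cohort."""

    seed: int = 0
    n_participants: int = 12
    rounds_per_participant: int = 2
    n_beats: int = 10
    pwv_range: tuple[float, float] = (1000.0, 2100.0)
    cohort_noise_sd: float = 40.0
    sqi: preprocessing.SqiConfig = field(default_factory=preprocessing.SqiConfig)
    omega: float = 80.0
    wpd_sqi_threshold: float = 2e-3
    model: str = "hierarchical"  # hierarchical | general | multivar-si | multivar-p2o
    boundary: float = 1600.0
    overlap: float = 400.0
    test_frac: float = 0.3
    oversample: bool = True
    ratio_pairs: tuple[tuple[str, str], ...] = (("age", "n_ms"), ("si", "cycle_len"),
                                                ("p2o", "cycle_len"))
    out_dir: str | None = None

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["sqi"] = dataclasses.asdict(self.sqi)
        return d


@dataclass
class RunResult:
    feature_table: pd.DataFrame
    cycle_table: pd.DataFrame
    exclusions: list[dict]
    reports: dict
    manifest: dict
    model: object | None = None


def extract_record(
    record: synth.SignalRecord,
    sqi: preprocessing.SqiConfig | None = None,
    omega: float = 80.0,
    wpd_sqi_threshold: float = 2e-3,
    height_cm: float | None = None,
) -> tuple[list[features.FeatureVector], list[dict]]:
    """Run preprocessing, screening, fiducials, WPD and per-cycle feature
    extraction on one record; returns accepted cycle vectors and an
    exclusion log."""
    exclusions: list[dict] = []
    ppg, ecg = preprocessing.preprocess(record.ppg, record.ecg, record.fs)
    r_peaks = preprocessing.detect_r_peaks(ecg, record.fs)
    valleys = preprocessing.detect_valleys(ppg, record.fs)
    tag = {"participant_id": record.participant_id, "round_id": record.round_id}
    try:
        cycles, report = preprocessing.segment_and_screen(
            ppg, ecg, valleys, r_peaks, sqi, fs=record.fs
        )
    except ValueError as exc:
        exclusions.append({**tag, "stage": "segmentation", "reason": str(exc)})
        return [], exclusions

    vectors: list[features.FeatureVector] = []
    flag_iter = iter(zip(report.pass_flags, report.reasons))
    for cyc in cycles:
        ok, reason = next(flag_iter)
        if not ok:
            exclusions.append({**tag, "stage": "sqi", "onset": cyc.onset_index,
                               "reason": reason})
            continue
        try:
            fset = fiducials.extract_fiducials(cyc)
        except ValueError as exc:
            exclusions.append({**tag, "stage": "fiducials", "onset": cyc.onset_index,
                               "reason": str(exc)})
            continue
        dec = wpd.decompose_pulse(cyc, fset, wpd.DecompositionConfig(omega=omega))
        if not wpd.wpd_quality(dec, cyc, wpd_sqi_threshold):
            exclusions.append({**tag, "stage": "wpd-sqi", "onset": cyc.onset_index,
                               "reason": f"mse {dec.wpd_sqi:.2e} above threshold"})
            continue
        vectors.append(features.extract_cycle_features(cyc, fset, dec, height_cm))
    return vectors, exclusions


def extract_cohort(cohort: synth.SyntheticCohort, config: RunConfig) -> RunResult:
    """Feature matrix (one row per measurement) for a synthetic cohort."""
    anthro = cohort.anthropometrics.set_index("participant_id")
    cycle_rows = []
    exclusions: list[dict] = []
    for rec in cohort.records:
        h = float(anthro.loc[rec.participant_id, "height_cm"])
        vecs, excl = extract_record(
            rec, config.sqi, config.omega, config.wpd_sqi_threshold, height_cm=h
        )
        exclusions.extend(excl)
        for v in vecs:
            row = v.to_series()
            row["measurement_id"] = f"{rec.participant_id}/{rec.round_id}"
            row["sequence_id"] = f"{rec.participant_id}/{rec.round_id}/seq"
            cycle_rows.append(row)
    if not cycle_rows:
        raise RuntimeError("no cycles accepted anywhere in the cohort")
    cycle_table = pd.DataFrame(cycle_rows)
    meas = features.aggregate_measurement(cycle_table)

    meta = cohort.measurements.copy()
    meta["measurement_id"] = meta["participant_id"] + "/" + meta["round_id"]
    meta = meta.set_index("measurement_id")
    dropped = meta.index.difference(meas.index)
    for mid in dropped:
        exclusions.append({"measurement_id": mid, "stage": "aggregation",
                           "reason": "no accepted cycles"})
    meta = meta.loc[meas.index]
    table = meas.join(meta[["participant_id", "true_pwv"]])
    table = table.join(anthro[["age", "height_cm", "weight_kg"]], on="participant_id")
    for mid, row in table.iterrows():
        basic = features.compute_body_lengths(
            row["height_cm"], age=row["age"], weight_kg=row["weight_kg"]
        )
        for fid, val in basic.values.items():
            table.loc[mid, fid] = val
    # measurement-level ratio features
    for u, v in config.ratio_pairs:
        if u in table.columns and v in table.columns:
            denom = table[v].to_numpy(float)
            ok = np.abs(denom) >= features.EPS_DENOM
            vals = np.where(ok, table[u].to_numpy(float) / np.where(ok, denom, 1.0), np.nan)
            table[f"{u}_over_{v}"] = vals
    return RunResult(
        feature_table=table, cycle_table=cycle_table, exclusions=exclusions,
        reports={}, manifest=config.to_manifest(),
    )


def run(config: RunConfig) -> RunResult:
    """Full reproducible run: generate cohort, extract features, fit the
    configured model on a participant-disjoint split, evaluate, and write
    artifacts when ``out_dir`` is set."""
    cohort = synth.synth_cohort(
        n_participants=config.n_participants,
        rounds_per_participant=config.rounds_per_participant,
        pwv_range=config.pwv_range,
        noise_sd=config.cohort_noise_sd,
        n_beats=config.n_beats,
        seed=config.seed,
    )
    result = extract_cohort(cohort, config)
    table = result.feature_table.dropna(axis=1, how="any")

    y = table["true_pwv"].to_numpy(float)
    pids = table["participant_id"].to_numpy()
    drop = ["true_pwv", "participant_id", "height_cm", "weight_kg"]
    X = table.drop(columns=[c for c in drop if c in table.columns])

    train_mask, test_mask = models.participant_split(pids, config.test_frac, config.seed)
    models.check_participant_disjoint(pids[train_mask], pids[test_mask])

    fitted = None
    if config.model.startswith("multivar"):
        variant = "si" if config.model.endswith("si") else "p2o"
        fitted = models.fit_multivariable(X[train_mask], y[train_mask], variant)
        x2 = models.multivariable_predictor(X[test_mask], variant)
        pred = fitted.predict(X[test_mask]["age"].to_numpy(), x2)
    else:
        Xtr, ytr = X[train_mask], y[train_mask]
        if config.oversample:
            df = Xtr.copy()
            df["pwv"] = ytr
            df = models.oversample_bins(df, seed=config.seed)
            ytr = df.pop("pwv").to_numpy()
            Xtr = df.drop(columns=["_oversampled"])
        if config.model == "hierarchical":
            fitted = models.fit_hierarchical(
                Xtr, ytr, tau=config.boundary, W=config.overlap, seed=config.seed,
                participants=pids[train_mask],
            )
            pred = models.predict_hierarchical(fitted, X[test_mask])
        elif config.model == "general":
            fitted = models.fit_general(Xtr, ytr, seed=config.seed)
            pred = fitted.predict(X[test_mask])
        else:
            raise ValueError(f"unknown model {config.model!r}")

    reports = evaluation.evaluate(pred, y[test_mask], pids[test_mask])
    ba = evaluation.bland_altman(pred, y[test_mask])
    result.reports = {
        "rounds": reports["rounds"].to_dict(),
        "participants": reports["participants"].to_dict(),
        "bland_altman": {k: ba[k] for k in ("bias", "loa_low", "loa_high")},
    }
    result.model = fitted
    result.manifest["n_test_measurements"] = int(test_mask.sum())
    result.manifest["n_train_measurements"] = int(train_mask.sum())

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.feature_table.to_csv(out / "features.csv")
        result.cycle_table.to_csv(out / "cycles.csv", index=False)
        ba["table"].to_csv(out / "bland_altman.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(result.reports, indent=2))
        (out / "exclusions.json").write_text(json.dumps(result.exclusions, indent=2))
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
    return result
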