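"""Synthetic wrist PPG/ECG generation with known ground truth.

A PPG pulse is modelled as the sum of five Gaussian component waves

    G(n Ts | Theta) = sum_i alpha_i * exp(-(n - beta_i)^2 / (2 gamma_i^2))

with per-component amplitude ``alpha`` (normalized units), position ``beta``
and width ``gamma`` (both in samples).  Records concatenate such pulses,
add an ECG channel whose R spike precedes each PPG valley by a configurable
pulse-arrival time (PAT), and optionally superimpose baseline wander, 60 Hz
powerline interference and white noise.  Cohorts assign each participant an
age and a latent stiffness that jointly drive PAT, the diastolic-wave
timing and the true pulse wave velocity, so that downstream feature
extraction and regression can be validated against planted relationships.

Everything here is a pure function of its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentParams",
    "ComponentSet",
    "SignalRecord",
    "RecordConfig",
    "SyntheticCohort",
    "DEFAULT_TEMPLATE",
    "synth_pulse",
    "synth_pulse_naive",
    "synth_record",
    "synth_cohort",
    "synth_feature_cohort",
    "write_record_csv",
    "read_record_csv",
]


@dataclass(frozen=True)
class ComponentParams:
    """One Gaussian component wave: amplitude, position and width.

    ``alpha`` is in normalized pulse units (> 0), ``beta`` and ``gamma``
    are in samples (``0 <= beta``, ``gamma > 0``).
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class ComponentSet:
    """Ordered set of exactly five component waves (G1..G5)."""

    components: tuple[ComponentParams, ...]

    def __post_init__(self) -> None:
        if len(self.components) != 5:
            raise ValueError(f"exactly 5 components required, got {len(self.components)}")
        betas = [c.beta for c in self.components]
        if any(b1 > b2 for b1, b2 in zip(betas, betas[1:])):
            raise ValueError(f"component positions must be non-decreasing, got {betas}")

    @classmethod
    def from_arrays(
        cls, alphas: Sequence[float], betas: Sequence[float], gammas: Sequence[float]
    ) -> "ComponentSet":
        return cls(tuple(ComponentParams(a, b, g) for a, b, g in zip(alphas, betas, gammas)))

    def as_flat(self) -> np.ndarray:
        """Parameters as [a1..a5, b1..b5, g1..g5]."""
        return np.array(
            [c.alpha for c in self.components]
            + [c.beta for c in self.components]
            + [c.gamma for c in self.components]
        )


@dataclass
class Annotations:
    """Construction ground truth carried alongside a synthetic record."""

    r_indices: np.ndarray
    valley_indices: np.ndarray
    t_indices: np.ndarray
    pat_samples: np.ndarray
    cycle_component_sets: list[ComponentSet]

    def to_dict(self) -> dict:
        return {
            "r_indices": self.r_indices.tolist(),
            "valley_indices": self.valley_indices.tolist(),
            "t_indices": self.t_indices.tolist(),
            "pat_samples": self.pat_samples.tolist(),
            "cycle_component_sets": [
                {
                    "alpha": [c.alpha for c in cs.components],
                    "beta": [c.beta for c in cs.components],
                    "gamma": [c.gamma for c in cs.components],
                }
                for cs in self.cycle_component_sets
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotations":
        return cls(
            r_indices=np.asarray(d["r_indices"], dtype=int),
            valley_indices=np.asarray(d["valley_indices"], dtype=int),
            t_indices=np.asarray(d["t_indices"], dtype=int),
            pat_samples=np.asarray(d["pat_samples"], dtype=int),
            cycle_component_sets=[
                ComponentSet.from_arrays(cs["alpha"], cs["beta"], cs["gamma"])
                for cs in d["cycle_component_sets"]
            ],
        )


@dataclass
class SignalRecord:
    """Time-aligned PPG and single-lead ECG with metadata."""

    ppg: np.ndarray
    ecg: np.ndarray
    fs: float = 256.0
    participant_id: str = "P000"
    round_id: str = "R0"
    annotations: Annotations | None = None

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        if len(self.ppg) != len(self.ecg):
            raise ValueError("ppg and ecg must have equal length")


# Template morphology as fractions of the cycle length M: a dominant
# forward wave with a crisp systolic takeoff, two systolic reflections,
# and a small diastolic pair (wrist pulses have weak diastolic features).
DEFAULT_TEMPLATE: dict[str, tuple[float, ...]] = {
    "alpha": (1.00, 0.55, 0.30, 0.30, 0.18),
    "beta_frac": (0.12, 0.22, 0.36, 0.58, 0.74),
    "gamma_frac": (0.038, 0.058, 0.078, 0.075, 0.150),
}


def _validate_theta(theta_set: ComponentSet, M: int) -> None:
    if M < 32:
        raise ValueError(f"cycle length M must be >= 32, got {M}")
    for c in theta_set.components:
        if c.beta >= M:
            raise ValueError(f"component position beta={c.beta} must be < M={M}")


def synth_pulse(theta_set: ComponentSet, M: int, fs: float = 256.0) -> np.ndarray:
    """Synthesize one PPG pulse of length ``M`` from five Gaussian components.

    Evaluates ``G(n Ts | Theta)`` at sample indices ``n = 0..M-1``.  Since
    both position and width are expressed in samples the sampling interval
    cancels and the result is independent of ``fs``.
    """
    _validate_theta(theta_set, M)
    n = np.arange(M, dtype=float)
    out = np.zeros(M)
    for c in theta_set.components:
        out += c.alpha * np.exp(-((n - c.beta) ** 2) / (2.0 * c.gamma**2))
    return out


def synth_pulse_naive(theta_set: ComponentSet, M: int, fs: float = 256.0) -> np.ndarray:
    """Brute-force per-sample double loop; the oracle for :func:`synth_pulse`."""
    _validate_theta(theta_set, M)
    import math

    out = np.empty(M)
    for n in range(M):
        acc = 0.0
        for c in theta_set.components:
            acc += c.alpha * math.exp(-((n - c.beta) ** 2) / (2.0 * c.gamma**2))
        out[n] = acc
    return out


@dataclass
class RecordConfig:
    """Generation parameters for one synthetic record."""

    heart_rate_bpm: float = 72.0
    n_beats: int = 20
    pat_samples: int = 180
    fs: float = 256.0
    template: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE)
    )
    jitter_sd: float = 0.0  # relative SD applied to alpha/beta/gamma per beat
    hrv_sd: float = 0.0  # relative SD of per-beat cycle length
    baseline_amp: float = 0.0  # baseline wander amplitude (normalized units)
    baseline_freq: float = 0.15  # Hz
    powerline_amp: float = 0.0  # 60 Hz interference amplitude
    noise_sd: float = 0.0  # additive white noise SD
    t_offset_s: float = 0.28  # R-to-T delay in seconds
    seed: int = 0


def _template_components(template: dict, M: int) -> ComponentSet:
    return ComponentSet.from_arrays(
        template["alpha"],
        [f * M for f in template["beta_frac"]],
        [f * M for f in template["gamma_frac"]],
    )


def synth_record(
    config: RecordConfig,
    participant_id: str = "P000",
    round_id: str = "R0",
) -> SignalRecord:
    """Generate a synchronized PPG/ECG record from ``config``.

    The PPG is a concatenation of five-Gaussian pulses; the ECG carries one
    narrow R spike ``pat_samples`` before each PPG valley and a wider T bump
    after it.  Ground-truth indices and per-cycle component sets are stored
    in the record's annotations.
    """
    if config.pat_samples <= 0:
        raise ValueError("pat_samples must be > 0 (R precedes the PPG valley)")
    if config.n_beats < 3:
        raise ValueError("n_beats must be >= 3 (cycle statistics undefined below)")

    rng = np.random.default_rng(config.seed)
    fs = config.fs
    M0 = int(round(fs * 60.0 / config.heart_rate_bpm))

    cycle_lengths = []
    for _ in range(config.n_beats):
        m = M0
        if config.hrv_sd > 0:
            m = int(round(M0 * (1.0 + rng.normal(0.0, config.hrv_sd))))
        cycle_lengths.append(max(m, 32))

    # a rendered but unannotated warm-up beat precedes the first annotated
    # one, so every annotated valley sits after a diastolic decay as in a
    # continuous recording; pulses are rendered with overlapping Gaussian
    # tails, giving a smooth concatenation
    lead = config.pat_samples + 16 + M0
    tail = M0 // 2
    total = lead + sum(cycle_lengths) + tail
    ppg = np.zeros(total)
    ecg = np.zeros(total)
    n_all = np.arange(total, dtype=float)

    def render(pos: int, comps: ComponentSet, m: int) -> None:
        lo, hi = max(0, pos - m), min(total, pos + 2 * m)
        rel = np.arange(lo, hi, dtype=float) - pos
        for c in comps.components:
            ppg[lo:hi] += c.alpha * np.exp(-((rel - c.beta) ** 2) / (2.0 * c.gamma**2))

    warm_pos = lead - M0
    render(warm_pos, _template_components(config.template, M0), M0)

    positions = []
    comp_sets = []
    pos = lead
    for m in cycle_lengths:
        base = _template_components(config.template, m)
        if config.jitter_sd > 0:
            flat = base.as_flat()
            flat = flat * (1.0 + rng.normal(0.0, config.jitter_sd, size=flat.size))
            flat[5:10] = np.sort(flat[5:10])  # keep positions ordered
            flat[:5] = np.maximum(flat[:5], 1e-3)
            flat[10:] = np.maximum(flat[10:], 1.0)
            base = ComponentSet.from_arrays(flat[:5], flat[5:10], flat[10:])
        render(pos, base, m)
        positions.append(pos)
        comp_sets.append(base)
        pos += m

    # the annotated valley of each beat is the true local minimum of the
    # clean signal near the nominal pulse start; the R spike is then placed
    # exactly one pulse-arrival time before it
    def clean_valley(p: int, m: int) -> int:
        lo = max(0, p - m // 4)
        hi = min(total, p + m // 4)
        return lo + int(np.argmin(ppg[lo:hi]))

    onsets_arr = np.array(
        [clean_valley(p, m) for p, m in zip(positions, cycle_lengths)], dtype=int
    )
    warm_valley = clean_valley(warm_pos, M0)
    r_indices = onsets_arr - config.pat_samples
    t_off = int(round(config.t_offset_s * fs))
    t_indices = r_indices + t_off

    # ECG morphology: narrow positive R spike, wider low T bump.
    warm_r = warm_valley - config.pat_samples
    for r, t in zip(
        np.concatenate([[warm_r], r_indices]), np.concatenate([[warm_r + t_off], t_indices])
    ):
        ecg += 1.0 * np.exp(-((n_all - r) ** 2) / (2.0 * 1.5**2))
        ecg += 0.25 * np.exp(-((n_all - t) ** 2) / (2.0 * 9.0**2))

    t_s = n_all / fs
    if config.baseline_amp > 0:
        wander = config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t_s + rng.uniform(0, 2 * np.pi)
        )
        ppg += wander
        ecg += 0.5 * wander
    if config.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ppg += config.powerline_amp * np.sin(2 * np.pi * 60.0 * t_s + phase)
        ecg += config.powerline_amp * np.sin(2 * np.pi * 60.0 * t_s + phase)
    if config.noise_sd > 0:
        ppg += rng.normal(0.0, config.noise_sd, size=total)
        ecg += rng.normal(0.0, config.noise_sd, size=total)

    ann = Annotations(
        r_indices=r_indices,
        valley_indices=onsets_arr,
        t_indices=t_indices,
        pat_samples=np.full(config.n_beats, config.pat_samples, dtype=int),
        cycle_component_sets=comp_sets,
    )
    return SignalRecord(
        ppg=ppg, ecg=ecg, fs=fs, participant_id=participant_id, round_id=round_id,
        annotations=ann,
    )


@dataclass
class SyntheticCohort:
    """A set of records with anthropometrics and per-measurement true PWV."""

    records: list[SignalRecord]
    anthropometrics: pd.DataFrame  # participant_id, age, height_cm, weight_kg
    measurements: pd.DataFrame  # participant_id, round_id, true_pwv, pat_samples
    generative_spec: dict


def synth_cohort(
    n_participants: int = 20,
    rounds_per_participant: int = 3,
    pwv_function: Callable[[float, float, float], float] | None = None,
    pwv_range: tuple[float, float] = (1000.0, 2100.0),
    noise_sd: float = 0.0,
    n_beats: int = 12,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a cohort whose morphology varies systematically with PWV.

    Each participant draws a latent stiffness ``s`` in [0, 1]; age increases
    with ``s`` and, per round, the pulse-arrival time shortens and the
    diastolic component waves shift earlier (shorter stiffness index) as
    ``s`` grows.  The true PWV is ``pwv_function(age, pat_samples, si_frac)``
    when given, else an affine map of ``s`` onto ``pwv_range``.  Recovery of
    the planted monotone relationships is the identifiability contract.
    """
    if n_participants < 4:
        raise ValueError("n_participants must be >= 4 for participant splitting")
    lo, hi = pwv_range
    if not (800.0 <= lo < hi <= 2400.0):
        raise ValueError(f"pwv_range must lie within [800, 2400], got {pwv_range}")

    rng = np.random.default_rng(seed)
    records: list[SignalRecord] = []
    anthro_rows = []
    meas_rows = []

    for p in range(n_participants):
        pid = f"P{p:03d}"
        s_p = rng.uniform(0.0, 1.0)
        age = float(np.clip(40.0 + 45.0 * s_p + rng.normal(0.0, 3.0), 25.0, 95.0))
        height = float(rng.uniform(150.0, 190.0))
        weight = float(rng.uniform(50.0, 95.0))
        anthro_rows.append(
            {"participant_id": pid, "age": age, "height_cm": height, "weight_kg": weight}
        )
        for r in range(rounds_per_participant):
            rid = f"R{r}"
            s_m = float(np.clip(s_p + rng.normal(0.0, 0.03), 0.0, 1.0))
            # PAT shortens with stiffness; always well under one cycle
            pat = int(round(150.0 - 70.0 * s_m))
            # diastolic waves move earlier with stiffness: shorter SI
            template = dict(DEFAULT_TEMPLATE)
            b = list(template["beta_frac"])
            b[3] = 0.58 - 0.04 * s_m
            b[4] = 0.74 - 0.02 * s_m
            template["beta_frac"] = tuple(b)
            si_frac = b[4] - template["beta_frac"][2]  # diastolic-systolic spacing proxy

            if pwv_function is not None:
                pwv = float(pwv_function(age, float(pat), float(si_frac)))
            else:
                pwv = lo + (hi - lo) * s_m
            if noise_sd > 0:
                pwv += float(rng.normal(0.0, noise_sd))
            pwv = float(np.clip(pwv, lo, hi))

            rec_cfg = RecordConfig(
                heart_rate_bpm=float(rng.uniform(60.0, 85.0)),
                n_beats=n_beats,
                pat_samples=pat,
                template=template,
                noise_sd=noise_sd * 0.0,  # PWV noise, not signal noise
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            records.append(synth_record(rec_cfg, participant_id=pid, round_id=rid))
            meas_rows.append(
                {
                    "participant_id": pid,
                    "round_id": rid,
                    "true_pwv": pwv,
                    "pat_samples": pat,
                    "si_frac": si_frac,
                    "age": age,
                }
            )

    spec = {
        "pwv_range": list(pwv_range),
        "noise_sd": noise_sd,
        "seed": seed,
        "pwv_function": "custom" if pwv_function is not None else "latent-affine",
    }
    return SyntheticCohort(
        records=records,
        anthropometrics=pd.DataFrame(anthro_rows),
        measurements=pd.DataFrame(meas_rows),
        generative_spec=spec,
    )


def synth_feature_cohort(
    n_measurements: int = 150,
    n_participants: int = 30,
    boundary: float = 1600.0,
    noise_sd: float = 60.0,
    n_noise_features: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Tabular cohort with a piecewise feature-to-PWV generative model.

    Emulates a measurement-level feature matrix in which one predictor
    (``pat``) is informative across the whole range while two others carry
    information only below/above the ``boundary`` — the regime structure a
    classify-then-regress model is designed for.  Returns
    ``(features, pwv, participant_ids)``.
    """
    if n_participants < 4:
        raise ValueError("n_participants must be >= 4")
    rng = np.random.default_rng(seed)
    pids = [f"P{p:03d}" for p in range(n_participants)]
    part = [pids[i % n_participants] for i in range(n_measurements)]

    # participant-level latent, measurement-level wobble
    s_part = {pid: rng.uniform(0.0, 1.0) for pid in pids}
    z = np.array([np.clip(s_part[p] + rng.normal(0.0, 0.08), 0.0, 1.0) for p in part])
    pwv = 900.0 + 1400.0 * z + rng.normal(0.0, noise_sd, size=n_measurements)

    feats = pd.DataFrame(index=range(n_measurements))
    feats["pat"] = 230.0 - 70.0 * z + rng.normal(0.0, 3.0, size=n_measurements)
    feats["age"] = np.array(
        [40.0 + 45.0 * s_part[p] for p in part]
    ) + rng.normal(0.0, 4.0, size=n_measurements)
    low_gap = np.maximum(0.0, boundary - pwv)
    high_gap = np.maximum(0.0, pwv - boundary)
    feats["si_low"] = 0.05 * low_gap + rng.normal(0.0, 1.5, size=n_measurements)
    feats["refl_high"] = 0.05 * high_gap + rng.normal(0.0, 1.5, size=n_measurements)
    for k in range(n_noise_features):
        feats[f"noise{k}"] = rng.normal(0.0, 1.0, size=n_measurements)

    return feats, pd.Series(pwv, name="pwv"), pd.Series(part, name="participant_id")


def write_record_csv(record: SignalRecord, path: str | Path) -> None:
    """Write a record as CSV (columns t, ppg, ecg) plus a JSON sidecar."""
    path = Path(path)
    t = np.arange(len(record.ppg)) / record.fs
    pd.DataFrame({"t": t, "ppg": record.ppg, "ecg": record.ecg}).to_csv(path, index=False)
    side = {
        "fs": record.fs,
        "participant_id": record.participant_id,
        "round_id": record.round_id,
        "annotations": record.annotations.to_dict() if record.annotations else None,
    }
    path.with_suffix(".json").write_text(json.dumps(side))


def read_record_csv(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`write_record_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    side_path = path.with_suffix(".json")
    fs, pid, rid, ann = 256.0, "P000", "R0", None
    if side_path.exists():
        side = json.loads(side_path.read_text())
        fs = side.get("fs", 256.0)
        pid = side.get("participant_id", "P000")
        rid = side.get("round_id", "R0")
        if side.get("annotations"):
            ann = Annotations.from_dict(side["annotations"])
    return SignalRecord(
        ppg=df["ppg"].to_numpy(), ecg=df["ecg"].to_numpy(), fs=fs,
        participant_id=pid, round_id=rid, annotations=ann,
    )
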