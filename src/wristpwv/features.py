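"""Feature stack: PPG morphology, WPD, ECG and basic-information features,
systematic ratio combination, and per-measurement aggregation.

Time features are stored in samples (the sampling interval is carried on
the cycle); amplitudes are in normalized units.  Notable members:

* ``P2O = M - n_sys`` — systolic peak to the next onset.
* the SDPPG age index ``(A_b - A_c - A_d - A_e) / A_a`` and its variant
  ``(A_b - A_c - A_d) / A_a`` (second-derivative amplitudes), correlates of
  the aortic augmentation index.
* ``SI = n_pd - n_ps`` — stiffness index from the synthesized systolic and
  diastolic wave peaks; robust on wrist pulses where the raw diastolic
  peak is often invisible.
* ``PAT = -n_R`` — pulse arrival time from the ECG R peak to the PPG
  valley, with PAT^2 and Height^2/PAT^2.
* heart-to-ankle and heart-to-brachium path lengths approximated from
  height: ``La = 0.8219 H + 12.328``, ``Lb = 0.2195 H - 2.073`` (cm).

Combined features divide one feature by another (id "u_over_v"); missing
denominators or magnitudes below ``eps`` propagate missingness.  Cycle
vectors aggregate to sequences by the median and sequences to measurements
by the mean of medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .preprocessing import PulseCycle
from .fiducials import FiducialSet
from .wpd import Decomposition

__all__ = [
    "FeatureVector",
    "FeatureCatalog",
    "CATALOG",
    "CANONICAL_IDS",
    "extract_ppg_features",
    "extract_wpd_features",
    "extract_ecg_features",
    "compute_body_lengths",
    "extract_cycle_features",
    "combine_ratio_features",
    "aggregate_measurement",
]

EPS_DENOM = 1e-9

# conventional numeric ids for the features this package pins by name
CANONICAL_IDS = {
    "p2o": 1,
    "A_c2": 18,
    "A_d2": 19,
    "A_e2": 20,
    "age": 23,
    "si": 51,
    "age2": 63,
}


@dataclass
class FeatureVector:
    """Named feature map with per-feature provenance."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set(self, fid: str, value: float | None, prov: str = "measured") -> None:
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            return
        self.values[fid] = float(value)
        self.provenance[fid] = prov

    def get(self, fid: str) -> float | None:
        return self.values.get(fid)

    def __contains__(self, fid: str) -> bool:
        return fid in self.values

    def update(self, other: "FeatureVector") -> "FeatureVector":
        self.values.update(other.values)
        self.provenance.update(other.provenance)
        return self

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


@dataclass
class FeatureCatalog:
    """Registry of feature definitions: id -> (family, description)."""

    registry: dict[str, tuple[str, str]] = field(default_factory=dict)

    def register(self, fid: str, family: str, description: str) -> None:
        if fid in self.registry:
            raise ValueError(f"duplicate feature id {fid}")
        self.registry[fid] = (family, description)

    def family(self, fid: str) -> str:
        return self.registry[fid][0]

    def ids(self, family: str | None = None) -> list[str]:
        if family is None:
            return list(self.registry)
        return [k for k, (fam, _) in self.registry.items() if fam == family]


def _build_catalog() -> FeatureCatalog:
    cat = FeatureCatalog()
    ppg = [
        ("p2o", "systolic peak to next onset, M - n_sys (samples)"),
        ("n_sys", "systolic peak position"), ("A_sys", "systolic peak amplitude"),
        ("n_notch", "dicrotic notch position"), ("A_notch", "notch amplitude"),
        ("n_dia", "diastolic peak position"), ("A_dia", "diastolic peak amplitude"),
        ("n_ms", "maximal-slope position"), ("A_ms1", "FDPPG amplitude at max slope"),
        ("n_a", "SDPPG a position"), ("n_b", "SDPPG b position"),
        ("n_c", "SDPPG c position"), ("n_d", "SDPPG d position"),
        ("n_e", "SDPPG e position"), ("n_f", "SDPPG f position"),
        ("A_a2", "SDPPG a amplitude"), ("A_b2", "SDPPG b amplitude"),
        ("A_c2", "SDPPG c amplitude"), ("A_d2", "SDPPG d amplitude"),
        ("A_e2", "SDPPG e amplitude"), ("A_f2", "SDPPG f amplitude"),
        ("age_index", "(A_b - A_c - A_d - A_e)/A_a on SDPPG"),
        ("age_index_v", "(A_b - A_c - A_d)/A_a on SDPPG"),
        ("cycle_len", "cycle length M (samples)"),
    ]
    wpd = (
        [(f"alpha{i}", f"component wave {i} amplitude") for i in range(1, 6)]
        + [(f"beta{i}", f"component wave {i} position") for i in range(1, 6)]
        + [(f"gamma{i}", f"component wave {i} width") for i in range(1, 6)]
        + [
            ("n_pf", "forward wave peak position"),
            ("n_ps", "systolic wave peak position"),
            ("n_pd", "diastolic wave peak position"),
            ("si", "stiffness index n_pd - n_ps"),
            ("beta3_minus_npf", "third component to forward-wave interval"),
            ("beta4_minus_npf", "fourth component to forward-wave interval"),
        ]
    )
    ecg = [
        ("n_R", "R-peak position relative to onset (negative)"),
        ("n_T", "T-peak position relative to onset"),
        ("pat", "pulse arrival time -n_R (samples)"),
        ("pat2", "PAT squared"),
        ("h2_over_pat2", "Height^2 / PAT^2 (cm^2/sample^2)"),
        ("r_to_ms", "R peak to maximal slope"),
        ("r_to_ps", "R peak to systolic-wave peak"),
        ("r_to_beta2", "R peak to component wave 2"),
    ]
    basic = [
        ("age", "age (years)"), ("age2", "age squared"),
        ("height", "height (cm)"), ("weight", "weight (kg)"), ("bmi", "BMI (kg/m^2)"),
        ("la", "heart-to-ankle length 0.8219 H + 12.328 (cm)"),
        ("lb", "heart-to-brachium length 0.2195 H - 2.073 (cm)"),
        ("la_minus_lb", "ankle-brachium path difference (cm)"),
        ("law", "arm-to-wrist length (cm)"), ("laf", "arm-to-finger length (cm)"),
    ]
    for fid, desc in ppg:
        cat.register(fid, "PPG", desc)
    for fid, desc in wpd:
        cat.register(fid, "WPD", desc)
    for fid, desc in ecg:
        cat.register(fid, "ECG", desc)
    for fid, desc in basic:
        cat.register(fid, "BASIC", desc)
    return cat


CATALOG = _build_catalog()


def extract_ppg_features(cycle: PulseCycle, fiducials: FiducialSet) -> FeatureVector:
    """PPG-pulse, FDPPG and SDPPG morphology features for one cycle."""
    v = FeatureVector()
    v.set("cycle_len", cycle.M)
    if fiducials.n_sys is not None:
        v.set("p2o", cycle.M - fiducials.n_sys)
        v.set("n_sys", fiducials.n_sys)
        v.set("A_sys", fiducials.A_sys)
    v.set("n_notch", fiducials.n_notch)
    v.set("A_notch", fiducials.A_notch)
    v.set("n_dia", fiducials.n_dia)
    v.set("A_dia", fiducials.A_dia)
    v.set("n_ms", fiducials.n_ms)
    v.set("A_ms1", fiducials.A_ms1)
    for p in "abcdef":
        v.set(f"n_{p}", fiducials.sdppg_pos(p))
        v.set(f"A_{p}2", fiducials.sdppg_amp(p))
    amps = {p: fiducials.sdppg_amp(p) for p in "abcde"}
    if all(amps[p] is not None for p in "abcd") and abs(amps["a"]) >= EPS_DENOM:
        v.set("age_index_v", (amps["b"] - amps["c"] - amps["d"]) / amps["a"])
        if amps["e"] is not None:
            v.set("age_index", (amps["b"] - amps["c"] - amps["d"] - amps["e"]) / amps["a"])
    return v


def extract_wpd_features(decomposition: Decomposition) -> FeatureVector:
    """Component-wave parameters and synthesized-wave timing features."""
    v = FeatureVector()
    for i, c in enumerate(decomposition.theta_hat.components, start=1):
        v.set(f"alpha{i}", c.alpha, "WPD-derived")
        v.set(f"beta{i}", c.beta, "WPD-derived")
        v.set(f"gamma{i}", c.gamma, "WPD-derived")
    v.set("n_pf", decomposition.n_pf, "WPD-derived")
    v.set("n_ps", decomposition.n_ps, "WPD-derived")
    v.set("n_pd", decomposition.n_pd, "WPD-derived")
    if decomposition.n_ps is not None and decomposition.n_pd is not None:
        v.set("si", decomposition.n_pd - decomposition.n_ps, "WPD-derived")
    if decomposition.n_pf is not None:
        v.set("beta3_minus_npf",
              decomposition.theta_hat.components[2].beta - decomposition.n_pf, "WPD-derived")
        v.set("beta4_minus_npf",
              decomposition.theta_hat.components[3].beta - decomposition.n_pf, "WPD-derived")
    return v


def extract_ecg_features(
    cycle: PulseCycle,
    fiducials: FiducialSet,
    height_cm: float | None = None,
    decomposition: Decomposition | None = None,
) -> FeatureVector:
    """Pulse-arrival-time and R-to-landmark interval features.

    The R peak precedes the PPG valley, so the cycle-relative position
    ``n_R`` is negative and ``PAT = -n_R``.
    """
    v = FeatureVector()
    n_r = fiducials.n_R if fiducials.n_R is not None else cycle.n_r
    if n_r is None:
        return v
    if n_r >= 0:
        raise ValueError("n_R must be negative (R precedes the PPG valley)")
    v.set("n_R", n_r)
    v.set("n_T", fiducials.n_T if fiducials.n_T is not None else cycle.n_t)
    pat = -float(n_r)
    v.set("pat", pat)
    v.set("pat2", pat**2)
    if height_cm is not None:
        v.set("h2_over_pat2", height_cm**2 / pat**2)
    if fiducials.n_ms is not None:
        v.set("r_to_ms", fiducials.n_ms - n_r)
    if decomposition is not None:
        if decomposition.n_ps is not None:
            v.set("r_to_ps", decomposition.n_ps - n_r)
        v.set("r_to_beta2", decomposition.theta_hat.components[1].beta - n_r)
    return v


def compute_body_lengths(
    height_cm: float,
    age: float | None = None,
    weight_kg: float | None = None,
    law_cm: float | None = None,
    laf_cm: float | None = None,
) -> FeatureVector:
    """Basic-information features, with arterial path lengths approximated
    from height: La = 0.8219 H + 12.328 and Lb = 0.2195 H - 2.073 (cm)."""
    if not (100.0 <= height_cm <= 220.0):
        raise ValueError(f"height {height_cm} cm outside the validated range [100, 220]")
    v = FeatureVector()
    la = 0.8219 * height_cm + 12.328
    lb = 0.2195 * height_cm - 2.073
    v.set("height", height_cm)
    v.set("la", la)
    v.set("lb", lb)
    v.set("la_minus_lb", la - lb)
    if age is not None:
        v.set("age", age)
        v.set("age2", age**2)
    if weight_kg is not None:
        v.set("weight", weight_kg)
        v.set("bmi", weight_kg / (height_cm / 100.0) ** 2)
    v.set("law", law_cm)
    v.set("laf", laf_cm)
    return v


def extract_cycle_features(
    cycle: PulseCycle,
    fiducials: FiducialSet,
    decomposition: Decomposition | None = None,
    height_cm: float | None = None,
    impute_from_wpd: bool = True,
) -> FeatureVector:
    """All per-cycle features merged; optionally substitutes missing raw
    diastolic timing by its WPD-synthesized counterpart (provenance
    "WPD-derived"), the fallback wrist pulses frequently need."""
    v = extract_ppg_features(cycle, fiducials)
    if decomposition is not None:
        v.update(extract_wpd_features(decomposition))
        if impute_from_wpd and "n_dia" not in v and decomposition.n_pd is not None:
            v.set("n_dia", decomposition.n_pd, "WPD-derived")
            amp = decomposition.diastolic[decomposition.n_pd] + decomposition.offset
            v.set("A_dia", amp, "WPD-derived")
    if cycle.n_r is not None:
        v.update(extract_ecg_features(cycle, fiducials, height_cm, decomposition))
    return v


def combine_ratio_features(
    vector: FeatureVector,
    pair_spec: list[tuple[str, str]] | None = None,
    eps: float = EPS_DENOM,
) -> FeatureVector:
    """Extend ``vector`` with ratio features u/v for ordered pairs (u, v).

    Defaults to all ordered pairs over the present features (diagonal
    excluded).  Pairs with a missing or near-zero denominator are skipped,
    propagating missingness.
    """
    pairs = pair_spec if pair_spec is not None else list(permutations(vector.values, 2))
    out = FeatureVector(dict(vector.values), dict(vector.provenance))
    for u, v in pairs:
        if u == v:
            continue
        uu, vv = vector.get(u), vector.get(v)
        if uu is None or vv is None or abs(vv) < eps:
            continue
        out.set(f"{u}_over_{v}", uu / vv, "combined")
    return out


def aggregate_measurement(
    cycle_table: pd.DataFrame,
    sequence_col: str = "sequence_id",
    measurement_col: str = "measurement_id",
) -> pd.DataFrame:
    """Median over cycles within a sequence, then mean of the sequence
    medians within a measurement; features missing in every sequence of a
    measurement are left NaN (dropped columns if empty everywhere)."""
    feature_cols = [c for c in cycle_table.columns if c not in (sequence_col, measurement_col)]
    if cycle_table.empty:
        raise ValueError("no accepted cycles to aggregate")
    seq = cycle_table.groupby([measurement_col, sequence_col])[feature_cols].median()
    meas = seq.groupby(level=0).mean()
    return meas.dropna(axis=1, how="all")
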