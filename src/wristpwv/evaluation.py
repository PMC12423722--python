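"""Error metrics, correlation, per-participant averaging and Bland-Altman
agreement.

Sign convention throughout: the error is measured minus estimated,
``e_j = v_j - v_hat_j``, so a positive mean error means underestimation.
MAE = E{|e|}, ME = E{e}, SD uses the N-1 denominator, RMSE = sqrt(E{e^2}).
Because some participants contribute several measurements, metrics are
reported both per round and per participant (pairs averaged within each
participant first, to avoid unbalanced weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EvalReport", "error_metrics", "correlation", "per_participant",
           "bland_altman", "evaluate"]


@dataclass
class EvalReport:
    MAE: float
    ME: float
    SD: float
    RMSE: float
    pearson_r: float | None
    p_value: float | None
    N: int
    level: str = "rounds"

    def to_dict(self) -> dict:
        return {
            "MAE": self.MAE, "ME": self.ME, "SD": self.SD, "RMSE": self.RMSE,
            "pearson_r": self.pearson_r, "p_value": self.p_value,
            "N": self.N, "level": self.level,
        }


def error_metrics(
    estimates: np.ndarray, references: np.ndarray, level: str = "rounds"
) -> EvalReport:
    """MAE, ME, SD (N-1) and RMSE of e = reference - estimate."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must have equal length")
    n = len(est)
    if n < 2:
        raise ValueError("need at least 2 pairs (SD undefined below)")
    e = ref - est
    r = p = None
    if n >= 3 and np.std(est) > 0 and np.std(ref) > 0:
        r, p = correlation(est, ref)
    return EvalReport(
        MAE=float(np.mean(np.abs(e))),
        ME=float(np.mean(e)),
        SD=float(np.std(e, ddof=1)),
        RMSE=float(np.sqrt(np.mean(e**2))),
        pearson_r=r,
        p_value=p,
        N=n,
        level=level,
    )


def correlation(
    estimates: np.ndarray, references: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation with a two-sided p-value (t transform, N-2 df for
    Pearson); Spearman available behind the flag."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if len(est) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(est) == 0 or np.std(ref) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        res = stats.pearsonr(est, ref)
    elif method == "spearman":
        res = stats.spearmanr(est, ref)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def per_participant(
    estimates: np.ndarray, references: np.ndarray, participant_ids
) -> tuple[np.ndarray, np.ndarray, list]:
    """Average the estimate and the reference within each participant;
    returns one pair per participant (order of first appearance)."""
    df = pd.DataFrame({
        "est": np.asarray(estimates, dtype=float),
        "ref": np.asarray(references, dtype=float),
        "pid": list(participant_ids),
    })
    g = df.groupby("pid", sort=False).mean()
    return g["est"].to_numpy(), g["ref"].to_numpy(), list(g.index)


def bland_altman(estimates: np.ndarray, references: np.ndarray) -> dict:
    """Per-pair (mean, difference) with bias and 1.96 SD limits of
    agreement; the difference is reference - estimate."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if len(est) < 2:
        raise ValueError("need at least 2 pairs")
    diff = ref - est
    mean = (ref + est) / 2.0
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "table": pd.DataFrame({"mean": mean, "difference": diff}),
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


def evaluate(
    estimates: np.ndarray, references: np.ndarray, participant_ids
) -> dict[str, EvalReport]:
    """Round-level and participant-level reports, always both."""
    round_rep = error_metrics(estimates, references, level="rounds")
    est_p, ref_p, _ = per_participant(estimates, references, participant_ids)
    part_rep = error_metrics(est_p, ref_p, level="participants")
    return {"rounds": round_rep, "participants": part_rep}
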