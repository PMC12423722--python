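"""Signal cleaning, beat detection, cycle segmentation and quality screening.

Baseline wander is removed by a discrete wavelet decomposition deep enough
that the approximation band lies below 0.5 Hz; 60 Hz interference by a
zero-phase IIR notch; the whole segment is then affinely normalized to
[-1, +1].  R peaks are found with an energy-based detector (bandpass ->
derivative -> squaring -> moving integration -> adaptive threshold) and PPG
valleys as the local minimum preceding each maximal systolic upstroke.
Cycles are screened with a cycle-length signal quality index (SQI): records
whose ECG or PPG cycle-length skewness or coefficient of variation exceed
their thresholds have their cycles excluded from feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "PulseCycle",
    "SqiConfig",
    "SqiReport",
    "remove_baseline",
    "suppress_powerline",
    "normalize_amplitude",
    "detect_r_peaks",
    "detect_valleys",
    "segment_and_screen",
    "preprocess",
]


@dataclass
class PulseCycle:
    """One PPG cycle s(n), n = 0..M-1, with its ECG context.

    ``onset_index`` is the absolute index of the PPG valley; ``r_index`` the
    absolute index of the paired R peak (before the onset, so the
    cycle-relative R position is negative).
    """

    samples: np.ndarray
    M: int
    Ts: float
    onset_index: int
    r_index: int | None = None
    t_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.M < 32:
            raise ValueError(f"cycle length M must be >= 32, got {self.M}")
        if len(self.samples) != self.M:
            raise ValueError("samples length must equal M")
        if self.r_index is not None and self.r_index >= self.onset_index:
            raise ValueError("r_index must precede onset_index")

    @property
    def n_r(self) -> int | None:
        """Cycle-relative R position (negative by construction)."""
        return None if self.r_index is None else self.r_index - self.onset_index

    @property
    def n_t(self) -> int | None:
        return None if self.t_index is None else self.t_index - self.onset_index


@dataclass
class SqiConfig:
    max_abs_skewness: float = 1.0
    max_cv: float = 0.2
    pairing_window_s: float = 1.0  # latest R within this span before the valley
    skew_sd_floor: float = 1.5  # samples; below this, length variation is quantization


@dataclass
class SqiReport:
    ppg_cycle_lengths: np.ndarray
    ecg_cycle_lengths: np.ndarray
    ppg_skewness: float
    ecg_skewness: float
    ppg_cv: float
    ecg_cv: float
    pass_flags: np.ndarray
    reasons: list[str] = field(default_factory=list)
    config: SqiConfig = field(default_factory=SqiConfig)


def remove_baseline(x: np.ndarray, fs: float, wavelet: str = "sym8") -> np.ndarray:
    """Remove sub-0.5 Hz drift by zeroing the deep wavelet approximation.

    The decomposition level is chosen so the approximation band lies
    below 0.5 Hz (level 9 at fs = 256); the approximation coefficients
    are zeroed and the signal reconstructed, leaving the pulse band
    intact.  With an orthogonal wavelet and periodized boundaries this is
    an exact orthogonal projection — applying it twice returns the same
    signal (to numerical precision on block-aligned lengths; other
    lengths are reflect-padded to the block size and cropped, which
    perturbs only the edge neighborhood).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("signal shorter than the decomposition support (need >= 2 s)")
    level = int(np.ceil(np.log2(fs / 0.5)))  # approx band fs / 2**(level+1) <= 0.25 Hz
    block = 2**level
    n = len(x)
    total = int(np.ceil(n / block)) * block
    xp = np.pad(x, (0, total - n), mode="reflect") if total > n else x
    with warnings.catch_warnings():
        # deep levels on short records trigger a harmless boundary notice
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(xp, wavelet, level=level, mode="periodization")
        coeffs[0] = np.zeros_like(coeffs[0])
        out = pywt.waverec(coeffs, wavelet, mode="periodization")
    return out[:n]


def suppress_powerline(x: np.ndarray, fs: float, freq: float = 60.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``freq`` (default 60 Hz)."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * freq:
        raise ValueError(f"sampling rate {fs} too low to notch {freq} Hz")
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, x)


def normalize_amplitude(x: np.ndarray) -> np.ndarray:
    """Affine map of the whole segment onto [-1, +1]."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise ValueError("constant signal has zero amplitude range")
    return (x - lo) * (2.0 / (hi - lo)) - 1.0


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.2) -> np.ndarray:
    """Energy-based QRS detection; returns ascending R-peak indices.

    Bandpass (5-30 Hz) -> derivative -> squaring -> moving-window
    integration (150 ms) -> adaptive threshold; each candidate is refined to
    the local ECG maximum within +/-100 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < fs:
        return np.array([], dtype=int)
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(30.0, 0.9 * nyq) / nyq], btype="band")
    f = sps.filtfilt(b, a, ecg)
    energy = np.convolve(np.gradient(f) ** 2, np.ones(int(0.15 * fs)), mode="same")
    if np.max(energy) <= 0:
        return np.array([], dtype=int)
    cand, _ = sps.find_peaks(energy, distance=int(refractory_s * fs))
    if len(cand) == 0:
        return np.array([], dtype=int)
    thr = 0.3 * np.median(energy[cand][np.argsort(energy[cand])[-max(3, len(cand) // 2):]])
    cand = cand[energy[cand] >= thr]
    half = int(0.1 * fs)
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(peaks)
    # reject non-QRS bumps (T waves) by amplitude: R dominates the lead
    if len(peaks) >= 3:
        amp_thr = 0.5 * float(np.median(ecg[peaks][np.argsort(ecg[peaks])[-max(3, len(peaks) // 2):]]))
        peaks = peaks[ecg[peaks] >= amp_thr]
    # enforce the refractory period after refinement
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refractory_s * fs:
            if ecg[p] > ecg[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.array(keep, dtype=int)


def detect_valleys(ppg: np.ndarray, fs: float) -> np.ndarray:
    """PPG onset detection: the minimum preceding each maximal systolic
    upstroke.

    The diastolic tail before the foot is nearly flat, so a per-beat
    argmin is noise-fragile.  Instead the (noise-stable) maximal-upstroke
    positions anchor the beats, each beat contributes its own
    upstroke-to-minimum offset, and the per-record median of those offsets
    places every valley — a single-beat record degenerates to the plain
    minimum search.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < fs:
        return np.array([], dtype=int)
    # zero-phase low-pass: the pulse lives below ~10 Hz, noise does not
    b, a = sps.butter(3, min(12.0, 0.45 * fs) / (fs / 2.0), btype="low")
    smooth = sps.filtfilt(b, a, ppg)
    d = np.gradient(smooth)
    if np.max(d) <= 0:
        return np.array([], dtype=int)
    # a pulsatile signal has brief steep upstrokes against a mostly flat
    # slope profile; a monotone trend does not
    if np.max(d) <= 1.5 * np.median(np.abs(d)):
        return np.array([], dtype=int)
    ups, _ = sps.find_peaks(d, height=0.35 * np.max(d), distance=int(0.3 * fs))
    if len(ups) == 0:
        return np.array([], dtype=int)

    left, right = int(0.35 * fs), int(0.45 * fs)
    full = [u for u in ups if u - left >= 0 and u + right < len(ppg)]
    if not full:
        # degenerate short record: plain minimum search per beat
        win = int(0.4 * fs)
        vals = [max(0, u - win) + int(np.argmin(smooth[max(0, u - win) : u + 1])) for u in ups]
        return np.unique(np.array(vals, dtype=int))

    # ensemble beat template: averaging across beats suppresses noise, so
    # its minimum is a reliable anchor for the upstroke-to-valley offset
    template = np.mean([ppg[u - left : u + right] for u in full], axis=0)
    # Savitzky-Golay smoothing preserves the quadratic shape of the foot
    # minimum (a moving average biases its position)
    win = min(21, 2 * (len(template) // 2) - 1)
    t_sm = sps.savgol_filter(template, win, 2)
    anchor = left - int(np.argmin(t_sm[: left + 1]))

    # per-beat alignment against the template (matched filter over the
    # whole beat, far more noise-stable than any single landmark)
    max_lag = 8
    valleys = []
    for u in ups:
        best_lag, best_score = 0, -np.inf
        for lag in range(-max_lag, max_lag + 1):
            lo, hi = u + lag - left, u + lag + right
            if lo < 0 or hi > len(ppg):
                continue
            seg = ppg[lo:hi]
            score = float(np.dot(seg, template))
            if score > best_score:
                best_score, best_lag = score, lag
        valleys.append(max(0, u + best_lag - anchor))
    return np.unique(np.array(valleys, dtype=int))


def _skewness(x: np.ndarray) -> float:
    """Bias-adjusted (Fisher-Pearson) sample skewness; 0 for constant input."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = np.std(x, ddof=1)
    if s == 0 or n < 3:
        return 0.0
    g1 = np.mean(((x - np.mean(x)) / np.std(x, ddof=0)) ** 3)
    return float(np.sqrt(n * (n - 1)) / (n - 2) * g1)


def _cv(x: np.ndarray) -> float:
    """Coefficient of variation, SD with the N-1 denominator."""
    m = np.mean(x)
    if m == 0:
        return 0.0
    return float(np.std(x, ddof=1) / m)


def segment_and_screen(
    ppg: np.ndarray,
    ecg: np.ndarray,
    valleys: np.ndarray,
    r_peaks: np.ndarray,
    sqi_config: SqiConfig | None = None,
    fs: float = 256.0,
) -> tuple[list[PulseCycle], SqiReport]:
    """Segment PPG into cycles, pair each with its R peak, apply the SQI.

    A cycle spans consecutive valleys and is paired with the latest R peak
    preceding its onset within the pairing window.  If the record's ECG or
    PPG cycle-length skewness or CV exceed their thresholds, all cycles are
    flagged as failing; cycles with no paired R peak fail with their own
    reason.
    """
    cfg = sqi_config or SqiConfig()
    valleys = np.asarray(valleys, dtype=int)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(valleys) < 4 or len(r_peaks) < 4:
        raise ValueError("need at least 3 cycles (4 valleys and 4 R peaks) for SQI statistics")

    ppg_lens = np.diff(valleys).astype(float)
    ecg_lens = np.diff(r_peaks).astype(float)

    def skew_gated(lens: np.ndarray) -> float:
        # sub-sample quantization jitter makes normalized skewness blow up
        if np.std(lens, ddof=1) <= cfg.skew_sd_floor:
            return 0.0
        return _skewness(lens)

    ppg_skew, ecg_skew = skew_gated(ppg_lens), skew_gated(ecg_lens)
    ppg_cv, ecg_cv = _cv(ppg_lens), _cv(ecg_lens)

    record_ok = (
        abs(ppg_skew) <= cfg.max_abs_skewness
        and abs(ecg_skew) <= cfg.max_abs_skewness
        and ppg_cv <= cfg.max_cv
        and ecg_cv <= cfg.max_cv
    )

    cycles: list[PulseCycle] = []
    flags: list[bool] = []
    reasons: list[str] = []
    window = int(cfg.pairing_window_s * fs)
    for k in range(len(valleys) - 1):
        onset, nxt = int(valleys[k]), int(valleys[k + 1])
        m = nxt - onset
        prior = r_peaks[(r_peaks < onset) & (r_peaks >= onset - window)]
        r_idx = int(prior[-1]) if len(prior) else None
        if m < 32:
            flags.append(False)
            reasons.append("cycle-too-short")
            continue
        cyc = PulseCycle(
            samples=ppg[onset:nxt], M=m, Ts=1.0 / fs, onset_index=onset, r_index=r_idx
        )
        cycles.append(cyc)
        if r_idx is None:
            flags.append(False)
            reasons.append("no-R-pairing")
        elif not record_ok:
            flags.append(False)
            reasons.append("record-sqi-fail")
        else:
            flags.append(True)
            reasons.append("pass")

    report = SqiReport(
        ppg_cycle_lengths=ppg_lens,
        ecg_cycle_lengths=ecg_lens,
        ppg_skewness=ppg_skew,
        ecg_skewness=ecg_skew,
        ppg_cv=ppg_cv,
        ecg_cv=ecg_cv,
        pass_flags=np.array(flags, dtype=bool),
        reasons=reasons,
        config=cfg,
    )
    return cycles, report


def preprocess(ppg: np.ndarray, ecg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Full cleaning chain: baseline removal, notch, [-1, +1] normalization."""
    out = []
    for x in (ppg, ecg):
        y = remove_baseline(x, fs)
        y = suppress_powerline(y, fs)
        out.append(normalize_amplitude(y))
    return out[0], out[1]
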