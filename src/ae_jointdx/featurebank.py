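"""Handcrafted feature bank for one AE window.

Sixteen features spanning four families, computed on the raw (unnormalised)
window so the voltage thresholds keep their physical meaning:

* time domain      — MAV, WL, ZC, SSC, RMS, NP, SSI, VAR
* autoregressive   — AR1..AR4, the coefficients of an order-4 Burg fit
* frequency domain — MF (median frequency), PF (peak frequency), Ceps
                     (maximum real-cepstrum component)
* complexity       — SampEn (m=2, r=0.2*SD), MFL, HFD (Kmax=10),
                     DFA (box sizes 30:10:300, first-order detrending)

The AR model contributes four values, so :func:`extract_all` returns a
19-entry named vector in the fixed order of :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram, welch

__all__ = [
    "FeatureParams",
    "FEATURE_NAMES",
    "extract_time_features",
    "extract_frequency_features",
    "extract_complexity_features",
    "fit_ar4",
    "extract_all",
]

logger = logging.getLogger(__name__)

#: Column order of the full feature vector.
FEATURE_NAMES = (
    "MAV", "WL", "ZC", "SSC", "RMS",
    "AR1", "AR2", "AR3", "AR4",
    "SampEn", "Ceps", "MFL", "HFD", "DFA",
    "MF", "PF", "NP", "SSI", "VAR",
)

#: Floor used for MFL on zero-variation input (log10 of the smallest
#: positive normal double), keeping vectors finite.
MFL_FLOOR = math.log10(np.finfo(float).tiny)


@dataclass(frozen=True)
class FeatureParams:
    """Tunable parameters of the bank.

    ``threshold`` (volts) gates the event-counting features ZC, SSC and NP;
    waveform length is the pure cumulative absolute difference and ignores
    it.  ``ar_emit`` selects whether the AR fit contributes all four
    coefficients (default) or only the fourth.
    """

    threshold: float = 1e-6
    sampen_m: int = 2
    sampen_r: float = 0.2
    hfd_kmax: int = 10
    dfa_box_sizes: tuple[int, ...] = tuple(range(30, 301, 10))
    ar_order: int = 4
    ar_emit: str = "all"  # "all" | "last"
    psd_method: str = "welch"  # "welch" | "periodogram"
    #: Welch segment length; None picks ~8 averaged segments (pwelch-style),
    #: capped at 4096 samples.
    psd_nperseg: int | None = None
    psd_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.hfd_kmax < 2:
            raise ValueError("hfd_kmax must be >= 2")
        boxes = np.asarray(self.dfa_box_sizes)
        if boxes.size < 2 or np.any(np.diff(boxes) <= 0):
            raise ValueError("dfa_box_sizes must be strictly increasing")
        if self.psd_method not in ("welch", "periodogram"):
            raise ValueError("psd_method must be 'welch' or 'periodogram'")


def extract_time_features(x: np.ndarray, params: FeatureParams) -> dict[str, float]:
    """Time-domain features MAV, WL, ZC, SSC, RMS, NP, SSI, VAR."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples (slope sign change undefined)")
    thr = params.threshold
    dx = np.diff(x)

    sign_change = x[:-1] * x[1:] < 0
    zc = int(np.count_nonzero(sign_change & (np.abs(dx) >= thr)))

    d_prev = x[1:-1] - x[:-2]
    d_next = x[1:-1] - x[2:]
    ssc_mask = (d_prev * d_next > 0) & (
        np.maximum(np.abs(d_prev), np.abs(d_next)) >= thr
    )
    ssc = int(np.count_nonzero(ssc_mask))

    peaks = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] >= thr)
    npks = int(np.count_nonzero(peaks))

    return {
        "MAV": float(np.mean(np.abs(x))),
        "WL": float(np.sum(np.abs(dx))),
        "ZC": float(zc),
        "SSC": float(ssc),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "NP": float(npks),
        "SSI": float(np.sum(x**2)),
        "VAR": float(np.var(x, ddof=1)),
    }


def _psd(x: np.ndarray, fs: float, params: FeatureParams):
    nperseg = params.psd_nperseg
    if nperseg is None:
        nperseg = max(64, min(4096, x.size // 4))
    nperseg = min(nperseg, x.size)
    if params.psd_method == "welch":
        return welch(
            x, fs=fs, window="hann", nperseg=nperseg,
            noverlap=int(params.psd_overlap * nperseg),
        )
    return periodogram(x, fs=fs)


def extract_frequency_features(
    x: np.ndarray, fs: float, params: FeatureParams
) -> dict[str, float]:
    """Spectral features MF, PF and the maximum real-cepstrum component.

    MF is the smallest frequency at which the cumulative PSD reaches half
    the total power; PF the frequency of the PSD maximum.  The cepstrum
    excludes quefrency 0 (dominated by overall log-energy).  All-zero input
    maps to the documented degenerate convention MF = PF = Ceps = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples for spectral features")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if not np.any(x):
        return {"MF": 0.0, "PF": 0.0, "Ceps": 0.0}

    freqs, pxx = _psd(x, fs, params)
    total = float(np.sum(pxx))
    if total <= 0:
        mf = pf = 0.0
    else:
        cum = np.cumsum(pxx)
        mf = float(freqs[np.searchsorted(cum, 0.5 * total)])
        pf = float(freqs[int(np.argmax(pxx))])

    mag = np.abs(np.fft.fft(x))
    ceps = np.fft.ifft(np.log(np.maximum(mag, np.finfo(float).tiny))).real
    return {"MF": mf, "PF": pf, "Ceps": float(np.max(ceps[1 : x.size // 2 + 1]))}


def _sampen(x: np.ndarray, m: int, r_frac: float) -> float:
    """Sample entropy with Chebyshev distance and self-matches excluded.

    Counts template pairs over indices 0..N-m-1 (the standard convention:
    the same N-m templates are used for both lengths m and m+1).  Returns 0
    for zero-variation input or when either count vanishes.
    """
    n = x.size
    sd = float(np.std(x))
    if sd == 0.0:
        logger.debug("SampEn degenerate input (zero variance); returning 0")
        return 0.0
    r = r_frac * sd
    n_templates = n - m
    # blocked over template rows to keep memory bounded on long windows
    block = max(16, int(4e6 // max(n_templates, 1)))
    b = a = 0
    for s in range(0, n_templates, block):
        e = min(s + block, n_templates)
        dm = np.abs(x[s:e, None] - x[None, :n_templates])
        for k in range(1, m):
            np.maximum(dm, np.abs(x[s + k : e + k, None] - x[None, k : n_templates + k]), out=dm)
        b += int(np.count_nonzero(dm <= r))
        np.maximum(dm, np.abs(x[s + m : e + m, None] - x[None, m : n_templates + m]), out=dm)
        a += int(np.count_nonzero(dm <= r))
    b -= n_templates  # self-matches
    a -= n_templates
    if a <= 0 or b <= 0:
        logger.debug("SampEn undefined (no matches); returning 0")
        return 0.0
    return float(-math.log(a / b))


def _higuchi(x: np.ndarray, kmax: int) -> float:
    """Higuchi fractal dimension: slope of log mean curve length vs log(1/k)."""
    n = x.size
    log_lk = []
    log_inv_k = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (((n - m - 1) // k) * k)
            lengths.append(dist * norm / k)
        if lengths:
            mean_l = np.mean(lengths)
            if mean_l > 0:
                log_lk.append(math.log(mean_l))
                log_inv_k.append(math.log(1.0 / k))
    if len(log_lk) < 2:
        return 0.0
    slope = np.polyfit(log_inv_k, log_lk, 1)[0]
    return float(slope)


def _dfa(x: np.ndarray, box_sizes: np.ndarray) -> float:
    """DFA scaling exponent with per-box first-order detrending."""
    y = np.cumsum(x - np.mean(x))
    n = y.size
    log_n, log_f = [], []
    for box in box_sizes:
        n_boxes = n // box
        if n_boxes < 2:
            continue
        segments = y[: n_boxes * box].reshape(n_boxes, box)
        t = np.arange(box)
        coeffs = np.polyfit(t, segments.T, 1)  # (2, n_boxes)
        trends = np.outer(coeffs[0], t) + coeffs[1][:, None]
        f = math.sqrt(np.mean((segments - trends) ** 2))
        if f > 0:
            log_n.append(math.log(box))
            log_f.append(math.log(f))
    if len(log_n) < 2:
        return 0.0
    return float(np.polyfit(log_n, log_f, 1)[0])


def extract_complexity_features(
    x: np.ndarray, params: FeatureParams
) -> dict[str, float]:
    """Nonlinear/fractal features SampEn, MFL, HFD and DFA."""
    x = np.asarray(x, dtype=float)
    boxes = np.asarray(params.dfa_box_sizes)
    if boxes.max() > x.size / 2:
        raise ValueError(
            f"largest DFA box {boxes.max()} exceeds half the window length {x.size}"
        )
    ssq = float(np.sum(np.diff(x) ** 2))
    if ssq > 0:
        mfl = math.log10(math.sqrt(ssq))
    else:
        logger.debug("MFL degenerate input (flat window); applying floor")
        mfl = MFL_FLOOR
    return {
        "SampEn": _sampen(x, params.sampen_m, params.sampen_r),
        "MFL": mfl,
        "HFD": _higuchi(x, params.hfd_kmax),
        "DFA": _dfa(x, boxes),
    }


def fit_ar4(x: np.ndarray, params: FeatureParams) -> dict[str, float]:
    """Order-``ar_order`` autoregressive fit by the Burg recursion.

    Coefficients follow the prediction convention ``x_t ~ sum_k a_k x_{t-k}``
    on the demeaned series.  Constant input yields all-zero coefficients.
    """
    x = np.asarray(x, dtype=float)
    order = params.ar_order
    if x.size <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples for an AR({order}) fit")
    x = x - x.mean()
    a = np.zeros(0)
    f = x.copy()
    b = x.copy()
    degenerate = False
    for _ in range(order):
        ff = f[1:]
        bb = b[:-1]
        den = float(ff @ ff + bb @ bb)
        if den <= 0:
            degenerate = True
            break
        k = 2.0 * float(ff @ bb) / den
        a = np.concatenate([a - k * a[::-1], [k]])
        f, b = ff - k * bb, bb - k * ff
    if degenerate:
        logger.debug("Burg fit degenerate input (constant window); returning zeros")
        a = np.zeros(order)
    if params.ar_emit == "last":
        return {f"AR{order}": float(a[-1])}
    return {f"AR{i + 1}": float(a[i]) for i in range(order)}


def extract_all(
    window: np.ndarray, fs: float, params: FeatureParams | None = None
) -> dict[str, float]:
    """The full 19-entry named feature vector for one window."""
    if params is None:
        params = FeatureParams()
    x = np.asarray(window, dtype=float)
    if params.ar_emit != "all":
        from dataclasses import replace

        params = replace(params, ar_emit="all")
    out: dict[str, float] = {}
    out.update(extract_time_features(x, params))
    out.update(fit_ar4(x, params))
    out.update(extract_complexity_features(x, params))
    out.update(extract_frequency_features(x, fs, params))
    return {name: out[name] for name in FEATURE_NAMES}
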