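"""Independent brute-force oracles used to verify the package.

Every function here recomputes a quantity from its mathematical definition
by a route deliberately different from the implementation (explicit index
loops, cdist-based neighbour counting, per-path convolution), so agreement
is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist


def time_features_loop(x, threshold):
    """All eight time-domain features by explicit index loops."""
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    zc = sum(
        1
        for i in range(n - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= threshold
    )
    ssc = 0
    for i in range(1, n - 1):
        d1, d2 = x[i] - x[i - 1], x[i] - x[i + 1]
        if d1 * d2 > 0 and max(abs(d1), abs(d2)) >= threshold:
            ssc += 1
    rms = math.sqrt(sum(v * v for v in x) / n)
    npk = sum(
        1
        for i in range(1, n - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= threshold
    )
    ssi = sum(v * v for v in x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    return {
        "MAV": mav, "WL": wl, "ZC": float(zc), "SSC": float(ssc),
        "RMS": rms, "NP": float(npk), "SSI": ssi, "VAR": var,
    }


def welch_psd_single_segment(x, fs):
    """Welch PSD for the single-segment case (nperseg = len(x)), written out:
    hann window (periodic), constant detrend, density scaling, one-sided."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * k / n)
    seg = (x - x.mean()) * w
    spec = np.fft.rfft(seg)
    pxx = (np.abs(spec) ** 2) / (fs * np.sum(w**2))
    pxx[1:] *= 2.0
    if n % 2 == 0:
        pxx[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, pxx


def median_peak_frequency(x, fs):
    freqs, pxx = welch_psd_single_segment(x, fs)
    total = pxx.sum()
    if total <= 0:
        return 0.0, 0.0
    cum = np.cumsum(pxx)
    mf = freqs[int(np.searchsorted(cum, 0.5 * total))]
    pf = freqs[int(np.argmax(pxx))]
    return float(mf), float(pf)


def max_real_cepstrum(x):
    x = np.asarray(x, dtype=float)
    mag = np.abs(np.fft.fft(x))
    ceps = np.fft.ifft(np.log(np.maximum(mag, np.finfo(float).tiny))).real
    return float(np.max(ceps[1 : x.size // 2 + 1]))


def sampen_cdist(x, m=2, r_frac=0.2):
    """Sample entropy via scipy cdist Chebyshev template distances."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    r = r_frac * sd
    tm = np.array([x[i : i + m] for i in range(n - m)])
    tm1 = np.array([x[i : i + m + 1] for i in range(n - m)])
    b = int(np.count_nonzero(cdist(tm, tm, "chebyshev") <= r)) - len(tm)
    a = int(np.count_nonzero(cdist(tm1, tm1, "chebyshev") <= r)) - len(tm1)
    if a <= 0 or b <= 0:
        return 0.0
    return -math.log(a / b)


def higuchi_loop(x, kmax):
    """Higuchi fractal dimension with fully explicit loops."""
    x = np.asarray(x, dtype=float)
    n = x.size
    lk, inv_k = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            n_int = (n - m - 1) // k
            if n_int < 1:
                continue
            total = 0.0
            for i in range(1, n_int + 1):
                total += abs(x[m + i * k] - x[m + (i - 1) * k])
            lengths.append(total * (n - 1) / (n_int * k) / k)
        if lengths and np.mean(lengths) > 0:
            lk.append(math.log(np.mean(lengths)))
            inv_k.append(math.log(1.0 / k))
    return float(np.polyfit(inv_k, lk, 1)[0])


def dfa_loop(x, box_sizes):
    """DFA exponent with per-box least-squares lines fitted one at a time."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    n = y.size
    log_n, log_f = [], []
    for box in box_sizes:
        n_boxes = n // box
        if n_boxes < 2:
            continue
        sq = 0.0
        count = 0
        t = np.arange(box)
        for b in range(n_boxes):
            seg = y[b * box : (b + 1) * box]
            slope, intercept = np.polyfit(t, seg, 1)
            resid = seg - (slope * t + intercept)
            sq += float(resid @ resid)
            count += box
        f = math.sqrt(sq / count)
        if f > 0:
            log_n.append(math.log(box))
            log_f.append(math.log(f))
    return float(np.polyfit(log_n, log_f, 1)[0])


def burg_loop(x, order):
    """Classic Burg lattice recursion, written independently with explicit
    error-vector bookkeeping; prediction convention x_t ~ sum a_k x_{t-k}."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    ef = list(x)
    eb = list(x)
    a = [1.0]
    for m in range(1, order + 1):
        num = 0.0
        den = 0.0
        for t in range(m, n):
            num += ef[t] * eb[t - 1]
            den += ef[t] ** 2 + eb[t - 1] ** 2
        k = 2.0 * num / den
        a_new = [1.0]
        for i in range(1, m):
            a_new.append(a[i] - k * a[m - i])
        a_new.append(-k)
        ef_new = [0.0] * n
        eb_new = [0.0] * n
        for t in range(m, n):
            ef_new[t] = ef[t] - k * eb[t - 1]
            eb_new[t] = eb[t - 1] - k * ef[t]
        ef, eb, a = ef_new, eb_new, a_new
    return -np.asarray(a[1:])


def relieff_double_loop(X, y, k):
    """ReliefF weights with explicit per-instance, per-class loops."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes = sorted(set(y.tolist()))
    priors = {c: float(np.sum(y == c)) / n for c in classes}
    rng = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng > 0, rng, 1.0)
    Z = (X - X.min(axis=0)) / scale
    Z[:, rng == 0] = 0.0
    W = np.zeros(p)
    for i in range(n):
        d = np.array([np.sum(np.abs(Z[i] - Z[j])) for j in range(n)])
        hit_pool = [j for j in range(n) if y[j] == y[i] and j != i]
        hits = sorted(hit_pool, key=lambda j: (d[j], hit_pool.index(j)))[:k]
        for f in range(p):
            W[f] -= sum(abs(Z[i, f] - Z[j, f]) for j in hits) / (n * k)
        for c in classes:
            if c == y[i]:
                continue
            pool = [j for j in range(n) if y[j] == c]
            misses = sorted(pool, key=lambda j: (d[j], pool.index(j)))[:k]
            wgt = priors[c] / (1.0 - priors[y[i]])
            for f in range(p):
                W[f] += wgt * sum(abs(Z[i, f] - Z[j, f]) for j in misses) / (n * k)
    return W


def scattering_paths_explicit(x, banks, config_orders=2):
    """Materialise every scattering path by explicit per-path convolution.

    Returns (s0, s1 dict by filter index, s2 dict by (i1, i2)) as pooled
    time series, mirroring the transform's reflect-pad / crop conventions
    but evaluating one path at a time with no shared intermediates.
    """
    bank1 = banks[0]
    n = x.size
    pad = n // 2
    xp = np.pad(x, pad, mode="reflect")
    phi = bank1.phi_hat

    def conv(sig_pad, filt_hat):
        return np.fft.ifft(np.fft.fft(sig_pad) * filt_hat)

    s0 = conv(xp, phi).real[pad : pad + n]
    s1 = {}
    u1_store = {}
    for i1 in range(len(bank1)):
        u1 = np.abs(conv(xp, bank1.psi_hat[i1]))
        u1_store[i1] = u1
        s1[i1] = np.maximum(conv(u1, phi).real[pad : pad + n], 0.0)
    s2 = {}
    if config_orders == 2:
        bank2 = banks[1]
        for i1 in range(len(bank1)):
            for i2 in range(len(bank2)):
                if bank2.center_frequencies[i2] >= bank1.bandwidths[i1]:
                    continue
                u2 = np.abs(conv(u1_store[i1], bank2.psi_hat[i2]))
                s2[(i1, i2)] = np.maximum(conv(u2, phi).real[pad : pad + n], 0.0)
    return s0, s1, s2


def pca_eig_oracle(X, n_components):
    """Explained-variance fractions from an explicit covariance eigendecomposition."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return evals[:n_components] / evals.sum()
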