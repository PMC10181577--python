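"""Two-order 1-D wavelet scattering transform with Gabor filter banks.

The scattering transform cascades wavelet convolution, complex modulus and
low-pass averaging:

    S0 = x * phi
    U1_{j1} = |x * psi_{j1}|          S1_{j1} = U1_{j1} * phi
    U2_{j1,j2} = |U1_{j1} * psi_{j2}| S2_{j1,j2} = U2_{j1,j2} * phi

with analytic Gabor (Gaussian frequency window) wavelets, a first bank of 8
wavelets per octave, a second of 1 per octave, and an averaging scale set by
the invariance time T.  The filters are preset — nothing is learned — and
the pooled coefficients are translation-stable: shifts much smaller than T
barely change them, while the modulus stages retain the high-frequency
(amplitude-modulation) structure that plain low-pass averaging discards.

Implementation notes
--------------------
* Filters are built directly on the FFT grid of the reflection-padded
  window.  Wavelets are zeroed on non-positive frequencies (analytic, no
  DC response), centred geometrically at ratio ``2**(1/Q)`` from just
  below Nyquist down to ``8 * fs / n_samples``, with bandwidth chosen so
  adjacent filters cross near -3 dB.
* Each bank is then made tight on its covered band by the pointwise
  normalisation ``psi_hat /= sqrt(max(L, 1/4))`` where ``L`` is the raw
  Littlewood-Paley sum: the energy-preservation sum is exactly 1 wherever
  the raw design reaches 1/4, and filters stay smooth.
* A nominal invariance scale larger than the window (the default 1 s
  against millisecond-scale windows) is capped at the window duration with
  a warning; pooling then amounts to one value per path.
* Convolutions are frequency-domain products on the padded grid, cropped
  back to the window; no subsampling is applied (full time resolution is
  kept until pooling), so the ``oversampling`` knob is accepted for
  interface compatibility but has no effect.
* Second-order paths follow the frequency-decreasing rule: (j1, j2) is
  kept when the centre frequency of psi_{j2} lies below the -3 dB full
  width of psi_{j1}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScatteringConfig",
    "FilterBank",
    "ScatterMatrix",
    "build_filter_banks",
    "scattering_transform",
    "scattering_features",
    "feature_names",
]

_SQRT_LN2 = math.sqrt(math.log(2.0))
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # half-power full width in sigma units


@dataclass(frozen=True)
class ScatteringConfig:
    """Network configuration: two orders, Gabor wavelets, Q = (8, 1), T = 1 s."""

    n_orders: int = 2
    invariance_scale: float = 1.0
    quality_factors: tuple[int, int] = (8, 1)
    wavelet_family: str = "gabor"
    oversampling: int = 0
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.n_orders not in (1, 2):
            raise ValueError("n_orders must be 1 or 2")
        if self.invariance_scale <= 0:
            raise ValueError("invariance_scale must be > 0")
        if any(q < 1 for q in self.quality_factors):
            raise ValueError("quality factors must be positive")
        if self.wavelet_family != "gabor":
            raise ValueError("only the gabor family is implemented")
        if self.oversampling < 0:
            raise ValueError("oversampling must be >= 0")


@dataclass
class FilterBank:
    """Analytic Gabor bank on the padded FFT grid, plus the shared low-pass."""

    center_frequencies: np.ndarray  # Hz, descending
    bandwidths: np.ndarray  # -3 dB full widths, Hz
    psi_hat: np.ndarray  # (n_filters, n_fft) real frequency responses
    phi_hat: np.ndarray  # (n_fft,) low-pass frequency response, unit DC gain
    fs: float
    n_fft: int
    quality_factor: int
    passband: tuple[float, float]  # band over which the LP sum is tight

    def __len__(self) -> int:
        return self.center_frequencies.size

    def littlewood_paley_sum(self) -> np.ndarray:
        """sum_j |psi_hat_j|^2 + |phi_hat|^2 over the frequency grid."""
        return np.sum(self.psi_hat**2, axis=0) + self.phi_hat**2


def _effective_invariance(config: ScatteringConfig, fs: float, n_samples: int) -> float:
    duration = n_samples / fs
    if config.invariance_scale > duration:
        warnings.warn(
            f"invariance scale {config.invariance_scale} s exceeds the window "
            f"duration {duration:.6g} s; capping at the window duration "
            "(global average pooling per path)",
            stacklevel=3,
        )
        return duration
    return config.invariance_scale


def build_filter_banks(
    config: ScatteringConfig, fs: float, n_samples: int
) -> list[FilterBank]:
    """Build one Gabor bank per order plus the shared averaging low-pass.

    Centre frequencies descend geometrically at ratio ``2**(1/Q)`` from
    ``(fs/2) * 2**(-1/Q)`` down to ``8 * fs / n_samples`` (the lowest
    frequency resolvable with a few oscillations inside the window).
    """
    if n_samples < 16:
        raise ValueError("need at least 16 samples to build filter banks")
    t_eff = _effective_invariance(config, fs, n_samples)

    pad = n_samples // 2
    n_fft = n_samples + 2 * pad
    freqs = np.fft.fftfreq(n_fft, d=1.0 / fs)

    sigma_t = t_eff / 2.0
    sigma_f = 1.0 / (2.0 * math.pi * sigma_t)
    phi_hat = np.exp(-(freqs**2) / (2.0 * sigma_f**2))

    banks = []
    # reach down to ~2 oscillations per window so slow amplitude-modulation
    # rates (burst rhythms) stay inside the second-order bank's coverage
    f_min = 2.0 * fs / n_samples
    for q in config.quality_factors[: config.n_orders]:
        r = 2.0 ** (1.0 / q)
        f_max = (fs / 2.0) / r
        centers = []
        f = f_max
        while f >= f_min:
            centers.append(f)
            f /= r
        if not centers:
            raise ValueError(
                "no wavelet fits between the low-pass cutoff and fs/2; "
                "window too short for this configuration"
            )
        centers = np.asarray(centers)
        sigmas = centers * (r - 1.0) / (2.0 * _SQRT_LN2)  # -3 dB crossing design
        psi_hat = np.exp(
            -((freqs[None, :] - centers[:, None]) ** 2) / (2.0 * sigmas[:, None] ** 2)
        )
        psi_hat[:, freqs <= 0] = 0.0

        lp_raw = np.sum(psi_hat**2, axis=0)
        psi_hat /= np.sqrt(np.maximum(lp_raw, 0.25))[None, :]

        pos = (freqs > 0) & (lp_raw >= 0.25)
        passband = (float(freqs[pos].min()), float(freqs[pos].max()))
        banks.append(
            FilterBank(
                center_frequencies=centers,
                bandwidths=_FWHM * sigmas,
                psi_hat=psi_hat,
                phi_hat=phi_hat,
                fs=fs,
                n_fft=n_fft,
                quality_factor=q,
                passband=passband,
            )
        )
    return banks


@dataclass
class ScatterMatrix:
    """Scattering coefficients of one window with path metadata.

    ``s1[i]`` is the pooled time series for first-bank filter ``i`` (centre
    frequencies descending); ``s2[k]`` corresponds to ``paths2[k] = (i1,
    i2)`` indexing (first bank, second bank), kept only on
    frequency-decreasing paths.
    """

    s0: np.ndarray  # (n,)
    s1: np.ndarray  # (p1, n)
    s2: np.ndarray  # (p2, n)
    paths2: list[tuple[int, int]]
    center_frequencies_1: np.ndarray
    center_frequencies_2: np.ndarray
    fs: float


def admissible_paths(bank1: FilterBank, bank2: FilterBank) -> list[tuple[int, int]]:
    """Frequency-decreasing (j1, j2) pairs: centre(psi_j2) < bandwidth(psi_j1)."""
    return [
        (i1, i2)
        for i1 in range(len(bank1))
        for i2 in range(len(bank2))
        if bank2.center_frequencies[i2] < bank1.bandwidths[i1]
    ]


def scattering_transform(
    x: np.ndarray,
    fs: float,
    config: ScatteringConfig | None = None,
    banks: list[FilterBank] | None = None,
) -> ScatterMatrix:
    """Compute S0/S1/S2 time series for one window.

    ``banks`` may be passed to reuse a filter design across windows of the
    same length; it must come from :func:`build_filter_banks` with the same
    (config, fs, len(x)).
    """
    if config is None:
        config = ScatteringConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if banks is None:
        banks = build_filter_banks(config, fs, x.size)
    bank1 = banks[0]
    n = x.size
    pad = n // 2
    if bank1.n_fft != n + 2 * pad:
        raise ValueError("filter banks were built for a different window length")

    xp = np.pad(x, pad, mode="reflect")
    X = np.fft.fft(xp)
    phi = bank1.phi_hat

    def lowpass_crop(U_pad: np.ndarray) -> np.ndarray:
        s = np.fft.ifft(np.fft.fft(U_pad) * phi).real[pad : pad + n]
        return np.maximum(s, 0.0)

    s0 = np.fft.ifft(X * phi).real[pad : pad + n]

    u1 = np.abs(np.fft.ifft(X[None, :] * bank1.psi_hat, axis=1))
    s1 = np.stack([lowpass_crop(u1[i]) for i in range(len(bank1))]) if len(bank1) else np.zeros((0, n))

    paths2: list[tuple[int, int]] = []
    s2_rows: list[np.ndarray] = []
    cf2 = np.zeros(0)
    if config.n_orders == 2:
        bank2 = banks[1]
        cf2 = bank2.center_frequencies
        pairs = admissible_paths(bank1, bank2)
        by_j1: dict[int, list[int]] = {}
        for i1, i2 in pairs:
            by_j1.setdefault(i1, []).append(i2)
        for i1, i2_list in by_j1.items():
            F1 = np.fft.fft(u1[i1])
            for i2 in i2_list:
                u2 = np.abs(np.fft.ifft(F1 * bank2.psi_hat[i2]))
                s2_rows.append(lowpass_crop(u2))
                paths2.append((i1, i2))
    s2 = np.stack(s2_rows) if s2_rows else np.zeros((0, n))

    return ScatterMatrix(
        s0=s0,
        s1=s1,
        s2=s2,
        paths2=paths2,
        center_frequencies_1=bank1.center_frequencies,
        center_frequencies_2=cf2,
        fs=fs,
    )


def scattering_features(
    matrix: ScatterMatrix, config: ScatteringConfig | None = None
) -> np.ndarray:
    """Fixed-length pooled feature vector: S0, then S1 by descending
    frequency, then S2 in (j1, j2) lexicographic order; one time-averaged
    value per path.  ``log_transform`` applies log(1e-12 + v)."""
    if config is None:
        config = ScatteringConfig()
    parts = [np.atleast_1d(np.mean(matrix.s0))]
    if matrix.s1.size:
        parts.append(np.mean(matrix.s1, axis=1))
    if matrix.s2.size:
        # paths2 is generated in (j1, j2) lexicographic order
        parts.append(np.mean(matrix.s2, axis=1))
    vec = np.concatenate(parts)
    if config.log_transform:
        vec = np.log(1e-12 + np.maximum(vec, 0.0))
    return vec


def feature_names(matrix: ScatterMatrix) -> list[str]:
    """Path labels aligned with :func:`scattering_features` output."""
    names = ["S0"]
    names += [f"S1_{i}" for i in range(matrix.s1.shape[0])]
    names += [f"S2_{i1}_{i2}" for i1, i2 in matrix.paths2]
    return names
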