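"""Synthetic acoustic-emission (AE) wear-signal generator.

A passive AE sensor on a loaded joint records short, enveloped stress-wave
bursts each time the articulating surfaces release energy.  The recorded
voltage is the source event train convolved with the propagation medium and
the (resonant) sensor electronics, plus electronic noise.  This module
renders that chain for five wear mechanisms — abrasive, adhesive,
burnishing, burnishing-to-scratching and scratching — so that the whole
downstream pipeline (windowing, feature extraction, scattering, benchmark)
can be exercised on labelled data of known provenance.

Each wear class is described by a :class:`ClassProfile`: a burst event train
(Poisson or jittered-periodic), a per-event asymmetric-exponential envelope
``(1 - exp(-t/rise)) * exp(-t/decay)`` multiplying a band-limited carrier
(band-passed white noise, or a fixed tone for the smoother adhesive
signature), superposed, convolved with a second-order resonant sensor
response and finally summed with Gaussian noise.  Only the qualitative
orderings between classes (relative amplitudes, event densities, carrier
smoothness) are physically constrained; the concrete defaults live in
``_BASE_PROFILES`` and are overridable.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, fftconvolve, sosfilt

__all__ = [
    "WearClass",
    "ClassProfile",
    "InstrumentResponse",
    "AESignal",
    "LabeledDataset",
    "PAPER_FS",
    "DESK_FS",
    "PRESETS",
    "default_profiles",
    "default_instrument",
    "draw_event_times",
    "simulate_signal",
    "simulate_dataset",
    "write_dataset",
    "load_manifest",
]

#: Nominal acquisition rate of the resonant AE chain the simulator emulates.
PAPER_FS = 2_000_000.0
#: Fast preset: all frequencies divided by 10, time constants multiplied by 10.
DESK_FS = 200_000.0

_MAX_SEED = 2**31 - 1


class WearClass(str, Enum):
    """The five joint wear mechanisms the pipeline discriminates."""

    ABRASIVE = "abrasive"
    ADHESIVE = "adhesive"
    BURNISHING = "burnishing"
    BURNISHING_TO_SCRATCHING = "burnishing_to_scratching"
    SCRATCHING = "scratching"


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one wear class.

    Parameters
    ----------
    burst_rate : float
        Expected AE events per second (0 renders a silent class).
    timing_model : {"poisson", "periodic"}
        Event-train law; "periodic" adds uniform jitter of
        ``timing_jitter`` times the mean inter-event interval.
    timing_jitter : float
        Jitter fraction in [0, 1); only used by the periodic model.
    amplitude_scale : float
        Median per-event amplitude in volts (carrier is unit-RMS).
    amplitude_dispersion : float
        Log-normal sigma of per-event amplitude scatter (>= 0).
    rise_tau, decay_tau : float
        Envelope time constants in seconds; AE bursts have a short rise,
        a peak and a longer transient decay, so ``rise_tau < decay_tau``.
    carrier_band : tuple of float
        (low, high) carrier band in Hz; must sit inside (0, fs/2).
    carrier_kind : {"broadband_noise", "tonal"}
        Band-passed white noise, or a fixed tone at the band centre with
        random phase (the smoother signature).
    noise_sigma : float
        Standard deviation of the additive sensor/electronics noise in
        volts; scaled by the dataset-level ``difficulty`` knob.
    """

    burst_rate: float
    timing_model: str
    timing_jitter: float
    amplitude_scale: float
    amplitude_dispersion: float
    rise_tau: float
    decay_tau: float
    carrier_band: tuple[float, float]
    carrier_kind: str
    noise_sigma: float
    spectral_peak: float | None = None
    peak_emphasis: float = 0.0

    def validate(self, fs: float | None = None) -> None:
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.timing_model not in ("poisson", "periodic"):
            raise ValueError(f"unknown timing_model {self.timing_model!r}")
        if not 0.0 <= self.timing_jitter < 1.0:
            raise ValueError("timing_jitter must be in [0, 1)")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")
        if self.amplitude_dispersion < 0:
            raise ValueError("amplitude_dispersion must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")
        low, high = self.carrier_band
        if not 0 < low < high:
            raise ValueError("carrier_band must satisfy 0 < low < high")
        if fs is not None and high >= fs / 2:
            raise ValueError(
                f"carrier_band {self.carrier_band} outside (0, fs/2) at fs={fs}"
            )
        if self.carrier_kind not in ("broadband_noise", "tonal"):
            raise ValueError(f"unknown carrier_kind {self.carrier_kind!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.spectral_peak is not None and not low < self.spectral_peak < high:
            raise ValueError("spectral_peak must lie inside carrier_band")
        if self.peak_emphasis < 0:
            raise ValueError("peak_emphasis must be >= 0")

    def scaled(self, factor: float) -> "ClassProfile":
        """Dilate the profile in frequency by ``factor`` (time scales 1/factor)."""
        low, high = self.carrier_band
        return replace(
            self,
            rise_tau=self.rise_tau / factor,
            decay_tau=self.decay_tau / factor,
            carrier_band=(low * factor, high * factor),
            spectral_peak=None
            if self.spectral_peak is None
            else self.spectral_peak * factor,
        )


@dataclass(frozen=True)
class InstrumentResponse:
    """Lumped propagation-plus-sensor impulse response.

    Modelled as a unit-gain second-order resonator, i.e. a damped sinusoid
    ``exp(-zeta*w0*t) * sin(wd*t)`` normalised to unit peak frequency gain.
    One resonance is enough to give the output the narrow-band ringing that
    a real resonant AE sensor imposes on every source event.
    """

    resonant_freq: float
    damping_ratio: float
    gain: float = 1.0

    def validate(self, fs: float | None = None) -> None:
        if self.resonant_freq <= 0:
            raise ValueError("resonant_freq must be > 0")
        if not 0 < self.damping_ratio < 1:
            raise ValueError("damping_ratio must be in (0, 1)")
        if fs is not None and self.resonant_freq >= fs / 2:
            raise ValueError("resonant_freq must be below fs/2")

    def scaled(self, factor: float) -> "InstrumentResponse":
        return replace(self, resonant_freq=self.resonant_freq * factor)

    def impulse_response(self, fs: float) -> np.ndarray:
        """Impulse-invariant discretisation, truncated at 1e-4 of the peak."""
        self.validate(fs)
        w0 = 2 * math.pi * self.resonant_freq
        wd = w0 * math.sqrt(1 - self.damping_ratio**2)
        t_max = math.log(1e4) / (self.damping_ratio * w0)
        n = max(int(math.ceil(t_max * fs)), 4)
        t = np.arange(n) / fs
        h = np.exp(-self.damping_ratio * w0 * t) * np.sin(wd * t)
        spectrum = np.abs(np.fft.rfft(h, 4 * n))
        h *= self.gain / spectrum.max()
        return h


@dataclass
class AESignal:
    """A finite real-valued voltage sequence with its sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class LabeledDataset:
    """Balanced set of (signal, wear class) records plus its provenance."""

    records: list[tuple[AESignal, WearClass]]
    seed: int
    profile_snapshot: dict[WearClass, ClassProfile]
    response: InstrumentResponse
    difficulty: float

    @property
    def labels(self) -> list[WearClass]:
        return [cls for _, cls in self.records]


# Concrete study conditions.  Only the orderings between classes are
# physically pinned down (adhesive quieter and smoother than abrasive;
# burnishing much denser in events; the transition slightly louder than
# burnishing; scratching loudest and densest); the numbers themselves are
# the package's calibration, kept in this one registry.
_BASE_PROFILES: dict[WearClass, ClassProfile] = {
    WearClass.ABRASIVE: ClassProfile(
        burst_rate=100.0, timing_model="periodic", timing_jitter=0.2,
        amplitude_scale=1.0, amplitude_dispersion=0.25,
        rise_tau=20e-6, decay_tau=200e-6,
        carrier_band=(250e3, 450e3), carrier_kind="broadband_noise",
        noise_sigma=0.02, spectral_peak=380e3, peak_emphasis=1.0,
    ),
    WearClass.ADHESIVE: ClassProfile(
        burst_rate=100.0, timing_model="periodic", timing_jitter=0.2,
        amplitude_scale=0.45, amplitude_dispersion=0.15,
        rise_tau=60e-6, decay_tau=250e-6,
        carrier_band=(200e3, 320e3), carrier_kind="tonal",
        noise_sigma=0.02,
    ),
    WearClass.BURNISHING: ClassProfile(
        burst_rate=400.0, timing_model="periodic", timing_jitter=0.2,
        amplitude_scale=0.5, amplitude_dispersion=0.25,
        rise_tau=10e-6, decay_tau=80e-6,
        carrier_band=(120e3, 200e3), carrier_kind="broadband_noise",
        noise_sigma=0.02, spectral_peak=160e3, peak_emphasis=1.0,
    ),
    WearClass.BURNISHING_TO_SCRATCHING: ClassProfile(
        burst_rate=400.0, timing_model="periodic", timing_jitter=0.25,
        amplitude_scale=0.85, amplitude_dispersion=0.25,
        rise_tau=10e-6, decay_tau=80e-6,
        carrier_band=(150e3, 280e3), carrier_kind="broadband_noise",
        noise_sigma=0.02, spectral_peak=220e3, peak_emphasis=1.0,
    ),
    WearClass.SCRATCHING: ClassProfile(
        burst_rate=700.0, timing_model="poisson", timing_jitter=0.0,
        amplitude_scale=1.6, amplitude_dispersion=0.3,
        rise_tau=8e-6, decay_tau=70e-6,
        carrier_band=(110e3, 560e3), carrier_kind="broadband_noise",
        noise_sigma=0.02, spectral_peak=300e3, peak_emphasis=1.0,
    ),
}

_BASE_RESPONSE = InstrumentResponse(resonant_freq=300e3, damping_ratio=0.3)

# Class-independent acquisition interference: sparse structure-borne clicks
# (friction/electrical transients) that reach the sensor like any other
# source event.  Their strength is tied to the profile's noise level, so a
# noise-free render (noise_sigma = 0, or difficulty 0) is interference-free.
CLICK_RATE = 150.0  # events per second
CLICK_GAIN = 25.0  # median click amplitude in units of noise_sigma
CLICK_DECAY = 30e-6  # decay time constant at the nominal 2 MHz chain
CLICK_DISPERSION = 0.5  # log-normal sigma of click amplitudes

#: Named render presets: full acquisition rate vs a 10x slowed desk rate.
PRESETS = {
    "paper": {"fs": PAPER_FS, "duration": 0.5},
    "desk": {"fs": DESK_FS, "duration": 0.1},
}


def default_profiles(preset: str = "paper") -> dict[WearClass, ClassProfile]:
    """Default generative profiles for the five classes, rendered for ``preset``."""
    factor = PRESETS[preset]["fs"] / PAPER_FS
    return {cls: prof.scaled(factor) for cls, prof in _BASE_PROFILES.items()}


def default_instrument(preset: str = "paper") -> InstrumentResponse:
    factor = PRESETS[preset]["fs"] / PAPER_FS
    return _BASE_RESPONSE.scaled(factor)


def draw_event_times(
    profile: ClassProfile, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw AE event onset times in [0, duration) under the profile's law."""
    if profile.burst_rate <= 0:
        return np.empty(0)
    if profile.timing_model == "poisson":
        count = rng.poisson(profile.burst_rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=count))
    else:
        period = 1.0 / profile.burst_rate
        offset = rng.uniform(0.0, period)
        base = np.arange(offset, duration, period)
        jitter = rng.uniform(-0.5, 0.5, size=base.size) * profile.timing_jitter * period
        times = np.sort(np.clip(base + jitter, 0.0, np.nextafter(duration, 0.0)))
    return times


def simulate_signal(
    cls: WearClass,
    profile: ClassProfile,
    response: InstrumentResponse,
    duration: float,
    fs: float,
    seed: int,
    difficulty: float = 1.0,
) -> AESignal:
    """Render one labelled AE recording.

    The render is fully determined by ``seed``: event times, per-event
    amplitudes (log-normal, median ``amplitude_scale``), carrier draws and
    the additive noise are consumed from one seeded generator in a fixed
    order, so the same seed is bit-reproducible and scaling
    ``amplitude_scale`` rescales the noise-free output linearly.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration * fs must be >= 1")
    profile.validate(fs)
    response.validate(fs)

    rng = np.random.default_rng(seed)
    events = draw_event_times(profile, duration, rng)

    source = np.zeros(n)
    if events.size:
        burst_len = int(math.ceil((profile.rise_tau + 8 * profile.decay_tau) * fs))
        burst_len = max(4, min(burst_len, n))
        t_loc = np.arange(burst_len) / fs
        envelope = (1.0 - np.exp(-t_loc / profile.rise_tau)) * np.exp(
            -t_loc / profile.decay_tau
        )
        if profile.carrier_kind == "broadband_noise":
            sos = butter(4, profile.carrier_band, btype="bandpass", fs=fs, output="sos")
            sos_peak = None
            if profile.spectral_peak is not None and profile.peak_emphasis > 0:
                f_pk = profile.spectral_peak
                sos_peak = butter(
                    4, (0.95 * f_pk, 1.05 * f_pk), btype="bandpass", fs=fs,
                    output="sos",
                )
        else:
            f_c = 0.5 * (profile.carrier_band[0] + profile.carrier_band[1])
        sigma = profile.amplitude_dispersion
        for t_ev in events:
            amp = profile.amplitude_scale * math.exp(
                rng.normal(0.0, sigma) - 0.5 * sigma**2
            ) if sigma > 0 else profile.amplitude_scale
            if profile.carrier_kind == "broadband_noise":
                white = rng.standard_normal(burst_len)
                carrier = sosfilt(sos, white)
                carrier /= max(carrier.std(), 1e-30)
                if sos_peak is not None:
                    peak = sosfilt(sos_peak, white)
                    peak /= max(peak.std(), 1e-30)
                    carrier = carrier + profile.peak_emphasis * peak
                    carrier /= max(carrier.std(), 1e-30)
            else:
                phase = rng.uniform(0.0, 2 * math.pi)
                carrier = math.sqrt(2.0) * np.sin(2 * math.pi * f_c * t_loc + phase)
            idx = int(round(t_ev * fs))
            if idx >= n:
                continue
            chunk = amp * envelope * carrier
            source[idx : idx + burst_len] += chunk[: n - idx]

    sigma_noise = profile.noise_sigma * difficulty
    if sigma_noise > 0:
        click_amp = CLICK_GAIN * sigma_noise
        click_decay = CLICK_DECAY * (PAPER_FS / fs)
        click_len = max(4, min(int(math.ceil(8 * click_decay * fs)), n))
        click_env = np.exp(-np.arange(click_len) / (click_decay * fs))
        n_clicks = rng.poisson(CLICK_RATE * duration)
        click_times = rng.uniform(0.0, duration, size=n_clicks)
        for t_ev in click_times:
            amp = click_amp * math.exp(
                rng.normal(0.0, CLICK_DISPERSION) - 0.5 * CLICK_DISPERSION**2
            )
            shape = click_env * rng.standard_normal(click_len)
            idx = int(round(t_ev * fs))
            if idx >= n:
                continue
            source[idx : idx + click_len] += amp * shape[: n - idx]

    h = response.impulse_response(fs)
    voltage = fftconvolve(source, h)[:n]
    if sigma_noise > 0:
        voltage = voltage + rng.normal(0.0, sigma_noise, size=n)
    return AESignal(voltage, fs)


def simulate_dataset(
    n_per_class: int,
    duration: float | None = None,
    fs: float | None = None,
    seed: int = 0,
    *,
    preset: str = "paper",
    profiles: dict[WearClass, ClassProfile] | None = None,
    response: InstrumentResponse | None = None,
    difficulty: float = 1.0,
) -> LabeledDataset:
    """Simulate a balanced labelled dataset of 5 * n_per_class recordings.

    Per-record seeds are derived deterministically from the master seed, so
    (seed, configuration) pins down every sample bit-for-bit.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if fs is None:
        fs = PRESETS[preset]["fs"]
    if duration is None:
        duration = PRESETS[preset]["duration"]
    if profiles is None:
        factor = fs / PAPER_FS
        profiles = {cls: p.scaled(factor) for cls, p in _BASE_PROFILES.items()}
    if response is None:
        response = _BASE_RESPONSE.scaled(fs / PAPER_FS)

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, _MAX_SEED, size=5 * n_per_class)
    records: list[tuple[AESignal, WearClass]] = []
    i = 0
    for cls in WearClass:
        for _ in range(n_per_class):
            sig = simulate_signal(
                cls, profiles[cls], response, duration, fs,
                seed=int(child_seeds[i]), difficulty=difficulty,
            )
            records.append((sig, cls))
            i += 1
    return LabeledDataset(records, seed, dict(profiles), response, difficulty)


def write_dataset(dataset: LabeledDataset, outdir: str | Path) -> Path:
    """Write each record as float32 WAV plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "seed", "duration_s", "fs_hz"])
        for i, (sig, cls) in enumerate(dataset.records):
            name = f"{cls.value}_{i:04d}.wav"
            wavfile.write(outdir / name, int(sig.fs), sig.samples.astype(np.float32))
            writer.writerow([name, cls.value, dataset.seed, sig.duration, sig.fs])
    return manifest


def load_manifest(manifest: str | Path) -> list[tuple[AESignal, WearClass]]:
    """Load (signal, class) records from a manifest CSV written by write_dataset."""
    manifest = Path(manifest)
    records = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            fs, data = wavfile.read(manifest.parent / row["path"])
            records.append((AESignal(np.asarray(data, dtype=float), float(fs)),
                            WearClass(row["class"])))
    return records
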