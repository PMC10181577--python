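"""Simulator contracts: class orderings, determinism, linearity, spectra."""

from dataclasses import replace

import numpy as np
import pytest

from ae_jointdx.preprocess import window_signal
from ae_jointdx.wearsim import (
    DESK_FS,
    WearClass,
    default_instrument,
    default_profiles,
    draw_event_times,
    load_manifest,
    simulate_dataset,
    simulate_signal,
    write_dataset,
)

DESK = dict(duration=0.05, fs=DESK_FS)


def test_default_profiles_cover_all_classes_and_orderings():
    profs = default_profiles()
    assert set(profs) == set(WearClass)
    assert profs[WearClass.ADHESIVE].amplitude_scale < profs[WearClass.ABRASIVE].amplitude_scale
    assert profs[WearClass.BURNISHING].burst_rate > profs[WearClass.ABRASIVE].burst_rate
    assert (
        profs[WearClass.BURNISHING_TO_SCRATCHING].amplitude_scale
        > profs[WearClass.BURNISHING].amplitude_scale
    )
    assert (
        profs[WearClass.SCRATCHING].amplitude_scale
        > profs[WearClass.BURNISHING_TO_SCRATCHING].amplitude_scale
    )
    # adhesive carrier is smoother: tonal rather than broadband
    assert profs[WearClass.ADHESIVE].carrier_kind == "tonal"
    assert profs[WearClass.ABRASIVE].carrier_kind == "broadband_noise"


def test_silent_profile_gives_all_zero_signal(desk_profiles, desk_instrument):
    silent = replace(
        desk_profiles[WearClass.ABRASIVE], burst_rate=0.0, noise_sigma=0.0
    )
    sig = simulate_signal(
        WearClass.ABRASIVE, silent, desk_instrument, seed=0, **DESK
    )
    assert np.all(sig.samples == 0.0)


def test_poisson_event_count_statistics(desk_profiles):
    """Mean event count over 200 seeds matches Poisson(rate * duration)."""
    profile = replace(
        desk_profiles[WearClass.SCRATCHING], burst_rate=100.0, timing_model="poisson"
    )
    counts = [
        draw_event_times(profile, 0.1, np.random.default_rng(s)).size
        for s in range(200)
    ]
    expected = 10.0
    assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 200)


def test_rms_ordering_of_dense_classes(desk_profiles, desk_instrument):
    """Median window RMS: scratching > transition > burnishing (20 seeds)."""
    med = {}
    for cls in (
        WearClass.BURNISHING,
        WearClass.BURNISHING_TO_SCRATCHING,
        WearClass.SCRATCHING,
    ):
        rms = []
        for s in range(20):
            sig = simulate_signal(
                cls, desk_profiles[cls], desk_instrument, seed=s, **DESK
            )
            ws = window_signal(sig, 5)
            rms.extend(np.sqrt(np.mean(w**2)) for w in ws)
        med[cls] = np.median(rms)
    assert (
        med[WearClass.SCRATCHING]
        > med[WearClass.BURNISHING_TO_SCRATCHING]
        > med[WearClass.BURNISHING]
    )


def test_same_seed_is_bit_identical(desk_profiles, desk_instrument):
    args = (WearClass.ABRASIVE, desk_profiles[WearClass.ABRASIVE], desk_instrument)
    a = simulate_signal(*args, seed=42, **DESK)
    b = simulate_signal(*args, seed=42, **DESK)
    assert np.array_equal(a.samples, b.samples)


def test_instrument_stage_is_linear_in_event_amplitude(desk_profiles, desk_instrument):
    base = replace(desk_profiles[WearClass.ABRASIVE], noise_sigma=0.0)
    doubled = replace(base, amplitude_scale=2 * base.amplitude_scale)
    a = simulate_signal(WearClass.ABRASIVE, base, desk_instrument, seed=3, **DESK)
    b = simulate_signal(WearClass.ABRASIVE, doubled, desk_instrument, seed=3, **DESK)
    np.testing.assert_allclose(b.samples, 2 * a.samples, rtol=1e-12)


@pytest.mark.parametrize("cls", list(WearClass))
def test_output_power_concentrated_in_carrier_band(cls, desk_profiles, desk_instrument):
    noiseless = replace(desk_profiles[cls], noise_sigma=0.0)
    sig = simulate_signal(cls, noiseless, desk_instrument, seed=5, **DESK)
    power = np.abs(np.fft.rfft(sig.samples)) ** 2
    freqs = np.fft.rfftfreq(sig.samples.size, 1.0 / sig.fs)
    low, high = noiseless.carrier_band
    inside = (freqs >= 0.5 * low) & (freqs <= 1.5 * high)
    assert power[inside].sum() / power.sum() >= 0.80


def test_dataset_is_balanced_and_deterministic():
    ds1 = simulate_dataset(4, seed=9, preset="desk", duration=0.01)
    ds2 = simulate_dataset(4, seed=9, preset="desk", duration=0.01)
    ds3 = simulate_dataset(4, seed=10, preset="desk", duration=0.01)
    assert len(ds1.records) == 20
    labels = [cls for _, cls in ds1.records]
    assert all(labels.count(cls) == 4 for cls in WearClass)
    for (a, _), (b, _) in zip(ds1.records, ds2.records):
        assert np.array_equal(a.samples, b.samples)
    assert any(
        not np.array_equal(a.samples, b.samples)
        for (a, _), (b, _) in zip(ds1.records, ds3.records)
    )


def test_wav_manifest_roundtrip(tmp_path):
    ds = simulate_dataset(1, seed=2, preset="desk", duration=0.01)
    manifest = write_dataset(ds, tmp_path)
    records = load_manifest(manifest)
    assert len(records) == 5
    for (orig, cls_o), (loaded, cls_l) in zip(ds.records, records):
        assert cls_o == cls_l
        assert loaded.fs == orig.fs
        np.testing.assert_allclose(loaded.samples, orig.samples, atol=1e-6)


def test_invalid_arguments_raise(desk_profiles, desk_instrument):
    prof = desk_profiles[WearClass.ABRASIVE]
    with pytest.raises(ValueError):
        simulate_signal(
            WearClass.ABRASIVE,
            replace(prof, carrier_band=(10e3, 150e3)),  # above fs/2 at desk rate
            desk_instrument, 0.01, DESK_FS, 0,
        )
    with pytest.raises(ValueError):
        simulate_signal(WearClass.ABRASIVE, prof, desk_instrument, -1.0, DESK_FS, 0)
    with pytest.raises(ValueError):
        simulate_dataset(0, preset="desk")
    with pytest.raises(ValueError):
        replace(prof, rise_tau=prof.decay_tau * 2).validate()
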