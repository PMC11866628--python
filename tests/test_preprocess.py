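"""Cleaning chain: filter response, transient repair, interpolation, reference, ICA."""

import numpy as np
import pytest

from eegtopo.montage import standard_montage
from eegtopo.preprocess import (
    ArtifactCriteria,
    DecompositionError,
    PreprocessParams,
    bandpass,
    detect_bad_channels,
    interpolate_channels,
    preprocess,
    remove_artifact_components,
    repair_transients,
    rereference_average,
)
from eegtopo.recording import Recording
from eegtopo.synth import CouplingSpec, generate_recording


def _rec_from(data: np.ndarray, fs: float = 500.0) -> Recording:
    labels = tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    return Recording(data=data, fs=fs, labels=labels)


def _sine_rec(freq: float, fs: float = 500.0, dur: float = 30.0, nchan: int = 2):
    t = np.arange(int(fs * dur)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return _rec_from(np.tile(x, (nchan, 1)), fs)


class TestMontage:
    def test_symmetric_neighbors_and_coverage(self):
        m = standard_montage()
        assert len(m.labels) == 19
        for ch, nbrs in m.neighbors.items():
            assert nbrs, ch
            for other in nbrs:
                assert ch in m.neighbors[other]

    def test_adjacent_pairs_are_neighbors(self):
        m = standard_montage()
        assert "Cz" in m.neighbors["C3"]
        assert "Fp2" in m.neighbors["Fp1"]
        assert "O2" not in m.neighbors["Fp1"]


class TestBandpass:
    def test_dc_removed(self):
        rec = _rec_from(np.full((3, 5000), 7.5))
        out = bandpass(rec, 1.0, 55.0)
        trim = slice(500, -500)
        assert np.max(np.abs(out.data[:, trim])) < 1e-6 * 7.5

    def test_midband_amplitude_preserved(self):
        out = bandpass(_sine_rec(10.0), 1.0, 55.0)
        mid = out.data[0, 2500:-2500]
        amp = (mid.max() - mid.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        out = bandpass(_sine_rec(0.2, dur=60.0), 1.0, 55.0)
        mid = out.data[0, 5000:-5000]
        amp = np.sqrt(2) * np.sqrt(np.mean(mid**2))
        assert amp < 10 ** (-20 / 20)

    def test_invalid_band_edges(self):
        rec = _sine_rec(10.0)
        with pytest.raises(ValueError):
            bandpass(rec, 0.0, 55.0)
        with pytest.raises(ValueError):
            bandpass(rec, 1.0, 300.0)  # above Nyquist


class TestRepairTransients:
    def test_fifty_fifty_blend(self):
        """A spike segment becomes the mean of its flanking windows."""
        fs = 100.0
        n = 1000
        rng = np.random.default_rng(0)
        x = rng.standard_normal(n)
        x[400:410] = 1.0  # preceding window value (to be overwritten below)
        data = np.vstack([x])
        # build: preceding window constant 1, spike, subsequent window constant 3
        data[0, 390:400] = 1.0
        data[0, 400:410] += 120.0  # spike
        data[0, 410:420] = 3.0
        rec = _rec_from(data, fs)
        out, report = repair_transients(rec, spike_z=8.0, flat_min=0.05)
        segs = [s for s in report.repaired_segments if s.reason == "spike"]
        assert segs
        seg = segs[0]
        assert np.allclose(out.data[0, seg.start:seg.end], 2.0)

    def test_clean_recording_untouched(self):
        rng = np.random.default_rng(1)
        rec = _rec_from(rng.standard_normal((2, 2000)))
        out, report = repair_transients(rec)
        assert np.array_equal(out.data, rec.data)
        assert report.repaired_segments == []

    def test_flat_and_spike_detected_with_reasons(self):
        fs = 500.0
        rng = np.random.default_rng(2)
        data = rng.standard_normal((1, 5000))
        data[0, 1000:1100] = 0.0  # 200-ms flat run
        data[0, 3000] = 60.0  # isolated large spike
        rec = _rec_from(data, fs)
        out, report = repair_transients(rec, spike_z=12.0, flat_min=0.1)
        reasons = {s.reason for s in report.repaired_segments}
        assert reasons == {"spike", "flat"}
        flat = next(s for s in report.repaired_segments if s.reason == "flat")
        assert flat.start >= 950 and flat.end <= 1150
        spike = next(s for s in report.repaired_segments if s.reason == "spike")
        assert spike.start <= 3000 < spike.end
        # unflagged samples bit-identical
        mask = np.ones(5000, bool)
        for s in report.repaired_segments:
            mask[s.start:s.end] = False
        assert np.array_equal(out.data[0, mask], rec.data[0, mask])


class TestInterpolation:
    def test_identical_neighbors_reproduce_signal(self):
        m = standard_montage()
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1000)
        data = np.tile(x, (19, 1))
        rec = Recording(data=data, fs=500.0, labels=m.labels)
        out = interpolate_channels(rec, {"Cz"}, m)
        assert np.allclose(out.data[m.index("Cz")], x)

    def test_empty_bad_set_is_identity(self):
        m = standard_montage()
        rng = np.random.default_rng(4)
        rec = Recording(data=rng.standard_normal((19, 500)), fs=500.0, labels=m.labels)
        out = interpolate_channels(rec, set(), m)
        assert np.array_equal(out.data, rec.data)

    def test_equal_weight_mean_of_good_neighbors(self):
        m = standard_montage()
        rng = np.random.default_rng(5)
        rec = Recording(data=rng.standard_normal((19, 400)), fs=500.0, labels=m.labels)
        bad = {"O1"}
        out = interpolate_channels(rec, bad, m)
        good = [nb for nb in m.neighbors["O1"] if nb not in bad]
        expected = rec.data[[m.index(nb) for nb in good]].mean(axis=0)
        assert np.allclose(out.data[m.index("O1")], expected)

    def test_all_neighbors_bad_raises(self):
        m = standard_montage()
        rng = np.random.default_rng(6)
        rec = Recording(data=rng.standard_normal((19, 400)), fs=500.0, labels=m.labels)
        bad = {"O1"} | set(m.neighbors["O1"])
        with pytest.raises(ValueError, match="O1"):
            interpolate_channels(rec, bad, m)

    def test_detect_bad_channel_by_neighbor_correlation(self):
        m = standard_montage()
        rng = np.random.default_rng(7)
        shared = rng.standard_normal(4000)
        data = shared + 0.2 * rng.standard_normal((19, 4000))
        data[m.index("T6")] = rng.standard_normal(4000)  # fully decorrelated
        rec = Recording(data=data, fs=500.0, labels=m.labels)
        assert detect_bad_channels(rec, m) == ["T6"]


class TestRereference:
    def test_zero_mean_per_sample(self, coupled_recording):
        out = rereference_average(coupled_recording)
        scale = np.abs(coupled_recording.data).max()
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10 * scale

    def test_idempotent(self, coupled_recording):
        once = rereference_average(coupled_recording)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_antisymmetric_pair_unchanged(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(1000)
        rec = _rec_from(np.vstack([s, -s]))
        out = rereference_average(rec)
        assert np.allclose(out.data, rec.data)


@pytest.fixture(scope="module")
def base_recording():
    return generate_recording(CouplingSpec(fs=128.0, duration=70.0), seed=42)


class TestArtifactRemoval:

    def test_frontal_low_freq_component_removed(self, base_recording):
        rec = base_recording
        t = np.arange(rec.n_samples) / rec.fs
        art = 300.0 * np.sin(2 * np.pi * 0.5 * t)
        data = rec.data.copy()
        for ch in ("Fp1", "Fp2"):
            data[rec.labels.index(ch)] += art
        dirty = rec.with_data(data)
        cleaned, report = remove_artifact_components(dirty)
        assert report.removed_components >= 1
        assert report.removed_components <= rec.n_channels
        for ch in ("Fp1", "Fp2"):
            i = rec.labels.index(ch)
            assert cleaned.data[i].var() < 0.5 * dirty.data[i].var()

    def test_nothing_to_remove_reconstructs_input(self, base_recording):
        criteria = ArtifactCriteria(kurtosis_z=1e9, frontal_ratio=1e9)
        out, report = remove_artifact_components(base_recording, criteria)
        assert report.removed_components == 0
        rel = np.abs(out.data - base_recording.data).max() / np.abs(
            base_recording.data
        ).max()
        assert rel < 1e-6

    def test_short_recording_rejected(self):
        rec = generate_recording(CouplingSpec(fs=128.0, duration=10.0), seed=0)
        with pytest.raises(ValueError, match="60"):
            remove_artifact_components(rec)

    def test_strict_convergence_raises_on_gaussian_sources(self, base_recording):
        criteria = ArtifactCriteria(strict_convergence=True, max_iter=50)
        with pytest.raises(DecompositionError) as err:
            remove_artifact_components(base_recording, criteria)
        assert err.value.max_iter == 50


class TestFullChain:
    def test_metadata_and_shape_preserved(self):
        rec = generate_recording(CouplingSpec(fs=128.0, duration=70.0), seed=11,
                                 subject_id="s07")
        out, _ = preprocess(rec, PreprocessParams(run_ica=False))
        assert out.data.shape == rec.data.shape
        assert out.labels == rec.labels
        assert out.fs == rec.fs
        assert out.subject_id == "s07"

    def test_approximately_idempotent_on_clean_data(self):
        rec = generate_recording(CouplingSpec(fs=128.0, duration=70.0), seed=12)
        params = PreprocessParams(run_ica=False)
        once, _ = preprocess(rec, params)
        twice, _ = preprocess(once, params)
        rms = np.sqrt(np.mean((twice.data - once.data) ** 2))
        # the second bandpass re-attenuates 1/f energy near the 1-Hz edge;
        # a 4th-order zero-phase Butterworth leaves a few percent there
        assert rms < 0.05 * np.sqrt(np.mean(once.data**2))
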