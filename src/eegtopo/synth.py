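"""Synthetic EEG with known ground-truth lagged coupling.

The generator emulates the signal structure that phase-lag-sensitive
connectivity estimation assumes: band-limited oscillatory components
shared between coupled channels with a fixed non-zero phase lag, a 1/f
background, and (optionally) instantaneous real-valued mixing that
mimics volume conduction. Because the mixing is instantaneous and real
it inflates zero-lag (real-part) coherence but adds no imaginary
coherence, so the generated data exercise exactly the confound the
imaginary-coherence estimator is designed to reject.

Coupling model
--------------
Each :class:`Oscillator` draws one narrowband Gaussian "common" source
(unit variance, Gaussian spectral envelope centred on ``freq`` with s.d.
``bandwidth / 2``). Channel ``k`` of the oscillator's channel set
receives::

    strength * shift(common, phase_k) + sqrt(1 - strength**2) * private_k

where the per-channel phases are spread evenly over ``[0, phase_lag]``
and ``private_k`` is an independent narrowband source with the same
envelope. The magnitude-squared coherence between two coupled channels
at the centre frequency is therefore ``strength**2`` in expectation,
with a phase equal to their lag difference — so imaginary coherence
grows monotonically with ``strength`` and vanishes at ``strength = 0``.

A full pre/post x active/sham study is produced by
:func:`generate_study`: every subject gets its own jittered baseline
coupling strengths (between-subject variability), pre and post segments
differ only in their noise realization, and post segments of active
conditions additionally receive the configured band-specific coupling
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import STANDARD_1020_LABELS
from .recording import Condition, Recording, Segment, Side
from .spectral import BANDS

DEFAULT_FS = 500.0
DEFAULT_DURATION = 420.0  # 7-minute resting segments

_FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
_MIDLINE = ("Fz", "Cz", "Pz", "F3", "F4")
_POSTERIOR = ("O1", "O2", "P3", "P4", "Pz", "T5", "T6")
_CENTRAL = ("C3", "Cz", "C4", "F3", "F4")
_TEMPORAL = ("T3", "T4", "C3", "C4")


@dataclass(frozen=True)
class Oscillator:
    """One band-limited coupled component.

    phase_lag is the total phase spread (radians) across the channel
    set; per-channel phases are evenly spaced over [0, phase_lag], so
    every coupled pair has a strictly positive lag difference below pi.
    """

    freq: float
    bandwidth: float
    channels: tuple[str, ...]
    phase_lag: float = 1.2
    strength: float = 0.4

    def validate(self, labels: tuple[str, ...]) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"oscillators.strength must be in [0, 1], got {self.strength}")
        if self.strength > 0 and len(self.channels) > 1 and not 0.0 < self.phase_lag < np.pi:
            raise ValueError(f"oscillators.phase_lag must be in (0, pi), got {self.phase_lag}")
        if self.freq <= 0 or self.bandwidth <= 0:
            raise ValueError("oscillators.freq and oscillators.bandwidth must be positive")
        missing = set(self.channels) - set(labels)
        if missing:
            raise ValueError(f"oscillators.channels not in montage: {sorted(missing)}")


def default_oscillators() -> tuple[Oscillator, ...]:
    """Resting-state-like coupling: one oscillator per canonical band."""
    return (
        Oscillator(2.0, 1.0, _FRONTAL, phase_lag=1.2, strength=0.30),
        Oscillator(6.0, 1.5, _MIDLINE, phase_lag=1.0, strength=0.30),
        Oscillator(10.0, 2.0, _POSTERIOR, phase_lag=1.3, strength=0.40),
        Oscillator(20.0, 4.0, _CENTRAL, phase_lag=1.0, strength=0.25),
        Oscillator(40.0, 5.0, _TEMPORAL, phase_lag=1.0, strength=0.15),
    )


@dataclass(frozen=True)
class CouplingSpec:
    """Full description of one synthetic recording's signal content."""

    n_channels: int = 19
    fs: float = DEFAULT_FS
    duration: float = DEFAULT_DURATION
    oscillators: tuple[Oscillator, ...] = field(default_factory=default_oscillators)
    noise_exponent: float = 1.0
    noise_level: float = 1.0
    mixing: np.ndarray | str = "identity"
    labels: tuple[str, ...] | None = None
    amplitude_uv: float = 20.0  # overall RMS scale in microvolts

    def resolved_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return tuple(self.labels)
        if self.n_channels == 19:
            return STANDARD_1020_LABELS
        return tuple(f"ch{i:02d}" for i in range(self.n_channels))

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.noise_level < 0:
            raise ValueError(f"noise_level must be >= 0, got {self.noise_level}")
        labels = self.resolved_labels()
        if len(labels) != self.n_channels:
            raise ValueError("labels length must equal n_channels")
        for osc in self.oscillators:
            osc.validate(labels)
        if not isinstance(self.mixing, str):
            m = np.asarray(self.mixing, float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError("mixing must be square with dimension n_channels")
            if np.linalg.matrix_rank(m) < self.n_channels:
                raise ValueError("mixing must have full rank")
        elif self.mixing != "identity":
            raise ValueError(f"mixing must be a matrix or 'identity', got {self.mixing!r}")


def _narrowband(rng: np.random.Generator, n: int, fs: float, f0: float, bw: float) -> np.ndarray:
    """Positive-frequency spectrum of a unit-variance narrowband Gaussian signal."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    envelope = np.exp(-0.5 * ((freqs - f0) / (bw / 2.0)) ** 2)
    envelope[0] = 0.0
    coefs = envelope * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    return coefs


def _to_time(coefs: np.ndarray, n: int) -> np.ndarray:
    x = np.fft.irfft(coefs, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    coefs = scale * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    return _to_time(coefs, n)


def generate_recording(
    spec: CouplingSpec,
    seed: int,
    *,
    subject_id: str = "s00",
    condition: Condition = Condition.SHAM,
    side: Side = Side.LEFT,
    segment: Segment = Segment.PRE,
) -> Recording:
    """Synthesize one recording. Identical (spec, seed) gives identical samples."""
    spec.validate()
    rng = np.random.default_rng(seed)
    labels = spec.resolved_labels()
    n = int(round(spec.fs * spec.duration))
    data = np.zeros((spec.n_channels, n))

    if spec.noise_level > 0:
        for c in range(spec.n_channels):
            data[c] += spec.noise_level * _pink_noise(rng, n, spec.fs, spec.noise_exponent)

    for osc in spec.oscillators:
        idx = [labels.index(ch) for ch in osc.channels]
        m = len(idx)
        common = _narrowband(rng, n, spec.fs, osc.freq, osc.bandwidth)
        phases = np.linspace(0.0, osc.phase_lag, m) if m > 1 else np.zeros(1)
        mix = osc.strength
        priv = np.sqrt(max(0.0, 1.0 - mix**2))
        for k, c in enumerate(idx):
            shifted = common * np.exp(-1j * phases[k])
            component = mix * _to_time(shifted, n)
            if priv > 0:
                component += priv * _to_time(
                    _narrowband(rng, n, spec.fs, osc.freq, osc.bandwidth), n
                )
            data[c] += component

    data *= spec.amplitude_uv
    if not isinstance(spec.mixing, str):
        data = np.asarray(spec.mixing, float) @ data

    if not np.all(np.isfinite(data)):
        raise RuntimeError("generated recording contains non-finite values")
    return Recording(
        data=data, fs=spec.fs, labels=labels,
        subject_id=subject_id, condition=condition, side=side, segment=segment,
    )


def mix_sources(rec: Recording, mixing: np.ndarray) -> Recording:
    """Apply an instantaneous channel mixing matrix sample-wise (volume conduction)."""
    m = np.asarray(mixing, float)
    if m.shape != (rec.n_channels, rec.n_channels):
        raise ValueError(
            f"mixing shape {m.shape} does not match {rec.n_channels} channels"
        )
    return rec.with_data(m @ rec.data)


def random_mixing(n: int, seed: int, leakage: float = 0.3) -> np.ndarray:
    """Diagonally dominant positive mixing: identity plus random positive leakage."""
    rng = np.random.default_rng(seed)
    off = rng.uniform(0.0, leakage, size=(n, n))
    np.fill_diagonal(off, 0.0)
    return np.eye(n) + off


# ---------------------------------------------------------------------------
# study-level generation


#: Default effect modules: four distributed 4-channel clusters. Several
#: small modules raise clustering without concentrating degrees on one
#: clique, which is what moves Cp, gamma and sigma together after
#: degree-preserving normalization.
_DEFAULT_EFFECT_MODULES = (
    ("O1", "P3", "T5", "C3"),
    ("O2", "P4", "T6", "C4"),
    ("Fz", "Cz", "Pz", "F3"),
    ("Fp1", "Fp2", "F7", "F4"),
)


@dataclass(frozen=True)
class Effect:
    """Band-specific coupling increase injected into active post segments.

    Realized as one extra oscillator per module — a new lagged common
    signal at the band centre with coupling strength ``increment`` among
    each module's channels — so within-module band connectivity rises in
    several distributed clusters.
    """

    band: str = "alpha"
    modules: tuple[tuple[str, ...], ...] = _DEFAULT_EFFECT_MODULES
    increment: float = 0.6
    phase_lag: float = 2.0

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(ch for module in self.modules for ch in module)

    def validate(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"effect.band must be one of {sorted(BANDS)}, got {self.band!r}")
        if not 0.0 <= self.increment <= 1.0:
            raise ValueError(f"effect.increment must be in [0, 1], got {self.increment}")
        if any(len(m) < 2 for m in self.modules):
            raise ValueError("every effect module needs at least 2 channels")

    def as_oscillators(self) -> tuple[Oscillator, ...]:
        low, high = BANDS[self.band]
        centre = 0.5 * (low + high)
        bw = max(1.0, (high - low) / 2.0)
        return tuple(
            Oscillator(centre, bw, module, phase_lag=self.phase_lag,
                       strength=self.increment)
            for module in self.modules
        )


_DEFAULT_CONDITIONS = (
    (Condition.ACTIVE, Side.LEFT),
    (Condition.SHAM, Side.LEFT),
    (Condition.ACTIVE, Side.RIGHT),
    (Condition.SHAM, Side.RIGHT),
)


@dataclass(frozen=True)
class StudyDesign:
    """Pre/post x active/sham crossover design with a known injected effect."""

    n_subjects: int = 26
    conditions: tuple[tuple[Condition, Side], ...] = _DEFAULT_CONDITIONS
    effect: Effect | None = field(default_factory=Effect)
    base_spec: CouplingSpec = field(default_factory=CouplingSpec)
    subject_variability: float = 0.15  # s.d. of multiplicative strength jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.effect is not None:
            self.effect.validate()
        self.base_spec.validate()


def _jitter_oscillators(
    oscillators: tuple[Oscillator, ...], rng: np.random.Generator, sd: float
) -> tuple[Oscillator, ...]:
    out = []
    for osc in oscillators:
        s = float(np.clip(osc.strength * (1.0 + sd * rng.standard_normal()), 0.02, 0.95))
        out.append(replace(osc, strength=s))
    return tuple(out)


def generate_study(design: StudyDesign) -> list[Recording]:
    """One pre and one post recording per subject per condition.

    Sham post segments are statistically identical to pre (same subject
    baseline, fresh noise). Active post segments additionally carry the
    design's effect oscillator.
    """
    design.validate()
    if design.n_subjects == 0:
        raise ValueError("n_subjects must be positive")
    master = np.random.default_rng(design.seed)
    recordings: list[Recording] = []
    for s in range(design.n_subjects):
        subject_id = f"s{s:02d}"
        subj_rng = np.random.default_rng(master.integers(2**31))
        base = replace(
            design.base_spec,
            oscillators=_jitter_oscillators(
                design.base_spec.oscillators, subj_rng, design.subject_variability
            ),
        )
        for cond, side in design.conditions:
            for segment in (Segment.PRE, Segment.POST):
                spec = base
                if (
                    segment is Segment.POST
                    and cond is Condition.ACTIVE
                    and design.effect is not None
                    and design.effect.increment > 0
                ):
                    spec = replace(
                        base, oscillators=base.oscillators + design.effect.as_oscillators()
                    )
                rec_seed = int(subj_rng.integers(2**31))
                recordings.append(
                    generate_recording(
                        spec, rec_seed,
                        subject_id=subject_id, condition=cond, side=side, segment=segment,
                    )
                )
    return recordings


def reduced_spec(fs: float = 128.0, duration: float = 30.0) -> CouplingSpec:
    """Desk-scale recording profile: same 19-channel coupling structure,
    shorter duration and lower sampling rate for fast simulation studies."""
    return CouplingSpec(fs=fs, duration=duration)


def reduced_design(
    n_subjects: int = 8,
    sides: tuple[Side, ...] = (Side.LEFT,),
    effect: Effect | None = None,
    seed: int = 0,
    fs: float = 128.0,
    duration: float = 30.0,
) -> StudyDesign:
    """Desk-scale study: active+sham arms per requested side."""
    conditions = tuple(
        (cond, side) for side in sides for cond in (Condition.ACTIVE, Condition.SHAM)
    )
    return StudyDesign(
        n_subjects=n_subjects,
        conditions=conditions,
        effect=effect,
        base_spec=reduced_spec(fs=fs, duration=duration),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture graphs for metric oracles


def make_fixture_graph(kind: str, params: dict | None = None, seed: int | None = None):
    """Small named graphs (as BinaryGraph) for exercising topology metrics."""
    from .graphmetrics import BinaryGraph

    import networkx as nx

    params = dict(params or {})
    n = int(params.get("n", 10))
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind in {"ring_lattice", "watts_strogatz"}:
        k = int(params.get("k", 4))
        if k % 2 != 0 or not 0 < k < n:
            raise ValueError(f"k must be even and 0 < k < n, got k={k}, n={n}")
        p = float(params.get("p", 0.0 if kind == "ring_lattice" else 0.1))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        g = nx.watts_strogatz_graph(n, k, p, seed=seed)
    elif kind == "erdos_renyi":
        p = float(params.get("p", 0.2))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown fixture graph kind {kind!r}")
    adj = nx.to_numpy_array(g, dtype=bool)
    np.fill_diagonal(adj, False)
    return BinaryGraph(adjacency=adj)
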