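"""Synthetic EEG question-answering studies with known ground truth.

No public recording accompanies the protocol this package targets, so the
generator emulates its structure: a continuous multichannel recording cut
into balanced two-class question epochs (max 30 s at 250 Hz), an event
table, and a 2-D electrode layout on concentric rings inside the unit head
disc (a rough stand-in for a geodesic net).

Both classes share 1/f^alpha ("pink") background noise.  True-memory
(class 1) epochs additionally carry a smooth spatial pattern — an amplitude
bump over a spatially contiguous subset of channels, tapered with distance
from a focal scalp point — driven by a theta-band sinusoidal carrier under
a slow half-sine envelope across the epoch.  The carrier keeps the effect
inside the 1-48 Hz analysis band (a purely static pattern would be removed
by the high-pass).  This is deliberately the minimal structure the
topomap texture features can detect; it makes no claim of biophysical
realism (no dipole forward model, no ERP components).  Optional eye-blink
transients can be injected on the frontal-most channels to exercise the
band-pass stage.

All randomness flows from one root seed through named spawned streams, so
regeneration is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io_preprocess import EEGRecording, ElectrodeLayout, EventTable

#: Nominal blink amplitude in microvolts.
BLINK_AMPLITUDE_UV = 100.0
BLINK_SIGMA_S = 0.05


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Desk-scale defaults: a 32-channel, 2-s-epoch study of 200 questions.

    ``effect_amplitude`` is the peak class-1 bump in microvolts; the default
    is 10x the background noise SD, a strong, cleanly recoverable effect.
    ``paper_scale()`` upsizes to the recording protocol's dimensions.
    """

    n_channels: int = 32
    sampling_rate: float = 250.0
    n_questions_per_class: int = 100
    epoch_seconds: float = 2.0
    effect_amplitude: float = 50.0
    effect_frequency_hz: float = 6.0
    effect_channel_fraction: float = 0.25
    noise_sd: float = 5.0
    pink_noise_exponent: float = 1.0
    artifact_rate: float = 0.0  # blinks per minute
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 4:
            raise ParameterError("n_channels must be >= 4")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.n_questions_per_class < 1:
            raise ParameterError("need at least 1 question per class")
        if not 0 < self.epoch_seconds <= 30:
            raise ParameterError("epoch_seconds must be in (0, 30]")
        if self.effect_amplitude < 0:
            raise ParameterError("effect_amplitude must be >= 0")
        if not 0 < self.effect_frequency_hz < self.sampling_rate / 2:
            raise ParameterError("effect_frequency_hz must be below Nyquist")
        if not 0 < self.effect_channel_fraction <= 1:
            raise ParameterError("effect_channel_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.pink_noise_exponent < 0:
            raise ParameterError("pink_noise_exponent must be >= 0")
        if self.artifact_rate < 0:
            raise ParameterError("artifact_rate must be >= 0")

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticStudyConfig":
        """93 channels and up-to-30-s epochs, for stress tests."""
        base = dict(n_channels=93, epoch_seconds=30.0)
        base.update(overrides)
        return cls(**base)


def generate_layout(n_channels: int, head_radius: float = 1.0) -> ElectrodeLayout:
    """Deterministic concentric-ring layout inside the head disc.

    Ring populations grow with radius (circumference), rings are rotated by
    the golden angle against each other to avoid radial alignment, and a
    center electrode is placed when a ring would hold a single channel.
    """
    if n_channels < 4:
        raise ParameterError("n_channels must be >= 4")
    n_rings = max(2, round(np.sqrt(n_channels / np.pi)) + 1)
    radii = head_radius * 0.92 * np.arange(1, n_rings + 1) / n_rings
    raw = radii / radii.sum() * n_channels
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts, outer first
    frac_order = np.argsort(-(raw - counts) - 1e-9 * np.arange(n_rings))
    for i in frac_order[: n_channels - counts.sum()]:
        counts[i] += 1
    xs, ys = [], []
    golden = np.pi * (3 - np.sqrt(5))
    for k, (r, c) in enumerate(zip(radii, counts)):
        if c == 0:
            continue
        theta = 2 * np.pi * np.arange(c) / c + k * golden
        xs.extend(r * np.cos(theta))
        ys.extend(r * np.sin(theta))
    pos = np.column_stack([xs, ys])[:n_channels]
    ids = tuple(f"ch{i:03d}" for i in range(pos.shape[0]))
    return ElectrodeLayout(ids, pos, head_radius=head_radius)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float,
                sd: float, sampling_rate: float) -> np.ndarray:
    """(M, T) noise with a 1/f^exponent power spectrum, per-channel SD = sd."""
    m, t = shape
    white = rng.standard_normal((m, t))
    if exponent == 0:
        return white * sd
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(t, d=1.0 / sampling_rate)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n=t, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    return x / np.where(x_sd > 0, x_sd, 1.0) * sd


def _effect_weights(layout: ElectrodeLayout, fraction: float) -> np.ndarray:
    """Per-channel weights of the class-1 spatial bump (0 outside it).

    The affected channels are the ones nearest a fixed parieto-central focal
    point, giving a spatially contiguous blob; weights taper smoothly
    (raised cosine in distance) from 1 at the focus to ~0 at the blob edge.
    """
    m = len(layout)
    n_eff = max(1, round(fraction * m))
    focus = np.array([0.0, 0.45 * layout.head_radius])
    d = np.linalg.norm(layout.positions - focus, axis=1)
    chosen = np.argsort(d, kind="stable")[:n_eff]
    w = np.zeros(m)
    # taper scale reaches past the blob edge so every chosen channel keeps
    # substantial weight even when the chosen distances are nearly equal
    d_scale = 1.5 * max(d[chosen].max(), 1e-9)
    w[chosen] = 0.5 * (1 + np.cos(np.pi * np.minimum(d[chosen] / d_scale, 1.0)))
    return w


def generate_study(
    cfg: SyntheticStudyConfig,
) -> tuple[EEGRecording, EventTable, ElectrodeLayout]:
    """One continuous recording with 2*n_questions_per_class labeled epochs.

    Epochs are back-to-back; label order is a seeded shuffle of a perfectly
    balanced label vector.  Class-1 epochs add the tapered spatial pattern
    times a half-sine envelope; blinks (if any) land at Poisson times on the
    frontal quarter of channels.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_noise, rng_labels, rng_art = (np.random.default_rng(s) for s in ss.spawn(3))
    layout = generate_layout(cfg.n_channels)
    m = len(layout)
    t_epoch = int(round(cfg.epoch_seconds * cfg.sampling_rate))
    if t_epoch < 2:
        raise ParameterError("epoch too short for the sampling rate")
    n_epochs = 2 * cfg.n_questions_per_class
    t_total = n_epochs * t_epoch

    x = _pink_noise(
        rng_noise, (m, t_total), cfg.pink_noise_exponent, cfg.noise_sd, cfg.sampling_rate
    )

    labels = np.repeat([1, 0], cfg.n_questions_per_class)
    labels = labels[rng_labels.permutation(n_epochs)]

    if cfg.effect_amplitude > 0:
        w = _effect_weights(layout, cfg.effect_channel_fraction)
        tt = (np.arange(t_epoch) + 0.5) / cfg.sampling_rate
        envelope = np.sin(np.pi * (np.arange(t_epoch) + 0.5) / t_epoch)
        carrier = np.sin(2 * np.pi * cfg.effect_frequency_hz * tt)
        bump = cfg.effect_amplitude * np.outer(w, envelope * carrier)
        for i in np.flatnonzero(labels == 1):
            x[:, i * t_epoch : (i + 1) * t_epoch] += bump

    if cfg.artifact_rate > 0:
        _add_blinks(x, layout, cfg, rng_art)

    rec = EEGRecording(
        x, cfg.sampling_rate, layout.channel_ids, subject_id=f"synthetic-{cfg.seed}"
    )
    events = EventTable(
        tuple(f"q{i:03d}" for i in range(n_epochs)),
        np.arange(n_epochs) * t_epoch,
        (np.arange(n_epochs) + 1) * t_epoch,
        labels,
    )
    return rec, events, layout


def _add_blinks(
    x: np.ndarray,
    layout: ElectrodeLayout,
    cfg: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> None:
    """Inject Gaussian-shaped frontal transients at Poisson times, in place."""
    m, t_total = x.shape
    minutes = t_total / cfg.sampling_rate / 60.0
    n_blinks = rng.poisson(cfg.artifact_rate * minutes)
    if n_blinks == 0:
        return
    frontal = np.argsort(-layout.positions[:, 1], kind="stable")[: max(1, m // 4)]
    taper = np.linspace(1.0, 0.3, frontal.size)
    sigma = BLINK_SIGMA_S * cfg.sampling_rate
    half = int(4 * sigma)
    shape = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    centers = rng.integers(half, t_total - half - 1, size=n_blinks)
    for c in centers:
        seg = slice(c - half, c + half + 1)
        x[np.ix_(frontal, range(seg.start, seg.stop))] += (
            BLINK_AMPLITUDE_UV * np.outer(taper, shape)
        )
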