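"""Synthetic multi-channel surface-EMG generation.

The generator emulates a word-handwriting acquisition protocol: each
recording holds one word class, written ``reps_per_class`` times with a
rest pause between repetitions, picked up by ``n_channels`` surface
electrodes sampled at ``fs``. Surface EMG during a contraction is modelled
phenomenologically as band-limited (35-450 Hz) Gaussian noise amplitude-
modulated by a slowly varying envelope. Each word class owns a fixed
multi-burst envelope per channel — a sequence of strokes drawn from a
per-subject shared stroke ("letter") library, so that words sharing
strokes are genuinely confusable — reused across repetitions with small
amplitude/timing jitter. Band-limited baseline noise is added throughout,
scaled to a configurable activation-to-rest signal-to-noise ratio.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_BAND = (35.0, 450.0)
DEFAULT_FILTER_ORDER = 4
# channel-averaged activation-epoch power every recording is scaled to
# (0.5 mV RMS, a typical surface-EMG contraction amplitude)
REFERENCE_ACTIVATION_POWER = 0.25
# power share of the spectrally flat component in every stroke carrier
FLAT_CARRIER_FRACTION = 0.10


class SynthError(ValueError):
    """Invalid synthetic-generation request (bad label or config)."""


@dataclass(frozen=True)
class GaussianBurst:
    """One envelope bump: ``amp * exp(-0.5 ((t - center)/width)^2)``.

    ``center`` and ``width`` are in seconds relative to the start of the
    word epoch; ``amp`` is in mV. ``peak_hz`` optionally gives the bump's
    carrier a gentle spectral resonance inside the 35-450 Hz band (None
    means a spectrally flat band-limited carrier).
    """

    amp: float
    center: float
    width: float
    peak_hz: float | None = None
    tremor_hz: float = 0.0
    tremor_depth: float = 0.0


# per-class profile: one tuple of bursts per channel
EnvelopeProfile = tuple[tuple[GaussianBurst, ...], ...]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic acquisition protocol.

    Defaults mirror the emulated protocol: 30 word classes, 10 repetitions
    per recording separated by 5 s of rest, 6 channels at 1000 Hz.
    ``snr_db`` is the ratio of mean activation-epoch power to mean rest
    power, in dB, averaged over channels; ``numpy.inf`` means a noise-free
    baseline. ``envelope_profile`` optionally overrides the per-class
    envelope draw (mapping word label -> profile).
    """

    n_classes: int = 30
    reps_per_class: int = 10
    n_channels: int = 6
    fs: float = 1000.0
    rest_duration: float = 5.0
    word_duration: float = 1.5
    lead_in: float = 2.0
    snr_db: float = 20.0
    seed: int = 0
    amp_jitter: float = 0.05
    time_jitter: float = 0.050
    n_letter_types: int = 64
    envelope_profile: dict[int, EnvelopeProfile] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise SynthError("n_classes must be >= 2")
        if self.reps_per_class < 2:
            raise SynthError("reps_per_class must be >= 2")
        if self.fs <= 2 * DEFAULT_BAND[1]:
            raise SynthError(
                f"fs={self.fs} must exceed twice the 450 Hz band edge"
            )

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class ActivationSegment:
    """Half-open sample span [start_sample, end_sample) of one repetition."""

    start_sample: int
    end_sample: int
    repetition_index: int

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ValueError("segment must have start_sample < end_sample")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EmgRecording:
    """One labelled recording: channels x samples matrix in mV at ``fs``.

    ``truth_segments`` carries ground-truth activation spans and is only
    populated for synthetic recordings.
    """

    subject_id: str
    word_label: int
    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    truth_segments: list[ActivationSegment] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def band_limit_sos(fs: float, band=DEFAULT_BAND, order=DEFAULT_FILTER_ORDER):
    """Second-order sections of the 35-450 Hz Butterworth band-pass."""
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def _carrier(
    rng: np.random.Generator,
    n: int,
    fs: float,
    peak_hz: float | None = None,
    peak_q: float = 1.5,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier of length ``n``.

    With ``peak_hz`` set, the white noise is first shaped by a gentle
    resonance at that frequency (before the 35-450 Hz band limit), giving
    the carrier a spectral identity inside the band.
    """
    white = rng.standard_normal(n)
    if peak_hz is not None:
        b, a = signal.iirpeak(peak_hz, peak_q, fs=fs)
        white = signal.filtfilt(b, a, white)
    x = signal.sosfiltfilt(band_limit_sos(fs), white)
    return x / np.std(x)


def _class_rng(seed: int, word_label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, word_label]))


def _record_rng(seed: int, subject_id: str, word_label: int) -> np.random.Generator:
    subj_key = zlib.crc32(str(subject_id).encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([seed, subj_key, word_label, 1])
    )


def draw_letter_library(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The shared stroke ("letter") alphabet of one simulated subject.

    Handwritten words are built from a common repertoire of strokes, so the
    library is drawn once per seed and shared by every word class: letter
    ``l`` recruits the channels with amplitude pattern ``amps[l]`` (mV),
    shifts each channel's carrier spectrum to resonance ``peaks[l]`` (Hz),
    and rides on a letter-specific physiological tremor (slow amplitude
    modulation at ``tremor_hz[l]`` with relative depth ``tremor_depth[l]``).
    Words sharing letters therefore produce genuinely ambiguous analysis
    windows, as real words sharing letters do.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    L, C = config.n_letter_types, config.n_channels
    amps = rng.uniform(0.15, 1.0, (L, C))
    peaks = rng.uniform(60.0, 240.0, (L, C))
    tremor_hz = rng.uniform(3.0, 15.0, L)
    tremor_depth = rng.uniform(0.1, 0.6, L)
    return amps, peaks, tremor_hz, tremor_depth


def draw_envelope_profile(
    config: SyntheticConfig, word_label: int
) -> EnvelopeProfile:
    """Draw the class-specific multi-burst envelope, one burst tuple per channel.

    A word is a sequence of 3-8 strokes drawn from the subject's shared
    letter library. Stroke times are shared across channels (all muscles
    co-activate at each pen stroke, cf. coincident bursts across probes) and
    are evenly spaced with class-specific jitter, with widths wide enough to
    overlap so the word stays continuously active (sustained pen contact).
    Each stroke recruits the channels with its letter's amplitude pattern
    and carrier resonance, so the word is a class-specific trajectory
    through cross-channel amplitude/spectrum space, multimodal at window
    scale. The draw depends only on (seed, word_label): every repetition
    and every subject sharing the seed reuses the same motor template.
    """
    letter_amps, letter_peaks, letter_trem_hz, letter_trem_depth = (
        draw_letter_library(config)
    )
    rng = _class_rng(config.seed, word_label)
    n_strokes = int(rng.integers(3, 9))
    letters = rng.integers(0, config.n_letter_types, n_strokes)
    span = (0.12 * config.word_duration, 0.88 * config.word_duration)
    spacing = (span[1] - span[0]) / max(n_strokes - 1, 1)
    centers = np.linspace(*span, n_strokes) + rng.uniform(
        -0.3 * spacing, 0.3 * spacing, n_strokes
    )
    widths = spacing * rng.uniform(0.45, 0.90, n_strokes)
    profile = []
    for ch in range(config.n_channels):
        profile.append(
            tuple(
                GaussianBurst(
                    float(letter_amps[l, ch]), float(c), float(w),
                    float(letter_peaks[l, ch]),
                    float(letter_trem_hz[l]), float(letter_trem_depth[l]),
                )
                for l, c, w in zip(letters, centers, widths)
            )
        )
    return tuple(profile)


def _render_envelope(
    profile_ch: tuple[GaussianBurst, ...],
    n: int,
    fs: float,
    amp_jit: np.ndarray,
    time_jit: np.ndarray,
) -> np.ndarray:
    """Render one channel's jittered envelope over an epoch of ``n`` samples."""
    t = np.arange(n) / fs
    env = np.zeros(n)
    for b, da, dt in zip(profile_ch, amp_jit, time_jit):
        env += b.amp * da * np.exp(-0.5 * ((t - b.center - dt) / b.width) ** 2)
    return env


def generate_recording(
    config: SyntheticConfig, word_label: int, subject_id: str = "S1"
) -> EmgRecording:
    """Generate one synthetic recording for ``word_label``.

    Layout: ``lead_in`` seconds of rest, then ``reps_per_class`` word epochs
    of ``word_duration`` seconds each separated (and followed) by
    ``rest_duration`` seconds of rest. Activation epochs are band-limited
    Gaussian carriers amplitude-modulated by the class envelope; baseline
    noise is scaled so the activation-to-rest power ratio matches
    ``snr_db`` (exactly, for snr_db > 0).
    """
    if not (1 <= word_label <= config.n_classes):
        raise SynthError(
            f"word_label {word_label} outside 1..{config.n_classes}"
        )
    if np.isfinite(config.snr_db) and config.snr_db <= 0:
        logger.warning(
            "snr_db=%.1f <= 0 dB: low-separability regime", config.snr_db
        )

    fs = config.fs
    word_n = int(round(config.word_duration * fs))
    rest_n = int(round(config.rest_duration * fs))
    lead_n = int(round(config.lead_in * fs))
    total_n = lead_n + config.reps_per_class * (word_n + rest_n)

    if config.envelope_profile is not None and word_label in config.envelope_profile:
        profile = config.envelope_profile[word_label]
        if len(profile) != config.n_channels:
            raise SynthError("envelope_profile channel count mismatch")
    else:
        profile = draw_envelope_profile(config, word_label)

    rng = _record_rng(config.seed, subject_id, word_label)

    segments = []
    starts = []
    for rep in range(config.reps_per_class):
        s = lead_n + rep * (word_n + rest_n)
        starts.append(s)
        segments.append(ActivationSegment(s, s + word_n, rep))

    data = np.zeros((config.n_channels, total_n))
    act_mask = np.zeros(total_n, dtype=bool)
    for s in starts:
        act_mask[s : s + word_n] = True

    n_strokes = max(len(p) for p in profile)
    reps = config.reps_per_class
    t = np.arange(word_n) / fs
    # stroke jitter is shared across channels: the whole pen stroke shifts
    amp_jit = rng.uniform(1 - config.amp_jitter, 1 + config.amp_jitter,
                          (reps, n_strokes))
    time_jit = rng.uniform(-config.time_jitter, config.time_jitter,
                           (reps, n_strokes))
    tremor_phase = rng.uniform(0.0, 2 * np.pi, (reps, n_strokes))

    sos = band_limit_sos(fs)
    for ch in range(config.n_channels):
        epochs = np.zeros((reps, word_n))
        for k, burst in enumerate(profile[ch]):
            # one carrier per stroke, batched over repetitions: a resonant
            # component mixed with a spectrally flat one — the interference
            # pattern is never purely resonant, which also keeps short-window
            # AR estimates stable instead of hugging the unit circle
            white = rng.standard_normal((reps, word_n))
            if burst.peak_hz is not None:
                b, a = signal.iirpeak(burst.peak_hz, 1.5, fs=fs)
                shaped = signal.sosfiltfilt(
                    sos, signal.filtfilt(b, a, white, axis=1), axis=1
                )
                shaped /= shaped.std(axis=1, keepdims=True)
                flat = signal.sosfiltfilt(
                    sos, rng.standard_normal((reps, word_n)), axis=1
                )
                flat /= flat.std(axis=1, keepdims=True)
                carrier = (
                    np.sqrt(1.0 - FLAT_CARRIER_FRACTION) * shaped
                    + np.sqrt(FLAT_CARRIER_FRACTION) * flat
                )
            else:
                carrier = signal.sosfiltfilt(sos, white, axis=1)
            carrier /= carrier.std(axis=1, keepdims=True)
            env = burst.amp * amp_jit[:, k : k + 1] * np.exp(
                -0.5
                * ((t[None, :] - burst.center - time_jit[:, k : k + 1]) / burst.width)
                ** 2
            )
            if burst.tremor_depth > 0.0:
                # letter-specific physiological tremor: slow amplitude
                # modulation riding on the stroke envelope
                env = env * (
                    1.0
                    + burst.tremor_depth
                    * np.sin(
                        2 * np.pi * burst.tremor_hz * t[None, :]
                        + tremor_phase[:, k : k + 1]
                    )
                )
            epochs += env * carrier

        bursts = np.zeros(total_n)
        for rep, s in enumerate(starts):
            bursts[s : s + word_n] = epochs[rep]
        data[ch] = bursts

    # normalise every recording to the same channel-averaged activation
    # power: words are not distinguishable by loudness, and the baseline
    # noise added below is the same instrumentation noise for every word
    burst_power = float(np.mean(data[:, act_mask] ** 2))
    data *= np.sqrt(REFERENCE_ACTIVATION_POWER / burst_power)

    if not np.isinf(config.snr_db):
        ratio = 10.0 ** (config.snr_db / 10.0)
        if ratio > 1.0 + 1e-9:
            # exact: (P_burst + sigma^2) / sigma^2 == ratio
            noise_var = REFERENCE_ACTIVATION_POWER / (ratio - 1.0)
        else:
            noise_var = REFERENCE_ACTIVATION_POWER / ratio
        for ch in range(config.n_channels):
            data[ch] += _carrier(rng, total_n, fs) * np.sqrt(noise_var)

    return EmgRecording(
        subject_id=str(subject_id),
        word_label=int(word_label),
        data=data,
        fs=fs,
        truth_segments=segments,
    )


def generate_dataset(
    config: SyntheticConfig, subject_id: str = "S1"
) -> list[EmgRecording]:
    """One recording per word class (n_classes recordings, labels 1..n)."""
    return [
        generate_recording(config, label, subject_id)
        for label in range(1, config.n_classes + 1)
    ]


def measured_snr_db(recording: EmgRecording) -> float:
    """Activation/rest power ratio in dB from the truth segments."""
    if not recording.truth_segments:
        raise ValueError("recording has no truth segments")
    mask = np.zeros(recording.n_samples, dtype=bool)
    for seg in recording.truth_segments:
        mask[seg.start_sample : seg.end_sample] = True
    act = float(np.mean(recording.data[:, mask] ** 2))
    rest = float(np.mean(recording.data[:, ~mask] ** 2))
    if rest == 0.0:
        return np.inf
    return 10.0 * np.log10(act / rest)


# ---------------------------------------------------------------------------
# plain-text I/O

def write_recording(recording: EmgRecording, path, segments_path=None) -> None:
    """Write a recording as key=value header lines plus a CSV sample matrix.

    Channels are columns; decimal point, no thousands separators. Truth
    segments (if any) go to ``segments_path`` as a
    ``start_sample,end_sample,repetition_index`` table.
    """
    with open(path, "w") as fh:
        fh.write(f"# subject={recording.subject_id}\n")
        fh.write(f"# label={recording.word_label}\n")
        fh.write(f"# fs={recording.fs}\n")
        fh.write(f"# channels={','.join(recording.channel_names)}\n")
        np.savetxt(fh, recording.data.T, delimiter=",", fmt="%.9g")
    if segments_path is not None and recording.truth_segments is not None:
        write_segments(recording.truth_segments, segments_path)


def read_recording(path, segments_path=None) -> EmgRecording:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = np.loadtxt(fh, delimiter=",", ndmin=2).T
    segments = read_segments(segments_path) if segments_path else None
    return EmgRecording(
        subject_id=header.get("subject", "unknown"),
        word_label=int(header.get("label", 0)),
        data=data,
        fs=float(header.get("fs", 1000.0)),
        channel_names=header.get("channels", "").split(",") if header.get("channels") else [],
        truth_segments=segments,
    )


def write_segments(segments: list[ActivationSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("start_sample,end_sample,repetition_index\n")
        for seg in segments:
            fh.write(f"{seg.start_sample},{seg.end_sample},{seg.repetition_index}\n")


def read_segments(path) -> list[ActivationSegment]:
    segs = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            if line.strip():
                a, b, r = line.strip().split(",")
                segs.append(ActivationSegment(int(a), int(b), int(r)))
    return segs


_CONFIG_FIELDS = (
    "n_classes reps_per_class n_channels fs rest_duration word_duration "
    "lead_in snr_db seed amp_jitter time_jitter".split()
)


def write_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(config, k) for k in _CONFIG_FIELDS}, fh, sort_keys=False
        )


def read_config(path) -> SyntheticConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SyntheticConfig(**{k: raw[k] for k in _CONFIG_FIELDS if k in raw})
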