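"""Sound analysis: filtering, syllable segmentation, features, clustering.

The stage mirrors a standard birdsong workflow. Recordings are high-pass
filtered at 200 Hz to strip low-frequency equipment noise, syllable
onsets/offsets are defined from a smoothed RMS envelope, and each detected
syllable is summarised by nine temporal-spectral descriptors:

    duration, mean frequency (+SD), mode frequency (+SD),
    Wiener entropy (+SD), first peak (+SD)

All spectral descriptors are computed per STFT frame (Hann window, 512
samples at 44.1 kHz, 50% hop) and aggregated as mean and SD across the
frames of the syllable, which is what gives each feature its SD companion.
Wiener entropy is the log ratio of geometric to arithmetic mean of the
per-frame power spectrum: 0 for white noise, strongly negative for tones.
"First peak" is the lowest-frequency local spectral maximum above the noise
floor, a fundamental-frequency proxy. Syllables are then classified by
k-means on z-scored features, with clusters mapped to call types by majority
vote against a reference labelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from sklearn.cluster import KMeans

from .types import OTHER, ConfigError

__all__ = [
    "SegmentationParams",
    "SyllableFeatures",
    "FEATURE_NAMES",
    "highpass",
    "detect_syllables",
    "extract_features",
    "features_to_array",
    "classify_kmeans",
    "map_clusters_to_types",
    "low_frequency_power_ratio",
    "rank_focal_channel",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "duration",
    "mean_freq",
    "mean_freq_sd",
    "mode_freq",
    "mode_freq_sd",
    "wiener_entropy",
    "wiener_entropy_sd",
    "first_peak",
    "first_peak_sd",
)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of filtering, segmentation and the STFT."""

    highpass_hz: float = 200.0
    frame: int = 512  # STFT window length, samples
    hop: int = 256
    envelope_smooth_s: float = 0.005
    envelope_threshold_db: float = 12.0  # above estimated noise floor
    min_syllable_s: float = 0.005
    min_gap_s: float = 0.005

    def __post_init__(self) -> None:
        if self.min_syllable_s <= 0 or self.min_gap_s <= 0:
            raise ConfigError("min_syllable_s and min_gap_s must be positive")
        if self.frame < 16 or not 0 < self.hop <= self.frame:
            raise ConfigError("need frame >= 16 and 0 < hop <= frame")


@dataclass(frozen=True)
class SyllableFeatures:
    """The nine temporal-spectral descriptors of one syllable."""

    duration: float
    mean_freq: float
    mean_freq_sd: float
    mode_freq: float
    mode_freq_sd: float
    wiener_entropy: float
    wiener_entropy_sd: float
    first_peak: float
    first_peak_sd: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def features_to_array(features: Sequence[SyllableFeatures]) -> np.ndarray:
    """Stack a feature collection into an (n, 9) array."""
    return np.vstack([f.to_array() for f in features])


def highpass(waveform: np.ndarray, sample_rate: int, cutoff: float = 200.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass filter.

    Attenuation one octave below the cutoff exceeds 20 dB; the Butterworth
    passband is ripple-free.
    """
    nyq = sample_rate / 2
    if not 0 < cutoff < nyq:
        raise ConfigError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq})")
    w = np.asarray(waveform, dtype=float)
    if w.size == 0 or not w.any():
        return w.copy()
    sos = signal.butter(4, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, w)


def _smoothed_rms(w: np.ndarray, sample_rate: int, smooth_s: float) -> np.ndarray:
    win = max(int(round(smooth_s * sample_rate)), 1)
    kernel = np.ones(win) / win
    power = np.convolve(w * w, kernel, mode="same")
    return np.sqrt(np.maximum(power, 0.0))


def detect_syllables(
    waveform: np.ndarray,
    sample_rate: int,
    params: SegmentationParams = SegmentationParams(),
) -> list[tuple[float, float]]:
    """Define syllable onsets/offsets from the smoothed RMS envelope.

    The noise floor is estimated as the 20th percentile of the envelope and
    the detection threshold sits ``envelope_threshold_db`` above it.
    Crossings are merged when separated by less than ``min_gap_s`` and then
    discarded when shorter than ``min_syllable_s``. Noise-only (or all-zero)
    audio yields an empty list.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size <= params.frame:
        raise ConfigError("audio shorter than one analysis frame")
    env = _smoothed_rms(w, sample_rate, params.envelope_smooth_s)
    floor = np.percentile(env, 20)
    threshold = floor * 10 ** (params.envelope_threshold_db / 20)
    mask = env > threshold
    if not mask.any():
        return []
    # rising/falling edges of the boolean mask
    d = np.diff(mask.astype(np.int8))
    onsets = list(np.flatnonzero(d == 1) + 1)
    offsets = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        onsets.insert(0, 0)
    if mask[-1]:
        offsets.append(w.size)
    segments = list(zip(onsets, offsets))
    # merge gaps shorter than min_gap_s
    min_gap = params.min_gap_s * sample_rate
    merged: list[list[int]] = []
    for a, b in segments:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = params.min_syllable_s * sample_rate
    return [
        (a / sample_rate, b / sample_rate) for a, b in merged if b - a >= min_len
    ]


def _frame_spectra(
    w: np.ndarray, sample_rate: int, params: SegmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectra of the Hann-windowed frames fully inside ``w``.

    Returns ``(freqs, P)`` with ``P`` of shape (n_frames, n_bins), restricted
    to the band [highpass_hz, Nyquist].
    """
    n = w.size
    if n < params.frame + params.hop:
        raise ConfigError("interval shorter than two analysis frames")
    window = signal.get_window("hann", params.frame)
    starts = np.arange(0, n - params.frame + 1, params.hop)
    frames = np.stack([w[s : s + params.frame] * window for s in starts])
    spec = np.fft.rfft(frames, axis=1)
    P = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(params.frame, d=1.0 / sample_rate)
    band = freqs >= params.highpass_hz
    return freqs[band], P[:, band]


def _first_peak(freqs: np.ndarray, p: np.ndarray, rel_floor: float = 0.05) -> float:
    """Lowest-frequency local maximum exceeding ``rel_floor`` x frame max."""
    floor = rel_floor * p.max()
    peaks, _ = signal.find_peaks(p, height=floor)
    if peaks.size:
        return float(freqs[peaks[0]])
    return float(freqs[int(np.argmax(p))])


def extract_features(
    waveform: np.ndarray,
    sample_rate: int,
    interval: Optional[tuple[float, float]] = None,
    params: SegmentationParams = SegmentationParams(),
) -> SyllableFeatures:
    """Compute the nine temporal-spectral descriptors for one syllable.

    ``interval`` selects ``(onset, offset)`` in seconds within ``waveform``;
    omit it to treat the whole array as the syllable. At least two STFT
    frames must fit inside the interval.
    """
    w = np.asarray(waveform, dtype=float)
    if interval is not None:
        onset, offset = interval
        if not (0 <= onset < offset <= w.size / sample_rate + 1e-9):
            raise ConfigError(f"interval {interval} outside the audio")
        i0 = int(round(onset * sample_rate))
        i1 = int(round(offset * sample_rate))
        seg = w[i0:i1]
        duration = offset - onset
    else:
        seg = w
        duration = w.size / sample_rate
    freqs, P = _frame_spectra(seg, sample_rate, params)

    tot = P.sum(axis=1)
    tot = np.where(tot > 0, tot, 1.0)
    centroid = (P * freqs).sum(axis=1) / tot
    mode = freqs[np.argmax(P, axis=1)]
    eps = np.finfo(float).tiny
    log_gmean = np.mean(np.log(P + eps), axis=1)
    log_amean = np.log(np.mean(P + eps, axis=1))
    wiener = log_gmean - log_amean  # <= 0, 0 for a flat spectrum
    first = np.array([_first_peak(freqs, p) for p in P])

    def ms(x: np.ndarray) -> tuple[float, float]:
        return float(np.mean(x)), float(np.std(x))

    mf, mf_sd = ms(centroid)
    mo, mo_sd = ms(mode)
    we, we_sd = ms(wiener)
    fp, fp_sd = ms(first)
    return SyllableFeatures(
        duration=float(duration),
        mean_freq=mf,
        mean_freq_sd=mf_sd,
        mode_freq=mo,
        mode_freq_sd=mo_sd,
        wiener_entropy=we,
        wiener_entropy_sd=we_sd,
        first_peak=fp,
        first_peak_sd=fp_sd,
    )


def classify_kmeans(
    features: Sequence[SyllableFeatures] | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster syllables by k-means on z-scored features.

    Runs ``restarts`` initialisations and keeps the solution with the lowest
    within-cluster sum of squares; deterministic given ``seed``. Returns
    ``(labels, centroids)`` with centroids in original feature units.
    """
    X = features if isinstance(features, np.ndarray) else features_to_array(features)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ConfigError(f"k={k} must lie in [1, n={n}]")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant dimensions carry no information
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(Z)
    centroids = km.cluster_centers_ * sd + mu
    return labels, centroids


def map_clusters_to_types(
    labels: np.ndarray, reference: Sequence[str], min_majority: float = 0.5
) -> tuple[np.ndarray, dict[int, str]]:
    """Map clusters to call types by majority vote against reference labels.

    Clusters whose majority share falls below ``min_majority`` map to
    ``"other"`` (mirroring the demotion of unclassifiable calls); the map is
    many-to-one, so two clusters may share a type. Returns the per-syllable
    call types and the cluster->type map.
    """
    labels = np.asarray(labels)
    ref = np.asarray([str(r) for r in reference])
    if labels.shape[0] != ref.shape[0]:
        raise ConfigError("labels and reference must align")
    mapping: dict[int, str] = {}
    for c in np.unique(labels):
        members = ref[labels == c]
        if members.size == 0:
            logger.warning("cluster %s is empty; mapped to %r", c, OTHER)
            mapping[int(c)] = OTHER
            continue
        values, counts = np.unique(members, return_counts=True)
        top = int(np.argmax(counts))
        share = counts[top] / members.size
        mapping[int(c)] = str(values[top]) if share > min_majority else OTHER
    return np.array([mapping[int(c)] for c in labels]), mapping


def low_frequency_power_ratio(
    waveform: np.ndarray, sample_rate: int, split_hz: float = 1000.0
) -> float:
    """Fraction of total spectral power below ``split_hz``.

    On-bird microphones pick up markedly more low-frequency power from the
    focal bird's own body than from other birds, so among channels capturing
    the same vocalisation the focal one ranks highest on this ratio.
    """
    w = np.asarray(waveform, dtype=float)
    P = np.abs(np.fft.rfft(w)) ** 2
    freqs = np.fft.rfftfreq(w.size, d=1.0 / sample_rate)
    total = P.sum()
    if total == 0:
        return math.nan
    return float(P[freqs < split_hz].sum() / total)


def rank_focal_channel(
    channels: Sequence[np.ndarray], sample_rate: int, split_hz: float = 1000.0
) -> int:
    """Index of the channel most likely to belong to the vocalising bird."""
    ratios = [low_frequency_power_ratio(c, sample_rate, split_hz) for c in channels]
    return int(np.nanargmax(ratios))
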