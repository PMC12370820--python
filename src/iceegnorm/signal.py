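"""DSP chain: raw referential multichannel segment -> relative band power.

The processing order mirrors standard clinical-iEEG practice: select an
interictal segment, screen channels, band-pass filter 0.5–80 Hz, resample
to 200 Hz with an anti-alias filter, common average reference, Welch PSD
(2 s Hann window, 1 s overlap), band power in five bands (with γ power-line
exclusions), then log10 + L1 normalisation to one RBP vector per contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import STANDARD_BANDS, BandDefinition

logger = logging.getLogger(__name__)


class NoInterictalWindowError(RuntimeError):
    """No segment window satisfies the interictal-distance requirement."""


@dataclass
class TimeSeriesSegment:
    """A multichannel voltage segment (channels x samples, µV)."""

    data: np.ndarray
    fs: float
    channels: List[str] = field(default_factory=list)
    subject: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("segment data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite samples")
        if not self.channels:
            self.channels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: Optional[float] = None,
                  channels: Optional[List[str]] = None) -> "TimeSeriesSegment":
        return TimeSeriesSegment(
            data=data,
            fs=self.fs if fs is None else fs,
            channels=list(self.channels) if channels is None else list(channels),
            subject=self.subject,
        )


@dataclass
class PSDEstimate:
    """Welch power spectral density per channel (µV²/Hz) on a uniform grid."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    channels: List[str]
    window_s: float
    overlap_s: float

    @property
    def df(self) -> float:
        """Frequency-grid spacing in Hz (reciprocal of the window length)."""
        return float(self.freqs[1] - self.freqs[0])


def select_segment(
    ictal_annotations: Sequence[Tuple[float, float]],
    total_duration: float,
    segment_length: float = 70.0,
    min_gap: float = 7200.0,
    step: float = 1.0,
) -> Tuple[float, float]:
    """Earliest window of ``segment_length`` s at least ``min_gap`` s from
    every annotated ictal interval.

    The gap is measured from the window to the nearest edge of each
    annotation; candidate onsets are scanned on a ``step``-second grid.

    Raises
    ------
    NoInterictalWindowError
        If no valid window exists within ``total_duration``.
    """
    for s, e in ictal_annotations:
        if not (0.0 <= s <= e <= total_duration):
            raise ValueError(f"annotation ({s}, {e}) outside [0, {total_duration}]")
    if segment_length <= 0 or segment_length > total_duration:
        raise NoInterictalWindowError("segment longer than the recording")

    t = 0.0
    while t + segment_length <= total_duration + 1e-9:
        ok = all(
            t >= e + min_gap or t + segment_length <= s - min_gap
            for s, e in ictal_annotations
        )
        if ok:
            return (t, t + segment_length)
        t += step
    raise NoInterictalWindowError(
        "no interictal window: no %.0f s window is >= %.0f s from all ictal events"
        % (segment_length, min_gap)
    )


def screen_channels(
    segment: TimeSeriesSegment,
    flat_range_uv: float = 1.0,
    amplitude_z: float = 5.0,
    line_ratio: float = 3.0,
    line_freqs: Sequence[float] = (50.0, 60.0),
) -> Tuple[np.ndarray, Dict[str, List[str]]]:
    """Flag flat, amplitude-outlier and line-noise-dominated channels.

    A documented heuristic approximation of visual/algorithmic channel
    review: channels are dropped when their peak-to-peak range falls below
    ``flat_range_uv`` µV, when the robust z-score of their standard
    deviation exceeds ``amplitude_z``, or when power within ±1 Hz of a
    mains frequency exceeds ``line_ratio`` times the neighbouring
    (±2–5 Hz) spectral power.

    Returns
    -------
    keep : boolean mask over channels
    reasons : dict channel label -> list of flag reasons
    """
    if segment.n_channels < 2:
        raise ValueError("channel screening requires at least 2 channels")

    x = segment.data
    reasons: Dict[str, List[str]] = {c: [] for c in segment.channels}

    rng_ = np.ptp(x, axis=1)
    flat = rng_ < flat_range_uv
    for i in np.flatnonzero(flat):
        reasons[segment.channels[i]].append("flat")

    sd = x.std(axis=1)
    usable = ~flat
    if usable.sum() >= 2:
        med = np.median(sd[usable])
        mad = np.median(np.abs(sd[usable] - med))
        scale = 1.4826 * mad
        if scale > 0:
            z = (sd - med) / scale
            for i in np.flatnonzero(z > amplitude_z):
                reasons[segment.channels[i]].append("amplitude outlier")

    # line noise: compare mains-band power against flanking bands
    nper = min(segment.n_samples, int(round(2.0 * segment.fs)))
    f, pxx = sps.welch(x, fs=segment.fs, window="hann", nperseg=nper,
                       noverlap=nper // 2, scaling="density", axis=-1)
    for f0 in line_freqs:
        if f0 + 1.0 >= segment.fs / 2:
            continue
        inband = (f >= f0 - 1.0) & (f <= f0 + 1.0)
        flank = ((f >= f0 - 5.0) & (f < f0 - 2.0)) | ((f > f0 + 2.0) & (f <= f0 + 5.0))
        if not inband.any() or not flank.any():
            continue
        num = pxx[:, inband].mean(axis=1)
        den = pxx[:, flank].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / den, 0.0)
        for i in np.flatnonzero(ratio > line_ratio):
            tag = f"line noise {f0:g} Hz"
            if tag not in reasons[segment.channels[i]]:
                reasons[segment.channels[i]].append(tag)

    keep = np.array([len(reasons[c]) == 0 for c in segment.channels])
    if not keep.any():
        raise ValueError("all channels flagged; nothing to analyse")
    flagged = {c: r for c, r in reasons.items() if r}
    if flagged:
        logger.info("screen_channels flagged %d/%d channels: %s",
                    len(flagged), segment.n_channels, flagged)
    return keep, flagged


def bandpass_filter(segment: TimeSeriesSegment, low: float = 0.5,
                    high: float = 80.0, order: int = 6) -> TimeSeriesSegment:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    if segment.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {segment.fs} Hz too low for a {high} Hz upper corner"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=segment.fs, output="sos")
    out = sps.sosfiltfilt(sos, segment.data, axis=-1)
    return segment.copy_with(out)


def downsample(segment: TimeSeriesSegment, target_fs: float = 200.0) -> TimeSeriesSegment:
    """Polyphase FIR resampling to ``target_fs`` (anti-alias included)."""
    if segment.fs < target_fs:
        raise ValueError("downsample cannot increase the sampling rate")
    if abs(segment.fs - target_fs) < 1e-9:
        return segment
    frac = Fraction(target_fs).limit_denominator(10000) / Fraction(
        segment.fs).limit_denominator(10000)
    out = sps.resample_poly(segment.data, frac.numerator, frac.denominator, axis=-1)
    return segment.copy_with(out, fs=target_fs)


def common_average_reference(segment: TimeSeriesSegment) -> TimeSeriesSegment:
    """Subtract the across-channel mean at every time point."""
    if segment.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    out = segment.data - segment.data.mean(axis=0, keepdims=True)
    return segment.copy_with(out)


def welch_psd(segment: TimeSeriesSegment, window_s: float = 2.0,
              overlap_s: float = 1.0) -> PSDEstimate:
    """Welch PSD with a Hann window, density scaling.

    A 2 s window forces a 0.5 Hz frequency grid.
    """
    nperseg = int(round(window_s * segment.fs))
    noverlap = int(round(overlap_s * segment.fs))
    if segment.n_samples < nperseg:
        raise ValueError("segment shorter than the Welch window")
    freqs, pxx = sps.welch(
        segment.data, fs=segment.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, scaling="density", axis=-1,
    )
    return PSDEstimate(freqs=freqs, psd=np.atleast_2d(pxx),
                       channels=list(segment.channels),
                       window_s=window_s, overlap_s=overlap_s)


def _band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    # half-open [low, high) on bin centres; exclusions use the same rule
    mask = (freqs >= band.low - 1e-9) & (freqs < band.high - 1e-9)
    for lo, hi in band.exclusions:
        mask &= ~((freqs >= lo - 1e-9) & (freqs < hi - 1e-9))
    return mask


def band_power(psd: PSDEstimate, band: BandDefinition) -> np.ndarray:
    """Integrated power over the band (rectangle rule, µV²), per channel.

    Frequency bins belong to a band when their centre lies in the
    half-open interval [low, high); excluded sub-intervals are removed
    with the same rule, so shared edges are never double counted.
    """
    df = psd.df
    if band.low < psd.freqs[0] - df / 2 or band.high > psd.freqs[-1] + df / 2:
        raise ValueError(
            f"band {band.name!r} [{band.low}, {band.high}] Hz outside the "
            f"PSD grid [{psd.freqs[0]}, {psd.freqs[-1]}] Hz"
        )
    mask = _band_mask(psd.freqs, band)
    return psd.psd[:, mask].sum(axis=1) * df


def relative_band_power(
    psd: PSDEstimate,
    bands: Sequence[BandDefinition] = STANDARD_BANDS,
) -> pd.DataFrame:
    """log10 band powers L1-normalised to sum to one per contact (RBP).

    Requires all band powers strictly positive and all log10 band powers
    of a channel to share one sign; with uniformly positive logs (band
    powers above 1 µV², the typical regime for µV-scale signals) a larger
    band power yields a larger RBP component.

    Returns a DataFrame (channels x bands), each row summing to 1.
    """
    powers = np.column_stack([band_power(psd, b) for b in bands])
    if np.any(powers <= 0):
        raise ValueError(
            "zero or negative band power encountered; raise the spectral "
            "floor (epsilon-floor config) or inspect the channel"
        )
    logs = np.log10(powers)
    signs_ok = np.all(logs > 0, axis=1) | np.all(logs < 0, axis=1)
    if not np.all(signs_ok):
        bad = [psd.channels[i] for i in np.flatnonzero(~signs_ok)]
        raise ValueError(
            f"log10 band powers change sign on channels {bad}; rescale the "
            "input units (e.g. record in µV) so all logs share one sign"
        )
    rbp = logs / logs.sum(axis=1, keepdims=True)
    return pd.DataFrame(rbp, index=pd.Index(psd.channels, name="channel"),
                        columns=[b.name for b in bands])


def extract_rbp(
    segment: TimeSeriesSegment,
    bands: Sequence[BandDefinition] = STANDARD_BANDS,
    low: float = 0.5,
    high: float = 80.0,
    target_fs: float = 200.0,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
    screen: bool = True,
    **screen_kwargs,
) -> pd.DataFrame:
    """Full chain: screen -> band-pass -> resample -> CAR -> Welch -> RBP.

    Returns one RBP row per retained contact.
    """
    if screen:
        keep, _ = screen_channels(segment, **screen_kwargs)
        segment = segment.copy_with(segment.data[keep],
                                    channels=[c for c, k in zip(segment.channels, keep) if k])
    seg = bandpass_filter(segment, low=low, high=high)
    seg = downsample(seg, target_fs=target_fs)
    seg = common_average_reference(seg)
    psd = welch_psd(seg, window_s=window_s, overlap_s=overlap_s)
    return relative_band_power(psd, bands=bands)
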