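"""Synthetic multi-hospital icEEG data with known ground truth.

Three generators cover the pipeline's inputs end to end:

- :func:`simulate_cohort` draws a multi-hospital normative RBP table from
  the exact random-intercept model the statistics layer fits (per-band
  intercept, linear age slope, optional sex offset, Gaussian hospital
  intercepts and residuals), independently per band, returning the drawn
  hospital effects as ground truth.
- :func:`simulate_recording` synthesises multichannel voltage segments
  with planted spectral content — a 1/f background (spectrally shaped
  white noise) plus fixed-amplitude random-phase oscillations scaled so
  analytic band-power ratios match requested targets — for validating the
  DSP chain against a closed-form oracle.
- :func:`simulate_parcellation` builds a compact synthetic volumetric
  parcellation with hemisphere-paired regions (a stand-in for an 82-region
  whole-brain atlas, using standard cortical/subcortical region names so
  the bilateral subcortical exclusions apply verbatim).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, get_band
from .cohort import NormativeTable, TABLE_COLUMNS
from .localisation import Parcellation, Region
from .signal import TimeSeriesSegment, _band_mask

# Desikan-Killiany cortical parcels (34) + subcortical structures (7):
# 41 base names -> 82 regions with hemisphere prefixes, matching the size
# of a Lausanne scale-36-style whole-brain atlas.
CORTICAL_BASE_NAMES = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "insula", "frontalpole",
)
SUBCORTICAL_BASE_NAMES = ("thalamus", "caudate", "putamen", "pallidum",
                          "hippocampus", "amygdala", "accumbens")
STANDARD_BASE_NAMES = CORTICAL_BASE_NAMES + SUBCORTICAL_BASE_NAMES  # 41

# Whole-brain RBP means (dimensionless, sum to 1) and per-year age slopes
# on the 1e-4/year scale of a large multi-centre icEEG cohort.
DEFAULT_BAND_INTERCEPTS = {"delta": 0.35, "theta": 0.22, "alpha": 0.18,
                           "beta": 0.15, "gamma": 0.10}
DEFAULT_BAND_AGE_SLOPES = {"delta": -6.1e-4, "theta": -0.8e-4,
                           "alpha": 4.1e-4, "beta": 2.9e-4, "gamma": -0.2e-4}
DEFAULT_BAND_SEX_OFFSETS = {b: 0.0 for b in BAND_NAMES}


@dataclass
class SimulationParams:
    """Generative parameters for a multi-hospital RBP cohort.

    The generative model per band is the random-intercept model
    ``RBP = beta0 + b_age * age + b_sex * male + u_hospital + eps`` with
    ``u ~ N(0, hospital_sd^2)`` and ``eps ~ N(0, residual_sd^2)``, drawn
    independently across bands (bands are modelled separately downstream,
    so simulated per-band values are not constrained to sum to 1).

    Defaults emulate the study conditions: 15 hospitals, ~34 subjects
    each (~500 subjects), ages 5–65, slopes on the 1e-4/year scale, and
    variance components giving an intraclass correlation near 0.14.
    """

    band_intercepts: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_INTERCEPTS))
    band_age_slopes: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AGE_SLOPES))
    band_sex_offsets: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_SEX_OFFSETS))
    hospital_sd: float = 0.02
    residual_sd: float = 0.05
    n_hospitals: int = 15
    subjects_per_hospital: int = 34
    age_range: Tuple[float, float] = (5.0, 65.0)
    sex_proportion: float = 0.5  # fraction male
    roi_probs: Dict[str, float] = field(
        default_factory=lambda: {"whole_brain": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hospital_sd < 0:
            raise ValueError("hospital_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.n_hospitals < 1:
            raise ValueError("need at least one hospital")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy a_min < a_max")
        if not 0.0 <= self.sex_proportion <= 1.0:
            raise ValueError("sex_proportion must lie in [0, 1]")
        if not self.roi_probs:
            raise ValueError("roi_probs must list at least one ROI")
        if any(not 0.0 <= p <= 1.0 for p in self.roi_probs.values()):
            raise ValueError("implantation probabilities must lie in [0, 1]")
        for d in (self.band_intercepts, self.band_age_slopes,
                  self.band_sex_offsets):
            missing = set(BAND_NAMES) - set(d)
            if missing:
                raise ValueError(f"band parameters missing {sorted(missing)}")


def simulate_cohort(params: SimulationParams
                    ) -> Tuple[NormativeTable, Dict]:
    """Draw a normative table from the random-intercept generative model.

    Returns the table (one row per subject x implanted ROI) and a ground
    truth record containing the parameters and every drawn hospital
    intercept (hospital x band).  Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    hospitals = [f"hosp{h:02d}" for h in range(1, params.n_hospitals + 1)]
    rois = list(params.roi_probs)
    u = rng.normal(0.0, params.hospital_sd,
                   size=(params.n_hospitals, len(BAND_NAMES)))
    hospital_effects = pd.DataFrame(u, index=hospitals, columns=BAND_NAMES)

    rows = []
    sid = 0
    for h, hosp in enumerate(hospitals):
        for _ in range(params.subjects_per_hospital):
            sid += 1
            subject = f"s{sid:04d}"
            age = rng.uniform(*params.age_range)
            male = rng.random() < params.sex_proportion
            implanted = [r for r in rois
                         if rng.random() < params.roi_probs[r]]
            for roi in implanted:
                vals = {}
                for b, band in enumerate(BAND_NAMES):
                    eps = rng.normal(0.0, params.residual_sd)
                    vals[band] = (params.band_intercepts[band]
                                  + params.band_age_slopes[band] * age
                                  + params.band_sex_offsets[band] * male
                                  + u[h, b] + eps)
                rows.append({"subject": subject, "hospital": hosp,
                             "age": age,
                             "sex": "male" if male else "female",
                             "roi": roi, **vals})
    df = (pd.DataFrame(rows, columns=TABLE_COLUMNS) if rows
          else pd.DataFrame(columns=TABLE_COLUMNS))
    table = NormativeTable(df=df, regions=rois, mirrored=True,
                           atlas="simulated")
    truth = {"params": params, "hospital_effects": hospital_effects}
    return table, truth


# ---------------------------------------------------------------------------
# planted-spectrum recordings


DEFAULT_OSCILLATIONS = {"delta": 2.5, "theta": 6.0, "alpha": 10.5,
                        "beta": 21.0, "gamma": 40.0}


@dataclass
class PlantedSpectrum:
    """Planted spectral content: 1/f background plus band oscillations.

    ``band_targets`` maps band name to target relative power; the
    generator scales one sinusoid per band (at ``oscillation_freqs``)
    on top of the shaped-noise background so that the analytic band-power
    shares match the targets.  ``total_power`` (µV²) sets the overall
    variance within the analysed bands; ``background_fraction`` of it is
    carried by the 1/f background.
    """

    band_targets: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_INTERCEPTS))
    background_exponent: float = 1.0
    oscillation_freqs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OSCILLATIONS))
    line_noise_amplitude: float = 0.0
    line_freq: float = 50.0
    total_power: float = 2500.0
    background_fraction: float = 0.3
    freq_jitter_hz: float = 0.4

    def __post_init__(self) -> None:
        if self.total_power < 0:
            raise ValueError("total_power must be >= 0")
        if self.total_power > 0 and not self.band_targets:
            raise ValueError("band_targets required when total_power > 0")
        if any(v <= 0 for v in self.band_targets.values()):
            raise ValueError("target relative powers must be positive")
        for band, f0 in self.oscillation_freqs.items():
            if not 0.5 <= f0 <= 80.0:
                raise ValueError(
                    f"oscillation for {band!r} at {f0} Hz outside 0.5-80 Hz")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")


def _planted_components(spectrum: PlantedSpectrum, fs: float, duration: float):
    """Deterministic background gains and oscillation amplitudes.

    Returns (freq grid, background amplitude gains per rFFT bin,
    oscillation amplitude per band) such that the analytic band powers
    hit ``band_targets`` x ``total_power`` exactly.
    """
    n = int(round(fs * duration))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    chi = spectrum.background_exponent
    with np.errstate(divide="ignore"):
        gains = np.where(freqs >= 0.5, freqs ** (-chi / 2.0), 0.0)
    gains[0] = 0.0

    # expected per-bin variance contribution of irfft(gains * rfft(white)):
    # (1/n) * w_k * gains_k^2 with w_k = 2 except at DC/Nyquist
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    bin_var = w * gains ** 2 / n

    bands = {name: get_band(name) for name in spectrum.band_targets}
    raw_bg = {name: float(bin_var[_band_mask(freqs, b)].sum())
              for name, b in bands.items()}
    total_raw = sum(raw_bg.values())

    rel = np.array([spectrum.band_targets[b] for b in bands])
    rel = rel / rel.sum()
    targets = {name: r * spectrum.total_power for name, r in zip(bands, rel)}

    if spectrum.background_fraction > 0 and total_raw > 0:
        scale = np.sqrt(spectrum.background_fraction * spectrum.total_power
                        / total_raw)
    else:
        scale = 0.0
    bg_power = {name: scale ** 2 * raw_bg[name] for name in bands}

    osc_amp = {}
    for name in bands:
        p_osc = targets[name] - bg_power[name]
        if p_osc < 0:
            raise ValueError(
                f"background power exceeds the target in band {name!r}; "
                "lower background_fraction or flatten the exponent")
        osc_amp[name] = np.sqrt(2.0 * p_osc)
        f0 = spectrum.oscillation_freqs.get(name)
        if f0 is None:
            raise ValueError(f"no oscillation frequency for band {name!r}")
        if f0 >= fs / 2.0:
            raise ValueError(f"oscillation {f0} Hz at or above Nyquist "
                             f"({fs / 2:g} Hz)")
        j = spectrum.freq_jitter_hz
        band = bands[name]
        if not (band.low <= f0 - j and f0 + j < band.high):
            raise ValueError(f"oscillation {f0}±{j} Hz leaves band {name!r}")
        for lo, hi in band.exclusions:
            if f0 + j > lo and f0 - j < hi:
                raise ValueError(f"oscillation {f0}±{j} Hz overlaps the "
                                 f"excluded interval ({lo}, {hi}) Hz")
    return freqs, scale * gains, osc_amp, bg_power


def analytic_band_powers(spectrum: PlantedSpectrum, fs: float = 512.0,
                         duration: float = 70.0) -> Dict[str, float]:
    """Closed-form planted band powers (µV²) — the DSP oracle."""
    if spectrum.total_power == 0:
        return {name: 0.0 for name in spectrum.band_targets}
    _, _, osc_amp, bg_power = _planted_components(spectrum, fs, duration)
    return {name: bg_power[name] + osc_amp[name] ** 2 / 2.0
            for name in spectrum.band_targets}


def simulate_recording(spectrum: PlantedSpectrum, n_channels: int = 50,
                       fs: float = 512.0, duration: float = 70.0,
                       seed: int = 0,
                       subject: str = "sim") -> TimeSeriesSegment:
    """Synthesise a referential multichannel segment with planted spectra.

    Each channel carries independently drawn 1/f-shaped noise plus one
    sinusoid per band with a channel-specific random phase and a small
    channel-specific frequency jitter (``freq_jitter_hz``) around the
    band's centre frequency.  Amplitudes are identical across channels,
    so every channel shares the planted band-power profile; the jitter
    keeps channels mutually incoherent, as oscillation peak frequencies
    vary across real contacts (a phase-coherent cohort would let the
    common average reference inject large cross-channel interference).
    """
    if fs < 200:
        raise ValueError("sampling rate must be >= 200 Hz")
    n = int(round(fs * duration))
    rng = np.random.default_rng(seed)
    if spectrum.total_power == 0:
        data = np.zeros((n_channels, n))
        return TimeSeriesSegment(data=data, fs=fs, subject=subject)

    freqs, gains, osc_amp, _ = _planted_components(spectrum, fs, duration)
    t = np.arange(n) / fs
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        white = rng.standard_normal(n)
        bg = np.fft.irfft(gains * np.fft.rfft(white), n=n)
        x = bg
        for name, amp in osc_amp.items():
            phase = rng.uniform(0, 2 * np.pi)
            f0 = spectrum.oscillation_freqs[name] + rng.uniform(
                -spectrum.freq_jitter_hz, spectrum.freq_jitter_hz)
            x = x + amp * np.sin(2 * np.pi * f0 * t + phase)
        if spectrum.line_noise_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x = x + spectrum.line_noise_amplitude * np.sin(
                2 * np.pi * spectrum.line_freq * t + phase)
        data[ch] = x
    return TimeSeriesSegment(data=data, fs=fs, subject=subject)


# ---------------------------------------------------------------------------
# synthetic parcellation


def simulate_parcellation(n_region_pairs: int = 41, voxel_spacing: float = 2.0,
                          seed: int = 0, blob_radius: float = 6.0
                          ) -> Parcellation:
    """A synthetic volumetric parcellation with homologous left/right pairs.

    Pair centres sit on a jittered lattice in the right hemisphere
    (x > 0) and are mirrored through the midline; each region is a
    compact ball of grey-matter voxel centres on a ``voxel_spacing`` mm
    grid.  With 41 pairs the standard cortical + subcortical base names
    are used, so the region universe matches an 82-region whole-brain
    atlas (synthetic stand-in — coordinates carry no anatomical meaning).
    """
    if n_region_pairs < 1:
        raise ValueError("need at least one region pair")
    rng = np.random.default_rng(seed)

    if n_region_pairs <= len(STANDARD_BASE_NAMES):
        # keep the subcortical names present whenever possible
        n_sub = min(len(SUBCORTICAL_BASE_NAMES), n_region_pairs)
        n_cort = n_region_pairs - n_sub
        bases = list(CORTICAL_BASE_NAMES[:n_cort]) + \
            list(SUBCORTICAL_BASE_NAMES[:n_sub])
    else:
        bases = list(STANDARD_BASE_NAMES) + [
            f"region{i:03d}" for i in range(n_region_pairs
                                            - len(STANDARD_BASE_NAMES))]

    # ball of voxel-centre offsets
    g = np.arange(-blob_radius, blob_radius + 1e-9, voxel_spacing)
    ox, oy, oz = np.meshgrid(g, g, g, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    offsets = offsets[np.linalg.norm(offsets, axis=1) <= blob_radius]

    # jittered lattice of pair centres, x > 0 (right hemisphere)
    pitch = 4 * blob_radius
    nx, ny = 3, 7
    centres = []
    for i in range(n_region_pairs):
        cx = 20.0 + pitch * (i % nx)
        cy = -60.0 + pitch * ((i // nx) % ny)
        cz = -20.0 + pitch * (i // (nx * ny))
        jitter = rng.uniform(-3.0, 3.0, size=3)
        centres.append(np.array([cx, cy, cz]) + jitter)

    regions = []
    for i, (base, centre) in enumerate(zip(bases, centres)):
        sub = base in SUBCORTICAL_BASE_NAMES
        right = centre + offsets
        left = right * np.array([-1.0, 1.0, 1.0])
        regions.append(Region(region_id=2 * i, name=f"Left-{base}",
                              voxels=left, subcortical=sub))
        regions.append(Region(region_id=2 * i + 1, name=f"Right-{base}",
                              voxels=right, subcortical=sub))
    return Parcellation(regions=regions, atlas=f"synthetic-{n_region_pairs}pair")


def standard_region_names() -> Tuple[str, ...]:
    """The 82 hemisphere-prefixed region names of the synthetic atlas."""
    out = []
    for base in STANDARD_BASE_NAMES:
        out.extend([f"Left-{base}", f"Right-{base}"])
    return tuple(out)
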