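"""Auxiliary physiological computations.

* Doppler volumetric flow per vessel (parabolic profile) and total cerebral
  blood flow summed over the internal carotid and vertebral arteries.
* Splanchnic segment volume from bioelectrical impedance.
* Microneurography: band-pass filtering, rectification and leaky integration
  of the raw neurogram, and sympathetic spike detection with an amplitude
  rule (deflection > 4.5 x baseline s.d.) plus a triphasic-morphology gate.
* ADFSCI hypotension-section scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "VesselMeasure",
    "Neurogram",
    "ADFSCIHypotension",
    "TemplateParams",
    "vessel_flow",
    "total_cbf",
    "segment_volume",
    "process_neurogram",
    "detect_spikes",
    "adfsci_hypotension_score",
    "triphasic_template",
    "synth_neurogram",
]

CBF_VESSELS = ("ICA_L", "ICA_R", "VA_L", "VA_R")
VALID_VESSELS = CBF_VESSELS + ("MCA_L", "MCA_R")


@dataclass(frozen=True)
class VesselMeasure:
    """One Doppler assessment: velocity (m/s) and B-mode mean diameter (m)."""

    vessel: str
    velocity: float
    diameter: float

    def __post_init__(self) -> None:
        if self.vessel not in VALID_VESSELS:
            raise ValueError(f"unknown vessel {self.vessel!r}; expected one of {VALID_VESSELS}")
        if self.velocity < 0 or self.diameter < 0:
            raise ValueError("velocity and diameter must be >= 0")


def vessel_flow(m: VesselMeasure) -> float:
    """Volumetric flow Q in mL/min assuming a parabolic velocity profile.

    Q = (FV/2) * pi * D^2 / 4 in m^3/s, converted to mL/min (x 6e7).  FV is
    the supplied Doppler velocity; the /2 converts the centerline (peak)
    velocity to the cross-sectional mean.  Callers holding an
    envelope-integrated mean velocity can pass ``2 * v_mean`` instead.
    """
    q_m3_s = (m.velocity / 2.0) * math.pi * m.diameter**2 / 4.0
    return q_m3_s * 6.0e7


def total_cbf(measures: Sequence[VesselMeasure]) -> float:
    """Total cerebral blood flow (mL/min): sum over left/right ICA and VA.

    Middle cerebral artery measures may be present but are excluded.
    """
    by_vessel = {m.vessel: m for m in measures}
    missing = [v for v in CBF_VESSELS if v not in by_vessel]
    if missing:
        raise ValueError(f"missing vessel measurement(s): {', '.join(missing)}")
    return float(sum(vessel_flow(by_vessel[v]) for v in CBF_VESSELS))


def segment_volume(length: float, resistance: float, r_eff: float = 1.0) -> float:
    """Body-segment volume estimate from bioelectrical impedance.

    V_geom = (L^2 * r_eff / R) * 1e6 with L the segment length in meters,
    r_eff the effective resistivity (ohm*m) and R the measured impedance
    (ohm).  Volume is inversely proportional to resistance.
    """
    if length <= 0:
        raise ValueError("segment length must be > 0 m")
    if resistance <= 0:
        raise ValueError("resistance must be > 0 ohm")
    return (length**2 * r_eff / resistance) * 1.0e6


# ---------------------------------------------------------------------------
# Microneurography


@dataclass
class Neurogram:
    """Raw microneurography record: samples (V) at ``fs`` Hz and a baseline
    window (stimulator off) used to estimate the noise floor."""

    samples: np.ndarray
    fs: float = 20_000.0
    baseline_window: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 2 * 2000.0:
            raise ValueError("sampling rate must exceed twice the 2 kHz band edge")
        b0, b1 = self.baseline_window
        if not 0 <= b0 < b1 <= len(self.samples) / self.fs:
            raise ValueError("baseline window must lie within the record")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def baseline_slice(self) -> slice:
        b0, b1 = self.baseline_window
        return slice(int(round(b0 * self.fs)), int(round(b1 * self.fs)))


def _bandpass_sos(fs: float, low: float = 300.0, high: float = 2000.0, order: int = 4):
    return _signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_neurogram(n: Neurogram, low: float = 300.0, high: float = 2000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (default 0.3-2.0 kHz)."""
    sos = _bandpass_sos(n.fs, low, high)
    return _signal.sosfiltfilt(sos, n.samples)


def process_neurogram(n: Neurogram, tau: float = 0.1) -> np.ndarray:
    """Multiunit mean-voltage neurogram: band-pass, full-wave rectify, and
    leaky-integrate with time constant ``tau`` (default 0.1 s).

    The integrator is a single-pole low-pass discretized at ``fs``; its
    output is non-negative and bounded by the running peak of the rectified
    signal.
    """
    if n.duration < 1.0:
        raise ValueError("record must be at least 1 s long")
    rect = np.abs(bandpass_neurogram(n))
    alpha = 1.0 - math.exp(-1.0 / (tau * n.fs))
    # y[k] = y[k-1] + alpha * (x[k] - y[k-1])
    y = _signal.lfilter([alpha], [1.0, alpha - 1.0], rect)
    return y


@dataclass(frozen=True)
class TemplateParams:
    """Triphasic spike template and detection thresholds.

    The template has three half-sine lobes (positive-negative-positive) with
    amplitude ratio 0.5 : -1 : 0.5 over ``duration`` seconds.  Candidates
    must exceed ``prescreen_sd`` baseline s.d. to be examined; the
    amplitude rule (``threshold_sd`` = 4.5 x baseline s.d.) is enforced on
    the matched-filter (template-projection) estimate of the negative
    deflection, which is robust to sample-level noise; the morphology gate
    requires a normalized correlation of ``correlation_min`` with the
    (band-pass filtered) template.
    """

    duration: float = 0.005       # s; lobes of ~1.7 ms keep the energy in band
    lobe_ratio: tuple[float, float, float] = (0.5, -1.0, 0.5)
    threshold_sd: float = 4.5
    prescreen_sd: float = 3.0
    correlation_min: float = 0.8
    refractory: float = 0.020     # s


def triphasic_template(fs: float, params: TemplateParams = TemplateParams()) -> np.ndarray:
    """Ideal triphasic waveform (unit negative peak) sampled at ``fs``."""
    n = max(9, int(round(params.duration * fs)))
    n -= n % 3  # three equal lobes
    lobe = n // 3
    t = np.sin(np.pi * np.arange(lobe) / lobe)
    wave = np.concatenate([r * t for r in params.lobe_ratio])
    return wave / np.abs(wave.min())


def _filtered_template(fs: float, params: TemplateParams) -> np.ndarray:
    """Template as seen after the acquisition band-pass (unit negative peak)."""
    raw = triphasic_template(fs, params)
    pad = len(raw) * 6
    padded = np.concatenate([np.zeros(pad), raw, np.zeros(pad)])
    sos = _bandpass_sos(fs)
    filt = _signal.sosfiltfilt(sos, padded)
    # trim to the energetic core; long tails only dilute the correlation
    center = int(np.argmin(filt))
    half = (2 * len(raw)) // 3
    seg = filt[max(0, center - half): center + half]
    return seg / np.abs(seg.min())


def detect_spikes(
    n: Neurogram,
    params: TemplateParams = TemplateParams(),
) -> np.ndarray:
    """Sympathetic action-potential spike times (s).

    Pipeline: band-pass the record; estimate the baseline s.d. from the
    stimulator-off window; find negative deflections past the prescreen
    threshold (refractory-spaced); for each candidate, fit the filtered
    triphasic template by least squares and keep the event when the fitted
    deflection exceeds ``threshold_sd`` x baseline s.d. and the normalized
    correlation with the template exceeds ``correlation_min``.
    """
    y = bandpass_neurogram(n)
    base = y[n.baseline_slice()]
    sd = float(np.std(base))
    if sd == 0:
        raise ValueError("degenerate baseline: zero standard deviation")

    tmpl = _filtered_template(n.fs, params)
    t_min = int(np.argmin(tmpl))
    tmpl_energy = float(np.dot(tmpl, tmpl))
    tmpl_c = tmpl - tmpl.mean()
    tmpl_c_norm = float(np.linalg.norm(tmpl_c))

    distance = max(1, int(round(params.refractory * n.fs)))
    idx, _ = _signal.find_peaks(-y, height=params.prescreen_sd * sd, distance=distance)

    hits: list[int] = []
    L = len(tmpl)
    jitter = max(1, int(round(0.0005 * n.fs)))  # +/-0.5 ms alignment search
    for i in idx:
        # noise shifts the apparent minimum; pick the alignment with the
        # largest template projection in a small neighborhood
        best_amp, best_lo = -np.inf, None
        for shift in range(-jitter, jitter + 1):
            lo = i + shift - t_min
            if lo < 0 or lo + L > len(y):
                continue
            a = float(np.dot(y[lo: lo + L], tmpl)) / tmpl_energy
            if a > best_amp:
                best_amp, best_lo = a, lo
        if best_lo is None:
            continue
        # matched-filter amplitude: template has unit negative peak, so the
        # fitted coefficient is the estimated deflection depth
        if best_amp < params.threshold_sd * sd:
            continue
        w = y[best_lo: best_lo + L]
        wc = w - w.mean()
        denom = float(np.linalg.norm(wc)) * tmpl_c_norm
        corr = float(np.dot(wc, tmpl_c)) / denom if denom > 0 else 0.0
        if corr < params.correlation_min:
            continue
        hits.append(i)
    return np.asarray(hits, dtype=float) / n.fs


def synth_neurogram(
    seed: int,
    fs: float = 20_000.0,
    duration: float = 12.0,
    baseline: float = 3.0,
    n_spikes: int = 20,
    snr_sd: float = 6.0,
    noise_sd: float = 1.0,
    params: TemplateParams = TemplateParams(),
    min_gap: float = 0.1,
) -> tuple[Neurogram, np.ndarray]:
    """Synthetic microneurography record with known spike times.

    Gaussian background noise plus triphasic events injected after the
    spike-free baseline window, scaled so the band-pass filtered deflection
    of each event equals ``snr_sd`` times the filtered-baseline s.d.
    Returns the neurogram and the true event times (s, at the template's
    negative peak).
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * fs))
    x = rng.normal(0.0, noise_sd, n_samp)

    # filtered-noise s.d. over the baseline window fixes the injection scale
    sos = _bandpass_sos(fs)
    sd_b = float(np.std(_signal.sosfiltfilt(sos, x)[: int(baseline * fs)]))

    raw = triphasic_template(fs, params)
    filt = _filtered_template(fs, params)
    # filtering preserves linear scaling: raw has unit peak, measure its
    # filtered depth to convert the target depth back to a raw scale
    pad = len(raw) * 6
    resp = _signal.sosfiltfilt(sos, np.concatenate([np.zeros(pad), raw, np.zeros(pad)]))
    depth_per_unit = float(np.abs(resp.min()))
    scale = snr_sd * sd_b / depth_per_unit

    t_lo = baseline + 0.05
    t_hi = duration - params.duration - 0.05
    gap = max(min_gap, params.refractory * 2)
    n_slots = int((t_hi - t_lo) / gap)
    if n_spikes > n_slots:
        raise ValueError("too many spikes for the record length")
    slots = rng.choice(n_slots, size=n_spikes, replace=False)
    starts = np.sort(t_lo + slots * gap + rng.uniform(0, gap - params.duration, n_spikes))

    raw_min = int(np.argmin(raw))
    true_times = []
    for s in starts:
        i0 = int(round(s * fs))
        x[i0: i0 + len(raw)] += scale * raw
        true_times.append((i0 + raw_min) / fs)
    ng = Neurogram(x, fs=fs, baseline_window=(0.0, baseline))
    return ng, np.asarray(true_times)


# ---------------------------------------------------------------------------
# ADFSCI


@dataclass(frozen=True)
class ADFSCIHypotension:
    """The seven-item hypotension section of the autonomic-dysfunction
    questionnaire; each item is scored on a five-point scale (default 0-4)."""

    items: tuple[int, ...]
    scale_min: int = 0
    scale_max: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(int(i) for i in self.items))
        if len(self.items) != 7:
            raise ValueError(f"hypotension section has exactly 7 items, got {len(self.items)}")
        for v in self.items:
            if not self.scale_min <= v <= self.scale_max:
                raise ValueError(
                    f"item score {v} outside scale [{self.scale_min}, {self.scale_max}]"
                )


def adfsci_hypotension_score(a: ADFSCIHypotension, symptomatic_cutoff: int = 2) -> tuple[int, int]:
    """Hypotension score (sum of the seven items) and the number of
    symptomatic items (score >= 2)."""
    score = int(sum(a.items))
    symptomatic = int(sum(1 for v in a.items if v >= symptomatic_cutoff))
    return score, symptomatic
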