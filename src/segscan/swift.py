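"""SWIFT (stored waveform inverse Fourier transform) isolation waveforms.

A SWIFT waveform is a broadband excitation constructed in the frequency
domain: every secular-frequency bin in the excitation band carries unit
magnitude except for a notch spanning the secular frequencies of the m/z
window to be retained, where the magnitude is zero.  Loading the inverse
transform of this design onto the trap resonantly ejects every ion whose
secular frequency falls in the excitation band while ions inside the notch
("zero intensity component") survive, isolating the chosen m/z segment.

Because secular frequency decreases with m/z, the notch's lower frequency
edge corresponds to the *upper* m/z bound of the window and vice versa.
A quadratic phase ramp is spread across the excitation bins to keep the
crest factor (peak/RMS) low, the standard SWIFT phase-scrambling practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trap import TrapConfig, beta_from_q, mathieu_q, \
    rf_voltage_for_center, secular_frequency

__all__ = [
    "SegmentWindow",
    "SwiftWaveform",
    "SwiftReport",
    "SegmentTooWideError",
    "cutoff_frequencies",
    "synthesize",
    "spectrum_report",
    "ions_retained",
]


class SegmentTooWideError(ValueError):
    """The window's low-m/z edge is unstable at the centre-ion RF voltage."""


class DegenerateWaveformError(ValueError):
    """Waveform has no signal content; spectral metrics undefined."""


@dataclass(frozen=True)
class SegmentWindow:
    """One m/z isolation window.

    ``width`` must be at least 5 Da — narrower notches cannot be resolved at
    realistic waveform durations.  There is no hard upper bound here: a wide
    window may serve as a full-range acquisition descriptor, and
    :func:`cutoff_frequencies` raises :class:`SegmentTooWideError` whenever a
    window cannot actually be SWIFT-isolated at the centre-ion operating
    point.
    """

    mz_low: float
    mz_high: float
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if not 0 < self.mz_low < self.mz_high:
            raise ValueError("require 0 < mz_low < mz_high")
        if self.width < 5.0:
            raise ValueError("window width must be at least 5 Da")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")

    @property
    def width(self) -> float:
        return self.mz_high - self.mz_low

    @property
    def center(self) -> float:
        return 0.5 * (self.mz_low + self.mz_high)

    def contains(self, mz: float) -> bool:
        """Half-open membership [mz_low, mz_high) so adjacent windows partition."""
        return self.mz_low <= mz < self.mz_high


@dataclass(frozen=True)
class SwiftWaveform:
    """Time-domain SWIFT waveform plus its frequency-domain design."""

    samples: np.ndarray          # unit-peak amplitude, arbitrary units
    sample_rate: float           # Hz
    notch_low: float             # Hz, lower notch edge (retained band)
    notch_high: float            # Hz
    passband_low: float          # Hz, excitation floor
    passband_high: float         # Hz, excitation ceiling

    def __post_init__(self) -> None:
        if not self.notch_low < self.notch_high < self.passband_high:
            raise ValueError("require notch_low < notch_high < passband_high")
        if self.passband_high > self.sample_rate / 2:
            raise ValueError("passband_high exceeds Nyquist")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def frequency_resolution(self) -> float:
        return self.sample_rate / len(self.samples)


@dataclass(frozen=True)
class SwiftReport:
    """Spectral quality metrics of a synthesized waveform."""

    notch_rejection_db: float
    passband_ripple_db: float
    crest_factor: float
    notch_low_measured: float
    notch_high_measured: float


def cutoff_frequencies(
    window: SegmentWindow, cfg: TrapConfig = TrapConfig()
) -> tuple[float, float]:
    """Notch edge frequencies (Hz) for a window, (f_low, f_high).

    The RF amplitude is set so the window's centre ion sits at
    ``cfg.q_center_target``; the notch then spans the secular frequencies
    of the window's m/z bounds: f_low from ``mz_high`` (lower q), f_high
    from ``mz_low`` (higher q).
    """
    v_rf = rf_voltage_for_center(window.center, cfg)
    q_low_edge = mathieu_q(window.mz_low, v_rf, cfg)
    if q_low_edge >= cfg.q_stability_limit:
        raise SegmentTooWideError(
            f"window [{window.mz_low}, {window.mz_high}]: q({window.mz_low}) = "
            f"{q_low_edge:.3f} >= stability limit at the centre-ion voltage"
        )
    f_low = secular_frequency(window.mz_high, v_rf, cfg)
    f_high = secular_frequency(window.mz_low, v_rf, cfg)
    return f_low, f_high


def _passband_limits(cfg: TrapConfig) -> tuple[float, float]:
    """Excitation band: secular frequencies from q = 0.05 (heavy ions) to q = 0.9."""
    f_floor = beta_from_q(0.05) * cfg.rf_frequency / 2.0
    f_ceil = beta_from_q(0.90) * cfg.rf_frequency / 2.0
    return f_floor, f_ceil


def synthesize(
    window: SegmentWindow,
    cfg: TrapConfig = TrapConfig(),
    sample_rate: float = 5e6,
    duration: float = 10e-3,
    phase_scheme: str = "quadratic",
    edge_taper_bins: int = 2,
) -> SwiftWaveform:
    """Synthesize the SWIFT waveform isolating ``window``.

    Frequency-domain construction on the FFT grid of ``duration`` seconds at
    ``sample_rate``: unit magnitude across the excitation band
    [q=0.05 .. q=0.9 secular frequencies], zero inside the notch, with a
    raised-cosine taper over ``edge_taper_bins`` bins at each notch edge to
    confine Gibbs leakage.  ``phase_scheme`` is ``"quadratic"`` (crest-factor
    bounded) or ``"zero"`` (all cosines in phase; used for comparison).

    The returned waveform is normalized to unit peak amplitude; absolute
    voltage scaling belongs to the hardware.
    """
    f_notch_low, f_notch_high = cutoff_frequencies(window, cfg)
    f_floor, f_ceil = _passband_limits(cfg)
    if sample_rate <= 2 * f_ceil:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz violates Nyquist for passband "
            f"ceiling {f_ceil:g} Hz"
        )
    if phase_scheme not in ("quadratic", "zero"):
        raise ValueError("phase_scheme must be 'quadratic' or 'zero'")

    n = int(round(sample_rate * duration))
    df = sample_rate / n
    notch_width = f_notch_high - f_notch_low
    if notch_width > 0 and df > notch_width / 4:
        raise ValueError(
            f"duration {duration:g} s too short: bin width {df:g} Hz exceeds "
            f"a quarter of the {notch_width:g} Hz notch"
        )

    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    mag = np.zeros_like(freqs)
    in_band = (freqs >= f_floor) & (freqs <= f_ceil)
    mag[in_band] = 1.0

    in_notch = (freqs >= f_notch_low) & (freqs <= f_notch_high)
    mag[in_notch] = 0.0
    # raised-cosine transition over edge_taper_bins bins just outside the notch
    if edge_taper_bins > 0:
        for edge, side in ((f_notch_low, -1), (f_notch_high, +1)):
            for b in range(1, edge_taper_bins + 1):
                f_t = edge + side * b * df
                idx = np.argmin(np.abs(freqs - f_t))
                if in_band[idx] and not in_notch[idx]:
                    w = 0.5 * (1 - math.cos(math.pi * b / (edge_taper_bins + 1)))
                    mag[idx] = min(mag[idx], w)

    exc = np.flatnonzero(mag > 0)
    phase = np.zeros_like(freqs)
    if phase_scheme == "quadratic" and exc.size > 1:
        # quadratic phase across excitation bins spreads energy in time
        rel = (exc - exc[0]).astype(float)
        phase[exc] = math.pi * rel**2 / exc.size

    spectrum = mag * np.exp(1j * phase)
    samples = np.fft.irfft(spectrum, n=n)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak
    return SwiftWaveform(
        samples=samples,
        sample_rate=sample_rate,
        notch_low=f_notch_low,
        notch_high=f_notch_high,
        passband_low=f_floor,
        passband_high=f_ceil,
    )


def spectrum_report(w: SwiftWaveform, transition_bins: int = 3) -> SwiftReport:
    """Measure notch rejection, passband ripple and crest factor from the FFT.

    ``transition_bins`` bins adjacent to each notch/passband edge are treated
    as transition regions and excluded from both the notch and passband
    statistics.  Rejection is the ratio (dB) of the median passband magnitude
    to the largest in-notch magnitude; ripple is max/min over the passband.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size == 0 or not np.any(x):
        raise DegenerateWaveformError("all-zero waveform: metrics undefined")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / w.sample_rate)
    df = w.frequency_resolution
    guard = transition_bins * df

    notch_mask = (freqs >= w.notch_low + guard) & (freqs <= w.notch_high - guard)
    pass_mask = (
        (freqs >= w.passband_low + guard)
        & (freqs <= w.passband_high - guard)
        & ~((freqs > w.notch_low - guard) & (freqs < w.notch_high + guard))
    )
    if not pass_mask.any():
        raise DegenerateWaveformError("no passband bins outside transitions")

    pass_mags = mags[pass_mask]
    ref = float(np.median(pass_mags))
    notch_peak = float(mags[notch_mask].max()) if notch_mask.any() else 0.0
    rejection = math.inf if notch_peak == 0 else 20.0 * math.log10(ref / notch_peak)
    ripple = 20.0 * math.log10(pass_mags.max() / pass_mags.min())
    crest = float(np.max(np.abs(x)) / np.sqrt(np.mean(x**2)))

    # measured notch edges: outermost bins below half the passband reference
    below = np.flatnonzero((mags < 0.5 * ref) & (freqs > w.passband_low)
                           & (freqs < w.passband_high))
    inside = below[(freqs[below] > w.notch_low - guard)
                   & (freqs[below] < w.notch_high + guard)]
    if inside.size:
        lo_meas, hi_meas = float(freqs[inside[0]]), float(freqs[inside[-1]])
    else:
        lo_meas = hi_meas = math.nan
    return SwiftReport(
        notch_rejection_db=rejection,
        passband_ripple_db=ripple,
        crest_factor=crest,
        notch_low_measured=lo_meas,
        notch_high_measured=hi_meas,
    )


def ions_retained(
    w: SwiftWaveform, secular_freqs: np.ndarray, threshold_db: float = -20.0
) -> np.ndarray:
    """Predict which ions survive the waveform.

    An ion is ejected when the waveform's spectral magnitude at its secular
    frequency exceeds ``threshold_db`` relative to the median passband level;
    ions in the notch see essentially zero drive and are retained.  Returns a
    boolean retain-mask aligned with ``secular_freqs``.
    """
    freqs = np.atleast_1d(np.asarray(secular_freqs, dtype=float))
    mags = np.abs(np.fft.rfft(w.samples))
    grid = np.fft.rfftfreq(len(w.samples), d=1.0 / w.sample_rate)
    pass_mask = (grid >= w.passband_low) & (grid <= w.passband_high) & ~(
        (grid >= w.notch_low) & (grid <= w.notch_high)
    )
    ref = np.median(mags[pass_mask])
    idx = np.clip(np.round(freqs / w.frequency_resolution).astype(int), 0,
                  len(mags) - 1)
    with np.errstate(divide="ignore"):
        level_db = 20.0 * np.log10(mags[idx] / ref)
    return level_db < threshold_db
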