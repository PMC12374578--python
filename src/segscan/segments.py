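"""Segment-scan planning and spectrum reconstruction.

A segment scan acquires narrow m/z windows one at a time (each isolated by a
SWIFT notch) and reconstructs the full spectrum by stitching the windows at
predefined merge boundaries inside the overlap regions.  This module plans
the window schedule, merges segment spectra, and provides the peak-level
measurements used for feature extraction: local-maxima peak picking in a
±0.3 Da window (mean-intensity fallback when no maximum exists), relative
intensity as peak area over total spectrum area, and FWHM estimation by
linear interpolation of the half-height crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .swift import SegmentWindow

__all__ = [
    "Spectrum",
    "SegmentSchedule",
    "PeakMeasurement",
    "MissingSegmentError",
    "NoDataError",
    "UnresolvedPeakError",
    "GRID_SPACING",
    "plan_segments",
    "merge_segments",
    "pick_peak",
    "relative_intensity",
    "estimate_fwhm",
]

#: default m/z grid spacing, Da (≥8 samples across a 0.4 Da FWHM peak)
GRID_SPACING = 0.05


class MissingSegmentError(ValueError):
    """A schedule window has no matching spectrum."""


class NoDataError(ValueError):
    """The requested m/z window lies outside the spectrum."""


class UnresolvedPeakError(ValueError):
    """Half-height crossings not bracketed near the apex."""


@dataclass
class Spectrum:
    """Ordered (m/z, intensity) profile with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly ascending")

    def __len__(self) -> int:
        return self.mz.size

    def slice(self, mz_low: float, mz_high: float) -> "Spectrum":
        """Sub-spectrum on the half-open interval [mz_low, mz_high)."""
        m = (self.mz >= mz_low) & (self.mz < mz_high)
        return Spectrum(self.mz[m], self.intensity[m], dict(self.metadata))


@dataclass(frozen=True)
class SegmentSchedule:
    """Ordered isolation windows plus the boundaries used when merging."""

    windows: tuple[SegmentWindow, ...]
    overlap: float
    merge_boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        ws = self.windows
        if not ws:
            raise ValueError("schedule needs at least one window")
        if any(b.mz_low <= a.mz_low for a, b in zip(ws, ws[1:])):
            raise ValueError("windows must be sorted by mz_low")
        for a, b in zip(ws, ws[1:]):
            if not math.isclose(a.mz_high - b.mz_low, self.overlap,
                                rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"adjacent windows [{a.mz_low},{a.mz_high}] and "
                    f"[{b.mz_low},{b.mz_high}] do not overlap by {self.overlap}"
                )
        if len(self.merge_boundaries) != len(ws) - 1:
            raise ValueError("need exactly one merge boundary per adjacent pair")
        for bnd, (a, b) in zip(self.merge_boundaries, zip(ws, ws[1:])):
            if not b.mz_low <= bnd <= a.mz_high:
                raise ValueError(
                    f"merge boundary {bnd} outside overlap [{b.mz_low},{a.mz_high}]"
                )
        if any(y <= x for x, y in zip(self.merge_boundaries,
                                      self.merge_boundaries[1:])):
            raise ValueError("merge boundaries must be strictly increasing")

    @property
    def mz_min(self) -> float:
        return self.windows[0].mz_low

    @property
    def mz_max(self) -> float:
        return self.windows[-1].mz_high

    def owned_interval(self, i: int) -> tuple[float, float]:
        """Half-open m/z interval the i-th window contributes to the merge."""
        lo = -math.inf if i == 0 else self.merge_boundaries[i - 1]
        hi = math.inf if i == len(self.windows) - 1 else self.merge_boundaries[i]
        return lo, hi


def plan_segments(
    mz_min: float,
    mz_max: float,
    width: float = 20.0,
    overlap: float = 5.0,
    polarity: str = "negative",
) -> SegmentSchedule:
    """Plan an isolation-window schedule covering [mz_min, mz_max].

    Windows of ``width`` Da step by ``width - overlap`` from ``mz_min`` until
    the last window's upper edge reaches ``mz_max``.  Merge boundaries default
    to the overlap midpoints, the points farthest from the window edges where
    SWIFT edge effects live.
    """
    if mz_max <= mz_min:
        raise ValueError("mz_max must exceed mz_min")
    if not width > overlap >= 0:
        raise ValueError("require width > overlap >= 0")
    step = width - overlap
    windows = []
    start = mz_min
    while True:
        windows.append(SegmentWindow(start, start + width, polarity))
        if start + width >= mz_max:
            break
        start += step
    boundaries = tuple(
        0.5 * (a.mz_high + b.mz_low) for a, b in zip(windows, windows[1:])
    )
    return SegmentSchedule(tuple(windows), overlap, boundaries)


def merge_segments(
    spectra: Sequence[Spectrum], schedule: SegmentSchedule
) -> Spectrum:
    """Stitch one spectrum per window into a full-range spectrum.

    Every output point is sourced from exactly one segment, chosen by the
    schedule's merge boundaries (half-open on the right, so a point exactly
    at a boundary belongs to the higher window).  Intensities are never
    rescaled or averaged across segments.
    """
    if len(spectra) != len(schedule.windows):
        missing = [
            f"[{w.mz_low}, {w.mz_high}]"
            for w in schedule.windows[len(spectra):]
        ]
        raise MissingSegmentError(
            f"expected {len(schedule.windows)} segment spectra, got "
            f"{len(spectra)}; missing windows: {', '.join(missing) or '?'}"
        )
    parts_mz, parts_int = [], []
    for i, (s, w) in enumerate(zip(spectra, schedule.windows)):
        meta_w = s.metadata.get("window")
        if meta_w is not None and tuple(meta_w) != (w.mz_low, w.mz_high):
            raise MissingSegmentError(
                f"segment {i} was acquired for window {meta_w}, schedule "
                f"expects [{w.mz_low}, {w.mz_high}]"
            )
        lo, hi = schedule.owned_interval(i)
        m = (s.mz >= lo) & (s.mz < hi)
        parts_mz.append(s.mz[m])
        parts_int.append(s.intensity[m])
    mz = np.concatenate(parts_mz)
    intensity = np.concatenate(parts_int)
    meta = {
        "scan_mode": "segment",
        "n_segments": len(spectra),
        "range": (schedule.mz_min, schedule.mz_max),
    }
    if spectra and "injection_time" in spectra[0].metadata:
        meta["injection_time"] = spectra[0].metadata["injection_time"]
    if spectra and "polarity" in spectra[0].metadata:
        meta["polarity"] = spectra[0].metadata["polarity"]
    return Spectrum(mz, intensity, meta)


@dataclass(frozen=True)
class PeakMeasurement:
    """One picked peak: location, intensity and how it was obtained."""

    target_mz: float
    picked_mz: float
    intensity: float
    method: str                      # "local_max" | "window_mean"
    relative_intensity: float | None = None
    fwhm: float | None = None
    polarity: str = "negative"

    @property
    def feature_id(self) -> str:
        """Polarity-tagged nominal-mass feature name, e.g. N146 / P104."""
        tag = "P" if self.polarity == "positive" else "N"
        return f"{tag}{round(self.target_mz)}"


def pick_peak(
    s: Spectrum, target_mz: float, half_window: float = 0.3
) -> PeakMeasurement:
    """Pick the peak nearest ``target_mz`` within ±``half_window`` Da.

    A local maximum is an interior grid point strictly greater than both
    neighbours.  Among several, the most intense wins; intensity ties break
    to the point closest to the target, then to the lower m/z.  When no local
    maximum exists (e.g. a monotone ramp), the mean intensity over the window
    is reported with ``method="window_mean"`` at the target m/z itself.
    """
    lo, hi = target_mz - half_window, target_mz + half_window
    idx = np.flatnonzero((s.mz >= lo) & (s.mz <= hi))
    if idx.size == 0:
        raise NoDataError(
            f"window [{lo:.3f}, {hi:.3f}] outside spectrum "
            f"[{s.mz[0] if len(s) else math.nan:.3f}, "
            f"{s.mz[-1] if len(s) else math.nan:.3f}]"
        )
    pol = s.metadata.get("polarity", "negative")
    candidates = []
    for i in idx:
        if 0 < i < len(s) - 1 and (
            s.intensity[i] > s.intensity[i - 1]
            and s.intensity[i] > s.intensity[i + 1]
        ):
            candidates.append(i)
    if not candidates:
        return PeakMeasurement(
            target_mz=target_mz,
            picked_mz=target_mz,
            intensity=float(np.mean(s.intensity[idx])),
            method="window_mean",
            polarity=pol,
        )
    # highest intensity, then nearest to target, then lower m/z; distances
    # rounded to 1e-9 Da so grid float jitter cannot decide a genuine tie
    best = min(
        candidates,
        key=lambda i: (
            -s.intensity[i],
            round(abs(s.mz[i] - target_mz), 9),
            s.mz[i],
        ),
    )
    return PeakMeasurement(
        target_mz=target_mz,
        picked_mz=float(s.mz[best]),
        intensity=float(s.intensity[best]),
        method="local_max",
        polarity=pol,
    )


def _apex_index(s: Spectrum, picked_mz: float) -> int:
    i = int(np.argmin(np.abs(s.mz - picked_mz)))
    if not (
        0 < i < len(s) - 1
        and s.intensity[i] >= s.intensity[i - 1]
        and s.intensity[i] >= s.intensity[i + 1]
    ):
        raise UnresolvedPeakError(f"no local maximum at m/z {picked_mz:.3f}")
    return i


def estimate_fwhm(s: Spectrum, picked_mz: float, max_reach: float = 1.0) -> float:
    """FWHM (Da) of the peak whose apex is at ``picked_mz``.

    Walks out from the apex to the first sample below half the apex height on
    each side and linearly interpolates the crossing.  Raises
    :class:`UnresolvedPeakError` if either crossing is not bracketed within
    ``max_reach`` Da of the apex.
    """
    i = _apex_index(s, picked_mz)
    half = s.intensity[i] / 2.0
    crossings = []
    for step in (-1, 1):
        j = i
        while True:
            j += step
            if j < 0 or j >= len(s) or abs(s.mz[j] - s.mz[i]) > max_reach:
                raise UnresolvedPeakError(
                    f"half height not bracketed within {max_reach} Da of apex "
                    f"{s.mz[i]:.3f}"
                )
            if s.intensity[j] < half:
                break
        # linear interpolation between j-step (above half) and j (below half)
        x0, x1 = s.mz[j - step], s.mz[j]
        y0, y1 = s.intensity[j - step], s.intensity[j]
        crossings.append(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    left, right = sorted(crossings)
    return float(right - left)


def _peak_extent(s: Spectrum, apex: int, fwhm: float | None) -> tuple[int, int]:
    """Indices [left, right] bounding the peak: first local minimum on each
    side, or ±3×FWHM from the apex, whichever comes first."""
    reach = 3.0 * fwhm if fwhm is not None else 3.0 * 0.4
    left = apex
    while left > 0 and abs(s.mz[left - 1] - s.mz[apex]) <= reach:
        if s.intensity[left - 1] > s.intensity[left]:
            break
        left -= 1
    right = apex
    while right < len(s) - 1 and abs(s.mz[right + 1] - s.mz[apex]) <= reach:
        if s.intensity[right + 1] > s.intensity[right]:
            break
        right += 1
    return left, right


def relative_intensity(
    p: PeakMeasurement,
    context: Spectrum,
    baseline_subtract: bool = True,
) -> float:
    """Peak area divided by total area of the containing spectrum.

    The containing spectrum is the full-scan spectrum in full-scan mode, or
    the segment spectrum that contains the peak in segment mode — the caller
    passes the appropriate ``context``.  The peak area is integrated
    (trapezoid) from the apex outward to the first local minimum on each side
    or to ±3×FWHM, whichever comes first; with ``baseline_subtract`` the
    straight line joining the extent endpoints is removed first.
    """
    if len(context) < 2:
        raise NoDataError("context spectrum too short to integrate")
    total = float(np.trapezoid(context.intensity, context.mz))
    if total <= 0:
        raise ZeroDivisionError("total spectrum area is zero; ratio undefined")
    if p.method == "window_mean":
        # no resolved peak: approximate area as mean intensity x pick window
        area = p.intensity * 0.6
    else:
        apex = _apex_index(context, p.picked_mz)
        try:
            fwhm = estimate_fwhm(context, p.picked_mz)
        except UnresolvedPeakError:
            fwhm = None
        left, right = _peak_extent(context, apex, fwhm)
        y = context.intensity[left : right + 1].copy()
        x = context.mz[left : right + 1]
        if baseline_subtract and len(y) > 1:
            base = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
            y = np.clip(y - base, 0.0, None)
        area = float(np.trapezoid(y, x))
    frac = min(max(area / total, 0.0), 1.0)
    return frac
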