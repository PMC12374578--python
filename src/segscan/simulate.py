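"""Synthetic instrument: full-scan and segment-scan spectra with space charge.

The simulator renders a ground-truth metabolite profile (m/z, ion arrival
rate) into measured spectra the way a miniature linear ion trap would see
them.  Trapped charge is the product of in-window arrival rate and injection
time; once it exceeds the trap's charge capacity, Coulomb repulsion among the
trapped ions degrades the measurement.  The distortion model is hinge-linear
in the relative overload ``x = max(0, N/capacity - 1)``:

* peak width grows:      sigma = sigma0 * (1 + broadening_coeff * x)
* centroids shift up:    mu    = mz + shift_coeff * x
* heights compress:      h     = h0 / (1 + saturation_coeff * x)

Zero overload reproduces the nominal instrument: Gaussian peaks of 0.4 Da
FWHM on a 0.05 Da grid.  The segment-scan advantage falls out of the charge
bookkeeping: each isolation window traps only its own ions, so a long
injection that overloads a full scan stays below capacity per segment.

The module also generates two-class sample cohorts with planted fold
changes, the synthetic stand-in for a tissue cohort that makes the
downstream statistics testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .segments import GRID_SPACING, SegmentSchedule, Spectrum
from .swift import SegmentWindow
from .trap import TrapConfig

__all__ = [
    "Compound",
    "GroundTruthProfile",
    "AcquisitionSettings",
    "SpaceChargeModel",
    "FeatureTable",
    "simulate_scan",
    "simulate_segment_run",
    "generate_cohort",
    "reference_profile",
]

#: nominal instrument resolution, Da FWHM
DESIGN_FWHM = 0.4
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class Compound:
    """One ground-truth species: observed m/z and ion arrival rate (ions/ms)."""

    mz: float
    abundance: float
    polarity: str = "negative"
    name: str = ""

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


@dataclass(frozen=True)
class GroundTruthProfile:
    """A set of compounds spanning m/z 50-500 with wide dynamic range."""

    compounds: tuple[Compound, ...]

    def __post_init__(self) -> None:
        if any(not 50.0 <= c.mz <= 500.0 for c in self.compounds):
            raise ValueError("all compound m/z must lie in [50, 500]")

    @property
    def mz_range(self) -> tuple[float, float]:
        mzs = [c.mz for c in self.compounds]
        return (min(mzs), max(mzs)) if mzs else (50.0, 500.0)

    def in_window(self, mz_low: float, mz_high: float) -> tuple[Compound, ...]:
        """Compounds inside the half-open window [mz_low, mz_high)."""
        return tuple(c for c in self.compounds if mz_low <= c.mz < mz_high)

    def total_rate(self, mz_low: float = -math.inf,
                   mz_high: float = math.inf) -> float:
        """Summed arrival rate (ions/ms) in the window."""
        return sum(c.abundance for c in self.compounds
                   if mz_low <= c.mz < mz_high)

    def with_m1_isotopes(self, fraction: float = 0.17) -> "GroundTruthProfile":
        """Add an M+1 isotopologue at +1.00336 Da for every compound.

        A single fixed fraction stands in for carbon isotope envelopes
        (0.17 matches a C16 lipid such as FA 16:0); isotope fine structure
        is out of scope.
        """
        extra = [
            replace(c, mz=c.mz + 1.00336, abundance=c.abundance * fraction,
                    name=f"{c.name} (M+1)" if c.name else "")
            for c in self.compounds
            if c.mz + 1.00336 <= 500.0
        ]
        return GroundTruthProfile(self.compounds + tuple(extra))


@dataclass(frozen=True)
class AcquisitionSettings:
    """How a scan is acquired."""

    injection_time: float = 60.0     # ms
    scan_mode: str = "full"          # "full" | "segment"
    noise_sd: float = 0.05           # relative (multiplicative, log scale)
    baseline_sd: float = 5.0         # counts, additive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injection_time < 0:
            raise ValueError("injection_time must be non-negative")
        if self.scan_mode not in ("full", "segment"):
            raise ValueError("scan_mode must be 'full' or 'segment'")


@dataclass(frozen=True)
class SpaceChargeModel:
    """Hinge-linear distortion of a scan above the trap's charge capacity."""

    capacity: float                  # ions at distortion onset
    broadening_coeff: float = 0.0    # fractional sigma growth per unit overload
    shift_coeff: float = 0.0         # Da per unit overload
    saturation_coeff: float = 0.0    # height compression per unit overload

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be positive")
        for name in ("broadening_coeff", "shift_coeff", "saturation_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def overload(self, trapped_charge: float) -> float:
        return max(0.0, trapped_charge / self.capacity - 1.0)

    @classmethod
    def none(cls) -> "SpaceChargeModel":
        """Ideal trap: infinite capacity, no distortion."""
        return cls(capacity=math.inf)

    @classmethod
    def calibrated(
        cls,
        profile: GroundTruthProfile,
        capacity_ms: float = 38.0,
        reference_ms: float = 60.0,
        source_mz: float = 255.23295,
        apparent_mz: float = 257.0,
        fwhm_factor: float = 2.0,
        suppression_factor: float = 4.0,
    ) -> "SpaceChargeModel":
        """Calibrate the model against a profile's full-scan charge budget.

        Capacity is the charge the profile delivers in ``capacity_ms``
        milliseconds (so shorter injections are clean); at ``reference_ms``
        the coefficients produce a centroid reading of ``apparent_mz`` for a
        peak truly at ``source_mz``, an FWHM grown by ``fwhm_factor`` and
        heights compressed by ``suppression_factor``.  The defaults encode
        the benchmark behaviour of a 60 ms overloaded full scan: a palmitate
        [M-H]- peak at m/z 255 reading as m/z 257, visible broadening, and
        suppression of low-abundance peaks.
        """
        rate = profile.total_rate()
        capacity = rate * capacity_ms
        x = reference_ms * rate / capacity - 1.0
        if x <= 0:
            raise ValueError("reference injection must overload the capacity")
        return cls(
            capacity=capacity,
            broadening_coeff=(fwhm_factor - 1.0) / x,
            shift_coeff=(apparent_mz - source_mz) / x,
            saturation_coeff=(suppression_factor - 1.0) / x,
        )


def _grid(mz_low: float, mz_high: float, spacing: float = GRID_SPACING) -> np.ndarray:
    """Absolute-aligned m/z grid so segment grids stitch without seams."""
    i0 = math.ceil(round(mz_low / spacing, 9))
    i1 = math.floor(round(mz_high / spacing, 9))
    return np.arange(i0, i1 + 1) * spacing


def _scan_rng(settings: AcquisitionSettings, mz_low: float, mz_high: float
              ) -> np.random.Generator:
    key = (settings.seed, int(round(mz_low * 1000)), int(round(mz_high * 1000)))
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_scan(
    profile: GroundTruthProfile,
    settings: AcquisitionSettings,
    window: SegmentWindow | None = None,
    cfg: TrapConfig | None = None,
    sc: SpaceChargeModel | None = None,
) -> Spectrum:
    """Render one scan of ``profile`` as a measured spectrum.

    ``window=None`` acquires the full m/z 50-500 range.  Trapped charge is
    the in-window arrival rate times the injection time; the space-charge
    model (default: none) distorts peaks according to the overload.  Noise —
    multiplicative log-normal on peak heights plus additive baseline — is
    drawn from a generator keyed on (seed, window), so identical settings
    give bit-identical spectra.
    """
    del cfg  # trap constants do not enter the rendering; kept for symmetry
    if sc is None:
        sc = SpaceChargeModel.none()
    if window is None:
        lo, hi = 50.0, 500.0
        pol = profile.compounds[0].polarity if profile.compounds else "negative"
    else:
        lo, hi = window.mz_low, window.mz_high
        pol = window.polarity
    mz = _grid(lo, hi)
    rng = _scan_rng(settings, lo, hi)

    compounds = profile.in_window(lo, hi)
    trapped = profile.total_rate(lo, hi) * settings.injection_time
    x = sc.overload(trapped)
    sigma = DESIGN_FWHM * _FWHM_TO_SIGMA * (1.0 + sc.broadening_coeff * x)
    shift = sc.shift_coeff * x
    compress = 1.0 / (1.0 + sc.saturation_coeff * x)

    intensity = np.zeros_like(mz)
    for c in compounds:
        ions = c.abundance * settings.injection_time * compress
        if ions <= 0:
            continue
        height = ions / (sigma * math.sqrt(2.0 * math.pi))
        height *= math.exp(rng.normal(0.0, settings.noise_sd))
        mu = c.mz + shift
        intensity += height * np.exp(-0.5 * ((mz - mu) / sigma) ** 2)
    intensity += np.abs(rng.normal(0.0, settings.baseline_sd, size=mz.size))

    meta = {
        "polarity": pol,
        "injection_time": settings.injection_time,
        "scan_mode": "full" if window is None else "segment",
        "window": (lo, hi),
        "trapped_charge": trapped,
        "overload": x,
        "seed": settings.seed,
    }
    return Spectrum(mz, intensity, meta)


def simulate_segment_run(
    profile: GroundTruthProfile,
    schedule: SegmentSchedule,
    settings: AcquisitionSettings,
    cfg: TrapConfig | None = None,
    sc: SpaceChargeModel | None = None,
) -> list[Spectrum]:
    """Acquire one spectrum per schedule window.

    Each window traps only its own ions, the mechanism behind the segment
    scan's sensitivity: per-window charge stays below capacity at injection
    times that would overload a full scan.
    """
    return [
        simulate_scan(profile, settings, window=w, cfg=cfg, sc=sc)
        for w in schedule.windows
    ]


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class FeatureTable:
    """Samples x features relative-intensity matrix with class labels."""

    values: pd.DataFrame             # index: sample ids, columns: feature ids
    labels: pd.Series                # aligned with values.index

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels must be indexed like values")
        if (self.values.values < 0).any():
            raise ValueError("feature values must be non-negative")
        if self.values.columns.duplicated().any():
            raise ValueError("feature ids must be unique")

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        labels = df.pop("label")
        return cls(df, labels)


def generate_cohort(
    n_per_class: Sequence[int] | int = 25,
    n_features: int = 200,
    planted: Sequence[tuple[int, float]] = (),
    noise_sigma: float = 0.35,
    seed: int = 0,
    class_names: Sequence[str] = ("control", "case"),
) -> FeatureTable:
    """Generate a two-class cohort of log-normal relative intensities.

    Each feature f has a log-mean drawn once per cohort; samples scatter
    around it with log-sd ``noise_sigma``.  ``planted`` lists
    ``(feature_index, fold_change)`` pairs: the second class's mean for that
    feature is multiplied by the fold change.  ``n_per_class`` may be a
    single int (balanced) or one count per class (imbalanced cohorts, as in
    a glioma-versus-normal comparison).  Deterministic under ``seed``.
    """
    if isinstance(n_per_class, int):
        counts = [n_per_class] * len(class_names)
    else:
        counts = list(n_per_class)
    if len(counts) != len(class_names) or len(class_names) != 2:
        raise ValueError("exactly two classes with one count each")
    for f_idx, fc in planted:
        if not 0 <= f_idx < n_features:
            raise ValueError(f"planted feature index {f_idx} out of range")
        if fc <= 0:
            raise ValueError("fold_change must be positive")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1516, n_features]))
    base_log_mean = rng.uniform(math.log(1e-4), math.log(1e-2), size=n_features)
    shift = np.zeros(n_features)
    for f_idx, fc in planted:
        shift[f_idx] = math.log(fc)

    feature_mz = rng.integers(50, 501, size=n_features)
    feature_pol = rng.choice(["N", "P"], size=n_features)
    feat_ids = [f"{p}{m}_{i:04d}" for i, (p, m) in
                enumerate(zip(feature_pol, feature_mz))]

    rows, labels, sample_ids = [], [], []
    for ci, (cname, n) in enumerate(zip(class_names, counts)):
        mu = base_log_mean + (shift if ci == 1 else 0.0)
        logs = rng.normal(mu, noise_sigma, size=(n, n_features))
        rows.append(np.exp(logs))
        labels += [cname] * n
        sample_ids += [f"{cname}_{j:03d}" for j in range(n)]
    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=feat_ids)
    return FeatureTable(values, pd.Series(labels, index=sample_ids, name="label"))


# ---------------------------------------------------------------------------
# reference profile

_ANCHORS = [
    # (name, [M-H]- m/z, ions/ms)  — monoisotopic mass minus 1.00728
    ("Lactic acid", 89.02441, 1500.0),
    ("Choline-related fragment", 102.09243, 60.0),
    ("Aspartic acid", 132.03023, 250.0),
    ("Glutamic acid", 146.04588, 800.0),
    ("2-Hydroxyglutaric acid", 147.02989, 100.0),
    ("Xanthine", 151.02615, 90.0),
    ("Allantoin", 157.03671, 60.0),
    ("N-Acetylaspartic acid", 174.04079, 300.0),
    ("Tyrosine", 180.06661, 120.0),
    ("FA 16:1 (palmitoleic acid)", 253.21730, 1200.0),
    ("FA 16:0 (palmitic acid)", 255.23295, 2000.0),
    ("FA 16:0 (M+1)", 256.23631, 340.0),
    ("FA 18:1 (oleic acid)", 281.24860, 900.0),
]


def reference_profile(
    n_filler: int = 170,
    total_rate: float = 30000.0,
    seed: int = 0,
    polarity: str = "negative",
) -> GroundTruthProfile:
    """Brain-tissue-like ground truth: ~183 species over m/z 50-500.

    Named anchor metabolites (lactate, glutamate, NAA, 2-HG, allantoin, the
    C16/C18 fatty acids and the palmitate M+1 isotope) carry fixed arrival
    rates; ``n_filler`` anonymous species with log-uniform abundances spanning
    three orders of magnitude fill the rest of the range, scaled so the total
    arrival rate is exactly ``total_rate`` ions/ms.  The fixed total makes
    the charge budget — and hence the space-charge calibration — reproducible
    regardless of the filler draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 240, n_filler]))
    anchors = [
        Compound(mz=mz, abundance=ab, polarity=polarity, name=name)
        for name, mz, ab in _ANCHORS
    ]
    anchor_rate = sum(a.abundance for a in anchors)
    if total_rate <= anchor_rate:
        raise ValueError("total_rate must exceed the anchor compounds' rate")

    mzs = np.sort(rng.uniform(52.0, 498.0, size=n_filler))
    # keep filler at least 0.8 Da away from anchors so they stay resolvable
    mzs = np.array([m for m in mzs
                    if all(abs(m - a.mz) > 0.8 for a in anchors)])
    raw = np.exp(rng.uniform(math.log(1.0), math.log(1000.0), size=mzs.size))
    scale = (total_rate - anchor_rate) / raw.sum()
    filler = [
        Compound(mz=float(m), abundance=float(r * scale), polarity=polarity)
        for m, r in zip(mzs, raw)
    ]
    return GroundTruthProfile(tuple(anchors + filler))
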