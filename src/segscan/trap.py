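"""Linear ion-trap (LIT) physics for a miniature mass spectrometer.

The radial motion of an ion in an RF-only linear quadrupole trap follows the
Mathieu equation with ``a = 0`` and

    q = 4 z e V / (m Omega^2 r0^2)

where ``V`` is the zero-to-peak RF amplitude, ``Omega = 2 pi f_RF`` the drive
angular frequency, ``r0`` the field radius and ``m`` the ion mass.  The ion
oscillates at the secular frequency ``f = beta * f_RF / 2`` where ``beta(q)``
is the Floquet exponent of the Mathieu equation; a supplementary AC in
resonance with this frequency ejects the ion.  Ions are radially stable for
``q`` below ~0.908.

This module provides the forward map (m/z, V) -> q -> beta -> secular
frequency, its inversions used for RF calibration (placing the centre ion of
an isolation window at a target q) and for converting an RF amplitude into
the ejected m/z, i.e. the mass calibration of a resonance-ejection scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml
from scipy.optimize import brentq

__all__ = [
    "TrapConfig",
    "IonState",
    "UnstableIonError",
    "mathieu_q",
    "beta_from_q",
    "q_from_beta",
    "secular_frequency",
    "rf_voltage_for_center",
    "ejection_mz",
]

#: unified atomic mass unit, kg
ATOMIC_MASS = 1.66053906660e-27
#: elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19


class UnstableIonError(ValueError):
    """Raised when an ion's Mathieu q lies at or beyond the stability boundary."""


@dataclass(frozen=True)
class TrapConfig:
    """Operating constants of the linear ion trap.

    Parameters
    ----------
    rf_frequency : float
        RF drive frequency Omega/2pi in Hz.  Default 1.033 MHz.
    ac_eject_frequency : float
        Resonance-ejection AC frequency in Hz.  Default 376 kHz.
    field_radius : float
        Field radius r0 in metres.  Default 4 mm (typical for a miniature
        rectilinear/linear trap; not critical — all isolation logic is
        ratio-based).
    q_center_target : float
        Mathieu q at which the centre ion of an isolation window is placed
        by RF calibration.  Default 0.65.
    q_stability_limit : float
        Boundary of the a=0 radial stability region.  Default 0.908.
    charge : int
        Ion charge state z; singly charged throughout for small metabolites.
    """

    rf_frequency: float = 1.033e6
    ac_eject_frequency: float = 376e3
    field_radius: float = 4e-3
    q_center_target: float = 0.65
    q_stability_limit: float = 0.908
    charge: int = 1

    def __post_init__(self) -> None:
        if self.rf_frequency <= 0:
            raise ValueError("rf_frequency must be positive")
        if not 0 < self.ac_eject_frequency < self.rf_frequency / 2:
            raise ValueError(
                "ac_eject_frequency must lie in (0, rf_frequency/2)"
            )
        if self.field_radius <= 0:
            raise ValueError("field_radius must be positive")
        if not 0 < self.q_center_target < self.q_stability_limit:
            raise ValueError("q_center_target must lie in (0, q_stability_limit)")
        if not 0 < self.q_stability_limit <= 0.908 + 1e-3:
            raise ValueError("q_stability_limit must lie in (0, 0.909]")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def omega(self) -> float:
        """Angular RF drive frequency, rad/s."""
        return 2.0 * math.pi * self.rf_frequency

    @property
    def beta_eject(self) -> float:
        """Floquet exponent at which the ejection AC is resonant."""
        return 2.0 * self.ac_eject_frequency / self.rf_frequency

    @classmethod
    def from_file(cls, path: str | Path) -> "TrapConfig":
        """Load a trap configuration from a YAML/flat key-value file.

        Recognised keys match the constructor arguments; units are Hz,
        metres and (downstream) volts zero-to-peak.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown trap config keys: {sorted(unknown)}")
        # YAML renders "1.033e6" as a string (no sign in the exponent);
        # coerce numerics so scientific notation works either way
        coerced = {
            k: (int(v) if k == "charge" else float(v)) for k, v in raw.items()
        }
        return cls(**coerced)


@dataclass(frozen=True)
class IonState:
    """Snapshot of one ion's trapping parameters at a given RF amplitude."""

    mz: float
    q: float
    beta: float
    secular_frequency: float


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v!r}")


def mathieu_q(mz: float, v_rf: float, cfg: TrapConfig = TrapConfig()) -> float:
    """Mathieu q of an ion of mass-to-charge ``mz`` (Th) at RF amplitude ``v_rf`` (V 0-p).

    q = 4 z e V / (m Omega^2 r0^2) with m = mz * z * u, so q is inversely
    proportional to m/z at fixed voltage and independent of z for fixed m/z.
    """
    _require_positive(mz=mz, v_rf=v_rf)
    return (
        4.0
        * ELEMENTARY_CHARGE
        * v_rf
        / (mz * ATOMIC_MASS * cfg.omega**2 * cfg.field_radius**2)
    )


def _cf_beta_squared(beta: float, q: float, depth: int) -> float:
    """Evaluate the a=0 Mathieu characteristic continued fraction.

    Returns the right-hand side of

        beta^2 = q^2/((2-beta)^2 - q^2/((4-beta)^2 - ...))
               + q^2/((2+beta)^2 - q^2/((4+beta)^2 - ...))

    truncated at ``depth`` terms (evaluated bottom-up for stability).
    """
    q2 = q * q
    total = 0.0
    for sign in (1.0, -1.0):
        denom = (2.0 * depth + sign * beta) ** 2
        for k in range(depth - 1, 0, -1):
            denom = (2.0 * k + sign * beta) ** 2 - q2 / denom
        total += q2 / denom
    return total


def beta_from_q(q: float, tol: float = 1e-12, q_limit: float = 0.908) -> float:
    """Floquet exponent beta of the a=0 Mathieu equation, by continued fraction.

    Solves the characteristic equation ``beta^2 = cf(beta, q)`` (continued
    fraction truncated at depth 64, converged far below ``tol`` for q < 0.908)
    with bracketed root finding on beta in (0, 1); the adiabatic estimate
    ``q/sqrt(2)`` seeds the bracket.

    Raises
    ------
    UnstableIonError
        If ``q >= q_limit`` (radially unstable at a = 0).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if q >= q_limit:
        raise UnstableIonError(f"q={q:.4f} at or beyond stability limit {q_limit}")
    if q == 0.0:
        return 0.0
    if q < 1e-6:
        return q / math.sqrt(2.0)  # adiabatic limit, truncation error O(q^3)

    depth = 64

    def h(beta: float) -> float:
        return beta * beta - _cf_beta_squared(beta, q, depth)

    lo = q / math.sqrt(2.0) * 0.5
    for _ in range(60):
        if h(lo) < 0:
            break
        lo *= 0.1
    hi = 1.0 - 1e-12
    if h(hi) <= 0 or h(lo) >= 0:
        raise UnstableIonError(f"no stable beta in (0,1) for q={q}")
    return brentq(h, lo, hi, xtol=tol)


def q_from_beta(beta: float, tol: float = 1e-12, q_limit: float = 0.908) -> float:
    """Invert beta(q) on the a=0 stability region by bracketed root finding."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    if beta == 0.0:
        return 0.0
    hi = q_limit - 1e-9
    if beta >= beta_from_q(hi, tol=tol, q_limit=q_limit):
        raise UnstableIonError(f"beta={beta:.4f} not reachable below q={q_limit}")
    return brentq(lambda q: beta_from_q(q, tol=tol, q_limit=q_limit) - beta,
                  1e-12, hi, xtol=1e-13)


def secular_frequency(
    mz: float, v_rf: float, cfg: TrapConfig = TrapConfig()
) -> float:
    """Radial secular frequency (Hz) of an ion at the given RF amplitude.

    f = beta(q) * f_RF / 2.  Strictly decreasing in m/z at fixed voltage.
    Raises :class:`UnstableIonError` if the ion is outside the stability
    region.
    """
    q = mathieu_q(mz, v_rf, cfg)
    return beta_from_q(q, q_limit=cfg.q_stability_limit) * cfg.rf_frequency / 2.0


def ion_state(mz: float, v_rf: float, cfg: TrapConfig = TrapConfig()) -> IonState:
    """Full :class:`IonState` (q, beta, secular frequency) for one ion."""
    q = mathieu_q(mz, v_rf, cfg)
    beta = beta_from_q(q, q_limit=cfg.q_stability_limit)
    return IonState(mz=mz, q=q, beta=beta,
                    secular_frequency=beta * cfg.rf_frequency / 2.0)


def rf_voltage_for_center(
    mz_center: float, cfg: TrapConfig = TrapConfig()
) -> float:
    """RF amplitude (V zero-to-peak) placing ``mz_center`` at the target q.

    Closed-form inversion of :func:`mathieu_q`; the round trip
    ``mathieu_q(m, rf_voltage_for_center(m))`` reproduces
    ``cfg.q_center_target`` to machine precision.  Linear in m/z.
    """
    _require_positive(mz_center=mz_center)
    return (
        cfg.q_center_target
        * mz_center
        * ATOMIC_MASS
        * cfg.omega**2
        * cfg.field_radius**2
        / (4.0 * ELEMENTARY_CHARGE)
    )


def ejection_mz(v_rf: float, cfg: TrapConfig = TrapConfig()) -> float:
    """m/z resonantly ejected at RF amplitude ``v_rf``.

    The ejected ion satisfies beta(q) = 2 f_AC / f_RF; this inverts that
    condition and the q relation, giving the mass calibration that maps an
    RF amplitude ramp onto an m/z axis.  Linear in ``v_rf``.
    """
    _require_positive(v_rf=v_rf)
    q_ej = q_from_beta(cfg.beta_eject, q_limit=cfg.q_stability_limit)
    return (
        4.0
        * ELEMENTARY_CHARGE
        * v_rf
        / (q_ej * ATOMIC_MASS * cfg.omega**2 * cfg.field_radius**2)
    )
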