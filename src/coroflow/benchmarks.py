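"""Closed-form laminar-tube benchmarks used to verify the flow solver.

Poiseuille (steady) and Womersley (oscillatory) solutions for a rigid
circular tube; standard analytic references in hemodynamic solver
verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .flow import BloodProperties


def poiseuille_pressure_drop(blood: BloodProperties, v_mean: float,
                             radius_m: float, length_m: float) -> float:
    """Pressure drop 8*mu*L*Q/(pi*R^4) in Pa at mean velocity v_mean."""
    Q = v_mean * np.pi * radius_m**2
    return 8.0 * blood.dynamic_viscosity * length_m * Q / (
        np.pi * radius_m**4)


def poiseuille_wss(blood: BloodProperties, v_mean: float,
                   radius_m: float) -> float:
    """Wall shear stress 4*mu*v_mean/R in Pa."""
    return 4.0 * blood.dynamic_viscosity * v_mean / radius_m


def womersley_number(radius_m: float, period_s: float,
                     blood: BloodProperties) -> float:
    """alpha = R sqrt(omega/nu)."""
    omega = 2.0 * np.pi / period_s
    return radius_m * np.sqrt(omega / blood.kinematic_viscosity)


@dataclass
class WomersleyFlow:
    """Pulsatile tube flow: steady Poiseuille + one oscillatory harmonic.

    The oscillatory part is normalized by its cross-section mean
    velocity amplitude ``v_osc`` (m/s), so the prescribed mean velocity
    is ``v_mean(t) = v_steady + v_osc*cos(omega t)``.  ``velocity(s, t)``
    evaluates the exact axial profile at radial fraction ``s = r/R``.
    """

    radius_m: float
    period_s: float
    blood: BloodProperties
    v_steady: float = 0.2
    v_osc: float = 0.1

    def __post_init__(self):
        self.omega = 2.0 * np.pi / self.period_s
        self.alpha = womersley_number(self.radius_m, self.period_s,
                                      self.blood)
        lam = 1j**1.5 * self.alpha
        self._lam = lam
        # F(s) = 1 - J0(lam*s)/J0(lam); area mean Fbar = 1 - 2 J1/(lam J0)
        self._j0lam = jv(0, lam)
        fbar = 1.0 - 2.0 * jv(1, lam) / (lam * self._j0lam)
        self._coef = self.v_osc / fbar  # complex profile amplitude

    def mean_velocity(self, t) -> np.ndarray:
        """Cross-section mean velocity at time(s) t (m/s)."""
        t = np.asarray(t, dtype=float)
        return self.v_steady + self.v_osc * np.cos(self.omega * t)

    def velocity(self, s, t) -> np.ndarray:
        """Exact axial velocity at radial fraction s in [0, 1], time t."""
        s = np.asarray(s, dtype=float)
        prof_steady = 2.0 * self.v_steady * (1.0 - s**2)
        F = 1.0 - jv(0, self._lam * s) / self._j0lam
        osc = np.real(self._coef * F * np.exp(1j * self.omega * t))
        return prof_steady + osc
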