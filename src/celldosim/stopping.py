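"""Charged-particle stopping power and CSDA range in liquid water.

Transport here is continuous-slowing-down (CSDA): a particle loses energy
along a straight track at the tabulated rate S(E) until its residual range is
exhausted.  The module ships plain-text stopping-power/range tables for
alphas and electrons in unit-density liquid water and interpolates them
log–log.

The packaged tables are *synthetic*: they are computed from stopping-power
theory rather than copied from a reference tabulation.

* alphas — Bethe formula with a Barkas-type effective charge
  (Z_eff = 2·(1 − exp(−125 β / 2^(2/3)))); below the Bragg peak, where the
  Bethe expansion breaks down, an empirical power law in energy is used,
  calibrated so that the integrated CSDA range reproduces the published
  alpha ranges in tissue (≈47 µm at 5.8 MeV and ≈85 µm at 8.4 MeV).  On the
  cellular domain simulated here all dose is deposited within the first
  ~20 µm of a 47–85 µm track, i.e. by the Bethe-valid region.
* electrons — Berger–Seltzer collision stopping-power formula (Møller
  scattering), mean excitation energy I = 75 eV; radiative losses (<2% below
  2 MeV in water) are neglected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "StoppingPowerTable",
    "RangeDomainError",
    "alpha_stopping_power_water",
    "electron_stopping_power_water",
    "build_table",
]

_ME_C2 = 0.51099895      # MeV
_M_ALPHA_C2 = 3727.379   # MeV
_K = 0.307075            # 4π N_A r_e² m_e c² [MeV·cm²/mol]
_Z_OVER_A = 0.55509      # water
_I_WATER = 75.0e-6       # MeV, mean excitation energy of liquid water

# Two-parameter calibration of the alpha table, solved once so the CSDA
# range integral reproduces BOTH published alpha ranges in unit-density
# tissue exactly: 47 µm at 5.8 MeV and 85 µm at 8.4 MeV.  The Bethe-region
# scale absorbs the shell/Barkas/Bloch corrections the bare formula lacks
# (~−2% in the 5–9 MeV window); the low-energy amplitude shapes the region
# below ~2 MeV.
_ALPHA_BETHE_SCALE = 0.978674
_ALPHA_LOWE_AMPLITUDE = 0.684243
_ALPHA_LOWE_SCALE_MEV = 1.2
_ALPHA_SUBPEAK_EXPONENT = 0.35

_DOMAIN = {"alpha": (1e-3, 10.0), "beta": (1e-3, 3.0)}


def _beta2(E: np.ndarray, mass: float) -> np.ndarray:
    gamma = 1.0 + E / mass
    return 1.0 - 1.0 / gamma**2


def alpha_stopping_power_water(E):
    """Alpha stopping power in liquid water [MeV·cm²/g] (Bethe region).

    Valid above the Bragg peak (~0.75 MeV); :func:`build_table` grafts the
    calibrated sub-peak extension below it.
    """
    E = np.asarray(E, dtype=float)
    b2 = _beta2(E, _M_ALPHA_C2)
    b = np.sqrt(b2)
    z_eff2 = 4.0 * (1.0 - np.exp(-125.0 * b / 2.0 ** (2.0 / 3.0))) ** 2
    L = np.log(2.0 * _ME_C2 * b2 / (1.0 - b2) / _I_WATER) - b2
    low_e = 1.0 + _ALPHA_LOWE_AMPLITUDE * np.exp(-E / _ALPHA_LOWE_SCALE_MEV)
    return _ALPHA_BETHE_SCALE * _K * z_eff2 * _Z_OVER_A / b2 * L * low_e


def electron_stopping_power_water(E):
    """Electron collision stopping power in liquid water [MeV·cm²/g]."""
    E = np.asarray(E, dtype=float)
    tau = E / _ME_C2
    gamma = tau + 1.0
    b2 = 1.0 - 1.0 / gamma**2
    F = 1.0 - b2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / gamma**2
    L = np.log(tau**2 * (tau + 2.0) / 2.0 / (_I_WATER / _ME_C2) ** 2) + F
    return 0.5 * _K * _Z_OVER_A / b2 * L


def build_table(kind: str, n_rows: int = 400) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (E [MeV], S [MeV·cm²/g], R [µm]) for ``kind`` in liquid water.

    The range is the CSDA integral R(E) = ∫₀ᴱ dE'/S(E') at unit density.
    """
    e_min, e_max = _DOMAIN[kind]
    if kind == "alpha":
        # locate the stopping-power peak of the Bethe(+low-E) expression,
        # then extend below it with the calibrated power law
        e_hi = np.logspace(np.log10(0.3), np.log10(e_max), 6000)
        s_hi = alpha_stopping_power_water(e_hi)
        ipk = int(np.argmax(s_hi))
        e_lo = np.logspace(np.log10(e_min), np.log10(e_hi[ipk]), 1200)[:-1]
        s_lo = s_hi[ipk] * (e_lo / e_hi[ipk]) ** _ALPHA_SUBPEAK_EXPONENT
        E = np.concatenate([e_lo, e_hi[ipk:]])
        S = np.concatenate([s_lo, s_hi[ipk:]])
        # analytic integral of the power-law segment from 0 to E[0]
        r0 = E[0] / S[0] / (1.0 - _ALPHA_SUBPEAK_EXPONENT)
    elif kind == "beta":
        E = np.logspace(np.log10(e_min), np.log10(e_max), 8000)
        S = electron_stopping_power_water(E)
        r0 = E[0] / S[0]
    else:  # pragma: no cover
        raise ValueError(f"unknown particle kind {kind!r}")
    R = (cumulative_trapezoid(1.0 / S, E, initial=0.0) + r0) * 1e4  # g/cm²→µm
    out_e = np.logspace(np.log10(e_min), np.log10(e_max), n_rows)
    out_s = np.exp(np.interp(np.log(out_e), np.log(E), np.log(S)))
    out_r = np.exp(np.interp(np.log(out_e), np.log(E), np.log(R)))
    return out_e, out_s, out_r


class RangeDomainError(ValueError):
    """Energy outside the tabulated domain."""


@dataclass
class StoppingPowerTable:
    """Log–log interpolated stopping-power/range table at unit density.

    ``energy_mev`` must be strictly increasing; ``range_um`` is the CSDA
    range and its inverse map E(R) is the same knot set read backwards.
    """

    particle_kind: str
    energy_mev: np.ndarray
    stopping_mev_cm2_g: np.ndarray
    range_um: np.ndarray
    density_g_cm3: float = 1.0
    _log_e: np.ndarray = field(init=False, repr=False)
    _log_s: np.ndarray = field(init=False, repr=False)
    _log_r: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energy_mev) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(np.diff(self.range_um) <= 0):
            raise ValueError("range must be strictly increasing in energy")
        if np.any(self.stopping_mev_cm2_g <= 0):
            raise ValueError("stopping power must be positive")
        self._log_e = np.log(self.energy_mev)
        self._log_s = np.log(self.stopping_mev_cm2_g)
        self._log_r = np.log(self.range_um)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_text(cls, text: str, particle_kind: str) -> "StoppingPowerTable":
        rows = np.loadtxt(io.StringIO(text))
        return cls(particle_kind, rows[:, 0], rows[:, 1], rows[:, 3])

    @classmethod
    def for_particle(cls, kind: str) -> "StoppingPowerTable":
        """Load the packaged liquid-water table for ``kind`` (alpha|beta)."""
        name = {"alpha": "alpha_water_stopping_synthetic.tsv",
                "beta": "electron_water_stopping_synthetic.tsv"}[kind]
        text = (resources.files("celldosim") / "data" / name).read_text()
        return cls.from_text(text, kind)

    # -- lookups -----------------------------------------------------------
    @property
    def energy_domain(self) -> tuple[float, float]:
        return float(self.energy_mev[0]), float(self.energy_mev[-1])

    def stopping_power(self, E):
        """S(E) [MeV/µm] at unit density (clamped below table minimum)."""
        E = np.asarray(E, dtype=float)
        self._check_domain(E)
        s = np.exp(np.interp(np.log(np.clip(E, self.energy_mev[0], None)),
                             self._log_e, self._log_s))
        return s * 1e-4 * self.density_g_cm3

    def csda_range(self, E):
        """CSDA range R(E) [µm]; 0 at E=0, error above the table domain."""
        scalar = np.isscalar(E)
        E = np.atleast_1d(np.asarray(E, dtype=float))
        self._check_domain(E)
        r = np.where(
            E < self.energy_mev[0],
            self.range_um[0] * np.sqrt(np.clip(E, 0, None) / self.energy_mev[0]),
            np.exp(np.interp(np.log(np.clip(E, self.energy_mev[0], None)),
                             self._log_e, self._log_r)),
        ) / self.density_g_cm3
        return float(r[0]) if scalar else r

    def energy_at_range(self, r):
        """Inverse map E(R) [MeV]; 0 for residual ranges below the table."""
        scalar = np.isscalar(r)
        r = np.atleast_1d(np.asarray(r, dtype=float)) * self.density_g_cm3
        e = np.where(
            r <= self.range_um[0],
            0.0,
            np.exp(np.interp(np.log(np.clip(r, self.range_um[0], None)),
                             self._log_r, self._log_e)),
        )
        return float(e[0]) if scalar else e

    def energy_after_path(self, E0, s):
        """Residual energy after a straight path of length ``s`` [µm].

        E(R(E0) − s) for s < R(E0), else 0; exact E0 at s = 0.
        """
        scalar = np.isscalar(E0) and np.isscalar(s)
        E0 = np.atleast_1d(np.asarray(E0, dtype=float))
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any(s < 0):
            raise ValueError("path length must be non-negative")
        r0 = self.csda_range(E0)
        out = np.where(s == 0.0, E0, self.energy_at_range(np.clip(r0 - s, 0.0, None)))
        return float(out[0]) if scalar else out

    def _check_domain(self, E) -> None:
        if np.any(np.asarray(E) < 0):
            raise RangeDomainError("energy must be non-negative")
        if np.any(np.asarray(E) > self.energy_mev[-1] * (1 + 1e-12)):
            raise RangeDomainError(
                f"energy above table domain (max {self.energy_mev[-1]} MeV)")

    # -- raw knots for the numba transport kernel --------------------------
    def interpolation_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """(log R [µm], log E [MeV]) knots for residual-range inversion."""
        return self._log_r - np.log(self.density_g_cm3), self._log_e
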