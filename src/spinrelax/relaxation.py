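"""Spectral density, dipolar constant and relaxation rates.

From fitted model-free parameters the spectral density is the cosine
transform of the total correlation function, a sum of two Lorentzians

    J(w) = (2/5) [ S2 tau_c / (1 + tau_c^2 w^2)
                   + (1 - S2) tau / (1 + tau^2 w^2) ],

and the longitudinal / transverse relaxation rates follow by combining
J at 0, the Larmor frequency w0 and 2 w0, scaled by the dipolar
constant

    K = (mu0 / 4 pi)^2 (3/2) hbar^2 gamma^4 I(I+1) / phi^6,

with phi the mean metal--proton distance.  Two labelled equation sets
are provided for the J-combinations (see :func:`relaxation_rates`);
they satisfy different analytic bounds on R1/R2, which the tests assert.

Everything in this module is SI: J in seconds, K in s^-2, rates in
s^-1.  phi is accepted in angstrom and converted internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants

from .correlation import ModelFreeParameters

__all__ = [
    "PhysicalSettings",
    "DipolarConstant",
    "RelaxationResult",
    "larmor_frequency",
    "spectral_density",
    "dipolar_constant",
    "relaxation_rates",
    "build_report",
    "EQUATION_SETS",
]

PS_TO_S = 1e-12
ANGSTROM_TO_M = 1e-10

EQUATION_SETS = ("as_printed", "standard_like_spin")

#: analytic upper bounds on R1/R2 for each equation set, given that
#: J(0) >= J(w0) >= J(2 w0) for any monotone spectral density
RATIO_BOUNDS = {"as_printed": 2.0 / 15.0, "standard_like_spin": 1.0}

_ALLOWED_SPINS_DOC = "half-integer or integer multiples of 1/2, > 0"


@dataclass(frozen=True)
class PhysicalSettings:
    """Field, nucleus and convention choices for the relaxation formulas.

    Attributes
    ----------
    b0_tesla : float
        Static field strength; 1.5 T is the standard clinical field at
        which contrast-agent relaxation values are quoted.
    gamma_mhz_per_tesla : float
        Cyclic gyromagnetic ratio of the relaxing nucleus; 42.58 MHz/T
        for the water proton.
    frequency_convention : {"angular", "cyclic"}
        "angular" uses w0 = 2 pi gamma B0 (required for the Lorentzian
        spectral densities); "cyclic" uses the literal nu0 = gamma B0.
    spin : float
        Spin quantum number I of the coupling partner (1/2, 1, 3/2, ...).
    planck_mode : {"hbar", "h"}
        Whether the dipolar constant carries hbar^2 (standard dipolar
        theory, the default) or h^2.
    gamma_partner_mhz_per_tesla : float or None
        If set, the dipolar constant uses the heteronuclear product
        gamma^2 gamma_partner^2 instead of gamma^4.
    temperature_c : float
        Metadata only; temperature enters none of the formulas here.
    """

    b0_tesla: float = 1.5
    gamma_mhz_per_tesla: float = 42.58
    frequency_convention: str = "angular"
    spin: float = 0.5
    planck_mode: str = "hbar"
    gamma_partner_mhz_per_tesla: float | None = None
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        if self.b0_tesla < 0:
            raise ValueError(f"b0_tesla must be >= 0, got {self.b0_tesla}")
        if self.gamma_mhz_per_tesla <= 0:
            raise ValueError("gamma_mhz_per_tesla must be positive")
        if self.frequency_convention not in ("angular", "cyclic"):
            raise ValueError(
                "frequency_convention must be 'angular' or 'cyclic', got "
                f"{self.frequency_convention!r}"
            )
        twice = 2.0 * self.spin
        if self.spin <= 0 or abs(twice - round(twice)) > 1e-9:
            raise ValueError(
                f"spin must be {_ALLOWED_SPINS_DOC}, got {self.spin}"
            )
        if self.planck_mode not in ("hbar", "h"):
            raise ValueError(
                f"planck_mode must be 'hbar' or 'h', got {self.planck_mode!r}"
            )

    @property
    def gamma_rad(self) -> float:
        """Angular gyromagnetic ratio in rad s^-1 T^-1."""
        return 2.0 * np.pi * self.gamma_mhz_per_tesla * 1e6

    def to_json_dict(self) -> dict:
        return {
            "b0_tesla": self.b0_tesla,
            "gamma_mhz_per_tesla": self.gamma_mhz_per_tesla,
            "frequency_convention": self.frequency_convention,
            "spin": self.spin,
            "planck_mode": self.planck_mode,
            "gamma_partner_mhz_per_tesla": self.gamma_partner_mhz_per_tesla,
            "temperature_c": self.temperature_c,
        }


DEFAULT_SETTINGS = PhysicalSettings()


def larmor_frequency(settings: PhysicalSettings = DEFAULT_SETTINGS) -> float:
    """Precession frequency w0 of the nucleus in B0, in s^-1.

    Cyclic convention returns nu0 = gamma B0 (Hz); angular (default)
    returns w0 = 2 pi nu0 (rad/s), which is what the Lorentzian
    spectral densities expect.
    """
    nu0 = settings.gamma_mhz_per_tesla * 1e6 * settings.b0_tesla
    if settings.frequency_convention == "cyclic":
        return nu0
    return 2.0 * np.pi * nu0


def spectral_density(params: ModelFreeParameters, omega) -> np.ndarray:
    """Model-free spectral density J(omega) in seconds.

    The exact cosine transform of the total correlation function,
    J(w) = 2 * integral_0^inf C(t) cos(w t) dt with the 1/5 prefactor
    of C folded in: a sum of two Lorentzians weighted by S2 and 1-S2.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    tau_c = params.tau_c * PS_TO_S
    tau = params.tau * PS_TO_S
    s2 = params.S2
    out = 0.4 * (
        s2 * tau_c / (1.0 + (tau_c * omega) ** 2)
        + (1.0 - s2) * tau / (1.0 + (tau * omega) ** 2)
    )
    return out if out.shape else float(out)


@dataclass(frozen=True)
class DipolarConstant:
    """Dipolar prefactor K (s^-2) and the inputs that produced it."""

    K: float
    phi_angstrom: float
    settings: PhysicalSettings

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")


def dipolar_constant(
    phi_angstrom: float, settings: PhysicalSettings = DEFAULT_SETTINGS
) -> DipolarConstant:
    """Dipolar constant K = (mu0/4pi)^2 (3/2) hbar^2 gamma^4 I(I+1) / phi^6.

    gamma enters as the angular ratio (rad/s/T); phi is converted from
    angstrom to metres here and nowhere else.  ``planck_mode="h"``
    substitutes h^2 for hbar^2; ``gamma_partner`` (if set on the
    settings) replaces gamma^4 with the heteronuclear product
    gamma^2 gamma_partner^2.
    """
    if phi_angstrom <= 0:
        raise ValueError(f"phi must be positive, got {phi_angstrom}")
    mu_factor = (constants.mu_0 / (4.0 * np.pi)) ** 2
    planck_sq = (
        constants.hbar**2 if settings.planck_mode == "hbar" else constants.h**2
    )
    gamma = settings.gamma_rad
    if settings.gamma_partner_mhz_per_tesla is not None:
        gamma_partner = 2.0 * np.pi * settings.gamma_partner_mhz_per_tesla * 1e6
        gamma4 = gamma**2 * gamma_partner**2
    else:
        gamma4 = gamma**4
    spin_factor = settings.spin * (settings.spin + 1.0)
    phi_m = phi_angstrom * ANGSTROM_TO_M
    K = mu_factor * 1.5 * planck_sq * gamma4 * spin_factor / phi_m**6
    return DipolarConstant(K=K, phi_angstrom=phi_angstrom, settings=settings)


@dataclass(frozen=True)
class RelaxationResult:
    """Relaxation times/rates under a named equation set."""

    T1: float
    T2: float
    R1: float
    R2: float
    equation_set: str

    def __post_init__(self) -> None:
        for name in ("T1", "T2", "R1", "R2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.T1 * self.R1 - 1.0) > 1e-9 or abs(
            self.T2 * self.R2 - 1.0
        ) > 1e-9:
            raise ValueError("R_i must equal 1/T_i")

    @property
    def ratio(self) -> float:
        """R1 / R2."""
        return self.R1 / self.R2

    @classmethod
    def from_rates(
        cls, R1: float, R2: float, equation_set: str = "tabulated"
    ) -> "RelaxationResult":
        return cls(
            T1=1.0 / R1, T2=1.0 / R2, R1=R1, R2=R2, equation_set=equation_set
        )

    @classmethod
    def from_times(
        cls, T1: float, T2: float, equation_set: str = "tabulated"
    ) -> "RelaxationResult":
        return cls(
            T1=T1, T2=T2, R1=1.0 / T1, R2=1.0 / T2, equation_set=equation_set
        )

    def to_json_dict(self) -> dict:
        return {
            "T1_s": self.T1,
            "T2_s": self.T2,
            "R1_per_s": self.R1,
            "R2_per_s": self.R2,
            "R1_over_R2": self.ratio,
            "equation_set": self.equation_set,
        }


def relaxation_rates(
    params: ModelFreeParameters,
    K: DipolarConstant,
    settings: PhysicalSettings = DEFAULT_SETTINGS,
    equation_set: str = "as_printed",
) -> RelaxationResult:
    """Longitudinal and transverse rates from J(w) and K.

    Two labelled J-combinations are available:

    * ``as_printed`` (default):
        R1 = K [J(w0) + J(2 w0)],
        R2 = K [4 J(0) + 10 J(w0) + J(2 w0)].
      This set obeys R1/R2 <= 2/15 for any monotone J.
    * ``standard_like_spin``: the conventional like-spin dipolar set
        R1 = K [J(w0) + 4 J(2 w0)],
        R2 = (K/2) [3 J(0) + 5 J(w0) + 2 J(2 w0)],
      with R1/R2 <= 1 and R1/R2 -> 1 in extreme narrowing.
    """
    if equation_set not in EQUATION_SETS:
        raise ValueError(
            f"equation_set must be one of {EQUATION_SETS}, got {equation_set!r}"
        )
    w0 = larmor_frequency(settings)
    j0 = spectral_density(params, 0.0)
    j1 = spectral_density(params, w0)
    j2 = spectral_density(params, 2.0 * w0)
    k = K.K
    if equation_set == "as_printed":
        r1 = k * (j1 + j2)
        r2 = k * (4.0 * j0 + 10.0 * j1 + j2)
    else:
        r1 = k * (j1 + 4.0 * j2)
        r2 = 0.5 * k * (3.0 * j0 + 5.0 * j1 + 2.0 * j2)
    return RelaxationResult(
        T1=1.0 / r1, T2=1.0 / r2, R1=r1, R2=r2, equation_set=equation_set
    )


def build_report(entries) -> pd.DataFrame:
    """Tabulate labelled relaxation results.

    ``entries`` is an iterable of (label, RelaxationResult, phi) tuples;
    the returned frame has T/R/ratio columns rounded to 3 decimals, the
    precision at which such values are conventionally quoted.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("need at least one entry")
    labels = [e[0] for e in entries]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    rows = []
    for label, res, phi in entries:
        rows.append(
            {
                "system": label,
                "T1_s": round(res.T1, 3),
                "T2_s": round(res.T2, 3),
                "R1_per_s": round(res.R1, 3),
                "R2_per_s": round(res.R2, 3),
                "R1_over_R2": round(res.ratio, 3),
                "phi_angstrom": round(phi, 2),
            }
        )
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
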