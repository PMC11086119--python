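"""Permittivity model for the microwave dielectric response of raw milk.

Over the 0.5–40 GHz band the complex permittivity of milk is dominated by
the orientational relaxation of bulk water, broadened by the colloidal
environment, with an ionic dc-conductivity loss and the high-frequency tail
of a slower, sub-band process.  The model is a single Cole–Cole dispersion
plus those two loss terms:

    eps*(w) = eps_inf + delta_eps / (1 + (i w tau)^alpha)
              + sigma_dc / (i w eps0)
              + A (i w)^(n - 1)

with ``w = 2 pi f`` in rad/s.  ``delta_eps`` is the dielectric strength of
the bulk-water dispersion, ``tau`` its relaxation time, ``alpha`` the
symmetric-broadening exponent (``alpha = 1`` recovers the Debye form),
``sigma_dc`` the dc conductivity in S/m, and ``A (i w)^(n-1)`` the Jonscher
power-law tail.

Conventions
-----------
* Frequencies are carried in GHz, relaxation times in ps, conductivity in
  S/m; the single point of unit conversion is :func:`omega_rad_per_s`.
* The principal branch is used for the fractional powers,
  ``(i w tau)^alpha = (w tau)^alpha exp(i alpha pi / 2)``, and the reported
  loss is ``eps'' = -Im eps*`` so that both the relaxation and the
  conductivity losses come out positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "EPS0",
    "CCParameters",
    "Spectrum",
    "LossComponents",
    "DomainError",
    "ValidationError",
    "omega_rad_per_s",
    "evaluate_permittivity",
    "relaxation_time_from_peak",
    "decompose_loss",
    "default_frequency_grid",
]

#: Vacuum permittivity in F/m.
EPS0 = 8.85e-12

#: Default measurement band in GHz.
BAND_GHZ = (0.5, 40.0)

#: Default number of simulated frequency points (VNA-like log density).
DEFAULT_GRID_POINTS = 201


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class ValidationError(ValueError):
    """A domain object violates its invariants."""


def omega_rad_per_s(frequency_ghz: np.ndarray | float) -> np.ndarray | float:
    """Angular frequency in rad/s for a frequency given in GHz.

    All GHz -> rad/s conversions in the package go through this function.
    """
    return 2.0 * np.pi * np.asarray(frequency_ghz, dtype=float) * 1e9


def default_frequency_grid(
    n_points: int = DEFAULT_GRID_POINTS,
    f_min_ghz: float = BAND_GHZ[0],
    f_max_ghz: float = BAND_GHZ[1],
) -> np.ndarray:
    """Log-spaced frequency grid (GHz) spanning the measurement band."""
    if n_points < 2 or f_min_ghz <= 0 or f_max_ghz <= f_min_ghz:
        raise DomainError("grid requires n_points >= 2 and 0 < f_min < f_max")
    return np.geomspace(f_min_ghz, f_max_ghz, n_points)


@dataclass
class CCParameters:
    """Parameter vector of the permittivity model.

    Attributes
    ----------
    eps_inf : float
        High-frequency permittivity limit (dimensionless, >= 1).
    delta_eps : float
        Dielectric strength of the bulk-water dispersion (> 0).
    tau : float
        Relaxation time in ps (> 0).
    alpha : float
        Symmetric-broadening exponent, 0 < alpha <= 1 (Debye at 1).
    sigma_dc : float
        dc conductivity in S/m (>= 0).
    jonscher_A : float
        Amplitude of the Jonscher tail ``A (i w)^(n-1)`` with w in rad/s;
        the term itself is dimensionless.  Defaults to 0 (term off).
    jonscher_n : float
        Jonscher exponent, 0 < n < 1.
    """

    eps_inf: float
    delta_eps: float
    tau: float
    alpha: float = 1.0
    sigma_dc: float = 0.0
    jonscher_A: float = 0.0
    jonscher_n: float = 0.8

    def validate(self) -> "CCParameters":
        if not np.all(np.isfinite(self.as_array())):
            raise ValidationError("parameters must be finite")
        if self.eps_inf < 1:
            raise ValidationError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.delta_eps <= 0:
            raise ValidationError(f"delta_eps must be > 0, got {self.delta_eps}")
        if self.tau <= 0:
            raise ValidationError(f"tau must be > 0 ps, got {self.tau}")
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.sigma_dc < 0:
            raise ValidationError(f"sigma_dc must be >= 0, got {self.sigma_dc}")
        if self.jonscher_A < 0:
            raise ValidationError(f"jonscher_A must be >= 0, got {self.jonscher_A}")
        if not 0 < self.jonscher_n < 1:
            raise ValidationError(f"jonscher_n must lie in (0, 1), got {self.jonscher_n}")
        return self

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.eps_inf, self.delta_eps, self.tau, self.alpha,
             self.sigma_dc, self.jonscher_A, self.jonscher_n],
            dtype=float,
        )

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CCParameters":
        return cls(**{k: float(d[k]) for k in
                      ("eps_inf", "delta_eps", "tau", "alpha",
                       "sigma_dc", "jonscher_A", "jonscher_n") if k in d})

    @property
    def loss_peak_frequency_ghz(self) -> float:
        """Loss-peak frequency of the relaxation term, f_max = 1/(2 pi tau)."""
        return 1e3 / (2.0 * np.pi * self.tau)


@dataclass
class Spectrum:
    """A complex permittivity spectrum on a frequency grid.

    ``frequencies`` are in GHz and strictly increasing; ``eps_real`` and
    ``eps_imag`` are the dimensionless storage and (non-negative) loss parts.
    ``meta`` carries acquisition metadata (sample id, replicate index,
    temperature in deg C ...).
    """

    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)

    def validate(self) -> "Spectrum":
        n = self.frequencies.size
        if not (self.eps_real.size == n == self.eps_imag.size):
            raise ValidationError("frequency and permittivity arrays differ in length")
        if n < 8:
            raise ValidationError(f"spectrum needs >= 8 points, got {n}")
        for name, arr in (("frequencies", self.frequencies),
                          ("eps_real", self.eps_real),
                          ("eps_imag", self.eps_imag)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        if np.any(self.frequencies <= 0):
            raise ValidationError("frequencies must be positive")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(self.eps_real <= 1):
            raise ValidationError("eps_real must exceed 1 for physical milk/water spectra")
        if np.any(self.eps_imag < 0):
            raise ValidationError("eps_imag (loss) must be non-negative")
        return self

    @property
    def n_points(self) -> int:
        return int(self.frequencies.size)

    def complex_permittivity(self) -> np.ndarray:
        """eps* = eps' - i eps'' (loss-positive convention)."""
        return self.eps_real - 1j * self.eps_imag


@dataclass
class LossComponents:
    """Additive decomposition of the dielectric loss eps'' by physical origin."""

    frequencies: np.ndarray
    relaxation: np.ndarray
    conductivity: np.ndarray
    jonscher: np.ndarray

    def total(self) -> np.ndarray:
        return self.relaxation + self.conductivity + self.jonscher


def _check_frequencies(frequencies: Sequence[float] | np.ndarray) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise DomainError("frequencies must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(f)):
        raise DomainError("frequencies must be finite")
    if np.any(f <= 0):
        raise DomainError("frequencies must be positive")
    return f


def _complex_terms(
    params: CCParameters, f_ghz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three complex terms of the model (relaxation incl. eps_inf last)."""
    w = omega_rad_per_s(f_ghz)
    tau_s = params.tau * 1e-12
    # principal branch: (i w tau)^alpha = (w tau)^alpha e^{i alpha pi/2}
    iwt_a = np.power(w * tau_s, params.alpha) * np.exp(1j * params.alpha * np.pi / 2.0)
    relax = params.delta_eps / (1.0 + iwt_a)
    cond = params.sigma_dc / (1j * w * EPS0)
    if params.jonscher_A > 0:
        jon = params.jonscher_A * np.power(
            w, params.jonscher_n - 1.0
        ) * np.exp(1j * (params.jonscher_n - 1.0) * np.pi / 2.0)
    else:
        jon = np.zeros_like(w, dtype=complex)
    return relax, cond, jon


def evaluate_permittivity(
    params: CCParameters,
    frequencies: Sequence[float] | np.ndarray,
    meta: Mapping[str, Any] | None = None,
) -> Spectrum:
    """Evaluate the permittivity model on a frequency grid.

    Parameters
    ----------
    params : CCParameters
        Model parameters; validated before evaluation.
    frequencies : array-like of float
        Frequencies in GHz, strictly positive.
    meta : mapping, optional
        Metadata copied onto the returned :class:`Spectrum`.

    Returns
    -------
    Spectrum
        ``eps_real = Re(eps*)`` and ``eps_imag = -Im(eps*)`` so that both
        relaxation and conductivity losses are positive.
    """
    params.validate()
    f = _check_frequencies(frequencies)
    relax, cond, jon = _complex_terms(params, f)
    eps = params.eps_inf + relax + cond + jon
    return Spectrum(
        frequencies=f,
        eps_real=eps.real,
        eps_imag=-eps.imag,
        meta=dict(meta or {}),
    )


def relaxation_time_from_peak(f_max_ghz: float) -> float:
    """Relaxation time in ps from a loss-peak frequency in GHz.

    tau = 1 / (2 pi f_max); the inverse of
    :attr:`CCParameters.loss_peak_frequency_ghz`.
    """
    if not (math.isfinite(f_max_ghz) and f_max_ghz > 0):
        raise DomainError(f"f_max must be a positive finite frequency, got {f_max_ghz}")
    return 1e3 / (2.0 * np.pi * f_max_ghz)


def decompose_loss(
    params: CCParameters, frequencies: Sequence[float] | np.ndarray
) -> LossComponents:
    """Split eps'' into its relaxation, conductivity and Jonscher parts.

    The parts sum (to floating tolerance) to the ``eps_imag`` returned by
    :func:`evaluate_permittivity` at the same frequencies; useful for
    inspecting e.g. the conductivity tail at the low end of the band.
    """
    params.validate()
    f = _check_frequencies(frequencies)
    relax, cond, jon = _complex_terms(params, f)
    return LossComponents(
        frequencies=f,
        relaxation=-relax.imag,
        conductivity=-cond.imag,
        jonscher=-jon.imag,
    )
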