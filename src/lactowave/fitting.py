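"""Bounded complex nonlinear least-squares fitting of the permittivity model.

A measured spectrum is fitted by minimising the stacked *relative* residual

    [ (eps'_model - eps'_obs) / eps'_obs ;
      (eps''_model - eps''_obs) / max(eps''_obs, floor) ]

subject to physical box bounds, since the instrument accuracy is itself
relative (about 5% on both parts).  The loss floor keeps the weight finite
where the observed loss passes near zero.

The fit is a multi-start trust-region least squares (scipy ``least_squares``):
a physics-based initial guess, plus seeded random perturbations of it, each
refined to convergence, best objective kept.  By default the Jonscher tail is
frozen at 0 — the sub-band process is not resolvable inside the measurement
band for most milk spectra — and can be freed with ``fit_jonscher=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    EPS0,
    CCParameters,
    DomainError,
    Spectrum,
    ValidationError,
    evaluate_permittivity,
    omega_rad_per_s,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "InitializationError",
    "InsufficientReplicatesError",
    "PARAM_BOUNDS",
    "initial_guess",
    "fit_spectrum",
    "replicate_parameter_sd",
]


class InitializationError(ValueError):
    """The spectrum is too degenerate to derive a starting point."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicate fits were supplied."""


#: Physical box bounds for the fit, generous for water/milk at 25 degC.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "eps_inf": (1.0, 10.0),
    "delta_eps": (1e-6, 120.0),
    "tau": (1.0, 50.0),          # ps
    "alpha": (0.5, 1.0),
    "sigma_dc": (0.0, 3.0),      # S/m
    "jonscher_A": (0.0, 50.0),
    "jonscher_n": (1e-3, 0.999),
}

_FREE_BASE = ("eps_inf", "delta_eps", "tau", "alpha", "sigma_dc")
_FREE_JONSCHER = _FREE_BASE + ("jonscher_A", "jonscher_n")


@dataclass
class FitOptions:
    """Configuration of :func:`fit_spectrum`.

    ``n_starts`` counts the physics-based guess plus seeded +-30%
    perturbations of it; ``eps_imag_floor`` is the denominator floor of the
    relative loss residual.
    """

    fit_jonscher: bool = False
    n_starts: int = 5
    seed: int = 0
    perturbation: float = 0.3
    eps_imag_floor: float = 0.05
    ftol: float = 1e-10
    max_nfev: int = 2000

    def free_names(self) -> tuple[str, ...]:
        return _FREE_JONSCHER if self.fit_jonscher else _FREE_BASE


@dataclass
class FitResult:
    """Outcome of fitting one spectrum.

    ``param_sd`` holds the per-parameter 1-sigma uncertainties from the
    Gauss-Newton covariance at the optimum (0 for frozen parameters);
    ``residual_rms`` is the RMS of the stacked relative residual.
    """

    params: CCParameters
    param_sd: dict[str, float]
    residual_rms: float
    n_points: int
    converged: bool
    n_starts_used: int
    options_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "param_sd": dict(self.param_sd),
            "residual_rms": float(self.residual_rms),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "n_starts_used": int(self.n_starts_used),
            "options_echo": dict(self.options_echo),
        }


def _clip_to_bounds(name: str, value: float) -> float:
    lo, hi = PARAM_BOUNDS[name]
    return float(min(max(value, lo), hi))


def initial_guess(spectrum: Spectrum) -> CCParameters:
    """Physics-based starting point for the fit.

    tau from the loss-peak position restricted to the upper half of the band
    (in log frequency), where the conductivity tail cannot win; (eps_inf,
    delta_eps) by solving the two-point Debye system
    ``eps'(f) = eps_inf + delta_eps / (1 + (w tau)^2)`` at the band
    endpoints — the band top (40 GHz) sits mid-dispersion for water-like
    tau, so the bare eps' value there badly overestimates eps_inf;
    sigma_dc from the low-frequency loss via eps'' ~ sigma/(w eps0).
    """
    spectrum.validate()
    f = spectrum.frequencies
    span = spectrum.eps_real[0] - spectrum.eps_real[-1]
    if span <= 0:
        raise InitializationError(
            "eps' does not decrease across the band (delta_eps estimate "
            f"{span:.3g} <= 0); spectrum looks flat or non-physical"
        )
    # restrict the peak search to the upper half of the log band
    f_mid = math.sqrt(f[0] * f[-1])
    upper = f >= f_mid
    i_peak = np.argmax(np.where(upper, spectrum.eps_imag, -np.inf))
    tau = _clip_to_bounds("tau", 1e3 / (2.0 * np.pi * f[i_peak]))
    wt2 = (omega_rad_per_s(f[[0, -1]]) * tau * 1e-12) ** 2
    k_lo, k_hi = 1.0 / (1.0 + wt2)
    delta_eps = span / (k_lo - k_hi)
    eps_inf = spectrum.eps_real[-1] - k_hi * delta_eps
    delta_eps = _clip_to_bounds("delta_eps", delta_eps)
    eps_inf = _clip_to_bounds("eps_inf", eps_inf)
    sigma_dc = _clip_to_bounds(
        "sigma_dc", max(spectrum.eps_imag[0] * omega_rad_per_s(f[0]) * EPS0, 0.0)
    )
    return CCParameters(
        eps_inf=eps_inf,
        delta_eps=delta_eps,
        tau=tau,
        alpha=0.95,
        sigma_dc=sigma_dc,
        jonscher_A=0.0,
        jonscher_n=0.8,
    )


def _model_parts(x: np.ndarray, names: tuple[str, ...], w: np.ndarray,
                 frozen: CCParameters) -> tuple[np.ndarray, np.ndarray]:
    """eps', eps'' of the model for free-parameter vector x (vectorised)."""
    p = {name: x[i] for i, name in enumerate(names)}
    eps_inf = p.get("eps_inf", frozen.eps_inf)
    delta_eps = p.get("delta_eps", frozen.delta_eps)
    tau = p.get("tau", frozen.tau)
    alpha = p.get("alpha", frozen.alpha)
    sigma = p.get("sigma_dc", frozen.sigma_dc)
    A = p.get("jonscher_A", frozen.jonscher_A)
    n = p.get("jonscher_n", frozen.jonscher_n)
    wt = w * tau * 1e-12
    iwt_a = np.power(wt, alpha) * np.exp(1j * alpha * np.pi / 2.0)
    eps = eps_inf + delta_eps / (1.0 + iwt_a) - 1j * sigma / (w * EPS0)
    if A > 0:
        eps = eps + A * np.power(w, n - 1.0) * np.exp(1j * (n - 1.0) * np.pi / 2.0)
    return eps.real, -eps.imag


def fit_spectrum(spectrum: Spectrum, options: FitOptions | None = None) -> FitResult:
    """Fit the permittivity model to a spectrum by multi-start least squares.

    Deterministic given ``options.seed``.  Never raises on non-convergence:
    if no start converges the best-effort parameters are returned with
    ``converged=False``.
    """
    options = options or FitOptions()
    spectrum.validate()
    names = options.free_names()
    w = omega_rad_per_s(spectrum.frequencies)
    obs_r = spectrum.eps_real
    obs_i = spectrum.eps_imag
    den_i = np.maximum(obs_i, options.eps_imag_floor)

    def residuals(x: np.ndarray) -> np.ndarray:
        mod_r, mod_i = _model_parts(x, names, w, guess)
        return np.concatenate(((mod_r - obs_r) / obs_r, (mod_i - obs_i) / den_i))

    guess = initial_guess(spectrum)
    if options.fit_jonscher:
        # give the tail a small foothold so its gradient is alive
        guess.jonscher_A = 1e-6
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    x0_base = np.clip(np.array([getattr(guess, n) for n in names]), lo, hi)

    rng = np.random.default_rng(options.seed)
    starts = [x0_base]
    for _ in range(max(options.n_starts, 1) - 1):
        fac = 1.0 + rng.uniform(-options.perturbation, options.perturbation,
                                size=x0_base.size)
        starts.append(np.clip(x0_base * fac, lo, hi))

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=options.ftol, xtol=options.ftol, gtol=options.ftol,
                max_nfev=options.max_nfev, x_scale="jac",
            )
        except Exception:  # pragma: no cover - scipy failure paths
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FitResult(
            params=guess, param_sd={n: float("nan") for n in names},
            residual_rms=float("nan"), n_points=spectrum.n_points,
            converged=False, n_starts_used=n_used,
            options_echo=asdict(options),
        )

    fitted = {n: float(v) for n, v in zip(names, best.x)}
    params = CCParameters(
        eps_inf=fitted.get("eps_inf", guess.eps_inf),
        delta_eps=fitted.get("delta_eps", guess.delta_eps),
        tau=fitted.get("tau", guess.tau),
        alpha=fitted.get("alpha", guess.alpha),
        sigma_dc=fitted.get("sigma_dc", guess.sigma_dc),
        jonscher_A=fitted.get("jonscher_A", 0.0),
        jonscher_n=fitted.get("jonscher_n", guess.jonscher_n),
    )
    m = best.fun.size
    residual_rms = float(np.sqrt(2.0 * best.cost / m))
    param_sd = _gauss_newton_sd(best.jac, best.fun, names)
    converged = bool(best.success)
    if converged:
        try:
            params.validate()
        except ValidationError:
            converged = False
    return FitResult(
        params=params, param_sd=param_sd, residual_rms=residual_rms,
        n_points=spectrum.n_points, converged=converged,
        n_starts_used=n_used, options_echo=asdict(options),
    )


def _gauss_newton_sd(jac: np.ndarray, fun: np.ndarray,
                     names: tuple[str, ...]) -> dict[str, float]:
    """1-sigma parameter SDs from the linearised covariance at the optimum."""
    m, p = jac.shape
    sd = {n: 0.0 for n in ("eps_inf", "delta_eps", "tau", "alpha",
                           "sigma_dc", "jonscher_A", "jonscher_n")}
    if m <= p:
        return sd
    s2 = float(fun @ fun) / (m - p)
    try:
        cov = np.linalg.pinv(jac.T @ jac) * s2
        diag = np.clip(np.diag(cov), 0.0, None)
        for n, v in zip(names, np.sqrt(diag)):
            sd[n] = float(v)
    except np.linalg.LinAlgError:  # pragma: no cover
        for n in names:
            sd[n] = float("nan")
    return sd


def replicate_parameter_sd(fits: Sequence[FitResult] | Iterable[FitResult]) -> dict[str, float]:
    """Sample SD (n-1 denominator) of each parameter across replicate fits.

    This is the replicate-measurement uncertainty of a sample measured
    several times in a row (>= 2 fits required).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicate fits to compute an SD, got {len(fits)}"
        )
    arrays = np.stack([f.params.as_array() for f in fits])
    names = ("eps_inf", "delta_eps", "tau", "alpha",
             "sigma_dc", "jonscher_A", "jonscher_n")
    sds = arrays.std(axis=0, ddof=1)
    return {n: float(s) for n, s in zip(names, sds)}
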