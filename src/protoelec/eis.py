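"""Complex nonlinear least-squares fitting of equivalent circuits to
impedance spectra.

The residual minimized is the weighted stack of real and imaginary
deviations; with the default modulus weighting the objective is

    S(θ) = Σ_i [ (Z'_i − Ẑ'_i(θ))² + (Z''_i − Ẑ''_i(θ))² ] / |Z_i|²

and the reported chi-squared is S at the optimum divided by the residual
degrees of freedom (2N − p). Parameters are fitted on a log10 scale
(all circuit parameters are positive and span many decades), with
bounds honoured, using scipy's trust-region-reflective least squares
through lmfit; optionally restarted from log-uniform jitters of the
initial guess to escape poor starts. Percent uncertainties come from
the local curvature (the covariance lmfit derives from the Jacobian).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .circuits import CircuitModel, build_named_circuit, evaluate_impedance
from .containers import ImpedanceSpectrum
from .errors import ConvergenceError, InsufficientDataError, InvalidSpecError

__all__ = ["FitResult", "NyquistSummary", "fit_circuit", "fit_named_circuit",
           "chi_squared", "nyquist_summary"]

_WEIGHTINGS = ("unit", "modulus", "proportional")


@dataclass
class FitResult:
    """Outcome of a circuit fit."""

    params: dict[str, float]
    rel_uncertainty_pct: dict[str, float]
    chi_squared: float
    n_iterations: int
    converged: bool
    at_bounds: list[str]
    message: str = ""

    def __post_init__(self) -> None:
        if self.chi_squared < 0:
            raise InvalidSpecError("chi_squared must be non-negative")


@dataclass
class NyquistSummary:
    """Real-axis extent and capacitive peak of a Nyquist plot."""

    z_real_min_ohm: float
    z_real_max_ohm: float
    z_imag_peak_ohm: float  # magnitude of the most negative Z'', reported >= 0


def _weights(z: np.ndarray, weighting: str) -> np.ndarray:
    if weighting not in _WEIGHTINGS:
        raise InvalidSpecError(f"weighting must be one of {_WEIGHTINGS}, got {weighting!r}")
    if weighting == "unit":
        return np.ones(len(z))
    if weighting == "modulus":
        mod = np.abs(z)
        if np.any(mod == 0):
            raise InvalidSpecError("modulus weighting undefined for zero-impedance points")
        return 1.0 / mod
    # proportional: weight real and imaginary parts by their own magnitude
    mod = np.maximum(np.abs(z), np.finfo(float).tiny)
    return 1.0 / mod


def _weighted_residual_sum(spectrum: ImpedanceSpectrum, model_z: np.ndarray, weighting: str) -> float:
    w = _weights(spectrum.z_ohm, weighting)
    d = spectrum.z_ohm - model_z
    return float(np.sum((w * d.real) ** 2 + (w * d.imag) ** 2))


def chi_squared(
    spectrum: ImpedanceSpectrum,
    model: CircuitModel,
    weighting: str = "modulus",
    n_params: int = 0,
) -> float:
    """Weighted residual statistic of a model against a spectrum.

    With ``n_params`` > 0 the sum is divided by the residual degrees of
    freedom (2N − n_params), matching the normalization used by
    :func:`fit_circuit`; with the default 0 the raw weighted sum is
    returned.
    """
    model_z = evaluate_impedance(model, spectrum.frequencies_hz)
    s = _weighted_residual_sum(spectrum, model_z, weighting)
    if n_params:
        dof = 2 * len(spectrum) - n_params
        if dof <= 0:
            raise InsufficientDataError("not enough points for the parameter count")
        return s / dof
    return s


def nyquist_summary(spectrum: ImpedanceSpectrum) -> NyquistSummary:
    """Min/max of Z' and the magnitude of the most negative Z''."""
    if len(spectrum) == 0:
        raise InsufficientDataError("empty spectrum")
    return NyquistSummary(
        z_real_min_ohm=float(spectrum.z_real.min()),
        z_real_max_ohm=float(spectrum.z_real.max()),
        z_imag_peak_ohm=float(max(0.0, -spectrum.z_imag.min())),
    )


def fit_circuit(
    spectrum: ImpedanceSpectrum,
    template: str | CircuitModel,
    initial: dict[str, float],
    bounds: dict[str, tuple[float, float]] | None = None,
    weighting: str = "modulus",
    n_restarts: int = 3,
    restart_seed: int = 2024,
    jitter_decades: float = 0.3,
) -> FitResult:
    """Fit one of the named circuit templates to a spectrum.

    ``initial`` maps every circuit parameter name to a starting value and
    must lie within ``bounds`` (default bounds are four decades around
    the initial; CPE exponents are bounded in [0.01, 1]). The best of
    ``n_restarts + 1`` runs — the supplied initial plus log-uniformly
    jittered copies drawn with a fixed seed — is returned, so fitting is
    deterministic.

    Raises
    ------
    InsufficientDataError
        If 2·N ≤ number of free parameters.
    """
    if len(spectrum) == 0:
        raise InsufficientDataError("empty spectrum")
    circuit_name = template.name if isinstance(template, CircuitModel) else template
    build_named_circuit(circuit_name, initial)  # validates names/values
    names = sorted(initial)
    n_p = len(names)
    if 2 * len(spectrum) <= n_p:
        raise InsufficientDataError(
            f"{len(spectrum)} points cannot constrain {n_p} parameters"
        )
    bounds = dict(bounds or {})
    for name in names:
        if name not in bounds:
            if _is_exponent(name):
                bounds[name] = (0.01, 1.0)
            else:
                v = initial[name]
                bounds[name] = (v * 1e-4, v * 1e4)
        lo, hi = bounds[name]
        if not (lo <= initial[name] <= hi):
            raise InvalidSpecError(f"initial {name}={initial[name]} outside bounds {bounds[name]}")
        if lo <= 0:
            raise InvalidSpecError(f"bounds for {name} must be positive (got {lo})")

    weights = _weights(spectrum.z_ohm, weighting)
    freqs = spectrum.frequencies_hz
    z_data = spectrum.z_ohm

    def residual(params: lmfit.Parameters) -> np.ndarray:
        vals = {n: 10.0 ** params[_log_key(n)].value for n in names}
        model = build_named_circuit(circuit_name, vals)
        z_model = evaluate_impedance(model, freqs)
        d = (z_data - z_model) * weights
        return np.concatenate([d.real, d.imag])

    rng = np.random.default_rng(restart_seed)
    starts = [dict(initial)]
    for _ in range(n_restarts):
        jittered = {
            n: float(np.clip(initial[n] * 10.0 ** rng.uniform(-jitter_decades, jitter_decades),
                             bounds[n][0], bounds[n][1]))
            for n in names
        }
        starts.append(jittered)

    best = None
    total_nfev = 0
    for start in starts:
        params = lmfit.Parameters()
        for n in names:
            lo, hi = bounds[n]
            params.add(_log_key(n), value=np.log10(start[n]),
                       min=np.log10(lo), max=np.log10(hi))
        try:
            result = lmfit.minimize(residual, params, method="least_squares",
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # a pathological start must not kill the whole fit
            continue
        total_nfev += result.nfev
        if best is None or result.chisqr < best.chisqr:
            best = result
    if best is None:
        raise ConvergenceError("all fit restarts failed")

    fitted = {n: 10.0 ** best.params[_log_key(n)].value for n in names}
    dof = 2 * len(spectrum) - n_p
    chi2 = float(best.chisqr) / dof

    # percent uncertainties: stderr of log10(p) maps to ~ln(10)*stderr relative
    rel_unc: dict[str, float] = {}
    for n in names:
        par = best.params[_log_key(n)]
        if par.stderr is not None and np.isfinite(par.stderr) and par.stderr < 15.0:
            rel_unc[n] = float(100.0 * (10.0 ** par.stderr - 1.0))
        else:
            # absent or astronomically large curvature estimate:
            # the parameter is unconstrained by the data
            rel_unc[n] = float("inf")

    at_bounds = []
    for n in names:
        lo, hi = bounds[n]
        span = np.log10(hi) - np.log10(lo)
        logv = np.log10(fitted[n])
        if min(logv - np.log10(lo), np.log10(hi) - logv) < 1e-6 * max(span, 1.0):
            at_bounds.append(n)

    converged = bool(best.success)
    if not converged:
        # never silent: surface the optimizer's message alongside the result
        message = f"fit did not converge: {best.message}"
    else:
        message = str(best.message)
    return FitResult(
        params=fitted,
        rel_uncertainty_pct=rel_unc,
        chi_squared=chi2,
        n_iterations=int(total_nfev),
        converged=converged,
        at_bounds=at_bounds,
        message=message,
    )


def fit_named_circuit(
    spectrum: ImpedanceSpectrum,
    circuit_name: str,
    initial: dict[str, float] | None = None,
    **kwargs,
) -> FitResult:
    """Convenience wrapper: fit a named circuit starting from the
    published parameters unless an explicit initial guess is given."""
    if initial is None:
        initial = dict(build_named_circuit_defaults(circuit_name))
    return fit_circuit(spectrum, circuit_name, initial, **kwargs)


def build_named_circuit_defaults(circuit_name: str) -> dict[str, float]:
    from . import circuits

    table = {
        "actin": circuits.ACTIN_FIT_PARAMS,
        "proteinoid": circuits.PROTEINOID_FIT_PARAMS,
        "mixture": circuits.MIXTURE_FIT_PARAMS,
    }
    if circuit_name not in table:
        raise InvalidSpecError(f"unknown circuit name {circuit_name!r}")
    return dict(table[circuit_name])


def _is_exponent(name: str) -> bool:
    return name in ("n1", "n")


def _log_key(name: str) -> str:
    return f"log10_{name}"
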