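"""Quadratic binding-isotherm models and K_d fitting.

Both binding assays (affinity probe CE and fluorescence anisotropy) report
a signal proportional to complex formation between a fixed concentration
``A`` of fluorescent aptamer and a varied concentration ``T`` of protein.
Because ``A`` is not negligible relative to ``K_d``, the equilibrium
complex concentration is the root of the mass-action quadratic

    [AT] = 0.5 * (A + T + Kd - sqrt((A + T + Kd)^2 - 4*A*T))

and the measured signal follows

    signal = constant / (1 + Kd / (T + [AT]))

with ``signal`` the ratioed free-DNA peak height (APCE) or the anisotropy
change r - r0.  The signal at T = 0 is defined as 0 by continuity.  An
alternative ``bound_fraction`` form, signal = constant * [AT] / A, is
provided for comparison; the form above is the default.

K_d and the amplitude are estimated by unweighted nonlinear least squares
with K_d parameterized on the log scale to enforce positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AVOGADRO",
    "IsothermModel",
    "BindingMeasurement",
    "FitResult",
    "LibrarySpec",
    "LibraryStatistics",
    "complex_concentration",
    "isotherm_signal",
    "fit_isotherm",
    "library_statistics",
]

AVOGADRO = 6.02214076e23

IsothermForm = Literal["as_printed", "bound_fraction"]
AssayMode = Literal["apce", "anisotropy"]


class BindingMeasurement(NamedTuple):
    """One titration point: protein concentration (nM), signal, replicate id."""

    T: float
    signal: float
    replicate: int = 1


@dataclass(frozen=True)
class IsothermModel:
    """Binding-model parameters for one experiment.

    A is the (constant) aptamer concentration in nM, Kd the dissociation
    constant in nM, constant the saturating signal amplitude in assay
    units.
    """

    mode: AssayMode
    A: float
    Kd: float
    constant: float
    form: IsothermForm = "as_printed"

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("aptamer concentration A must be > 0")
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")

    def signal(self, T):
        return isotherm_signal(T, self.A, self.Kd, self.constant, self.form)


def complex_concentration(A, T, Kd):
    """Equilibrium aptamer-protein complex concentration (nM).

    Root of the mass-action quadratic; the discriminant is clamped at zero
    where round-off drives it slightly negative.  Valid for A, T >= 0 and
    Kd > 0; the result lies in [0, min(A, T)].
    """
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be > 0")
    if np.any(A < 0) or np.any(T < 0):
        raise ValueError("concentrations must be >= 0")
    s = A + T + Kd
    disc = np.maximum(s * s - 4.0 * A * T, 0.0)
    out = 0.5 * (s - np.sqrt(disc))
    return out if out.ndim else float(out)


def isotherm_signal(T, A: float, Kd: float, constant: float, form: IsothermForm = "as_printed"):
    """Model signal at protein concentration T (nM), vectorized over T."""
    T = np.asarray(T, dtype=float)
    ct = complex_concentration(A, T, Kd)
    if form == "as_printed":
        denom = T + ct
        with np.errstate(divide="ignore"):
            out = np.where(denom > 0, constant / (1.0 + Kd / np.where(denom > 0, denom, 1.0)), 0.0)
    elif form == "bound_fraction":
        out = constant * np.asarray(ct) / A
    else:
        raise ValueError(f"unknown isotherm form {form!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitResult:
    Kd_hat: float
    constant_hat: float
    se_Kd: float
    se_constant: float
    rss: float
    converged: bool
    n_obs: int
    message: str = ""


def fit_isotherm(
    data: Sequence[BindingMeasurement] | Sequence[tuple],
    A: float,
    mode: AssayMode = "apce",
    form: IsothermForm = "as_printed",
) -> FitResult:
    """Least-squares (Kd, constant) estimates from titration data.

    Requires at least 4 distinct protein concentrations.  Initial values:
    Kd0 = median nonzero T, constant0 = max observed signal.  Standard
    errors come from the Gauss-Newton curvature of the objective at the
    optimum (delta method for the log-Kd parameterization).
    """
    pts = [BindingMeasurement(*p) if not isinstance(p, BindingMeasurement) else p for p in data]
    T = np.array([p.T for p in pts], dtype=float)
    y = np.array([p.signal for p in pts], dtype=float)
    if len(np.unique(T)) < 4:
        raise ValueError("need at least 4 distinct protein concentrations")
    if np.allclose(y, 0.0):
        raise ValueError("all signals are zero: Kd is unidentifiable")

    kd0 = float(np.median(T[T > 0]))
    c0 = float(np.max(np.abs(y)))

    def residuals(theta):
        log_kd, c = theta
        return isotherm_signal(T, A, math.exp(log_kd), c, form) - y

    sol = least_squares(
        residuals,
        x0=np.array([math.log(kd0), c0]),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        method="lm",
    )
    log_kd, c_hat = sol.x
    kd_hat = math.exp(log_kd)
    rss = float(np.sum(sol.fun**2))
    n, p = len(y), 2
    converged = bool(sol.success) and np.isfinite(kd_hat)

    se_kd = se_c = float("nan")
    if converged and n > p:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n - p)
            se_log_kd = math.sqrt(max(cov[0, 0], 0.0))
            se_kd = kd_hat * se_log_kd  # delta method
            se_c = math.sqrt(max(cov[1, 1], 0.0))
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        Kd_hat=kd_hat,
        constant_hat=float(c_hat),
        se_Kd=se_kd,
        se_constant=se_c,
        rss=rss,
        converged=converged,
        n_obs=n,
        message=str(sol.message),
    )


@dataclass(frozen=True)
class LibrarySpec:
    """Random-region length (nt) and amount of input DNA (pmol)."""

    N: int
    amount_pmol: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.amount_pmol <= 0:
            raise ValueError("amount_pmol must be > 0")


class LibraryStatistics(NamedTuple):
    num_possible: int
    molecules: float
    expected_abundance: float


def library_statistics(spec: LibrarySpec) -> LibraryStatistics:
    """Combinatorics of a random library: 4^N sequences, molecule count,
    and the expected copies of any individual sequence in the input."""
    num_possible = 4**spec.N
    molecules = spec.amount_pmol * 1e-12 * AVOGADRO
    return LibraryStatistics(num_possible, molecules, molecules / num_possible)
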