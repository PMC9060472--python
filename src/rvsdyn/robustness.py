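"""Sensitivity and robustness statistics of types and populations.

The per-type sensitivity

    ω_γ = Σ_γ' ((f_γ - f_γ') / f_γ) · π[γ', γ] / μ_γ

is the variation-weighted mean relative fitness loss of γ's variants: ω
near its upper bound of 1 marks a fragile type whose variants reproduce
much more slowly; ω ≈ 0 marks a robust type surrounded by equally fit
variants; ω < 0 marks a type whose variants are on average fitter.  The
bound ω_γ < 1 holds for every valid model because the weights
π[γ', γ]/μ_γ sum to one and rates are positive.  ω is a 0/0 for types
that never vary (μ_γ = 0) and is reported as undefined (NaN), not zero.

The expected growth potential can be rewritten through ω:

    φ(n) = N ln{ Σ_γ f_γ n_γ  -  Σ_γ μ_γ ω_γ f_γ n_γ }

an algebraic identity with the direct definition, which makes explicit
that lower sensitivities raise φ.  In the regime where every type varies
with (nearly) the same probability μ, the population-level aggregate

    Ω(n) = (F(n) - F_π(n)) / F(n),   F(n) = Σ f_γ n_γ,
    F_π(n) = Σ_{γ, γ'≠γ} f_γ' π[γ', γ] n_γ / μ

is the growth-weighted mean of the per-type ω and enters the restricted
potential linearly: ψ ≈ Σ n ln f - Σ ln n! + N ln F(n) - μ N Ω(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import RestrictedRegimeError
from .forces import expected_growth_potential
from .model import ModelSpec, check_composition


@dataclass(frozen=True)
class SensitivityReport:
    """Per-type and population-level sensitivity of one composition."""

    omega: np.ndarray  # per-type ω (NaN where μ_γ = 0)
    mu: np.ndarray  # per-type variation probabilities
    F_n: float  # cumulative growth Σ f_γ n_γ
    F_pi_n: float  # cumulative growth upon variations
    Omega_n: float  # population sensitivity
    common_mu: float  # the common μ of the restricted regime


@dataclass(frozen=True)
class StrongSelectionPhi:
    """Strong-selection approximation of φ with its explicit error term.

    ``approx + const`` approximates the exact φ for populations whose
    present types all reproduce at roughly the reference rate ``f_high``;
    the constant is ``N ln(N f_high)`` (the value of φ when all present
    types have rate exactly f_high and variations are rare).
    """

    approx: float  # -Σ μ_γ ω_γ n_γ
    const: float  # N ln(N f_high)
    exact: float
    error: float  # exact - (approx + const)
    within_tolerance: bool


def type_sensitivity(spec: ModelSpec) -> np.ndarray:
    """Per-type sensitivity ω; NaN flags types with μ_γ = 0 (undefined).

    Always strictly below 1; may be negative when likely variants are
    fitter than the parent type.
    """
    f = spec.f
    pi = spec.pi
    mu = spec.mu
    # rel[γ', γ] = (f_γ - f_γ') / f_γ ; the γ' = γ term vanishes
    rel = (f[None, :] - f[:, None]) / f[None, :]
    raw = (rel * pi).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(mu > 0, raw / np.where(mu > 0, mu, 1.0), np.nan)
    return omega


def phi_via_sensitivity(spec: ModelSpec, n) -> float:
    """φ computed through the sensitivity identity.

    φ = N ln(F(n) - Σ μ_γ ω_γ f_γ n_γ); equal to the direct expected
    growth potential, but evaluated along an independent algebraic route
    (used as a two-route consistency check).  Types with μ_γ = 0
    contribute nothing to the correction sum.
    """
    n = check_composition(spec, n)
    omega = type_sensitivity(spec)
    mu = spec.mu
    correction = np.where(mu > 0, mu * np.nan_to_num(omega) * spec.f * n, 0.0).sum()
    arg = float(spec.f @ n - correction)
    if arg <= 0:
        from .errors import DegenerateModelError

        raise DegenerateModelError("sensitivity-route φ undefined: non-positive argument")
    return spec.N * float(np.log(arg))


def strong_selection_phi(
    spec: ModelSpec, n, f_high: float, rel_tol: float = 0.05
) -> StrongSelectionPhi:
    """First-order φ for populations of near-equal, high reproduction rates.

    approx = -Σ_γ μ_γ ω_γ n_γ, const = N ln(N f_high).  A warning (not an
    error) is attached when some present type's rate deviates from
    ``f_high`` by more than ``rel_tol`` relatively: the formula is then
    still evaluated but is not expected to be accurate.
    """
    n = check_composition(spec, n)
    present = n > 0
    within = bool(
        np.all(np.abs(spec.f[present] - f_high) <= rel_tol * f_high)
    )
    if not within:
        warnings.warn(
            "strong-selection approximation requested but some present types "
            f"have rates outside {rel_tol:.0%} of f_high={f_high:g}",
            stacklevel=2,
        )
    omega = type_sensitivity(spec)
    mu = spec.mu
    approx = -float(np.where(mu > 0, mu * np.nan_to_num(omega) * n, 0.0).sum())
    const = spec.N * float(np.log(spec.N * f_high))
    exact = expected_growth_potential(spec, n)
    return StrongSelectionPhi(
        approx=approx, const=const, exact=exact,
        error=exact - (approx + const), within_tolerance=within,
    )


def _require_common_mu(spec: ModelSpec, mu: float, rel_tol: float) -> None:
    if mu <= 0:
        raise RestrictedRegimeError("common variation probability mu must be > 0")
    if spec.K == 1:
        return  # no variation channel exists; treat as the formal common-mu limit
    dev = np.abs(spec.mu - mu)
    if np.any(dev > rel_tol * mu):
        worst = int(np.argmax(dev))
        raise RestrictedRegimeError(
            f"type {spec.labels[worst]} has mu_gamma = {spec.mu[worst]:.6g}, "
            f"outside relative tolerance {rel_tol:g} of the common mu = {mu:.6g}; "
            "the population sensitivity is defined only in the common-mu regime"
        )


def variation_growth(spec: ModelSpec) -> np.ndarray:
    """Per-type expected off-diagonal growth b_γ = Σ_{γ'≠γ} f_γ' π[γ', γ]."""
    off = spec.pi.copy()
    np.fill_diagonal(off, 0.0)
    return spec.f @ off


def population_sensitivity(
    spec: ModelSpec, n, mu: float, rel_tol: float = 1e-6
) -> SensitivityReport:
    """Population sensitivity Ω(n) in the common-μ regime.

    Ω = (F - F_π)/F with F = Σ f_γ n_γ and F_π = Σ_{γ,γ'≠γ} f_γ' π[γ',γ] n_γ / μ.
    Equals the growth-weighted mean Σ ω_γ f_γ n_γ / F when every μ_γ = μ,
    and ω_γ exactly for a monomorphic population of type γ.  Refused when
    the per-type μ_γ are heterogeneous beyond ``rel_tol``.
    """
    n = check_composition(spec, n)
    _require_common_mu(spec, mu, rel_tol)
    F_n = float(spec.f @ n)
    F_pi = float(variation_growth(spec) @ n) / mu
    return SensitivityReport(
        omega=type_sensitivity(spec),
        mu=spec.mu,
        F_n=F_n,
        F_pi_n=F_pi,
        Omega_n=(F_n - F_pi) / F_n,
        common_mu=float(mu),
    )


def population_sensitivity_profile(
    spec: ModelSpec, comps: np.ndarray, mu: float, rel_tol: float = 1e-6
) -> np.ndarray:
    """Vectorized Ω over an (S, K) array of compositions (common-μ regime)."""
    _require_common_mu(spec, mu, rel_tol)
    C = np.asarray(comps, dtype=np.int64)
    F = C @ spec.f
    F_pi = (C @ variation_growth(spec)) / mu
    return (F - F_pi) / F


def restricted_potential(
    spec: ModelSpec, n, mu: float, rel_tol: float = 1e-6
) -> float:
    """Restricted-regime potential ψ ≈ Σ n ln f - Σ ln n! + N ln F(n) - μ N Ω(n).

    First-order in μ around the exact potential; agreement with the exact
    ψ improves as μ -> 0.  Ω enters linearly, so ∂ψ/∂μ at fixed conditional
    variant kernel is -N Ω(n).
    """
    report = population_sensitivity(spec, n, mu, rel_tol)
    n = check_composition(spec, n)
    return (
        float(n @ np.log(spec.f))
        - float(gammaln(n + 1).sum())
        + spec.N * float(np.log(report.F_n))
        - mu * spec.N * report.Omega_n
    )


def restricted_potential_vector(
    spec: ModelSpec, comps: np.ndarray, mu: float, rel_tol: float = 1e-6
) -> np.ndarray:
    """Vectorized restricted ψ over an (S, K) array of compositions."""
    C = np.asarray(comps, dtype=np.int64)
    Omega = population_sensitivity_profile(spec, C, mu, rel_tol)
    F = C @ spec.f
    return (
        C @ np.log(spec.f)
        - gammaln(C + 1).sum(axis=1)
        + spec.N * np.log(F)
        - mu * spec.N * Omega
    )
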