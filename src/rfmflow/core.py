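"""Ribosome flow model dynamics and non-spectral steady-state solvers.

The RFM describes ribosome traffic along an mRNA chain of ``n`` sites with
normalized occupancies ``x_i in [0, 1]``:

    dx_1/dt = lambda_0 (1 - x_1) - lambda_1 x_1 (1 - x_2)
    dx_i/dt = lambda_{i-1} x_{i-1} (1 - x_i) - lambda_i x_i (1 - x_{i+1})
    dx_n/dt = lambda_{n-1} x_{n-1} (1 - x_n) - lambda_n x_n

Every trajectory converges to a unique equilibrium ``e`` in the open unit
cube; the steady-state translation rate is ``R = lambda_n * e_n``, and at
equilibrium all n+1 flux expressions agree:

    lambda_0 (1 - e_1) = lambda_i e_i (1 - e_{i+1}) = lambda_n e_n = R.

Two independent routes to the steady state live here — direct numerical
integration of the ODEs and bisection on the continued-fraction (CF)
equation obtained by eliminating the densities — and serve as oracles for
the spectral route in :mod:`rfmflow.spectral`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .profiles import RateProfile

__all__ = [
    "SteadyState",
    "Trajectory",
    "rfm_rhs",
    "integrate_rfm",
    "steady_state_ode",
    "steady_state_cf",
    "densities_from_rate",
    "equilibrium_densities",
]


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium of one RFM instance.

    Attributes
    ----------
    R
        Steady-state translation rate ``lambda_n * e_n`` (1/time).
    e
        Equilibrium site densities ``(e_1, ..., e_n)``, each in (0, 1).
    method
        Which solver produced it: ``ode``, ``continued_fraction`` or
        ``spectral``.
    residual
        ``|lambda_0 (1 - e_1) - R|``, the entry-flux mismatch.
    """

    R: float
    e: np.ndarray | None
    method: str
    residual: float


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    converged: bool
    final_rate: float


def rfm_rhs(profile: RateProfile, x: np.ndarray) -> np.ndarray:
    """Right-hand side of the RFM ODEs at state ``x = (x_1, ..., x_n)``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (profile.n,):
        raise ValueError(
            f"state has {x.size} entries but profile has n={profile.n} sites"
        )
    lam = profile.rates
    # flux[i] = flow across bond i: lambda_0(1-x_1), interior hops, exit.
    flux = np.empty(profile.n + 1)
    flux[0] = lam[0] * (1.0 - x[0])
    flux[1:-1] = lam[1:-1] * x[:-1] * (1.0 - x[1:])
    flux[-1] = lam[-1] * x[-1]
    return flux[:-1] - flux[1:]


def integrate_rfm(profile: RateProfile, x0, t_final: float,
                  rtol: float = 1e-10, atol: float = 1e-12,
                  conv_tol: float = 1e-9) -> Trajectory:
    """Integrate the RFM from ``x0`` up to ``t_final``.

    Uses a stiff-capable adaptive integrator (LSODA).  The trajectory must
    remain in the unit cube; leaving it beyond integration tolerance is an
    error.  ``converged`` is set when the final infinity norm of the
    vector field drops below ``conv_tol``.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0.0) or np.any(x0 > 1.0):
        raise ValueError("initial state must lie in the unit cube")

    def rhs(_t, x):
        return rfm_rhs(profile, x)

    sol = solve_ivp(rhs, (0.0, t_final), x0, method="LSODA",
                    rtol=rtol, atol=atol, dense_output=False)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"RFM integration failed: {sol.message}")
    slack = 1e3 * max(rtol, atol)
    if sol.y.min() < -slack or sol.y.max() > 1.0 + slack:
        raise RuntimeError("trajectory left the unit cube beyond tolerance")
    states = np.clip(sol.y.T, 0.0, 1.0)
    xf = states[-1]
    converged = bool(np.max(np.abs(rfm_rhs(profile, xf))) < conv_tol)
    return Trajectory(times=sol.t, states=states, converged=converged,
                      final_rate=float(profile.rates[-1] * xf[-1]))


def steady_state_ode(profile: RateProfile, tol: float = 1e-9,
                     max_chunks: int = 40) -> SteadyState:
    """Steady state by integrating the ODEs until the flow stalls.

    Integrates in geometrically growing time chunks from the half-full
    state until ``||dx/dt||_inf < tol``.
    """
    x = np.full(profile.n, 0.5)
    # relaxation time scales inversely with the slowest rate
    t_chunk = 10.0 / float(profile.rates.min())
    for _ in range(max_chunks):
        traj = integrate_rfm(profile, x, t_chunk, conv_tol=tol)
        x = traj.states[-1]
        if traj.converged:
            R = float(profile.rates[-1] * x[-1])
            residual = abs(profile.rates[0] * (1.0 - x[0]) - R)
            return SteadyState(R=R, e=x, method="ode", residual=residual)
        t_chunk *= 2.0
    resid = float(np.max(np.abs(rfm_rhs(profile, x))))
    raise RuntimeError(
        f"ODE steady state did not converge; last ||dx/dt||_inf = {resid:.3e}"
    )


def densities_from_rate(profile: RateProfile, R: float) -> np.ndarray:
    """Backward recursion for the densities given a trial rate ``R``.

    ``e_n = R / lambda_n`` and ``e_i = R / (lambda_i (1 - e_{i+1}))``;
    entries may leave (0, 1) for an infeasible ``R``.
    """
    lam = profile.rates
    n = profile.n
    e = np.empty(n)
    e[n - 1] = R / lam[n]
    for i in range(n - 1, 0, -1):
        denom = lam[i] * (1.0 - e[i])
        if denom <= 0.0:
            e[: i] = np.inf  # infeasible branch; caller treats as e >= 1
            return e
        e[i - 1] = R / denom
    return e


def _rfm_jacobian(profile: RateProfile, x: np.ndarray) -> np.ndarray:
    """Dense Jacobian of the RFM vector field (tridiagonal structure)."""
    lam = profile.rates
    n = profile.n
    J = np.zeros((n, n))
    for i in range(n):
        lo = lam[i] * x[i - 1] if i > 0 else lam[0]
        hi = 1.0 - x[i + 1] if i < n - 1 else 1.0
        J[i, i] = -lo - lam[i + 1] * hi if i > 0 else -lam[0] - lam[1] * hi
        if i > 0:
            J[i, i - 1] = lam[i] * (1.0 - x[i])
        if i < n - 1:
            J[i, i + 1] = lam[i + 1] * x[i]
    return J


def equilibrium_densities(profile: RateProfile, R: float,
                          tol: float = 1e-10) -> np.ndarray:
    """Equilibrium densities for a converged rate ``R``, Newton-polished.

    The backward recursion alone is exponentially unstable whenever
    densities sit near 1 (per-site error amplification
    ``e_i / (1 - e_{i+1}) > 1``), so its output only seeds a Newton solve
    of the full steady-state system; the result is validated against the
    flux-balance relations.
    """
    from scipy.optimize import root

    lam = profile.rates

    def solve_from(x0):
        sol = root(lambda x: rfm_rhs(profile, x), x0,
                   jac=lambda x: _rfm_jacobian(profile, x), method="hybr",
                   tol=1e-13)
        e = sol.x
        flux = np.concatenate((
            [lam[0] * (1.0 - e[0])],
            lam[1:-1] * e[:-1] * (1.0 - e[1:]),
            [lam[-1] * e[-1]],
        ))
        ok = (np.all(e > 0.0) and np.all(e < 1.0)
              and np.max(np.abs(flux - R)) <= tol * max(R, 1.0))
        return ok, e

    seed = densities_from_rate(profile, R)
    x0 = np.where(np.isfinite(seed), np.clip(seed, 1e-9, 1.0 - 1e-9), 0.5)
    ok, e = solve_from(x0)
    if not ok:
        # relax toward the (globally attracting) equilibrium, then re-polish
        traj = integrate_rfm(profile, np.full(profile.n, 0.5),
                             200.0 / float(lam.min()), conv_tol=np.inf)
        ok, e = solve_from(traj.states[-1])
    if not ok:
        raise RuntimeError("density recovery failed the flux-balance check")
    return e


def steady_state_cf(profile: RateProfile, tol: float = 4e-16,
                    with_densities: bool = True) -> SteadyState:
    """Steady state from the continued-fraction equation by bisection.

    Eliminating the densities through the backward recursion turns the
    flux-balance conditions into a single scalar equation
    ``g(R) = lambda_0 (1 - e_1(R)) - R = 0`` on ``(0, min_i lambda_i)``.
    ``g(0+) = lambda_0 > 0`` and any trial ``R`` driving a density to 1 or
    beyond is counted as ``g < 0``, so bisection contracts onto the unique
    feasible root.  ``with_densities=False`` skips the (comparatively
    costly) density recovery when only ``R`` is needed.
    """
    lam = profile.rates
    lo, hi = 0.0, float(lam.min())

    def g_negative(R: float) -> bool:
        e = densities_from_rate(profile, R)
        if not np.all(np.isfinite(e)) or e[0] >= 1.0:
            return True
        return lam[0] * (1.0 - e[0]) - R < 0.0

    if not g_negative(hi * (1.0 - 1e-16)):
        # cannot happen for a valid profile (R < min rate strictly); guard.
        raise RuntimeError("bisection bracket failure: g(min rate) >= 0")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g_negative(mid):
            hi = mid
        else:
            lo = mid
        if hi - lo <= tol * hi:
            break
    R = 0.5 * (lo + hi)
    if not with_densities:
        return SteadyState(R=float(R), e=None, method="continued_fraction",
                           residual=float(hi - lo))
    e = equilibrium_densities(profile, R, tol=1e-7)
    residual = abs(lam[0] * (1.0 - e[0]) - R)
    return SteadyState(R=float(R), e=e, method="continued_fraction",
                       residual=float(residual))
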