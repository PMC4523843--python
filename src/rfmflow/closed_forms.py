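"""Closed-form rates and sensitivities for two special RFM families.

THRFM (totally homogeneous RFM): every rate equals a common value
``lambda_c``.  The spectral matrix is ``lambda_c^{-1/2}`` times a
tridiagonal Toeplitz matrix whose Perron pair is known in closed form
(``rho = 2 cos(theta)``, ``v_j = sin(j theta)`` with
``theta = pi / (n + 3)``), giving

    R   = lambda_c / (4 cos^2 theta)
    s_i = sin((i+1) theta) sin((i+2) theta) / (2 (n+3) cos^3 theta),

independent of ``lambda_c``.  The sensitivity profile is symmetric and
center-peaked; the edge effect ``Delta(n) = s_{floor(n/2)} / s_0`` grows
without bound with ``n``.

HSRFM (homogeneous and symmetric RFM): equal interior rates ``lambda_c``
with boundary rates coupled by ``lambda_0 + lambda_n = lambda_c``; write
``alpha = lambda_0 / lambda_c``.  The Perron pair of the scaled matrix is
analytic: ``rho = (alpha (1 - alpha))^{-1/2}`` with eigenvector
``v_1 = sqrt(alpha) mu``, ``v_j = mu^j`` (interior),
``v_{n+2} = sqrt(1 - alpha) mu^{n+2}``, where
``mu = sqrt(alpha / (1 - alpha))``.  Hence ``R = lambda_c alpha (1-alpha)``
independent of ``n``, interior sensitivities form an exact geometric
sequence with ratio ``alpha / (1 - alpha)``, and — because perturbing
``lambda_0`` forces ``lambda_n = lambda_c - lambda_0`` — the coupled
boundary sensitivities are ``s_0 = 1 - 2 alpha = -s_n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import RateProfile, make_profile
from .spectral import SensitivityProfile, SpectralData, build_matrix

__all__ = [
    "ThrfmSpec",
    "HsrfmSpec",
    "thrfm_rate",
    "thrfm_sensitivities",
    "edge_effect",
    "hsrfm_spectral_pair",
    "hsrfm_rate",
    "hsrfm_sensitivities",
]


@dataclass(frozen=True)
class ThrfmSpec:
    """Totally homogeneous chain: ``n`` sites, common rate ``lambda_c``."""

    n: int
    lambda_c: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.lambda_c > 0:
            raise ValueError("lambda_c must be positive")

    @property
    def theta(self) -> float:
        return np.pi / (self.n + 3)

    def profile(self) -> RateProfile:
        return make_profile("homogeneous", n=self.n, lambda_c=self.lambda_c)


@dataclass(frozen=True)
class HsrfmSpec:
    """Homogeneous-symmetric chain: boundaries coupled by
    ``lambda_0 + lambda_n = lambda_c``."""

    n: int
    lambda_c: float = 1.0
    alpha: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.lambda_c > 0:
            raise ValueError("lambda_c must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def lambda_0(self) -> float:
        return self.alpha * self.lambda_c

    @property
    def lambda_n(self) -> float:
        return (1.0 - self.alpha) * self.lambda_c

    @property
    def mu(self) -> float:
        """Geometric decay ratio of the interior sensitivities,
        ``alpha / (1 - alpha)`` (< 1 iff initiation is rate limiting)."""
        return self.alpha / (1.0 - self.alpha)

    def profile(self) -> RateProfile:
        return make_profile("hsrfm", n=self.n, lambda_c=self.lambda_c,
                            alpha=self.alpha)


# ---------------------------------------------------------------------------
# THRFM


def thrfm_rate(spec: ThrfmSpec) -> float:
    """``R = lambda_c / (4 cos^2(pi/(n+3)))``; decreases to lambda_c/4."""
    return spec.lambda_c / (4.0 * np.cos(spec.theta) ** 2)


def thrfm_sensitivities(spec: ThrfmSpec) -> SensitivityProfile:
    """Closed-form sensitivities of the totally homogeneous chain.

    Independent of ``lambda_c``; symmetric about the chain center where
    the maximum sits.
    """
    th = spec.theta
    i = np.arange(spec.n + 1)
    s = (np.sin((i + 1) * th) * np.sin((i + 2) * th)
         / (2.0 * (spec.n + 3) * np.cos(th) ** 3))
    return SensitivityProfile(s=s, mode="unconstrained", method="closed_form")


def edge_effect(n: int, lambda_c: float = 1.0) -> float:
    """Center-to-edge sensitivity ratio ``Delta(n) = s_{floor(n/2)} / s_0``.

    Quantifies how much more sensitive the translation rate is to a rate
    at the middle of a homogeneous chain than at its 5' edge; strictly
    increasing in ``n`` and unbounded.
    """
    if n < 2:
        raise ValueError("edge effect requires n >= 2")
    s = thrfm_sensitivities(ThrfmSpec(n=n, lambda_c=lambda_c)).s
    return float(s[n // 2] / s[0])


# ---------------------------------------------------------------------------
# HSRFM


def hsrfm_spectral_pair(spec: HsrfmSpec,
                        residual_tol: float = 1e-12) -> SpectralData:
    """Analytic Perron pair of the HSRFM matrix, residual-checked.

    The eigenvector is verified against the matrix (``||Av - zeta v||_inf``
    below ``residual_tol`` after normalization) before being returned, so
    a transcription error in the analytic form cannot pass silently.
    """
    a = spec.alpha
    n = spec.n
    mu = np.sqrt(a / (1.0 - a))
    zeta = (a * (1.0 - a) * spec.lambda_c) ** -0.5
    j = np.arange(1, n + 3)  # 1-based entry indices
    v = mu ** j.astype(float)
    v[0] *= np.sqrt(a)
    v[-1] *= np.sqrt(1.0 - a)
    v = v / np.linalg.norm(v)

    diag, off = build_matrix(spec.profile())
    Av = np.zeros_like(v)
    Av[:-1] += off * v[1:]
    Av[1:] += off * v[:-1]
    resid = np.max(np.abs(Av - zeta * v))
    if resid > residual_tol * zeta:
        raise RuntimeError(
            f"analytic HSRFM eigenpair fails the residual check: {resid:.3e}"
        )
    return SpectralData(dim=n + 2, zeta=float(zeta), v=v)


def hsrfm_rate(spec: HsrfmSpec) -> float:
    """``R = lambda_c * alpha * (1 - alpha)``, independent of ``n``."""
    return spec.lambda_c * spec.alpha * (1.0 - spec.alpha)


def hsrfm_sensitivities(spec: HsrfmSpec,
                        coupled: bool = True) -> SensitivityProfile:
    """Closed-form HSRFM sensitivities.

    Interior entries come from applying the eigenvector sensitivity
    formula to the analytic Perron pair; consecutive interior ratios are
    exactly ``mu = alpha/(1-alpha)``, so ``ln s_i`` is linear inside the
    chain.  With ``coupled=True`` (default) the boundary entries honour
    the ``lambda_0 + lambda_n = lambda_c`` constraint — raising initiation
    lowers termination — giving ``s_0 = 1 - 2 alpha`` and
    ``s_n = -(1 - 2 alpha)``; at ``alpha = 1/2`` the boundaries are
    stationary and the interior is flat at ``1/(4(n+1))``.  With
    ``coupled=False`` all entries are the unconstrained derivatives.
    """
    pair = hsrfm_spectral_pair(spec)
    lam = spec.profile().rates
    v = pair.v
    s = 2.0 * pair.zeta ** -3 * lam ** -1.5 * v[:-1] * v[1:]
    if not coupled:
        return SensitivityProfile(s=s, mode="unconstrained",
                                  method="closed_form")
    s = s.copy()
    s[0] = 1.0 - 2.0 * spec.alpha
    s[-1] = -(1.0 - 2.0 * spec.alpha)
    return SensitivityProfile(s=s, mode="coupled_boundary",
                              method="closed_form")
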