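"""TASEP: stochastic simulation and exact steady-state references.

The totally asymmetric simple exclusion process on an open lattice of
``N`` sites: particles enter site 1 at rate ``lambda_0`` (if free), hop
``i -> i+1`` at rate ``lambda_i`` (if the target is free) and exit from
site ``N`` at rate ``lambda_N``.  Three routes to its steady state live
here:

* :func:`simulate_tasep` — event-driven continuous-time kinetic Monte
  Carlo (Gillespie), numba-jitted, starting from an empty chain with a
  configurable burn-in;
* :func:`master_equation_current` — exact stationary distribution of the
  ``2^N``-state generator (small ``N`` only);
* :func:`exact_current_homogeneous` — the closed-form current of the
  homogeneous open-boundary TASEP, ``J = Z(N-1)/Z(N)`` with the standard
  partition function, evaluated in log-domain so it is stable to
  ``N >= 200``.

These are the references against which the mean-field (RFM) predictions
are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import spsolve
from scipy.special import gammaln, logsumexp

from .profiles import RateProfile

__all__ = [
    "TasepConfig",
    "TasepResult",
    "HomogeneousTasepSpec",
    "simulate_tasep",
    "master_equation_current",
    "exact_current_homogeneous",
    "tasep_sensitivity_fd",
    "exact_current_sensitivity",
]


@dataclass(frozen=True)
class TasepConfig:
    """One simulation setup: rates, event budget, burn-in, seeding."""

    rates: RateProfile
    events: int = 1_000_000
    burn_in: int = 100_000
    seed: int = 0
    replicates: int = 4

    def __post_init__(self):
        if self.events <= 0:
            raise ValueError("event budget must be positive")
        if not 0 <= self.burn_in:
            raise ValueError("burn-in must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class TasepResult:
    """Stationary averages from Monte Carlo.

    ``occupancy`` are time-averaged site densities, ``current`` the exit
    flux J (particles/time) averaged over replicates with standard error
    ``sem``; ``seed`` and ``steps`` record provenance.
    """

    occupancy: np.ndarray
    current: float
    sem: float
    seed: int
    steps: int
    currents: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class HomogeneousTasepSpec:
    """Homogeneous open-boundary TASEP: internal hop rates one, entry
    ``alpha``, exit ``beta``."""

    N: int
    alpha: float
    beta: float

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")

    def profile(self) -> RateProfile:
        rates = np.ones(self.N + 1)
        rates[0] = self.alpha
        rates[-1] = self.beta
        return RateProfile(rates)


# ---------------------------------------------------------------------------
# Kinetic Monte Carlo


@njit(cache=True)
def _kmc(lam, events, burn_in, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = lam.size - 1
    x = np.zeros(N, dtype=np.uint8)
    occ_time = np.zeros(N)
    rates = np.empty(N + 1)
    total_time = 0.0
    exits = 0
    for step in range(burn_in + events):
        # enabled transition rates: 0 entry, 1..N-1 hops, N exit
        rates[0] = lam[0] if x[0] == 0 else 0.0
        for i in range(1, N):
            rates[i] = lam[i] if (x[i - 1] == 1 and x[i] == 0) else 0.0
        rates[N] = lam[N] if x[N - 1] == 1 else 0.0
        rtot = 0.0
        for i in range(N + 1):
            rtot += rates[i]
        dt = np.random.exponential(1.0 / rtot)
        recording = step >= burn_in
        if recording:
            total_time += dt
            for i in range(N):
                if x[i] == 1:
                    occ_time[i] += dt
        u = np.random.random() * rtot
        acc = 0.0
        k = N
        for i in range(N + 1):
            acc += rates[i]
            if u < acc:
                k = i
                break
        if k == 0:
            x[0] = 1
        elif k == N:
            x[N - 1] = 0
            if recording:
                exits += 1
        else:
            x[k - 1] = 0
            x[k] = 1
    return occ_time, total_time, exits


def _replicate_seeds(seed: int, replicates: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return np.array([int(s) % (2**31 - 1)
                     for s in ss.generate_state(replicates)], dtype=np.int64)


def simulate_tasep(config: TasepConfig) -> TasepResult:
    """Continuous-time KMC of the exclusion process from an empty chain.

    Runs ``config.replicates`` independent chains; the current is the
    post-burn-in exit count per unit time, and ``sem`` its standard error
    across replicates.  Fixed ``seed`` gives bit-identical results.
    """
    lam = config.rates.rates
    N = config.rates.n
    seeds = _replicate_seeds(config.seed, config.replicates)
    occ = np.zeros(N)
    currents = np.empty(config.replicates)
    for r, s in enumerate(seeds):
        occ_time, total_time, exits = _kmc(lam, config.events,
                                           config.burn_in, s)
        occ += occ_time / total_time
        currents[r] = exits / total_time
    occ /= config.replicates
    J = float(currents.mean())
    sem = float(currents.std(ddof=1) / np.sqrt(config.replicates)) \
        if config.replicates > 1 else float("nan")
    return TasepResult(occupancy=occ, current=J, sem=sem, seed=config.seed,
                       steps=config.events * config.replicates,
                       currents=currents)


# ---------------------------------------------------------------------------
# Exact references


def master_equation_current(rates: RateProfile, cap: int = 12):
    """Exact stationary current and occupancies from the 2^N master equation.

    Builds the continuous-time generator over all ``2^N`` occupation
    configurations, solves for the stationary distribution, and returns
    ``(J, occupancy)`` with ``J`` the expected exit flux.  The exponential
    state space limits this to short chains (default cap ``N <= 12``).
    """
    N = rates.n
    if N > cap:
        raise ValueError(f"master equation limited to N <= {cap} (got {N})")
    lam = rates.rates
    nstates = 1 << N
    rows, cols, vals = [], [], []

    def add(src, dst, rate):
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for s in range(nstates):
        if not s & 1:  # site 1 free -> entry
            add(s, s | 1, lam[0])
        for i in range(1, N):  # hop site i -> i+1 (bits i-1 -> i)
            if (s >> (i - 1)) & 1 and not (s >> i) & 1:
                add(s, s ^ (1 << (i - 1)) ^ (1 << i), lam[i])
        if (s >> (N - 1)) & 1:  # exit
            add(s, s ^ (1 << (N - 1)), lam[N])

    Q = csc_matrix((vals, (rows, cols)), shape=(nstates, nstates)).tolil()
    # replace the last balance equation with the normalization sum(pi) = 1
    Q[nstates - 1, :] = 1.0
    b = np.zeros(nstates)
    b[-1] = 1.0
    pi = spsolve(Q.tocsc(), b)
    occ = np.array([
        pi[(np.arange(nstates) >> i) & 1 == 1].sum() for i in range(N)
    ])
    J = float(lam[N] * occ[N - 1])
    return J, occ


def _log_partition(N: int, alpha: float, beta: float) -> float:
    """log Z_N of the homogeneous open-boundary TASEP.

    Z_N = sum_{p=1}^{N} p (2N-1-p)! / (N! (N-p)!) *
          (beta^{-p-1} - alpha^{-p-1}) / (beta^{-1} - alpha^{-1}),
    with the last quotient expanded as the geometric sum
    sum_{k=0}^{p} alpha^{-(p-k)} beta^{-k} — positive termwise and valid
    in the alpha = beta limit — so the whole sum is a log-sum-exp.
    """
    if N == 0:
        return 0.0
    la, lb = np.log(alpha), np.log(beta)
    terms = []
    for p in range(1, N + 1):
        logc = (np.log(p) + gammaln(2 * N - p) - gammaln(N + 1)
                - gammaln(N - p + 1))
        k = np.arange(p + 1)
        logq = logsumexp(-(p - k) * la - k * lb)
        terms.append(logc + logq)
    return float(logsumexp(terms))


def exact_current_homogeneous(spec: HomogeneousTasepSpec) -> float:
    """Closed-form stationary current ``J = Z(N-1)/Z(N)``.

    Log-domain evaluation keeps the factorial/boundary-fugacity products
    finite for ``N`` of at least several hundred.
    """
    lz_n = _log_partition(spec.N, spec.alpha, spec.beta)
    lz_nm1 = _log_partition(spec.N - 1, spec.alpha, spec.beta)
    return float(np.exp(lz_nm1 - lz_n))


# ---------------------------------------------------------------------------
# Sensitivities


def tasep_sensitivity_fd(config: TasepConfig, which_rate: int,
                         delta: float, common_random_numbers: bool = True):
    """Monte-Carlo estimate of ``dJ/d lambda_i`` by paired simulation.

    Per replicate, simulates the nominal and the perturbed chain
    (``lambda_i + delta``) — with the same RNG seed when
    ``common_random_numbers`` — and averages ``(J' - J)/delta``.  Returns
    ``(mean, sem)``.  The estimate is noise-dominated for small ``delta``:
    the induced change in J is easily masked by the inherent stochasticity
    of the process, which is why exact references exist alongside.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if config.replicates < 2:
        raise ValueError("need >= 2 replicates for an error bar")
    lam = config.rates
    pert = lam.perturbed(which_rate, delta=delta)
    seeds = _replicate_seeds(config.seed, config.replicates)
    diffs = np.empty(config.replicates)
    for r, s in enumerate(seeds):
        s2 = s if common_random_numbers else (s + 7919) % (2**31 - 1)
        _, t0, ex0 = _kmc(lam.rates, config.events, config.burn_in, s)
        _, t1, ex1 = _kmc(pert.rates, config.events, config.burn_in, s2)
        diffs[r] = (ex1 / t1 - ex0 / t0) / delta
    mean = float(diffs.mean())
    sem = float(diffs.std(ddof=1) / np.sqrt(config.replicates))
    return mean, sem


def exact_current_sensitivity(spec: HomogeneousTasepSpec,
                              delta: float = 1e-6) -> float:
    """Deterministic ``dJ/d alpha`` by central differencing the exact current."""
    if spec.alpha - delta <= 0:
        raise ValueError("delta must be smaller than alpha")
    up = exact_current_homogeneous(
        HomogeneousTasepSpec(spec.N, spec.alpha + delta, spec.beta))
    dn = exact_current_homogeneous(
        HomogeneousTasepSpec(spec.N, spec.alpha - delta, spec.beta))
    return (up - dn) / (2.0 * delta)
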