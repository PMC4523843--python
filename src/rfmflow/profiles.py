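"""Rate profiles for the ribosome flow model (RFM) and TASEP.

An RFM/TASEP instance with ``n`` sites is defined by ``n + 1`` positive
rates ``(lambda_0, ..., lambda_n)``: ``lambda_0`` is the initiation (entry)
rate, ``lambda_1 ... lambda_{n-1}`` are elongation (hop) rates, and
``lambda_n`` is the termination (exit) rate.  Rates carry units of 1/time.

This module provides the :class:`RateProfile` container, TSV serialization
(two columns ``index`` and ``rate``, '#' comments), and the synthetic
profile generators used throughout: homogeneous chains, the
homogeneous-symmetric (HSRFM) boundary pattern, slow-codon clusters, and
seeded random log-uniform profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RateProfile", "read_profile", "write_profile", "make_profile"]


@dataclass(frozen=True)
class RateProfile:
    """Ordered rates ``(lambda_0, ..., lambda_n)`` of an n-site chain.

    Parameters
    ----------
    rates
        Sequence of ``n + 1`` strictly positive finite reals, 1/time.
        ``rates[0]`` is initiation, ``rates[-1]`` termination.
    """

    rates: np.ndarray = field()

    def __init__(self, rates) -> None:
        arr = np.asarray(rates, dtype=float).copy()
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(
                "a rate profile needs at least two rates (n >= 1 sites)"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
            raise ValueError("all rates must be strictly positive and finite")
        arr.flags.writeable = False
        object.__setattr__(self, "rates", arr)

    @property
    def n(self) -> int:
        """Number of sites (one less than the number of rates)."""
        return self.rates.size - 1

    def __len__(self) -> int:
        return self.rates.size

    def __getitem__(self, i):
        return self.rates[i]

    def reversed(self) -> "RateProfile":
        """Profile with the rate order flipped, ``(lambda_n, ..., lambda_0)``.

        The steady-state translation rate is invariant under this reversal
        (the particle-hole / left-right symmetry of the model).
        """
        return RateProfile(self.rates[::-1])

    def perturbed(self, i: int, factor: float | None = None,
                  delta: float | None = None) -> "RateProfile":
        """Copy with rate ``i`` multiplied by ``factor`` or shifted by ``delta``."""
        new = self.rates.copy()
        if factor is not None:
            new[i] *= factor
        if delta is not None:
            new[i] += delta
        return RateProfile(new)


# ---------------------------------------------------------------------------
# TSV serialization


def write_profile(profile: RateProfile, path) -> None:
    """Write a profile as two-column TSV (``index<TAB>rate``), full precision."""
    path = Path(path)
    lines = ["index\trate"]
    for i, lam in enumerate(profile.rates):
        lines.append(f"{i}\t{lam:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path) -> RateProfile:
    """Read a two-column TSV profile; '#' lines are comments.

    Raises
    ------
    ValueError
        On a malformed line, non-contiguous indices, or a non-positive
        rate; the message names the offending line number.
    """
    path = Path(path)
    indices: list[int] = []
    rates: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols[:2] != ["index", "rate"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header 'index<TAB>rate'"
                )
            header_seen = True
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            idx = int(cols[0])
            lam = float(cols[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparsable entry ({exc})") from None
        if not np.isfinite(lam) or lam <= 0.0:
            raise ValueError(f"{path}:{lineno}: rate must be positive and finite")
        indices.append(idx)
        rates.append(lam)
    if not header_seen:
        raise ValueError(f"{path}: missing 'index<TAB>rate' header")
    if indices != list(range(len(indices))):
        raise ValueError(f"{path}: indices must be contiguous from 0")
    return RateProfile(rates)


# ---------------------------------------------------------------------------
# Synthetic profile generators


def make_profile(kind: str, *, n: int, lambda_c: float = 1.0,
                 lambda_0: float | None = None, lambda_n: float | None = None,
                 alpha: float | None = None,
                 center: int | None = None, width: int = 1, q: float = 0.5,
                 low: float = 0.1, high: float = 10.0,
                 seed: int | None = None) -> RateProfile:
    """Build one of the standard synthetic rate profiles.

    Parameters
    ----------
    kind
        ``homogeneous`` — all rates ``lambda_c``, with optional distinct
        boundary rates ``lambda_0`` / ``lambda_n``.
        ``hsrfm`` — interior rates ``lambda_c`` with coupled boundaries
        ``lambda_0 = alpha * lambda_c`` and ``lambda_n = (1 - alpha) * lambda_c``.
        ``slow_cluster`` — homogeneous chain with a contiguous block of
        ``width`` rates around ``center`` set to ``q`` (a slow-codon cluster).
        ``random_loguniform`` — rates drawn log-uniformly from
        ``[low, high]`` with the given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "homogeneous":
        rates = np.full(n + 1, float(lambda_c))
        if lambda_0 is not None:
            rates[0] = lambda_0
        if lambda_n is not None:
            rates[-1] = lambda_n
        return RateProfile(rates)
    if kind == "hsrfm":
        if alpha is None or not 0.0 < alpha < 1.0:
            raise ValueError("hsrfm requires 0 < alpha < 1")
        rates = np.full(n + 1, float(lambda_c))
        rates[0] = alpha * lambda_c
        rates[-1] = (1.0 - alpha) * lambda_c
        return RateProfile(rates)
    if kind == "slow_cluster":
        if center is None:
            center = n // 2
        lo = center - (width - 1) // 2
        hi = lo + width  # rates lo .. hi-1 are slowed
        if lo < 0 or hi > n + 1:
            raise ValueError("slow cluster falls outside the rate index range 0..n")
        rates = np.full(n + 1, float(lambda_c))
        rates[lo:hi] = q
        return RateProfile(rates)
    if kind == "random_loguniform":
        rng = np.random.default_rng(seed)
        rates = np.exp(rng.uniform(np.log(low), np.log(high), size=n + 1))
        return RateProfile(rates)
    raise ValueError(f"unknown profile kind: {kind!r}")
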