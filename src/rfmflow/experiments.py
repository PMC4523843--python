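"""Experiment drivers: regenerate the standard figure-style analyses.

Each experiment writes a TSV result table plus a JSON provenance sidecar
(config echo, seeds, package version) to an output directory.  Default
parameters match the canonical setups (n = 1000 slow-codon scan, n = 200
sensitivity profiles, N = n = 30 / beta = 0.3 RFM-vs-TASEP comparison) but
every scale knob is configurable so the same shapes can be reproduced
cheaply.  Plotting is a cosmetic optional layer; no result depends on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .closed_forms import (HsrfmSpec, ThrfmSpec, hsrfm_sensitivities,
                           thrfm_rate, thrfm_sensitivities)
from .profiles import RateProfile, make_profile
from .spectral import sensitivities_spectral, translation_rate_spectral
from .tasep import (HomogeneousTasepSpec, TasepConfig,
                    exact_current_sensitivity)

__all__ = ["EXPERIMENTS", "run_experiment"]


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.12g}" if isinstance(v, float) else str(v)
                for v in row) + "\n")


def _sidecar(path: Path, experiment: str, params: dict) -> None:
    meta = {"experiment": experiment, "params": params,
            "rfmflow_version": __version__}
    path.write_text(json.dumps(meta, indent=2, default=str) + "\n")


def slow_codon_scan(outdir: Path, *, n: int = 1000,
                    widths=(1, 2, 3), q_grid=None, **_) -> Path:
    """Translation rate vs slow-cluster rate q, for several cluster widths.

    A contiguous block of slow rates at the chain center; R increases
    with q and decreases with cluster width.
    """
    if q_grid is None:
        q_grid = np.linspace(0.1, 1.0, 19)
    rows = []
    for w in widths:
        for q in q_grid:
            prof = make_profile("slow_cluster", n=n, center=n // 2,
                                width=int(w), q=float(q))
            rows.append((int(w), float(q),
                         translation_rate_spectral(prof).R))
    out = outdir / "slow_codon_scan.tsv"
    _write_tsv(out, ["width", "q", "R"], rows)
    _sidecar(outdir / "slow_codon_scan.json", "slow_codon_scan",
             {"n": n, "widths": list(widths), "q_grid": list(map(float, q_grid))})
    return out


def sensitivity_profile(outdir: Path, *, n: int = 200, lambda_c: float = 1.0,
                        lambda_0: float | None = None,
                        lambda_n: float | None = None,
                        profile: RateProfile | None = None, **_) -> Path:
    """Sensitivities s_i (and ln s_i) along one profile."""
    if profile is None:
        profile = make_profile("homogeneous", n=n, lambda_c=lambda_c,
                               lambda_0=lambda_0, lambda_n=lambda_n)
    s = sensitivities_spectral(profile).s
    rows = [(i, float(si), float(np.log(si))) for i, si in enumerate(s)]
    out = outdir / "sensitivity_profile.tsv"
    _write_tsv(out, ["i", "s_i", "ln_s_i"], rows)
    _sidecar(outdir / "sensitivity_profile.json", "sensitivity_profile",
             {"n": profile.n, "rates_head": profile.rates[:3].tolist(),
              "rates_tail": profile.rates[-3:].tolist()})
    return out


def thrfm_compare(outdir: Path, *, n: int = 10, lambda_c: float = 1.0,
                  with_tasep: bool = False, events: int = 200_000,
                  replicates: int = 4, seed: int = 0, **_) -> Path:
    """Closed-form vs spectral THRFM sensitivities, optionally vs TASEP MC."""
    spec = ThrfmSpec(n=n, lambda_c=lambda_c)
    closed = thrfm_sensitivities(spec).s
    numeric = sensitivities_spectral(spec.profile()).s
    rows = []
    for i in range(n + 1):
        rows.append([i, float(closed[i]), float(numeric[i])])
    header = ["i", "s_closed_form", "s_spectral"]
    if with_tasep:
        from .tasep import tasep_sensitivity_fd
        cfg = TasepConfig(rates=spec.profile(), events=events,
                          burn_in=events // 10, seed=seed,
                          replicates=replicates)
        header += ["s_tasep_mc", "s_tasep_sem"]
        for i in range(n + 1):
            m, sem = tasep_sensitivity_fd(cfg, i, delta=0.1 * lambda_c)
            rows[i] += [float(m), float(sem)]
    out = outdir / "thrfm_compare.tsv"
    _write_tsv(out, header, rows)
    _sidecar(outdir / "thrfm_compare.json", "thrfm_compare",
             {"n": n, "lambda_c": lambda_c, "with_tasep": with_tasep,
              "events": events, "replicates": replicates, "seed": seed,
              "R_closed_form": thrfm_rate(spec)})
    return out


def hsrfm_compare(outdir: Path, *, n: int = 10, lambda_c: float = 1.0,
                  alpha: float = 0.3, **_) -> Path:
    """Closed-form HSRFM sensitivities vs the numeric spectral path."""
    spec = HsrfmSpec(n=n, lambda_c=lambda_c, alpha=alpha)
    closed = hsrfm_sensitivities(spec).s
    unconstrained = sensitivities_spectral(spec.profile()).s
    rows = [(i, float(closed[i]), float(unconstrained[i]))
            for i in range(n + 1)]
    out = outdir / "hsrfm_compare.tsv"
    _write_tsv(out, ["i", "s_closed_coupled", "s_spectral_unconstrained"], rows)
    _sidecar(outdir / "hsrfm_compare.json", "hsrfm_compare",
             {"n": n, "lambda_c": lambda_c, "alpha": alpha})
    return out


def rfm_vs_tasep(outdir: Path, *, N: int = 30, beta: float = 0.3,
                 alpha_grid=None, delta: float = 1e-4, **_) -> Path:
    """Mean-field vs exact-TASEP initiation sensitivity across alpha.

    Compares dR/d lambda_0 of the RFM with n = N against the deterministic
    dJ/d alpha of the homogeneous TASEP; the two agree away from the
    alpha = beta phase-transition line and deviate near it.
    """
    if alpha_grid is None:
        alpha_grid = np.arange(0.05, 0.51, 0.05)
    rows = []
    for a in alpha_grid:
        prof = make_profile("homogeneous", n=N, lambda_c=1.0,
                            lambda_0=float(a), lambda_n=beta)
        s0 = float(sensitivities_spectral(prof).s[0])
        dj = exact_current_sensitivity(
            HomogeneousTasepSpec(N=N, alpha=float(a), beta=beta), delta=delta)
        rows.append((float(a), s0, float(dj)))
    out = outdir / "rfm_vs_tasep.tsv"
    _write_tsv(out, ["alpha", "rfm_s0", "tasep_dJ_dalpha"], rows)
    _sidecar(outdir / "rfm_vs_tasep.json", "rfm_vs_tasep",
             {"N": N, "beta": beta, "alpha_grid": list(map(float, alpha_grid)),
              "delta": delta})
    return out


EXPERIMENTS = {
    "slow_codon_scan": slow_codon_scan,
    "sensitivity_profile": sensitivity_profile,
    "thrfm_compare": thrfm_compare,
    "hsrfm_compare": hsrfm_compare,
    "rfm_vs_tasep": rfm_vs_tasep,
}


def run_experiment(experiment: str, outdir, plot: bool = False,
                   **params) -> Path:
    """Run one named experiment; returns the path of its TSV table."""
    try:
        fn = EXPERIMENTS[experiment]
    except KeyError:
        raise ValueError(
            f"unknown experiment {experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}") from None
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = fn(outdir, **params)
    if plot:
        plot_table(table)
    return table


def plot_table(tsv_path: Path) -> Path:
    """Cosmetic line plot of a result table (columns 2.. against column 1)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.genfromtxt(tsv_path, delimiter="\t", names=True)
    names = data.dtype.names
    fig, ax = plt.subplots()
    for col in names[1:]:
        ax.plot(data[names[0]], data[col], marker=".", label=col)
    ax.set_xlabel(names[0])
    ax.legend()
    out = Path(tsv_path).with_suffix(".png")
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
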