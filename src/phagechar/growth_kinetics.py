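"""One-step growth parameter estimation: latent period, burst time, burst size.

The one-step growth assay follows a synchronized single infection cycle:
plaque-forming units per ml stay at the initially infected cell count during
the latent period, rise as cells lyse, and plateau once the burst is
complete.  The estimator fits a three-phase model (flat / log-linear rise /
flat) in log10 titer by exhaustive grid search over breakpoint pairs on the
sampling grid.  Burst size follows the assay's own definition: mean plateau
titer divided by mean pre-rise titer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, FlatCurveError


@dataclass
class GrowthCurve:
    """A PFU(t) time series; ``times`` in minutes starting at 0, strictly increasing."""

    times: np.ndarray
    titers: np.ndarray
    n0: float | None = None   # initially infected cells per ml; pre-rise mean when None
    moi: float = 0.01

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.asarray(self.titers, dtype=float)
        if self.times.shape != self.titers.shape or self.times.size < 5:
            raise ValueError("need matched times/titers with at least 5 samples")
        if self.times[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.titers <= 0):
            raise ValueError("titers must be positive")


@dataclass
class GrowthParams:
    """Estimated (or generating) one-step growth parameters."""

    latent_min: float
    burst_time_min: float
    burst_size: float
    fit_rss: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.latent_min < self.burst_time_min):
            raise ValueError("require 0 <= latent < burst_time")
        if self.burst_size < 1:
            raise ValueError("burst size must be >= 1")


def estimate_growth_params(curve: GrowthCurve, grid_dt: float | None = None) -> GrowthParams:
    """Fit the three-phase model and return the growth parameters.

    Breakpoints are restricted to observed time points (optionally thinned to
    a ``grid_dt`` subgrid); every admissible pair leaving >= 2 samples in each
    phase is scored by residual sum of squares in log10 space.  The latent
    period is the first breakpoint, the burst time the second; burst size is
    ``mean(plateau titers) / mean(pre-rise titers)`` with the pre-rise phase
    excluding the first breakpoint sample and the plateau including every
    sample from the second breakpoint on.  Ties break toward the earliest
    breakpoint pair.
    """
    t, y = curve.times, curve.titers
    if y.max() < 2.0 * y[0]:
        raise FlatCurveError("titers never exceed twice the initial value; no rise to fit")
    logy = np.log10(y)
    grid = t if grid_dt is None else t[np.isclose(np.mod(t, grid_dt), 0)
                                       | np.isclose(np.mod(t, grid_dt), grid_dt)]
    best: tuple[float, float, float] | None = None  # (rss, latent, burst_time)
    for ai in range(len(grid)):
        for bi in range(ai + 1, len(grid)):
            latent, burst = grid[ai], grid[bi]
            pre = t < latent
            rise = (t >= latent) & (t < burst)
            plat = t >= burst
            if pre.sum() < 2 or rise.sum() < 2 or plat.sum() < 2:
                continue
            lo = logy[pre].mean()
            hi = logy[plat].mean()
            model = np.where(
                pre, lo,
                np.where(plat, hi, lo + (hi - lo) * (t - latent) / (burst - latent)),
            )
            rss = float(((logy - model) ** 2).sum())
            if best is None or rss < best[0] - 1e-12:
                best = (rss, float(latent), float(burst))
    if best is None:
        raise DegenerateFitError("no breakpoint pair leaves >= 2 samples per phase")
    rss, latent, burst = best
    pre_mean = y[t < latent].mean()
    plat_mean = y[t >= burst].mean()
    return GrowthParams(latent_min=latent, burst_time_min=burst,
                        burst_size=float(plat_mean / pre_mean), fit_rss=rss)


def _fmt(x: float) -> str:
    r = round(x, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


def summarize_replicates(replicates: list[GrowthParams]) -> dict[str, tuple[float, float, str]]:
    """Per-parameter mean and sample standard deviation over replicates,
    with a ``"mean ± sd"`` display string (the assay's reporting convention)."""
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to summarize")
    out: dict[str, tuple[float, float, str]] = {}
    for name in ("burst_size", "latent_min", "burst_time_min"):
        vals = np.array([getattr(r, name) for r in replicates], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        out[name] = (mean, sd, f"{_fmt(mean)} ± {_fmt(sd)}")
    return out
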