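"""Linkage disequilibrium: pairwise r², Hill–Weir decay fitting and rolling
LD evolution along chromosomes.

r² is the squared correlation of allele dosages (AA=0, AB=1, BB=2) over
pairwise-complete samples — the composite, genotype-based measure, which for
near-inbred RILs is essentially the haplotype measure.  The expected decay
of r² with recombination-scale parameter C = a·d and sample size n follows
Hill and Weir:

    E[r²] = (10+C) / ((2+C)(11+C)) * [1 + (3+C)(12+12C+C²) / (n(2+C)(11+C))]

with a single free coefficient a (per-bp recombination scale) fitted by
nonlinear least squares.  The decay distance is the smallest d where the
fitted curve crosses a threshold (0.2 by convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import GenotypeMatrix, PhysicalMap

__all__ = ["LDMatrix", "pairwise_r2", "hill_weir_expectation", "HillWeirFit",
           "fit_hill_weir", "decay_distance", "ld_evolution", "FitError"]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    def __init__(self, msg, best_a=None, diagnostics=None):
        super().__init__(msg)
        self.best_a = best_a
        self.diagnostics = diagnostics


@dataclass
class LDMatrix:
    """Symmetric pairwise r² for the placed markers of one chromosome."""

    chromosome: str
    marker_ids: np.ndarray
    positions: np.ndarray
    r2: np.ndarray        # (m, m), NaN where undefined
    n_samples: np.ndarray  # (m, m) pairwise-complete counts

    def pairs(self) -> pd.DataFrame:
        """Upper-triangular (distance_bp, r2) pairs, defined entries only."""
        iu = np.triu_indices(len(self.positions), k=1)
        d = np.abs(self.positions[iu[0]] - self.positions[iu[1]])
        r2 = self.r2[iu]
        ok = np.isfinite(r2)
        return pd.DataFrame({"distance": d[ok], "r2": r2[ok]})


def pairwise_r2(G: GenotypeMatrix, pmap: PhysicalMap, chromosome: str,
                min_samples: int = 10) -> LDMatrix:
    """Pairwise-complete squared dosage correlation for the placed markers
    on one chromosome.  Pairs with fewer than ``min_samples`` complete
    samples, and pairs involving a (conditionally) monomorphic marker, are
    reported missing (NaN), never 0."""
    tab = pmap.table[pmap.table["chromosome"] == chromosome]
    keep = [m for m in tab.index if m in set(G.marker_ids)]
    if len(keep) < 2:
        raise ValueError(f"fewer than two placed markers on {chromosome}")
    tab = tab.loc[keep].sort_values("position")
    sub = G.take_markers(G.marker_index(tab.index))
    d = sub.dosage()
    valid = np.isfinite(d).astype(float)
    x = np.nan_to_num(d)

    n = valid.T @ valid
    sx = x.T @ valid
    sxx = (x * x).T @ valid
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_i = sxx / n - (sx / n) ** 2
        var_j = var_i.T
        r2 = cov ** 2 / (var_i * var_j)
    r2[n < min_samples] = np.nan
    r2[(var_i <= 1e-12) | (var_j <= 1e-12)] = np.nan
    np.fill_diagonal(r2, np.where(np.isfinite(np.diag(r2)), 1.0, np.nan))
    return LDMatrix(chromosome, tab.index.to_numpy(object),
                    tab["position"].to_numpy(float), r2, n.astype(int))


def hill_weir_expectation(d, a: float, n: int) -> np.ndarray:
    """Expected r² at distance d for recombination scale C = a*d and sample
    size n."""
    C = np.asarray(d, dtype=float) * a
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + (3.0 + C) * (12.0 + 12.0 * C + C * C) / (n * (2.0 + C) * (11.0 + C))
    return base * corr


@dataclass
class HillWeirFit:
    a: float               # recombination scale per unit distance (C = a*d)
    n: int
    rss: float
    n_pairs: int
    boundary: bool = False  # a pinned at the 0 boundary
    distance_unit: str = "bp"

    def predict(self, d) -> np.ndarray:
        return hill_weir_expectation(d, self.a, self.n)

    def decay_distance(self, threshold: float = 0.2) -> float:
        return decay_distance(self, threshold)


def fit_hill_weir(pairs, n: int, *, r2=None) -> HillWeirFit:
    """Fit the decay coefficient ``a`` (with C = a·d) by nonlinear least
    squares over a >= 0.

    ``pairs`` is a DataFrame with columns distance/r2, or an array of
    distances when ``r2`` is given separately.
    """
    if r2 is None:
        d = np.asarray(pairs["distance"], float)
        y = np.asarray(pairs["r2"], float)
    else:
        d = np.asarray(pairs, float)
        y = np.asarray(r2, float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < 10 or len(np.unique(d)) < 2:
        raise ValueError("need >= 10 pairs spanning more than one distance")

    def resid(loga):
        return hill_weir_expectation(d, np.exp(loga[0]), n) - y

    # coarse log-grid start, then refine; a=0 handled as a boundary case
    grid = np.concatenate([[0.0], np.geomspace(1e-3 / d.max(), 1e4 / d.max(), 60)])
    sses = [float(np.sum((hill_weir_expectation(d, a, n) - y) ** 2)) for a in grid]
    a0 = grid[int(np.argmin(sses))]
    if a0 == 0.0:
        plateau = hill_weir_expectation(0.0, 0.0, n)
        warnings.warn("LD does not decay with distance; a pinned at 0 "
                      f"(plateau E[r2]={plateau:.3f})", stacklevel=2)
        return HillWeirFit(0.0, n, min(sses), len(d), boundary=True)
    sol = optimize.least_squares(resid, x0=[np.log(a0)], method="lm", max_nfev=2000)
    if not sol.success:
        raise FitError("Hill–Weir fit did not converge",
                       best_a=float(np.exp(sol.x[0])),
                       diagnostics={"status": sol.status, "msg": sol.message})
    a = float(np.exp(sol.x[0]))
    return HillWeirFit(a, n, float(np.sum(sol.fun ** 2)), len(d))


def decay_distance(fit: HillWeirFit, threshold: float = 0.2,
                   d_max: float = 1e12) -> float:
    """Smallest distance where the fitted curve falls to ``threshold``,
    by monotone bisection; inf when the curve never crosses."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    f0 = float(fit.predict(0.0))
    if f0 <= threshold:
        return 0.0
    if fit.a <= 0 or float(fit.predict(d_max)) > threshold:
        warnings.warn("fitted LD curve never crosses the threshold", stacklevel=2)
        return np.inf
    lo, hi = 0.0, 1.0
    while float(fit.predict(hi)) > threshold and hi < d_max:
        hi *= 2.0
    return float(optimize.brentq(lambda d: float(fit.predict(d)) - threshold,
                                 lo, min(hi, d_max), xtol=1e-9, rtol=1e-14))


def ld_evolution(ldm: LDMatrix, radius: float = 500_000.0,
                 window: int = 30) -> pd.DataFrame:
    """Two-stage smoothed LD profile along a chromosome.

    Stage 1: per marker, the mean r² to all other markers within ``radius``
    bp (self excluded); markers without any neighbor in range stay missing
    and are excluded from stage 2.  Stage 2: centered rolling mean over
    ``window`` consecutive markers in map order, truncated at the edges.
    """
    m = len(ldm.positions)
    local = np.full(m, np.nan)
    pos = ldm.positions
    for i in range(m):
        near = np.abs(pos - pos[i]) <= radius
        near[i] = False
        vals = ldm.r2[i, near]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            local[i] = float(np.mean(vals))
    out = pd.DataFrame({"marker": ldm.marker_ids, "position": pos,
                        "ld_local": local})
    informative = out.dropna(subset=["ld_local"]).copy()
    if len(informative) < window:
        warnings.warn(f"{ldm.chromosome}: fewer informative markers than the "
                      "window; profile returned unsmoothed", stacklevel=2)
        informative["ld_smooth"] = informative["ld_local"]
    else:
        informative["ld_smooth"] = (informative["ld_local"]
                                    .rolling(window, center=True, min_periods=1)
                                    .mean())
    return out.merge(informative[["marker", "ld_smooth"]], on="marker", how="left")
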