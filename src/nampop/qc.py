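"""Genotype quality control and marker summary statistics.

Filters follow the array-QC conventions for RIL populations: samples with a
call rate below 80% or heterozygosity above 20% are dropped first, then
markers are filtered by the same thresholds computed on the retained
samples.  Thresholds are strict as printed ("less than 80%", "more than
20%"): boundary values are retained.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PhysicalMap

__all__ = [
    "filter_samples", "filter_markers", "family_stats", "maf_spectrum",
    "family_intersections", "polymorphic_sets", "snp_density_bins",
]

log = logging.getLogger(__name__)


def _rates(calls: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """(call rate, het fraction among non-missing) along the given axis."""
    n = calls.shape[axis]
    nonmiss = (calls != MISSING).sum(axis=axis)
    het = (calls == 1).sum(axis=axis)
    call_rate = nonmiss / n if n else np.zeros_like(nonmiss, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(nonmiss > 0, het / nonmiss, 0.0)
    return call_rate, het_frac


def filter_samples(G: GenotypeMatrix, min_call_fraction: float = 0.8,
                   max_het_fraction: float = 0.2,
                   ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples with call rate < ``min_call_fraction`` or heterozygosity
    (AB among non-missing calls) > ``max_het_fraction``."""
    call_rate, het = _rates(G.calls, axis=1)
    low_call = call_rate < min_call_fraction
    high_het = het > max_het_fraction
    drop = low_call | high_het
    removed = pd.DataFrame({
        "sample": G.sample_ids[drop],
        "call_rate": call_rate[drop],
        "het_fraction": het[drop],
        "reason": np.where(low_call[drop], "low_call_rate", "high_heterozygosity"),
    })
    out = G.take_samples(~drop)
    if out.n_samples == 0:
        warnings.warn("all samples removed by sample filter", stacklevel=2)
    return out, removed


def filter_markers(G: GenotypeMatrix, min_call_fraction: float = 0.8,
                   max_het_fraction: float = 0.2,
                   ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers genotyped in < ``min_call_fraction`` of samples or
    heterozygous in > ``max_het_fraction``; apply after the sample filter."""
    call_rate, het = _rates(G.calls, axis=0)
    low_call = call_rate < min_call_fraction
    high_het = het > max_het_fraction
    drop = low_call | high_het
    removed = pd.DataFrame({
        "marker": G.marker_ids[drop],
        "call_rate": call_rate[drop],
        "het_fraction": het[drop],
        "reason": np.where(low_call[drop], "low_call_rate", "high_heterozygosity"),
    })
    out = G.take_markers(~drop)
    if out.n_markers == 0:
        warnings.warn("all markers removed by marker filter", stacklevel=2)
    return out, removed


def _polymorphic_mask(calls: np.ndarray) -> np.ndarray:
    """Marker is polymorphic if a homozygote class plus a different call
    class is observed (AA+BB, AA+AB or BB+AB) among non-missing calls."""
    has_aa = (calls == 0).any(axis=0)
    has_ab = (calls == 1).any(axis=0)
    has_bb = (calls == 2).any(axis=0)
    return (has_aa & has_bb) | (has_aa & has_ab) | (has_bb & has_ab)


def polymorphic_sets(G: GenotypeMatrix) -> dict[str, set]:
    """Per family, the set of markers polymorphic among that family's RILs."""
    out: dict[str, set] = {}
    for fam in pd.unique(G.families[G.ril_mask()]):
        sub = G.select_family(fam)
        mask = _polymorphic_mask(sub.calls)
        out[fam] = set(G.marker_ids[mask])
    return out


def family_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-family RIL counts, polymorphic marker counts and mean
    heterozygosity / failure (missing) percentages."""
    rows = []
    for fam in pd.unique(G.families[G.ril_mask()]):
        sub = G.select_family(fam)
        if sub.n_samples < 2:
            log.warning("family %s has fewer than 2 RILs", fam)
        _, het = _rates(sub.calls, axis=1)
        call_rate, _ = _rates(sub.calls, axis=1)
        rows.append({
            "family": fam,
            "n_rils": sub.n_samples,
            "n_polymorphic": int(_polymorphic_mask(sub.calls).sum()),
            "mean_heterozygosity_pct": 100.0 * float(np.mean(het)),
            "mean_failure_rate_pct": 100.0 * float(np.mean(1.0 - call_rate)),
            "flagged_small": sub.n_samples < 2,
        })
    return pd.DataFrame(rows)


def maf_spectrum(G: GenotypeMatrix, scope: str = "population"):
    """Per-marker minor allele frequency from non-missing calls (AB counts
    half toward each allele).  ``scope='population'`` returns one Series;
    ``scope='family'`` a markers x families DataFrame.  All-missing markers
    are NaN."""
    def _maf(calls: np.ndarray) -> np.ndarray:
        d = calls.astype(float)
        d[calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(d, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    rils = G.take_samples(G.ril_mask())
    if scope == "population":
        return pd.Series(_maf(rils.calls), index=rils.marker_ids, name="maf")
    if scope == "family":
        cols = {fam: _maf(G.select_family(fam).calls)
                for fam in pd.unique(rils.families)}
        return pd.DataFrame(cols, index=rils.marker_ids)
    raise ValueError("scope must be 'population' or 'family'")


def family_intersections(poly_sets: dict[str, set],
                         max_exhaustive: int = 12) -> dict[tuple, int]:
    """Exclusive (UpSet-style) intersection counts of per-family polymorphic
    marker sets: for each subset of families, the number of markers
    polymorphic in exactly those families.

    Zero counts are included when the family count allows exhaustive subset
    enumeration (<= ``max_exhaustive`` families); otherwise only observed
    membership patterns are reported.
    """
    if not poly_sets:
        raise ValueError("need at least one family")
    fams = sorted(poly_sets)
    counts: dict[tuple, int] = {}
    if len(fams) <= max_exhaustive:
        for k in range(1, len(fams) + 1):
            for combo in itertools.combinations(fams, k):
                counts[combo] = 0
    union = set().union(*poly_sets.values())
    for marker in union:
        pattern = tuple(f for f in fams if marker in poly_sets[f])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def snp_density_bins(pmap: PhysicalMap, polymorphic=None,
                     bin_size: int = 10_000_000,
                     all_markers=None) -> pd.DataFrame:
    """Counts of available and polymorphic markers in half-open genomic bins
    ``[k*bin_size, (k+1)*bin_size)`` per chromosome.

    ``polymorphic`` is a set of marker ids; ``all_markers`` (optional) is the
    full marker universe, used only to log how many are unplaced.
    """
    if all_markers is not None:
        unplaced = [m for m in all_markers if m not in pmap]
        if unplaced:
            log.info("snp_density_bins: %d unplaced markers excluded", len(unplaced))
    polymorphic = set() if polymorphic is None else set(polymorphic)
    rows = []
    for chrom, sub in pmap.table.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        bins = pos // bin_size
        n_bins = int(bins.max()) + 1 if len(bins) else 0
        avail = np.bincount(bins, minlength=n_bins)
        is_poly = sub.index.isin(polymorphic)
        poly = np.bincount(bins[is_poly], minlength=n_bins)
        for k in range(n_bins):
            rows.append({"chromosome": chrom, "bin": k,
                         "start": k * bin_size, "end": (k + 1) * bin_size,
                         "n_available": int(avail[k]), "n_polymorphic": int(poly[k])})
    return pd.DataFrame(rows, columns=["chromosome", "bin", "start", "end",
                                       "n_available", "n_polymorphic"])
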