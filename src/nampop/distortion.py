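"""Founder-contribution distortion scan within a biparental RIL family.

Within each family the two founder alleles are expected 50:50 at every
locus.  Markers are polarized by founder origin (heterozygous or missing RIL
calls dropped; markers monomorphic between the founders, founder-missing or
founder-heterozygous filtered out), tested with a 1-df chi-squared
goodness-of-fit against 50:50, and the per-marker p-values are averaged in
5 Mb bins and -log-transformed (natural log by default).  Each bin score is
signed +1 when the recurrent founder is over-represented and -1 when the
alternative founder is, and only bins with at least three markers are
reported.  Genome-wide significance uses a Bonferroni threshold
-log(alpha / n_markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, PhysicalMap

__all__ = ["PolarizedFamily", "polarize_family", "locus_gof", "binned_scan",
           "scan_threshold"]

log = logging.getLogger(__name__)

RF_HOM, ALT_HOM = 0, 1


@dataclass
class PolarizedFamily:
    """RIL calls of one family recoded by founder origin.

    ``codes`` is (n_rils, n_markers) with 0 = RF homozygote, 1 = ALT
    homozygote, -1 = missing (heterozygous calls are treated as failed).
    Retained markers are polymorphic between the founder pair.
    """

    family_id: str
    marker_ids: np.ndarray
    codes: np.ndarray
    dropped: pd.DataFrame  # marker, reason

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def polarize_family(G_family: GenotypeMatrix, rf_calls: np.ndarray,
                    alt_calls: np.ndarray, family_id: str | None = None,
                    ) -> PolarizedFamily:
    """Recode a family's RIL calls by founder origin.

    ``rf_calls`` and ``alt_calls`` are the founder call codes (0/1/2/-1)
    aligned to ``G_family.marker_ids``.  Markers where a founder call is
    missing or heterozygous, or where the founders agree, are dropped.
    """
    rf = np.asarray(rf_calls)
    alt = np.asarray(alt_calls)
    if rf.shape != (G_family.n_markers,) or alt.shape != (G_family.n_markers,):
        raise ValueError("founder calls must align with the family's markers")

    founder_missing = (rf == MISSING) | (alt == MISSING)
    founder_het = (rf == 1) | (alt == 1)
    monomorphic = ~founder_missing & ~founder_het & (rf == alt)
    keep = ~(founder_missing | founder_het | monomorphic)

    reasons = np.full(G_family.n_markers, "", dtype=object)
    reasons[founder_missing] = "founder_missing"
    reasons[founder_het & ~founder_missing] = "founder_heterozygous"
    reasons[monomorphic] = "founder_monomorphic"
    dropped = pd.DataFrame({"marker": G_family.marker_ids[~keep],
                            "reason": reasons[~keep]})

    calls = G_family.calls[:, keep]
    rf_k = rf[keep]
    alt_k = alt[keep]
    codes = np.full(calls.shape, MISSING, dtype=np.int8)
    codes[calls == rf_k[None, :]] = RF_HOM
    codes[calls == alt_k[None, :]] = ALT_HOM
    codes[calls == 1] = MISSING  # heterozygous RIL calls set as failed
    fam = family_id or (G_family.families[0] if G_family.n_samples else "family")
    return PolarizedFamily(fam, G_family.marker_ids[keep], codes, dropped)


def locus_gof(n_rf: int, n_alt: int) -> tuple[float, float, str | None]:
    """1-df chi-squared goodness-of-fit of founder counts against 50:50.

    Returns (chi2, p, direction) with direction 'RF', 'ALT' or None on a tie.
    """
    n = n_rf + n_alt
    if n < 1:
        raise ValueError("no informative calls at locus")
    expected = n / 2.0
    chi2 = (n_rf - expected) ** 2 / expected + (n_alt - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    direction = "RF" if n_rf > n_alt else ("ALT" if n_alt > n_rf else None)
    return float(chi2), p, direction


def binned_scan(pf: PolarizedFamily, pmap: PhysicalMap,
                bin_size: int = 5_000_000, min_markers: int = 3,
                log_base: float = np.e) -> pd.DataFrame:
    """Signed, binned distortion scores for one polarized family.

    Per bin: the mean of per-marker goodness-of-fit p-values,
    -log-transformed, signed by the bin's majority founder direction
    (weighted by informative call counts).  Bins with fewer than
    ``min_markers`` informative markers are suppressed.
    """
    placed = np.array([m in pmap for m in pf.marker_ids])
    n_unplaced = int((~placed).sum())
    if n_unplaced:
        log.info("binned_scan(%s): %d unplaced markers excluded",
                 pf.family_id, n_unplaced)

    rows = []
    idx = np.flatnonzero(placed)
    if len(idx) == 0:
        return pd.DataFrame(columns=["family", "chromosome", "start", "end",
                                     "n_markers", "mean_p", "signed_score",
                                     "direction"])
    loc = pmap.positions(pf.marker_ids[idx])
    n_rf_all = (pf.codes[:, idx] == RF_HOM).sum(axis=0)
    n_alt_all = (pf.codes[:, idx] == ALT_HOM).sum(axis=0)

    df = pd.DataFrame({
        "chromosome": loc["chromosome"].to_numpy(),
        "bin": loc["position"].to_numpy() // bin_size,
        "n_rf": n_rf_all, "n_alt": n_alt_all,
    })
    df = df[df["n_rf"] + df["n_alt"] >= 1]
    for (chrom, b), sub in df.groupby(["chromosome", "bin"], sort=True):
        if len(sub) < min_markers:
            continue
        pvals = [locus_gof(r, a)[1] for r, a in zip(sub["n_rf"], sub["n_alt"])]
        mean_p = float(np.mean(pvals))
        score = -np.log(mean_p) / np.log(log_base) if mean_p > 0 else np.inf
        rf_tot, alt_tot = int(sub["n_rf"].sum()), int(sub["n_alt"].sum())
        if rf_tot > alt_tot:
            sign, direction = 1.0, "RF"
        elif alt_tot > rf_tot:
            sign, direction = -1.0, "ALT"
        else:
            sign, direction = 0.0, None
        rows.append({"family": pf.family_id, "chromosome": chrom,
                     "start": int(b) * bin_size, "end": (int(b) + 1) * bin_size,
                     "n_markers": len(sub), "mean_p": mean_p,
                     "signed_score": sign * score if np.isfinite(score) else sign * np.inf,
                     "direction": direction})
    return pd.DataFrame(rows, columns=["family", "chromosome", "start", "end",
                                       "n_markers", "mean_p", "signed_score",
                                       "direction"])


def scan_threshold(n_markers_population: int, alpha: float = 0.05,
                   log_base: float = np.e) -> float:
    """Bonferroni threshold on |signed score|: -log(alpha / n_markers)."""
    if n_markers_population < 1:
        raise ValueError("need at least one marker")
    return float(-np.log(alpha / n_markers_population) / np.log(log_base))
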