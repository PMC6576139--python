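"""Kinship mixed-model association scan with PC covariates, QTN calling and
candidate-gene lookup.

The scan follows the EMMA strategy: under the null model
``y = X beta + u + e`` with ``u ~ N(0, sigma2_g K)``, the variance ratio
``delta = sigma2_e / sigma2_g`` is estimated once by REML, profiled over the
spectral decomposition of K; each marker is then tested by generalized least
squares with intercept + principal-component covariates, using the null
variance structure, with a Wald t-test on the allele-substitution
coefficient.  With K = I this reduces exactly to ordinary least squares.

QTNs are markers below a Bonferroni cutoff (nominal alpha / number of
markers), deduplicated across traits; candidate genes are protein-coding
gene models within +/-500 kb of each QTN (closed interval, any overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix, PhysicalMap
from .diversity import pca

__all__ = ["kinship", "mlm_scan", "call_qtns", "genes_near_qtns", "MlmResult"]

log = logging.getLogger(__name__)


def kinship(G: GenotypeMatrix, jitter: float = 1e-6) -> pd.DataFrame:
    """VanRaden-type realized relationship matrix: centered-dosage
    cross-product scaled by marker count, with a diagonal jitter (<= 1e-6)
    to keep it numerically positive semidefinite."""
    d = G.dosage()
    col_mean = np.nanmean(d, axis=0)
    if not np.isfinite(col_mean).any():
        raise ValueError("degenerate genotype matrix")
    x = np.where(np.isfinite(d), d, col_mean[None, :]) - col_mean[None, :]
    if float(np.abs(x).max(initial=0.0)) == 0.0:
        raise ValueError("all-constant genotypes: kinship undefined")
    K = x @ x.T / G.n_markers
    K += jitter * np.eye(G.n_samples)
    return pd.DataFrame(K, index=G.sample_ids, columns=G.sample_ids)


def _emma_delta(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                bounds=(-10.0, 10.0), n_grid: int = 100):
    """REML estimate of delta = sigma2_e/sigma2_g on the eigenbasis of K."""
    n, p = X.shape
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_reml(log_delta):
        w = lam + np.exp(log_delta)
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / w))
        s2 = rss / (n - p)
        _, ld = np.linalg.slogdet(XtWX)
        return 0.5 * ((n - p) * np.log(s2) + np.sum(np.log(w)) + ld)

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    vals = np.array([neg_reml(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"delta optimization failed: {res.message}")
    delta = float(np.exp(res.x))
    return delta, lam, U


@dataclass
class MlmResult:
    table: pd.DataFrame     # marker, maf, effect, se, p
    delta: float
    sigma2_g: float
    sigma2_e: float
    skipped: list[str]


def mlm_scan(y: pd.Series, G: GenotypeMatrix, K: pd.DataFrame | None = None,
             n_pcs: int = 3, min_maf: float = 0.01) -> MlmResult:
    """Single-marker kinship mixed-model scan with PC covariates.

    ``y`` is indexed by sample id (typically genotype BLUPs); markers with
    MAF below ``min_maf`` are skipped and logged.  Effects are
    allele-substitution coefficients in trait units.
    """
    order = [s for s in G.sample_ids if s in y.index]
    if len(order) < G.n_samples:
        G = G.take_samples(np.isin(G.sample_ids, order))
    yv = y.loc[list(G.sample_ids)].to_numpy(float)
    n = len(yv)

    covs = [np.ones((n, 1))]
    if n_pcs > 0:
        scores, _ = pca(G, n_components=n_pcs)
        covs.append(scores.to_numpy())
    X0 = np.hstack(covs)

    Km = np.eye(n) if K is None else K.loc[list(G.sample_ids), list(G.sample_ids)].to_numpy()
    delta, lam, U = _emma_delta(yv, X0, Km)
    w = lam + delta
    # null variance components on the trait scale
    Xt0, yt = U.T @ X0, U.T @ yv
    Xw = Xt0 / w[:, None]
    beta0 = np.linalg.solve(Xt0.T @ Xw, Xw.T @ yt)
    r0 = yt - Xt0 @ beta0
    s2g = float(np.sum(r0 * r0 / w)) / (n - X0.shape[1])
    s2e = s2g * delta

    d = G.dosage()
    col_mean = np.nanmean(d, axis=0)
    dos = np.where(np.isfinite(d), d, col_mean[None, :])
    freq = col_mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    sw = 1.0 / np.sqrt(w)
    ys = yt * sw
    X0s = Xt0 * sw[:, None]
    Ms = (U.T @ dos) * sw[:, None]  # transformed marker dosages

    rows, skipped = [], []
    p_fixed = X0.shape[1] + 1
    dof = n - p_fixed
    for j, marker in enumerate(G.marker_ids):
        if not np.isfinite(maf[j]) or maf[j] < min_maf:
            skipped.append(str(marker))
            continue
        Xj = np.column_stack([X0s, Ms[:, j]])
        XtX = Xj.T @ Xj
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            skipped.append(str(marker))
            continue
        beta = XtX_inv @ (Xj.T @ ys)
        resid = ys - Xj @ beta
        s2 = float(resid @ resid) / dof
        se = float(np.sqrt(s2 * XtX_inv[-1, -1]))
        tstat = beta[-1] / se if se > 0 else np.nan
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
        rows.append({"marker": marker, "maf": float(maf[j]),
                     "effect": float(beta[-1]), "se": se, "p": p})
    if skipped:
        log.info("mlm_scan: skipped %d markers (MAF < %g or singular)",
                 len(skipped), min_maf)
    return MlmResult(pd.DataFrame(rows, columns=["marker", "maf", "effect",
                                                 "se", "p"]),
                     delta, s2g, s2e, skipped)


def call_qtns(scans: dict[str, pd.DataFrame], n_markers: int,
              alpha: float = 0.1, pmap: PhysicalMap | None = None,
              ) -> pd.DataFrame:
    """Bonferroni QTN calls across one or more trait scans.

    ``scans`` maps trait name to a scan table (marker, effect, p).  Markers
    significant for several traits are reported once with the joint trait
    list and per-trait effects.
    """
    cutoff = alpha / n_markers
    hits: dict[str, dict] = {}
    for trait, tab in scans.items():
        sig = tab[tab["p"] < cutoff]
        for row in sig.itertuples():
            h = hits.setdefault(row.marker, {"traits": [], "effects": [], "pvalues": []})
            h["traits"].append(trait)
            h["effects"].append(float(row.effect))
            h["pvalues"].append(float(row.p))
    rows = []
    for marker in sorted(hits, key=str):
        h = hits[marker]
        chrom, pos = None, None
        if pmap is not None and marker in pmap:
            loc = pmap.table.loc[marker]
            chrom, pos = loc["chromosome"], int(loc["position"])
        rows.append({"marker": marker, "chromosome": chrom, "position": pos,
                     "traits": ", ".join(h["traits"]),
                     "effects": h["effects"], "p_values": h["pvalues"],
                     "min_p": min(h["pvalues"])})
    return pd.DataFrame(rows, columns=["marker", "chromosome", "position",
                                       "traits", "effects", "p_values", "min_p"])


def genes_near_qtns(qtns: pd.DataFrame, annotation, window: int = 500_000,
                    protein_coding_only: bool = True,
                    ) -> tuple[dict[str, list[str]], list[str]]:
    """Gene models within ``window`` bp of each QTN (closed interval, any
    overlap counts) from a GFF3 annotation (path or gffutils FeatureDB).

    Returns (marker -> gene id list, unique genes across QTNs).  Raises on
    chromosome names absent from the annotation.
    """
    import gffutils

    if isinstance(annotation, gffutils.FeatureDB):
        db = annotation
    else:
        db = gffutils.create_db(str(annotation), ":memory:",
                                merge_strategy="create_unique", keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        biotype = (g.attributes.get("biotype") or g.attributes.get("gene_biotype")
                   or ["protein_coding"])[0]
        if protein_coding_only and biotype != "protein_coding":
            continue
        genes.append((g.seqid, g.start, g.end, g.id))
    ann_chroms = {g[0] for g in genes}

    missing = sorted({str(c) for c in qtns["chromosome"] if c is not None}
                     - ann_chroms)
    if missing:
        raise ValueError(f"QTN chromosomes absent from annotation: {missing}")

    per_qtn: dict[str, list[str]] = {}
    for row in qtns.itertuples():
        lo, hi = row.position - window, row.position + window
        per_qtn[row.marker] = sorted(gid for chrom, start, end, gid in genes
                                     if chrom == row.chromosome
                                     and end >= lo and start <= hi)
    unique = sorted({g for lst in per_qtn.values() for g in lst})
    return per_qtn, unique
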