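"""Replicated simulation studies of the pipeline's operating characteristics.

Each routine sets up a NAM-style simulation with known ground truth, runs
the corresponding analysis stage, and reports how well the truth is
recovered: residual heterozygosity after selfing, Haldane recombinant
fractions, segregation-distortion scan calibration and power, Hill–Weir
parameter recovery and the multiparental LD-decay contrast, neighbor-joining
topology recovery, the identity-kinship reduction of the mixed-model scan to
OLS, trial variance-component recovery, and QTN detection power.

These studies back both the test suite and ``scripts/acceptance.py``; every
routine is driven by an explicit seed and returns plain dictionaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhysicalMap
from .distortion import binned_scan, polarize_family, scan_threshold
from .diversity import allele_sharing_distance, nj_tree
from .genome import Chromosome, GenomeModel
from .gwas import call_qtns, kinship, mlm_scan
from .ld import decay_distance, fit_hill_weir, hill_weir_expectation, pairwise_r2
from .simulate import (SelectionSpec, SimConfig, simulate_family,
                       simulate_founders, simulate_nam, simulate_trial,
                       substream)
from .trial import fit_trial_model, heritability

__all__ = [
    "f6_heterozygosity", "haldane_recombination", "distortion_calibration",
    "hill_weir_recovery", "pooled_vs_family_decay", "nj_recovery",
    "emma_ols_equivalence", "varcomp_recovery", "qtn_power",
]


def _scan_genome(markers_per_chromosome: int = 80) -> GenomeModel:
    return GenomeModel.regular(n_chromosomes=2, chrom_length_bp=100_000_000,
                               chrom_length_cm=100.0,
                               markers_per_chromosome=markers_per_chromosome)


def f6_heterozygosity(seed: int, n_rils: int = 1000,
                      generations: int = 5) -> dict:
    """Residual per-locus heterozygosity after k selfing generations
    (expected (1/2)^k)."""
    genome = GenomeModel([Chromosome("c1", 1000, 0.0)],
                         pd.DataFrame({"marker": ["m1"], "chromosome": ["c1"],
                                       "bp": [500]}))
    panel = simulate_founders(genome, 2, 1.0, seed=seed)
    sim = SimConfig(n_families=1, rils_per_family=n_rils,
                    generations_of_selfing=generations, seed=seed)
    fs = simulate_family(panel, panel.alt_ids()[0], genome, sim)
    het = float((fs.truth[:, 0] == 1).mean())
    return {"observed_pct": 100.0 * het,
            "expected_pct": 100.0 * 0.5 ** generations,
            "n": n_rils}


def haldane_recombination(seed: int, d_cm=(1.0, 10.0, 50.0, 100.0),
                          n_meioses: int = 10_000) -> dict:
    """Observed vs Haldane-expected recombinant gamete fractions."""
    from .simulate import _batch_gametes

    rows = []
    for d in d_cm:
        bp_per_cm = 1_000_000
        genome = GenomeModel(
            [Chromosome("c1", int(max(d, 1) + 2) * bp_per_cm, d + 2.0)],
            pd.DataFrame({"marker": ["m1", "m2"], "chromosome": ["c1", "c1"],
                          "bp": [bp_per_cm, int((1 + d) * bp_per_cm)]}))
        rng = substream(seed, "haldane", int(d * 10))
        h0 = np.zeros((n_meioses, 2), np.uint8)
        h1 = np.ones((n_meioses, 2), np.uint8)
        gam = _batch_gametes(h0, h1, genome, rng)
        rows.append({"d_cm": d,
                     "observed": float((gam[:, 0] != gam[:, 1]).mean()),
                     "expected": 0.5 * (1 - np.exp(-2 * d / 100.0))})
    return {"table": pd.DataFrame(rows), "n": n_meioses}


def distortion_calibration(seed: int, n_replicates: int = 200,
                           n_rils: int = 200, s: float = 1.0) -> dict:
    """Type-I rate and selected-locus power of the binned distortion scan.

    Neutral replicates measure the mean fraction of bins whose |signed
    score| exceeds the Bonferroni threshold; selected replicates (viability
    s against the alternative-founder homozygote at 50 Mb on chr1) measure
    how often the containing or an adjacent 5 Mb bin exceeds it with the
    recurrent founder favored.
    """
    genome = _scan_genome()
    pmap = PhysicalMap(genome.placement_table())
    thr = scan_threshold(genome.n_markers)
    locus = ("chr1", 50_000_000)
    sel = [SelectionSpec(locus, s, "against_alt_hom")]

    def scan(rep_seed, selection):
        panel = simulate_founders(genome, 2, 1.0, seed=rep_seed)
        sim = SimConfig(n_families=1, rils_per_family=n_rils, seed=rep_seed)
        fs = simulate_family(panel, panel.alt_ids()[0], genome, sim, selection)
        pf = polarize_family(fs.genotypes, (2 * fs.rf_allele).astype(np.int8),
                             (2 * fs.alt_allele).astype(np.int8))
        return binned_scan(pf, pmap)

    null_fracs = []
    for rep in range(n_replicates):
        out = scan(substream(seed, "null", rep).integers(2 ** 31), ())
        null_fracs.append(float((out["signed_score"].abs() > thr).mean()))

    hits = 0
    for rep in range(n_replicates):
        out = scan(substream(seed, "sel", rep).integers(2 ** 31), sel)
        sig = out[(out["chromosome"] == locus[0]) & (out["signed_score"] > thr)]
        hit = any(row.start - 5_000_000 <= locus[1] <= row.end + 5_000_000
                  for row in sig.itertuples())
        hits += hit

    return {"type1_bin_fraction": float(np.mean(null_fracs)),
            "power": hits / n_replicates,
            "threshold": thr, "n_replicates": n_replicates, "n_rils": n_rils}


def hill_weir_recovery(n: int = 100, a_true: float = 1e-7,
                       n_points: int = 200) -> dict:
    """Self-consistency: refit the decay coefficient from noise-free curve
    points."""
    d = np.linspace(1e3, 5e7, n_points)
    y = hill_weir_expectation(d, a_true, n)
    fit = fit_hill_weir(pd.DataFrame({"distance": d, "r2": y}), n)
    return {"a_true": a_true, "a_fitted": fit.a,
            "rel_error_pct": 100.0 * abs(fit.a - a_true) / a_true,
            "decay_distance_mb": decay_distance(fit) / 1e6, "n": n_points}


def pooled_vs_family_decay(seed: int, n_families: int = 12,
                           rils_per_family: int = 100) -> dict:
    """Fitted LD decay distance of the pooled NAM vs each single family."""
    genome = GenomeModel.regular(n_chromosomes=1, chrom_length_bp=100_000_000,
                                 chrom_length_cm=100.0,
                                 markers_per_chromosome=60)
    panel = simulate_founders(genome, n_families + 1, 0.5, seed=seed)
    sim = SimConfig(n_families=n_families, rils_per_family=rils_per_family,
                    seed=seed)
    G, _ = simulate_nam(panel, genome, sim)
    pmap = PhysicalMap(genome.placement_table())
    family_decay = {}
    for fam in sorted(set(G.families)):
        sub = G.select_family(fam)
        ldm = pairwise_r2(sub, pmap, "chr1")
        fit = fit_hill_weir(ldm.pairs(), sub.n_samples)
        family_decay[fam] = decay_distance(fit)
    ldm = pairwise_r2(G, pmap, "chr1")
    pooled = decay_distance(fit_hill_weir(ldm.pairs(), G.n_samples))
    return {"pooled_mb": pooled / 1e6,
            "min_family_mb": min(family_decay.values()) / 1e6,
            "family_decay_mb": {k: v / 1e6 for k, v in family_decay.items()},
            "n": G.n_samples}


def nj_recovery(seed: int, n_replicates: int = 20, max_taxa: int = 12) -> dict:
    """Exact topology recovery of NJ on random additive distance matrices."""
    import skbio

    rng = substream(seed, "nj")
    exact = 0
    for rep in range(n_replicates):
        n = int(rng.integers(4, max_taxa + 1))
        labels = [f"t{i:02d}" for i in range(n)]
        nodes = [skbio.TreeNode(name=l) for l in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            a, b = nodes[i], nodes[j]
            a.length = float(rng.uniform(0.1, 1.0))
            b.length = float(rng.uniform(0.1, 1.0))
            nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
            nodes.append(skbio.TreeNode(children=[a, b]))
        truth = nodes[0]
        tips = {t.name: t for t in truth.tips()}
        d = np.zeros((n, n))
        for x in range(n):
            for y in range(x + 1, n):
                d[x, y] = d[y, x] = tips[labels[x]].distance(tips[labels[y]])
        from .diversity import DistanceMatrix
        D = DistanceMatrix(np.asarray(labels, object), d,
                           np.full((n, n), 1000), np.zeros((n, n), bool))
        exact += nj_tree(D).compare_rfd(truth) == 0.0
    return {"fraction_exact": exact / n_replicates,
            "n_replicates": n_replicates}


def emma_ols_equivalence(seed: int, n: int = 120, m: int = 50) -> dict:
    """Max |p_MLM - p_OLS| over markers when K is the identity."""
    rng = substream(seed, "emma-ols")
    codes = rng.integers(0, 3, (n, m)).astype(np.int8)
    G = GenotypeMatrix(codes, [f"s{i:03d}" for i in range(n)],
                       [f"mk{j:03d}" for j in range(m)], ["f1"] * n)
    y = pd.Series(rng.normal(0, 1, n), index=G.sample_ids)
    K = pd.DataFrame(np.eye(n), index=G.sample_ids, columns=G.sample_ids)
    res = mlm_scan(y, G, K, n_pcs=0)
    x = codes.astype(float)
    maxdiff = 0.0
    from scipy import stats
    for row in res.table.itertuples():
        j = list(G.marker_ids).index(row.marker)
        X = np.column_stack([np.ones(n), x[:, j]])
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        r = y.to_numpy() - X @ beta
        s2 = float(r @ r) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p_ols = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
        maxdiff = max(maxdiff, abs(row.p - p_ols))
    return {"max_abs_p_difference": maxdiff, "n": n, "n_markers": m}


def varcomp_recovery(seed: int, n_replicates: int = 20, n_genotypes: int = 300,
                     sigma2_g: float = 1.0, sigma2_e: float = 1.0) -> dict:
    """Genotypic-variance recovery on balanced 3-location x 2-rep designs."""
    estimates, h2s = [], []
    for rep in range(n_replicates):
        rep_seed = int(substream(seed, "vc", rep).integers(2 ** 31))
        rng = substream(rep_seed, "effects")
        eff = pd.Series(rng.normal(0.0, np.sqrt(sigma2_g), n_genotypes),
                        index=[f"g{i:03d}" for i in range(n_genotypes)])
        rec = simulate_trial(eff, {"locations": 3, "reps": 2, "rows": 15,
                                   "cols": 20},
                             {"gl": 0.25, "rep": 0.1, "col": 0.1, "row": 0.1,
                              "resid": sigma2_e}, seed=rep_seed)
        vc, _ = fit_trial_model(rec)
        estimates.append(vc.sigma2["genotype"])
        h2s.append(heritability(vc))
    mean_est = float(np.mean(estimates))
    h2_true = sigma2_g / (sigma2_g + 0.25 / 3 + sigma2_e / 6)
    return {"sigma2_g_true": sigma2_g, "sigma2_g_mean": mean_est,
            "rel_error_pct": 100.0 * abs(mean_est - sigma2_g) / sigma2_g,
            "h2_mean_pct": 100.0 * float(np.mean(h2s)),
            "h2_true_pct": 100.0 * h2_true,
            "n_replicates": n_replicates}


def qtn_power(seed: int, n_replicates: int = 50, effect: float = 1.5,
              h2: float = 0.9, link_window: float = 5e6) -> dict:
    """Power to call a Bonferroni-significant QTN at or within ``link_window``
    of a causal marker of allele-substitution effect ``effect`` (trait-class
    difference 2*effect, e.g. 3 days) in a 12 x 100 RIL NAM.

    The trait is the causal effect plus a polygenic background, with
    broad-sense heritability ``h2``.
    """
    genome = GenomeModel.regular(n_chromosomes=2, chrom_length_bp=100_000_000,
                                 chrom_length_cm=100.0,
                                 markers_per_chromosome=40)
    pmap = PhysicalMap(genome.placement_table())
    causal = genome.marker_ids[20]
    causal_loc = pmap.table.loc[causal]

    hits = 0
    for rep in range(n_replicates):
        rep_seed = int(substream(seed, "qtn", rep).integers(2 ** 31))
        panel = simulate_founders(genome, 13, 0.5, seed=rep_seed)
        sim = SimConfig(n_families=12, rils_per_family=100, seed=rep_seed)
        G, _ = simulate_nam(panel, genome, sim)
        rng = substream(rep_seed, "trait")
        d = G.dosage()
        cm = np.nanmean(d, axis=0)
        dos = np.where(np.isfinite(d), d, cm)
        j = list(G.marker_ids).index(causal)
        genetic = effect * dos[:, j] + dos @ rng.normal(0, 0.1, G.n_markers)
        evar = np.var(genetic) * (1 - h2) / h2
        y = pd.Series(genetic + rng.normal(0, np.sqrt(evar), G.n_samples),
                      index=G.sample_ids)
        res = mlm_scan(y, G, kinship(G), n_pcs=3)
        qtns = call_qtns({"trait": res.table}, n_markers=len(res.table),
                         alpha=0.1, pmap=pmap)
        hits += any(row.chromosome == causal_loc["chromosome"]
                    and abs(row.position - causal_loc["position"]) <= link_window
                    for row in qtns.itertuples())
    return {"power": hits / n_replicates, "n_replicates": n_replicates,
            "n_rils": 1200, "effect_class_difference": 2 * effect}
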