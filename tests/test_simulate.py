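"""Simulator unit and property tests: founder panels, Haldane meiosis,
single-seed descent with viability selection, array artifacts and trials."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nampop import (Chromosome, GenomeModel, SelectionSpec, SimConfig,
                    inject_array_artifacts, meiosis, simulate_family,
                    simulate_founders, simulate_nam, simulate_trial)
from nampop.simulate import _batch_gametes, substream


def two_marker_genome(d_cm, length_cm=200.0):
    bp_per_cm = 1_000_000
    return GenomeModel(
        [Chromosome("c1", int(length_cm * bp_per_cm), length_cm)],
        pd.DataFrame({"marker": ["m1", "m2"], "chromosome": ["c1", "c1"],
                      "bp": [bp_per_cm, int((1 + d_cm) * bp_per_cm)]}))


def selfing_chain_oracle(k, s, mode="against_alt_hom"):
    """Independent oracle: 3-state selfing chain with within-line viability
    rejection (per-parent conditional renormalization).

    States (rf_hom, het, alt_hom); returns final genotype distribution.
    """
    target = {"against_rf_hom": 0, "against_het": 1, "against_alt_hom": 2}[mode]
    rows = np.array([[1.0, 0.0, 0.0],
                     [0.25, 0.5, 0.25],
                     [0.0, 0.0, 1.0]])
    weights = np.ones(3)
    weights[target] = 1.0 - s
    T = rows * weights[None, :]
    norm = T.sum(axis=1, keepdims=True)
    T = np.divide(T, norm, out=np.zeros_like(T), where=norm > 0)
    p = np.array([0.0, 1.0, 0.0])
    for _ in range(k):
        p = p @ T
    return p


class TestFounders:
    def test_zero_divergence_gives_identical_founders(self, small_genome):
        panel = simulate_founders(small_genome, 4, 0.0, seed=1)
        assert np.all(panel.haplotypes == panel.haplotypes[0])
        for alt in panel.alt_ids():
            assert panel.polymorphic_in_cross(alt).sum() == 0

    def test_full_divergence_makes_every_marker_polymorphic(self, small_genome):
        panel = simulate_founders(small_genome, 2, 1.0, seed=1)
        assert panel.polymorphic_in_cross(panel.alt_ids()[0]).all()

    def test_half_divergence_polymorphism_fraction(self, small_genome):
        # brute-force recount of RF-vs-founder differences over a large panel
        panel = simulate_founders(small_genome, 51, 0.5, seed=7)
        diffs = [panel.polymorphic_in_cross(a).mean() for a in panel.alt_ids()]
        m = small_genome.n_markers
        se = np.sqrt(0.25 / (m * len(diffs)))
        assert abs(np.mean(diffs) - 0.5) < 4 * se

    def test_founders_are_homozygous_encoded(self, founder_panel):
        assert set(np.unique(founder_panel.haplotypes)) <= {0, 1}

    def test_degenerate_genome_rejected(self):
        g = GenomeModel([Chromosome("c1", 1000, 1.0)],
                        pd.DataFrame(columns=["marker", "chromosome", "bp"]))
        with pytest.raises(ValueError, match="degenerate"):
            simulate_founders(g, 3, 0.5)


class TestMeiosis:
    def test_homozygous_parent_transmits_itself(self, small_genome):
        h = np.ones(small_genome.n_markers, dtype=np.uint8)
        gam = meiosis((h, h), small_genome, seed=0)
        assert np.array_equal(gam, h)

    def test_zero_distance_never_recombines(self):
        g = GenomeModel([Chromosome("c1", 1000, 0.0)],
                        pd.DataFrame({"marker": ["m1", "m2"],
                                      "chromosome": ["c1", "c1"], "bp": [10, 20]}))
        h0, h1 = np.array([0, 0], np.uint8), np.array([1, 1], np.uint8)
        rng = substream(3, "t")
        gams = _batch_gametes(np.tile(h0, (2000, 1)), np.tile(h1, (2000, 1)), g, rng)
        assert (gams[:, 0] == gams[:, 1]).all()

    @pytest.mark.parametrize("d_cm", [1.0, 10.0, 50.0, 100.0])
    def test_recombinant_fraction_matches_haldane(self, d_cm):
        genome = two_marker_genome(d_cm)
        h0 = np.zeros(2, np.uint8)
        h1 = np.ones(2, np.uint8)
        rng = substream(17, "haldane", int(d_cm))
        n = 10_000
        gams = _batch_gametes(np.tile(h0, (n, 1)), np.tile(h1, (n, 1)), genome, rng)
        rec = float((gams[:, 0] != gams[:, 1]).mean())
        expected = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 4 * se


@pytest.fixture(scope="module")
def one_locus():
    g = GenomeModel([Chromosome("c1", 1000, 0.0)],
                    pd.DataFrame({"marker": ["m1"], "chromosome": ["c1"],
                                  "bp": [500]}))
    panel = simulate_founders(g, 2, 1.0, seed=5)
    return g, panel


class TestSingleSeedDescent:

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_residual_heterozygosity_halves_per_selfing(self, one_locus, k):
        g, panel = one_locus
        sim = SimConfig(n_families=1, rils_per_family=1000,
                        generations_of_selfing=k, seed=11)
        fs = simulate_family(panel, panel.alt_ids()[0], g, sim)
        het = float((fs.truth[:, 0] == 1).mean())
        expected = 0.5 ** k
        sd = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(het - expected) < 3 * sd

    def test_neutral_rf_allele_frequency_is_half(self, one_locus):
        g, panel = one_locus
        sim = SimConfig(n_families=1, rils_per_family=1000, seed=13)
        fs = simulate_family(panel, panel.alt_ids()[0], g, sim)
        rf_dos = np.where(fs.truth[:, 0] == 2 * panel.rf_haplotype[0], 2,
                          np.where(fs.truth[:, 0] == 1, 1, 0))
        freq = rf_dos.mean() / 2.0
        # per-line allele-freq variance from the k=5 genotype distribution
        p = selfing_chain_oracle(5, 0.0)
        var = p[0] * 1 + p[1] * 0.25 - 0.5 ** 2
        assert abs(freq - 0.5) < 3 * np.sqrt(var / 1000)

    @pytest.mark.parametrize("mode,s", [("against_alt_hom", 1.0),
                                        ("against_alt_hom", 0.5),
                                        ("against_het", 1.0)])
    def test_selection_matches_conditional_chain_oracle(self, one_locus, mode, s):
        g, panel = one_locus
        sim = SimConfig(n_families=1, rils_per_family=2000, seed=29)
        spec = SelectionSpec(("c1", 500), s, mode)
        fs = simulate_family(panel, panel.alt_ids()[0], g, sim, [spec])
        rf = panel.rf_haplotype[0]
        rf_dos = np.where(fs.truth[:, 0] == 2 * rf, 2,
                          np.where(fs.truth[:, 0] == 1, 1, 0))
        freq = rf_dos.mean() / 2.0
        p = selfing_chain_oracle(5, s, mode)
        exp_freq = p[0] + p[1] / 2.0
        var = p[0] + p[1] * 0.25 - exp_freq ** 2
        assert abs(freq - exp_freq) < 4 * np.sqrt(max(var, 1e-6) / 2000)

    def test_impossible_selection_raises_naming_locus(self, one_locus):
        g, panel = one_locus
        sim = SimConfig(n_families=1, rils_per_family=5, seed=3)
        specs = [SelectionSpec(("c1", 500), 1.0, m)
                 for m in ("against_alt_hom", "against_rf_hom", "against_het")]
        from nampop import SimulationError
        with pytest.raises(SimulationError, match="c1"):
            simulate_family(panel, panel.alt_ids()[0], g, sim, specs,
                            retry_cap=5, line_retry_cap=2)

    def test_fixed_seed_reproducible(self, small_genome, founder_panel):
        sim = SimConfig(n_families=2, rils_per_family=20, seed=99)
        a, _ = simulate_nam(founder_panel, small_genome, sim)
        b, _ = simulate_nam(founder_panel, small_genome, sim)
        assert np.array_equal(a.calls, b.calls)
        assert list(a.sample_ids) == list(b.sample_ids)


class TestArrayArtifacts:
    def test_zero_rates_identity(self, small_nam, founder_panel):
        G, _ = small_nam
        sim = SimConfig(missing_rate=0.0, het_error_rate=0.0,
                        ascertainment_fraction=0.0, seed=1)
        out, log = inject_array_artifacts(G, sim, founders=founder_panel)
        assert np.array_equal(out.calls, G.calls)
        assert log.n_set_missing == 0 and log.n_het_errors == 0
        assert log.masked_markers == []

    def test_missing_rate_binomial(self, small_nam, founder_panel):
        G, _ = small_nam
        sim = SimConfig(missing_rate=0.2, het_error_rate=0.0,
                        ascertainment_fraction=0.0, seed=2)
        out, log = inject_array_artifacts(G, sim, founders=founder_panel)
        n_calls = G.calls.size
        expected = 0.2 * n_calls
        sd = np.sqrt(n_calls * 0.2 * 0.8)
        assert abs(log.n_set_missing - expected) < 3 * sd
        assert (out.calls == -1).sum() >= log.n_set_missing

    def test_full_ascertainment_masks_every_private_marker(self, small_nam,
                                                           founder_panel):
        G, _ = small_nam
        sim = SimConfig(missing_rate=0.0, het_error_rate=0.0,
                        ascertainment_fraction=1.0, seed=3)
        out, log = inject_array_artifacts(G, sim, founders=founder_panel)
        private = founder_panel.fv_private_markers()
        assert set(log.masked_markers) == set(map(str, G.marker_ids[private]))
        # recount: masked columns are monomorphic at the RF call
        for j in np.flatnonzero(private):
            col = out.calls[:, j]
            assert len(np.unique(col)) == 1
            assert col[0] == 2 * founder_panel.rf_haplotype[j]

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            SimConfig(missing_rate=1.5)


class TestTrialSimulation:
    def test_noise_free_single_location_is_exact(self):
        eff = pd.Series([1.0, -2.0, 0.5], index=["g1", "g2", "g3"])
        rec = simulate_trial(eff, {"locations": 1, "reps": 1, "rows": 1, "cols": 3},
                             {}, seed=0, mu=10.0)
        got = rec.set_index("genotype")["value"]
        for g in eff.index:
            assert got[g] == pytest.approx(10.0 + eff[g])

    def test_zero_genotype_variance_gives_f_near_one(self):
        # ANOVA oracle: with identical genotype effects the among-genotype
        # mean square should match the residual mean square
        eff = pd.Series(0.0, index=[f"g{i}" for i in range(30)])
        fvals = []
        for rep in range(20):
            rec = simulate_trial(eff, {"locations": 1, "reps": 3, "rows": 5,
                                       "cols": 6},
                                 {"resid": 1.0}, seed=100 + rep)
            groups = [sub["value"].to_numpy()
                      for _, sub in rec.groupby("genotype")]
            fvals.append(stats.f_oneway(*groups).statistic)
        assert np.mean(fvals) == pytest.approx(1.0, abs=0.25)

    def test_residual_variance_moment(self):
        eff = pd.Series(0.0, index=[f"g{i}" for i in range(50)])
        rec = simulate_trial(eff, {"locations": 2, "reps": 2, "rows": 5,
                                   "cols": 10},
                             {"resid": 2.0}, seed=8)
        v = float(np.var(rec["value"]))
        assert v == pytest.approx(2.0, rel=0.25)

    def test_invalid_variance_rejected(self):
        eff = pd.Series([0.0], index=["g1"])
        with pytest.raises(ValueError):
            simulate_trial(eff, {"locations": 1, "reps": 1, "rows": 1, "cols": 1},
                           {"resid": np.nan})
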