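"""Quality control of a simulated NAM genotype matrix.

Applies the sample filter (call rate >= 80%, heterozygosity <= 20%) and the
marker filter (same thresholds, on retained samples), then summarizes each
family: RIL count, polymorphic markers, heterozygosity and failure rates.
The intersection counts show how many polymorphic markers are exclusive to
each family combination (UpSet semantics).
"""

from nampop import (GenomeModel, SimConfig, inject_array_artifacts,
                    simulate_founders, simulate_nam)
from nampop.qc import (family_intersections, family_stats, filter_markers,
                       filter_samples, polymorphic_sets)

genome = GenomeModel.regular(n_chromosomes=2, chrom_length_bp=100_000_000,
                             chrom_length_cm=100.0, markers_per_chromosome=50)
founders = simulate_founders(genome, 4, divergence=0.5, seed=11)
sim = SimConfig(n_families=3, rils_per_family=50, missing_rate=0.05,
                het_error_rate=0.01, ascertainment_fraction=0.1, seed=11)
clean, _ = simulate_nam(founders, genome, sim)
G, _ = inject_array_artifacts(clean, sim, founders=founders)

G, dropped_samples = filter_samples(G)
G, dropped_markers = filter_markers(G)
print(f"after QC: {G.n_samples} samples x {G.n_markers} markers "
      f"({len(dropped_samples)} samples, {len(dropped_markers)} markers removed)")

print(family_stats(G).round(2).to_string(index=False))

sets = polymorphic_sets(G)
inter = family_intersections(sets)
top = sorted(inter.items(), key=lambda kv: -kv[1])[:5]
print("\nlargest exclusive intersections (families -> marker count):")
for fams, count in top:
    print(f"  {'+'.join(fams)}: {count}")
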