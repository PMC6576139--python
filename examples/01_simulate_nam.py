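"""Simulate a small NAM population and inspect its genotype table.

Builds a 4-family x 40-RIL population on a 2-chromosome genome, overlays
array-like measurement artifacts, and prints the residual heterozygosity —
which should sit near (1/2)^5 = 3.1% of the segregating calls, the expected
leftover after five selfing generations.
"""

import numpy as np

from nampop import (GenomeModel, SimConfig, inject_array_artifacts,
                    simulate_founders, simulate_nam)

genome = GenomeModel.regular(n_chromosomes=2, chrom_length_bp=100_000_000,
                             chrom_length_cm=100.0, markers_per_chromosome=50)
founders = simulate_founders(genome, n_founders=5, divergence=0.5, seed=7)
sim = SimConfig(n_families=4, rils_per_family=40, missing_rate=0.02,
                het_error_rate=0.005, ascertainment_fraction=0.1, seed=7)

clean, families = simulate_nam(founders, genome, sim)
observed, log = inject_array_artifacts(clean, sim, founders=founders)

print(f"{clean.n_samples} RILs x {clean.n_markers} markers in "
      f"{len(families)} families")
seg = np.mean([f.genotypes.calls[:, f.rf_allele != f.alt_allele] == 1
               for f in families.values()][0])
print(f"residual heterozygosity at segregating markers: {100 * seg:.2f}% "
      f"(expected {100 * 0.5 ** 5:.2f}%)")
print(f"artifacts: {log.n_set_missing} calls set missing, "
      f"{log.n_het_errors} spurious heterozygotes, "
      f"{len(log.masked_markers)} FV-private markers masked")
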