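"""From multi-environment trial plots to QTNs.

Simulates an alpha-lattice trial over 3 locations x 2 replications where a
single marker carries a 3-day allele-class effect, fits the row-column
mixed model by REML (genotype, genotype-by-location, replication,
column-in-rep and row-in-rep random; location fixed), reports broad-sense
heritability, and scans the genotype BLUPs with the kinship mixed model.
The causal marker should come out as the top Bonferroni-significant QTN.
"""

import numpy as np
import pandas as pd

from nampop import (GenomeModel, PhysicalMap, SimConfig, simulate_founders,
                    simulate_nam, simulate_trial)
from nampop.gwas import call_qtns, kinship, mlm_scan
from nampop.simulate import substream
from nampop.trial import fit_trial_model, heritability

genome = GenomeModel.regular(n_chromosomes=2, chrom_length_bp=100_000_000,
                             chrom_length_cm=100.0, markers_per_chromosome=40)
founders = simulate_founders(genome, 7, divergence=0.5, seed=37)
sim = SimConfig(n_families=6, rils_per_family=50, seed=37)
G, _ = simulate_nam(founders, genome, sim)
pmap = PhysicalMap(genome.placement_table())

causal = genome.marker_ids[20]
rng = substream(37, "trait")
dos = np.nan_to_num(G.dosage())
genetic = 1.5 * dos[:, 20] + dos @ rng.normal(0, 0.1, G.n_markers)
effects = pd.Series(genetic, index=G.sample_ids)

records = simulate_trial(effects, {"locations": 3, "reps": 2,
                                   "rows": 15, "cols": 20},
                         {"gl": 0.3, "rep": 0.1, "col": 0.1, "row": 0.1,
                          "resid": 1.0}, seed=37, trait="DB", mu=70.0)
vc, blups = fit_trial_model(records)
print("variance components:", {k: round(v, 2) for k, v in vc.sigma2.items()})
print(f"broad-sense heritability (entry-mean): {100 * heritability(vc):.1f}%")

res = mlm_scan(blups, G, kinship(G), n_pcs=3)
qtns = call_qtns({"DB": res.table}, n_markers=len(res.table), alpha=0.1,
                 pmap=pmap)
print(f"\n{len(qtns)} QTNs at the Bonferroni 0.1 cutoff "
      f"(causal marker: {causal}):")
print(qtns[["marker", "chromosome", "position", "traits", "min_p"]]
      .to_string(index=False))
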