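"""Founder-dosage scan, cluster-FDR threshold, and FAP fine-mapping.

A trait with a planted WSB-founder effect is scanned across markers with
adaptive permutation p-values; a null p-value matrix illustrates the
cluster-specific genome-wide threshold; and constructed fine-mapping variants
are grouped by founder-allele pattern.
"""

import numpy as np
import pandas as pd

from bwdyn.genetics import (
    FOUNDERS,
    cluster_fdr_threshold,
    fap_group_variants,
    fap_table,
    founder_scan,
)
from bwdyn.simulate import apply_planted_effect, simulate_founder_genotypes

n, m, planted = 300, 15, 4
dosages = simulate_founder_genotypes(n, m, seed=5)
rng = np.random.default_rng(6)
trait = apply_planted_effect(rng.normal(size=n), dosages[planted],
                             FOUNDERS.index("WSB"), 1.2)
scan = founder_scan(trait, dosages, max_perm=2000, seed=5)
top = min(scan, key=lambda r: (r.p_perm, -r.lod))
print(f"scan of {m} markers: top marker {top.marker_id} "
      f"(planted {dosages[planted].marker_id}), LOD {top.lod:.2f}, "
      f"p_perm {top.p_perm:.4f} from {top.n_perm_used} permutations")

P = pd.DataFrame(rng.uniform(size=(2000, 6)), columns=[f"t{i}" for i in range(6)])
P.iloc[:40, 0] = rng.uniform(0, 1e-5, 40)  # one phenotype with real signal
clusters = {f"t{i}": (1 if i < 3 else 2) for i in range(6)}
per_cluster, study = cluster_fdr_threshold(P, clusters, alpha=0.05, seed=0)
print(f"cluster thresholds {per_cluster} -> study-wide {study:.3g}")

variants = [
    ("v1", 63_900_000, (frozenset({"WSB"}), frozenset(FOUNDERS) - {"WSB"}), 6.0),
    ("v2", 64_100_000, (frozenset({"WSB"}), frozenset(FOUNDERS) - {"WSB"}), 5.2),
    ("v3", 64_300_000, (frozenset({"NOD", "CAST"}),
                        frozenset(FOUNDERS) - {"NOD", "CAST"}), 4.1),
]
print(fap_table(fap_group_variants(variants)).to_string(index=False))
# The top FAP group collects the variants whose minor allele is carried by the
# same founder subset and ranks them by the strongest LOD in the group.
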