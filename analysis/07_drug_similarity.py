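#!/usr/bin/env python
"""Chemical and phenotypic drug-drug similarity on simulated drug data.

Simulates a drug-gene interaction table and MACCS-length fingerprints,
computes the pairwise Tanimoto similarity/dissimilarity matrices and the
phenotypic (shared-target) correlation matrix, and reports the extreme
pairs.  Writes results/drugsim/.
"""

from pathlib import Path

import numpy as np

from kinvar.drugsim import phenotypic_similarity, profiles_from_targets, similarity_matrices
from kinvar.simulate import simulate_drug_data, write_drug_data

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "drugsim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    targets, fingerprints = simulate_drug_data(n_drugs=28, n_genes=10, fp_length=166, seed=11)
    write_drug_data(targets, fingerprints, OUT)

    sim, dissim = similarity_matrices(fingerprints)
    sim.to_csv(OUT / "tanimoto_sim.tsv", sep="\t")
    dissim.to_csv(OUT / "tanimoto_dissim.tsv", sep="\t")
    off = sim.where(~np.eye(len(sim), dtype=bool))
    print(f"{len(fingerprints)} drugs; max pairwise Tanimoto {off.max().max():.2f}, "
          f"max dissimilarity {(1 - off).max().max():.2f}")

    profiles = profiles_from_targets(targets)
    corr = phenotypic_similarity(profiles)
    corr.to_csv(OUT / "phenotypic_corr.tsv", sep="\t")
    pairs = corr.where(~np.eye(len(corr), dtype=bool)).stack()
    perfect = pairs[pairs > 0.999]
    print(f"{len(perfect) // 2} drug pairs with identical target profiles (correlation 1)")
    if not perfect.empty:
        a, b = perfect.index[0]
        print(f"  e.g. {a} and {b}: chemical Tanimoto {sim.loc[a, b]:.2f}, phenotypic 1.00")


if __name__ == "__main__":
    main()
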