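#!/usr/bin/env python
"""Proportion tests of the focal exchange spectrum against each comparison
population, with BH-FDR, plus the exclusive-intersection (UpSet) rows of the
per-comparison significant sets.

Because the simulated comparison cohorts are the same size as the focal
cohort, the pooled two-sample z-test is used (the one-sample form assumes a
fixed reference proportion and is anti-conservative at equal n).  Writes
results/compare/.
"""

from pathlib import Path

from kinvar.compare import (
    compare_populations,
    exclusive_intersections,
    intersections_to_frame,
    results_to_frame,
    significant_pairs,
)
from kinvar.exchange import count_exchanges
from kinvar.io import read_variants

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "compare"
COMPARISONS = ("AMR", "AFR", "EUR", "EAS", "SAS")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    focal = count_exchanges(
        read_variants(ROOT / "sim" / "variants_INDIGEN.tsv", "INDIGEN"), "INDIGEN"
    )
    named_sets = {}
    for pop in COMPARISONS:
        cmp_matrix = count_exchanges(
            read_variants(ROOT / "sim" / f"variants_{pop}.tsv", pop), pop
        )
        results, skipped = compare_populations(focal, cmp_matrix, alpha=0.05, two_sample=True)
        results_to_frame(results).to_csv(OUT / f"indigen_vs_{pop}.tsv", sep="\t", index=False)
        sig = {f"{r}>{a}" for r, a in significant_pairs(results)}
        named_sets[pop] = sig
        print(f"INDIGEN vs {pop}: {len(results)} pairs tested, {len(skipped)} skipped, "
              f"{len(sig)} significant: {sorted(sig) or '-'}")
    rows = exclusive_intersections(named_sets)
    intersections_to_frame(rows).to_csv(OUT / "upset.tsv", sep="\t", index=False)
    print("exclusive intersections (members: size):",
          ", ".join(f"{'|'.join(r.members)}:{r.size}" for r in rows) or "none")


if __name__ == "__main__":
    main()
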