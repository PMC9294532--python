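#!/usr/bin/env python
"""Structure-dataset construction and threshold classification.

Regenerates the simulated study, attaches synthetic crystal-structure
metadata and synthetic per-residue measurements (stand-ins for the tables a
solvent-accessibility / conservation / stability / docking pipeline would
export), applies the five-filter cascade to the focal cohort and runs every
threshold classifier on the retained variants.  Writes results/structure/.
"""

from collections import Counter
from pathlib import Path

from kinvar.simulate import (
    simulate_cohorts,
    simulate_structure_data,
    write_annotations,
    write_structure_records,
)
from kinvar.structure import classify_annotations, structure_filter

import importlib.util

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "structure"


def load_config():
    spec = importlib.util.spec_from_file_location(
        "sim_driver", ROOT / "analysis" / "01_simulate_cohorts.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod.CONFIG


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohorts = simulate_cohorts(load_config())
    records, annotations = simulate_structure_data(
        cohorts, n_structured_genes=20, seed=77, population="INDIGEN"
    )
    write_structure_records(records, OUT / "structures_synthetic.tsv")
    write_annotations(annotations, OUT / "annotations_synthetic.tsv")

    focal = cohorts.variants["INDIGEN"]
    kept, excluded = structure_filter(focal, records, af_min=0.10)
    first_fail = Counter(e.filter_number for e in excluded)
    print(f"filter cascade: {len(kept)}/{len(focal)} focal variants retained")
    for f in sorted(first_fail):
        print(f"  filter {f}: {first_fail[f]} excluded")

    kept_keys = {(v.gene, v.protein_pos, v.ref_aa, v.alt_aa) for v in kept}
    kept_annotations = [
        a for a in annotations
        if (a.gene, a.protein_pos, a.ref_aa, a.alt_aa) in kept_keys
    ]
    table = classify_annotations(kept_annotations)
    table.to_csv(OUT / "classified.tsv", sep="\t", index=False)
    for col in ("exposure", "stability", "flexibility", "conservation_class",
                "hydro_direction", "binding_label"):
        print(f"  {col}: {dict(Counter(table[col].dropna()))}")


if __name__ == "__main__":
    main()
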