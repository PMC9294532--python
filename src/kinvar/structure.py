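"""Structure-dataset filter cascade and per-residue threshold classifiers.

The structural analysis is restricted to variants that can actually be
inspected on a crystal structure.  The cascade applies, in order:

1. a crystal structure exists for the gene;
2. a drug is known against the protein (soft by default — the structural
   set keeps genes without drug interactions, the docking set does not);
3. the variant position is crystallized (resolved in the structure);
4. structure/sequence coverage >= 70%, with an exception for variants whose
   position is crystallized despite lower overall coverage;
5. allele frequency >= 10% in the focal cohort.

Each excluded variant is tagged with the FIRST failing filter number.

The downstream classifiers turn third-party per-residue measurements
(relative solvent accessibility, ConSurf-style relative conservation,
folding-energy and vibrational-entropy changes, hydrogen-bond counts,
docking binding energies) into categorical labels with fixed thresholds:

* buried/exposed at 5% relative accessibility (>= 5 is exposed);
* destabilizing iff ddG < 0; flexibility increased iff ddS > 0;
* highly conserved below -1, highly variable above +1;
* hydrophobicity change on the Fauchere-Pliska octanol/water pi scale,
  significant beyond |delta| = 2;
* H-bond delta = after - before (loss is negative);
* binding-energy delta = E_native - E_mutant (negative: the mutant binds
  the drug more weakly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, InputError, RecordError
from .io import AA_SET, Variant

# Fauchere & Pliska side-chain hydrophobicity scale: pi = log P of the
# N-acetyl amino-acid amide in octanol/water, relative to glycine.
FAUCHERE_PLISKA: dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: DSSP secondary-structure alphabet collapsed to three states.
SS_GROUPS = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
}


def ss_group(ss_code: str) -> str:
    """Collapse a DSSP code to helix / strand / loop."""
    return SS_GROUPS.get(ss_code.upper(), "loop")


@dataclass(frozen=True)
class StructureRecord:
    """Crystal-structure metadata for one gene."""

    gene: str
    pdb_id: str
    coverage: float
    crystallized_positions: frozenset[int]
    has_drug: bool

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise RecordError(f"{self.gene}/{self.pdb_id}: coverage {self.coverage} outside [0, 1]")


def parse_ranges(text: str) -> frozenset[int]:
    """Parse ``30-120,140-300`` (1-based inclusive spans) into a position set."""
    positions: set[int] = set()
    for span in str(text).split(","):
        span = span.strip()
        if not span:
            continue
        if "-" in span:
            lo, hi = span.split("-", 1)
            lo, hi = int(lo), int(hi)
            if lo > hi:
                raise RecordError(f"invalid span {span!r}")
            positions.update(range(lo, hi + 1))
        else:
            positions.add(int(span))
    return frozenset(positions)


def format_ranges(positions: Iterable[int]) -> str:
    """Inverse of :func:`parse_ranges`: compact comma-separated spans."""
    pos = sorted(set(positions))
    if not pos:
        return ""
    spans = []
    lo = prev = pos[0]
    for p in pos[1:]:
        if p == prev + 1:
            prev = p
            continue
        spans.append((lo, prev))
        lo = prev = p
    spans.append((lo, prev))
    return ",".join(f"{a}-{b}" if a != b else str(a) for a, b in spans)


STRUCTURE_COLUMNS = ("gene", "pdb_id", "coverage", "crystallized_ranges", "has_drug")


def read_structures(path) -> list[StructureRecord]:
    """Read structure metadata TSV (see :data:`STRUCTURE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not set(STRUCTURE_COLUMNS) <= set(df.columns):
        raise FormatError(f"{path}: need columns {STRUCTURE_COLUMNS}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StructureRecord(
                gene=str(row.gene),
                pdb_id=str(row.pdb_id),
                coverage=float(row.coverage),
                crystallized_positions=parse_ranges(row.crystallized_ranges),
                has_drug=str(row.has_drug).strip().lower() in {"1", "true", "yes"},
            )
        )
    return out


def write_structures(records: Sequence[StructureRecord], path) -> None:
    rows = [
        {
            "gene": r.gene,
            "pdb_id": r.pdb_id,
            "coverage": f"{r.coverage:.4g}",
            "crystallized_ranges": format_ranges(r.crystallized_positions),
            "has_drug": int(r.has_drug),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(STRUCTURE_COLUMNS)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Exclusion:
    """A variant removed by the cascade, with the first failing filter."""

    variant: Variant
    filter_number: int
    reason: str


def structure_filter(
    variants: Iterable[Variant],
    records: Iterable[StructureRecord],
    af_min: float = 0.10,
    af_inclusive: bool = True,
    coverage_min: float = 0.70,
    require_drug: bool = False,
    coverage_exception: bool = True,
) -> tuple[list[Variant], list[Exclusion]]:
    """Apply the five-filter structure-dataset cascade.

    Parameters
    ----------
    require_drug : bool
        Enforce filter 2 (drug availability).  Off by default: the
        structural set keeps drug-less genes; enable it to reproduce the
        docking subset.
    coverage_exception : bool
        Keep low-coverage structures when the variant position itself is
        crystallized (on by default).

    Returns the retained variants (input order) and one
    :class:`Exclusion` per removed variant, carrying the first failing
    filter number (1-5).
    """
    by_gene = {r.gene: r for r in records}
    kept: list[Variant] = []
    excluded: list[Exclusion] = []
    for v in variants:
        rec = by_gene.get(v.gene)
        if rec is None:
            excluded.append(Exclusion(v, 1, "no crystal structure for gene"))
            continue
        if require_drug and not rec.has_drug:
            excluded.append(Exclusion(v, 2, "no drug against the protein"))
            continue
        crystallized = v.protein_pos in rec.crystallized_positions
        if not crystallized:
            excluded.append(Exclusion(v, 3, "variant position not crystallized"))
            continue
        if rec.coverage < coverage_min and not (coverage_exception and crystallized):
            excluded.append(
                Exclusion(v, 4, f"coverage {rec.coverage:.2f} < {coverage_min:.2f}")
            )
            continue
        af_ok = v.af >= af_min if af_inclusive else v.af > af_min
        if not af_ok:
            excluded.append(Exclusion(v, 5, f"allele frequency {v.af:.3f} below {af_min:.2f}"))
            continue
        kept.append(v)
    return kept, excluded


# --- threshold classifiers -------------------------------------------------

def classify_exposure(rel_accessibility: float, cutoff: float = 5.0) -> str:
    """Buried/exposed at the relative-solvent-accessibility cutoff (>= exposed)."""
    if rel_accessibility < 0:
        raise InputError(f"relative accessibility {rel_accessibility} is negative")
    return "exposed" if rel_accessibility >= cutoff else "buried"


def classify_stability(ddG: float, ddS: float) -> tuple[str, str]:
    """Stability/flexibility labels from folding-energy and entropy changes.

    Destabilizing iff ddG < 0 (kcal/mol); flexibility increased iff ddS > 0
    (kcal/mol/K).  Zero maps to the non-flagged label in both cases.
    """
    stability = "destabilizing" if ddG < 0 else "stabilizing"
    flexibility = "increased" if ddS > 0 else "decreased"
    return stability, flexibility


def classify_conservation(score: float) -> str:
    """Three-way conservation class at the -1/+1 relative-score thresholds."""
    if score < -1.0:
        return "highly_conserved"
    if score > 1.0:
        return "highly_variable"
    return "intermediate"


def hydrophobicity_delta(
    ref_aa: str, alt_aa: str, threshold: float = 2.0
) -> tuple[float, str]:
    """Hydrophobicity change of a substitution on the Fauchere-Pliska scale.

    ``delta = pi(ref) - pi(alt)``: positive means the mutant residue is LESS
    hydrophobic (hydrophobicity decreased).  The class is ``increase`` for
    delta <= -threshold, ``decrease`` for delta >= +threshold, else
    ``no_significant_change``.  For the sign-only tally use
    :func:`hydrophobicity_direction`.
    """
    if ref_aa not in AA_SET or alt_aa not in AA_SET:
        raise InputError(f"nonstandard residue in {ref_aa}->{alt_aa}")
    delta = FAUCHERE_PLISKA[ref_aa] - FAUCHERE_PLISKA[alt_aa]
    if delta <= -threshold:
        cls = "increase"
    elif delta >= threshold:
        cls = "decrease"
    else:
        cls = "no_significant_change"
    return delta, cls


def hydrophobicity_direction(ref_aa: str, alt_aa: str) -> str:
    """Sign-only view: 'decreased' / 'increased' / 'unchanged' hydrophobicity."""
    delta, _ = hydrophobicity_delta(ref_aa, alt_aa)
    if delta > 0:
        return "decreased"
    if delta < 0:
        return "increased"
    return "unchanged"


def hbond_delta(hbonds_before: int, hbonds_after: int) -> int:
    """Hydrogen-bond count change, after - before (a loss is negative)."""
    if hbonds_before < 0 or hbonds_after < 0:
        raise InputError("hydrogen-bond counts must be non-negative")
    return hbonds_after - hbonds_before


def binding_delta(e_native: float, e_mutant: float) -> tuple[float, str]:
    """Binding-energy change between native and mutant docked complexes.

    Energies in kcal/mol, more negative = stronger binding.
    ``delta = e_native - e_mutant``; a negative delta means the mutant binds
    more weakly (label ``decrease``), positive means stronger mutant binding
    (``increase``), zero ``no_change``.
    """
    delta = e_native - e_mutant
    if delta < 0:
        label = "decrease"
    elif delta > 0:
        label = "increase"
    else:
        label = "no_change"
    return delta, label


# --- bundled per-variant classification ------------------------------------

@dataclass(frozen=True)
class ResidueAnnotation:
    """Third-party per-residue measurements for one variant site.

    Optional fields are None when the upstream tool produced no value.
    """

    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    rel_accessibility: float | None = None
    ss_code: str | None = None
    conservation: float | None = None
    ddG: float | None = None
    ddS: float | None = None
    hbonds_before: int | None = None
    hbonds_after: int | None = None
    e_native: float | None = None
    e_mutant: float | None = None


ANNOTATION_COLUMNS = (
    "gene", "protein_pos", "ref_aa", "alt_aa", "rel_accessibility", "ss_code",
    "conservation", "ddG", "ddS", "hbonds_before", "hbonds_after",
    "e_native", "e_mutant",
)


def read_annotations(path) -> list[ResidueAnnotation]:
    """Read a residue-annotation TSV; empty cells become None."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "protein_pos", "ref_aa", "alt_aa"} <= set(df.columns):
        raise FormatError(f"{path}: need at least gene, protein_pos, ref_aa, alt_aa")

    def opt(row, col, cast):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    out = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        out.append(
            ResidueAnnotation(
                gene=str(row["gene"]),
                protein_pos=int(row["protein_pos"]),
                ref_aa=str(row["ref_aa"]),
                alt_aa=str(row["alt_aa"]),
                rel_accessibility=opt(row, "rel_accessibility", float),
                ss_code=opt(row, "ss_code", str),
                conservation=opt(row, "conservation", float),
                ddG=opt(row, "ddG", float),
                ddS=opt(row, "ddS", float),
                hbonds_before=opt(row, "hbonds_before", int),
                hbonds_after=opt(row, "hbonds_after", int),
                e_native=opt(row, "e_native", float),
                e_mutant=opt(row, "e_mutant", float),
            )
        )
    return out


def classify_annotation(ann: ResidueAnnotation) -> dict:
    """Run every applicable threshold classifier on one annotation.

    Measurements that are missing yield None labels (classification skipped)
    rather than errors, so a partially annotated table still classifies.
    """
    out: dict = {
        "gene": ann.gene,
        "protein_pos": ann.protein_pos,
        "ref_aa": ann.ref_aa,
        "alt_aa": ann.alt_aa,
    }
    out["exposure"] = (
        None if ann.rel_accessibility is None else classify_exposure(ann.rel_accessibility)
    )
    out["ss_group"] = None if ann.ss_code is None else ss_group(ann.ss_code)
    out["conservation_class"] = (
        None if ann.conservation is None else classify_conservation(ann.conservation)
    )
    if ann.ddG is None or ann.ddS is None:
        out["stability"] = out["flexibility"] = None
    else:
        out["stability"], out["flexibility"] = classify_stability(ann.ddG, ann.ddS)
    delta, cls = hydrophobicity_delta(ann.ref_aa, ann.alt_aa)
    out["hydro_delta"] = delta
    out["hydro_class"] = cls
    out["hydro_direction"] = hydrophobicity_direction(ann.ref_aa, ann.alt_aa)
    if ann.hbonds_before is None or ann.hbonds_after is None:
        out["hbond_delta"] = None
    else:
        out["hbond_delta"] = hbond_delta(ann.hbonds_before, ann.hbonds_after)
    if ann.e_native is None or ann.e_mutant is None:
        out["binding_delta"] = out["binding_label"] = None
    else:
        out["binding_delta"], out["binding_label"] = binding_delta(ann.e_native, ann.e_mutant)
    return out


def classify_annotations(annotations: Iterable[ResidueAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([classify_annotation(a) for a in annotations])
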