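"""Synthetic multi-population variant cohorts with known ground truth.

The real analysis runs on cohort-scale nonsynonymous variant tables (a
focal Indian cohort against the five continental reference populations).
Those tables cannot ship with the package, so this module generates
statistically analogous data with fully known parameters:

* a reference proteome of ``n_genes`` kinase-like proteins with i.i.d.
  uniform residue composition (or a user-supplied composition), so the
  normalization denominators are nontrivial and known exactly;
* one or two non-overlapping domain intervals per protein covering a
  configurable fraction of its length;
* per-population variant tables drawn from a weighted table of ordered
  ref->alt exchange pairs.  The default weights put extra mass on the
  exchange pairs reported as frequent in human missense data (R->W, C->Y,
  L->F, K->E, N->D, A->T, ...) on top of a uniform floor, so that common
  pairs reach test-relevant expected counts at cohort size;
* population-specific "spikes": multiplicative weight on chosen pairs, the
  planted signal that downstream comparison tests must recover;
* Beta-distributed allele frequencies (default Beta(0.5, 5), a
  low-frequency-heavy spectrum).

Every variant is placed at a proteome position whose reference residue
matches the sampled ref amino acid, so the emitted tables are internally
consistent and parse with zero drops.  A fixed seed reproduces every
artifact byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SimConfigError
from .io import (
    AA_ORDER,
    AA_SET,
    DomainInterval,
    Variant,
    write_domains,
    write_fasta,
    write_variants,
)
from .structure import StructureRecord, ResidueAnnotation, format_ranges

#: Elevated sampling weights for exchange pairs frequent in missense data;
#: every other ordered pair keeps the uniform floor weight of 1.
DEFAULT_ELEVATED_WEIGHTS: dict[tuple[str, str], float] = {
    ("R", "W"): 8.0, ("R", "Q"): 6.0, ("R", "H"): 6.0, ("C", "Y"): 6.0,
    ("L", "F"): 5.0, ("K", "E"): 5.0, ("N", "D"): 5.0, ("A", "T"): 5.0,
    ("T", "A"): 4.0, ("V", "I"): 4.0, ("I", "V"): 4.0, ("E", "K"): 4.0,
    ("G", "R"): 4.0, ("P", "L"): 4.0, ("S", "N"): 4.0, ("A", "V"): 4.0,
    ("D", "N"): 4.0,
}


def default_exchange_table() -> dict[tuple[str, str], float]:
    """Uniform floor of 1 on all 380 ordered pairs plus the elevated set."""
    table = {
        (r, a): 1.0 for r in AA_ORDER for a in AA_ORDER if r != a
    }
    table.update(DEFAULT_ELEVATED_WEIGHTS)
    return table


@dataclass
class SimConfig:
    """Parameters of one synthetic multi-population cohort.

    Defaults are the conditions used throughout the package's own analyses:
    cohorts of 5000 variants over 40 proteins, a focal population plus the
    five continental comparison populations, Beta(0.5, 5) allele
    frequencies and ~45% of each protein under domain annotation.
    """

    n_genes: int = 40
    protein_length_range: tuple[int, int] = (300, 800)
    n_variants_per_population: int = 5000
    populations: tuple[str, ...] = ("INDIGEN", "AMR", "AFR", "EUR", "EAS", "SAS")
    exchange_rate_table: Mapping[tuple[str, str], float] | None = None
    spike_pairs: tuple[tuple[str, str, str, float], ...] = ()
    af_beta_params: tuple[float, float] = (0.5, 5.0)
    domain_fraction: float = 0.45
    residue_composition: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes", f"must be >= 1, got {self.n_genes}")
        lo, hi = self.protein_length_range
        if lo < 30 or hi < lo:
            raise SimConfigError(
                "protein_length_range", f"need 30 <= min <= max, got ({lo}, {hi})"
            )
        if self.n_variants_per_population < 0:
            raise SimConfigError(
                "n_variants_per_population",
                f"must be >= 0, got {self.n_variants_per_population}",
            )
        if not self.populations:
            raise SimConfigError("populations", "need at least one population label")
        if len(set(self.populations)) != len(self.populations):
            raise SimConfigError("populations", "labels must be unique")
        if self.exchange_rate_table is not None:
            weights = list(self.exchange_rate_table.values())
            if any(w < 0 for w in weights):
                raise SimConfigError("exchange_rate_table", "weights must be >= 0")
            if not any(w > 0 for w in weights):
                raise SimConfigError("exchange_rate_table", "need at least one positive weight")
            for ref, alt in self.exchange_rate_table:
                if ref not in AA_SET or alt not in AA_SET or ref == alt:
                    raise SimConfigError(
                        "exchange_rate_table", f"invalid pair ({ref!r}, {alt!r})"
                    )
        for pop, ref, alt, mult in self.spike_pairs:
            if pop not in self.populations:
                raise SimConfigError("spike_pairs", f"unknown population {pop!r}")
            if ref not in AA_SET or alt not in AA_SET or ref == alt:
                raise SimConfigError("spike_pairs", f"invalid pair ({ref!r}, {alt!r})")
            if mult <= 0:
                raise SimConfigError("spike_pairs", f"multiplier must be > 0, got {mult}")
        a, b = self.af_beta_params
        if a <= 0 or b <= 0:
            raise SimConfigError("af_beta_params", f"Beta parameters must be > 0, got ({a}, {b})")
        if not 0.0 < self.domain_fraction < 1.0:
            raise SimConfigError(
                "domain_fraction", f"must be in (0, 1), got {self.domain_fraction}"
            )
        if self.residue_composition is not None:
            if any(w < 0 for w in self.residue_composition.values()):
                raise SimConfigError("residue_composition", "weights must be >= 0")
            if sum(self.residue_composition.values()) <= 0:
                raise SimConfigError("residue_composition", "weights must sum to > 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    realized_counts: dict[str, dict[tuple[str, str], int]]
    spike_pairs: tuple[tuple[str, str, str, float], ...]
    domains: list[DomainInterval]
    allele_frequencies: dict[str, np.ndarray]
    pair_probabilities: dict[str, dict[tuple[str, str], float]]


@dataclass
class Cohorts:
    """One synthetic study: per-population variants plus shared references."""

    variants: dict[str, list[Variant]]
    proteome: dict[str, str]
    domains: list[DomainInterval] = field(default_factory=list)
    ground_truth: GroundTruth | None = None

    def write(self, outdir) -> None:
        """Write all artifacts as plain text under ``outdir``.

        One ``variants_<POP>.tsv`` per population, ``reference.fasta`` and
        ``domains.tsv``.  Output is deterministic given the config seed.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pop, variants in self.variants.items():
            write_variants(variants, outdir / f"variants_{pop}.tsv")
        write_fasta(self.proteome, outdir / "reference.fasta")
        write_domains(self.domains, outdir / "domains.tsv")


def _gene_name(i: int) -> str:
    return f"KIN{i + 1:04d}"


def _make_proteome(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    lo, hi = config.protein_length_range
    aas = np.array(list(AA_ORDER))
    if config.residue_composition is None:
        probs = None
    else:
        w = np.array([config.residue_composition.get(aa, 0.0) for aa in AA_ORDER])
        probs = w / w.sum()
    proteome = {}
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aas, size=length, p=probs)
        proteome[_gene_name(i)] = "".join(seq)
    return proteome


def _make_domains(
    config: SimConfig, proteome: Mapping[str, str], rng: np.random.Generator
) -> list[DomainInterval]:
    """One or two non-overlapping intervals per protein, uniformly placed,
    jointly covering ~domain_fraction of the sequence."""
    domains: list[DomainInterval] = []
    for gene, seq in proteome.items():
        length = len(seq)
        total = max(1, round(config.domain_fraction * length))
        n_dom = int(rng.integers(1, 3))  # 1 or 2
        if n_dom == 2 and total >= 2:
            d1 = int(rng.integers(1, total))
            parts = [d1, total - d1]
        else:
            parts = [total]
        free = length - total
        gaps = rng.multinomial(free, [1.0 / (len(parts) + 1)] * (len(parts) + 1))
        pos = 0
        for k, width in enumerate(parts):
            pos += int(gaps[k])
            start = pos + 1  # 1-based inclusive
            end = pos + width
            suffix = "" if len(parts) == 1 else f"_{k + 1}"
            domains.append(DomainInterval(gene=gene, name=f"PK_dom{suffix}", start=start, end=end))
            pos = end
    return domains


def _site_index(proteome: Mapping[str, str]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-residue site catalogue: aa -> (gene-name array, 1-based position array)."""
    genes: dict[str, list[str]] = {aa: [] for aa in AA_ORDER}
    positions: dict[str, list[int]] = {aa: [] for aa in AA_ORDER}
    for gene, seq in proteome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for aa in AA_ORDER:
            hits = np.flatnonzero(arr == aa.encode())
            if hits.size:
                genes[aa].extend([gene] * hits.size)
                positions[aa].extend((hits + 1).tolist())
    return {
        aa: (np.array(genes[aa], dtype=object), np.array(positions[aa], dtype=np.int64))
        for aa in AA_ORDER
    }


def simulate_cohorts(config: SimConfig) -> Cohorts:
    """Generate the full synthetic study described by ``config``.

    All randomness flows from ``config.seed``; identical configs produce
    identical (byte-for-byte, once written) artifacts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteome = _make_proteome(config, rng)
    domains = _make_domains(config, proteome, rng)
    sites = _site_index(proteome)

    table = dict(
        config.exchange_rate_table
        if config.exchange_rate_table is not None
        else default_exchange_table()
    )
    pairs = sorted(table)
    base_weights = np.array([table[p] for p in pairs], dtype=float)
    # A pair whose reference residue never occurs in the proteome cannot be
    # placed; its weight is dropped before normalization.
    placeable = np.array([sites[ref][1].size > 0 for ref, _ in pairs])
    base_weights = np.where(placeable, base_weights, 0.0)
    if base_weights.sum() <= 0:
        raise SimConfigError(
            "exchange_rate_table",
            "no positive-weight pair has a placeable reference residue",
        )

    alpha, beta = config.af_beta_params
    n = config.n_variants_per_population
    variants: dict[str, list[Variant]] = {}
    realized: dict[str, dict[tuple[str, str], int]] = {}
    afs: dict[str, np.ndarray] = {}
    pair_probs: dict[str, dict[tuple[str, str], float]] = {}

    for pop in config.populations:
        weights = base_weights.copy()
        for spop, ref, alt, mult in config.spike_pairs:
            if spop == pop and (ref, alt) in table:
                weights[pairs.index((ref, alt))] *= mult
            elif spop == pop:
                raise SimConfigError(
                    "spike_pairs", f"pair ({ref}, {alt}) absent from exchange_rate_table"
                )
        probs = weights / weights.sum()
        pair_probs[pop] = {p: float(pr) for p, pr in zip(pairs, probs) if pr > 0}

        idx = rng.choice(len(pairs), size=n, p=probs) if n else np.array([], dtype=int)
        af = rng.beta(alpha, beta, size=n)
        # Vectorized site placement: per reference residue, draw uniform site
        # indices for all variants needing that residue at once.
        refs = np.array([pairs[i][0] for i in idx], dtype="U1") if n else np.array([], dtype="U1")
        alts = np.array([pairs[i][1] for i in idx], dtype="U1") if n else np.array([], dtype="U1")
        site_genes = np.empty(n, dtype=object)
        site_pos = np.empty(n, dtype=np.int64)
        for aa in AA_ORDER:
            mask = refs == aa
            m = int(mask.sum())
            if m == 0:
                continue
            gene_arr, pos_arr = sites[aa]
            picks = rng.integers(gene_arr.size, size=m)
            site_genes[mask] = gene_arr[picks]
            site_pos[mask] = pos_arr[picks]
        variants[pop] = [
            Variant(
                gene=site_genes[k],
                protein_pos=int(site_pos[k]),
                ref_aa=str(refs[k]),
                alt_aa=str(alts[k]),
                af=float(af[k]),
                population=pop,
            )
            for k in range(n)
        ]
        counts = np.bincount(idx, minlength=len(pairs))
        realized[pop] = {p: int(c) for p, c in zip(pairs, counts) if c}
        afs[pop] = af

    truth = GroundTruth(
        realized_counts=realized,
        spike_pairs=config.spike_pairs,
        domains=domains,
        allele_frequencies=afs,
        pair_probabilities=pair_probs,
    )
    return Cohorts(variants=variants, proteome=proteome, domains=domains, ground_truth=truth)


def simulate_drug_data(
    n_drugs: int, n_genes: int, fp_length: int = 166, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Random drug-gene interaction table and binary fingerprints.

    Every drug receives at least one target gene; target counts follow
    1 + Poisson(1) capped at the panel size (drugs are mildly promiscuous).
    Fingerprints are i.i.d. Bernoulli(0.3) bit vectors of ``fp_length``
    (166 emulates MACCS keys; any positive length is accepted).
    """
    if n_drugs < 1:
        raise SimConfigError("n_drugs", f"must be >= 1, got {n_drugs}")
    if n_genes < 1:
        raise SimConfigError("n_genes", f"must be >= 1, got {n_genes}")
    if fp_length < 1:
        raise SimConfigError("fp_length", f"must be >= 1, got {fp_length}")
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    rows = []
    fingerprints: dict[str, np.ndarray] = {}
    for d in range(n_drugs):
        drug = f"DRUG{d + 1:03d}"
        n_targets = min(n_genes, 1 + int(rng.poisson(1.0)))
        targets = rng.choice(n_genes, size=n_targets, replace=False)
        for t in sorted(targets):
            rows.append({"drug_id": drug, "gene": genes[t]})
        fingerprints[drug] = (rng.random(fp_length) < 0.3).astype(np.uint8)
    return pd.DataFrame(rows, columns=["drug_id", "gene"]), fingerprints


def write_drug_data(
    drug_targets: pd.DataFrame, fingerprints: Mapping[str, np.ndarray], outdir
) -> None:
    """Write the drug-gene TSV and a ``drug_id  bitstring`` fingerprint TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drug_targets.to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)
    rows = [
        {"drug_id": d, "bitstring": "".join(map(str, bits))}
        for d, bits in fingerprints.items()
    ]
    pd.DataFrame(rows, columns=["drug_id", "bitstring"]).to_csv(
        outdir / "fingerprints.tsv", sep="\t", index=False
    )


def read_fingerprints(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return {
        str(r.drug_id): np.array([int(c) for c in str(r.bitstring)], dtype=np.uint8)
        for r in df.itertuples(index=False)
    }


def simulate_structure_data(
    cohorts: Cohorts,
    n_structured_genes: int | None = None,
    seed: int = 0,
    population: str | None = None,
) -> tuple[list[StructureRecord], list[ResidueAnnotation]]:
    """Synthetic crystal-structure metadata and per-residue annotations.

    This is a stand-in for the tables a structural pipeline (solvent
    accessibility, conservation, stability prediction, H-bond counting,
    docking) would export: coverage and crystallized spans per structure,
    and plausible marginal distributions for every downstream measurement.
    It exists so the filter cascade and the threshold classifiers are
    exercisable end-to-end; its values carry no biological meaning.
    """
    rng = np.random.default_rng(seed)
    genes = list(cohorts.proteome)
    if n_structured_genes is None:
        n_structured_genes = max(1, len(genes) // 2)
    chosen = sorted(rng.choice(len(genes), size=min(n_structured_genes, len(genes)), replace=False))

    records: list[StructureRecord] = []
    for i in chosen:
        gene = genes[i]
        length = len(cohorts.proteome[gene])
        coverage = float(rng.uniform(0.5, 1.0))
        span = max(1, round(coverage * length))
        start = int(rng.integers(1, length - span + 2))
        records.append(
            StructureRecord(
                gene=gene,
                pdb_id=f"9{rng.integers(100, 1000)}",
                coverage=coverage,
                crystallized_positions=frozenset(range(start, start + span)),
                has_drug=bool(rng.random() < 0.8),
            )
        )

    structured = {r.gene for r in records}
    annotations: list[ResidueAnnotation] = []
    pops = cohorts.variants if population is None else {population: cohorts.variants[population]}
    for pop_variants in pops.values():
        for v in pop_variants:
            if v.gene not in structured:
                continue
            before = int(rng.poisson(2.0))
            e_native = float(rng.uniform(-13.0, -5.0))
            annotations.append(
                ResidueAnnotation(
                    gene=v.gene,
                    protein_pos=v.protein_pos,
                    ref_aa=v.ref_aa,
                    alt_aa=v.alt_aa,
                    rel_accessibility=float(np.clip(rng.exponential(25.0), 0.0, 100.0)),
                    ss_code=str(rng.choice(list("HGIEBTS-"))),
                    conservation=float(rng.normal(0.0, 1.0)),
                    ddG=float(rng.normal(-0.3, 1.5)),
                    ddS=float(rng.normal(0.2, 0.8)),
                    hbonds_before=before,
                    hbonds_after=max(0, before + int(rng.integers(-2, 3))),
                    e_native=e_native,
                    e_mutant=float(e_native + rng.normal(1.0, 2.5)),
                )
            )
    return records, annotations


def write_annotations(annotations: Sequence[ResidueAnnotation], path) -> None:
    from .structure import ANNOTATION_COLUMNS

    rows = [{c: getattr(a, c) for c in ANNOTATION_COLUMNS} for a in annotations]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_structure_records(records: Sequence[StructureRecord], path) -> None:
    from .structure import write_structures

    write_structures(records, path)
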