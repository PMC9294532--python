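"""Readers and writers for the shared data model.

Input formats are plain text: tab-separated variant tables (one per
population), a reference proteome in FASTA, and Pfam-style domain interval
tables.  All protein coordinates are 1-based inclusive, matching HGVS and
PfamScan conventions, and stay 1-based everywhere in the package.

A variant row needs a gene symbol, a protein position, reference and
alternate residues (one- or three-letter code, or a combined protein-change
string such as ``R275H`` / ``p.Arg275His``) and an allele frequency.
Synonymous rows (ref == alt) are rejected: the analysis is defined over
nonsynonymous variants only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError, RecordError

log = logging.getLogger(__name__)

#: The 20 standard amino acids in fixed alphabetical one-letter order.
#: This ordering indexes every 20x20 matrix in the package.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ORDER)

#: Three-letter -> one-letter residue codes (standard amino acids only).
THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_PROTEIN_CHANGE_RE = re.compile(
    r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$"
)


def normalize_residue(code: str) -> str:
    """Return the one-letter code for ``code`` (one- or three-letter).

    Raises
    ------
    RecordError
        If the code is not one of the 20 standard amino acids.
    """
    code = code.strip()
    if len(code) == 1:
        aa = code.upper()
    elif len(code) == 3:
        aa = THREE_TO_ONE.get(code.upper(), "?")
    else:
        aa = "?"
    if aa not in AA_SET:
        raise RecordError(f"unknown residue code {code!r}")
    return aa


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse a protein-change string like ``R275H`` or ``p.Arg275His``.

    Returns ``(ref_aa, position, alt_aa)`` with one-letter residues.
    """
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if m is None:
        raise RecordError(f"unparseable protein change {text!r}")
    ref, pos, alt = m.groups()
    return normalize_residue(ref), int(pos), normalize_residue(alt)


@dataclass(frozen=True)
class Variant:
    """One nonsynonymous variant at the protein level.

    Attributes
    ----------
    gene : str
        Gene symbol.
    protein_pos : int
        1-based residue index in the gene's protein sequence.
    ref_aa, alt_aa : str
        One-letter reference and alternate residues; must differ.
    af : float
        Allele frequency in the population this record came from, in [0, 1].
    population : str
        Population label the record belongs to.
    rsid : str or None
        Optional variant identifier.
    """

    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    af: float
    population: str = ""
    rsid: str | None = None

    def __post_init__(self):
        if self.ref_aa not in AA_SET:
            raise RecordError(f"ref_aa {self.ref_aa!r} is not a standard residue")
        if self.alt_aa not in AA_SET:
            raise RecordError(f"alt_aa {self.alt_aa!r} is not a standard residue")
        if self.ref_aa == self.alt_aa:
            raise RecordError(
                f"synonymous record {self.gene} {self.ref_aa}{self.protein_pos}"
                f"{self.alt_aa}: ref and alt residues are equal"
            )
        if self.protein_pos < 1:
            raise RecordError(f"protein_pos {self.protein_pos} must be >= 1")
        if not 0.0 <= self.af <= 1.0:
            raise RecordError(f"allele frequency {self.af} outside [0, 1]")


@dataclass(frozen=True)
class DomainInterval:
    """A named domain region of a protein, 1-based inclusive."""

    gene: str
    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise RecordError(
                f"domain {self.name} on {self.gene}: invalid interval "
                f"[{self.start}, {self.end}]"
            )

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ReferenceComposition:
    """Residue counts over a set of reference protein sequences.

    ``counts[a]`` is the number of occurrences of residue ``a`` across the
    analyzed gene set; ``total`` is the summed sequence length (excluding
    non-standard characters).  This is the denominator of the normalized
    exchange matrix and of the mutability score.
    """

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def count(self, aa: str) -> int:
        return self.counts.get(aa, 0)

    def fraction(self, aa: str) -> float:
        """Frequency of occurrence of ``aa`` among all counted residues."""
        if self.total == 0:
            return 0.0
        return self.counts.get(aa, 0) / self.total


VARIANT_COLUMNS = ("gene", "protein_pos", "ref_aa", "alt_aa", "af")


def read_variants(
    path,
    population: str = "",
    strict: bool = False,
) -> list[Variant]:
    """Read a variant table (TSV, ``#`` comments ignored) into Variants.

    The table must carry a ``gene`` and ``af`` column plus either the
    (``protein_pos``, ``ref_aa``, ``alt_aa``) triple or a single
    ``protein_change`` column holding strings like ``R275H`` or
    ``p.Arg275His``.  An ``rsid`` column is picked up when present.

    Malformed rows are logged with their line number and skipped; with
    ``strict=True`` the first bad row raises :class:`RecordError` instead.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = set(df.columns)
    has_triple = {"protein_pos", "ref_aa", "alt_aa"} <= cols
    has_change = "protein_change" in cols
    if "gene" not in cols or "af" not in cols or not (has_triple or has_change):
        raise FormatError(
            f"{path}: need columns gene, af and either "
            f"(protein_pos, ref_aa, alt_aa) or protein_change; got {sorted(cols)}"
        )

    variants: list[Variant] = []
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            if has_triple and not pd.isna(row["protein_pos"]):
                pos = int(row["protein_pos"])
                ref = normalize_residue(str(row["ref_aa"]))
                alt = normalize_residue(str(row["alt_aa"]))
            else:
                ref, pos, alt = parse_protein_change(str(row["protein_change"]))
            rsid = row.get("rsid")
            variants.append(
                Variant(
                    gene=str(row["gene"]),
                    protein_pos=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    af=float(row["af"]),
                    population=population,
                    rsid=None if rsid is None or pd.isna(rsid) else str(rsid),
                )
            )
        except (RecordError, ValueError) as exc:
            if strict:
                raise RecordError(f"{path} line {i}: {exc}") from exc
            n_bad += 1
            log.warning("%s line %d: skipped (%s)", path, i, exc)
    if n_bad:
        log.warning("%s: %d malformed row(s) skipped", path, n_bad)
    return variants


def write_variants(variants: Iterable[Variant], path) -> None:
    """Write variants as TSV with the canonical five-column header."""
    rows = [
        {
            "gene": v.gene,
            "protein_pos": v.protein_pos,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "af": f"{v.af:.6g}",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


_EXCLUDED_CHARS = frozenset("XUBZJO*")


def composition_from_fasta(
    path, gene_subset: Iterable[str] | None = None
) -> ReferenceComposition:
    """Count residues over the FASTA sequences of ``gene_subset``.

    The first whitespace-delimited token of each FASTA header is the gene
    symbol.  Exactly one sequence per gene is required (a duplicate header
    raises :class:`FormatError`).  Ambiguity codes and selenocysteine
    (X, U, B, Z, J, O, ``*``) are excluded from the counts with a logged
    warning; anything else outside the 20 standard residues raises.
    """
    subset = None if gene_subset is None else set(gene_subset)
    counts: dict[str, int] = {aa: 0 for aa in AA_ORDER}
    seen: set[str] = set()
    n_excluded = 0
    n_used = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id.split()[0]
        if subset is not None and gene not in subset:
            continue
        if gene in seen:
            raise FormatError(f"{path}: duplicate sequence for gene {gene}")
        seen.add(gene)
        n_used += 1
        for ch in str(rec.seq).upper():
            if ch in AA_SET:
                counts[ch] += 1
            elif ch in _EXCLUDED_CHARS:
                n_excluded += 1
            else:
                raise RecordError(f"{path}: invalid sequence character {ch!r} in {gene}")
    if n_used == 0:
        raise InputError(f"{path}: no sequences match the requested gene subset")
    if subset is not None and seen != subset:
        missing = sorted(subset - seen)
        log.warning("%s: no sequence for gene(s) %s", path, ", ".join(missing))
    if n_excluded:
        log.warning("%s: %d non-standard residue(s) excluded from counts", path, n_excluded)
    return ReferenceComposition(counts=counts, total=sum(counts.values()))


def composition_from_sequences(seqs: Mapping[str, str]) -> ReferenceComposition:
    """Composition straight from an in-memory ``gene -> sequence`` mapping."""
    counts: dict[str, int] = {aa: 0 for aa in AA_ORDER}
    for seq in seqs.values():
        for ch in seq.upper():
            if ch in AA_SET:
                counts[ch] += 1
    return ReferenceComposition(counts=counts, total=sum(counts.values()))


DOMAIN_COLUMNS = ("gene", "hmm_name", "hmm_start", "hmm_end")


def read_domains(path, strict: bool = False) -> list[DomainInterval]:
    """Read a domain table TSV (``gene  hmm_name  hmm_start  hmm_end``).

    Overlapping intervals on one gene are permitted and preserved.  Rows with
    ``start > end`` are record errors (skipped with a logged line number, or
    fatal under ``strict=True``).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not set(DOMAIN_COLUMNS) <= set(df.columns):
        raise FormatError(f"{path}: need columns {DOMAIN_COLUMNS}, got {list(df.columns)}")
    out: list[DomainInterval] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            out.append(
                DomainInterval(
                    gene=str(row["gene"]),
                    name=str(row["hmm_name"]),
                    start=int(row["hmm_start"]),
                    end=int(row["hmm_end"]),
                )
            )
        except (RecordError, ValueError) as exc:
            if strict:
                raise RecordError(f"{path} line {i}: {exc}") from exc
            log.warning("%s line %d: skipped (%s)", path, i, exc)
    return out


def write_domains(intervals: Sequence[DomainInterval], path) -> None:
    rows = [
        {"gene": d.gene, "hmm_name": d.name, "hmm_start": d.start, "hmm_end": d.end}
        for d in intervals
    ]
    pd.DataFrame(rows, columns=list(DOMAIN_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path) -> None:
    """Write a ``gene -> sequence`` mapping as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for gene in seqs:
            fh.write(f">{gene}\n")
            seq = seqs[gene]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
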