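"""Chemical-class views of the exchange spectrum.

Two built-in classifications of the 20 residues by side-chain chemistry:

* ``SCHEME12`` — twelve overlapping classes (a residue may belong to
  several, e.g. Arg is both Basic and Hydrophilic).  Used for the
  class-to-class conversion matrix.
* ``SCHEME6`` — six pairwise-disjoint classes chosen to avoid repetition
  (Aliphatic, Hydroxyl, Cyclic, Aromatic, Basic, Acidic).  Four residues
  (N, Q, C, M) belong to no class and are tallied in explicit
  ``unclassified`` margins rather than silently dropped.  Used for the net
  gain/loss analysis.

Under an overlapping scheme a single variant increments every
(ref-class, alt-class) cell whose classes contain the respective residues,
so the matrix total is sum over variants of |classes(ref)| * |classes(alt)|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import FormatError, InputError
from .io import AA_SET, Variant


@dataclass(frozen=True)
class ClassScheme:
    """A named partition (or cover) of the residues by chemical class."""

    name: str
    classes: Mapping[str, frozenset[str]]
    disjoint: bool = False

    def __post_init__(self):
        for cname, members in self.classes.items():
            if not members:
                raise InputError(f"scheme {self.name}: class {cname} is empty")
            bad = members - AA_SET
            if bad:
                raise InputError(
                    f"scheme {self.name}: class {cname} has non-standard "
                    f"residues {sorted(bad)}"
                )
        if self.disjoint:
            seen: set[str] = set()
            for cname, members in self.classes.items():
                overlap = seen & members
                if overlap:
                    raise InputError(
                        f"scheme {self.name} declared disjoint but residues "
                        f"{sorted(overlap)} appear in more than one class"
                    )
                seen |= members

    def classes_of(self, aa: str) -> list[str]:
        return [c for c, members in self.classes.items() if aa in members]

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)


def _fs(residues: str) -> frozenset[str]:
    return frozenset(residues)


SCHEME12 = ClassScheme(
    name="scheme12",
    classes={
        "Hydrophilic": _fs("STYNQDEKRH"),
        "Hydrophobic": _fs("GAVPLIMWCF"),
        "Non-polar": _fs("GAVPLIMWF"),
        "Uncharged polar": _fs("STCYNQ"),
        "Aliphatic": _fs("GAVLI"),
        "Hydroxyl": _fs("ST"),
        "Amides": _fs("NQ"),
        "Basic": _fs("KRH"),
        "Acidic": _fs("DE"),
        "Aromatic": _fs("FYW"),
        "Cyclic": _fs("P"),
        "Sulpho": _fs("CM"),
    },
    disjoint=False,
)

SCHEME6 = ClassScheme(
    name="scheme6",
    classes={
        "Aliphatic": _fs("GAVLI"),
        "Hydroxyl": _fs("ST"),
        "Cyclic": _fs("P"),
        "Aromatic": _fs("FYW"),
        "Basic": _fs("KRH"),
        "Acidic": _fs("DE"),
    },
    disjoint=True,
)


def read_scheme(path, name: str | None = None, disjoint: bool = False) -> ClassScheme:
    """Read a custom scheme from TSV ``class_name  residues``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"class_name", "residues"} <= set(df.columns):
        raise FormatError(f"{path}: need columns class_name, residues")
    classes = {
        str(r.class_name): _fs(str(r.residues).upper()) for r in df.itertuples()
    }
    return ClassScheme(name=name or str(path), classes=classes, disjoint=disjoint)


@dataclass
class ClassExchangeMatrix:
    """K x K class-conversion counts plus unclassified-residue margins."""

    counts: pd.DataFrame
    scheme: ClassScheme
    unclassified_ref: int = 0
    unclassified_alt: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def class_exchange_counts(
    variants: Iterable[Variant], scheme: ClassScheme = SCHEME12
) -> ClassExchangeMatrix:
    """Count conversions from each ref class to each alt class.

    Each variant increments every cell (C_ref, C_alt) with ref_aa in C_ref
    and alt_aa in C_alt.  A residue belonging to no class of the scheme is
    counted once in the matching unclassified margin.
    """
    names = scheme.class_names
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    idx = {c: i for i, c in enumerate(names)}
    un_ref = un_alt = 0
    for v in variants:
        ref_classes = scheme.classes_of(v.ref_aa)
        alt_classes = scheme.classes_of(v.alt_aa)
        if not ref_classes:
            un_ref += 1
        if not alt_classes:
            un_alt += 1
        for cr in ref_classes:
            for ca in alt_classes:
                counts[idx[cr], idx[ca]] += 1
    return ClassExchangeMatrix(
        counts=pd.DataFrame(counts, index=names, columns=names),
        scheme=scheme,
        unclassified_ref=un_ref,
        unclassified_alt=un_alt,
    )


@dataclass
class NetShift:
    """Per-class residue counts at variant sites, reference vs alternate.

    ``delta[c] = alt_count[c] - ref_count[c]``: positive means a net gain of
    that class after substitution, negative a net loss.
    """

    ref_count: dict[str, int]
    alt_count: dict[str, int]
    unclassified_ref: int
    unclassified_alt: int
    scheme: ClassScheme = field(repr=False, default=SCHEME6)

    @property
    def delta(self) -> dict[str, int]:
        return {
            c: self.alt_count[c] - self.ref_count[c] for c in self.scheme.class_names
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "ref_count": self.ref_count[c],
                "alt_count": self.alt_count[c],
                "delta": self.alt_count[c] - self.ref_count[c],
            }
            for c in self.scheme.class_names
        ]
        return pd.DataFrame(rows)


def net_class_shift(variants: Iterable[Variant], scheme: ClassScheme = SCHEME6) -> NetShift:
    """Net gain/loss of each chemical class across variant sites.

    Requires a disjoint scheme so every residue contributes to at most one
    class on each side.
    """
    if not scheme.disjoint:
        raise InputError(f"net_class_shift requires a disjoint scheme, got {scheme.name}")
    ref_count = {c: 0 for c in scheme.class_names}
    alt_count = {c: 0 for c in scheme.class_names}
    un_ref = un_alt = 0
    for v in variants:
        rc = scheme.classes_of(v.ref_aa)
        ac = scheme.classes_of(v.alt_aa)
        if rc:
            ref_count[rc[0]] += 1
        else:
            un_ref += 1
        if ac:
            alt_count[ac[0]] += 1
        else:
            un_alt += 1
    return NetShift(
        ref_count=ref_count,
        alt_count=alt_count,
        unclassified_ref=un_ref,
        unclassified_alt=un_alt,
        scheme=scheme,
    )


def cluster_order(matrix: ClassExchangeMatrix) -> list[str]:
    """Row ordering from average-linkage hierarchical clustering.

    Euclidean distance over matrix rows; returns class names in dendrogram
    leaf order.  Emitted as an ordering only — no figure is drawn here.
    """
    data = matrix.counts.to_numpy(dtype=float)
    if data.shape[0] < 3:
        return list(matrix.counts.index)
    order = leaves_list(linkage(data, method="average", metric="euclidean"))
    return [matrix.counts.index[i] for i in order]
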