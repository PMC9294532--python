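"""Position of variants relative to annotated protein domains.

A variant is ``within`` a domain when its residue index falls inside any
annotated interval (1-based, inclusive at both ends); its distance is then
0.  Positions before the first interval are ``pre`` (distance to the first
start); everything else — after the last interval or between two intervals —
is ``post``, with distance to the nearest interval boundary.  Genes without
any domain annotation yield ``no_domain`` and are reported separately from
the three-way counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import DomainInterval, Variant

CATEGORIES = ("pre", "within", "post", "no_domain")


@dataclass(frozen=True)
class DomainClassification:
    """Where one variant sits relative to its gene's domain intervals."""

    variant: Variant
    category: str
    distance: int
    domain_name: str | None = None


def classify_position(
    protein_pos: int, intervals: Sequence[DomainInterval]
) -> tuple[str, int, str | None]:
    """Classify a residue position against a gene's domain intervals.

    Returns ``(category, distance, domain_name)`` where ``domain_name`` is
    the containing interval for ``within`` and the nearest interval
    otherwise (None for ``no_domain``).
    """
    if not intervals:
        return "no_domain", 0, None
    for iv in intervals:
        if protein_pos in iv:
            return "within", 0, iv.name
    first_start = min(iv.start for iv in intervals)
    if protein_pos < first_start:
        nearest = min(intervals, key=lambda iv: iv.start)
        return "pre", first_start - protein_pos, nearest.name
    # After the first domain but inside no interval: post, distance to the
    # nearest boundary of any interval.
    def gap(iv: DomainInterval) -> int:
        return min(abs(protein_pos - iv.start), abs(protein_pos - iv.end))

    nearest = min(intervals, key=gap)
    return "post", gap(nearest), nearest.name


def classify_variants(
    variants: Iterable[Variant], intervals: Iterable[DomainInterval]
) -> list[DomainClassification]:
    """Classify every variant against its own gene's intervals."""
    by_gene: dict[str, list[DomainInterval]] = defaultdict(list)
    for iv in intervals:
        by_gene[iv.gene].append(iv)
    out = []
    for v in variants:
        category, distance, name = classify_position(v.protein_pos, by_gene.get(v.gene, []))
        out.append(DomainClassification(v, category, distance, name))
    return out


def domain_summary(
    classifications: Iterable[DomainClassification],
) -> pd.DataFrame:
    """Category counts per population (pre/within/post; no_domain separate)."""
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {c: 0 for c in CATEGORIES})
    for c in classifications:
        counts[c.variant.population][c.category] += 1
    rows = [
        {"population": pop, **cat_counts}
        for pop, cat_counts in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["population", *CATEGORIES])


def classifications_to_frame(
    classifications: Sequence[DomainClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.variant.gene,
                "protein_pos": c.variant.protein_pos,
                "ref_aa": c.variant.ref_aa,
                "alt_aa": c.variant.alt_aa,
                "category": c.category,
                "distance": c.distance,
                "domain_name": c.domain_name or "",
            }
            for c in classifications
        ],
        columns=["gene", "protein_pos", "ref_aa", "alt_aa", "category", "distance", "domain_name"],
    )
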