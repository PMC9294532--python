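"""Amino-acid exchange matrices and mutability scores.

The exchange matrix counts, for one population, how often each reference
residue is substituted by each alternate residue across all nonsynonymous
variants.  Counts are normalized against the residue composition of the
reference proteome:

    normalized[ref][alt] = counts[ref][alt] / composition.count(ref) * 100

so a cell reads "percent of the reference pool of that residue observed
substituted to the alternate residue".  A frequency-scale view (percent /
100) is provided alongside, since published figures use both axes.

Mutability of a residue type ``a`` is the number of observed substitutions
at ``a`` sites (after an allele-frequency filter) divided by the frequency
of occurrence of ``a`` in the reference sequences:

    mutability[a] = n_variants(ref_aa == a) / (count(a) / total_residues)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError
from .io import AA_ORDER, ReferenceComposition, Variant

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass
class ExchangeMatrix:
    """20x20 exchange counts (and, once normalized, percentages).

    Rows index the reference residue, columns the alternate residue, both in
    :data:`kinvar.io.AA_ORDER`.  The diagonal is structurally zero because
    synonymous records never enter the data model.
    """

    counts: np.ndarray
    population: str = ""
    normalized: np.ndarray | None = None

    @property
    def n_variants(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized_frequency(self) -> np.ndarray:
        """Frequency-scale (0-1) view of the percent-scale normalization."""
        if self.normalized is None:
            raise InputError("matrix has not been normalized")
        return self.normalized / 100.0

    def count(self, ref_aa: str, alt_aa: str) -> int:
        return int(self.counts[AA_INDEX[ref_aa], AA_INDEX[alt_aa]])

    def to_frame(self, which: str = "counts") -> pd.DataFrame:
        data = self.counts if which == "counts" else self.normalized
        if data is None:
            raise InputError("matrix has not been normalized")
        order = list(AA_ORDER)
        return pd.DataFrame(data, index=order, columns=order)


def count_exchanges(variants: Iterable[Variant], population: str = "") -> ExchangeMatrix:
    """Tally ref->alt residue exchanges into a 20x20 count matrix."""
    counts = np.zeros((20, 20), dtype=np.int64)
    for v in variants:
        counts[AA_INDEX[v.ref_aa], AA_INDEX[v.alt_aa]] += 1
    return ExchangeMatrix(counts=counts, population=population)


def normalize(matrix: ExchangeMatrix, composition: ReferenceComposition) -> ExchangeMatrix:
    """Fill the percent-scale normalized matrix against a reference composition.

    Rows whose reference residue never occurs in the composition must be
    all-zero in the counts; otherwise the composition cannot have produced
    the variants and a :class:`ConsistencyError` is raised.
    """
    ref_counts = np.array([composition.count(aa) for aa in AA_ORDER], dtype=float)
    normalized = np.zeros_like(matrix.counts, dtype=float)
    for i, aa in enumerate(AA_ORDER):
        row_total = matrix.counts[i].sum()
        if ref_counts[i] == 0:
            if row_total > 0:
                raise ConsistencyError(
                    f"{row_total} exchange(s) observed at {aa} sites but the "
                    f"reference composition contains no {aa}"
                )
            continue
        normalized[i] = matrix.counts[i] / ref_counts[i] * 100.0
    return ExchangeMatrix(
        counts=matrix.counts, population=matrix.population, normalized=normalized
    )


@dataclass
class MutabilityScores:
    """Per-residue mutability (observed substitutions over reference frequency)."""

    scores: dict[str, float] = field(default_factory=dict)
    af_threshold: float = 0.0
    population: str = ""

    def __getitem__(self, aa: str) -> float:
        return self.scores.get(aa, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aa": list(AA_ORDER), "mutability": [self[aa] for aa in AA_ORDER]}
        )


def mutability(
    variants: Sequence[Variant],
    composition: ReferenceComposition,
    af_threshold: float = 0.10,
    inclusive: bool = True,
    population: str = "",
) -> MutabilityScores:
    """Compute mutability scores over variants passing the AF filter.

    Parameters
    ----------
    af_threshold : float
        Minimum allele frequency; variants below it are excluded before
        counting.  Default 0.10, the common-variant cut used throughout the
        analysis.
    inclusive : bool
        If True (default) the filter is ``af >= threshold``, else strictly
        ``af > threshold``.
    """
    if not 0.0 <= af_threshold <= 1.0:
        raise InputError(f"af_threshold {af_threshold} outside [0, 1]")
    if inclusive:
        kept = [v for v in variants if v.af >= af_threshold]
    else:
        kept = [v for v in variants if v.af > af_threshold]

    scores: dict[str, float] = {}
    for aa in AA_ORDER:
        n = sum(1 for v in kept if v.ref_aa == aa)
        if n == 0:
            scores[aa] = 0.0
            continue
        if composition.count(aa) == 0:
            raise ConsistencyError(
                f"{n} substitution(s) at {aa} sites but the reference "
                f"composition contains no {aa}"
            )
        scores[aa] = n / composition.fraction(aa)
    return MutabilityScores(scores=scores, af_threshold=af_threshold, population=population)
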