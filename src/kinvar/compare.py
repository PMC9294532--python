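"""Cross-population comparison of exchange proportions.

For each ref->alt residue pair, the focal cohort's exchange proportion is
tested against the comparison cohort's proportion with a one-proportion
z-test:

    z = (k/n - p0) / sqrt(p0 (1 - p0) / n)

with ``k`` the focal pair count, ``n`` the focal total and ``p0`` the
comparison proportion; the p-value is the two-sided standard-normal tail.
Benjamini-Hochberg adjustment is applied jointly across all tested pairs of
one comparison, and a pair is significant when its adjusted value falls
below alpha.

By default the proportion denominator is the cohort's total variant count;
``condition_on_ref=True`` instead conditions on exchanges leaving the same
reference residue.  Pairs with comparison proportion 0 or 1 are skipped (the
z statistic is undefined there), as are pairs absent from both cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .exchange import AA_INDEX, ExchangeMatrix
from .io import AA_ORDER


def one_prop_ztest(k: int, n: int, p0: float) -> tuple[float, float]:
    """One-proportion z-test of ``k`` successes in ``n`` trials against p0.

    Returns ``(z, p)`` with a two-sided normal p-value.  No continuity
    correction is applied.
    """
    if not 0.0 < p0 < 1.0:
        raise InputError(f"p0 must be strictly inside (0, 1), got {p0}")
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise InputError(f"k={k} outside [0, n={n}]")
    z = (k / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * norm.sf(abs(z))
    return z, min(p, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class TestResult:
    """Outcome of the proportion test for one exchange pair."""

    ref_aa: str
    alt_aa: str
    k_focal: int
    n_focal: int
    p0: float
    z: float
    p: float
    q: float
    significant: bool

    @property
    def pair(self) -> str:
        return f"{self.ref_aa}>{self.alt_aa}"


@dataclass(frozen=True)
class SkippedPair:
    """A pair excluded from testing, with the reason."""

    ref_aa: str
    alt_aa: str
    reason: str


def compare_populations(
    focal: ExchangeMatrix,
    comparison: ExchangeMatrix,
    alpha: float = 0.05,
    condition_on_ref: bool = False,
    two_sample: bool = False,
) -> tuple[list[TestResult], list[SkippedPair]]:
    """Test every exchange pair of the focal cohort against a comparison.

    Parameters
    ----------
    alpha : float
        FDR level; ``significant`` means BH-adjusted value < alpha.
    condition_on_ref : bool
        Use exchanges from the pair's reference residue as the denominator
        instead of the cohort total.
    two_sample : bool
        Non-default variant: a two-sample pooled z-test treating the
        comparison cohort as a sample rather than a fixed null proportion.

    Returns the test results (one per tested pair) and the skipped pairs.
    """
    if focal.n_variants == 0:
        raise InputError("focal cohort has no variants")
    if comparison.n_variants == 0:
        raise InputError("comparison cohort has no variants")

    tested: list[dict] = []
    skipped: list[SkippedPair] = []
    for i, ref in enumerate(AA_ORDER):
        for j, alt in enumerate(AA_ORDER):
            if ref == alt:
                continue
            k = int(focal.counts[i, j])
            k_cmp = int(comparison.counts[i, j])
            if k == 0 and k_cmp == 0:
                continue  # null pair: not part of the tested family
            if condition_on_ref:
                n = int(focal.counts[i].sum())
                n_cmp = int(comparison.counts[i].sum())
            else:
                n = focal.n_variants
                n_cmp = comparison.n_variants
            if n == 0:
                skipped.append(SkippedPair(ref, alt, "focal denominator is zero"))
                continue
            p0 = k_cmp / n_cmp if n_cmp else 0.0
            if not 0.0 < p0 < 1.0:
                skipped.append(
                    SkippedPair(ref, alt, f"comparison proportion {p0:g} not in (0, 1)")
                )
                continue
            if two_sample:
                pooled = (k + k_cmp) / (n + n_cmp)
                se = math.sqrt(pooled * (1 - pooled) * (1 / n + 1 / n_cmp))
                z = 0.0 if se == 0 else (k / n - p0) / se
                p = min(2.0 * norm.sf(abs(z)), 1.0)
            else:
                z, p = one_prop_ztest(k, n, p0)
            tested.append(
                {"ref": ref, "alt": alt, "k": k, "n": n, "p0": p0, "z": z, "p": p}
            )

    if not tested:
        return [], skipped
    q = bh_adjust([t["p"] for t in tested])
    results = [
        TestResult(
            ref_aa=t["ref"],
            alt_aa=t["alt"],
            k_focal=t["k"],
            n_focal=t["n"],
            p0=t["p0"],
            z=t["z"],
            p=t["p"],
            q=float(qi),
            significant=bool(qi < alpha),
        )
        for t, qi in zip(tested, q)
    ]
    return results, skipped


def significant_pairs(results: Iterable[TestResult]) -> set[tuple[str, str]]:
    return {(r.ref_aa, r.alt_aa) for r in results if r.significant}


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "k_focal": r.k_focal,
                "n_focal": r.n_focal,
                "p0": r.p0,
                "z": r.z,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "ref_aa", "alt_aa", "k_focal", "n_focal", "p0", "z", "p", "q", "significant",
        ],
    )


@dataclass(frozen=True)
class IntersectionRow:
    """One exclusive-intersection row: elements found in exactly these sets."""

    members: tuple[str, ...]
    elements: frozenset

    @property
    def size(self) -> int:
        return len(self.elements)


def exclusive_intersections(named_sets: Mapping[str, set]) -> list[IntersectionRow]:
    """Partition the union of named sets by exact membership signature.

    UpSet-plot semantics: each element of the union lands in exactly one row,
    keyed by the full subset of input sets containing it.  Rows are sorted by
    size descending, ties broken lexicographically by the member-name tuple.
    """
    if not named_sets:
        raise InputError("need at least one named set")
    union = set().union(*named_sets.values())
    groups: dict[tuple[str, ...], set] = {}
    for el in union:
        sig = tuple(sorted(name for name, s in named_sets.items() if el in s))
        groups.setdefault(sig, set()).add(el)
    rows = [IntersectionRow(members=sig, elements=frozenset(els)) for sig, els in groups.items()]
    rows.sort(key=lambda r: (-r.size, r.members))
    return rows


def intersections_to_frame(rows: Sequence[IntersectionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "members": "|".join(r.members),
                "size": r.size,
                "elements": ";".join(sorted(map(str, r.elements))),
            }
            for r in rows
        ],
        columns=["members", "size", "elements"],
    )
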