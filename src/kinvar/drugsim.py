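"""Drug similarity: chemical (fingerprint Tanimoto) and phenotypic (shared
targets).

Chemical similarity between two drugs is the Tanimoto coefficient of their
binary fingerprints (MACCS-style 166-key or Morgan-style bit vectors):
|a AND b| / |a OR b|.  Dissimilarity is 1 - similarity.  The package
consumes precomputed bitstrings, so no cheminformatics toolkit is needed to
run the analysis; fingerprint generation from structures is a producer-side
concern.

Phenotypic similarity between two drugs is the Pearson correlation (phi
coefficient) of their binary target-indicator vectors over a common gene
panel: drugs hitting the same targets get coefficient 1 even when they are
chemically unrelated.  A drug with a constant profile (targets every panel
gene, or none) has undefined correlations, reported as missing (NaN) rather
than silently zero.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

log = logging.getLogger(__name__)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length binary vectors.

    Both-empty fingerprints return 0.0 with a logged warning (the 0/0 case
    carries no similarity information).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        log.warning("tanimoto of two empty fingerprints: returning 0")
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def similarity_matrices(
    fingerprints: Mapping[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Tanimoto similarity and (1 - similarity) dissimilarity.

    Returns two symmetric DataFrames indexed by drug id; the similarity
    diagonal is exactly 1 and the dissimilarity diagonal exactly 0.
    """
    ids = list(fingerprints)
    if len(ids) < 2:
        raise InputError("need at least two fingerprints")
    lengths = {np.asarray(fingerprints[d]).size for d in ids}
    if len(lengths) != 1:
        raise InputError(f"fingerprints have mixed lengths {sorted(lengths)}")
    n = len(ids)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto(fingerprints[ids[i]], fingerprints[ids[j]])
            sim[i, j] = sim[j, i] = s
    sim_df = pd.DataFrame(sim, index=ids, columns=ids)
    dissim_df = 1.0 - sim_df
    np.fill_diagonal(dissim_df.values, 0.0)
    return sim_df, dissim_df


def profiles_from_targets(
    drug_targets: pd.DataFrame, gene_panel: list[str] | None = None
) -> pd.DataFrame:
    """Binary drug x gene indicator matrix from a drug-gene edge table.

    ``drug_targets`` needs columns ``drug_id`` and ``gene``.  The panel
    defaults to all genes seen in the table, sorted.
    """
    if not {"drug_id", "gene"} <= set(drug_targets.columns):
        raise FormatError("drug-target table needs columns drug_id, gene")
    panel = sorted(drug_targets["gene"].unique()) if gene_panel is None else list(gene_panel)
    drugs = sorted(drug_targets["drug_id"].unique())
    profiles = pd.DataFrame(0, index=drugs, columns=panel, dtype=int)
    for row in drug_targets.itertuples(index=False):
        if row.gene in profiles.columns:
            profiles.loc[row.drug_id, row.gene] = 1
    return profiles


def phenotypic_similarity(profiles: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Drug-drug correlation matrix over binary target profiles.

    ``profiles`` is a drug x gene 0/1 matrix on a shared panel.  Pearson on
    binary vectors equals the phi coefficient; ``method='spearman'`` is
    offered as an alternative.  Constant profiles produce NaN rows/columns.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise InputError("need >= 2 drugs over a panel of >= 2 genes")
    if method not in {"pearson", "spearman"}:
        raise InputError(f"unknown correlation method {method!r}")
    # corr() works column-wise: transpose so drugs become columns.
    return profiles.T.corr(method=method)
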