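"""Expression-atlas arithmetic: FPKM, detectability and tissue-specificity
filters, and the log-scale heatmap matrix.

FPKM[g, t] = counts[g, t] / (gene length in kb * library size in millions).
A gene is detectable when FPKM > 1 in at least one tissue; tissue-specific
when FPKM > 1 in exactly one tissue and FPKM < 1 in all others (both
inequalities strict by default — a value of exactly 1 anywhere else
disqualifies the gene; ``inclusive_low`` relaxes the second to <= 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``library_sizes`` defaults to the per-tissue column sums of ``counts``.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    len_kb = lengths / 1_000.0
    lib_m = library_sizes / 1e6
    return counts.div(len_kb, axis=0).div(lib_m, axis=1)


def detectable_genes(matrix: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Genes with FPKM strictly above ``threshold`` in at least one tissue."""
    mask = (matrix > threshold).any(axis=1)
    return set(matrix.index[mask])


def tissue_specific_genes(matrix: pd.DataFrame, inclusive_low: bool = False) -> dict[str, str]:
    """Map gene -> tissue for genes expressed (> 1 FPKM) in exactly one
    tissue and below 1 FPKM in every other tissue."""
    if matrix.shape[1] < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    vals = matrix.to_numpy()
    above = vals > 1.0
    below = vals <= 1.0 if inclusive_low else vals < 1.0
    one_above = above.sum(axis=1) == 1
    rest_below = (above | below).all(axis=1) & (below.sum(axis=1) == matrix.shape[1] - 1)
    sel = one_above & rest_below
    out: dict[str, str] = {}
    for gi in np.flatnonzero(sel):
        ti = int(np.argmax(above[gi]))
        out[str(matrix.index[gi])] = str(matrix.columns[ti])
    return out


def heatmap_matrix(
    matrix: pd.DataFrame,
    gene_subset: list[str] | None = None,
    pseudocount: float = 1.0,
    top: int | None = None,
) -> pd.DataFrame:
    """log2(FPKM + pseudocount), restricted to a gene subset, rows ordered by
    maximum expression descending; ``top`` keeps the highest-expressed rows
    (the top-100 view)."""
    if pseudocount <= 0 and (matrix.to_numpy() <= 0).any():
        raise ValueError("pseudocount must be positive when zeros are present")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    sub = matrix.loc[list(gene_subset)] if gene_subset is not None else matrix
    log = np.log2(sub + pseudocount)
    order = log.max(axis=1).sort_values(ascending=False, kind="stable").index
    log = log.loc[order]
    if top is not None:
        log = log.iloc[:top]
    return log
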