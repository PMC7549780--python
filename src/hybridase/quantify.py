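"""Per-gene counting of accepted read pairs and the low-count filter.

Counts use concordantly aligned, uniquely classified read pairs only.
For hybrid libraries, A-specific pairs feed the chicken-allele (HG) matrix
and B-specific pairs the quail-allele (HQ) matrix; common pairs (mapped to
both genomes) are removed before counting.  The low-count filter excludes
any gene whose count falls below the threshold (default 1) in any sample
of the matrix it is applied to.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .dualmap import OriginCall

# genome A plays the chicken (G) side, genome B the quail (Q) side
CALL_TO_ALLELE = {"A_specific": "HG", "B_specific": "HQ"}


def count_pairs(
    calls: Sequence[OriginCall],
    gene_universe: Sequence[str],
    mode: str = "hybrid",
) -> dict[str, pd.Series]:
    """Tally accepted pairs into per-gene count vectors.

    Hybrid mode returns ``{"HG": ..., "HQ": ...}`` (one vector per allele);
    parental mode returns a single ``{"counts": ...}`` vector.  Each
    accepted pair increments exactly one gene in exactly one vector; common
    and discarded pairs increment nothing.
    """
    if mode not in ("parental", "hybrid"):
        raise ValueError(f"unknown mode {mode!r}")
    keys = ["HG", "HQ"] if mode == "hybrid" else ["counts"]
    tallies = {k: dict.fromkeys(gene_universe, 0) for k in keys}
    for c in calls:
        if c.call in ("common", "discarded"):
            continue
        if c.gene is None:
            raise RuntimeError(
                f"accepted call for pair {c.read_pair_id} carries no gene"
            )
        key = CALL_TO_ALLELE[c.call] if mode == "hybrid" else "counts"
        if c.gene not in tallies[key]:
            raise RuntimeError(f"pair {c.read_pair_id}: gene {c.gene} not in universe")
        tallies[key][c.gene] += 1
    return {
        k: pd.Series(v, name=k, dtype=int).reindex(gene_universe)
        for k, v in tallies.items()
    }


def filter_low_counts(matrix: pd.DataFrame, threshold: int = 1) -> pd.DataFrame:
    """Retain exactly the genes with count >= threshold in every sample.

    A gene is excluded as soon as its count falls below the threshold in
    ANY sample of the matrix.  Idempotent; threshold 0 retains everything.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (matrix >= threshold).all(axis=1)
    return matrix.loc[keep]


def retained_genes(matrix: pd.DataFrame, threshold: int = 1) -> list[str]:
    return list(filter_low_counts(matrix, threshold).index)
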