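"""Cross-series concordance and misregulation (pattern D) classification.

Stage-contrast direction calls from the four series — quail (Q), chicken
(G), and the hybrid's quail- and chicken-derived alleles (HQ, HG) — are
compared pairwise (3x3 direction tables, percent concordance, Pearson r of
log2 fold changes) and combined per gene into a 4-tuple profile.

A gene is *eligible* when it is upregulated between stages in both
parental species.  Among eligible genes:

    A  both hybrid alleles upregulated (concordant with parents)
    B  only the chicken-derived allele (HG) upregulated
    C  only the quail-derived allele (HQ) upregulated
    D  neither allele upregulated — the misregulated class

The four-digit code renders the (Q, G, HQ, HG) directions with
1 = up, 2 = down, 0 = unaltered (cosmetic output; carries no logic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DIRECTIONS = ("up", "down", "unaltered")
DIGIT = {"up": "1", "down": "2", "unaltered": "0"}
SERIES_ORDER = ("Q", "G", "HQ", "HG")


def common_universe(*retained_lists: Sequence[str]) -> list[str]:
    """Intersection of per-series retained-gene lists, in first-list order."""
    if len(retained_lists) < 2:
        raise ValueError("need at least two retained-gene lists")
    common = set(retained_lists[0])
    for lst in retained_lists[1:]:
        common &= set(lst)
    if not common:
        warnings.warn("empty common gene universe; downstream results will be empty")
    return [g for g in retained_lists[0] if g in common]


@dataclass
class ConcordanceResult:
    """Pairwise comparison of two series' stage contrasts."""

    label_x: str
    label_y: str
    table: pd.DataFrame  # 3x3 counts, rows = X-series direction
    percent: pd.DataFrame  # same cells as percent of the universe
    percent_same_direction: float
    pearson_r: float  # NaN when a log2fc vector has zero variance
    universe_size: int

    def transposed(self) -> "ConcordanceResult":
        return ConcordanceResult(
            self.label_y, self.label_x, self.table.T, self.percent.T,
            self.percent_same_direction, self.pearson_r, self.universe_size,
        )


def concordance(
    de_x: pd.DataFrame,
    de_y: pd.DataFrame,
    universe: Sequence[str],
    label_x: str = "X",
    label_y: str = "Y",
) -> ConcordanceResult:
    """3x3 direction cross-table and log2FC correlation over a universe.

    Both inputs must be gene-indexed frames with ``direction`` and
    ``log2fc`` columns covering every universe gene.
    """
    genes = list(universe)
    for name, de in ((label_x, de_x), (label_y, de_y)):
        missing = set(genes) - set(de.index)
        if missing:
            raise ValueError(
                f"series {name} lacks {len(missing)} universe genes "
                f"(e.g. {sorted(missing)[:3]})"
            )
    dx = de_x.loc[genes, "direction"]
    dy = de_y.loc[genes, "direction"]
    table = pd.DataFrame(0, index=list(DIRECTIONS), columns=list(DIRECTIONS))
    for a, b in zip(dx, dy):
        table.loc[a, b] += 1
    n = len(genes)
    percent = table / n * 100.0 if n else table * np.nan
    same = float(np.diag(table).sum())
    pct_same = round(same / n * 100.0, 1) if n else float("nan")

    fx = de_x.loc[genes, "log2fc"].to_numpy(dtype=float)
    fy = de_y.loc[genes, "log2fc"].to_numpy(dtype=float)
    if n < 2 or fx.std() == 0 or fy.std() == 0:
        warnings.warn(
            f"pearson_r undefined for {label_x} vs {label_y}: zero-variance log2fc"
        )
        r = float("nan")
    else:
        # population (denominator-n) covariance formula; n cancels in r
        r = float(np.corrcoef(fx, fy)[0, 1])
    return ConcordanceResult(label_x, label_y, table, percent, pct_same, r, n)


def classify_pattern(directions: Sequence[str]) -> tuple[str, str]:
    """Label one gene's (Q, G, HQ, HG) direction 4-tuple.

    Returns ``(pattern, four_digit_code)``.  Eligibility requires
    upregulation in both parents; pattern D means neither hybrid allele is
    upregulated (down and unaltered both count as no upregulation).
    """
    if len(directions) != 4:
        raise ValueError("need exactly 4 directions (Q, G, HQ, HG)")
    for d in directions:
        if d not in DIRECTIONS:
            raise ValueError(f"unknown direction {d!r}")
    q, g, hq, hg = directions
    code = "".join(DIGIT[d] for d in directions)
    if not (q == "up" and g == "up"):
        return "not_eligible", code
    hq_up, hg_up = hq == "up", hg == "up"
    if hq_up and hg_up:
        return "A", code
    if hg_up:
        return "B", code
    if hq_up:
        return "C", code
    return "D", code


def build_profiles(
    de_by_series: Mapping[str, pd.DataFrame],
    universe: Sequence[str],
    sex: str,
) -> pd.DataFrame:
    """Per-gene pattern profiles for one sex over its own universe."""
    missing = [s for s in SERIES_ORDER if s not in de_by_series]
    if missing:
        raise ValueError(f"missing series {missing}")
    rows = []
    for gene in universe:
        dirs = [str(de_by_series[s].loc[gene, "direction"]) for s in SERIES_ORDER]
        pattern, code = classify_pattern(dirs)
        rows.append(
            {
                "gene": gene,
                "sex": sex,
                "dir_Q": dirs[0],
                "dir_G": dirs[1],
                "dir_HQ": dirs[2],
                "dir_HG": dirs[3],
                "code": code,
                "pattern": pattern,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "sex", "dir_Q", "dir_G", "dir_HQ", "dir_HG", "code", "pattern"],
    )


def misregulated_sets(profiles_by_sex: Mapping[str, pd.DataFrame]) -> dict:
    """Union/intersection bookkeeping of eligible and pattern-D genes.

    ``eligible_union``: upregulated in both parents in at least one sex.
    ``patternD_union``: pattern D in at least one sex; ``patternD_
    intersection``: pattern D in both sexes.  Per-sex sets are returned for
    provenance.
    """
    eligible, pat_d = {}, {}
    for sex, prof in profiles_by_sex.items():
        eligible[sex] = set(prof.loc[prof["pattern"] != "not_eligible", "gene"])
        pat_d[sex] = set(prof.loc[prof["pattern"] == "D", "gene"])
    sexes = list(profiles_by_sex)
    eligible_union = set().union(*eligible.values())
    d_union = set().union(*pat_d.values())
    d_inter = set.intersection(*pat_d.values()) if sexes else set()
    return {
        "eligible_union": eligible_union,
        "eligible_per_sex": eligible,
        "patternD_per_sex": pat_d,
        "patternD_union": d_union,
        "patternD_intersection": d_inter,
    }
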