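"""Per-gene negative-binomial Wald test of the stage contrast.

A deliberately small DESeq2-style analogue: median-of-ratios size factors,
a per-gene method-of-moments dispersion shared by both stage groups, exact
per-group NB mean fits at fixed dispersion, a Wald test on the log2 fold
change (stage XIII/XIV over stage X), Benjamini-Hochberg adjustment within
one test family, and the fixed three-way direction call:

    up        FDR < 0.05 and FC > 2
    down      FDR < 0.05 and FC < 0.5
    unaltered otherwise (all inequalities strict)

No dispersion shrinkage toward a trend, no LFC shrinkage, no outlier
handling, no independent filtering.

The NB parametrization is variance = mu + alpha * mu^2 (r = 1/alpha).  The
per-group log-likelihood is strictly concave in log(mean), so the MLE is
the unique root of the score and is found by bracketed root finding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

ALPHA_MIN = 1e-8
REFERENCE_STAGE = "X"
TARGET_STAGE = "XIII_XIV"
LN2 = np.log(2.0)


def estimate_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization.

    The pseudo-reference is the per-gene geometric mean over samples,
    computed on genes with all counts positive; the size factor of a
    sample is the median over those genes of count / reference.
    """
    counts = matrix.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "lower the count filter threshold"
        )
    sub = counts[all_pos]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def estimate_dispersion(
    counts: np.ndarray, size_factors: np.ndarray, groups: np.ndarray
) -> float:
    """Method-of-moments dispersion on normalized counts, pooled over groups.

    alpha = max(ALPHA_MIN, (pooled within-group variance - pooled mean)
    / pooled mean^2).  Degenerate genes (zero mean or under-dispersed)
    return ALPHA_MIN.
    """
    y = np.asarray(counts, dtype=float) / np.asarray(size_factors, dtype=float)
    labels = np.asarray(groups)
    ss, df = 0.0, 0
    for g in np.unique(labels):
        yg = y[labels == g]
        ss += float(((yg - yg.mean()) ** 2).sum())
        df += len(yg) - 1
    if df < 1:
        return ALPHA_MIN
    var = ss / df
    mean = float(y.mean())
    if mean <= 0:
        return ALPHA_MIN
    return max(ALPHA_MIN, (var - mean) / mean**2)


def moderate_dispersions(
    raw: np.ndarray, residual_df: int, prior_df: float = 10.0
) -> np.ndarray:
    """Squeeze per-gene dispersions toward the family-wide common value.

    The per-gene method-of-moments estimate carries only ``residual_df``
    degrees of freedom (4 at 3 vs 3 replicates), which makes a plug-in
    Wald test anti-conservative.  Borrowing strength across the genes of
    one test family — a precision-weighted pull toward the family mean
    dispersion, in the spirit of edgeR's common-dispersion moderation —
    restores calibration without modelling any mean-dispersion trend:

        alpha_i <- (df * alpha_i + prior_df * mean(alpha)) / (df + prior_df)
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw
    common = float(raw.mean())
    out = (residual_df * raw + prior_df * common) / (residual_df + prior_df)
    return np.maximum(out, ALPHA_MIN)


def _fit_group_mean(
    counts: np.ndarray, size_factors: np.ndarray, alpha: float, floor: float
) -> float:
    """MLE of the NB group mean q (mu_j = s_j q) at fixed dispersion.

    The score in eta = ln q is K_total at -inf and -n*r at +inf and the
    log-likelihood is strictly concave in eta, so brentq on the score is
    exact.  An all-zero group returns the pseudo-mean floor.
    """
    k = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    if k.sum() == 0:
        return floor
    r = 1.0 / alpha

    def score(eta: float) -> float:
        mu = s * np.exp(eta)
        return float((k - (k + r) * mu / (r + mu)).sum())

    hi = float(np.max(k / s)) * 4.0 + 10.0
    lo = min(floor / 10.0, 1e-6)
    q = np.exp(optimize.brentq(score, np.log(lo), np.log(hi), xtol=1e-12))
    return max(q, floor)


def _observed_information_log2(
    counts: np.ndarray, size_factors: np.ndarray, q: float, alpha: float
) -> float:
    """Observed information of the log2-scale group mean at the fit."""
    k = np.asarray(counts, dtype=float)
    mu = np.asarray(size_factors, dtype=float) * q
    r = 1.0 / alpha
    return float(LN2**2 * ((k + r) * r * mu / (r + mu) ** 2).sum())


def nb_wald_test(
    counts: np.ndarray,
    size_factors: np.ndarray,
    stages: np.ndarray,
    dispersion: float,
) -> dict[str, float]:
    """Wald test of one gene's stage XIII/XIV vs stage X contrast.

    Fits per-stage means by exact 1-D NB likelihood maximization at the
    given dispersion; log2fc = log2(q_target / q_reference); the standard
    error comes from the observed information of the two log2-scale mean
    parameters; p is the two-sided standard-normal tail of
    z = log2fc / se.
    """
    if dispersion < ALPHA_MIN:
        raise ValueError(f"dispersion must be >= {ALPHA_MIN}")
    k = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    labels = np.asarray(stages)
    if k.sum() == 0:
        raise RuntimeError("all-zero gene reached the Wald test; filter upstream")
    floor = 0.5 / float(s.mean())
    out = {}
    info = {}
    for stage in (REFERENCE_STAGE, TARGET_STAGE):
        m = labels == stage
        if m.sum() < 2:
            raise ValueError(f"stage {stage} has fewer than 2 samples")
        q = _fit_group_mean(k[m], s[m], dispersion, floor)
        out[stage] = q
        info[stage] = _observed_information_log2(k[m], s[m], q, dispersion)
    log2fc = float(np.log2(out[TARGET_STAGE] / out[REFERENCE_STAGE]))
    se = float(np.sqrt(1.0 / info[REFERENCE_STAGE] + 1.0 / info[TARGET_STAGE]))
    z = log2fc / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {
        "base_mean": float((k / s).mean()),
        "log2fc": log2fc,
        "se": se,
        "wald_z": z,
        "p_value": p,
        "q_ref": out[REFERENCE_STAGE],
        "q_target": out[TARGET_STAGE],
    }


def nb_loglik(counts, size_factors, q, alpha):
    """Full NB log-likelihood of one group at mean q; used by oracles."""
    k = np.asarray(counts, dtype=float)
    mu = np.asarray(size_factors, dtype=float) * q
    r = 1.0 / alpha
    return float(
        (
            special.gammaln(k + r)
            - special.gammaln(r)
            - special.gammaln(k + 1)
            + r * np.log(r / (r + mu))
            + k * np.log(mu / (r + mu))
        ).sum()
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_direction(fdr: float, fc: float) -> str:
    """Three-way direction call from (FDR, fold change), FC = 2**log2fc."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    if fdr < 0.05 and fc > 2.0:
        return "up"
    if fdr < 0.05 and fc < 0.5:
        return "down"
    return "unaltered"


def de_analysis(
    matrix: pd.DataFrame,
    stages: pd.Series,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Stage-contrast DE for one series x sex count matrix.

    One test family: BH adjustment is applied across the genes of this
    matrix, and per-gene method-of-moments dispersions are moderated
    toward the family-wide mean (see ``moderate_dispersions``) unless
    explicit dispersions are supplied.  Returns a gene-indexed frame with
    base_mean, log2fc, se, wald_z, p_value, fdr and the direction call.
    """
    stages = stages.reindex(matrix.columns)
    if stages.isna().any():
        missing = list(stages.index[stages.isna()])
        raise ValueError(f"samples without stage label: {missing}")
    if size_factors is None:
        size_factors = estimate_size_factors(matrix)
    s = size_factors.reindex(matrix.columns).to_numpy(dtype=float)
    labels = stages.to_numpy()
    counts_arr = matrix.to_numpy(dtype=float)

    if dispersions is not None:
        alphas = np.maximum(
            dispersions.reindex(matrix.index).to_numpy(dtype=float), ALPHA_MIN
        )
    else:
        raw = np.array(
            [estimate_dispersion(k, s, labels) for k in counts_arr]
        )
        residual_df = len(labels) - len(np.unique(labels))
        alphas = moderate_dispersions(raw, residual_df)

    rows = []
    for gene, k, alpha in zip(matrix.index, counts_arr, alphas):
        res = nb_wald_test(k, s, labels, float(alpha))
        res["gene"] = gene
        res["dispersion"] = float(alpha)
        rows.append(res)
    out = pd.DataFrame(rows).set_index("gene")
    out["fdr"] = adjust_bh(out["p_value"].to_numpy())
    out["direction"] = [
        call_direction(f, 2.0**lfc) for f, lfc in zip(out["fdr"], out["log2fc"])
    ]
    return out[
        ["base_mean", "log2fc", "se", "wald_z", "p_value", "fdr", "direction", "dispersion"]
    ]
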