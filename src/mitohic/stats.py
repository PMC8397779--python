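"""Shared statistical helpers: BH adjustment, z-scores, exact tests,
a negative-binomial Wald test and an empirical-Bayes moderated t-test.

The two-group count test (method-of-moments dispersion + Wald test on the
log-mean difference) and the moderated t (pooled variance shrunk toward the
global mean variance) are this package's documented substitutes for packaged
differential-analysis tools; they reproduce the decision thresholds used
downstream (adjusted p and fold-change cutoffs) without wrapping external
software.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    good = np.isfinite(p)
    if good.any():
        out[good] = multipletests(p[good], method="fdr_bh")[1]
    return out


def zscore_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise z-scores; constant rows map to zero rather than NaN."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Sample odds ratio ad/bc and two-sided exact p-value.

    A zero marginal makes the odds ratio undefined; by convention the p-value
    is then 1 and the result is flagged (third return value False).
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    marginals = [a + b, c + d, a + c, b + d]
    if 0 in marginals:
        return np.nan, 1.0, False
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), True


def signed_rank(x: np.ndarray, y: np.ndarray, exact_below: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact distribution for fewer than ``exact_below`` informative pairs,
    normal approximation above.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    diff = x - y
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    mode = "exact" if diff.size < exact_below else "approx"
    return float(sps.wilcoxon(diff, method=mode).pvalue)


# ---------------------------------------------------------------------------
# negative-binomial two-group Wald test
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion over a genes x samples table.

    Per-gene alpha = max(0, (s^2 - mean) / mean^2), averaged (trimmed 10%)
    across genes with positive means; pooling stabilises the estimate at the
    few-replicate sample sizes typical of this design.
    """
    counts = np.asarray(counts, float)
    mu = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    ok = mu > 0
    alpha = np.clip((var[ok] - mu[ok]) / mu[ok] ** 2, 0, None)
    if alpha.size == 0:
        return 1e-8
    return float(max(sps.trim_mean(alpha, 0.1), 1e-8)) if alpha.size > 2 else float(
        max(alpha.mean(), 1e-8)
    )


def nb_wald_test(
    counts_a: np.ndarray, counts_b: np.ndarray, alpha: float | None = None
) -> pd.DataFrame:
    """Per-row two-group NB Wald test on the log fold change b vs a.

    ``counts_*`` are genes x replicates raw counts. Var(log mean) is obtained
    by the delta method from the NB variance mu + alpha mu^2:
    Var(log xbar) ~ (1/mu + alpha) / n. Returns log2 fold change, raw p and
    BH-adjusted p per row.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if alpha is None:
        # within-group estimates: pooling across conditions would absorb the
        # condition effect into the dispersion
        alpha = 0.5 * (estimate_dispersion(a) + estimate_dispersion(b))
    na, nb = a.shape[1], b.shape[1]
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    usable = (mu_a > 0) & (mu_b > 0)
    eps = 0.5  # continuity pad for near-zero means in the variance term only
    var_a = (1.0 / np.maximum(mu_a, eps) + alpha) / na
    var_b = (1.0 / np.maximum(mu_b, eps) + alpha) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_b / mu_a)
        z = (np.log(mu_b) - np.log(mu_a)) / np.sqrt(var_a + var_b)
    p = 2 * sps.norm.sf(np.abs(z))
    p[~usable] = np.nan
    lfc[~usable] = np.nan
    return pd.DataFrame(
        {"log2FC": lfc, "pvalue": p, "padj": bh_adjust(p), "tested": usable}
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t-test
# ---------------------------------------------------------------------------

def moderated_t_test(
    x: np.ndarray, y: np.ndarray, prior_df: float = 4.0
) -> pd.DataFrame:
    """Per-row two-group t-test with variance shrinkage.

    The pooled per-row variance is shrunk toward the global mean variance
    with ``prior_df`` pseudo-degrees of freedom:
    s2_mod = (d0 * s0^2 + d * s2) / (d0 + d); the statistic is referenced to
    a t distribution with d0 + d degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.shape[1], y.shape[1]
    d = nx + ny - 2
    if d <= 0:
        raise ValueError("need at least 2 total residual degrees of freedom")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    s2 = ((x - mx[:, None]) ** 2).sum(axis=1) + ((y - my[:, None]) ** 2).sum(axis=1)
    s2 = s2 / d
    s0 = np.nanmean(s2[s2 > 0]) if np.any(s2 > 0) else 1e-12
    s2_mod = (prior_df * s0 + d * s2) / (prior_df + d)
    se = np.sqrt(s2_mod * (1 / nx + 1 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (my - mx) / se
    p = 2 * sps.t.sf(np.abs(t), df=prior_df + d)
    return pd.DataFrame(
        {"diff": my - mx, "t": t, "pvalue": p, "padj": bh_adjust(p)}
    )


def kmeans_labels(
    x: np.ndarray, k: int, seed: int, restarts: int = 50
) -> np.ndarray:
    """k-means labels with a fixed seed and multiple restarts (deterministic)."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(np.asarray(x, float))


def relabel_by_score(labels: np.ndarray, scores: np.ndarray, descending=True) -> np.ndarray:
    """Renumber cluster labels 1..k ordered by per-cluster mean of ``scores``.

    Makes k-means labels reproducible and interpretable (e.g. cluster 1 =
    strongest control mid-G1 signal).
    """
    uniq = np.unique(labels)
    means = {u: scores[labels == u].mean() for u in uniq}
    order = sorted(uniq, key=lambda u: means[u], reverse=descending)
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in labels])
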