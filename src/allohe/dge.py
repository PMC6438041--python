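"""Differential expression: RLE normalisation, a negative-binomial
conditional exact test with common dispersion, FDR control, and the
consensus / top-ranked DEG selection rules used for allo- vs autotriploid
comparisons.

The test treats each gene's pseudo-counts (raw counts divided by RLE size
factors, rounded) as negative binomial with a dispersion common to all
genes, estimated by method of moments.  Conditional on the two group
totals' sum, the group-A total follows a distribution free of the unknown
mean, giving an exact two-sided p-value by summing the probabilities of
all outcomes no more likely than the observed one.  This is a documented
stand-in for an external DE package: any table with the same columns
(gene, logFC, logCPM, pvalue, qvalue) can be plugged into the downstream
consensus, enrichment and PIE stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["gene_id", "logFC", "logCPM", "pvalue", "qvalue", "status"]


# ----------------------------------------------------------------------
def rle_size_factors(matrix: pd.DataFrame, rescale: bool = True) -> pd.Series:
    """Relative-log-expression (median-of-ratios) size factors.

    For each sample, the factor is the median over genes with nonzero
    counts in every sample of count / geometric-mean-across-samples.
    With ``rescale`` the factors are divided by their geometric mean so
    they multiply to one; normalised counts are raw counts / factor.
    """
    counts = matrix.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "filter the matrix to expressed genes first"
        )
    log_counts = np.log(counts[all_nonzero])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    if rescale:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize_counts(matrix: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Raw counts divided per sample by their RLE size factor."""
    return matrix.div(size_factors, axis=1)


# ----------------------------------------------------------------------
def _common_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray], min_total: int
) -> float:
    """Method-of-moments common NB dispersion across genes.

    Per gene and group, phi is estimated as (s^2 - m) / m^2 from the
    normalised counts; estimates are averaged over genes whose total
    pseudo-count reaches ``min_total`` (low-count genes destabilise the
    moments).
    """
    keep = pseudo.sum(axis=1) >= min_total
    if not keep.any():
        return 1e-8
    ests = []
    weights = []
    for idx in groups:
        sub = pseudo[np.ix_(keep, idx)]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append(((v[ok] - m[ok]) / m[ok] ** 2))
        weights.append(np.full(ok.sum(), len(idx) - 1, dtype=float))
    est = np.concatenate(ests)
    w = np.concatenate(weights)
    if est.size == 0:
        return 1e-8
    phi = float(np.sum(est * w) / np.sum(w))
    return max(phi, 1e-8)


def _exact_pvalue(s_a: int, t: int, r_a: float, r_b: float) -> float:
    """Two-sided conditional exact p for group-A total ``s_a`` given the
    grand total ``t``, with NB shape ``r_a``/``r_b`` per group.

    The conditional pmf over s = 0..t is proportional to
    C(s + r_a - 1, s) * C(t - s + r_b - 1, t - s); the p-value sums the
    probabilities of all outcomes less probable than the observed one plus
    half the probability of outcomes exactly as probable (the mid-p
    "double tail" construction, which keeps the discrete test close to
    its nominal size instead of strictly conservative).
    """
    s = np.arange(t + 1, dtype=float)
    logw = (
        gammaln(s + r_a)
        - gammaln(s + 1.0)
        + gammaln(t - s + r_b)
        - gammaln(t - s + 1.0)
    )
    logw -= logsumexp(logw)
    obs = logw[s_a]
    below = logw < obs - 1e-10
    tied = np.abs(logw - obs) <= 1e-10
    p = 0.0
    if below.any():
        p += float(np.exp(logsumexp(logw[below])))
    p += 0.5 * float(np.exp(logsumexp(logw[tied])))
    return min(1.0, p)


def nb_test(
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    min_total: int = 10,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB exact test of equal means between two sample groups.

    Returns a frame with ``gene_id, logFC, logCPM, pvalue, qvalue,
    status`` sorted as the input.  ``logFC`` is log2 of the ratio of group
    mean pseudo-counts (prior 0.5 per group); positive means higher in
    ``group_a``.  All-zero genes get p = 1 and status ``all_zero``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    samples = list(group_a) + list(group_b)
    missing = [s for s in samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")

    pseudo = np.rint(
        matrix[samples].to_numpy(dtype=float)
        / size_factors[samples].to_numpy(dtype=float)
    )
    n_a, n_b = len(group_a), len(group_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    phi = (
        dispersion
        if dispersion is not None
        else _common_dispersion(pseudo, [idx_a, idx_b], min_total)
    )
    r_a, r_b = n_a / phi, n_b / phi

    s_a = pseudo[:, idx_a].sum(axis=1)
    s_b = pseudo[:, idx_b].sum(axis=1)
    mean_lib = max(pseudo.sum(axis=0).mean(), 1.0)

    logfc = np.log2((s_a / n_a + 0.5) / (s_b / n_b + 0.5))
    logcpm = np.log2(((s_a + s_b) / (n_a + n_b) + 0.5) / mean_lib * 1e6)

    pvals = np.ones(len(pseudo))
    status = np.full(len(pseudo), "ok", dtype=object)
    for i in range(len(pseudo)):
        t = int(s_a[i] + s_b[i])
        if t == 0:
            status[i] = "all_zero"
            continue
        pvals[i] = _exact_pvalue(int(s_a[i]), t, r_a, r_b)

    out = pd.DataFrame(
        {
            "gene_id": matrix.index.to_numpy(),
            "logFC": logfc,
            "logCPM": logcpm,
            "pvalue": pvals,
            "status": status,
        }
    )
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out[RESULT_COLUMNS[:4] + ["qvalue", "status"]]


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
def compare_cultivars(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cultivar_a: str,
    cultivar_b: str,
    size_factors: pd.Series | None = None,
    **kwargs,
) -> pd.DataFrame:
    """NB test between two cultivars' replicate groups.

    Size factors default to RLE on the full matrix (global normalisation);
    pass precomputed factors to normalise per comparison instead.
    """
    if size_factors is None:
        size_factors = rle_size_factors(matrix)
    groups = {}
    for c in (cultivar_a, cultivar_b):
        s = sample_sheet.loc[sample_sheet["cultivar"] == c, "sample"].tolist()
        if not s:
            raise ValueError(f"no samples for cultivar {c!r}")
        groups[c] = s
    res = nb_test(matrix, size_factors, groups[cultivar_a], groups[cultivar_b], **kwargs)
    res.attrs["comparison"] = f"{cultivar_a}_vs_{cultivar_b}"
    return res


def consensus_degs(
    results: list[pd.DataFrame],
    q_threshold: float = 0.05,
    require_sign_concordance: bool = True,
) -> list[str]:
    """Genes significant in every comparison (optionally with a concordant
    fold-change sign), i.e. the consensus DEG set for one allopolyploid
    tested against each of three autotriploid cultivars."""
    if not results:
        raise ValueError("no comparison results given")
    universe = set(results[0]["gene_id"])
    for r in results[1:]:
        if set(r["gene_id"]) != universe:
            raise ValueError("comparisons do not share a gene universe")
    sig_sets = []
    signs: dict[str, set[float]] = {g: set() for g in universe}
    for r in results:
        sig = r.loc[r["qvalue"] <= q_threshold]
        sig_sets.append(set(sig["gene_id"]))
        for g, fc in zip(sig["gene_id"], sig["logFC"]):
            signs[g].add(float(np.sign(fc)))
    consensus = set.intersection(*sig_sets)
    if require_sign_concordance:
        consensus = {g for g in consensus if len(signs[g]) == 1 and 0.0 not in signs[g]}
    return sorted(consensus)


def top_ranked_intersection(
    result_a: pd.DataFrame, result_b: pd.DataFrame, k: int = 150
) -> list[str]:
    """Intersection of the two top-``k`` gene lists ranked by ascending p.

    Ties at the boundary are broken by gene-id lexicographic order, which
    makes the selection deterministic; genes ranked below ``k`` in either
    list cannot affect the result.
    """
    import warnings

    def top(res: pd.DataFrame) -> set[str]:
        kk = k
        if kk > len(res):
            warnings.warn(
                f"k={k} exceeds the {len(res)}-gene universe; clamping",
                stacklevel=3,
            )
            kk = len(res)
        ranked = res.sort_values(["pvalue", "gene_id"], kind="mergesort")
        return set(ranked["gene_id"].head(kk))

    return sorted(top(result_a) & top(result_b))
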