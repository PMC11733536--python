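"""Single-sample gene set enrichment analysis (ssGSEA) and downstream tests.

The score for one sample follows the rank-weighted running-sum statistic of
the ssGSEA lineage implemented in the GSVA package: expression ranks r_g in
{1..N} are assigned ascending (highest expression gets N), genes are walked in
decreasing-rank order, and the score is the *sum* over all positions of the
difference between the weighted in-set ECDF (weights r_g^alpha) and the
unweighted out-of-set ECDF. With ``normalize`` the scores are divided by the
global score range across the matrix. The maximum-deviation (KS-like)
statistic is available behind ``statistic="max"``.

Downstream: per-group top-signature tallies and Welch t-tests of scores with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SSGSEAParams",
    "ssgsea_score",
    "score_matrix",
    "top_signature_tally",
    "differential_enrichment",
]


@dataclass
class SSGSEAParams:
    alpha: float = 0.75
    normalize: bool = False
    tie_policy: str = "ordinal_by_input_order"  # or "average"
    statistic: str = "sum"  # or "max" (largest-magnitude deviation)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tie_policy not in ("ordinal_by_input_order", "average"):
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        if self.statistic not in ("sum", "max"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def _ranks(expr: np.ndarray, tie_policy: str) -> np.ndarray:
    """Ranks in {1..N}, ascending by expression (N = highest). Ordinal policy
    breaks ties by input order (earlier gene ranks higher)."""
    n = len(expr)
    if tie_policy == "average":
        return stats.rankdata(expr, method="average")
    # stable sort of (-expr, input position): earlier input wins ties
    order_desc = np.argsort(-expr, kind="stable")
    ranks = np.empty(n)
    ranks[order_desc] = np.arange(n, 0, -1)
    return ranks


def ssgsea_score(
    expr: np.ndarray,
    in_set: np.ndarray,
    params: SSGSEAParams | None = None,
) -> float:
    """ssGSEA score of one gene set in one sample.

    Parameters
    ----------
    expr
        Expression values over the N-gene universe.
    in_set
        Boolean mask (length N) of gene-set membership. At least one member
        must be present and the set must not cover the whole universe.

    Returns NaN (with a warning) when no set gene is present. The
    ``normalize`` flag is applied at the matrix level (`score_matrix`), since
    the normalisation constant is the score range across all samples.
    """
    params = params or SSGSEAParams()
    expr = np.asarray(expr, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = len(expr)
    n_in = int(in_set.sum())
    if n_in == 0:
        logger.warning("gene set has no members in the expression universe")
        return float("nan")
    if n_in >= n:
        raise ValueError("gene set must not cover the whole universe")

    ranks = _ranks(expr, params.tie_policy)
    order = np.argsort(-ranks, kind="stable")  # decreasing rank walk
    member = in_set[order]
    r_walk = ranks[order]

    w = np.where(member, r_walk ** params.alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~member) / (n - n_in)
    diff = p_in - p_out
    if params.statistic == "sum":
        return float(diff.sum())
    return float(diff[np.argmax(np.abs(diff))])


def score_matrix(
    expr: pd.DataFrame,
    signatures: dict[str, list[str]],
    params: SSGSEAParams | None = None,
) -> pd.DataFrame:
    """Score every signature in every sample.

    ``expr`` is samples x genes (bulk samples or single cells — the code path
    is identical). Signatures with no gene in the universe give NaN columns.
    With ``params.normalize`` all scores are divided by the global score range.
    """
    params = params or SSGSEAParams()
    genes = expr.columns
    masks = {
        name: genes.isin(set(gset)) for name, gset in signatures.items()
    }
    X = expr.to_numpy(dtype=float)
    out = np.full((X.shape[0], len(masks)), np.nan)
    for j, (name, mask) in enumerate(masks.items()):
        if not mask.any():
            logger.warning("signature %s shares no genes with the matrix", name)
            continue
        for i in range(X.shape[0]):
            out[i, j] = ssgsea_score(X[i], mask, params)
    scores = pd.DataFrame(out, index=expr.index, columns=list(masks))
    if params.normalize:
        rng_ = np.nanmax(out) - np.nanmin(out)
        if rng_ > 0:
            scores = scores / rng_
    return scores


def top_signature_tally(
    scores: pd.DataFrame,
    group_of: dict | pd.Series,
    k: int = 1,
) -> pd.DataFrame:
    """Per-group counts of each signature appearing in a sample's top k.

    Ties at the k-boundary include every tied signature (logged). Samples with
    all scores missing are excluded with a warning. Returns groups x
    signatures counts.
    """
    group_of = pd.Series(group_of)
    tallies: dict[str, dict[str, int]] = {}
    for sample, row in scores.iterrows():
        vals = row.dropna()
        if vals.empty:
            logger.warning("sample %s has no scores; excluded from tally", sample)
            continue
        cutoff = vals.nlargest(min(k, len(vals))).min()
        top = vals.index[vals >= cutoff]
        if len(top) > k:
            logger.info("sample %s: tie at the top-%d boundary (%d signatures)",
                        sample, k, len(top))
        g = group_of[sample]
        bucket = tallies.setdefault(g, {})
        for sig in top:
            bucket[sig] = bucket.get(sig, 0) + 1
    return pd.DataFrame(tallies).T.reindex(columns=scores.columns).fillna(0).astype(int)


def differential_enrichment(
    scores: pd.DataFrame,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Welch t-test of each signature's scores between two sample groups, with
    Benjamini-Hochberg adjustment across signatures.

    ``group_a``/``group_b`` are sample-id collections. Missing scores are
    dropped pairwise; the effect size is the raw mean difference (A - B).
    """
    a = scores.loc[list(group_a)]
    b = scores.loc[list(group_b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for sig in scores.columns:
        xa, xb = a[sig].dropna(), b[sig].dropna()
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"signature": sig, "mean_diff": np.nan, "t": np.nan, "p": np.nan})
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"signature": sig, "mean_diff": xa.mean() - xb.mean(),
                     "t": float(t), "p": float(p)})
    res = pd.DataFrame(rows).set_index("signature")
    ok = res["p"].notna()
    res["padj"] = np.nan
    if ok.any():
        res.loc[ok, "padj"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res
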