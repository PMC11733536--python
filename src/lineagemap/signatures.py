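"""Cell-type gene signatures: derivation, discriminance filtering, ortholog
mapping, tumor-type signature selection, and GMT I/O.

Signatures are 75-100 gene lists marking a cell population, derived by
Wilcoxon rank-sum differential expression of each population against all other
cells, ranked by average log2 fold change, with ribosomal and mitochondrial
symbols removed. Nondiscriminant signatures — those frequently among the top
scorers across an unrelated background cohort — are excluded by a
top-decile-by-appearance rule with tie extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sc_core import CellMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "OrthologMap",
    "derive_signatures",
    "discriminance_filter",
    "map_orthologs",
    "tumor_signatures",
    "simple_wald_de",
    "read_gmt",
    "write_gmt",
    "remove_housekeeping_symbols",
]

HUMAN_RIBO_SUBSTRINGS = ("RPS", "RPL", "MRPS", "MRPL")
MOUSE_RIBO_SUBSTRINGS = ("Rps", "Rpl", "Mrps", "Mrpl")
HUMAN_MITO_PREFIX = "MT-"
MOUSE_MITO_PREFIX = "mt-"

MIN_SIGNATURE_GENES = 75
MAX_SIGNATURE_GENES = 100


@dataclass
class GeneSignature:
    """A named, ordered marker gene list with its source and class label."""

    name: str
    genes: list[str]
    source: str = ""
    class_label: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OrthologMap:
    """One-to-one gene correspondence between two species.

    Built from a raw pair table; any source or target gene participating in
    more than one pair is dropped entirely (no 1-to-1 match).
    """

    pairs: dict[str, str]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OrthologMap":
        src = table.iloc[:, 0].astype(str)
        tgt = table.iloc[:, 1].astype(str)
        src_counts = src.value_counts()
        tgt_counts = tgt.value_counts()
        keep = src.map(src_counts).eq(1) & tgt.map(tgt_counts).eq(1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d ortholog pairs without a 1-to-1 match", dropped)
        return cls(pairs=dict(zip(src[keep], tgt[keep])))

    def __contains__(self, gene: str) -> bool:
        return gene in self.pairs

    def __getitem__(self, gene: str) -> str:
        return self.pairs[gene]


def remove_housekeeping_symbols(genes, species: str = "human") -> list[str]:
    """Drop ribosomal (symbol containing RPS/RPL/MRPS/MRPL) and mitochondrial
    (symbol starting with MT-) genes; mouse casing applied when requested."""
    if species == "human":
        ribo, mito = HUMAN_RIBO_SUBSTRINGS, HUMAN_MITO_PREFIX
    elif species == "mouse":
        ribo, mito = MOUSE_RIBO_SUBSTRINGS, MOUSE_MITO_PREFIX
    else:
        raise ValueError(f"unknown species {species!r}")
    return [
        g for g in genes
        if not g.startswith(mito) and not any(sub in g for sub in ribo)
    ]


# ---------------------------------------------------------------------------
# Signature derivation


def derive_signatures(
    nm: NormalizedMatrix,
    raw: CellMatrix,
    population_of: dict | pd.Series,
    species: str = "human",
    max_genes: int = MAX_SIGNATURE_GENES,
    min_genes: int = MIN_SIGNATURE_GENES,
    padj_threshold: float = 0.05,
    source: str = "",
) -> list[GeneSignature]:
    """Marker signatures per cell population by one-vs-rest Wilcoxon rank-sum.

    Per population, each gene is tested against all other cells (normal
    approximation with tie correction); genes significant after BH adjustment
    (padj < ``padj_threshold``) with positive average log2 fold change are
    sorted by log2 FC descending, ribosomal/mitochondrial symbols removed, and
    the list truncated to the top ``max_genes``. Populations yielding fewer
    than ``min_genes`` genes are dropped (logged). Populations with fewer than
    two cells are skipped with a warning.

    Average log2 FC is mean(in-group) - mean(out-group) of log-normalized
    values, converted from the natural-log to the log2 scale.
    """
    pop = pd.Series({c: population_of[c] for c in nm.cells})
    if pop.nunique() < 2:
        raise ValueError("need at least two populations")
    dense = nm.to_dense()  # genes x cells
    cell_pos = pd.Series(np.arange(len(nm.cells)), index=nm.cells)

    out: list[GeneSignature] = []
    for p in sorted(pop.unique()):
        in_idx = cell_pos[pop[pop == p].index].to_numpy()
        out_idx = cell_pos[pop[pop != p].index].to_numpy()
        if len(in_idx) < 2:
            logger.warning("population %s has fewer than 2 cells; skipped", p)
            continue
        x_in, x_out = dense[:, in_idx], dense[:, out_idx]
        _, pvals = stats.mannwhitneyu(x_in, x_out, axis=1, alternative="two-sided")
        padj = multipletests(pvals, method="fdr_bh")[1]
        log2fc = (x_in.mean(axis=1) - x_out.mean(axis=1)) / math.log(2)
        ok = (padj < padj_threshold) & (log2fc > 0)
        ranked = [
            nm.genes[i] for i in np.argsort(-log2fc, kind="stable") if ok[i]
        ]
        ranked = remove_housekeeping_symbols(ranked, species=species)[:max_genes]
        if len(ranked) < min_genes:
            logger.info("population %s yields %d genes (< %d); no signature emitted",
                        p, len(ranked), min_genes)
            continue
        out.append(GeneSignature(name=str(p), genes=ranked, source=source,
                                 class_label=str(p)))
    return out


# ---------------------------------------------------------------------------
# Discriminance filter


def discriminance_filter(
    signatures: list[GeneSignature],
    background_scores: pd.DataFrame,
    top_k: int = 10,
    decile: float = 0.10,
) -> tuple[list[GeneSignature], pd.DataFrame]:
    """Exclude nondiscriminant signatures against a background cohort.

    Per background sample, the ``top_k`` highest-scoring signatures are noted;
    signatures are ranked by the number of samples in which they appear. Among
    the A signatures with at least one appearance, the top decile
    (``ceil(decile * A)``) are excluded, extending the cut to every signature
    tied with the last excluded appearance count. Signatures never appearing
    in any top-k are always retained.

    Returns the retained signatures and a report with each signature's
    appearance count and excluded flag.
    """
    if background_scores.empty:
        raise ValueError("background score matrix is empty")
    names = [s.name for s in signatures]
    missing = set(names) - set(background_scores.columns)
    if missing:
        raise ValueError(f"background scores lack candidate signatures: {sorted(missing)}")

    counts = pd.Series(0, index=pd.Index(names, name="signature"), dtype=int)
    sub = background_scores[names]
    for _, row in sub.iterrows():
        vals = row.dropna()
        if vals.empty:
            continue
        cutoff = vals.nlargest(min(top_k, len(vals))).min()
        counts[vals.index[vals >= cutoff]] += 1

    appearing = counts[counts >= 1].sort_values(ascending=False, kind="stable")
    excluded: set[str] = set()
    if len(appearing):
        n_excl = math.ceil(decile * len(appearing))
        boundary = appearing.iloc[n_excl - 1]
        excluded = set(appearing.index[appearing >= boundary])
    report = pd.DataFrame({
        "appearances": counts,
        "excluded": counts.index.isin(excluded),
    })
    retained = [s for s in signatures if s.name not in excluded]
    return retained, report


# ---------------------------------------------------------------------------
# Ortholog mapping


def map_orthologs(
    signatures: list[GeneSignature],
    omap: OrthologMap,
) -> list[GeneSignature]:
    """Translate signatures into the target gene space, keeping order and
    dropping genes without a one-to-one match. Signatures may fall below the
    75-gene floor here (the floor applies before mapping); short or empty
    results are retained with a warning."""
    out = []
    for s in signatures:
        mapped = [omap[g] for g in s.genes if g in omap]
        if not mapped:
            logger.warning("signature %s has no orthologs in the target space", s.name)
        elif len(mapped) < MIN_SIGNATURE_GENES:
            logger.warning("signature %s shrank to %d genes after ortholog mapping",
                           s.name, len(mapped))
        out.append(GeneSignature(name=s.name, genes=mapped, source=s.source,
                                 class_label=s.class_label))
    return out


# ---------------------------------------------------------------------------
# Tumor-type signatures from DE tables


REQUIRED_DE_COLUMNS = ("gene", "log2fc", "base_mean", "wald_stat", "padj")


def tumor_signatures(
    de_tables: dict[str, pd.DataFrame],
    target_group: str,
    n: int = 100,
    padj_threshold: float = 0.05,
    min_base_mean: float = 100.0,
    min_abs_log2fc: float = 1.0,
) -> GeneSignature:
    """Tumor-type signature from pairwise DE tables of the target group
    against every other group.

    Each table must be oriented so positive log2 FC means higher in the
    target group. Per comparison, genes must satisfy padj < 0.05, base mean >
    100 and log2 FC > 1 (target-upregulated); survivors are intersected
    across all comparisons, ranked by the mean Wald statistic, and the top
    ``n`` form the signature.
    """
    if not de_tables:
        raise ValueError("need at least one pairwise comparison")
    survivors: dict[str, set] = {}
    wald: dict[str, pd.Series] = {}
    for comp, df in de_tables.items():
        missing = set(REQUIRED_DE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"comparison {comp}: missing DE columns {sorted(missing)}")
        ok = (
            (df["padj"] < padj_threshold)
            & (df["base_mean"] > min_base_mean)
            & (df["log2fc"] > min_abs_log2fc)
        )
        survivors[comp] = set(df.loc[ok, "gene"])
        wald[comp] = df.set_index("gene")["wald_stat"]

    common = set.intersection(*survivors.values())
    if not common:
        per_comp = {c: len(s) for c, s in survivors.items()}
        raise ValueError(
            f"no gene passes all comparisons; per-comparison survivors: {per_comp}"
        )
    mean_wald = pd.Series({
        g: np.mean([wald[c].get(g, np.nan) for c in de_tables]) for g in common
    }).sort_values(ascending=False, kind="stable")
    top = mean_wald.index[:n].tolist()
    return GeneSignature(name=target_group, genes=top, class_label=target_group)


def simple_wald_de(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Normal-theory Wald test on log counts for synthetic bulk cohorts.

    A deliberately simple DE backend for generated data (per-gene two-sample
    z on log2(count + pseudocount), pooled-variance Wald statistic, BH
    adjustment). Not equivalent to a negative-binomial GLM fit; real DE
    tables are expected as inputs to :func:`tumor_signatures`.
    Orientation: positive log2 FC = higher in ``counts_a``.
    """
    genes = counts_a.index
    la = np.log2(counts_a.to_numpy(dtype=float) + pseudocount)
    lb = np.log2(counts_b.to_numpy(dtype=float) + pseudocount)
    na, nb = la.shape[1], lb.shape[1]
    diff = la.mean(axis=1) - lb.mean(axis=1)
    var = la.var(axis=1, ddof=1) / na + lb.var(axis=1, ddof=1) / nb
    se = np.sqrt(np.maximum(var, 1e-12))
    wald_stat = diff / se
    p = 2 * stats.norm.sf(np.abs(wald_stat))
    padj = multipletests(p, method="fdr_bh")[1]
    base_mean = np.hstack([counts_a.to_numpy(), counts_b.to_numpy()]).mean(axis=1)
    return pd.DataFrame({
        "gene": genes, "log2fc": diff, "base_mean": base_mean,
        "wald_stat": wald_stat, "padj": padj,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path) -> list[GeneSignature]:
    sigs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, description, genes")
            sigs.append(GeneSignature(name=parts[0], class_label=parts[1],
                                      genes=[g for g in parts[2:] if g]))
    return sigs


def write_gmt(signatures: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, s.class_label or "na", *s.genes]) + "\n")
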