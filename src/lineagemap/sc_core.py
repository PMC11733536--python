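"""Core data model and shared conventions for single-cell expression data.

Holds the gene-by-cell count matrix container, library-size log-normalization
(counts scaled to a fixed total per cell, then ``log1p``), per-cluster
expression profiles (mean log-normalized expression and detection rate), and
cell-cycle scoring by the binned-control-gene procedure.

All matrices are genes x cells; per-cluster profiles are clusters x genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "CellMatrix",
    "NormalizedMatrix",
    "ClusterProfile",
    "CellCycleParams",
    "read_cell_matrix",
    "normalize",
    "qc_filter",
    "cluster_profiles",
    "cell_cycle_scores",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Components of a dataset disagree in shape or identifiers."""


def _as_csr(x) -> sp.csr_matrix:
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


class CellMatrix:
    """Genes x cells count matrix with per-cell and per-gene metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows, cells as columns. Dense
        arrays are converted to CSR; sparse inputs are kept sparse.
    genes, cells
        Unique identifiers for rows and columns.
    cell_meta
        Optional per-cell table (e.g. ``sample``, ``cluster`` columns),
        indexed by cell id in the same order as ``cells``.
    gene_meta
        Optional per-gene table (``symbol``, ``chromosome``, ``start``,
        ``end``); genomic columns are optional.
    """

    def __init__(self, counts, genes, cells, cell_meta=None, gene_meta=None):
        self.counts = _as_csr(counts)
        self.genes = pd.Index(genes, name="gene")
        self.cells = pd.Index(cells, name="cell")
        if not self.genes.is_unique:
            dup = self.genes[self.genes.duplicated()][:5].tolist()
            raise ConsistencyError(f"duplicate gene identifiers: {dup}")
        if not self.cells.is_unique:
            dup = self.cells[self.cells.duplicated()][:5].tolist()
            raise ConsistencyError(f"duplicate cell identifiers: {dup}")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ConsistencyError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ConsistencyError("counts must be non-negative")
        self.cell_meta = self._align_meta(cell_meta, self.cells, "cell_meta")
        self.gene_meta = self._align_meta(gene_meta, self.genes, "gene_meta")

    @staticmethod
    def _align_meta(meta, index, name):
        if meta is None:
            return pd.DataFrame(index=index)
        meta = pd.DataFrame(meta)
        if not index.isin(meta.index).all():
            missing = index[~index.isin(meta.index)][:5].tolist()
            raise ConsistencyError(f"{name} missing entries for {missing}")
        return meta.loc[index]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shape(self):
        return self.counts.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, cell_ids) -> "CellMatrix":
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            raise KeyError("unknown cell identifiers in subset")
        return CellMatrix(
            self.counts[:, idx],
            self.genes,
            self.cells[idx],
            self.cell_meta.iloc[idx] if len(self.cell_meta.columns) else None,
            self.gene_meta if len(self.gene_meta.columns) else None,
        )

    def subset_genes(self, gene_ids) -> "CellMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            raise KeyError("unknown gene identifiers in subset")
        return CellMatrix(
            self.counts[idx],
            self.genes[idx],
            self.cells,
            self.cell_meta if len(self.cell_meta.columns) else None,
            self.gene_meta.iloc[idx] if len(self.gene_meta.columns) else None,
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


class NormalizedMatrix:
    """Log-normalized expression on the same axes as its source counts.

    Values are ``log(1 + scale_factor * count / cell_total)`` (natural log);
    cells with zero total get all-zero columns.
    """

    def __init__(self, values, genes, cells, scale_factor):
        self.values = _as_csr(values)
        self.genes = pd.Index(genes, name="gene")
        self.cells = pd.Index(cells, name="cell")
        self.scale_factor = float(scale_factor)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ConsistencyError("normalized values do not match axes")
        if self.values.nnz and self.values.data.min() < 0:
            raise ConsistencyError("log-normalized values must be >= 0")

    @property
    def shape(self):
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.genes, columns=self.cells)


@dataclass
class ClusterProfile:
    """Per-cluster summary of expression: mean log-normalized value and
    detection rate (fraction of cells with count > 0) for every gene."""

    clusters: pd.Index
    mean_expr: pd.DataFrame  # clusters x genes
    detection_rate: pd.DataFrame  # clusters x genes
    n_cells: pd.Series  # per cluster

    def __post_init__(self):
        dr = self.detection_rate.to_numpy()
        if dr.size and (dr.min() < 0 or dr.max() > 1):
            raise ConsistencyError("detection rates must lie in [0, 1]")


@dataclass
class CellCycleParams:
    """Parameters of binned-control cell-cycle scoring: genes are binned by
    average expression into ``n_bins`` equal-frequency bins and
    ``n_ctrl_per_bin`` control genes are drawn from each bin that contains a
    phase gene."""

    n_bins: int = 24
    n_ctrl_per_bin: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 1 or self.n_ctrl_per_bin < 1:
            raise ValueError("n_bins and n_ctrl_per_bin must be >= 1")


# ---------------------------------------------------------------------------
# I/O


def _read_tsv_maybe_gz(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def _find_one(d: Path, stems) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = d / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {d}")


def read_cell_matrix(path, format: str = "mtx_dir", *, dedup: bool = False) -> CellMatrix:
    """Read a count matrix from disk.

    ``mtx_dir``: a directory with a MatrixMarket triplet (``matrix.mtx[.gz]``)
    plus ``features.tsv[.gz]`` (or ``genes.tsv``) and ``barcodes.tsv[.gz]``.
    ``dense_tsv``: genes as rows, cells as columns, header row of cell ids,
    first column gene ids.

    Duplicate gene symbols raise unless ``dedup`` is set, in which case they
    are disambiguated with a ``.1``, ``.2``... suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        mtx = _find_one(path, ["matrix.mtx"])
        feat = _find_one(path, ["features.tsv", "genes.tsv"])
        bc = _find_one(path, ["barcodes.tsv"])
        try:
            counts = _as_csr(mmread(str(mtx)))
        except Exception as e:  # noqa: BLE001 - report file context
            raise FormatError(f"malformed MatrixMarket file {mtx}: {e}") from e
        features = _read_tsv_maybe_gz(feat, header=None)
        barcodes = _read_tsv_maybe_gz(bc, header=None)
        genes = features.iloc[:, 0].astype(str)
        cells = barcodes.iloc[:, 0].astype(str)
        if counts.shape != (len(genes), len(cells)):
            raise ConsistencyError(
                f"matrix is {counts.shape} but features/barcodes give "
                f"({len(genes)}, {len(cells)})"
            )
        gene_meta = None
        if features.shape[1] >= 2:
            gene_meta = pd.DataFrame({"symbol": features.iloc[:, 1].astype(str).values})
    elif format == "dense_tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as e:  # noqa: BLE001
            raise FormatError(f"malformed dense TSV {path}: {e}") from e
        counts = df.to_numpy()
        genes = pd.Series(df.index.astype(str))
        cells = pd.Series(df.columns.astype(str))
        gene_meta = None
    else:
        raise ValueError(f"unknown format {format!r}")

    if genes.duplicated().any():
        if not dedup:
            dups = genes[genes.duplicated()].unique()[:5].tolist()
            raise FormatError(f"duplicate gene identifiers (dedup disabled): {dups}")
        counter: dict[str, int] = {}
        out = []
        for g in genes:
            if g in counter:
                counter[g] += 1
                out.append(f"{g}.{counter[g]}")
            else:
                counter[g] = 0
                out.append(g)
        genes = pd.Series(out)

    gm = None
    if gene_meta is not None:
        gene_meta.index = pd.Index(genes, name="gene")
        gm = gene_meta
    return CellMatrix(counts, genes, cells, gene_meta=gm)


def qc_filter(
    m: CellMatrix,
    min_genes: int | None = None,
    min_counts: int | None = None,
    max_counts: int | None = None,
    max_mito_frac: float | None = None,
    mito_prefix: str = "MT-",
) -> tuple[CellMatrix, pd.DataFrame]:
    """Filter cells by standard QC thresholds.

    Thresholds are per-sample configuration, not defaults — every argument is
    opt-in. Mitochondrial fraction uses genes whose identifier starts with
    ``mito_prefix``. Returns the filtered matrix and a per-cell report of the
    metrics with the first failed rule (empty string = kept).
    """
    totals = m.cell_totals().astype(float)
    n_genes = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    mito_mask = np.asarray(m.genes.str.startswith(mito_prefix), dtype=bool)
    mito = np.asarray(m.counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 0.0)

    failed = np.full(m.n_cells, "", dtype=object)
    if min_genes is not None:
        failed[(failed == "") & (n_genes < min_genes)] = "min_genes"
    if min_counts is not None:
        failed[(failed == "") & (totals < min_counts)] = "min_counts"
    if max_counts is not None:
        failed[(failed == "") & (totals > max_counts)] = "max_counts"
    if max_mito_frac is not None:
        failed[(failed == "") & (mito_frac > max_mito_frac)] = "max_mito_frac"
    report = pd.DataFrame({
        "n_counts": totals, "n_genes": n_genes, "mito_frac": mito_frac,
        "failed": failed,
    }, index=m.cells)
    kept = m.cells[failed == ""]
    if not len(kept):
        raise ValueError("QC thresholds removed every cell")
    logger.info("QC removed %d of %d cells", m.n_cells - len(kept), m.n_cells)
    return m.subset_cells(kept), report


# ---------------------------------------------------------------------------
# Normalization and profiles


def normalize(m: CellMatrix, scale_factor: float = 10_000) -> NormalizedMatrix:
    """Library-size normalize to ``scale_factor`` counts per cell, then log1p.

    Cells with zero total counts yield all-zero columns (with a warning):
    there is no defined proportion to scale.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    totals = m.cell_totals().astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts; left all-zero", int(zero.sum()))
    inv = np.zeros_like(totals)
    inv[~zero] = scale_factor / totals[~zero]
    scaled = m.counts.astype(float).multiply(sp.csr_matrix(inv)).tocsr()
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(scaled, m.genes, m.cells, scale_factor)


def cluster_profiles(
    nm: NormalizedMatrix,
    raw: CellMatrix,
    cluster_of,
    min_cells: int = 20,
) -> ClusterProfile:
    """Per-cluster mean log-normalized expression and raw-count detection rate.

    Clusters with fewer than ``min_cells`` cells are dropped (and logged).
    ``cluster_of`` maps cell id -> cluster id and must cover every cell.
    """
    assign = pd.Series({c: cluster_of[c] for c in nm.cells})
    if assign.isna().any():
        raise ConsistencyError("every cell must be assigned to a cluster")
    sizes = assign.value_counts()
    keep = sizes[sizes >= min_cells]
    dropped = sizes.index.difference(keep.index)
    if len(dropped):
        logger.info(
            "dropping %d clusters with fewer than %d cells: %s",
            len(dropped), min_cells, list(dropped),
        )
    if keep.empty:
        raise ValueError(f"no cluster has at least {min_cells} cells")
    clusters = pd.Index(sorted(keep.index), name="cluster")

    vals = nm.values.tocsc()
    detected = raw.counts.tocsc().astype(bool)
    means, rates, ncells = [], [], []
    cell_pos = pd.Series(np.arange(len(nm.cells)), index=nm.cells)
    for cl in clusters:
        idx = cell_pos[assign[assign == cl].index].to_numpy()
        means.append(np.asarray(vals[:, idx].mean(axis=1)).ravel())
        # sparse bool mean can exceed 1 by float epsilon
        rates.append(np.clip(np.asarray(detected[:, idx].mean(axis=1)).ravel(), 0.0, 1.0))
        ncells.append(len(idx))
    return ClusterProfile(
        clusters=clusters,
        mean_expr=pd.DataFrame(means, index=clusters, columns=nm.genes),
        detection_rate=pd.DataFrame(rates, index=clusters, columns=nm.genes),
        n_cells=pd.Series(ncells, index=clusters, name="n_cells"),
    )


def cell_cycle_scores(
    nm: NormalizedMatrix,
    phase_gene_lists: dict,
    params: CellCycleParams | None = None,
) -> pd.DataFrame:
    """Per-cell phase scores: mean expression of phase genes minus mean
    expression of matched control genes.

    Controls are drawn by binning all genes into ``n_bins`` equal-frequency
    bins of average expression and sampling ``n_ctrl_per_bin`` genes (without
    replacement) from every bin containing at least one phase gene. Fixed
    seed gives bit-identical scores.
    """
    params = params or CellCycleParams()
    rng = np.random.default_rng(params.seed)
    dense = nm.to_dense()
    gene_pos = pd.Series(np.arange(len(nm.genes)), index=nm.genes)
    avg = dense.mean(axis=1)
    # equal-frequency bins; duplicates dropped for degenerate distributions
    bins = pd.qcut(pd.Series(avg, index=nm.genes), params.n_bins, duplicates="drop")

    out = {}
    for phase, genes in phase_gene_lists.items():
        present = [g for g in genes if g in gene_pos.index]
        if not present:
            raise ValueError(f"phase list {phase!r} empty after intersection with matrix genes")
        phase_bins = bins.loc[present].unique()
        ctrl: list[str] = []
        for b in phase_bins:
            members = bins.index[bins == b].to_numpy()
            k = min(params.n_ctrl_per_bin, len(members))
            ctrl.extend(rng.choice(members, size=k, replace=False))
        phase_idx = gene_pos[present].to_numpy()
        ctrl_idx = gene_pos[ctrl].to_numpy()
        out[phase] = dense[phase_idx].mean(axis=0) - dense[ctrl_idx].mean(axis=0)
    return pd.DataFrame(out, index=nm.cells)
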