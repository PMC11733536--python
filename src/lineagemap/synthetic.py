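"""Lineage-structured synthetic data with known ground truth.

Every pipeline stage is testable offline through this module: it generates
single-cell count matrices organised into telencephalic classes (MGE-derived,
CGE/LGE-derived, excitatory, glia, immune) with class-specific expression of a
panel of patterning transcription factors, pseudobulk tumor cohorts mixing
those classes, count matrices carrying block copy-number events, and
replicate/control/ATAC peak sets for the CUT&RUN refinement stage.

Counts are negative-binomial (the standard overdispersed model for UMI data)
with Bernoulli dropout; panel-TF identity is encoded in both the mean and the
detection probability, mirroring the two features the fingerprint classifier
consumes. All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import Peak
from .sc_core import CellMatrix

__all__ = [
    "LineageSpec",
    "CNAEvent",
    "CNASpec",
    "DEFAULT_TF_PANEL",
    "synthetic_gene_meta",
    "make_reference",
    "make_tumor_cohort",
    "make_cnv_dataset",
    "make_peak_sets",
]

TF_PANEL_GENES = [
    "FOXG1", "PAX6", "EMX1", "EMX2", "TBR1", "EOMES",
    "GSX2", "NKX2-1", "LHX6", "DLX1", "DLX2", "DLX5", "DLX6",
]

# Per class: TF -> (mean counts when detected, detection probability).
# Encodes the qualitative regional logic of telencephalic patterning:
# FOXG1 pan-telencephalic; NKX2-1/LHX6 MGE; GSX2 LGE/CGE; DLX1/2/5/6 all
# GABAergic; PAX6/EMX1/EMX2/TBR1/EOMES dorsal-excitatory.
DEFAULT_TF_PANEL: dict[str, dict[str, tuple[float, float]]] = {
    "MGE": {
        "FOXG1": (5.0, 0.90), "NKX2-1": (4.0, 0.80), "LHX6": (4.0, 0.85),
        "DLX1": (3.0, 0.80), "DLX2": (3.0, 0.80), "DLX5": (3.0, 0.75),
        "DLX6": (3.0, 0.75), "GSX2": (0.3, 0.10), "PAX6": (0.2, 0.05),
        "EMX1": (0.05, 0.02), "EMX2": (0.05, 0.02), "TBR1": (0.05, 0.02),
        "EOMES": (0.05, 0.02),
    },
    "CGE_LGE": {
        "FOXG1": (5.0, 0.90), "GSX2": (3.0, 0.70), "DLX1": (3.0, 0.80),
        "DLX2": (3.0, 0.80), "DLX5": (3.0, 0.75), "DLX6": (3.0, 0.75),
        "NKX2-1": (0.05, 0.02), "LHX6": (0.2, 0.06), "PAX6": (0.5, 0.15),
        "EMX1": (0.05, 0.02), "EMX2": (0.05, 0.02), "TBR1": (0.05, 0.02),
        "EOMES": (0.05, 0.02),
    },
    "excitatory": {
        "FOXG1": (5.0, 0.90), "PAX6": (2.0, 0.50), "EMX1": (3.0, 0.70),
        "EMX2": (3.0, 0.70), "TBR1": (4.0, 0.80), "EOMES": (2.0, 0.50),
        "GSX2": (0.05, 0.02), "NKX2-1": (0.05, 0.02), "LHX6": (0.05, 0.02),
        "DLX1": (0.1, 0.03), "DLX2": (0.1, 0.03), "DLX5": (0.05, 0.02),
        "DLX6": (0.05, 0.02),
    },
    "glia": {
        "FOXG1": (2.0, 0.50), "PAX6": (2.0, 0.45), "EMX2": (1.0, 0.30),
        "EMX1": (0.3, 0.10), "TBR1": (0.1, 0.03), "EOMES": (0.1, 0.03),
        "GSX2": (0.5, 0.15), "NKX2-1": (0.1, 0.03), "LHX6": (0.05, 0.02),
        "DLX1": (0.1, 0.03), "DLX2": (0.1, 0.03), "DLX5": (0.05, 0.02),
        "DLX6": (0.05, 0.02),
    },
    "immune": {tf: (0.02, 0.01) for tf in TF_PANEL_GENES},
}


@dataclass
class LineageSpec:
    """Parameters of the synthetic lineage-structured reference."""

    classes: tuple[str, ...] = ("MGE", "CGE_LGE", "excitatory", "glia", "immune")
    tf_panel: dict = field(default_factory=lambda: DEFAULT_TF_PANEL)
    n_clusters_per_class: int = 5
    cells_per_cluster: tuple[int, int] = (30, 80)
    dropout: float = 0.9  # Bernoulli retention probability for background genes
    dispersion: float = 0.1  # NB dispersion; variance = mu + dispersion * mu^2
    seed: int = 0
    n_genes: int = 2000
    n_chromosomes: int = 20
    n_markers_per_class: int = 120
    marker_fold: float = 8.0
    background_log_mean: float = float(np.log(0.5))
    background_log_sd: float = 1.0
    cluster_jitter_sd: float = 0.25

    def __post_init__(self):
        if not (0 < self.dropout <= 1):
            raise ValueError("dropout retention must be in (0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_clusters_per_class < 1:
            raise ValueError("need at least one cluster per class")
        for cls in self.classes:
            if cls not in self.tf_panel:
                raise ValueError(f"no TF panel profile for class {cls!r}")


@dataclass
class CNAEvent:
    """One copy-number event over a contiguous block of the ordered genome
    (global gene indices, end exclusive)."""

    chrom: str
    start_index: int
    end_index: int
    fold_change: float

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")
        if self.start_index >= self.end_index:
            raise ValueError("empty gene index range")


@dataclass
class CNASpec:
    events: list[CNAEvent] = field(default_factory=list)
    affected_fraction: float = 0.5

    def __post_init__(self):
        if not (0 <= self.affected_fraction <= 1):
            raise ValueError("affected fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Synthetic genome


def synthetic_gene_meta(n_genes: int = 2000, n_chromosomes: int = 20) -> pd.DataFrame:
    """Ordered synthetic genome: genes split evenly across chromosomes, 10 kb
    apart, panel TFs occupying the first slots of chromosome 1."""
    per_chrom = n_genes // n_chromosomes
    names, chroms, starts = [], [], []
    for i in range(n_genes):
        c = i // per_chrom
        pos = i % per_chrom
        chroms.append(f"chr{min(c, n_chromosomes - 1) + 1}")
        starts.append(pos * 10_000 + 1_000)
        if i < len(TF_PANEL_GENES):
            names.append(TF_PANEL_GENES[i])
        else:
            names.append(f"GENE{i:04d}")
    meta = pd.DataFrame({
        "symbol": names,
        "chromosome": chroms,
        "start": starts,
        "end": [s + 1_000 for s in starts],
    }, index=pd.Index(names, name="gene"))
    return meta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 (size = 1/dispersion)."""
    size = 1.0 / dispersion
    mu = np.clip(mu, 1e-12, None)
    return rng.negative_binomial(size, size / (size + mu))


# ---------------------------------------------------------------------------
# Reference generator


def _class_means(spec: LineageSpec):
    """Background means, per-class marker boosts and marker gene sets.

    Drawn from a generator seeded by ``spec.seed`` alone, so the class
    structure (which genes mark which class) is a property of the spec and is
    shared between the reference and any cohort generated from it.
    """
    rng = np.random.default_rng(spec.seed)
    gene_meta = synthetic_gene_meta(spec.n_genes, spec.n_chromosomes)
    genes = gene_meta.index
    n_panel = len(TF_PANEL_GENES)
    base = np.exp(rng.normal(spec.background_log_mean, spec.background_log_sd,
                             size=spec.n_genes))
    base[:n_panel] = 0.0  # panel TFs handled separately

    # disjoint per-class marker sets among background genes
    candidates = rng.permutation(np.arange(n_panel, spec.n_genes))
    markers = {}
    class_mu = {}
    for i, cls in enumerate(spec.classes):
        sel = candidates[i * spec.n_markers_per_class:(i + 1) * spec.n_markers_per_class]
        markers[cls] = genes[sel].tolist()
        mu = base.copy()
        mu[sel] = np.maximum(mu[sel], 1.0) * spec.marker_fold
        class_mu[cls] = mu
    return gene_meta, class_mu, markers


def make_reference(spec: LineageSpec | None = None, seed: int | None = None):
    """Generate a lineage-structured reference count matrix.

    Returns a :class:`CellMatrix` whose ``cell_meta`` carries the ground-truth
    ``class`` and ``cluster`` of every cell. Cluster-level lognormal jitter on
    panel-TF means and mild jitter on detection probabilities make clusters
    within a class distinct without blurring class boundaries.

    The class structure (marker genes, background means) is a function of
    ``spec.seed``; ``seed`` controls only cell sampling, so two calls with
    different ``seed`` give independent datasets of the *same* populations
    (e.g. a reference/query pair for annotation).
    """
    spec = spec or LineageSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    gene_meta, class_mu, _markers = _class_means(spec)
    genes = gene_meta.index
    n_panel = len(TF_PANEL_GENES)
    panel_pos = {tf: i for i, tf in enumerate(TF_PANEL_GENES)}

    blocks, classes_of_cells, clusters_of_cells = [], [], []
    lo, hi = spec.cells_per_cluster
    for cls in spec.classes:
        for k in range(spec.n_clusters_per_class):
            cluster_id = f"{cls}_{k}"
            n_cells = int(rng.integers(lo, hi + 1))
            mu = np.tile(class_mu[cls], (n_cells, 1))  # cells x genes
            retain_p = np.full(spec.n_genes, spec.dropout)
            for tf, (tf_mu, tf_p) in spec.tf_panel[cls].items():
                j = panel_pos[tf]
                mu[:, j] = tf_mu * np.exp(rng.normal(0, spec.cluster_jitter_sd))
                retain_p[j] = np.clip(
                    tf_p * np.exp(rng.normal(0, spec.cluster_jitter_sd / 2)), 0, 1
                )
            counts = _nb_draw(rng, mu, spec.dispersion)
            mask = rng.random(counts.shape) < retain_p[None, :]
            counts = counts * mask
            blocks.append(counts)
            classes_of_cells.extend([cls] * n_cells)
            clusters_of_cells.extend([cluster_id] * n_cells)

    if not blocks:
        raise ValueError("degenerate spec: no clusters generated")
    all_counts = np.vstack(blocks).T  # genes x cells
    cells = pd.Index([f"cell{i:05d}" for i in range(all_counts.shape[1])], name="cell")
    cell_meta = pd.DataFrame(
        {"class": classes_of_cells, "cluster": clusters_of_cells, "sample": "synthetic"},
        index=cells,
    )
    return CellMatrix(all_counts, genes, cells, cell_meta=cell_meta, gene_meta=gene_meta)


# ---------------------------------------------------------------------------
# Pseudobulk tumor cohorts


def make_tumor_cohort(
    spec: LineageSpec,
    groups: dict[str, dict[str, float]],
    n_per_group: int,
    n_cells_per_sample: int = 200,
    seed: int = 0,
):
    """Pseudobulk cohort: each sample is the summed counts of cells drawn from
    a named mixture of lineage classes.

    Returns ``(bulk, sample_meta)``: a genes x samples count table and a table
    with each sample's group and ground-truth dominant class.
    """
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    for name, mix in groups.items():
        if not mix:
            raise ValueError(f"group {name!r} has an empty mixture")
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ValueError(f"group {name!r}: mixture proportions must sum to 1")
        for cls in mix:
            if cls not in spec.classes:
                raise ValueError(f"group {name!r}: unknown class {cls!r}")

    rng = np.random.default_rng(seed)
    gene_meta, class_mu, _ = _class_means(spec)
    panel_pos = {tf: i for i, tf in enumerate(TF_PANEL_GENES)}

    cols, meta = {}, []
    for gname, mix in groups.items():
        cls_names = list(mix)
        probs = np.array([mix[c] for c in cls_names])
        for s in range(n_per_group):
            sid = f"{gname}_s{s}"
            n_by_class = rng.multinomial(n_cells_per_sample, probs)
            total = np.zeros(spec.n_genes, dtype=np.int64)
            for cls, n_c in zip(cls_names, n_by_class):
                if n_c == 0:
                    continue
                mu = np.tile(class_mu[cls], (n_c, 1))
                retain_p = np.full(spec.n_genes, spec.dropout)
                for tf, (tf_mu, tf_p) in spec.tf_panel[cls].items():
                    j = panel_pos[tf]
                    mu[:, j] = tf_mu
                    retain_p[j] = tf_p
                counts = _nb_draw(rng, mu, spec.dispersion)
                counts = counts * (rng.random(counts.shape) < retain_p[None, :])
                total += counts.sum(axis=0)
            cols[sid] = total
            meta.append({
                "sample": sid, "group": gname,
                "dominant_class": cls_names[int(np.argmax(probs))],
            })
    bulk = pd.DataFrame(cols, index=gene_meta.index)
    return bulk, pd.DataFrame(meta).set_index("sample")


# ---------------------------------------------------------------------------
# Copy-number fixture


def make_cnv_dataset(
    cna: CNASpec,
    n_cells: int = 400,
    seed: int = 0,
    n_genes: int = 2000,
    n_chromosomes: int = 20,
    base_log_mean: float = float(np.log(8.0)),
    base_log_sd: float = 0.6,
    dispersion: float = 0.05,
    dropout: float = 0.95,
) -> CellMatrix:
    """Count matrix with a malignant subpopulation carrying block CNAs.

    Gene base means are lognormal around 8 counts so the whole genome clears
    the expression cutoff of the CNV scorer; malignant cells (the spec's
    ``affected_fraction``) have the event blocks' means multiplied by the fold
    change. ``cell_meta['malignant']`` records the ground truth.
    """
    rng = np.random.default_rng(seed)
    gene_meta = synthetic_gene_meta(n_genes, n_chromosomes)
    for ev in cna.events:
        if ev.end_index > n_genes:
            raise ValueError("CNA event outside the synthetic genome")
    base = np.exp(rng.normal(base_log_mean, base_log_sd, size=n_genes))

    n_mal = int(round(cna.affected_fraction * n_cells))
    malignant = np.zeros(n_cells, dtype=bool)
    malignant[:n_mal] = True

    mu = np.tile(base, (n_cells, 1))
    for ev in cna.events:
        mu[malignant, ev.start_index:ev.end_index] *= ev.fold_change
    counts = _nb_draw(rng, mu, dispersion)
    counts = counts * (rng.random(counts.shape) < dropout)

    cells = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    cell_meta = pd.DataFrame(
        {"malignant": malignant, "sample": "synthetic"}, index=cells
    )
    return CellMatrix(counts.T, gene_meta.index, cells,
                      cell_meta=cell_meta, gene_meta=gene_meta)


# ---------------------------------------------------------------------------
# Peak-set fixture


def make_peak_sets(
    n_true: int,
    n_control_only: int,
    genome_length: int = 1_000_000,
    seed: int = 0,
):
    """Replicate/control/ATAC narrowPeak sets with known surviving intervals.

    ``n_true`` peaks pass every filter and appear identically in both CUT&RUN
    replicates and (padded by 50 bp) in the ATAC set. ``n_control_only``
    decoys are valid peaks overlapped by a control peak. Three additional
    threshold decoys fail exactly one rule each: -log10 q = 6.0, signalValue
    = 6.0, and length = 10,000 bp. Ground truth lists the intervals the
    refinement pipeline should emit.
    """
    if n_true < 0 or n_control_only < 0:
        raise ValueError("peak counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_slots_needed = n_true + n_control_only + 3
    slot = 20_000  # room for the 10 kb length decoy plus padding
    if n_slots_needed * slot > genome_length:
        raise ValueError("genome too short for the requested peak count")
    slots = rng.permutation(genome_length // slot)[:n_slots_needed]

    def peak(name, start, end, signal=8.0, q=8.0):
        return Peak(chrom="chr1", start=int(start), end=int(end), name=name,
                    score=int(min(1000, q * 100)), strand=".",
                    signal_value=signal, p_value=q + 1, q_value=q,
                    summit=(end - start) // 2)

    rep1, rep2, control, atac, truth = [], [], [], [], []
    i = 0
    for t in range(n_true):
        start = slots[i] * slot + int(rng.integers(0, 5_000)); i += 1
        end = start + int(rng.integers(300, 900))
        rep1.append(peak(f"true{t}", start, end))
        rep2.append(peak(f"true{t}", start, end))
        atac.append(peak(f"atac_true{t}", start - 50, end + 50, signal=5.0, q=6.0))
        truth.append(("chr1", start, end))
    for d in range(n_control_only):
        start = slots[i] * slot + int(rng.integers(0, 5_000)); i += 1
        end = start + int(rng.integers(300, 900))
        rep1.append(peak(f"ctrl_decoy{d}", start, end))
        rep2.append(peak(f"ctrl_decoy{d}", start, end))
        atac.append(peak(f"atac_ctrl_decoy{d}", start - 50, end + 50, signal=5.0, q=6.0))
        control.append(peak(f"control{d}", start - 20, start + 200, signal=3.0, q=5.0))
    # threshold decoys: each violates exactly one rule
    specs = [("q_decoy", dict(q=6.0)), ("sig_decoy", dict(signal=6.0)),
             ("len_decoy", dict())]
    for name, kw in specs:
        start = slots[i] * slot + 100; i += 1
        length = 10_000 if name == "len_decoy" else int(rng.integers(300, 900))
        end = start + length
        rep1.append(peak(name, start, end, **kw))
        rep2.append(peak(name, start, end, **kw))
        atac.append(peak(f"atac_{name}", start - 50, end + 50, signal=5.0, q=6.0))
    truth.sort(key=lambda iv: iv[1])
    return {"rep1": rep1, "rep2": rep2, "control": control, "atac": atac,
            "truth": truth}
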