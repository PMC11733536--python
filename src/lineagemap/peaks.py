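"""CUT&RUN peak refinement against tag-only controls and ATAC accessibility.

Implements the post-calling filter chain: removal of peaks overlapping control
peaks by at least a minimum number of base pairs, removal of weak or oversized
peaks by q-value / signal / length thresholds, nucleotide-level intersection of
the two CUT&RUN replicates with the ATAC peak set, and export of fixed-width
windows around interval centers for motif scanning.

Intervals follow the BED convention: 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakFilterParams",
    "read_narrowpeak",
    "write_narrowpeak",
    "write_bed",
    "filter_cutrun",
    "filter_atac",
    "intersect_consensus",
    "motif_windows",
]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "summit",
]


@dataclass
class Peak:
    """One ENCODE narrowPeak record (BED6+4)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0  # -log10, sentinel -1 when absent
    q_value: float = -1.0  # -log10, sentinel -1 when absent
    summit: int = -1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakFilterParams:
    """Filter thresholds; boundary values are removed, not kept (a peak with
    -log10 q exactly at the cutoff fails the filter)."""

    control_overlap_bp: int = 10
    min_neglog10_q_cutrun: float = 6.0
    min_signal_cutrun: float = 6.0
    max_len: int = 10_000
    min_neglog10_q_atac: float = 4.0
    min_signal_atac: float = 2.0


# ---------------------------------------------------------------------------
# I/O


def read_narrowpeak(path) -> list[Peak]:
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{i}: expected 10 narrowPeak columns, got {len(parts)}")
            try:
                peaks.append(Peak(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    name=parts[3], score=int(float(parts[4])), strand=parts[5],
                    signal_value=float(parts[6]), p_value=float(parts[7]),
                    q_value=float(parts[8]), summit=int(parts[9]),
                ))
            except ValueError as e:
                raise ValueError(f"{path}:{i}: malformed narrowPeak line: {e}") from e
    return peaks


def write_narrowpeak(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write("\t".join(str(x) for x in (
                p.chrom, p.start, p.end, p.name, p.score, p.strand,
                p.signal_value, p.p_value, p.q_value, p.summit,
            )) + "\n")


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end) triples as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Interval primitives


def overlap_length(s1: int, e1: int, s2: int, e2: int) -> int:
    """Overlap in bp between two half-open intervals (0 when disjoint)."""
    return max(0, min(e1, e2) - max(s1, s2))


def merge_intervals(intervals) -> list[tuple[str, int, int]]:
    """Union of half-open intervals as maximal disjoint runs, sorted."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def _intersect_two(a, b) -> list[tuple[str, int, int]]:
    """Intersection of two merged, sorted interval sets."""
    from collections import defaultdict

    a_by, b_by = defaultdict(list), defaultdict(list)
    for c, s, e in a:
        a_by[c].append((s, e))
    for c, s, e in b:
        b_by[c].append((s, e))
    out = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                out.append((chrom, s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return out


# ---------------------------------------------------------------------------
# Filters


def _peak_intervals(peaks) -> list[tuple[str, int, int]]:
    return [(p.chrom, p.start, p.end) for p in peaks]


def filter_cutrun(
    peaks: list[Peak],
    controls: list[list[Peak]],
    params: PeakFilterParams | None = None,
) -> tuple[list[Peak], pd.DataFrame]:
    """Refine CUT&RUN peaks against control replicates and quality thresholds.

    Removes peaks that (a) overlap any control peak by >= ``control_overlap_bp``,
    (b) have -log10 q <= ``min_neglog10_q_cutrun``, (c) have signalValue <=
    ``min_signal_cutrun``, or (d) are >= ``max_len`` bp long. A missing q-value
    (sentinel -1) fails the q filter. Returns the retained peaks and a removal
    report attributing each removal to the first rule it violated.
    """
    params = params or PeakFilterParams()
    ctrl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for cset in controls:
        for c, s, e in merge_intervals(_peak_intervals(cset)) if cset else []:
            ctrl_by_chrom.setdefault(c, []).append((s, e))

    def control_hit(p: Peak) -> bool:
        return any(
            overlap_length(p.start, p.end, s, e) >= params.control_overlap_bp
            for s, e in ctrl_by_chrom.get(p.chrom, [])
        )

    kept, removed = [], []
    for p in peaks:
        if control_hit(p):
            removed.append((p.name, "control_overlap"))
        elif p.q_value <= params.min_neglog10_q_cutrun:
            removed.append((p.name, "q_value"))
        elif p.signal_value <= params.min_signal_cutrun:
            removed.append((p.name, "signal_value"))
        elif p.length >= params.max_len:
            removed.append((p.name, "length"))
        else:
            kept.append(p)
    report = pd.DataFrame(removed, columns=["peak", "rule"])
    return kept, report


def filter_atac(
    peaks: list[Peak],
    params: PeakFilterParams | None = None,
    blacklist=None,
    allowed_chroms=None,
) -> tuple[list[Peak], pd.DataFrame]:
    """Filter ATAC peaks: non-standard chromosomes, blacklist overlap (any bp),
    then q/signal/length thresholds with the ATAC cutoffs."""
    params = params or PeakFilterParams()
    allowed = set(allowed_chroms) if allowed_chroms is not None else None
    bl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if blacklist:
        for c, s, e in merge_intervals(blacklist):
            bl_by_chrom.setdefault(c, []).append((s, e))

    kept, removed = [], []
    for p in peaks:
        if allowed is not None and p.chrom not in allowed:
            removed.append((p.name, "chromosome"))
        elif any(overlap_length(p.start, p.end, s, e) > 0
                 for s, e in bl_by_chrom.get(p.chrom, [])):
            removed.append((p.name, "blacklist"))
        elif p.q_value <= params.min_neglog10_q_atac:
            removed.append((p.name, "q_value"))
        elif p.signal_value <= params.min_signal_atac:
            removed.append((p.name, "signal_value"))
        elif p.length >= params.max_len:
            removed.append((p.name, "length"))
        else:
            kept.append(p)
    report = pd.DataFrame(removed, columns=["peak", "rule"])
    return kept, report


def intersect_consensus(rep1, rep2, atac) -> list[tuple[str, int, int]]:
    """Base-pair-level triple intersection of two CUT&RUN replicates and the
    ATAC peak set: a position survives iff covered in all three sets; maximal
    runs of surviving positions are emitted as intervals."""
    sets = []
    for peaks in (rep1, rep2, atac):
        ivs = _peak_intervals(peaks) if peaks and isinstance(peaks[0], Peak) else list(peaks)
        if not ivs:
            return []
        sets.append(merge_intervals(ivs))
    return _intersect_two(_intersect_two(sets[0], sets[1]), sets[2])


def scan_pwm(
    sequence: str,
    pwm,
    background=(0.25, 0.25, 0.25, 0.25),
    threshold: float = 0.0,
) -> list[tuple[int, float]]:
    """Log-odds scan of a position weight matrix along one sequence strand.

    ``pwm`` is a length-L list of (A, C, G, T) probability rows. Returns
    (offset, score) for every window whose summed log2-odds against the
    background exceeds ``threshold``. Plumbing for user-supplied matrices —
    a simple scanner, not a motif-discovery tool; ambiguous bases score as
    the background (log-odds 0).
    """
    import math

    alphabet = {"A": 0, "C": 1, "G": 2, "T": 3}
    logodds = [
        [math.log2(max(row[b], 1e-9) / background[b]) for b in range(4)]
        for row in pwm
    ]
    L = len(logodds)
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - L + 1):
        score = 0.0
        for j in range(L):
            b = alphabet.get(seq[i + j])
            if b is not None:
                score += logodds[j][b]
        if score > threshold:
            hits.append((i, score))
    return hits


def motif_windows(consensus, flank: int = 100) -> list[tuple[str, int, int]]:
    """Fixed windows around interval centers, ``[center - flank, center + flank)``,
    clipped at position 0; ``center = floor((start + end) / 2)``."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for chrom, start, end in consensus:
        center = (start + end) // 2
        out.append((chrom, max(0, center - flank), center + flank))
    return out
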