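"""Peak-set overlap, TSS-window target assignment and promoter counting.

All interval arithmetic is 0-based half-open; two intervals intersect iff
they share at least one base. Intersection uses a per-chromosome sorted
sweep (merge the query set, binary-search each subject), which matches the
brute-force all-pairs definition.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, GenomicInterval, ReadTag


@dataclass(frozen=True)
class OverlapSummary:
    """Pairwise peak-set overlap counts and percentages (both directions)."""

    set_a: str
    set_b: str
    n_a: int
    n_b: int
    n_a_overlapping: int
    n_b_overlapping: int

    @property
    def pct_a(self) -> float:
        return 100.0 * self.n_a_overlapping / self.n_a

    @property
    def pct_b(self) -> float:
        return 100.0 * self.n_b_overlapping / self.n_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_a": self.set_a,
                    "set_b": self.set_b,
                    "n_a": self.n_a,
                    "n_b": self.n_b,
                    "n_a_overlapping": self.n_a_overlapping,
                    "n_b_overlapping": self.n_b_overlapping,
                    "pct_a": round(self.pct_a, 1),
                    "pct_b": round(self.pct_b, 1),
                }
            ]
        )


def _merged_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge intervals per chromosome into disjoint sorted (starts, ends)."""
    grouped = defaultdict(list)
    for iv in intervals:
        grouped[iv.chrom].append((iv.start, iv.end))
    merged = {}
    for chrom, pairs in grouped.items():
        pairs.sort()
        starts, ends = [], []
        for start, end in pairs:
            if ends and start <= ends[-1]:  # touching intervals stay separate...
                if start < ends[-1]:  # ...only true overlaps merge
                    ends[-1] = max(ends[-1], end)
                    continue
            starts.append(start)
            ends.append(end)
        # abutting intervals may remain unmerged; ends are still sorted,
        # which is all the sweep needs
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def intersect_any(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean per interval of ``a``: does it overlap >= 1 bp of any b interval?"""
    merged = _merged_by_chrom(b)
    out = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        if iv.chrom not in merged:
            continue
        starts, ends = merged[iv.chrom]
        j = int(np.searchsorted(starts, iv.end, side="left")) - 1
        # after merging, ends are non-decreasing, so only the rightmost
        # candidate with start < iv.end can reach past iv.start
        out[i] = j >= 0 and ends[j] > iv.start
    return out


def overlap_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) index pairs with a[i] overlapping b[j] (sorted sweep)."""
    b_by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for j, iv in enumerate(b):
        b_by_chrom[iv.chrom].append((iv.start, iv.end, j))
    for entries in b_by_chrom.values():
        entries.sort()
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        entries = b_by_chrom.get(iv.chrom)
        if not entries:
            continue
        starts = [e[0] for e in entries]
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        for start, end, j in entries[:hi]:
            if end > iv.start:
                pairs.append((i, j))
    return pairs


def overlap_summary(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapSummary:
    """Count peaks of each set intersecting >= 1 peak of the other."""
    if not a:
        raise ValueError(f"peak set {name_a!r} is empty")
    if not b:
        raise ValueError(f"peak set {name_b!r} is empty")
    return OverlapSummary(
        set_a=name_a,
        set_b=name_b,
        n_a=len(a),
        n_b=len(b),
        n_a_overlapping=int(intersect_any(a, b).sum()),
        n_b_overlapping=int(intersect_any(b, a).sum()),
    )


def tss_windows(
    annotation: GeneAnnotation, flank: int = 1500
) -> list[GenomicInterval]:
    """Symmetric +/- flank windows around every TSS, inclusive on both ends.

    A window around TSS t is ``[max(t - flank, 0), t + flank + 1)`` — width
    ``2*flank + 1`` away from the chromosome start. Strand does not change
    the geometry. The window carries the gene id as its name.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows = []
    for row in annotation.table.itertuples(index=False):
        start = max(int(row.tss) - flank, 0)
        windows.append(
            GenomicInterval(
                row.chrom, start, int(row.tss) + flank + 1, row.strand,
                0.0, row.gene_id,
            )
        )
    return windows


def assign_targets(
    peaks: Sequence[GenomicInterval], windows: Sequence[GenomicInterval]
) -> tuple[set[str], dict[str, list[str]]]:
    """Genes whose TSS window (any of them) intersects >= 1 peak.

    Returns the deduplicated target gene set and, per target gene, the
    names of the supporting peaks.
    """
    support: dict[str, list[str]] = {}
    for w_idx, p_idx in overlap_pairs(windows, peaks):
        gene = windows[w_idx].name
        peak = peaks[p_idx].name or f"peak_{p_idx}"
        support.setdefault(gene, [])
        if peak not in support[gene]:
            support[gene].append(peak)
    return set(support), support


def select_promoter(
    annotation: GeneAnnotation, promoter_scores: Sequence[float]
) -> pd.DataFrame:
    """Pick each gene's representative promoter: the TSS with maximal score.

    ``promoter_scores`` aligns with the annotation rows (one score per TSS,
    typically the normalized enrichment of an active-promoter mark such as
    H3K4me3). Ties go to the smallest genomic coordinate. Missing scores
    are an error naming the gene.
    """
    scores = np.asarray(promoter_scores, dtype=float)
    if scores.shape[0] != len(annotation.table):
        raise ValueError("one score per TSS is required")
    table = annotation.table.copy()
    table["promoter_score"] = scores
    bad = table.loc[~np.isfinite(scores), "gene_id"].unique()
    if len(bad):
        raise ValueError(f"genes with unscored TSS: {sorted(bad)}")
    chosen = (
        table.sort_values(
            ["gene_id", "promoter_score", "tss"],
            ascending=[True, False, True],
            kind="stable",
        )
        .groupby("gene_id", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    return chosen[["gene_id", "chrom", "tss", "strand", "promoter_score"]]


def promoter_counts(
    chip_tags: Sequence[ReadTag],
    control_tags: Sequence[ReadTag],
    windows: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Paired (s, r) counts of tag 5' ends per TSS window.

    Tags are expected pre-shifted per the track's convention. Overlapping
    windows count independently. Region ids come from the window names.
    """
    def by_chrom(tags):
        grouped = defaultdict(list)
        for t in tags:
            grouped[t.chrom].append(t.five_prime)
        return {c: np.sort(np.asarray(p)) for c, p in grouped.items()}

    chip = by_chrom(chip_tags)
    ctrl = by_chrom(control_tags)

    def count(pos_map, w):
        pos = pos_map.get(w.chrom)
        if pos is None:
            return 0
        return int(
            np.searchsorted(pos, w.end, "left") - np.searchsorted(pos, w.start, "left")
        )

    rows = [
        {
            "region_id": w.name or f"window_{i}",
            "s": count(chip, w),
            "r": count(ctrl, w),
        }
        for i, w in enumerate(windows)
    ]
    return pd.DataFrame(rows, columns=["region_id", "s", "r"])
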