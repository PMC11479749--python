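"""Split-read junction caller for circular DNA.

A circle whose sequence was amplified by rolling-circle amplification
produces reads that cross its start-end joint. Aligned against the linear
reference, such a read splits: a matched segment abutting one circle
boundary plus a soft-clipped remainder whose sequence belongs at the other
boundary. The caller scans alignments for terminal soft-clips, re-maps each
clipped sequence against the reference near the candidate partner boundary
(exact match, or one mismatch via a pigeonhole split), collects the implied
(start, end) junction evidence, clusters evidence whose boundaries agree
within a tolerance, and emits one circle per sufficiently supported cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedSegment:
    """Minimal alignment record: position, match/soft-clip CIGAR, MAPQ, bases.

    ``cigar`` is an ordered list of (op, length) with op in {"M", "S"};
    soft-clips may appear only at the ends and at least one M is required.
    """

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost mapped base
    cigar: list[tuple[str, int]]
    mapq: int
    seq: str

    def __post_init__(self):
        ops = [op for op, _ in self.cigar]
        if "M" not in ops:
            raise ValueError(f"{self.read_id}: CIGAR has no match segment")
        if any(op == "S" for op in ops[1:-1]):
            raise ValueError(f"{self.read_id}: internal soft-clip")

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op == "M")

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar[-1][0] == "S" else 0


@dataclass(frozen=True)
class JunctionEvidence:
    """One read's vote for a circle junction (start < end, half-open)."""

    chrom: str
    circle_start: int
    circle_end: int
    read_id: str
    side: str  # "right" or "left": which terminal clip anchored the call

    def __post_init__(self):
        if not self.circle_start < self.circle_end:
            raise ValueError("circle_start must be < circle_end")


@dataclass(frozen=True)
class EccRecord:
    """A called circle on a 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    split_support: int
    gc: float
    sample_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class CallerParams:
    """Tunable thresholds of the junction caller.

    min_clip_len: shortest soft-clip considered junction evidence (bp).
    min_mapq: minimum mapping quality of the anchoring segment.
    boundary_tolerance: max per-endpoint disagreement within a cluster (bp).
    min_split_reads: junction reads required to call a circle.
    min_circle_len: shortest callable circle (bp).
    max_circle_len: longest circle the clip re-mapping search anticipates;
        the search window extends 2 kb beyond it.
    """

    min_clip_len: int = 20
    min_mapq: int = 20
    boundary_tolerance: int = 5
    min_split_reads: int = 2
    min_circle_len: int = 100
    max_circle_len: int = 10_000
    max_mismatches: int = 1

    @property
    def search_window(self) -> int:
        return self.max_circle_len + 2_000


def gc_of_interval(genome, chrom: str, start: int, end: int) -> float:
    """GC fraction of a genomic interval, ignoring ambiguous bases.

    Raises an error naming the interval if it lies outside the chromosome.
    """
    seq = genome.fetch(chrom, start, end)  # genome raises on out-of-bounds
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    return gc / denom if denom else float("nan")


def _find_clip_matches(window: str, clip: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (offset, n_mismatch) placements of ``clip`` in ``window``.

    Exact matches come from substring search; single-mismatch placements are
    recovered by the pigeonhole principle (one half of the clip must match
    exactly) and verified by direct comparison.
    """
    hits: dict[int, int] = {}
    i = window.find(clip)
    while i != -1:
        hits[i] = 0
        i = window.find(clip, i + 1)
    if max_mismatches >= 1:
        k = len(clip)
        h = k // 2
        carr = np.frombuffer(clip.encode(), dtype=np.uint8)
        warr = np.frombuffer(window.encode(), dtype=np.uint8)
        for half, delta in ((clip[:h], 0), (clip[h:], h)):
            j = window.find(half)
            while j != -1:
                off = j - delta
                if 0 <= off <= len(window) - k and off not in hits:
                    mm = int((warr[off : off + k] != carr).sum())
                    if mm <= max_mismatches:
                        hits[off] = mm
                j = window.find(half, j + 1)
    return sorted(hits.items())


def extract_junction_candidates(
    segments: Iterable[AlignedSegment],
    genome,
    params: CallerParams | None = None,
    counters: dict | None = None,
) -> list[JunctionEvidence]:
    """Scan alignments for soft-clip junction evidence.

    For a right clip the matched segment ends at a candidate circle end and
    the clipped bases are searched upstream (they belong at the circle
    start); for a left clip the segment starts at a candidate circle start
    and the clip is searched downstream. Among valid placements the one
    with fewest mismatches — ties broken toward the boundary closest to the
    anchor, i.e. the shortest circle — wins. Clips shorter than
    ``min_clip_len`` or reads below ``min_mapq`` are skipped; unmappable
    clips increment the ``unmapped_clip`` counter.
    """
    params = params or CallerParams()
    counters = counters if counters is not None else {}
    counters.setdefault("unmapped_clip", 0)
    counters.setdefault("segments", 0)
    evidence: list[JunctionEvidence] = []
    lengths = genome.lengths
    for seg in segments:
        counters["segments"] += 1
        if seg.mapq < params.min_mapq:
            continue
        clen = lengths.get(seg.chrom)
        if clen is None:
            continue
        # right terminal clip: clip maps at the circle start, upstream
        if seg.right_clip >= params.min_clip_len:
            clip = seg.seq[len(seg.seq) - seg.right_clip :]
            e0 = seg.reference_end
            lo = max(0, e0 - params.search_window)
            hi = e0  # clip must land strictly before the circle end
            ev = None
            if hi - lo >= len(clip):
                window = genome.fetch(seg.chrom, lo, hi)
                best = None
                for off, mm in _find_clip_matches(window, clip, params.max_mismatches):
                    p = lo + off
                    if p + len(clip) <= e0 and p < e0:
                        cand = (mm, -(p), p)  # fewer mismatches, then closest to anchor
                        if best is None or cand < best:
                            best = cand
                if best is not None:
                    ev = JunctionEvidence(seg.chrom, best[2], e0, seg.read_id, "right")
            if ev is not None:
                evidence.append(ev)
            else:
                counters["unmapped_clip"] += 1
        # left terminal clip: clip maps ending at the circle end, downstream
        if seg.left_clip >= params.min_clip_len:
            clip = seg.seq[: seg.left_clip]
            s0 = seg.pos
            lo = s0
            hi = min(clen, s0 + params.search_window + len(clip))
            ev = None
            if hi - lo >= len(clip):
                window = genome.fetch(seg.chrom, lo, hi)
                best = None
                for off, mm in _find_clip_matches(window, clip, params.max_mismatches):
                    q = lo + off + len(clip)  # exclusive circle end
                    if lo + off >= s0 and q > s0:
                        cand = (mm, q, q)
                        if best is None or cand < best:
                            best = cand
                if best is not None:
                    ev = JunctionEvidence(seg.chrom, s0, best[2], seg.read_id, "left")
            if ev is not None:
                evidence.append(ev)
            else:
                counters["unmapped_clip"] += 1
    return evidence


def _lower_median(values: list[int]) -> int:
    """Median with even-count ties resolved toward the smaller coordinate."""
    vs = sorted(values)
    return vs[(len(vs) - 1) // 2]


def cluster_and_call(
    evidence: list[JunctionEvidence],
    genome,
    params: CallerParams | None = None,
    sample_id: str = "",
) -> list[EccRecord]:
    """Cluster junction evidence into called circles.

    Evidence on the same chromosome joins a cluster when both endpoints lie
    within ``boundary_tolerance`` of the cluster's current consensus
    (per-endpoint lower median). Clusters with fewer than
    ``min_split_reads`` members, or a consensus shorter than
    ``min_circle_len``, are discarded. Output is sorted (chrom, start, end).
    """
    params = params or CallerParams()
    by_chrom: dict[str, list[JunctionEvidence]] = {}
    for ev in evidence:
        by_chrom.setdefault(ev.chrom, []).append(ev)

    records: list[EccRecord] = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.circle_start, e.circle_end))
        open_clusters: list[dict] = []
        closed: list[dict] = []
        for ev in evs:
            # clusters whose consensus start is far behind can never match again
            still_open = []
            for cl in open_clusters:
                if cl["med_start"] < ev.circle_start - params.boundary_tolerance:
                    closed.append(cl)
                else:
                    still_open.append(cl)
            open_clusters = still_open
            placed = False
            for cl in open_clusters:
                if (
                    abs(ev.circle_start - cl["med_start"]) <= params.boundary_tolerance
                    and abs(ev.circle_end - cl["med_end"]) <= params.boundary_tolerance
                ):
                    cl["starts"].append(ev.circle_start)
                    cl["ends"].append(ev.circle_end)
                    cl["med_start"] = _lower_median(cl["starts"])
                    cl["med_end"] = _lower_median(cl["ends"])
                    placed = True
                    break
            if not placed:
                open_clusters.append(
                    {
                        "starts": [ev.circle_start],
                        "ends": [ev.circle_end],
                        "med_start": ev.circle_start,
                        "med_end": ev.circle_end,
                    }
                )
        closed.extend(open_clusters)
        for cl in closed:
            n = len(cl["starts"])
            start, end = cl["med_start"], cl["med_end"]
            if n < params.min_split_reads or end - start < params.min_circle_len:
                continue
            gc = gc_of_interval(genome, chrom, start, end)
            records.append(EccRecord(chrom, start, end, n, gc, sample_id))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def call_sample(
    alignments: str | Path | Iterable[AlignedSegment],
    genome,
    params: CallerParams | None = None,
    sample_id: str = "",
) -> list[EccRecord]:
    """End-to-end calling for one sample: SAM/BAM path or segment iterable."""
    params = params or CallerParams()
    if isinstance(alignments, (str, Path)):
        from eccv.io import read_alignments

        alignments = read_alignments(alignments)
    counters: dict = {}
    evidence = extract_junction_candidates(alignments, genome, params, counters)
    if counters.get("unmapped_clip"):
        logger.info(
            "%s: %d clips could not be re-mapped (of %d segments)",
            sample_id or "sample",
            counters["unmapped_clip"],
            counters["segments"],
        )
    return cluster_and_call(evidence, genome, params, sample_id)
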