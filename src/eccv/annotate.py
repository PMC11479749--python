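"""Functional annotation of circles against genomic interval tracks.

Circles are intersected with three track classes — gene bodies,
transposable elements, and candidate cis-regulatory elements (cCREs) — and
a circle overlapping any single gene by more than 75 bp is flagged as an
"eccGene". Circles are unstranded, so strand is ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from eccv.caller import EccRecord

logger = logging.getLogger(__name__)

TRACK_CLASSES = ("gene", "transposable_element", "cCRE")
ECC_GENE_MIN_OVERLAP = 75  # strict: a hit must exceed this many bp


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    name: str
    subclass: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """Named intervals of one class (gene / transposable_element / cCRE)."""

    track_class: str
    features: list[Feature]

    def __post_init__(self):
        for f in self.features:
            if not (0 <= f.start < f.end):
                raise ValueError(f"invalid interval {f.chrom}:{f.start}-{f.end}")
            if not f.name:
                raise ValueError("feature names must be non-empty")

    @classmethod
    def from_bed(cls, path: str | Path, track_class: str) -> "AnnotationTrack":
        """Load BED4/BED6; column 4 is the name, column 5 the subclass."""
        feats = []
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                feats.append(
                    Feature(f[0], int(f[1]), int(f[2]), f[3],
                            f[4] if len(f) > 4 else "")
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: malformed BED record") from exc
        return cls(track_class, feats)

    @classmethod
    def from_gff3(cls, path: str | Path, feature_type: str = "gene") -> "AnnotationTrack":
        """Collapse a GFF3 to gene-body intervals (1-based inclusive on disk)."""
        feats = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "")
            feats.append(Feature(f[0], int(f[3]) - 1, int(f[4]), name, f[2]))
        return cls("gene", feats)


@dataclass(frozen=True)
class Hit:
    name: str
    subclass: str
    overlap_bp: int
    fraction_of_feature: float


@dataclass
class EccAnnotation:
    """Per-circle overlap hits by track class plus the eccGene flag."""

    key: tuple[str, int, int]
    hits: dict[str, list[Hit]] = field(default_factory=dict)
    is_ecc_gene: bool = False
    ecc_gene_names: list[str] = field(default_factory=list)


def _build_index(track: AnnotationTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in track.features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def overlap_annotate(
    records: Sequence[EccRecord],
    tracks: Iterable[AnnotationTrack],
    known_chroms: set[str] | None = None,
) -> list[EccAnnotation]:
    """Intersect circles with each track; half-open intervals, strand ignored.

    ``overlap_bp`` is the length of the intersection (abutting intervals do
    not overlap). Track features on chromosomes absent from
    ``known_chroms`` are skipped with a warning. Hits are sorted by
    descending overlap, then name, so output is deterministic regardless of
    track order.
    """
    anns = [EccAnnotation((r.chrom, r.start, r.end)) for r in records]
    for track in tracks:
        feats = track.features
        if known_chroms is not None:
            bad = {f.chrom for f in feats} - known_chroms
            if bad:
                logger.warning(
                    "track %s: skipping features on unknown chromosomes %s",
                    track.track_class, sorted(bad),
                )
                feats = [f for f in feats if f.chrom in known_chroms]
        trees = _build_index(AnnotationTrack(track.track_class, feats))
        for r, ann in zip(records, anns):
            hits = []
            for iv in trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end):
                f: Feature = iv.data
                ov = min(r.end, f.end) - max(r.start, f.start)
                if ov > 0:
                    hits.append(Hit(f.name, f.subclass, ov, ov / f.length))
            hits.sort(key=lambda h: (-h.overlap_bp, h.name, h.subclass))
            ann.hits.setdefault(track.track_class, []).extend(hits)
    for ann in anns:
        classify_ecc_gene(ann)
    return anns


def classify_ecc_gene(ann: EccAnnotation,
                      min_overlap: int = ECC_GENE_MIN_OVERLAP) -> EccAnnotation:
    """Flag eccGenes: any gene hit with overlap strictly above ``min_overlap`` bp."""
    gene_hits = ann.hits.get("gene", [])
    names = sorted({h.name for h in gene_hits if h.overlap_bp > min_overlap})
    ann.is_ecc_gene = bool(names)
    ann.ecc_gene_names = names
    return ann


def annotation_table(anns: Sequence[EccAnnotation]):
    import pandas as pd

    rows = []
    for ann in anns:
        chrom, start, end = ann.key
        row = {"chrom": chrom, "start": start, "end": end,
               "is_eccGene": ann.is_ecc_gene,
               "eccGene_names": ",".join(ann.ecc_gene_names)}
        for cls in TRACK_CLASSES:
            hits = ann.hits.get(cls, [])
            row[f"{cls}_hits"] = ";".join(
                f"{h.name}|{h.subclass}|{h.overlap_bp}" for h in hits
            )
        rows.append(row)
    return pd.DataFrame(rows)
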