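"""File formats: SAM alignments, FASTQ reads, BED circle catalogs, manifests.

All genomic coordinates on disk follow BED conventions (0-based half-open).
Region strings like ``chr10:78950400-78950928`` are parsed as 1-based
inclusive, the convention of genome browsers, and converted internally.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from eccv.caller import AlignedSegment, EccRecord


class ParseError(ValueError):
    pass


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive region string into 0-based half-open coords."""
    try:
        chrom, span = region.replace(",", "").split(":")
        lo, hi = span.replace("‐", "-").replace("‑", "-").split("-")
        start, end = int(lo) - 1, int(hi)
    except ValueError as exc:
        raise ParseError(f"cannot parse region {region!r}") from exc
    if not 0 <= start < end:
        raise ParseError(f"invalid region {region!r}")
    return chrom, start, end


def write_fastq(segments: Iterable[AlignedSegment], path: str | Path,
                quality_char: str = "I") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"@{seg.read_id}\n{seg.seq}\n+\n{quality_char * len(seg.seq)}\n")
    return path


def _sam_header(genome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": genome.lengths[c]} for c in genome.chrom_names],
        }
    )


def write_sam(segments: Iterable[AlignedSegment], genome, path: str | Path) -> Path:
    """Write segments as a text SAM with SQ headers, MAPQ and soft-clip CIGARs."""
    path = Path(path)
    header = _sam_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            a = pysam.AlignedSegment(header)
            a.query_name = seg.read_id
            a.query_sequence = seg.seq
            a.flag = 0
            a.reference_id = header.references.index(seg.chrom)
            a.reference_start = seg.pos
            a.mapping_quality = seg.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in seg.cigar)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seg.seq))
            out.write(a)
    return path


_CIGAR_OPS = {0: "M", 4: "S", 7: "M", 8: "M"}


def read_alignments(path: str | Path) -> list[AlignedSegment]:
    """Read a SAM/BAM file into minimal match/soft-clip segments.

    Hard clips are ignored; deletions/insertions are not expected from the
    ideal-alignment simulator, and reads containing them are folded into
    match blocks on the reference (sufficient for junction detection on
    real data, where small indels do not move a clip boundary materially).
    """
    segments = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.query_sequence is None:
                continue
            cigar: list[tuple[str, int]] = []
            for op, n in read.cigartuples or []:
                sym = _CIGAR_OPS.get(op)
                if sym == "M" and cigar and cigar[-1][0] == "M":
                    cigar[-1] = ("M", cigar[-1][1] + n)
                elif sym is not None:
                    cigar.append((sym, n))
                elif op == 2:  # deletion consumes reference within the match
                    if cigar and cigar[-1][0] == "M":
                        cigar[-1] = ("M", cigar[-1][1] + n)
            if not any(op == "M" for op, _ in cigar):
                continue
            segments.append(
                AlignedSegment(
                    read.query_name,
                    read.reference_name,
                    read.reference_start,
                    cigar,
                    read.mapping_quality,
                    read.query_sequence,
                )
            )
    return segments


def write_truth_bed(truth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for c in truth:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample_id}\t{c.copies}\n")
    return path


def read_truth_bed(path: str | Path):
    from eccv.simulate import CircleTruth

    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        try:
            out.append(CircleTruth(f[0], int(f[1]), int(f[2]), f[3], int(f[4])))
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: malformed truth BED record") from exc
    return out


def write_ecc_bed(records: Iterable[EccRecord], path: str | Path) -> Path:
    """BED6+2: chrom, start, end, name=sample:idx, score=split_support,
    strand='.', then length and gc."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            name = f"{r.sample_id or 'ecc'}:{i}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.split_support}\t.\t"
                f"{r.length}\t{r.gc:.4f}\n"
            )
    return path


def read_ecc_bed(path: str | Path, sample_id: str = "") -> list[EccRecord]:
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            support = int(float(f[4])) if len(f) > 4 else 0
            gc = float(f[7]) if len(f) > 7 else float("nan")
            sid = sample_id or (f[3].rsplit(":", 1)[0] if len(f) > 3 else "")
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: malformed BED record") from exc
        records.append(EccRecord(chrom, start, end, support, gc, sid))
    return records


def read_cohort_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest TSV: sample_id, group, bed/sam path column(s), mapped_reads."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
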