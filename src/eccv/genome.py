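"""Reference genome handling: synthetic genome generation and FASTA access.

A genome here is anything with ``fetch(chrom, start, end) -> str`` and a
``lengths`` mapping; both the in-memory :class:`SyntheticGenome` and the
:class:`FastaGenome` wrapper over an indexed FASTA satisfy that contract,
so the caller and the statistics layer work identically on simulated and
real references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenomeError(ValueError):
    """Invalid genome configuration or out-of-bounds access."""


@dataclass
class SyntheticGenome:
    """An in-memory random genome with a controlled GC composition."""

    chrom_names: list[str]
    sequences: dict[str, str]
    base_gc: float
    _gc_cumsum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise GenomeError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]

    def gc_cumsum(self, chrom: str) -> np.ndarray:
        """Cumulative count of G/C bases; entry i = #GC in seq[:i]."""
        if chrom not in self._gc_cumsum:
            arr = np.frombuffer(self.sequences[chrom].encode(), dtype=np.uint8)
            is_gc = (arr == ord("G")) | (arr == ord("C"))
            cs = np.zeros(len(arr) + 1, dtype=np.int64)
            np.cumsum(is_gc, out=cs[1:])
            self._gc_cumsum[chrom] = cs
        return self._gc_cumsum[chrom]

    def write_fasta(self, path: str | Path, width: int = 80) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom in self.chrom_names:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path


class FastaGenome:
    """Adapter exposing the genome contract over an indexed FASTA file."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))
        self.chrom_names = list(self._fa.keys())

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self._fa[c]) for c in self.chrom_names}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        n = len(self._fa[chrom])
        if not (0 <= start < end <= n):
            raise GenomeError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {n}"
            )
        return str(self._fa[chrom][start:end]).upper()


def generate_genome(
    chrom_lengths: dict[str, int],
    base_gc: float = 0.41,
    seed: int | np.random.Generator = 0,
) -> SyntheticGenome:
    """Generate a random genome with i.i.d. bases at a target GC fraction.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp; every length must be positive.
    base_gc
        Target fraction of G+C bases, in [0, 1]. Each base is drawn
        independently, so for chromosomes of 100 kb or more the realized GC
        lands within ~0.005 of the target.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    if not 0.0 <= base_gc <= 1.0:
        raise GenomeError(f"base_gc must be in [0,1], got {base_gc}")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise GenomeError(f"chromosome {chrom!r} has non-positive length {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - base_gc) / 2, base_gc / 2, base_gc / 2, (1 - base_gc) / 2])
    sequences = {}
    for chrom, length in chrom_lengths.items():
        idx = rng.choice(4, size=length, p=p)
        sequences[chrom] = _BASES[idx].tobytes().decode()
    return SyntheticGenome(list(chrom_lengths), sequences, base_gc)
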