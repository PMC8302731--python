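"""Read-level preprocessing ahead of alignment.

Long single-end reads are split into non-overlapping 60-base fragments
from the 5' end (a terminal remainder is kept only when long enough to
remain alignable), and fragments whose arithmetic-mean Phred quality is
below 17 are eliminated.  The comparison is strict: a mean of exactly 17
is kept.  After alignment, reads overlapping a user-supplied interval
blacklist (rRNA/tRNA/snRNA/snoRNA/repeat annotations, or any BED) can be
removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from intervaltree import IntervalTree

__all__ = [
    "FastqRead",
    "ReadFragmentPolicy",
    "split_read",
    "filter_by_mean_phred",
    "read_fastq",
    "write_fastq",
    "prep_fastq",
    "load_blacklist",
    "blacklist_filter",
]


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str
    quality: str  # encoded quality string

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"record {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass(frozen=True)
class ReadFragmentPolicy:
    fragment_length: int = 60
    terminal_min_length: int = 25
    phred_min_mean: float = 17.0
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not self.fragment_length >= self.terminal_min_length >= 1:
            raise ValueError("need fragment_length >= terminal_min_length >= 1")
        if self.phred_min_mean < 0:
            raise ValueError("phred_min_mean must be >= 0")


def split_read(read: FastqRead, policy: ReadFragmentPolicy = ReadFragmentPolicy()) -> list[FastqRead]:
    """5'-anchored split into consecutive fragments of fixed length.

    The final sub-length remainder is emitted only if it is at least
    ``terminal_min_length`` nt; fragment ids suffix the parent id with an
    ordinal (``/1``, ``/2``, ...).
    """
    frags = []
    L = policy.fragment_length
    for ordinal, start in enumerate(range(0, len(read.sequence), L), start=1):
        seq = read.sequence[start : start + L]
        if len(seq) < L and len(seq) < policy.terminal_min_length:
            break
        frags.append(FastqRead(f"{read.id}/{ordinal}", seq, read.quality[start : start + L]))
    return frags


def mean_phred(read: FastqRead, offset: int = 33) -> float:
    scores = [ord(c) - offset for c in read.quality]
    if any(s < 0 or s > 93 for s in scores):
        raise ValueError(f"record {read.id}: quality not decodable at offset {offset}")
    return sum(scores) / len(scores) if scores else 0.0


def filter_by_mean_phred(
    reads: Iterable[FastqRead], policy: ReadFragmentPolicy = ReadFragmentPolicy()
) -> tuple[list[FastqRead], int]:
    """Keep reads with mean Phred >= threshold ("lower than" is strict)."""
    kept, dropped = [], 0
    for read in reads:
        if mean_phred(read, policy.phred_offset) < policy.phred_min_mean:
            dropped += 1
        else:
            kept.append(read)
    return kept, dropped


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRead(entry.name, entry.sequence, entry.quality)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def prep_fastq(
    in_path: str | Path,
    out_path: str | Path,
    policy: ReadFragmentPolicy = ReadFragmentPolicy(),
) -> dict[str, int]:
    """Fragment + quality-filter a FASTQ file; returns stage counters."""
    n_in = n_frag = 0
    kept: list[FastqRead] = []
    dropped = 0
    for read in read_fastq(in_path):
        n_in += 1
        frags = split_read(read, policy)
        n_frag += len(frags)
        good, bad = filter_by_mean_phred(frags, policy)
        kept.extend(good)
        dropped += bad
    write_fastq(kept, out_path)
    return {"reads_in": n_in, "fragments": n_frag, "dropped_low_q": dropped, "written": len(kept)}


# ---------------------------------------------------------------------------
# post-alignment interval blacklist
# ---------------------------------------------------------------------------

def load_blacklist(path: str | Path) -> dict[str, IntervalTree]:
    """BED (0-based half-open) -> per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            if end > start:
                trees.setdefault(fields[0], IntervalTree()).addi(start, end)
    return trees


def blacklist_filter(
    alignments: Iterable[pysam.AlignedSegment],
    regions: dict[str, IntervalTree],
) -> tuple[list[pysam.AlignedSegment], int]:
    """Drop alignments whose aligned span overlaps a region by >= 1 nt.

    Intervals are half-open, so an alignment abutting a region end has
    zero overlap and is kept.  Returns survivors (input order) and the
    number removed.
    """
    kept, removed = [], 0
    for aln in alignments:
        tree = regions.get(aln.reference_name) if not aln.is_unmapped else None
        if tree is not None and tree.overlap(aln.reference_start, aln.reference_end):
            removed += 1
        else:
            kept.append(aln)
    return kept, removed
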