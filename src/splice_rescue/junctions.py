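"""Splice-junction extraction and junction-read PSI quantification.

The percent-spliced-in (PSI) of an internal cassette exon *n* is computed
from junction reads alone:

    PSI(n) = J(n-1, n) / ( J(n-1, n) + J(n-1, n+1) )

where J(a, b) counts reads whose spliced alignment joins the end of exon
*a* to the start of exon *b*.  Only the upstream-anchored junctions enter
the ratio (inclusion = (n-1, n), skipping = (n-1, n+1)); a symmetric mode
that averages in the downstream inclusion junction (n, n+1) is available
behind a flag for general use.  Coverage is expressed in reads per
million junction reads (rpm): (J_incl + J_skip) * 1e6 / total junction
reads in the sample.

Junctions are keyed by ``(chrom, donor_end, acceptor_start, strand)``
with 0-based half-open coordinates, i.e. the skipped interval of the
CIGAR N operation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pysam

__all__ = [
    "JunctionKey",
    "JunctionCounts",
    "Exon",
    "GeneModel",
    "ExonPsiRecord",
    "extract_junctions",
    "compute_psi",
    "coverage_rpm",
    "read_gene_models_gtf",
    "write_gene_models_gtf",
]

#: (chrom, donor exon end, acceptor exon start, strand); coordinates
#: 0-based half-open, strand carried but not used for matching
JunctionKey = tuple[str, int, int, str]

_REF_CONSUMING_MATCH = {0, 7, 8}  # M, =, X


@dataclass
class JunctionCounts:
    """Per-sample junction read counts."""

    sample: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            _, donor_end, acceptor_start, _ = key
            if donor_end >= acceptor_start:
                raise ValueError(f"junction {key}: donor end must precede acceptor start")
            if n < 0:
                raise ValueError(f"junction {key}: negative count")

    @property
    def total_junction_reads(self) -> int:
        return sum(self.counts.values())

    def get(self, chrom: str, donor_end: int, acceptor_start: int) -> int:
        """Count for a junction, summed over strand annotations."""
        return sum(
            n
            for (c, d, a, _), n in self.counts.items()
            if (c, d, a) == (chrom, donor_end, acceptor_start)
        )


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered exons of one representative transcript.

    Exons are listed 5'->3' in transcript orientation; for minus-strand
    genes that means decreasing genomic coordinates.  Only internal exons
    (with both neighbours) receive a PSI.
    """

    gene_id: str
    strand: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        coords = [(e.start, e.end) for e in self.exons]
        genomic = sorted(coords)
        if self.strand == "+" and coords != genomic:
            raise ValueError(f"{self.gene_id}: + strand exons not sorted 5'->3'")
        if self.strand == "-" and coords != genomic[::-1]:
            raise ValueError(f"{self.gene_id}: - strand exons not sorted 5'->3'")
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def internal_exon_ordinals(self) -> list[int]:
        """1-based ordinals (transcript order) of internal exons."""
        return list(range(2, len(self.exons)))

    def junction_key(self, ordinal_a: int, ordinal_b: int) -> tuple[str, int, int]:
        """Genomic (chrom, donor_end, acceptor_start) joining two exons."""
        ea = self.exons[ordinal_a - 1]
        eb = self.exons[ordinal_b - 1]
        left, right = (ea, eb) if ea.start <= eb.start else (eb, ea)
        return (self.chrom, left.end, right.start)


@dataclass
class ExonPsiRecord:
    """PSI of one internal exon computed from upstream-anchored junctions."""

    gene_id: str
    exon_ordinal: int
    j_incl: int
    j_skip: int
    psi: float | None
    coverage_rpm: float

    @property
    def defined(self) -> bool:
        return self.psi is not None


def extract_junctions(
    alignments: str | Path | pysam.AlignmentFile,
    sample: str | None = None,
    min_anchor: int = 8,
) -> tuple[JunctionCounts, int]:
    """Tally junction observations from spliced alignments.

    Every N operation of a primary, non-duplicate, mapped alignment
    contributes one observation of the skipped interval, provided the
    aligned (M/=/X) anchors immediately flanking the gap are both
    >= ``min_anchor``.  Returns the counts and the number of N operations
    rejected by the anchor rule.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        path = str(alignments)
        mode = "rb" if path.endswith(".bam") else "r"
        alignments = pysam.AlignmentFile(path, mode)
        close = True
        if sample is None:
            sample = Path(path).stem
    counter: Counter[JunctionKey] = Counter()
    rejected = 0
    try:
        for aln in alignments.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            cigar = aln.cigartuples
            if cigar is None:
                raise ValueError(f"alignment {aln.query_name} has no CIGAR")
            strand = "-" if aln.is_reverse else "+"
            ref_pos = aln.reference_start
            # anchor = matched bases between consecutive N gaps
            anchors: list[int] = [0]
            gaps: list[tuple[int, int]] = []  # (donor_end, acceptor_start)
            for op, length in cigar:
                if op in _REF_CONSUMING_MATCH:
                    anchors[-1] += length
                    ref_pos += length
                elif op == 3:  # N
                    gaps.append((ref_pos, ref_pos + length))
                    anchors.append(0)
                    ref_pos += length
                elif op == 2:  # D consumes reference but is not an anchor match
                    ref_pos += length
            for i, (donor_end, acceptor_start) in enumerate(gaps):
                if anchors[i] >= min_anchor and anchors[i + 1] >= min_anchor:
                    counter[(aln.reference_name, donor_end, acceptor_start, strand)] += 1
                else:
                    rejected += 1
    finally:
        if close:
            alignments.close()
    return JunctionCounts(sample or "sample", dict(counter)), rejected


def compute_psi(
    counts: JunctionCounts,
    models: list[GeneModel],
    symmetric: bool = False,
) -> tuple[list[ExonPsiRecord], int]:
    """Per-internal-exon PSI from junction counts.

    Returns the PSI records and a diagnostics counter: the number of
    junction reads in ``counts`` that match no model boundary (they stay
    in ``counts`` but are ignored here).  With ``symmetric=True`` the
    inclusion evidence averages the upstream (n-1, n) and downstream
    (n, n+1) junctions instead of using the upstream one alone.
    """
    total = counts.total_junction_reads
    records: list[ExonPsiRecord] = []
    used: Counter[tuple[str, int, int]] = Counter()
    for model in models:
        for n in model.internal_exon_ordinals():
            incl_key = model.junction_key(n - 1, n)
            skip_key = model.junction_key(n - 1, n + 1)
            j_incl = counts.get(*incl_key)
            j_skip = counts.get(*skip_key)
            used[incl_key] += j_incl
            used[skip_key] += j_skip
            if symmetric:
                down_key = model.junction_key(n, n + 1)
                j_down = counts.get(*down_key)
                used[down_key] += j_down
                j_incl = (j_incl + j_down) / 2
            denom = j_incl + j_skip
            psi = (j_incl / denom) if denom > 0 else None
            rpm = (j_incl + j_skip) * 1e6 / total if total > 0 else 0.0
            records.append(
                ExonPsiRecord(model.gene_id, n, int(round(j_incl)), j_skip, psi, rpm)
            )
    matched_keys = set(used)
    unmatched_reads = sum(
        n for (c, d, a, _), n in counts.counts.items() if (c, d, a) not in matched_keys
    )
    return records, unmatched_reads


def coverage_rpm(record: ExonPsiRecord, counts: JunctionCounts) -> float:
    """(J_incl + J_skip) per million total junction reads of the sample."""
    total = counts.total_junction_reads
    if total <= 0:
        raise ValueError("total junction reads must be positive")
    return (record.j_incl + record.j_skip) * 1e6 / total


# ---------------------------------------------------------------------------
# GTF I/O (1-based closed on disk, 0-based half-open in memory)
# ---------------------------------------------------------------------------

def write_gene_models_gtf(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for i, ex in enumerate(m.exons, start=1):
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{ex.chrom}\tsplice_rescue\texon\t{ex.start + 1}\t{ex.end}\t."
                    f"\t{m.strand}\t.\t{attrs}\n"
                )


def read_gene_models_gtf(
    path: str | Path, transcript_ids: set[str] | None = None
) -> list[GeneModel]:
    """Read exon features of user-designated representative transcripts.

    ``transcript_ids`` restricts to the given transcripts; with ``None``
    every transcript in the file is taken as representative (one model
    per transcript).
    """
    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            if fields[2] != "exon":
                continue
            attrs = dict(
                (kv.split(" ", 1)[0], kv.split(" ", 1)[1].strip('"'))
                for kv in (s.strip() for s in fields[8].split(";"))
                if " " in kv
            )
            tx = attrs.get("transcript_id", attrs.get("gene_id", f"tx{lineno}"))
            if transcript_ids is not None and tx not in transcript_ids:
                continue
            rec = by_tx.setdefault(
                tx,
                {"gene": attrs.get("gene_id", tx), "strand": fields[6], "exons": []},
            )
            rec["exons"].append(Exon(fields[0], int(fields[3]) - 1, int(fields[4])))
    models = []
    for tx, rec in by_tx.items():
        exons = sorted(rec["exons"], key=lambda e: e.start, reverse=rec["strand"] == "-")
        models.append(GeneModel(rec["gene"], rec["strand"], exons))
    return models
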