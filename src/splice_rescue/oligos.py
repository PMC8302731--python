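"""Sequence fixtures around the IKBKAP exon 20 donor site.

Familial dysautonomia (FD) is caused by the intronic IVS20+6 T>C point
mutation of *IKBKAP* (*ELP1*), which weakens U1 snRNP recognition of the
exon 20 5' splice site and induces exon skipping.  The experimental
literature characterises this locus with a small set of 25-nt RNA
oligonucleotides covering the donor site and the first ~75 nt of intron 20
(wild-type and mutant donor, three candidate SRSF6 enhancer sites and a
mutated site-b).  This module packages those oligos as typed records and
reassembles the contiguous genomic context from them by exact
suffix--prefix overlap, so that downstream element scans operate on a
single coordinate frame anchored at the exon/intron boundary.

Sequences are stored RNA-side (ACGU); 5'-biotin and 3'-dTdT handles used
for pull-down chemistry are not part of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "OligoRole",
    "OligoRecord",
    "AssembledRegion",
    "load_paper_oligos",
    "get_oligo",
    "assemble_tiled_region",
    "assemble_donor_region",
    "AssemblyError",
]

RNA_ALPHABET = frozenset("ACGU")

#: first five intronic nucleotides of the canonical donor site used to
#: locate the exon/intron boundary inside an assembly
INTRON_START_MOTIF = "GUAAG"


class OligoRole(str, Enum):
    donor_wt = "donor_wt"
    donor_fd = "donor_fd"
    site_a = "site_a"
    site_b = "site_b"
    site_c = "site_c"
    site_b_mt = "site_b_mt"


@dataclass(frozen=True)
class OligoRecord:
    """A pull-down RNA oligo: identifier, RNA sequence and functional role."""

    id: str
    sequence: str
    role: OligoRole

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"oligo {self.id}: non-RNA characters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# Registry of the six published 25-mers.  The donor pair differs only at
# intron position +6 (U in the reference, C in the FD mutant); the three
# "site" oligos tile intron 20, and site_b_mt carries four substitutions
# that disrupt the SRSF6 motif at +45..+50.
_OLIGOS: tuple[OligoRecord, ...] = (
    OligoRecord("oAM153", "UUGGACAAGUAAGUGCCAUUGUACU", OligoRole.donor_wt),
    OligoRecord("oAM154", "UUGGACAAGUAAGCGCCAUUGUACU", OligoRole.donor_fd),
    OligoRecord("oAM155", "UUGUACUGUUUGCGACUAGUUAGCU", OligoRole.site_a),
    OligoRecord("oAM156", "GUUAGCUUGUGAUUUAUGUGUGAAG", OligoRole.site_b),
    OligoRecord("oAM209", "AAGACAAUAAGUAUUUUAUUACAAU", OligoRole.site_c),
    OligoRecord("oAM167", "GUUAGCUUGUGAUUUAUAUACAAAG", OligoRole.site_b_mt),
)


def load_paper_oligos() -> list[OligoRecord]:
    """Return the six published IKBKAP oligo records (all 25 nt)."""
    return list(_OLIGOS)


def get_oligo(oligo_id: str) -> OligoRecord:
    for rec in _OLIGOS:
        if rec.id == oligo_id:
            return rec
    raise KeyError(f"unknown oligo id {oligo_id!r}")


class AssemblyError(ValueError):
    """Raised when tiles cannot be merged by unique exact overlaps."""


@dataclass
class AssembledRegion:
    """A contiguous RNA region reassembled from overlapping tiles.

    ``boundary_offset`` is the number of exonic nucleotides at the 5' end,
    i.e. ``sequence[boundary_offset]`` is intron position +1 (the G of the
    GUAAG donor motif).  It is ``None`` when the assembly contains no
    recognisable exon/intron boundary.
    """

    sequence: str
    boundary_offset: int | None
    tile_layout: list[tuple[str, int]] = field(default_factory=list)
    provenance: list[int] = field(default_factory=list)  # overlap lengths

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate helpers -------------------------------------------------
    def index_of(self, position: int) -> int:
        """0-based string index of a splice-site-relative position.

        Intronic positions are positive (+1 = first intronic base), exonic
        positions negative (-1 = last exonic base); there is no position 0.
        """
        if self.boundary_offset is None:
            raise ValueError("assembly has no exon/intron boundary")
        if position == 0:
            raise ValueError("splice-site-relative coordinates have no position 0")
        if position > 0:
            idx = self.boundary_offset + position - 1
        else:
            idx = self.boundary_offset + position
        if not 0 <= idx < len(self.sequence):
            raise IndexError(f"position {position:+d} outside assembled region")
        return idx

    def position_of(self, index: int) -> int:
        """Inverse of :meth:`index_of`."""
        if self.boundary_offset is None:
            raise ValueError("assembly has no exon/intron boundary")
        if not 0 <= index < len(self.sequence):
            raise IndexError(index)
        off = index - self.boundary_offset
        return off + 1 if off >= 0 else off

    def intron_slice(self, start: int, end: int) -> str:
        """Sequence between intron positions ``start``..``end`` inclusive."""
        return self.sequence[self.index_of(start) : self.index_of(end) + 1]


def _admissible_overlaps(left: str, right: str, min_overlap: int) -> list[int]:
    upper = min(len(left), len(right))
    return [
        k
        for k in range(min_overlap, upper + 1)
        if left[-k:] == right[:k]
    ]


def assemble_tiled_region(
    tiles: list[OligoRecord],
    min_overlap: int = 3,
    boundary_offset: int | None = None,
) -> AssembledRegion:
    """Merge ordered tiles on their exact suffix--prefix overlaps.

    Consecutive tiles must share exactly one admissible overlap of length
    >= ``min_overlap``; several admissible overlap lengths make the layout
    ambiguous and raise :class:`AssemblyError` instead of guessing.  The
    exon/intron boundary is located by the unique occurrence of the GUAAG
    donor motif unless ``boundary_offset`` is given explicitly.
    """
    if not tiles:
        raise AssemblyError("no tiles to assemble")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    sequence = tiles[0].sequence
    layout: list[tuple[str, int]] = [(tiles[0].id, 0)]
    overlaps: list[int] = []
    for prev, cur in zip(tiles, tiles[1:]):
        ks = _admissible_overlaps(sequence, cur.sequence, min_overlap)
        if not ks:
            raise AssemblyError(
                f"no exact overlap of length >= {min_overlap} between "
                f"{prev.id} and {cur.id}"
            )
        if len(ks) > 1:
            raise AssemblyError(
                f"ambiguous overlap between {prev.id} and {cur.id} "
                f"(admissible lengths {ks}); provide an explicit layout"
            )
        k = ks[0]
        layout.append((cur.id, len(sequence) - k))
        overlaps.append(k)
        sequence += cur.sequence[k:]

    if boundary_offset is None:
        hits = [
            i
            for i in range(len(sequence) - len(INTRON_START_MOTIF) + 1)
            if sequence.startswith(INTRON_START_MOTIF, i)
        ]
        boundary_offset = hits[0] if len(hits) == 1 else None

    region = AssembledRegion(sequence, boundary_offset, layout, overlaps)
    for tile, (_, off) in zip(tiles, layout):  # invariant: exact substrings
        assert sequence[off : off + len(tile)] == tile.sequence
    return region


def write_region_fasta(
    region: AssembledRegion,
    path,
    name: str = "region",
    as_dna: bool = True,
) -> None:
    """Write an assembled region as FASTA.

    Genomic fixtures are emitted DNA-side (U->T) by default since
    alignment formats are DNA-space; pass ``as_dna=False`` to keep RNA.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq = region.sequence.replace("U", "T") if as_dna else region.sequence
    desc = (
        f"boundary_offset={region.boundary_offset}"
        if region.boundary_offset is not None
        else ""
    )
    SeqIO.write([SeqRecord(Seq(seq), id=name, description=desc)], str(path), "fasta")


def assemble_donor_region(variant: str = "fd", min_overlap: int = 3) -> AssembledRegion:
    """Assemble the exon-20/intron-20 context from the published oligos.

    ``variant`` selects the donor tile: ``"fd"`` (IVS20+6 T>C) or ``"wt"``.
    The result is an 83-nt region with 8 exonic nt followed by intron
    positions +1..+75.
    """
    donor = get_oligo("oAM154" if variant == "fd" else "oAM153")
    tiles = [donor, get_oligo("oAM155"), get_oligo("oAM156"), get_oligo("oAM209")]
    return assemble_tiled_region(tiles, min_overlap=min_overlap)
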