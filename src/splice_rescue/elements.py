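"""Donor-site/U1 complementarity and SR-protein enhancer-motif scanning.

Two sequence-level analyses of a 5' splice site and its intronic
neighbourhood:

* **U1 register** -- the nine donor nucleotides at positions -3..+6 are
  base-paired, antiparallel, against the 5'-terminal single-stranded end
  of U1 snRNA.  Positions that cannot form a Watson-Crick pair (or, by
  default, a G:U wobble) are reported as mismatches.  For the IKBKAP
  exon 20 donor this reproduces the classical picture: the reference
  site pairs at all positions except -1, and the familial-dysautonomia
  IVS20+6 T>C substitution adds a second mismatch at +6.

* **SELEX PWM scanning** -- candidate splicing-enhancer motifs for SR
  proteins are located by sliding a SELEX-derived position weight matrix
  (the ESEfinder score matrices) over a window around the splice site and
  reporting L-mers whose additive score reaches the factor-specific
  threshold.  Coordinates are splice-site-relative: intron +1 is the
  first intronic base, exonic positions are negative, there is no 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .oligos import AssembledRegion

__all__ = [
    "DonorContext",
    "U1Register",
    "MismatchReport",
    "PwmModel",
    "MotifHit",
    "VariantComparison",
    "donor_context",
    "u1_mismatches",
    "load_pwm",
    "available_factors",
    "scan_pwm",
    "compare_variant_motifs",
]

DONOR_POSITIONS = (-3, -2, -1, 1, 2, 3, 4, 5, 6)

#: 5' end of human U1 snRNA (nucleotides 1-11).  Nucleotides 3-11 pair
#: with the donor positions +6..-3 in antiparallel register.
U1_5PRIME_TEMPLATE = "AUACUUACCUG"

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class DonorContext:
    """The nine donor nucleotides at -3..+6 (-1 last exonic, +1 first intronic)."""

    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        seq = _normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 9:
            raise ValueError(f"donor context must be 9 nt, got {len(seq)}")
        if set(seq) - set("ACGU"):
            raise ValueError(f"donor context has non-ACGU characters: {seq}")

    def base_at(self, position: int) -> str:
        return self.sequence[DONOR_POSITIONS.index(position)]


@dataclass(frozen=True)
class U1Register:
    """Pairing register of the donor -3..+6 window against the U1 5' end.

    ``template`` is the U1 snRNA 5' end written 5'->3'; donor position +6
    pairs template nucleotide 3, and each step towards the exon advances
    one template nucleotide (antiparallel duplex), so -3 pairs nt 11.
    """

    template: str = U1_5PRIME_TEMPLATE
    wobble_policy: str = "wc_plus_gu"  # or "wc_only"

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", _normalize_rna(self.template))
        if len(self.template) < 11:
            raise ValueError("U1 template must cover nucleotides 1-11")
        if self.wobble_policy not in ("wc_only", "wc_plus_gu"):
            raise ValueError(f"unknown wobble policy {self.wobble_policy!r}")

    def template_partner(self, position: int) -> str:
        """U1 nucleotide paired with a donor position (1-based nt 3..11)."""
        nt_index = 3 + (6 - position) if position > 0 else 8 - position
        return self.template[nt_index - 1]

    def is_paired(self, donor_base: str, position: int) -> bool:
        pair = (donor_base, self.template_partner(position))
        if pair in _WATSON_CRICK:
            return True
        return self.wobble_policy == "wc_plus_gu" and pair in _WOBBLE


@dataclass(frozen=True)
class MismatchReport:
    mismatch_positions: frozenset[int]
    paired_positions: frozenset[int]

    @property
    def n_paired(self) -> int:
        return len(self.paired_positions)


def donor_context(
    region: AssembledRegion,
    variant: tuple[int, str] | None = None,
    source: str = "",
) -> DonorContext:
    """Extract the -3..+6 donor window from an assembled region.

    ``variant`` optionally applies one substitution given as
    ``(intron_position, base)`` before extraction, e.g. ``(6, "C")`` turns
    the reference context into the IVS20+6 T>C mutant.
    """
    start = region.index_of(-3)
    end = region.index_of(6)
    if end + 1 > len(region.sequence):
        raise IndexError("donor window extends past sequence end")
    seq = list(region.sequence[start : end + 1])
    if variant is not None:
        pos, base = variant
        seq[DONOR_POSITIONS.index(pos)] = _normalize_rna(base)
    return DonorContext("".join(seq), source=source)


def u1_mismatches(context: DonorContext, register: U1Register | None = None) -> MismatchReport:
    """Call paired/mismatched donor positions under the U1 register."""
    register = register or U1Register()
    paired = frozenset(
        p for p in DONOR_POSITIONS if register.is_paired(context.base_at(p), p)
    )
    return MismatchReport(frozenset(DONOR_POSITIONS) - paired, paired)


# ---------------------------------------------------------------------------
# SELEX position-weight-matrix scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class PwmModel:
    """A SELEX score matrix with its hit threshold.

    ``matrix`` has shape (L, 4) with columns A, C, G, U; a candidate
    L-mer's score is the sum of its per-position entries and counts as a
    hit when score >= threshold (threshold equality is a hit).
    """

    factor: str
    matrix: np.ndarray
    threshold: float
    provenance: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if not np.isfinite(m).all() or not np.isfinite(self.threshold):
            raise ValueError("PWM entries and threshold must be finite")
        if not self.provenance:
            raise ValueError("PWM provenance must be non-empty")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def score(self, lmer: str) -> float:
        lmer = _normalize_rna(lmer)
        if len(lmer) != self.length:
            raise ValueError(f"expected {self.length}-mer, got {len(lmer)}-mer")
        return float(
            sum(self.matrix[i, _BASE_INDEX[b]] for i, b in enumerate(lmer))
        )


@dataclass(frozen=True)
class MotifHit:
    """An above-threshold PWM match in splice-site-relative coordinates."""

    start: int  # relative coordinate of the first nucleotide of the L-mer
    sequence: str
    score: float
    above_threshold: bool = True


@dataclass
class VariantComparison:
    substituted_positions: list[int]  # relative coordinates
    ref_hits: list[MotifHit]
    alt_scores: dict[int, float] = field(default_factory=dict)
    lost_hits: list[MotifHit] = field(default_factory=list)


def _matrix_dir() -> Path:
    return Path(str(resources.files("splice_rescue").joinpath("data/matrices")))


def available_factors() -> list[str]:
    return sorted(p.stem for p in _matrix_dir().glob("*.tsv"))


def load_pwm(factor: str) -> PwmModel:
    """Load a bundled SELEX matrix (e.g. ``"SRSF6"``) with its threshold."""
    path = _matrix_dir() / f"{factor}.tsv"
    if not path.exists():
        raise KeyError(
            f"no bundled matrix for {factor!r}; available: {available_factors()}"
        )
    threshold = None
    provenance = []
    rows = []
    header_seen = False
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            provenance.append(body)
            if body.startswith("threshold:"):
                threshold = float(body.split(":", 1)[1])
            continue
        if not line.strip():
            continue
        if not header_seen:  # column header
            header_seen = True
            continue
        fields = line.split("\t")
        rows.append([float(x) for x in fields[1:5]])
    if threshold is None:
        raise ValueError(f"matrix file {path} lacks a threshold line")
    return PwmModel(factor, np.array(rows), threshold, "; ".join(provenance))


def _relative_to_index(region: AssembledRegion, position: int) -> int:
    # like AssembledRegion.index_of but allowing out-of-sequence values
    if region.boundary_offset is None:
        raise ValueError("region has no exon/intron boundary")
    if position == 0:
        raise ValueError("no position 0 in splice-site-relative coordinates")
    return region.boundary_offset + (position - 1 if position > 0 else position)


def scan_pwm(
    region: AssembledRegion,
    pwm: PwmModel,
    window: tuple[int, int] = (-100, 100),
    include_subthreshold: bool = False,
) -> list[MotifHit]:
    """Score every L-mer start inside ``window`` and return hits.

    ``window`` bounds the *start* positions of candidate L-mers in
    splice-site-relative coordinates; L-mers must lie fully inside the
    covered sequence.  Hits (score >= threshold) are returned sorted by
    start; with ``include_subthreshold`` every scored position is
    returned, which the brute-force oracle tests rely on.
    """
    lo, hi = window
    if lo == 0 or hi == 0:
        raise ValueError("window bounds use splice-site-relative coordinates (no 0)")
    starts = [p for p in range(lo, hi + 1) if p != 0]
    hits: list[MotifHit] = []
    any_covered = False
    for p in starts:
        idx = _relative_to_index(region, p)
        if idx < 0 or idx + pwm.length > len(region.sequence):
            continue
        any_covered = True
        lmer = region.sequence[idx : idx + pwm.length]
        s = pwm.score(lmer)
        if s >= pwm.threshold or include_subthreshold:
            hits.append(MotifHit(p, lmer, s, s >= pwm.threshold))
    if not any_covered:
        warnings.warn(
            f"window {window} entirely outside the covered sequence", stacklevel=2
        )
    return hits


def compare_variant_motifs(
    ref: AssembledRegion,
    alt: AssembledRegion,
    pwm: PwmModel,
    window: tuple[int, int] = (-100, 100),
) -> VariantComparison:
    """Position-wise comparison of PWM sites between two aligned regions.

    Both regions must have equal length and the same boundary.  Reference
    hits whose score in the variant falls below the threshold are
    classified as lost.
    """
    if len(ref.sequence) != len(alt.sequence):
        raise ValueError("ref and alt sequences differ in length")
    if ref.boundary_offset != alt.boundary_offset:
        raise ValueError("ref and alt regions have different boundaries")
    subs = [
        ref.position_of(i)
        for i, (a, b) in enumerate(zip(ref.sequence, alt.sequence))
        if a != b
    ]
    ref_hits = scan_pwm(ref, pwm, window)
    alt_scores: dict[int, float] = {}
    lost: list[MotifHit] = []
    for hit in ref_hits:
        idx = _relative_to_index(alt, hit.start)
        alt_scores[hit.start] = pwm.score(alt.sequence[idx : idx + pwm.length])
        if alt_scores[hit.start] < pwm.threshold:
            lost.append(hit)
    return VariantComparison(subs, ref_hits, alt_scores, lost)
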