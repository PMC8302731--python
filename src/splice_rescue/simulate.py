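"""Synthetic data with known ground truth.

Generators for the quantities the pipeline consumes:

* cassette-exon junction counts across two conditions with replicates,
  drawn binomially from known per-exon inclusion levels (PSI) at a known
  per-exon junction depth;
* spliced SAM reads whose CIGAR N operations encode exactly the
  simulated junctions, so junction extraction can be tested end-to-end;
* four-parameter-logistic (4PL) reporter dose-response tables with
  Gaussian noise.

The default experimental design mirrors a small fibroblast study: two
conditions ("control" and "treated") with two replicates each.  Counts
are binomial -- no overdispersion -- unless ``dispersion`` is set, in
which case inclusion probabilities are jittered per sample with a beta
distribution.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from .junctions import Exon, GeneModel, JunctionCounts

__all__ = [
    "SyntheticTruth",
    "ReporterTruth",
    "make_gene_models",
    "simulate_junction_counts",
    "simulate_spliced_sam",
    "simulate_reporter_data",
    "four_pl",
]

CONDITIONS = ("control", "treated")


@dataclass
class SyntheticTruth:
    """Ground truth for a cassette-exon simulation.

    ``psi`` maps condition -> per-exon true inclusion fraction; exon i of
    the truth is the internal exon (ordinal 2) of gene i.  ``depth`` is
    the junction depth allocated to each exon in every sample.
    """

    psi: dict[str, list[float]]
    depth: int = 500
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.psi.values()}
        if len(sizes) != 1:
            raise ValueError("per-condition PSI vectors differ in length")
        for cond, vals in self.psi.items():
            for p in vals:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{cond}: PSI {p} outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be a positive integer")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_exons(self) -> int:
        return len(next(iter(self.psi.values())))

    @property
    def conditions(self) -> list[str]:
        return list(self.psi)

    def sample_names(self) -> list[str]:
        return [f"{c}_rep{r}" for c in self.conditions for r in range(1, self.replicates + 1)]

    def grouping(self) -> dict[str, str]:
        return {s: s.rsplit("_rep", 1)[0] for s in self.sample_names()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def random(
        cls,
        n_exons: int,
        seed: int,
        depth: int = 500,
        replicates: int = 2,
        delta: list[float] | None = None,
    ) -> "SyntheticTruth":
        """Uniform control PSI; treated PSI shifted by ``delta`` (clipped)."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.0, 1.0, size=n_exons)
        shift = np.zeros(n_exons) if delta is None else np.asarray(delta, dtype=float)
        treated = np.clip(base + shift, 0.0, 1.0)
        return cls(
            psi={"control": base.tolist(), "treated": treated.tolist()},
            depth=depth,
            replicates=replicates,
            seed=seed,
        )


def make_gene_models(
    n_exons: int,
    chrom: str = "chrS",
    exon_length: int = 100,
    intron_length: int = 200,
    spacing: int = 1000,
) -> list[GeneModel]:
    """One three-exon gene per simulated cassette exon, on a plus strand."""
    models = []
    cursor = 0
    for i in range(n_exons):
        exons = []
        pos = cursor
        for _ in range(3):
            exons.append(Exon(chrom, pos, pos + exon_length))
            pos += exon_length + intron_length
        models.append(GeneModel(f"gene{i + 1:04d}", "+", exons))
        cursor = pos + spacing
    return models


def simulate_junction_counts(
    truth: SyntheticTruth,
    models: list[GeneModel] | None = None,
    dispersion: float = 0.0,
) -> tuple[dict[str, JunctionCounts], list[GeneModel]]:
    """Binomial junction counts per sample.

    For each internal exon, the inclusion junction count is drawn
    Binomial(depth, PSI_true) and the skipping count is the remainder,
    so inclusion + skipping always equals the allocated depth.  With
    ``dispersion`` > 0 the per-sample success probability is drawn from
    Beta with mean PSI_true and the given dispersion (over-dispersed
    counts); the default is plain binomial sampling.
    """
    if models is None:
        models = make_gene_models(truth.n_exons)
    if len(models) != truth.n_exons:
        raise ValueError("model count does not match truth")
    rng = np.random.default_rng(truth.seed)
    out: dict[str, JunctionCounts] = {}
    for cond in truth.conditions:
        psi = np.asarray(truth.psi[cond], dtype=float)
        for rep in range(1, truth.replicates + 1):
            sample = f"{cond}_rep{rep}"
            counts = {}
            for model, p in zip(models, psi):
                if dispersion > 0 and 0 < p < 1:
                    a = p * (1 - dispersion) / dispersion
                    b = (1 - p) * (1 - dispersion) / dispersion
                    p = rng.beta(a, b)
                incl = int(rng.binomial(truth.depth, p))
                skip = truth.depth - incl
                # zero-count junctions are not observable and are omitted
                if incl > 0:
                    chrom, d_end, a_start = model.junction_key(1, 2)
                    counts[(chrom, d_end, a_start, model.strand)] = incl
                if skip > 0:
                    chrom, d_end, a_start = model.junction_key(1, 3)
                    counts[(chrom, d_end, a_start, model.strand)] = skip
            out[sample] = JunctionCounts(sample, counts)
    return out, models


def simulate_spliced_sam(
    counts: dict[str, JunctionCounts],
    models: list[GeneModel],
    out_dir: str | Path,
    read_length: int = 50,
    min_anchor: int = 8,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one SAM file per sample encoding the junction counts.

    Each junction observation becomes one primary spliced read with
    ``a M gap N b M`` CIGAR, anchors a = b = read_length // 2, placed so
    the N operation spans exactly the simulated junction interval.
    """
    anchor = read_length // 2
    if anchor < min_anchor:
        raise ValueError("read_length must be >= 2 x anchor length")
    exon_len = min(len(e) for m in models for e in m.exons)
    if exon_len < anchor:
        raise ValueError(f"exon length {exon_len} shorter than anchor {anchor}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms: dict[str, int] = {}
    for m in models:
        for e in m.exons:
            chroms[e.chrom] = max(chroms.get(e.chrom, 0), e.end + 1)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chroms.items())],
        }
    )
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    for sample, jc in counts.items():
        path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            serial = 0
            for (chrom, donor_end, acc_start, strand), n in sorted(jc.counts.items()):
                gap = acc_start - donor_end
                for _ in range(n):
                    serial += 1
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{sample}.r{serial:07d}"
                    a.query_sequence = "".join(
                        rng.choice(list("ACGT"), size=2 * anchor)
                    )
                    a.query_qualities = pysam.qualitystring_to_array("I" * 2 * anchor)
                    a.flag = 0 if strand == "+" else 16
                    a.reference_id = header.get_tid(chrom)
                    a.reference_start = donor_end - anchor
                    a.mapping_quality = 60
                    a.cigartuples = [(0, anchor), (3, gap), (0, anchor)]
                    fh.write(a)
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Reporter dose-response simulation
# ---------------------------------------------------------------------------

def four_pl(dose, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic response at the given dose(s)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


@dataclass
class ReporterTruth:
    """Ground truth for a 4PL reporter simulation."""

    bottom: float = 0.0
    top: float = 100.0
    ec50: float = 2.0
    hill: float = 1.0
    doses: list[float] = field(
        default_factory=lambda: [0.05, 0.15, 0.5, 1.5, 5.0, 15.0, 50.0, 150.0]
    )
    replicates: int = 4
    noise_scale: float = 0.05  # fraction of |top - bottom|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        d = np.asarray(self.doses, dtype=float)
        if len(d) and not (np.diff(d) > 0).all():
            raise ValueError("dose grid must be strictly increasing")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def simulate_reporter_data(truth: ReporterTruth, compound: str = "synthetic"):
    """Noisy 4PL responses as a tidy table.

    Returns a pandas DataFrame with columns compound, dose_uM, response,
    replicate, seed; responses are the 4PL curve plus Gaussian noise of
    standard deviation ``noise_scale * |top - bottom|``.
    """
    import pandas as pd

    rng = np.random.default_rng(truth.seed)
    rows = []
    sigma = truth.noise_scale * abs(truth.top - truth.bottom)
    for dose in truth.doses:
        mu = float(four_pl(dose, truth.bottom, truth.top, truth.ec50, truth.hill))
        for rep in range(1, truth.replicates + 1):
            resp = mu + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            rows.append(
                {
                    "compound": compound,
                    "dose_uM": dose,
                    "response": resp,
                    "replicate": rep,
                    "seed": truth.seed,
                }
            )
    return pd.DataFrame(rows)
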