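"""Differential-splicing screen: replicate averaging, coverage filtering,
delta-PSI ranking and event counting.

The screen compares two conditions (e.g. vehicle vs. splice-modulator
treatment).  Per-sample PSI values are averaged within each condition
(arithmetic mean over samples where PSI is defined), and exons are ranked
by |delta PSI| = |mean PSI(treated) - mean PSI(control)|.  An exon enters
the ranking only if its junction coverage exceeds the rpm threshold
(default: strictly more than 15 reads per million junction reads,
computed on pooled replicate counts per condition) in at least one of the
two conditions.  Events are counted at an inclusive |delta PSI| cutoff
(default 0.1).  No significance testing is attached: the screen ranks by
effect size only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .junctions import ExonPsiRecord, JunctionCounts

__all__ = [
    "ScreenConfig",
    "ConditionSummary",
    "DeltaPsiRecord",
    "average_replicates",
    "condition_coverage_rpm",
    "screen_delta_psi",
    "count_events",
    "export_top_k",
]

ExonId = tuple[str, int]  # (gene id, exon ordinal)


@dataclass(frozen=True)
class ScreenConfig:
    coverage_rpm_min: float = 15.0  # strict ">"
    coverage_rule: str = "either_condition"  # or "both_conditions"
    event_cutoff: float = 0.1  # inclusive ">="
    top_k: int = 100

    def __post_init__(self) -> None:
        if self.coverage_rpm_min <= 0 or self.event_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.coverage_rule not in ("either_condition", "both_conditions"):
            raise ValueError(f"unknown coverage rule {self.coverage_rule!r}")


@dataclass
class ConditionSummary:
    """Per-exon mean PSI within one condition."""

    condition: str
    mean_psi: dict[ExonId, float | None] = field(default_factory=dict)
    n_defined: dict[ExonId, int] = field(default_factory=dict)


@dataclass
class DeltaPsiRecord:
    exon: ExonId
    mean_psi_control: float | None
    mean_psi_treated: float | None
    delta_psi: float | None
    passes_coverage: bool
    rank: int | None = None

    @property
    def abs_delta(self) -> float | None:
        return None if self.delta_psi is None else abs(self.delta_psi)


def average_replicates(
    per_sample: dict[str, list[ExonPsiRecord]],
    grouping: dict[str, str],
) -> dict[str, ConditionSummary]:
    """Arithmetic mean of per-sample PSI values per condition.

    Samples where an exon's PSI is undefined are ignored for that exon;
    an exon is undefined in a condition only if every sample is.
    """
    unknown = set(per_sample) - set(grouping)
    if unknown:
        raise KeyError(f"samples missing from grouping: {sorted(unknown)}")
    summaries: dict[str, ConditionSummary] = {}
    for sample, records in per_sample.items():
        cond = grouping[sample]
        summary = summaries.setdefault(cond, ConditionSummary(cond))
        for rec in records:
            key = (rec.gene_id, rec.exon_ordinal)
            summary.mean_psi.setdefault(key, None)
            summary.n_defined.setdefault(key, 0)
            if rec.psi is None:
                continue
            k = summary.n_defined[key]
            prev = summary.mean_psi[key] or 0.0
            summary.mean_psi[key] = (prev * k + rec.psi) / (k + 1)
            summary.n_defined[key] = k + 1
    return summaries


def condition_coverage_rpm(
    per_sample_records: dict[str, list[ExonPsiRecord]],
    per_sample_counts: dict[str, JunctionCounts],
    grouping: dict[str, str],
) -> dict[str, dict[ExonId, float]]:
    """Pooled coverage per condition: sum of (J_incl + J_skip) over the
    condition's samples per million summed junction reads."""
    out: dict[str, dict[ExonId, float]] = {}
    totals: dict[str, int] = {}
    sums: dict[str, dict[ExonId, int]] = {}
    for sample, records in per_sample_records.items():
        cond = grouping[sample]
        totals[cond] = totals.get(cond, 0) + per_sample_counts[sample].total_junction_reads
        bucket = sums.setdefault(cond, {})
        for rec in records:
            key = (rec.gene_id, rec.exon_ordinal)
            bucket[key] = bucket.get(key, 0) + rec.j_incl + rec.j_skip
    for cond, bucket in sums.items():
        total = totals[cond]
        out[cond] = {
            key: (n * 1e6 / total if total > 0 else 0.0) for key, n in bucket.items()
        }
    return out


def screen_delta_psi(
    means: dict[str, ConditionSummary],
    coverage: dict[str, dict[ExonId, float]],
    config: ScreenConfig = ScreenConfig(),
    control: str = "control",
    treated: str = "treated",
) -> list[DeltaPsiRecord]:
    """Rank coverage-passing exons by |delta PSI|, descending.

    Ties are broken deterministically by gene id then exon ordinal,
    ascending.  Exons failing the coverage rule, or with an undefined
    mean in either condition, carry no rank.
    """
    if not means:
        return []
    ctrl = means[control]
    trt = means[treated]
    exon_ids = sorted(set(ctrl.mean_psi) | set(trt.mean_psi))
    records: list[DeltaPsiRecord] = []
    for key in exon_ids:
        mc = ctrl.mean_psi.get(key)
        mt = trt.mean_psi.get(key)
        cov_c = coverage.get(control, {}).get(key, 0.0)
        cov_t = coverage.get(treated, {}).get(key, 0.0)
        above = (cov_c > config.coverage_rpm_min, cov_t > config.coverage_rpm_min)
        passes = any(above) if config.coverage_rule == "either_condition" else all(above)
        delta = (mt - mc) if (mc is not None and mt is not None) else None
        records.append(DeltaPsiRecord(key, mc, mt, delta, passes))
    rankable = [r for r in records if r.passes_coverage and r.delta_psi is not None]
    rankable.sort(key=lambda r: (-abs(r.delta_psi), r.exon[0], r.exon[1]))
    for rank, rec in enumerate(rankable, start=1):
        rec.rank = rank
    return records


def count_events(records: list[DeltaPsiRecord], cutoff: float = 0.1) -> int:
    """Number of coverage-passing exons with |delta PSI| >= cutoff."""
    return sum(
        1
        for r in records
        if r.passes_coverage and r.abs_delta is not None and r.abs_delta >= cutoff
    )


def export_top_k(
    records: list[DeltaPsiRecord],
    k: int,
    table_path: str | Path | None = None,
    plot_path: str | Path | None = None,
    highlight: ExonId | None = None,
    header_lines: list[str] | None = None,
) -> list[DeltaPsiRecord]:
    """First k ranked records, optionally written as TSV and rank scatter."""
    ranked = sorted(
        (r for r in records if r.rank is not None), key=lambda r: r.rank
    )
    if k > len(ranked):
        import warnings

        warnings.warn(
            f"requested top {k} but only {len(ranked)} ranked records", stacklevel=2
        )
    top = ranked[:k]
    if table_path is not None:
        with open(table_path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(
                "rank\tgene\texon_ordinal\tmean_psi_control\tmean_psi_treated"
                "\tdelta_psi\tabs_delta\n"
            )
            for r in top:
                fh.write(
                    f"{r.rank}\t{r.exon[0]}\t{r.exon[1]}\t{r.mean_psi_control:.6g}"
                    f"\t{r.mean_psi_treated:.6g}\t{r.delta_psi:.6g}\t{r.abs_delta:.6g}\n"
                )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.scatter([r.rank for r in top], [r.abs_delta for r in top], s=12, c="0.3")
        if highlight is not None:
            hl = [r for r in top if r.exon == highlight]
            if hl:
                ax.scatter(
                    [r.rank for r in hl], [r.abs_delta for r in hl], s=30, c="crimson"
                )
        ax.set_xlabel("rank")
        ax.set_ylabel("|delta PSI|")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return top
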