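"""Replicate averaging, coverage filtering and delta-PSI ranking."""

import numpy as np
import pytest

from splice_rescue import (
    ExonPsiRecord,
    JunctionCounts,
    ScreenConfig,
    average_replicates,
    condition_coverage_rpm,
    count_events,
    export_top_k,
    screen_delta_psi,
)
from splice_rescue.screen import DeltaPsiRecord


def rec(gene, ordinal, j_incl, j_skip, total=1_000_000):
    psi = j_incl / (j_incl + j_skip) if j_incl + j_skip else None
    rpm = (j_incl + j_skip) * 1e6 / total
    return ExonPsiRecord(gene, ordinal, j_incl, j_skip, psi, rpm)


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        per_sample = {
            "a1": [rec("g", 2, 20, 80)],   # 0.2
            "a2": [rec("g", 2, 40, 60)],   # 0.4
        }
        means = average_replicates(per_sample, {"a1": "control", "a2": "control"})
        assert means["control"].mean_psi[("g", 2)] == pytest.approx(0.3)
        assert means["control"].n_defined[("g", 2)] == 2

    def test_undefined_samples_are_ignored(self):
        per_sample = {
            "a1": [rec("g", 2, 50, 50)],
            "a2": [rec("g", 2, 0, 0)],  # undefined
        }
        means = average_replicates(per_sample, {"a1": "c", "a2": "c"})
        assert means["c"].mean_psi[("g", 2)] == pytest.approx(0.5)
        assert means["c"].n_defined[("g", 2)] == 1

    def test_all_undefined_stays_undefined(self):
        per_sample = {"a1": [rec("g", 2, 0, 0)]}
        means = average_replicates(per_sample, {"a1": "c"})
        assert means["c"].mean_psi[("g", 2)] is None

    def test_single_replicate_is_identity(self):
        per_sample = {"a1": [rec("g", 2, 30, 10)]}
        means = average_replicates(per_sample, {"a1": "c"})
        assert means["c"].mean_psi[("g", 2)] == pytest.approx(0.75)

    def test_unknown_sample_errors(self):
        with pytest.raises(KeyError):
            average_replicates({"x": []}, {})


def make_screen_inputs(spec):
    """spec: exon -> dict(cond -> (j_incl, j_skip, total)) with one sample each."""
    per_sample, per_counts, grouping = {}, {}, {}
    for cond in ("control", "treated"):
        sample = f"{cond}_rep1"
        grouping[sample] = cond
        recs, counts = [], {}
        for i, (exon, conds) in enumerate(sorted(spec.items())):
            j_incl, j_skip, total = conds[cond]
            recs.append(rec(exon[0], exon[1], j_incl, j_skip, total))
            counts[("chrS", 10_000 * i + 100, 10_000 * i + 300, "+")] = j_incl
            counts[("chrS", 10_000 * i + 100, 10_000 * i + 600, "+")] = j_skip
        filler = total - sum(counts.values())
        if filler > 0:
            counts[("chrS", 1, 50, "+")] = filler
        per_sample[sample] = recs
        per_counts[sample] = JunctionCounts(sample, counts)
    return per_sample, per_counts, grouping


class TestCoverageRule:
    def test_sixteen_rpm_in_treated_only_passes_either_rule(self):
        spec = {("g1", 2): {"control": (5, 5, 1_000_000), "treated": (8, 8, 1_000_000)}}
        per_sample, per_counts, grouping = make_screen_inputs(spec)
        means = average_replicates(per_sample, grouping)
        cov = condition_coverage_rpm(per_sample, per_counts, grouping)
        records = screen_delta_psi(means, cov, ScreenConfig())
        assert records[0].passes_coverage
        both = screen_delta_psi(
            means, cov, ScreenConfig(coverage_rule="both_conditions")
        )
        assert not both[0].passes_coverage

    def test_exactly_fifteen_rpm_is_excluded(self):
        spec = {("g1", 2): {"control": (10, 5, 1_000_000), "treated": (7, 8, 1_000_000)}}
        per_sample, per_counts, grouping = make_screen_inputs(spec)
        means = average_replicates(per_sample, grouping)
        cov = condition_coverage_rpm(per_sample, per_counts, grouping)
        assert cov["control"][("g1", 2)] == pytest.approx(15.0)
        records = screen_delta_psi(means, cov, ScreenConfig())
        assert not records[0].passes_coverage
        assert records[0].rank is None


def brute_force_screen(per_sample, per_counts, grouping, rpm_min=15.0):
    """Plain-loop re-derivation of means, coverage, ranking and ranks."""
    conds = sorted(set(grouping.values()))
    exons = sorted({(r.gene_id, r.exon_ordinal) for recs in per_sample.values() for r in recs})
    means = {}
    cov = {}
    for cond in conds:
        samples = [s for s, c in grouping.items() if c == cond]
        for exon in exons:
            vals = []
            j_sum = 0
            total = 0
            for s in samples:
                total += sum(per_counts[s].counts.values())
                for r in per_sample[s]:
                    if (r.gene_id, r.exon_ordinal) == exon:
                        j_sum += r.j_incl + r.j_skip
                        if r.psi is not None:
                            vals.append(r.psi)
            means[(cond, exon)] = sum(vals) / len(vals) if vals else None
            cov[(cond, exon)] = j_sum * 1e6 / total
    rows = []
    for exon in exons:
        mc, mt = means[("control", exon)], means[("treated", exon)]
        passes = cov[("control", exon)] > rpm_min or cov[("treated", exon)] > rpm_min
        if passes and mc is not None and mt is not None:
            rows.append((-(abs(mt - mc)), exon[0], exon[1]))
    rows.sort()
    return {(g, o): i + 1 for i, (_, g, o) in enumerate(rows)}


class TestRankingOracle:
    def test_fifty_exon_instance_matches_brute_force(self):
        rng = np.random.default_rng(7)
        spec = {}
        for i in range(50):
            exon = (f"g{i:03d}", 2)
            spec[exon] = {}
            for cond in ("control", "treated"):
                depth = int(rng.integers(0, 60))
                j_incl = int(rng.binomial(depth, rng.uniform())) if depth else 0
                spec[exon][cond] = (j_incl, depth - j_incl, 1_000_000)
        per_sample, per_counts, grouping = make_screen_inputs(spec)
        means = average_replicates(per_sample, grouping)
        cov = condition_coverage_rpm(per_sample, per_counts, grouping)
        records = screen_delta_psi(means, cov, ScreenConfig())
        expected = brute_force_screen(per_sample, per_counts, grouping)
        got = {r.exon: r.rank for r in records if r.rank is not None}
        assert got == expected

    def test_ranking_is_a_contiguous_permutation(self):
        spec = {
            (f"g{i}", 2): {
                "control": (30, 10, 1_000_000),
                "treated": (10 + i, 30 - i, 1_000_000),
            }
            for i in range(10)
        }
        per_sample, per_counts, grouping = make_screen_inputs(spec)
        means = average_replicates(per_sample, grouping)
        cov = condition_coverage_rpm(per_sample, per_counts, grouping)
        ranks = [r.rank for r in screen_delta_psi(means, cov) if r.rank is not None]
        assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_invariant_under_sample_relabelling(self):
        spec = {
            ("g1", 2): {"control": (30, 10, 1_000_000), "treated": (10, 30, 1_000_000)},
            ("g2", 2): {"control": (20, 20, 1_000_000), "treated": (25, 15, 1_000_000)},
        }
        per_sample, per_counts, grouping = make_screen_inputs(spec)
        means1 = average_replicates(per_sample, grouping)
        cov1 = condition_coverage_rpm(per_sample, per_counts, grouping)
        r1 = screen_delta_psi(means1, cov1)
        renamed = {f"x_{k}": v for k, v in per_sample.items()}
        recount = {f"x_{k}": v for k, v in per_counts.items()}
        regroup = {f"x_{k}": v for k, v in grouping.items()}
        means2 = average_replicates(renamed, regroup)
        cov2 = condition_coverage_rpm(renamed, recount, regroup)
        r2 = screen_delta_psi(means2, cov2)
        assert [(r.exon, r.rank, r.delta_psi) for r in r1] == [
            (r.exon, r.rank, r.delta_psi) for r in r2
        ]


class TestCountEvents:
    @staticmethod
    def make(deltas, passes=True):
        return [
            DeltaPsiRecord(("g", i + 2), 0.0, d, d, passes) for i, d in enumerate(deltas)
        ]

    def test_inclusive_boundary(self):
        assert count_events(self.make([0.05, 0.10, 0.30]), 0.1) == 2

    def test_empty(self):
        assert count_events([], 0.1) == 0

    def test_failing_coverage_not_counted(self):
        assert count_events(self.make([0.5], passes=False), 0.1) == 0

    def test_monotone_in_cutoff(self):
        records = self.make([0.01 * i for i in range(40)])
        counts = [count_events(records, c) for c in (0.05, 0.1, 0.2, 0.3)]
        assert counts == sorted(counts, reverse=True)

    def test_exact_dyadic_boundary(self):
        # 0.625 - 0.5 is exactly representable, so the boundary is sharp
        records = [DeltaPsiRecord(("g", 2), 0.5, 0.625, 0.625 - 0.5, True)]
        assert count_events(records, 0.125) == 1
        assert count_events(records, 0.1250001) == 0


class TestExportTopK:
    def _ranked(self, n):
        recs = [
            DeltaPsiRecord(("g%02d" % i, 2), 0.2, 0.2 + 0.01 * i, 0.01 * i, True)
            for i in range(n)
        ]
        recs.sort(key=lambda r: -r.abs_delta)
        for i, r in enumerate(recs):
            r.rank = i + 1
        return recs

    def test_top_k_rows(self, tmp_path):
        top = export_top_k(self._ranked(200), 100, table_path=tmp_path / "t.tsv")
        assert len(top) == 100
        assert [r.rank for r in top] == list(range(1, 101))
        lines = (tmp_path / "t.tsv").read_text().splitlines()
        assert len(lines) == 101  # header + 100 rows

    def test_k_of_one_returns_the_maximum(self):
        top = export_top_k(self._ranked(5), 1)
        assert top[0].rank == 1
        assert top[0].abs_delta == pytest.approx(0.04)

    def test_k_larger_than_available_warns_and_writes_all(self, tmp_path):
        with pytest.warns(UserWarning):
            top = export_top_k(self._ranked(3), 10, table_path=tmp_path / "t.tsv")
        assert len(top) == 3
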