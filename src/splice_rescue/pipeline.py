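"""Config-driven orchestration of the analysis stages.

A run is described by a single YAML document with one block per stage;
stages can be toggled independently and execute in dependency order
(simulate -> junctions -> PSI -> delta-PSI screen; element scan and
potency are independent).  Every output carries the run seed in a header
line, and a MANIFEST file records each artifact with a content hash so
reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import (
    ScreenConfig,
    SyntheticTruth,
    assemble_donor_region,
    average_replicates,
    compute_psi,
    condition_coverage_rpm,
    count_events,
    donor_context,
    export_top_k,
    extract_junctions,
    load_pwm,
    scan_pwm,
    screen_delta_psi,
    simulate_junction_counts,
    simulate_spliced_sam,
    u1_mismatches,
)
from .potency import ec_at, fit_4pl, normalize_reporter

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class SimulateStage:
    enabled: bool = False
    exons: int = 50
    depth: int = 500
    replicates: int = 2
    spike_index: int | None = None
    spike_delta: float = 0.0


@dataclass
class ScreenStage:
    enabled: bool = False
    rpm_min: float = 15.0
    coverage_rule: str = "either_condition"
    cutoff: float = 0.1
    top_k: int = 100


@dataclass
class ElementsStage:
    enabled: bool = False
    variant: str = "fd"
    factor: str = "SRSF6"
    window: tuple[int, int] = (-100, 100)


@dataclass
class PotencyStage:
    enabled: bool = False
    table: str | None = None
    reference: tuple[str, float] | None = None
    level: float = 0.25


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "splice_rescue_out"
    simulate: SimulateStage = field(default_factory=SimulateStage)
    screen: ScreenStage = field(default_factory=ScreenStage)
    elements: ElementsStage = field(default_factory=ElementsStage)
    potency: PotencyStage = field(default_factory=PotencyStage)


_STAGE_TYPES = {
    "simulate": SimulateStage,
    "screen": ScreenStage,
    "elements": ElementsStage,
    "potency": PotencyStage,
}


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse + validate a config, reporting every violation at once."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    cfg = RunConfig()
    known_top = {"seed", "out_dir", *_STAGE_TYPES}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown key {key!r}")
    if "seed" in raw:
        if not isinstance(raw["seed"], int) or raw["seed"] < 0:
            errors.append("seed: must be a non-negative integer")
        else:
            cfg.seed = raw["seed"]
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])
    for name, cls in _STAGE_TYPES.items():
        block = raw.get(name)
        if block is None:
            continue
        if not isinstance(block, dict):
            errors.append(f"{name}: must be a mapping")
            continue
        stage = getattr(cfg, name)
        valid_fields = set(cls.__dataclass_fields__)
        for key, value in block.items():
            if key not in valid_fields:
                errors.append(f"{name}.{key}: unknown key")
                continue
            if key == "window" and value is not None:
                value = tuple(value)
            if key == "reference" and value is not None:
                value = (str(value[0]), float(value[1]))
            setattr(stage, key, value)
    sim = cfg.simulate
    if sim.exons < 1:
        errors.append("simulate.exons: must be >= 1")
    if sim.depth < 1:
        errors.append("simulate.depth: must be a positive integer")
    if sim.replicates < 1:
        errors.append("simulate.replicates: must be >= 1")
    if cfg.screen.rpm_min <= 0:
        errors.append("screen.rpm_min: must be positive")
    if cfg.screen.cutoff <= 0:
        errors.append("screen.cutoff: must be positive")
    if cfg.screen.coverage_rule not in ("either_condition", "both_conditions"):
        errors.append("screen.coverage_rule: unknown rule")
    if cfg.elements.variant not in ("fd", "wt"):
        errors.append("elements.variant: must be 'fd' or 'wt'")
    if not 0 < cfg.potency.level < 1:
        errors.append("potency.level: must be inside (0, 1)")
    if cfg.potency.enabled and cfg.potency.table is None:
        errors.append("potency.table: required when potency stage is enabled")
    if cfg.potency.enabled and cfg.potency.table and not Path(cfg.potency.table).exists():
        errors.append(f"potency.table: path {cfg.potency.table!r} does not exist")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[splice-rescue] {msg}", file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute enabled stages; returns the report dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    outputs: list[Path] = []
    complete = False
    try:
        if cfg.simulate.enabled:
            t0 = time.perf_counter()
            try:
                delta = [0.0] * cfg.simulate.exons
                if cfg.simulate.spike_index is not None:
                    delta[cfg.simulate.spike_index] = cfg.simulate.spike_delta
                truth = SyntheticTruth.random(
                    cfg.simulate.exons,
                    seed=cfg.seed,
                    depth=cfg.simulate.depth,
                    replicates=cfg.simulate.replicates,
                    delta=delta,
                )
                counts, models = simulate_junction_counts(truth)
                sam_dir = out / "sam"
                simulate_spliced_sam(counts, models, sam_dir, seed=cfg.seed)
                truth.to_json(out / "truth.json")
                outputs.append(out / "truth.json")
                per_sample_records = {}
                for sample in truth.sample_names():
                    jc, _ = extract_junctions(sam_dir / f"{sample}.sam", sample=sample)
                    recs, _ = compute_psi(jc, models)
                    per_sample_records[sample] = recs
                    path = out / f"psi_{sample}.tsv"
                    with open(path, "w") as fh:
                        fh.write(f"# seed: {cfg.seed}\n")
                        fh.write("gene\texon_ordinal\tj_incl\tj_skip\tpsi\tcoverage_rpm\n")
                        for r in recs:
                            psi = "NA" if r.psi is None else f"{r.psi:.6g}"
                            fh.write(
                                f"{r.gene_id}\t{r.exon_ordinal}\t{r.j_incl}\t{r.j_skip}"
                                f"\t{psi}\t{r.coverage_rpm:.6g}\n"
                            )
                    outputs.append(path)
                report["stages"]["simulate"] = {
                    "exons": cfg.simulate.exons,
                    "samples": truth.sample_names(),
                }
                if cfg.screen.enabled:
                    grouping = truth.grouping()
                    means = average_replicates(per_sample_records, grouping)
                    per_sample_counts = {
                        s: extract_junctions(sam_dir / f"{s}.sam", sample=s)[0]
                        for s in truth.sample_names()
                    }
                    coverage = condition_coverage_rpm(
                        per_sample_records, per_sample_counts, grouping
                    )
                    sc = ScreenConfig(
                        coverage_rpm_min=cfg.screen.rpm_min,
                        coverage_rule=cfg.screen.coverage_rule,
                        event_cutoff=cfg.screen.cutoff,
                        top_k=cfg.screen.top_k,
                    )
                    records = screen_delta_psi(means, coverage, sc)
                    top_path = out / "top_events.tsv"
                    export_top_k(
                        records,
                        sc.top_k,
                        table_path=top_path,
                        header_lines=[f"seed: {cfg.seed}"],
                    )
                    outputs.append(top_path)
                    report["stages"]["screen"] = {
                        "ranked": sum(1 for r in records if r.rank is not None),
                        "events": count_events(records, sc.event_cutoff),
                    }
            except Exception as exc:  # noqa: BLE001
                raise StageError("simulate/screen", exc) from exc
            _log(f"simulate/screen done in {time.perf_counter() - t0:.2f}s")

        if cfg.elements.enabled:
            t0 = time.perf_counter()
            try:
                region = assemble_donor_region(cfg.elements.variant)
                ctx = donor_context(region, source=cfg.elements.variant)
                mm = u1_mismatches(ctx)
                pwm = load_pwm(cfg.elements.factor)
                hits = scan_pwm(region, pwm, tuple(cfg.elements.window))
                mpath = out / "donor_mismatches.tsv"
                with open(mpath, "w") as fh:
                    fh.write(f"# seed: {cfg.seed}\n")
                    fh.write("context\tposition\tstatus\n")
                    for p in sorted(
                        mm.mismatch_positions | mm.paired_positions,
                        key=lambda x: (x > 0, abs(x) if x < 0 else x),
                    ):
                        status = "mismatch" if p in mm.mismatch_positions else "paired"
                        fh.write(f"{ctx.sequence}\t{p:+d}\t{status}\n")
                hpath = out / "motif_hits.tsv"
                with open(hpath, "w") as fh:
                    fh.write(f"# seed: {cfg.seed}\n# factor: {pwm.factor}\n")
                    fh.write("start\tend\tsequence\tscore\tthreshold\n")
                    for h in hits:
                        end = h.start + pwm.length - 1
                        fh.write(
                            f"{h.start:+d}\t{end:+d}\t{h.sequence}\t{h.score:.3f}"
                            f"\t{pwm.threshold}\n"
                        )
                outputs += [mpath, hpath]
                report["stages"]["elements"] = {
                    "mismatches": sorted(mm.mismatch_positions),
                    "hits": [h.start for h in hits],
                }
            except Exception as exc:  # noqa: BLE001
                raise StageError("elements", exc) from exc
            _log(f"elements done in {time.perf_counter() - t0:.2f}s")

        if cfg.potency.enabled:
            t0 = time.perf_counter()
            try:
                import pandas as pd

                table = pd.read_csv(cfg.potency.table, sep="\t", comment="#")
                if cfg.potency.reference is not None:
                    table = normalize_reporter(table, cfg.potency.reference)
                fits = {}
                for compound, sub in table.groupby("compound"):
                    fit = fit_4pl(sub)
                    fit.ec25 = ec_at(fit, cfg.potency.level) if fit.converged else None
                    fits[compound] = {
                        "bottom": fit.bottom,
                        "top": fit.top,
                        "ec50": fit.ec50,
                        "hill": fit.hill,
                        "converged": fit.converged,
                        f"ec{int(cfg.potency.level * 100)}": fit.ec25,
                    }
                fpath = out / "potency.json"
                fpath.write_text(json.dumps({"seed": cfg.seed, "fits": fits}, indent=2))
                outputs.append(fpath)
                report["stages"]["potency"] = {"compounds": sorted(fits)}
            except Exception as exc:  # noqa: BLE001
                raise StageError("potency", exc) from exc
            _log(f"potency done in {time.perf_counter() - t0:.2f}s")
        complete = True
    finally:
        manifest = {
            "seed": cfg.seed,
            "complete": complete,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs if p.exists()},
        }
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    return report


def load_and_run(path: str | Path) -> dict:
    return run_pipeline(validate_config(path))


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)
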