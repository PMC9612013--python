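"""End-to-end pipeline: simulate -> detect structure -> phase -> variants -> tree.

A single YAML config drives all stages with explicit per-stage seeds; every
run writes a manifest (tool version, config echo, per-stage output checksums
and wall-clock, warnings) so deterministic stages can be verified to
reproduce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, PlastokitError
from .simulate import (
    PlastomeSpec,
    PopulationSpec,
    ReadSimParams,
    simulate_plastome,
    simulate_reads,
    simulate_population,
    two_clade_newick,
    write_fastq,
)
from .structure import build_isoform, detect_partition
from .phasing import phase_reads
from .variants import (
    build_coordinate_map,
    classify_columns,
    intersect_markers,
    write_variants,
)
from .trees import bootstrap_support, clade_test, root_tree, write_tree

_STAGES = ("simulate", "structure", "phase", "variants", "tree")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str
    overwrite: bool = False
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    plastome: PlastomeSpec | None = None
    reads: ReadSimParams | None = None
    population: dict | None = None
    structure: dict = field(default_factory=lambda: {"min_len": 500, "max_mismatch_frac": 0.0})
    phase: dict = field(default_factory=lambda: {"anchor_min": 500, "min_identity": 0.85})
    variants: dict = field(default_factory=lambda: {"min_minor_count": 1, "reference_id": None})
    tree: dict | None = None


_SCHEMA = {
    "out_dir": str,
    "overwrite": bool,
    "stages": dict,
    "plastome": dict,
    "reads": dict,
    "population": dict,
    "structure": dict,
    "phase": dict,
    "variants": dict,
    "tree": dict,
}
_SECTION_KEYS = {
    "stages": set(_STAGES),
    "plastome": {"lsc_len", "ssc_len", "ir_len", "gc_content", "seed"},
    "reads": {
        "n_reads", "length_mean", "length_sd", "mismatch_rate", "ins_rate",
        "del_rate", "mixture_ratio", "seed",
    },
    "population": {
        "newick", "subst_rate_scale", "indel_rate", "indel_len_geom_p", "seed",
    },
    "structure": {"min_len", "max_mismatch_frac"},
    "phase": {"anchor_min", "min_identity"},
    "variants": {"min_minor_count", "reference_id", "markers_a", "markers_b"},
    "tree": {"mode", "bootstrap", "seed", "outgroup", "query"},
}


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SECTION_KEYS[section]
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")


def validate_config(source) -> RunConfig:
    """Parse and strictly validate a YAML config (path, text, or dict).

    Unknown keys are rejected; every enabled stochastic stage must carry an
    explicit seed.
    """
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError("out_dir is required")
    stages = {s: True for s in _STAGES}
    stages.update(raw.get("stages", {}))
    _check_keys("stages", raw.get("stages", {}))
    for section in ("plastome", "reads", "population", "structure", "phase", "variants", "tree"):
        if section in raw:
            if not isinstance(raw[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            _check_keys(section, raw[section])

    cfg = RunConfig(out_dir=str(raw["out_dir"]), overwrite=bool(raw.get("overwrite", False)),
                    stages=stages)
    if stages["simulate"]:
        for section, cls in (("plastome", PlastomeSpec), ("reads", ReadSimParams)):
            params = dict(raw.get(section, {}))
            if "seed" not in params:
                raise ConfigError(f"stochastic stage section {section!r} requires an explicit seed")
            try:
                setattr(cfg, section, cls(**params))
            except (TypeError, PlastokitError) as exc:
                raise ConfigError(f"invalid {section} parameters: {exc}") from exc
        pop = dict(raw.get("population", {}))
        if pop:
            if "seed" not in pop:
                raise ConfigError("stochastic stage section 'population' requires an explicit seed")
            if "newick" not in pop:
                raise ConfigError("population section requires a newick tree")
            cfg.population = pop
    for section in ("structure", "phase", "variants"):
        merged = dict(getattr(cfg, section))
        merged.update(raw.get(section, {}))
        setattr(cfg, section, merged)
    if stages["tree"]:
        tr = dict(raw.get("tree", {}))
        tr.setdefault("mode", "snv_only")
        tr.setdefault("bootstrap", 200)
        if "seed" not in tr:
            raise ConfigError("stochastic stage section 'tree' requires an explicit seed")
        cfg.tree = tr
    return cfg


def default_demo_config(out_dir, seed: int = 7) -> RunConfig:
    """Small, fully deterministic synthetic run exercising every stage.

    A 10 kb plastome with 1 kb IRs, 150 error-free reads at mixture 0.5, and
    a 12-leaf two-clade population (plus outgroup) at ~25 expected
    substitutions per branch; the monophyly query puts one "purple" leaf in
    each clade — the synthetic analogue of a polyphyletic cultivar group.
    """
    return validate_config(
        {
            "out_dir": str(out_dir),
            "overwrite": True,
            "plastome": {"lsc_len": 6000, "ssc_len": 2000, "ir_len": 1000,
                         "gc_content": 0.38, "seed": seed},
            "reads": {"n_reads": 150, "length_mean": 3500.0, "length_sd": 600.0,
                      "mismatch_rate": 0.0, "ins_rate": 0.0, "del_rate": 0.0,
                      "mixture_ratio": 0.5, "seed": seed + 1},
            "population": {"newick": two_clade_newick(6, 0.0025, outgroup="OG"),
                           "subst_rate_scale": 1.0, "indel_rate": 0.02,
                           "indel_len_geom_p": 0.5, "seed": seed + 2},
            "structure": {"min_len": 500, "max_mismatch_frac": 0.0},
            "tree": {"mode": "snv_only", "bootstrap": 100, "seed": seed + 3,
                     "outgroup": ["OG"], "query": ["A1", "B1"]},
        }
    )


@dataclass
class RunManifest:
    """Checksummed record of one pipeline run."""

    version: str
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config": self.config,
             "stages": self.stages, "warnings": self.warnings},
            indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(cfg: RunConfig) -> dict:
    d = {
        "out_dir": cfg.out_dir,
        "overwrite": cfg.overwrite,
        "stages": cfg.stages,
        "structure": cfg.structure,
        "phase": cfg.phase,
        "variants": cfg.variants,
        "tree": cfg.tree,
        "population": cfg.population,
    }
    d["plastome"] = asdict(cfg.plastome) if cfg.plastome else None
    d["reads"] = asdict(cfg.reads) if cfg.reads else None
    return d


def run_pipeline(cfg: RunConfig) -> tuple[RunManifest, str]:
    """Execute enabled stages in dependency order; stop at the first failure.

    Returns the manifest and a collated plain-text report.  Stage outputs
    live under ``cfg.out_dir``; the manifest (with checksums of everything
    written) is saved there as ``manifest.json`` and the report as
    ``report.txt`` even on partial failure, so a run can be inspected and
    resumed.
    """
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.overwrite:
        raise ConfigError(f"output directory {out} is not empty (set overwrite: true)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=_config_echo(cfg))
    report_lines: list[str] = [f"plastokit {__version__} pipeline report", ""]
    state: dict = {}

    def finish_stage(name: str, t0: float, outputs: list[Path]):
        manifest.stages[name] = {
            "seconds": round(time.monotonic() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }

    try:
        if cfg.stages["simulate"]:
            t0 = time.monotonic()
            genome, partition = simulate_plastome(cfg.plastome)
            iso_a = build_isoform(genome, partition, "canonical")
            iso_b = build_isoform(genome, partition, "noncanonical")
            records, read_truth = simulate_reads(iso_a, iso_b, cfg.reads)
            files = []
            for name, seq in (("genome", genome), ("isoform_canonical", iso_a),
                              ("isoform_noncanonical", iso_b)):
                p = out / f"{name}.fasta"
                p.write_text(f">{name}\n{seq}\n")
                files.append(p)
            partition.to_bed(out / "partition_truth.bed")
            write_fastq(records, out / "reads.fastq")
            read_truth.to_csv(out / "read_truth.tsv", sep="\t", index=False)
            files += [out / "partition_truth.bed", out / "reads.fastq", out / "read_truth.tsv"]
            pop = None
            if cfg.population:
                spec = PopulationSpec(
                    tree=cfg.population["newick"],
                    subst_rate_scale=cfg.population.get("subst_rate_scale", 1.0),
                    indel_rate=cfg.population.get("indel_rate", 0.0),
                    indel_len_geom_p=cfg.population.get("indel_len_geom_p", 0.5),
                    seed=cfg.population["seed"],
                )
                pop = simulate_population(genome, spec)
                pop.alignment.to_fasta(out / "population_alignment.fasta")
                pop.variant_truth.to_csv(out / "variant_truth.tsv", sep="\t", index=False)
                files += [out / "population_alignment.fasta", out / "variant_truth.tsv"]
            state.update(genome=genome, partition=partition, records=records,
                         read_truth=read_truth, population=pop)
            finish_stage("simulate", t0, files)
            report_lines += [
                f"simulate: genome {len(genome)} bp "
                f"(LSC {partition.region('LSC').length}, IR {partition.ir_length}, "
                f"SSC {partition.region('SSC').length}), {len(records)} reads",
            ]

        if cfg.stages["structure"]:
            t0 = time.monotonic()
            detected = detect_partition(state["genome"], **cfg.structure)
            detected.to_bed(out / "partition_detected.bed")
            detected.to_tsv(out / "partition_detected.tsv")
            state["detected"] = detected
            finish_stage("structure", t0,
                         [out / "partition_detected.bed", out / "partition_detected.tsv"])
            agree = detected == state.get("partition")
            report_lines.append(
                f"structure: detected LSC/IR/SSC/IR partition"
                + (f" (matches planted truth: {agree})" if "partition" in state else "")
            )

        if cfg.stages["phase"]:
            t0 = time.monotonic()
            phase_dir = out / "phasing"
            result, calls = phase_reads(
                state["records"], state["genome"], state["detected"],
                anchor_min=cfg.phase["anchor_min"],
                min_identity=cfg.phase["min_identity"],
                out_dir=phase_dir,
            )
            state["phasing"] = result
            truth = state["read_truth"].set_index("read")["isoform"]
            label_of = {"canonical": "A", "noncanonical": "B"}
            classified = [c for c in calls.values() if c.call != "unclassified"]
            correct = sum(1 for c in classified if truth[c.read_id] == label_of[c.call])
            acc = 100.0 * correct / len(classified) if classified else float("nan")
            state["phasing_accuracy"] = acc
            finish_stage("phase", t0, sorted(phase_dir.iterdir()))
            report_lines += [
                "phase: " + result.report().replace("\n", "; ").rstrip("; "),
                f"phase: truth-checked accuracy on classified spanning reads: {acc:.1f}%",
            ]

        if cfg.stages["variants"]:
            t0 = time.monotonic()
            pop = state.get("population")
            if pop is None:
                raise ConfigError("variants stage needs the population simulation upstream")
            al = pop.alignment
            vt, ie = classify_columns(al, min_minor_count=cfg.variants["min_minor_count"])
            ref_id = cfg.variants.get("reference_id") or al.ids[0]
            cmap = build_coordinate_map(al, ref_id)
            ref_seq = al.row(ref_id).replace("-", "")
            write_variants(vt, cmap, ref_seq, out / "variants.tsv", out / "variants.vcf",
                           chrom=ref_id)
            files = [out / "variants.tsv", out / "variants.vcf"]
            report_lines.append(
                f"variants: {vt.n_snvs} SNVs, {ie.n_events} indel events "
                f"({ie.n_columns} indel columns)"
            )
            markers_a = cfg.variants.get("markers_a")
            markers_b = cfg.variants.get("markers_b")
            if markers_a is None and markers_b is None and vt.n_snvs:
                # demo stand-in lists: overlapping subsets of the planted SNVs
                ref_positions = sorted(
                    p for p in (cmap.to_ref(x) for x in vt.positions()) if p is not None
                )
                k = len(ref_positions)
                list_a, list_b = ref_positions[: 2 * k // 3], ref_positions[k // 3 :]
                for name, lst in (("markers_a", list_a), ("markers_b", list_b)):
                    (out / f"{name}.tsv").write_text("".join(f"{p}\n" for p in lst))
                markers_a, markers_b = out / "markers_a.tsv", out / "markers_b.tsv"
                files += [markers_a, markers_b]
            if markers_a is not None and markers_b is not None:
                mi = intersect_markers(vt, cmap, markers_a, markers_b)
                state["markers"] = mi
                (out / "marker_intersection.tsv").write_text(
                    "".join(f"{k}\t{v}\n" for k, v in mi.sizes.items())
                )
                files.append(out / "marker_intersection.tsv")
                report_lines.append(
                    "variants: marker intersection "
                    + ", ".join(f"{k}={v}" for k, v in mi.sizes.items())
                )
            state.update(variant_table=vt, indels=ie, cmap=cmap)
            finish_stage("variants", t0, files)

        if cfg.stages["tree"]:
            t0 = time.monotonic()
            pop = state.get("population")
            if pop is None:
                raise ConfigError("tree stage needs the population simulation upstream")
            tr = cfg.tree
            tree = bootstrap_support(pop.alignment, n_reps=tr["bootstrap"], seed=tr["seed"],
                                     mode=tr["mode"])
            files = [out / "tree.nwk"]
            outgroup = tr.get("outgroup") or []
            verdict = None
            if outgroup:
                rooted = root_tree(tree, outgroup)
                write_tree(rooted, out / "tree.nwk")
                if tr.get("query"):
                    verdict = clade_test(rooted, tr["query"])
                    (out / "monophyly.txt").write_text(verdict.as_text())
                    files.append(out / "monophyly.txt")
            else:
                write_tree(tree, out / "tree.nwk")
            state["tree"] = tree
            finish_stage("tree", t0, files)
            report_lines.append(
                f"tree: NJ ({tr['mode']}), {tr['bootstrap']} bootstrap replicates"
            )
            if verdict is not None:
                report_lines.append(
                    f"tree: query {sorted(verdict.query)} monophyletic={verdict.is_monophyletic} "
                    f"min_clades={verdict.min_clades}"
                )
    finally:
        report = "\n".join(report_lines) + "\n"
        (out / "report.txt").write_text(report)
        manifest.to_json(out / "manifest.json")
    return manifest, report
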