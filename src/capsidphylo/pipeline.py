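"""End-to-end structure-vs-sequence phylogeny runs.

One call executes the whole analysis the library implements piecewise:
trim N-terminal arms, build the all-vs-all core-RMSD matrix and its NJ
tree, align the sequences and build the bootstrapped NJ sequence tree,
profile every structure against a designated reference, and compare the
two trees (Robinson-Foulds, host-clade monophyly).  Every artifact is
written to the output directory together with a plain-text log and a
machine-readable JSON manifest holding all parameters and the seed.
"""

from __future__ import annotations

import json
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .phylo import (
    all_vs_all_matrix,
    bootstrap_support,
    host_monophyly,
    nj_build,
    progressive_msa,
    rf_distance,
    write_newick,
)
from .profile import (
    RegionSpec,
    average_profiles,
    per_residue_deviation,
    profiles_table,
    region_summary,
    write_attribute_file,
)
from .structio import (
    SequenceRecord,
    parse_segment_spec,
    read_ca_structure,
    read_fasta,
    write_fasta,
)
from .superpose import AlignParams, pair_align, trim_nterm_arm


@dataclass(frozen=True)
class StructureInput:
    path: str
    label: str
    chain: str | None = None
    trim_boundary: int | None = None
    predicted: bool = False


@dataclass
class RunConfig:
    """Full-pipeline configuration (a TOML file mirrors these fields)."""

    structures: list[StructureInput]
    outdir: str
    reference: str | None = None
    sequences_path: str | None = None
    regions: list[RegionSpec] = field(default_factory=list)
    hosts: dict[str, str] = field(default_factory=dict)
    align_params: AlignParams = field(default_factory=AlignParams)
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels):
            raise ValueError("structure labels must be unique")
        for s in self.structures:
            if not Path(s.path).exists():
                raise FileNotFoundError(s.path)

    @staticmethod
    def from_toml(path: str | Path, **overrides) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        base = Path(path).parent
        structures = [
            StructureInput(
                path=str((base / s["path"]).resolve()),
                label=s.get("label", Path(s["path"]).stem),
                chain=s.get("chain"),
                trim_boundary=s.get("trim_boundary"),
                predicted=s.get("predicted", False),
            )
            for s in raw.get("structures", [])
        ]
        regions = [
            RegionSpec(name, parse_segment_spec(spec))
            for name, spec in raw.get("regions", {}).items()
        ]
        ap = raw.get("align", {})
        cfg = dict(
            structures=structures,
            outdir=str(base / raw.get("outdir", "pipeline_out")),
            reference=raw.get("reference"),
            sequences_path=(
                str((base / raw["sequences"]).resolve()) if "sequences" in raw else None
            ),
            regions=regions,
            hosts=raw.get("hosts", {}),
            align_params=AlignParams(
                d0=ap.get("d0", 5.0),
                gap_open=ap.get("gap_open", -1.0),
                gap_extend=ap.get("gap_extend", -0.1),
                max_iter=ap.get("max_iter", 20),
                core_cutoff=ap.get("core_cutoff", 4.0),
            ),
            bootstrap_reps=raw.get("bootstrap_reps", 1000),
            seed=raw.get("seed", 0),
        )
        cfg.update(overrides)
        return RunConfig(**cfg)


def read_host_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (label, host), optional header line."""
    hosts = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        lab, host = line.split("\t")[:2]
        if lab.lower() == "label":
            continue
        hosts[lab] = host
    return hosts


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_structure_phylogeny_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict (also written as
    ``summary.json``).  Any stage failure aborts with the stage name and
    leaves a FAILED marker next to the partial outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        line = f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}"
        log_lines.append(line)

    def fail(stage: str, exc: Exception):
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, exc) from exc

    summary: dict = {}
    log(f"capsidphylo {__version__}, python {sys.version.split()[0]}")
    log(f"seed={config.seed} bootstrap_reps={config.bootstrap_reps} "
        f"align={config.align_params}")

    # --- load structures
    try:
        structures = [
            read_ca_structure(s.path, chain=s.chain, label=s.label, predicted=s.predicted)
            for s in config.structures
        ]
        if len(structures) < 3:
            raise ValueError("phylogeny needs >= 3 structures")
        trim = {
            s.label: s.trim_boundary
            for s in config.structures
            if s.trim_boundary is not None
        }
        log(f"loaded {len(structures)} structures; trim boundaries for {sorted(trim)}")
    except Exception as exc:
        fail("load", exc)

    # --- structure tree
    try:
        dm = all_vs_all_matrix(structures, config.align_params, trim)
        (outdir / "structure_distmat.phylip").write_text(dm.to_phylip())
        struct_tree = nj_build(dm)
        (outdir / "structure_tree.nwk").write_text(write_newick(struct_tree))
        summary["n_structures"] = len(structures)
        summary["mean_pairwise_rmsd"] = float(
            dm.d[~(dm.d == 0)].mean() if (dm.d > 0).any() else 0.0
        )
        log(f"all-vs-all matrix done; mean off-diagonal RMSD "
            f"{summary['mean_pairwise_rmsd']:.3f} A")
    except Exception as exc:
        fail("structure_tree", exc)

    # --- sequence tree
    try:
        if config.sequences_path:
            seqs = read_fasta(config.sequences_path)
        else:
            seqs = [SequenceRecord(s.label, s.sequence) for s in structures]
        msa = progressive_msa(seqs)
        write_fasta(msa.records, outdir / "alignment.fasta")
        seq_tree = bootstrap_support(msa, config.bootstrap_reps, config.seed)
        (outdir / "sequence_tree.nwk").write_text(write_newick(seq_tree))
        log(f"sequence tree built ({config.bootstrap_reps} bootstrap replicates)")
    except Exception as exc:
        fail("sequence_tree", exc)

    # --- profiles against the reference
    try:
        ref_label = config.reference or structures[0].label
        by_label = {s.label: s for s in structures}
        ref = by_label[ref_label]
        if ref_label in trim:
            ref = trim_nterm_arm(ref, trim[ref_label])
        profiles = {}
        for s in structures:
            if s.label == ref_label:
                continue
            other = trim_nterm_arm(s, trim[s.label]) if s.label in trim else s
            corr, sup = pair_align(ref, other, config.align_params)
            profiles[s.label] = per_residue_deviation(ref, other, corr, sup)
        mean_prof = average_profiles(list(profiles.values()))
        profiles_table(profiles, mean_prof).to_csv(
            outdir / "profile.tsv", sep="\t", index=False, float_format="%.4f"
        )
        write_attribute_file(mean_prof, outdir / "mean_profile.attr")
        if config.regions:
            region_summary(mean_prof, config.regions).to_csv(
                outdir / "region_summary.tsv", sep="\t", index=False
            )
        summary["reference"] = ref_label
        summary["max_mean_profile"] = float(max(mean_prof.values.values()))
        log(f"profiles vs {ref_label} done; max averaged deviation "
            f"{summary['max_mean_profile']:.2f} A")
    except Exception as exc:
        fail("profiles", exc)

    # --- tree comparison + hosts
    try:
        summary["rf_structure_vs_sequence"] = rf_distance(struct_tree, seq_tree)
        log(f"RF(structure tree, sequence tree) = "
            f"{summary['rf_structure_vs_sequence']}")
        if config.hosts:
            report = host_monophyly(struct_tree, config.hosts)
            report.to_csv(outdir / "host_report_structure.tsv", sep="\t", index=False)
            report_seq = host_monophyly(seq_tree, config.hosts)
            report_seq.to_csv(outdir / "host_report_sequence.tsv", sep="\t", index=False)
            summary["hosts_monophyletic_structure"] = int(report["monophyletic"].sum())
            summary["hosts_monophyletic_sequence"] = int(report_seq["monophyletic"].sum())
    except Exception as exc:
        fail("compare", exc)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "bootstrap_reps": config.bootstrap_reps,
        "align_params": vars(config.align_params).copy()
        if hasattr(config.align_params, "__dict__")
        else {
            "d0": config.align_params.d0,
            "gap_open": config.align_params.gap_open,
            "gap_extend": config.align_params.gap_extend,
            "max_iter": config.align_params.max_iter,
            "core_cutoff": config.align_params.core_cutoff,
        },
        "structures": [vars(s).copy() if hasattr(s, "__dict__") else s.path
                       for s in config.structures],
        "summary": summary,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
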