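"""End-to-end orchestration: from genomes (or a supplied alignment) to the
report bundle — coding alignment, event tables, branch counts, distance
matrices, likelihood/clock reports, dated tree and a reproducibility
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import align_genomes
from .chronology import (ClockCalibration, calibrate_rate, chronology_table,
                         date_nodes, write_chronology)
from .distances import (bootstrap_se, distance_matrix, p_distance,
                        tn93_gamma_distance, write_phylip_matrix)
from .genome import (AnnotatedGenome, extract_coding_alignment,
                     read_alignment, read_genome, write_alignment)
from .likelihood import (SubstitutionModel, alrt_support, clock_lrt,
                         optimize_branch_lengths)
from .trees import RootedTree
from .variants import (annotate_events, call_events, find_islands,
                       classify_sharing, map_to_branches, merge_micro_events,
                       write_branch_counts, write_event_table)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    genome_paths: list[str] = field(default_factory=list)
    genome_format: str = "genbank"
    alignment_path: str | None = None     # bypass internal alignment
    region_tables: dict[str, str] = field(default_factory=dict)
    root_id: str = ""
    focal_taxa: list[str] = field(default_factory=list)
    topology: str = ""                    # newick text or path
    calibration_taxa: list[str] = field(default_factory=list)
    calibration_age: float = 0.0
    gamma_shape: float = 0.1
    bootstrap_replicates: int = 1000
    complete_deletion: bool = False
    merge_max_gap: int = 2
    merge_min_components: int = 3
    island_max_gap: int = 60
    island_min_events: int = 4
    exclude_dloop: bool = True
    out_dir: str = "bovimito_out"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if not self.genome_paths and not self.alignment_path:
            raise ValueError("no genomes or alignment supplied")
        if not self.root_id:
            raise ValueError("root_id is required")
        if self.calibration_taxa and self.calibration_age <= 0:
            raise ValueError("calibration age must be positive")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict.

    Deterministic for a fixed seed.  Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are preserved in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "bovimito", "version": __version__, "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items()
                       if not k.startswith("_")},
        "inputs": {},
        "artifacts": {},
    }
    stage = "load"
    try:
        genomes: dict[str, AnnotatedGenome] = {}
        for p in config.genome_paths:
            g = read_genome(p, config.genome_format,
                            region_table=config.region_tables.get(
                                Path(p).stem))
            genomes[g.id] = g
            manifest["inputs"][str(p)] = _sha256(p)

        stage = "align"
        if config.alignment_path:
            aln = read_alignment(config.alignment_path, ref_id=config.root_id
                                 if config.root_id else None)
            manifest["inputs"][str(config.alignment_path)] = _sha256(
                config.alignment_path)
        else:
            aln = align_genomes(list(genomes.values()), config.root_id)
        write_alignment(aln, out / "aligned.fasta")
        manifest["artifacts"]["aligned.fasta"] = True

        stage = "coding-extraction"
        if config.exclude_dloop and genomes:
            coding = extract_coding_alignment(aln, genomes)
        else:
            coding = aln
        write_alignment(coding, out / "coding.fasta")
        manifest["artifacts"]["coding.fasta"] = True
        manifest["coding_columns"] = coding.length

        stage = "variant-catalog"
        events = call_events(coding, config.root_id)
        merged = merge_micro_events(events, config.merge_max_gap,
                                    config.merge_min_components)
        if genomes.get(config.root_id):
            merged = annotate_events(merged, genomes[config.root_id])
        write_event_table(merged, out / "events.tsv")
        manifest["artifacts"]["events.tsv"] = True
        manifest["event_counts"] = {
            "raw": len(events), "merged": len(merged)}

        tree: RootedTree | None = None
        if config.topology:
            text = config.topology
            if Path(text).exists():
                text = Path(text).read_text()
            tree = RootedTree.from_newick(text)

        if config.focal_taxa and tree is not None:
            stage = "branch-mapping"
            patterns = classify_sharing(merged, config.focal_taxa,
                                        config.root_id)
            counts = map_to_branches(patterns, tree)
            write_branch_counts(counts, out / "branch_counts.tsv")
            manifest["artifacts"]["branch_counts.tsv"] = True
            # raw (unmerged) tally alongside the merged one
            raw_counts = map_to_branches(
                classify_sharing(events, config.focal_taxa, config.root_id),
                tree)
            manifest["branch_counts"] = {
                "merged": {k: v[1] for k, v in counts.branch_counts.items()},
                "raw": {k: v[1] for k, v in raw_counts.branch_counts.items()},
            }

        stage = "distances"
        pmat = distance_matrix(coding, p_distance,
                               complete_deletion=config.complete_deletion)
        pmat.to_csv(out / "p_distances.tsv", sep="\t", float_format="%.6g")
        tmat = distance_matrix(coding, tn93_gamma_distance,
                               shape=config.gamma_shape,
                               complete_deletion=config.complete_deletion)
        tmat.to_csv(out / "tn93_distances.tsv", sep="\t", float_format="%.6g")
        write_phylip_matrix(tmat, out / "tn93_distances.phy")
        if config.bootstrap_replicates >= 2:
            import pandas as pd

            taxa = coding.taxa
            se = pd.DataFrame(0.0, index=taxa, columns=taxa)
            for i, a in enumerate(taxa):
                for b in taxa[i + 1:]:
                    v = bootstrap_se(coding, a, b, p_distance,
                                     replicates=config.bootstrap_replicates,
                                     seed=config.seed,
                                     complete_deletion=config.complete_deletion)
                    se.loc[a, b] = se.loc[b, a] = v
            se.to_csv(out / "p_distance_se.tsv", sep="\t",
                      float_format="%.6g")
            manifest["artifacts"]["p_distance_se.tsv"] = True
        manifest["artifacts"]["p_distances.tsv"] = True
        manifest["artifacts"]["tn93_distances.tsv"] = True

        if tree is not None:
            stage = "likelihood"
            model = SubstitutionModel.from_alignment(
                coding, alpha=config.gamma_shape if config.gamma_shape > 0
                else 1.0)
            opt_tree, opt_model, lnl = optimize_branch_lengths(
                coding, tree, model, optimize_model=True)
            manifest["lnL"] = lnl
            manifest["gamma_shape_mle"] = opt_model.alpha
            manifest["ts_tv_ratio"] = opt_model.kappa
            supports = alrt_support(coding, opt_tree, opt_model)
            (out / "optimized.nwk").write_text(
                opt_tree.to_newick(supports=True) + "\n")
            manifest["artifacts"]["optimized.nwk"] = True
            manifest["alrt_supports"] = {k: v for k, v in supports.items()}

            stage = "clock-test"
            clock = clock_lrt(coding, tree, opt_model)
            manifest["clock_lrt"] = {
                "lnL_free": clock.lnl_free, "lnL_clock": clock.lnl_clock,
                "statistic": clock.statistic, "df": clock.df,
                "p_value": clock.p_value}

            if config.calibration_taxa:
                stage = "dating"
                calib = ClockCalibration(frozenset(config.calibration_taxa),
                                         config.calibration_age)
                rate = calibrate_rate(opt_tree, calib)
                dated = date_nodes(opt_tree, rate)
                rows = chronology_table(dated, rate)
                write_chronology(rows, out / "chronology.tsv")
                (out / "dated.nwk").write_text(
                    dated.to_newick(ages=True) + "\n")
                manifest["artifacts"]["chronology.tsv"] = True
                manifest["artifacts"]["dated.nwk"] = True
                manifest["rate_subs_per_site_per_year"] = rate.rate
                manifest["node_ages_years"] = {
                    r["node"]: r["age_years"] for r in rows}

        if len(coding.taxa) == 2:
            stage = "two-genome-comparison"
            islands = find_islands(events, config.island_max_gap,
                                   config.island_min_events,
                                   genome=genomes.get(config.root_id))
            subs = sum(1 for e in events if e.kind == "substitution")
            indels = sum(1 for e in events if e.is_indel)
            report = {
                "total_differences": len(events),
                "substitutions": subs, "indels": indels,
                "islands": [vars(i) for i in islands],
            }
            (out / "two_genome_report.json").write_text(
                json.dumps(report, indent=2, default=list) + "\n")
            manifest["artifacts"]["two_genome_report.json"] = True
            manifest["two_genome"] = {k: report[k] for k in
                                      ("total_differences", "substitutions",
                                       "indels")}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
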