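"""End-to-end orchestration and knowledgebase export.

run_pipeline executes the full analysis: homolog search against a
sequence database, extension of the seed alignment, gap-fraction
trimming, distance + neighbor-joining tree inference with bootstrap
supports (several independent bootstrap runs, plus any externally
computed trees), consensus subfamily extraction, per-sequence
annotation (cofactor call, triad report, conservation), kinetics
aggregation and a JSON/CSV knowledgebase bundle.  Re-running with the
same config and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as sio
from .features import RegionDefinitions, cofactor_preference, triad_check
from .kinetics import family_summary
from .msa import Alignment, add_to_seed, conservation, reference_numbering, trim_columns
from .pairwise import ScoringScheme, collect_homologs
from .phylo import bootstrap_supports, distance_matrix, nj_tree
from .subfamilies import SubfamilyPartition, consensus_subfamilies

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    seed_alignment: str
    database: str
    out_dir: str
    trees: list[str] = field(default_factory=list)
    kinetics_table: str | None = None
    regions_file: str | None = None
    reference_id: str | None = None  # default: first seed row
    e_max: float = 1e-3
    coverage: float = 0.9
    gap_fraction: float = 0.8
    support: float = 0.5
    conservation_threshold: float = 0.9
    bootstrap: int = 100
    n_tree_sets: int = 3
    min_size: int = 2
    max_fraction: float = 0.5
    distance_model: str = "poisson"
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in [
            ("coverage", 0.0, 1.0), ("gap_fraction", 0.0, 1.0),
            ("support", 0.0, 1.0), ("conservation_threshold", 0.0, 1.0),
            ("max_fraction", 0.0, 1.0),
        ]:
            val = getattr(self, name)
            if not lo < val <= hi:
                raise ConfigError(f"{name} must be in ({lo}, {hi}], got {val}")
        if self.e_max <= 0:
            raise ConfigError("e_max must be positive")
        if self.bootstrap < 1 or self.n_tree_sets < 1:
            raise ConfigError("bootstrap and n_tree_sets must be >= 1")
        for path in self._input_paths():
            if not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")

    def _input_paths(self) -> list[str]:
        paths = [self.seed_alignment, self.database, *self.trees]
        for opt in (self.kinetics_table, self.regions_file):
            if opt:
                paths.append(opt)
        return paths

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class KnowledgebaseBundle:
    """Flat, serializable view of one pipeline run."""

    schema_version: str
    tree_newick: str
    proteins: list[dict]  # per-protein annotation records
    kinetics_summary: dict | None
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "knowledgebase.json").write_text(self.to_json())
        import csv

        with open(out_dir / "subfamilies.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["protein_id", "subfamily"])
            for rec in self.proteins:
                writer.writerow([rec["protein_id"], rec["subfamily"]])


def export_knowledgebase(partition: SubfamilyPartition, annotations: dict,
                         kinetics_summary: dict | None, tree,
                         provenance: dict | None = None) -> KnowledgebaseBundle:
    """Assemble a knowledgebase bundle over a common protein-id namespace.

    Proteins present in the kinetics summary but absent from the tree
    are kept and flagged external.
    """
    tree_leaves = {t.name for t in tree.tips()}
    proteins = []
    ids = sorted(set(annotations) | partition.all_leaves)
    orphans = sorted(set(annotations) - tree_leaves)
    for pid in ids:
        rec = {
            "protein_id": pid,
            "subfamily": partition.subfamily_of(pid),
            "external": pid not in tree_leaves,
        }
        rec.update(annotations.get(pid, {}))
        proteins.append(rec)
    if orphans:
        logger.info("%d proteins flagged external (not in tree)", len(orphans))
    return KnowledgebaseBundle(
        schema_version="1",
        tree_newick=sio.tree_to_newick(tree),
        proteins=proteins,
        kinetics_summary=kinetics_summary,
        provenance=provenance or {},
    )


def run_pipeline(cfg: PipelineConfig) -> KnowledgebaseBundle:
    """Run every stage in order and write all intermediates to cfg.out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    def log(stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        stage_log.append(entry)
        logger.info("stage %s: %s", stage, counts)

    scheme = ScoringScheme()
    seed_aln = Alignment.from_records(sio.read_fasta(cfg.seed_alignment))
    database = sio.read_fasta(cfg.database)
    log("load", seed_rows=seed_aln.n_rows, seed_columns=seed_aln.length,
        database_sequences=len(database))

    seed_ids = set(seed_aln.ids)
    queries = [r.ungap() for r in seed_aln.records]
    candidates = [r for r in database if r.id not in seed_ids]
    hits = collect_homologs(queries, candidates, e_max=cfg.e_max,
                            cov_min=cfg.coverage, s=scheme)
    hit_ids = {h.db_id for h in hits}
    log("search", candidates=len(candidates), hits=len(hits))
    with open(out / "hits.csv", "w") as fh:
        fh.write("db_id,best_query,score,evalue,coverage,identity\n")
        for h in sorted(hits, key=lambda h: h.db_id):
            fh.write(f"{h.db_id},{h.best_query},{h.score:g},{h.evalue:.3g},"
                     f"{h.coverage:.3f},{h.identity}\n")

    new_seqs = [r for r in database if r.id in hit_ids]
    extended, dropped = add_to_seed(seed_aln, new_seqs, scheme)
    log("extend", rows=extended.n_rows, dropped_insertions=sum(map(len, dropped.values())))
    sio.write_fasta(list(extended.records), out / "extended.fasta")

    trimmed, removed = trim_columns(extended, cfg.gap_fraction)
    log("trim", columns_in=extended.length, columns_removed=len(removed),
        columns_out=trimmed.length)
    sio.write_fasta(list(trimmed.records), out / "trimmed.fasta")

    dm = distance_matrix(trimmed, model=cfg.distance_model)
    reference_tree = nj_tree(dm)
    trees = []
    for k in range(cfg.n_tree_sets):
        boot = bootstrap_supports(trimmed, reference_tree, n=cfg.bootstrap,
                                  model=cfg.distance_model, seed=cfg.seed + k)
        trees.append(boot)
        sio.write_newick(boot, out / f"nj_boot{k + 1}.nwk")
    log("tree", leaves=trimmed.n_rows, bootstrap=cfg.bootstrap, tree_sets=cfg.n_tree_sets)

    for path in cfg.trees:
        trees.append(sio.read_newick(path))
    if cfg.trees:
        log("import_trees", external_trees=len(cfg.trees))

    partition = consensus_subfamilies(trees, min_support=cfg.support,
                                      min_size=cfg.min_size,
                                      max_fraction=cfg.max_fraction)
    log("subfamilies", n_subfamilies=len(partition.subfamilies),
        unassigned=len(partition.unassigned))
    with open(out / "partition.csv", "w") as fh:
        fh.write("leaf_id,subfamily\n")
        for leaf, name in partition.labels().items():
            fh.write(f"{leaf},{name}\n")

    ref_id = cfg.reference_id or seed_aln.ids[0]
    refmap = reference_numbering(trimmed, ref_id)
    regions = (RegionDefinitions.from_toml(cfg.regions_file)
               if cfg.regions_file else RegionDefinitions.default())
    profile = conservation(trimmed)
    annotations = {}
    for rec in trimmed.records:
        call = cofactor_preference(rec, regions, refmap)
        triad = triad_check(rec, refmap)
        annotations[rec.id] = {
            "cofactor_call": call.call,
            "cofactor_evidence": call.evidence,
            "triad_canonical": triad.all_canonical,
            "triad": {str(e.position): e.observed for e in triad.entries},
        }
    log("annotate", rows=len(annotations),
        conserved_columns=int((profile.modal_frequency > cfg.conservation_threshold).sum()))

    kin_summary = None
    if cfg.kinetics_table:
        records = sio.read_table(cfg.kinetics_table, "kinetics")
        kin_summary = family_summary(records)
        log("kinetics", records=len(records),
            pairs_with_efficiency=kin_summary["n_pairs_with_efficiency"])

    provenance = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "package_version": __version__,
        "stages": stage_log,
    }
    bundle = export_knowledgebase(partition, annotations, kin_summary,
                                  trees[0], provenance)
    bundle.write(out)
    cfg.to_file(out / "config.effective.yaml")
    with open(out / "stages.jsonl", "w") as fh:
        for entry in stage_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    log("export", proteins=len(bundle.proteins))
    return bundle
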