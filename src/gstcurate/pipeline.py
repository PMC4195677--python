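"""End-to-end orchestration: bundle I/O, configuration and the full run.

A *bundle* is a directory holding one species' data in plain-text formats:
``genome.fasta``, ``models.gff3``, ``proteins.fasta``, ``anchors.json`` and
(for templates with spliced genes) ``isoforms.json``; targets additionally
carry the ground-truth ``ledger.json``.  ``run_pipeline`` simulates a
template family, derives diverged defect-bearing targets, and emits per
target the curation TSV/JSON/GFF3 reports, the splice-support TSV, the
synteny event TSV and per-class newick trees, plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .curation import (CatalyticAnchor, CurationConfig, curate_panel,
                       write_reports)
from .genome import (extract_cds, read_genome, read_gff3, read_fasta,
                     translate_cds, write_fasta, write_gff3)
from .phylo import distance_matrix, neighbor_joining, to_newick
from .simulate import (DEFECT_KINDS, FamilyBundle, FamilySpec,
                       GroundTruthRecord, _compatible, evolve_target,
                       generate_family, inject_error, inject_rearrangement,
                       ledger_to_json)
from .splice import (IsoformTemplate, SpliceConfig, TemplateExon,
                     TemplateIsoform, project_isoforms, projection_to_frame)
from .synteny import compare_maps, events_to_frame


@dataclass
class TargetSpec:
    species_tag: str
    divergence: float
    n_defects: int = 8


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "gstcurate_run"
    genes_per_cluster: tuple[int, ...] = (11, 14, 4, 4, 1, 2)
    targets: list[TargetSpec] = field(default_factory=lambda: [
        TargetSpec("Dsim", 0.02), TargetSpec("Dyak", 0.05),
        TargetSpec("Dvir", 0.10)])
    curation: CurationConfig = field(default_factory=CurationConfig)
    splice: SpliceConfig = field(default_factory=SpliceConfig)
    phylo_k: int = 20
    tree_gap_penalty: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "targets" in raw:
            raw["targets"] = [TargetSpec(**t) if isinstance(t, dict) else t
                              for t in raw["targets"]]
        if isinstance(raw.get("curation"), dict):
            raw["curation"] = CurationConfig(**raw["curation"])
        if isinstance(raw.get("splice"), dict):
            raw["splice"] = SpliceConfig(**raw["splice"])
        if "genes_per_cluster" in raw:
            raw["genes_per_cluster"] = tuple(raw["genes_per_cluster"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        checks = [
            ("curation.k_max", 1 <= self.curation.k_max <= 4),
            ("curation.max_edits", 1 <= self.curation.max_edits <= 4),
            ("curation.length_frac", 0 < self.curation.length_frac < 1),
            ("curation.rescue_window", self.curation.rescue_window > 0),
            ("splice.min_intron", self.splice.min_intron >= 4),
            ("splice.anchor_floor", 0 < self.splice.anchor_floor <= 1),
            ("phylo_k", self.phylo_k in (4, 20)),
        ]
        for t in self.targets:
            checks.append((f"targets[{t.species_tag}].divergence",
                           0 <= t.divergence < 0.5))
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError("invalid config keys: " + ", ".join(bad))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(bundle: FamilyBundle, out_dir: str | Path,
                 ledger: list[GroundTruthRecord] | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome.scaffolds, out / "genome.fasta")
    write_gff3(bundle.models, out / "models.gff3")
    write_fasta(bundle.proteins, out / "proteins.fasta")
    anchors = {k: list(a.positions) for k, a in bundle.anchors.items()}
    (out / "anchors.json").write_text(json.dumps(anchors, indent=1))
    iso = {}
    for label, tpl in bundle.isoform_templates.items():
        iso[label] = [{"tag": i.tag,
                       "exons": [{"seq": e.seq, "role": e.role}
                                 for e in i.exons],
                       "utr5": i.utr5, "utr3": i.utr3}
                      for i in tpl.isoforms]
    (out / "isoforms.json").write_text(json.dumps(iso, indent=1))
    if ledger is not None:
        ledger_to_json(ledger, out / "ledger.json")


def read_bundle(in_dir: str | Path, species_tag: str) -> FamilyBundle:
    d = Path(in_dir)
    genome = read_genome(d / "genome.fasta", species_tag)
    models = read_gff3(d / "models.gff3", genome)
    proteins = read_fasta(d / "proteins.fasta")
    anchors = {}
    if (d / "anchors.json").exists():
        raw = json.loads((d / "anchors.json").read_text())
        anchors = {k: CatalyticAnchor(k, tuple(v)) for k, v in raw.items()}
    iso_templates = {}
    if (d / "isoforms.json").exists():
        raw = json.loads((d / "isoforms.json").read_text())
        for label, items in raw.items():
            iso_templates[label] = IsoformTemplate(label, [
                TemplateIsoform(i["tag"],
                                [TemplateExon(e["seq"], e["role"])
                                 for e in i["exons"]],
                                utr5=i.get("utr5"), utr3=i.get("utr3"))
                for i in items])
    return FamilyBundle(species_tag, genome, models, proteins, anchors,
                        iso_templates)


# ---------------------------------------------------------------------------
# stage drivers
# ---------------------------------------------------------------------------

def make_target(template: FamilyBundle, tspec: TargetSpec, seed: int
                ) -> tuple[FamilyBundle, list[GroundTruthRecord]]:
    target = evolve_target(template, tspec.divergence, seed,
                           tspec.species_tag)
    rng = np.random.default_rng(seed + 1)
    ledger: list[GroundTruthRecord] = []
    plain = [m for m in target.models
             if m.ortholog_label not in template.isoform_templates]
    if tspec.n_defects and plain:
        step = max(1, len(plain) // tspec.n_defects)
        ki = 0
        for m in plain[::step][: tspec.n_defects]:
            for attempt in range(len(DEFECT_KINDS)):
                kind = DEFECT_KINDS[(ki + attempt) % len(DEFECT_KINDS)]
                if not _compatible(kind, m):
                    continue
                try:
                    ledger.append(inject_error(target, m.gene_id, kind, rng))
                except Exception:
                    continue
                ki += attempt + 1
                break
    return target, ledger


def run_curation(template: FamilyBundle, target: FamilyBundle,
                 out_dir: Path, cfg: CurationConfig):
    verdicts = curate_panel(target.genome, target.models, template.proteins,
                            template.anchors, cfg)
    write_reports(verdicts, target.models, out_dir)
    return verdicts


def run_splice(template: FamilyBundle, target: FamilyBundle, out_dir: Path,
               cfg: SpliceConfig):
    results = []
    for label, tpl in template.isoform_templates.items():
        try:
            gene = target.model_by_label(label)
        except KeyError:
            continue
        a, b = gene.span
        scaffold = target.genome[gene.scaffold_id]
        locus = scaffold[max(0, a - 300): min(len(scaffold), b + 300)]
        results.append(project_isoforms(tpl, locus, cfg))
    df = projection_to_frame(results)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "splice_support.tsv", sep="\t", index=False)
    return results


def run_synteny(template: FamilyBundle, target: FamilyBundle, out_dir: Path,
                seed: int, shuffle: bool = True):
    tmap = template.gene_map()
    gmap = target.gene_map()
    if shuffle:
        rng = np.random.default_rng(seed)
        gmap, _ = inject_rearrangement(gmap, "INVERT_BLOCK", rng)
        gmap, _ = inject_rearrangement(gmap, "TRANSPOSE_GENE", rng)
    cmp = compare_maps(tmap, gmap)
    out_dir.mkdir(parents=True, exist_ok=True)
    events_to_frame(cmp["events"]).to_csv(out_dir / "synteny_events.tsv",
                                          sep="\t", index=False)
    (out_dir / "synteny_summary.json").write_text(json.dumps(
        {"breakpoint_distance": cmp["breakpoint_distance"],
         "permutation": cmp["permutation"].values}, indent=1))
    return cmp


def run_trees(template: FamilyBundle, targets: list[FamilyBundle],
              out_dir: Path, k: int = 20):
    out_dir.mkdir(parents=True, exist_ok=True)
    trees = {}
    for klass in sorted({m.class_label for m in template.models}):
        labels = [m.ortholog_label for m in template.models
                  if m.class_label == klass]
        seqs: dict[str, str] = {}
        for label in labels:
            seqs[f"{template.species_tag}_{label}"] = \
                template.proteins[label]
        for tgt in targets:
            for label in labels:
                try:
                    gene = tgt.model_by_label(label)
                except KeyError:
                    continue
                tr = translate_cds(extract_cds(tgt.genome, gene),
                                   partial=True)
                if tr.stop_free and tr.length_aa > 0:
                    seqs[f"{tgt.species_tag}_{label}"] = tr.protein
        if len(seqs) < 3:
            continue
        try:
            dm = distance_matrix(seqs, k=k)
        except Exception:
            continue
        tree = neighbor_joining(dm)
        text = to_newick(tree)
        (out_dir / f"tree_{klass}.nwk").write_text(text + "\n")
        dm.to_tsv(out_dir / f"distances_{klass}.tsv")
        trees[klass] = tree
    return trees


def run_pipeline(cfg: PipelineConfig) -> dict:
    """The full synthetic 'paper run'; returns a summary dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = FamilySpec(genes_per_cluster=cfg.genes_per_cluster, seed=cfg.seed)
    template = generate_family(spec)
    write_bundle(template, out / "template")
    summary = {"targets": {}}
    targets = []
    for i, tspec in enumerate(cfg.targets):
        target, ledger = make_target(template, tspec, cfg.seed + 101 * (i + 1))
        targets.append(target)
        tdir = out / tspec.species_tag
        write_bundle(target, tdir, ledger)
        verdicts = run_curation(template, target, tdir, cfg.curation)
        run_splice(template, target, tdir, cfg.splice)
        cmp = run_synteny(template, target, tdir, cfg.seed + 7 * (i + 1))
        cat_counts: dict[str, int] = {}
        for v in verdicts:
            cat_counts[v.category] = cat_counts.get(v.category, 0) + 1
        summary["targets"][tspec.species_tag] = {
            "divergence": tspec.divergence,
            "n_genes": len(target.models),
            "categories": cat_counts,
            "breakpoint_distance": cmp["breakpoint_distance"],
        }
    trees = run_trees(template, targets, out / "trees", cfg.phylo_k)
    summary["n_trees"] = len(trees)
    manifest = {"version": __version__, "config": asdict(cfg),
                "config_hash": cfg.digest(), "seed": cfg.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    summary["manifest"] = manifest
    return summary
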