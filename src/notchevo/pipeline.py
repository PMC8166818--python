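"""End-to-end pipeline orchestration and the packaged fixture bundle.

``run_pipeline`` wires the stages — classify, gain/loss, truncation,
expression, tree — over a :class:`PipelineManifest` of input paths, and
writes TSV outputs plus a machine-readable JSON run report.  Every output
file carries a provenance header with the config hash and seed, and a run
is byte-reproducible given the same manifest and seed.

``make_fixtures`` emits a complete synthetic dataset with a truth
manifest: planted architectures for every family signature, four planted
truncation mutations (one per mechanism), the mollusc case-study tree and
paralog-resolved presence/absence matrix (single gain of Delta2 in the
ancestor of gastropods+cephalopods+bivalves, three independent gastropod
losses), a planted-subtype protein alignment, and a ligand expression
matrix in which Delta1/Delta2 are complementary and Jagged tracks Delta2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .architecture import (
    GeneModel,
    build_presence_absence,
    classify_gene,
    default_signatures,
    filter_hits,
    read_signatures,
    resolve_overlaps,
    write_signatures,
)
from .config import RunConfig
from .errors import ValidationError
from .expression import comparison_table, nearest_profile, profile_similarity, stage_peak_report
from .gainloss import annotate_losses, clade_map, gainloss_matrix
from .io_formats import (
    read_domain_hits,
    read_expression_matrix,
    read_fasta,
    read_newick,
    read_presence_absence,
    read_table,
    write_domain_hits,
    write_expression_matrix,
    write_fasta,
    write_presence_absence,
    write_table,
    SequenceRecord,
)
from .phylo import MultipleAlignment, bootstrap_support, root_on_outgroup, assign_subtype_by_clade, trim_alignment
from .truncation import ParalogPair, align_paralogs, classify_mechanism, translate
from . import synthetic

log = logging.getLogger("notchevo")

STAGES = ("classify", "gainloss", "truncation", "expression", "tree")


@dataclasses.dataclass
class PipelineManifest:
    """Input paths and stage selection for one pipeline run.

    Paths may be absent when the corresponding stage is not selected.
    Relative paths are resolved against the manifest file's directory.
    """

    out_dir: Path
    stages: tuple = STAGES
    config: RunConfig = dataclasses.field(default_factory=RunConfig)
    domain_hits: Path | None = None
    proteins: Path | None = None
    species_map: Path | None = None
    signatures: Path | None = None
    species_tree: Path | None = None
    presence_absence: Path | None = None
    cds: Path | None = None
    truncation_pairs: Path | None = None
    expression: Path | None = None
    expression_pairs: Path | None = None
    alignment: Path | None = None
    outgroup: str | None = None
    subtype_references: Path | None = None

    _PATH_KEYS = (
        "domain_hits", "proteins", "species_map", "signatures", "species_tree",
        "presence_absence", "cds", "truncation_pairs", "expression",
        "expression_pairs", "alignment", "subtype_references",
    )

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {', '.join(sorted(unknown))}")
        required = {
            "classify": ("domain_hits", "proteins", "species_map"),
            "gainloss": ("species_tree", "presence_absence"),
            "truncation": ("cds", "truncation_pairs"),
            "expression": ("expression",),
            "tree": ("alignment",),
        }
        for stage in self.stages:
            for key in required[stage]:
                path = getattr(self, key)
                if path is None:
                    raise ValidationError(f"stage {stage!r} requires manifest key {key!r}")
                if not Path(path).exists():
                    raise ValidationError(f"manifest path does not exist: {path}")

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path | None = None) -> "PipelineManifest":
        base = Path(path).parent
        kwargs: dict = {}
        config_path = None
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key: value'")
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key in cls._PATH_KEYS:
                kwargs[key] = base / value
            elif key == "stages":
                kwargs["stages"] = tuple(s.strip() for s in value.split(",") if s.strip())
            elif key == "out_dir":
                kwargs["out_dir"] = base / value
            elif key == "outgroup":
                kwargs["outgroup"] = value
            elif key == "config":
                config_path = base / value
            else:
                raise ValidationError(f"{path}:{lineno}: unknown manifest key {key!r}")
        if out_dir is not None:
            kwargs["out_dir"] = Path(out_dir)
        if "out_dir" not in kwargs:
            raise ValidationError(f"{path}: manifest must declare out_dir")
        if config_path is not None:
            kwargs["config"] = RunConfig.from_file(config_path)
        return cls(**kwargs)


def _load_genes(manifest: PipelineManifest, cfg: RunConfig) -> list[GeneModel]:
    hits = filter_hits(read_domain_hits(manifest.domain_hits), cfg.e_value_threshold)
    proteins = {r.id: r for r in read_fasta(manifest.proteins, "protein")}
    species = dict(
        read_table(manifest.species_map)[["gene_id", "species_id"]].itertuples(
            index=False, name=None
        )
    )
    by_gene: dict[str, list] = {}
    for hit in hits:
        by_gene.setdefault(hit.gene_id, []).append(hit)
    genes = []
    for gene_id in sorted(proteins):
        if gene_id not in species:
            raise ValidationError(f"gene {gene_id!r} missing from species map")
        genes.append(
            GeneModel(
                gene_id,
                species[gene_id],
                proteins[gene_id],
                hits=resolve_overlaps(by_gene.get(gene_id, [])),
            )
        )
    return genes


def _stage_classify(manifest: PipelineManifest, cfg: RunConfig, header: str, report: dict) -> None:
    signatures = (
        read_signatures(manifest.signatures)
        if manifest.signatures
        else default_signatures(cfg)
    )
    genes = _load_genes(manifest, cfg)
    assignments = [(classify_gene(g, signatures, cfg), g.species_id) for g in genes]
    rows = [
        {
            "gene_id": a.gene_id,
            "species_id": sp,
            "family": a.family,
            "domains": ";".join(f"{d}:{n}" for d, n in sorted(a.matched_requirements.items())) or "-",
        }
        for a, sp in assignments
    ]
    write_table(pd.DataFrame(rows), manifest.out_dir / "assignments.tsv", header)
    species = sorted({sp for _, sp in assignments})
    families = sorted({a.family for a, _ in assignments if a.family != "unassigned"})
    presence, counts = build_presence_absence(assignments, species, families)
    write_presence_absence(presence, manifest.out_dir / "classified_presence.tsv", header)
    write_table(
        counts.reset_index().rename(columns={"index": "family"}),
        manifest.out_dir / "classified_gene_counts.tsv",
        header,
    )
    report["classify"] = {
        "n_genes": len(genes),
        "n_unassigned": sum(a.family == "unassigned" for a, _ in assignments),
        "families": families,
    }


def _stage_gainloss(manifest: PipelineManifest, cfg: RunConfig, header: str, report: dict) -> None:
    tree = read_newick(manifest.species_tree)
    matrix = read_presence_absence(manifest.presence_absence)
    histories = gainloss_matrix(tree, matrix)
    rows = []
    for h in histories:
        rows.append(
            {
                "family": h.family,
                "gain_clade": "+".join(sorted(h.gain_edge)),
                "origin_at_root": int(h.origin_at_root),
                "n_losses": h.n_losses,
                "losses": ";".join(annotate_losses(h)) or "-",
            }
        )
    write_table(pd.DataFrame(rows), manifest.out_dir / "gainloss_histories.tsv", header)
    report["gainloss"] = {
        h.family: {
            "gain_clade": sorted(h.gain_edge),
            "n_losses": h.n_losses,
            "losses": annotate_losses(h),
            "origin_at_root": h.origin_at_root,
        }
        for h in histories
    }


def _stage_truncation(manifest: PipelineManifest, cfg: RunConfig, header: str, report: dict) -> None:
    cds = {r.id: r for r in read_fasta(manifest.cds, "dna")}
    pairs = read_table(manifest.truncation_pairs)
    rows = []
    for ref_id, alt_id in pairs[["ref_id", "alt_id"]].itertuples(index=False, name=None):
        for gid in (ref_id, alt_id):
            if gid not in cds:
                raise ValidationError(f"CDS {gid!r} not in {manifest.cds}")

        def _gene(gid: str) -> GeneModel:
            prot, _ = translate(cds[gid].sequence)
            return GeneModel(
                gid,
                "NA",
                SequenceRecord(gid, "", prot or "M", "protein"),
                cds[gid],
            )

        pair = ParalogPair(_gene(ref_id), _gene(alt_id), cfg.anchor_residue)
        rep = classify_mechanism(pair, config=cfg)
        rows.append(
            {
                "ref_id": ref_id,
                "alt_id": alt_id,
                "premature": int(rep.premature),
                "mechanism": rep.mechanism,
                "causal_edit": rep.causal_edit.describe() if rep.causal_edit else "-",
                "alt_stop_codon": rep.alt_stop_codon_index or "-",
                "ref_length_codons": rep.ref_length_codons,
                "anchor_offset": "-" if rep.anchor_offset is None else rep.anchor_offset,
                "within_window": "indeterminate" if rep.within_window is None else int(rep.within_window),
                "n_alternate_edits": len(rep.alternates),
            }
        )
    write_table(pd.DataFrame(rows), manifest.out_dir / "truncation_report.tsv", header)
    report["truncation"] = {
        f"{r['ref_id']}|{r['alt_id']}": {"mechanism": r["mechanism"], "premature": bool(r["premature"])}
        for r in rows
    }


def _stage_expression(manifest: PipelineManifest, cfg: RunConfig, header: str, report: dict) -> None:
    matrix = read_expression_matrix(manifest.expression)
    comparisons = []
    nearest_report: dict = {}
    if manifest.expression_pairs:
        spec_table = read_table(manifest.expression_pairs)
        for kind, a, b in spec_table[["kind", "gene_a", "gene_b"]].itertuples(index=False, name=None):
            if kind == "pair":
                comparisons.append(
                    profile_similarity(
                        matrix.profile(a), matrix.profile(b), "spearman", cfg, a, b
                    )
                )
            elif kind == "nearest":
                candidates = [g.strip() for g in b.split(";")]
                ranking = nearest_profile(a, candidates, matrix, "spearman", cfg)
                comparisons.extend(ranking)
                nearest_report[a] = [c.gene_b for c in ranking]
            else:
                raise ValidationError(f"unknown expression comparison kind {kind!r}")
    write_table(
        comparison_table(comparisons, cfg), manifest.out_dir / "expression_comparisons.tsv", header
    )
    write_table(
        stage_peak_report(matrix, config=cfg), manifest.out_dir / "expression_peaks.tsv", header
    )
    report["expression"] = {
        "comparisons": {
            f"{c.gene_a}|{c.gene_b}": {"score": round(c.score, 6), "relation": c.relation}
            for c in comparisons
        },
        "nearest": nearest_report,
    }


def _stage_tree(manifest: PipelineManifest, cfg: RunConfig, header: str, report: dict) -> None:
    msa = MultipleAlignment(read_fasta(manifest.alignment, "protein"))
    supported = bootstrap_support(
        msa, cfg.bootstrap_reps, cfg.rng_seed, max_gap_fraction=cfg.gap_fraction_trim
    )
    newick = supported.newick_with_support()
    (manifest.out_dir / "tree_with_support.nwk").write_text(f"[{header}]\n{newick}\n")
    report["tree"] = {"n_taxa": len(msa.records), "bootstrap_reps": supported.reps}
    if manifest.subtype_references:
        refs_df = read_table(manifest.subtype_references)
        refs = dict(refs_df[["gene_id", "subtype"]].itertuples(index=False, name=None))
        if manifest.outgroup is None:
            raise ValidationError("subtype assignment requires an outgroup leaf")
        rooted = root_on_outgroup(supported.tree, manifest.outgroup)
        queries = sorted(
            {l.taxon.label for l in rooted.leaf_node_iter()}
            - set(refs)
            - {manifest.outgroup}
        )
        verdicts = assign_subtype_by_clade(rooted, refs, queries)
        write_table(
            pd.DataFrame(
                [{"gene_id": q, "subtype": verdicts[q]} for q in queries]
            ),
            manifest.out_dir / "subtype_assignments.tsv",
            header,
        )
        report["tree"]["subtypes"] = verdicts


_STAGE_FUNCS = {
    "classify": _stage_classify,
    "gainloss": _stage_gainloss,
    "truncation": _stage_truncation,
    "expression": _stage_expression,
    "tree": _stage_tree,
}


def run_pipeline(manifest: PipelineManifest) -> dict:
    """Execute the selected stages and write outputs plus report.json.

    Returns the run report (also written as JSON).  Deterministic given
    the manifest and config seed; every output carries a header with the
    config hash and seed.
    """
    manifest.validate()
    cfg = manifest.config
    manifest.out_dir.mkdir(parents=True, exist_ok=True)
    header = f"notchevo config={cfg.config_hash()} seed={cfg.rng_seed}"
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.rng_seed, "stages": list(manifest.stages)}
    for stage in STAGES:
        if stage not in manifest.stages:
            continue
        log.info("stage %s: start", stage)
        _STAGE_FUNCS[stage](manifest, cfg, header, report)
        log.info("stage %s: done", stage)
    (manifest.out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


# ---------------------------------------------------------------------------
# Fixture bundle


def _truth_to_json(obj):
    if isinstance(obj, frozenset):
        inner = sorted(obj, key=str)
        if inner and isinstance(inner[0], frozenset):
            return sorted([sorted(x) for x in inner])
        return sorted(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def make_fixtures(seed: int, out_dir: str | Path, force: bool = False) -> Path:
    """Write the complete synthetic dataset plus truth manifest.

    The bundle contains everything ``run_pipeline`` needs, with a
    ``truth.json`` recording every planted expectation, and a
    ``manifest.txt`` wiring the files into a full run.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(rng_seed=seed, bootstrap_reps=100)
    cfg.to_file(out / "config.txt")
    truth: dict = {"seed": seed}

    # --- architectures: one gene per family per fixture taxon, following
    # the case-study presence/absence matrix (Delta1/Delta2 are both
    # architecture-level Delta genes).
    signatures = default_signatures(cfg)
    write_signatures(signatures, out / "signatures.tsv")
    pa, pa_truth = synthetic.mollusc_presence_matrix()
    arch_of = {
        "Notch": "Notch", "Delta1": "Delta", "Delta2": "Delta", "Jagged": "Jagged",
        "Presenilin": "Presenilin", "Su(H)": "Su(H)", "Hes": "Hes", "Helt": "Helt",
    }
    genes, truths = [], {}
    k = 0
    for family in pa.index:
        for taxon in pa.columns:
            if not pa.loc[family, taxon]:
                continue
            gene_id = f"{taxon}|{family}"
            gene, g_truth = synthetic.generate_gene_with_architecture(
                arch_of[family],
                signatures,
                seed=seed * 100003 + k,
                gene_id=gene_id,
                species_id=taxon,
            )
            genes.append(gene)
            truths[gene_id] = g_truth.payload["architecture_family"]
            k += 1
    write_fasta([g.protein for g in genes], out / "proteins.fasta")
    write_domain_hits(
        [h for g in genes for h in g.hits], out / "domain_hits.tsv", "synthetic fixture"
    )
    write_table(
        pd.DataFrame(
            [{"gene_id": g.gene_id, "species_id": g.species_id} for g in genes]
        ),
        out / "gene_species.tsv",
    )
    truth["architecture"] = truths

    # --- species tree and paralog-resolved presence/absence
    (out / "species_tree.nwk").write_text(synthetic.MOLLUSC_TREE_NEWICK + "\n")
    write_presence_absence(pa, out / "presence_absence.tsv", "synthetic fixture")
    truth["gainloss"] = {
        "family": "Delta2",
        "gain_edge": pa_truth.payload["gain_edge"],
        "loss_edges": pa_truth.payload["loss_edges"],
    }

    # --- truncation plants: one pair per mechanism; the reference carries
    # an arginine anchor a few codons upstream of the target.
    cds_records, pair_rows = [], []
    truth["truncation"] = {}
    for m_idx, mechanism in enumerate(synthetic.MECHANISM_CHOICES):
        plant_seed = seed * 1009 + m_idx
        target = 60
        for attempt in range(200):
            ref_cds = synthetic.random_cds(150, seed=plant_seed + 7919 * attempt)
            # force an anchor arginine five codons upstream of the target
            a0 = 3 * (target - 6)
            ref_cds = ref_cds[:a0] + "CGT" + ref_cds[a0 + 3 :]
            try:
                alt_cds, p_truth = synthetic.plant_truncation(
                    ref_cds, mechanism, target, seed=plant_seed + attempt
                )
                break
            except Exception:
                continue
        else:
            raise ValidationError(f"could not plant {mechanism} fixture")
        ref_id, alt_id = f"ref_{mechanism}", f"alt_{mechanism}"
        cds_records.append(SequenceRecord(ref_id, "", ref_cds, "dna"))
        cds_records.append(SequenceRecord(alt_id, "", alt_cds, "dna"))
        pair_rows.append({"ref_id": ref_id, "alt_id": alt_id})
        truth["truncation"][f"{ref_id}|{alt_id}"] = p_truth.payload
    write_fasta(cds_records, out / "cds.fasta")
    write_table(pd.DataFrame(pair_rows), out / "truncation_pairs.tsv")

    # --- expression
    expr, e_truth = synthetic.mollusc_expression_matrix(seed)
    from .expression import ExpressionMatrix

    write_expression_matrix(
        ExpressionMatrix(expr, "RPKM"), out / "expression.tsv", "synthetic fixture"
    )
    write_table(
        pd.DataFrame(
            [
                {"kind": "pair", "gene_a": "Delta1", "gene_b": "Delta2"},
                {"kind": "nearest", "gene_a": "Jagged", "gene_b": "Delta1;Delta2"},
            ]
        ),
        out / "expression_pairs.tsv",
    )
    truth["expression"] = e_truth.payload

    # --- planted-subtype alignment for the tree stage
    msa, refs, s_truth = synthetic.planted_subtype_alignment(seed)
    write_fasta(msa.records, out / "alignment.fasta")
    write_table(
        pd.DataFrame(
            [{"gene_id": g, "subtype": s} for g, s in sorted(refs.items())]
        ),
        out / "subtype_references.tsv",
    )
    truth["subtypes"] = s_truth.payload["subtypes"]
    truth["outgroup"] = s_truth.payload["outgroup"]

    manifest_text = "\n".join(
        [
            "# notchevo fixture manifest",
            "out_dir: results",
            "config: config.txt",
            f"stages: {', '.join(STAGES)}",
            "domain_hits: domain_hits.tsv",
            "proteins: proteins.fasta",
            "species_map: gene_species.tsv",
            "signatures: signatures.tsv",
            "species_tree: species_tree.nwk",
            "presence_absence: presence_absence.tsv",
            "cds: cds.fasta",
            "truncation_pairs: truncation_pairs.tsv",
            "expression: expression.tsv",
            "expression_pairs: expression_pairs.tsv",
            "alignment: alignment.fasta",
            "subtype_references: subtype_references.tsv",
            f"outgroup: {s_truth.payload['outgroup']}",
        ]
    )
    (out / "manifest.txt").write_text(manifest_text + "\n")
    (out / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True, default=_truth_to_json) + "\n"
    )
    return out
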