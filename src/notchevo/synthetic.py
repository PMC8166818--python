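"""Synthetic fixtures with planted truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed and
returns both the data and a :class:`PlantedTruth` record that fully
determines the expected output of the corresponding analysis stage:

* genes with planted domain architectures (family classification truth);
* paralog CDS pairs with a planted premature-termination mutation of one
  of the four mechanisms (mechanism + exact edit coordinate truth);
* presence/absence vectors simulated under a single-gain/multiple-loss
  history on a species tree (gain and loss edge truth);
* stage-profile pairs with planted similar/complementary/unrelated
  structure (relation truth);
* random rooted binary trees (topology truth for NJ consistency tests).

Domain instances are emitted as coordinate annotations in hit tables, not
as sequence motifs: the classification logic under test consumes hit
tables, and profile-HMM scanning is outside this package's scope.  Indel
coordinates in truncation truths are left-normalised (an edit inside a
homopolymer run is recorded at the run's first base) to match the
canonical gap placement of the aligner.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .architecture import (
    ArchitectureSignature,
    GeneModel,
    HES_HEY_SUBTYPES,
    architecture_family_of,
    classify_gene,
    default_signatures,
)
from .errors import PlantError, ValidationError
from .gainloss import clade_map, leaf_labels
from .io_formats import DomainHitRow, SequenceRecord, tree_from_string
from .phylo import DistanceMatrix, MultipleAlignment
from .truncation import STOP_CODONS, translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in STOP_CODONS
)

#: Gene-family labels accepted by the gene generator: the nine core
#: pathway genes plus the Dll catch-all.
FAMILY_LABELS = (
    "Notch", "Delta", "Jagged", "Dll", "Presenilin", "Su(H)",
) + HES_HEY_SUBTYPES

# Typical domain lengths (residues) used to lay out synthetic hits.
_DOMAIN_LEN = {
    "EGF": 35, "DSL": 45, "MNLL": 50, "LNR": 35, "ANK": 33, "TM": 23,
    "VWC": 60, "Presenilin": 250, "LAG1-DNAbind": 100, "bHLH": 55, "Orange": 40,
}

DECOY_DOMAINS = ("Homeobox", "SH2", "WD40", "Kinase")


@dataclasses.dataclass
class PlantedTruth:
    kind: str  # architecture | truncation | gainloss | expression | tree
    payload: dict


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------------------
# Planted domain architectures


def generate_gene_with_architecture(
    family_label: str,
    signature_set: Sequence[ArchitectureSignature] | None = None,
    seed: int = 0,
    gene_id: str | None = None,
    species_id: str = "SYN",
) -> tuple[GeneModel, PlantedTruth]:
    """Generate a gene whose hit table realises one family signature.

    ``family_label`` may be any of the nine core pathway genes (the four
    Hes/Hey-related subtypes share the superfamily signature) or a family
    of a custom signature set.  The generated hits are non-overlapping,
    ordered along the protein, and classify to the planted architecture
    family and no more specific one.
    """
    sigs = list(signature_set) if signature_set is not None else default_signatures()
    arch_label = architecture_family_of(family_label)
    sig = next((s for s in sigs if s.family == arch_label), None)
    if sig is None:
        raise ValidationError(f"unknown family label {family_label!r}")
    rng = _rng(seed)
    gene_id = gene_id or f"{species_id}_{family_label.replace('/', '_')}_{seed}"

    hits: list[DomainHitRow] = []
    pos = int(rng.integers(5, 40))
    for domain, lo, hi in sig.requirements:
        cap = hi if hi is not None else lo + 3
        count = int(rng.integers(lo, cap + 1))
        for _ in range(count):
            length = _DOMAIN_LEN.get(domain, 40)
            start = pos
            end = start + length - 1
            hits.append(
                DomainHitRow(
                    gene_id=gene_id,
                    domain_name=domain,
                    pfam_accession=None,
                    env_start=start,
                    env_end=end,
                    e_value=float(10.0 ** rng.uniform(-30, -8)),
                )
            )
            pos = end + 1 + int(rng.integers(5, 30))
    # The bHLH superfamily genes additionally carry the hairy/orange motif.
    if arch_label == "Hes/Hey-related" and signature_set is None:
        start = pos
        end = start + _DOMAIN_LEN["Orange"] - 1
        hits.append(
            DomainHitRow(gene_id, "Orange", None, start, end, float(10.0 ** rng.uniform(-20, -8)))
        )
        pos = end + 1 + int(rng.integers(5, 30))

    protein = SequenceRecord(
        gene_id, f"synthetic {family_label}", random_protein(pos + int(rng.integers(5, 20)), rng),
        "protein",
    )
    gene = GeneModel(gene_id, species_id, protein, hits=hits)
    assigned = classify_gene(gene, sigs).family
    if assigned != arch_label:
        raise AssertionError(
            f"generator contract violated: planted {arch_label}, classified {assigned}"
        )
    truth = PlantedTruth(
        "architecture",
        {"family": family_label, "architecture_family": arch_label, "gene_id": gene_id},
    )
    return gene, truth


def add_decoy_domain(gene: GeneModel, seed: int = 0) -> GeneModel:
    """Return a copy of the gene with one extra hit of an unrelated domain.

    The decoy's name appears in no shipped signature, so classification
    must be unchanged.
    """
    rng = _rng(seed)
    decoy = str(rng.choice(DECOY_DOMAINS))
    length = 60
    start = len(gene.protein) + 1 + int(rng.integers(3, 15))
    end = start + length - 1
    protein = SequenceRecord(
        gene.protein.id,
        gene.protein.description,
        gene.protein.sequence + random_protein(end - len(gene.protein) + 10, rng),
        "protein",
    )
    hits = list(gene.hits) + [
        DomainHitRow(gene.gene_id, decoy, None, start, end, 1e-10)
    ]
    return GeneModel(gene.gene_id, gene.species_id, protein, gene.cds, hits)


# ---------------------------------------------------------------------------
# Planted truncation mutations


def random_cds(n_codons: int, seed: int = 0, rng: np.random.Generator | None = None) -> str:
    """ATG + (n-2) sense codons + stop: a clean open reading frame.

    Internal codons are drawn from the 61 sense codons only, so no
    incidental in-frame stop can occur.
    """
    if n_codons < 3:
        raise ValidationError("need at least 3 codons (start, one sense, stop)")
    rng = rng if rng is not None else _rng(seed)
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(body) + stop


def _check_ref(ref: str) -> int:
    if len(ref) % 3:
        raise ValidationError("ref CDS length must be divisible by 3")
    if not ref.startswith("ATG"):
        raise ValidationError("ref CDS must begin with ATG")
    if ref[-3:] not in STOP_CODONS:
        raise ValidationError("ref CDS must end with a stop codon")
    n = len(ref) // 3
    _, stop = translate(ref)
    if stop != n:
        raise ValidationError("ref CDS contains an internal in-frame stop")
    return n


def _normalize_insertion(ref: str, pos: int, base: str) -> int:
    """Leftmost equivalent position for inserting ``base`` before ``pos``."""
    while pos > 0 and ref[pos - 1] == base:
        pos -= 1
    return pos


def _normalize_deletion(ref: str, pos: int) -> int:
    """Leftmost equivalent position for deleting the base at ``pos``."""
    while pos > 0 and ref[pos - 1] == ref[pos]:
        pos -= 1
    return pos


MECHANISM_CHOICES = (
    "insertion_stop",
    "substitution_nonsense",
    "deletion_frameshift",
    "insertion_frameshift",
)


def plant_truncation(
    ref_cds: str, mechanism: str, target_codon: int, seed: int = 0
) -> tuple[str, PlantedTruth]:
    """Introduce one premature-termination edit at a target codon.

    Returns the derived CDS and the truth record (mechanism, exact
    left-normalised edit coordinate in derived-sequence space, bases
    involved, resulting stop codon index).  Raises
    :class:`~notchevo.errors.PlantError` when no single edit at the target
    codon realises the requested mechanism — e.g. a nonsense substitution
    at a codon one base away from no stop, or a frameshift whose shifted
    frame reaches the reference stop without a novel stop codon.
    """
    ref = ref_cds.upper()
    n_codons = _check_ref(ref)
    if not 1 < target_codon < n_codons:
        raise ValidationError("target_codon must be strictly inside the ORF")
    if mechanism not in MECHANISM_CHOICES:
        raise ValidationError(f"unknown mechanism {mechanism!r}")
    rng = _rng(seed)
    t0 = 3 * (target_codon - 1)
    codon = ref[t0 : t0 + 3]
    candidates: list[dict] = []

    if mechanism == "substitution_nonsense":
        for off in range(3):
            for base in "ACGT":
                if base == codon[off]:
                    continue
                new_codon = codon[:off] + base + codon[off + 1 :]
                if new_codon in STOP_CODONS:
                    candidates.append(
                        {
                            "alt": ref[: t0 + off] + base + ref[t0 + off + 1 :],
                            "alt_pos": t0 + off,
                            "ref_base": codon[off],
                            "alt_base": base,
                            "stop": target_codon,
                        }
                    )
    elif mechanism == "insertion_stop":
        for off in range(3):
            for base in "ACGT":
                if off == 0:
                    new_codon = base + codon[0] + codon[1]
                elif off == 1:
                    new_codon = codon[0] + base + codon[1]
                else:
                    new_codon = codon[0] + codon[1] + base
                if new_codon not in STOP_CODONS:
                    continue
                pos = t0 + off
                npos = _normalize_insertion(ref, pos, base)
                if not t0 <= npos < t0 + 3:
                    continue  # canonical position slides out of the stop codon
                candidates.append(
                    {
                        "alt": ref[:pos] + base + ref[pos:],
                        "alt_pos": npos,
                        "ref_base": "",
                        "alt_base": base,
                        "stop": target_codon,
                    }
                )
    elif mechanism == "deletion_frameshift":
        for off in range(3):
            pos = t0 + off
            alt = ref[:pos] + ref[pos + 1 :]
            stop_idx = translate(alt)[1]
            if stop_idx is None or not target_codon <= stop_idx < n_codons:
                continue
            npos = _normalize_deletion(ref, pos)
            if npos > 3 * (stop_idx - 1):
                continue  # the shift must begin at or before the novel stop
            candidates.append(
                {
                    "alt": alt,
                    "alt_pos": npos,
                    "ref_base": ref[pos],
                    "alt_base": "",
                    "stop": stop_idx,
                }
            )
    else:  # insertion_frameshift
        for off in range(3):
            for base in "ACGT":
                pos = t0 + off
                alt = ref[:pos] + base + ref[pos:]
                stop_idx = translate(alt)[1]
                if stop_idx is None or not target_codon <= stop_idx < n_codons:
                    continue
                npos = _normalize_insertion(ref, pos, base)
                lo = 3 * (stop_idx - 1)
                if npos + 1 > lo:
                    continue  # inserted base inside/at the stop: that is insertion_stop
                candidates.append(
                    {
                        "alt": alt,
                        "alt_pos": npos,
                        "ref_base": "",
                        "alt_base": base,
                        "stop": stop_idx,
                    }
                )

    if not candidates:
        raise PlantError(
            f"no single {mechanism} edit at codon {target_codon} yields the "
            "requested mechanism; try a different target codon"
        )
    pick = candidates[int(rng.integers(len(candidates)))]
    truth = PlantedTruth(
        "truncation",
        {
            "mechanism": mechanism,
            "alt_pos": pick["alt_pos"],  # 0-based, left-normalised, alt coords
            "ref_base": pick["ref_base"],
            "alt_base": pick["alt_base"],
            "target_codon": target_codon,
            "stop_codon": pick["stop"],
        },
    )
    return pick["alt"], truth


# ---------------------------------------------------------------------------
# Planted gain/loss histories


def simulate_gainloss(
    tree: dendropy.Tree,
    gain_edge: frozenset,
    loss_edges: Sequence[frozenset],
    family: str = "family",
) -> tuple[dict, PlantedTruth]:
    """Leaf presence vector implied by a single-gain/multiple-loss history.

    ``gain_edge`` and each loss edge are clades (frozensets of leaf
    labels); every loss must lie strictly below the gain and losses must
    be pairwise non-nested.
    """
    clades = set(clade_map(tree).values())
    if gain_edge not in clades:
        raise ValidationError("gain_edge is not a clade of the tree")
    losses = [frozenset(l) for l in loss_edges]
    for loss in losses:
        if loss not in clades:
            raise ValidationError(f"loss edge {sorted(loss)} is not a clade")
        if not (loss < gain_edge):
            raise ValidationError(
                f"loss edge {sorted(loss)} does not lie strictly below the gain edge"
            )
    for i, a in enumerate(losses):
        for b in losses[i + 1 :]:
            if a <= b or b <= a:
                raise ValidationError("loss edges must be pairwise non-nested")
    lost = frozenset().union(*losses) if losses else frozenset()
    presence = {
        leaf: int(leaf in gain_edge and leaf not in lost)
        for leaf in leaf_labels(tree)
    }
    truth = PlantedTruth(
        "gainloss",
        {"family": family, "gain_edge": gain_edge, "loss_edges": frozenset(losses)},
    )
    return presence, truth


# ---------------------------------------------------------------------------
# Planted expression relations

EXPRESSION_SCALE = 10.0  # RPKM-like stage profiles span roughly 0-10


def generate_expression_pair(
    n_stages: int, relation: str, noise_sd: float, seed: int = 0
) -> tuple[tuple[np.ndarray, np.ndarray], PlantedTruth]:
    """Two stage profiles with a planted trend relation.

    ``similar``: the second profile is a positive affine transform of the
    first plus Gaussian noise; ``complementary``: a negative affine
    transform plus noise; ``unrelated``: independent draws.  Profiles are
    on an RPKM-like 0-10 scale and noise_sd is in the same units.
    """
    if n_stages < 4:
        raise ValidationError("need >= 4 stages (rank correlation degenerate)")
    if relation not in ("similar", "complementary", "unrelated"):
        raise ValidationError(f"unknown relation {relation!r}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    rng = _rng(seed)
    x = rng.uniform(0.0, EXPRESSION_SCALE, size=n_stages)
    slope = float(rng.uniform(0.5, 2.0))
    intercept = float(rng.uniform(0.0, 2.0))
    if relation == "similar":
        y = slope * x + intercept
    elif relation == "complementary":
        y = slope * (EXPRESSION_SCALE - x) + intercept
    else:
        y = rng.uniform(0.0, EXPRESSION_SCALE, size=n_stages)
    y = y + rng.normal(0.0, noise_sd, size=n_stages)
    truth = PlantedTruth(
        "expression",
        {"relation": relation, "slope": slope, "intercept": intercept, "noise_sd": noise_sd},
    )
    return (x, y), truth


# ---------------------------------------------------------------------------
# Random trees and additive distances


def generate_random_tree(
    n_leaves: int, seed: int = 0, labels: Sequence[str] | None = None
) -> dendropy.Tree:
    """Random rooted binary tree with uniform(0.1, 2.0) branch lengths."""
    if n_leaves < 3:
        raise ValidationError("need >= 3 leaves")
    rng = _rng(seed)
    if labels is None:
        labels = [f"T{k:02d}" for k in range(1, n_leaves + 1)]
    elif len(labels) != n_leaves:
        raise ValidationError("label count does not match n_leaves")

    def bl() -> str:
        return f"{rng.uniform(0.1, 2.0):.6f}"

    nodes = [f"{lab}:{bl()}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    tree = tree_from_string(f"({nodes[0]},{nodes[1]});")
    tree.is_rooted = True
    return tree


def tree_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Additive leaf-to-leaf path-length distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Planted alignments for bootstrap and subtype tests


def planted_split_alignment(
    n_taxa: int = 8,
    signal_columns: int = 20,
    private_columns_per_taxon: int = 2,
    constant_columns: int = 10,
    seed: int = 0,
) -> tuple[MultipleAlignment, PlantedTruth]:
    """Protein alignment supporting exactly one internal bipartition.

    The first half of the taxa carry A and the second half C in every
    signal column; per-taxon private columns (a W unique to one row) add
    star-like variation that supports no conflicting split.
    """
    if n_taxa < 4 or n_taxa % 2:
        raise ValidationError("n_taxa must be even and >= 4")
    labels = [f"X{k:02d}" for k in range(1, n_taxa + 1)]
    ncol = signal_columns + n_taxa * private_columns_per_taxon + constant_columns
    arr = np.full((n_taxa, ncol), "G", dtype="<U1")
    arr[: n_taxa // 2, :signal_columns] = "A"
    arr[n_taxa // 2 :, :signal_columns] = "C"
    col = signal_columns
    for k in range(n_taxa):
        arr[k, col : col + private_columns_per_taxon] = "W"
        col += private_columns_per_taxon
    msa = MultipleAlignment.from_array(labels, arr)
    split = frozenset(
        {frozenset(labels[: n_taxa // 2]), frozenset(labels[n_taxa // 2 :])}
    )
    return msa, PlantedTruth("tree", {"split": split})


def planted_subtype_alignment(
    seed: int = 0, refs_per_subtype: int = 2
) -> tuple[MultipleAlignment, dict, PlantedTruth]:
    """Alignment of bHLH-superfamily genes with planted subtype clades.

    Each of the four Hes/Hey-related subtypes gets a block of diagnostic
    columns shared by its references and one query; a dedicated outgroup
    taxon (label in the truth payload) carries its own block and anchors
    the rooting.  The truth records the query -> subtype map.
    """
    rng = _rng(seed)
    subtype_residue = {"Hes": "H", "Hey": "K", "Helt": "L", "Cwo": "Q"}
    block = 10
    n_members = len(subtype_residue) * (refs_per_subtype + 1) + 1
    ncol = block * (len(subtype_residue) + 1) + 2 * n_members
    labels, rows = [], []
    reference_labels: dict = {}
    query_truth: dict = {}
    private0 = block * (len(subtype_residue) + 1)
    for s_idx, (subtype, res) in enumerate(subtype_residue.items()):
        members = [f"{subtype}_ref{i}" for i in range(1, refs_per_subtype + 1)]
        members.append(f"{subtype}_query")
        for member in members:
            row = np.full(ncol, "G", dtype="<U1")
            row[s_idx * block : (s_idx + 1) * block] = res
            # two private columns per member keep every leaf distinct
            private = private0 + 2 * len(labels)
            row[private : private + 2] = "W"
            labels.append(member)
            rows.append(row)
            if member.endswith("query"):
                query_truth[member] = subtype
            else:
                reference_labels[member] = subtype
    out_row = np.full(ncol, "G", dtype="<U1")
    out_row[len(subtype_residue) * block : (len(subtype_residue) + 1) * block] = "Y"
    out_row[private0 + 2 * len(labels) : private0 + 2 * len(labels) + 2] = "W"
    labels.append("outgroup")
    rows.append(out_row)
    msa = MultipleAlignment.from_array(labels, np.vstack(rows))
    return msa, reference_labels, PlantedTruth(
        "tree", {"subtypes": query_truth, "outgroup": "outgroup"}
    )


# ---------------------------------------------------------------------------
# The mollusc case study (single-gain, three-gastropod-loss pattern)

MOLLUSC_TAXA = (
    "Agr_chiton",
    "Bgl_gastropod",
    "Lgi_gastropod",
    "Ech_gastropod",
    "Hdh_gastropod",
    "Aca_gastropod",
    "Obi_cephalopod",
    "Cgi_bivalve",
    "Mye_bivalve",
)

MOLLUSC_TREE_NEWICK = (
    "(Agr_chiton:1.0,((Bgl_gastropod:0.6,(Lgi_gastropod:0.5,(Ech_gastropod:0.4,"
    "(Hdh_gastropod:0.3,Aca_gastropod:0.3):0.1):0.1):0.1):0.4,"
    "(Obi_cephalopod:0.7,(Cgi_bivalve:0.4,Mye_bivalve:0.4):0.3):0.3):0.5);"
)

#: Conchiferan clade: every fixture taxon except the chiton outgroup.
MOLLUSC_GAIN_CLADE = frozenset(t for t in MOLLUSC_TAXA if t != "Agr_chiton")
MOLLUSC_DELTA2_LOSSES = frozenset(
    {frozenset({"Bgl_gastropod"}), frozenset({"Ech_gastropod"}), frozenset({"Aca_gastropod"})}
)


def mollusc_tree() -> dendropy.Tree:
    """The fixture species tree: chiton outgroup, then gastropods vs
    cephalopod+bivalves (a conventional conchiferan topology)."""
    tree = tree_from_string(MOLLUSC_TREE_NEWICK)
    tree.is_rooted = True
    return tree


def mollusc_presence_matrix() -> tuple[pd.DataFrame, PlantedTruth]:
    """Paralog-resolved presence/absence matrix of the case-study pattern.

    Delta2 is present throughout Gastropoda+Cephalopoda+Bivalvia except in
    three gastropods that lost it independently, and absent from the
    chiton; Helt is additionally lost in a gastropod subclade.
    """
    families = ["Notch", "Delta1", "Delta2", "Jagged", "Presenilin", "Su(H)", "Hes", "Helt"]
    df = pd.DataFrame(1, index=families, columns=list(MOLLUSC_TAXA), dtype=int)
    for taxon in MOLLUSC_TAXA:
        df.loc["Delta2", taxon] = int(
            taxon in MOLLUSC_GAIN_CLADE
            and frozenset({taxon}) not in MOLLUSC_DELTA2_LOSSES
        )
    for taxon in ("Bgl_gastropod", "Ech_gastropod", "Hdh_gastropod", "Aca_gastropod"):
        df.loc["Helt", taxon] = 0
    truth = PlantedTruth(
        "gainloss",
        {
            "family": "Delta2",
            "gain_edge": MOLLUSC_GAIN_CLADE,
            "loss_edges": MOLLUSC_DELTA2_LOSSES,
        },
    )
    return df, truth


MOLLUSC_STAGES = ("Z", "C", "B", "G", "T", "D", "U", "J")


def mollusc_expression_matrix(seed: int = 0) -> tuple[pd.DataFrame, PlantedTruth]:
    """Stage-resolved ligand expression with the planted ligand pattern.

    Delta1 peaks early in development and declines; Delta2 is its
    complement (rising after the mid-larval stages); Jagged tracks Delta2
    (the bivalve pattern, where Jagged resembles Delta2 more than Delta1).
    """
    rng = _rng(seed)
    d1 = np.array([9.0, 8.0, 6.5, 5.0, 3.0, 2.0, 1.0, 0.5])
    d2 = 10.0 - d1
    jag = 0.9 * d2 + 0.3
    noise = rng.normal(0.0, 0.05, size=(3, len(MOLLUSC_STAGES)))
    values = np.clip(np.vstack([d1, d2, jag]) + noise, 0.0, None)
    df = pd.DataFrame(
        values, index=["Delta1", "Delta2", "Jagged"], columns=list(MOLLUSC_STAGES)
    )
    truth = PlantedTruth(
        "expression",
        {
            "complementary_pairs": [("Delta1", "Delta2")],
            "nearest": {"Jagged": ["Delta2", "Delta1"]},
        },
    )
    return df.round(4), truth
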