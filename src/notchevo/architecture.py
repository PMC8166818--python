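"""Domain-architecture gene-family classification.

The Notch-pathway family definitions are encoded as
:class:`ArchitectureSignature` objects — counted domain requirements per
family — and applied to per-gene domain-hit lists.  The shipped default
signature set covers the nine core pathway genes:

* **Notch**: several EGF repeats, exactly three LNR repeats, a TM domain
  and several ANK repeats.
* **Delta**: a DSL domain, an MNLL domain and EGF repeats.
* **Jagged**: the Delta architecture plus a VWC domain.
* **Delta-like (Dll)**: any DSL-bearing gene that does not satisfy the
  full Delta architecture (lost EGF repeats or other motifs).
* **Presenilin** and **Su(H)**: defined by the Presenilin and
  BTD/LAG1-DNAbind domains respectively.
* **Hes/Hey-related**: the bHLH(+Orange) superfamily covering Hes, Hey,
  Helt and Cwo.  Architecture cannot separate these four subtypes — they
  share the bHLH+Orange layout — so this module assigns the superfamily
  label only and subtype resolution is delegated to clade assignment in
  :mod:`notchevo.phylo`.

"Several" has no numeric value in the verbal definitions; it is
operationalised as ``RunConfig.several_min_count`` (default 2) and is the
weakest common reading.  Signatures constrain only the domains they name
(plus an optional forbidden set), so decoy domains never change a verdict.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import RunConfig
from .errors import AmbiguousClassificationError, ValidationError
from .io_formats import DomainHitRow, SequenceRecord, log

UNBOUNDED = None

#: Domain vocabulary used by the shipped signature set.
KNOWN_DOMAINS = (
    "EGF", "DSL", "MNLL", "LNR", "ANK", "VWC", "TM",
    "Presenilin", "LAG1-DNAbind", "bHLH", "Orange",
)

#: The four bHLH-superfamily subtypes resolved by phylogeny, not architecture.
HES_HEY_SUBTYPES = ("Hes", "Hey", "Helt", "Cwo")
HES_HEY_SUPERFAMILY = "Hes/Hey-related"


@dataclasses.dataclass
class GeneModel:
    """A gene with its protein (and optionally CDS) sequence and domain hits."""

    gene_id: str
    species_id: str
    protein: SequenceRecord
    cds: SequenceRecord | None = None
    hits: list[DomainHitRow] = dataclasses.field(default_factory=list)
    cds_length_flag: str | None = None

    def __post_init__(self) -> None:
        for hit in self.hits:
            if hit.gene_id != self.gene_id:
                raise ValidationError(
                    f"hit for {hit.gene_id!r} attached to gene {self.gene_id!r}"
                )
            if hit.env_end > len(self.protein):
                raise ValidationError(
                    f"{self.gene_id}/{hit.domain_name}: hit end {hit.env_end} "
                    f"beyond protein length {len(self.protein)}"
                )
        if self.cds is not None:
            expected = 3 * (len(self.protein) + 1)  # + stop codon
            if len(self.cds) != expected:
                # Real gene models frequently deviate (trailing UTR fragments,
                # missing stop); flag rather than reject.
                self.cds_length_flag = (
                    f"cds length {len(self.cds)} != 3*(protein+stop) = {expected}"
                )

    def domain_counts(self) -> Counter:
        return Counter(h.domain_name for h in self.hits)


@dataclasses.dataclass
class ArchitectureSignature:
    """Counted domain requirements defining one gene family.

    ``requirements`` is an ordered list of ``(domain_name, min_count,
    max_count)`` with ``max_count=None`` meaning unbounded.  ``forbidden``
    domains must be absent.  When ``order_enforced`` is true the first
    occurrence of each required domain must appear in the listed order
    along the protein (off by default; the family definitions do not state
    an order requirement).
    """

    family: str
    requirements: list[tuple[str, int, int | None]]
    forbidden: frozenset = frozenset()
    order_enforced: bool = False

    def __post_init__(self) -> None:
        for domain, lo, hi in self.requirements:
            if lo < 1:
                raise ValidationError(
                    f"{self.family}/{domain}: required min_count must be >= 1"
                )
            if hi is not None and hi < lo:
                raise ValidationError(f"{self.family}/{domain}: max_count < min_count")

    @property
    def specificity(self) -> int:
        """Number of required domain types (more = more specific)."""
        return len(self.requirements)

    def unmet(self, counts: Counter, first_start: dict) -> list[str]:
        """Reasons this signature is not satisfied (empty list = satisfied)."""
        reasons = []
        for domain, lo, hi in self.requirements:
            n = counts.get(domain, 0)
            if n < lo:
                reasons.append(f"{domain}: have {n}, need >= {lo}")
            elif hi is not None and n > hi:
                reasons.append(f"{domain}: have {n}, need <= {hi}")
        for domain in sorted(self.forbidden):
            if counts.get(domain, 0):
                reasons.append(f"{domain}: forbidden but present")
        if not reasons and self.order_enforced:
            starts = [first_start[d] for d, _, _ in self.requirements]
            if starts != sorted(starts):
                reasons.append("required domains out of order")
        return reasons

    def matches(self, counts: Counter, first_start: dict) -> bool:
        return not self.unmet(counts, first_start)


def default_signatures(config: RunConfig | None = None) -> list[ArchitectureSignature]:
    """The shipped Notch-pathway signature set.

    Seven architecture signatures cover the nine core pathway genes: the
    four Hes/Hey-related subtypes are architecturally identical and share
    the superfamily signature.
    """
    cfg = config or RunConfig()
    k = cfg.several_min_count
    return [
        ArchitectureSignature(
            "Notch",
            [("EGF", k, UNBOUNDED), ("LNR", 3, 3), ("TM", 1, UNBOUNDED), ("ANK", k, UNBOUNDED)],
        ),
        ArchitectureSignature(
            "Delta", [("MNLL", 1, UNBOUNDED), ("DSL", 1, UNBOUNDED), ("EGF", 1, UNBOUNDED)]
        ),
        ArchitectureSignature(
            "Jagged",
            [
                ("MNLL", 1, UNBOUNDED),
                ("DSL", 1, UNBOUNDED),
                ("EGF", 1, UNBOUNDED),
                ("VWC", 1, UNBOUNDED),
            ],
        ),
        # Catch-all for DSL-bearing genes that fail the full Delta layout.
        ArchitectureSignature("Dll", [("DSL", 1, UNBOUNDED)]),
        ArchitectureSignature("Presenilin", [("Presenilin", 1, UNBOUNDED)]),
        ArchitectureSignature("Su(H)", [("LAG1-DNAbind", 1, UNBOUNDED)]),
        ArchitectureSignature(HES_HEY_SUPERFAMILY, [("bHLH", 1, UNBOUNDED)]),
    ]


def architecture_family_of(label: str) -> str:
    """Map a gene-family label to its architecture-level signature label."""
    return HES_HEY_SUPERFAMILY if label in HES_HEY_SUBTYPES else label


@dataclasses.dataclass
class FamilyAssignment:
    gene_id: str
    family: str  # signature family or "unassigned"
    matched_requirements: dict
    failure_reasons: list  # (family, reason) near-misses


# ---------------------------------------------------------------------------
# Signature-file round trip (structured text: one family per block)


def write_signatures(signatures: Sequence[ArchitectureSignature], path: str | Path) -> None:
    lines = ["# notchevo architecture signatures", "# family\tdomain\tmin\tmax"]
    for sig in signatures:
        for domain, lo, hi in sig.requirements:
            lines.append(f"{sig.family}\t{domain}\t{lo}\t{'*' if hi is None else hi}")
        for domain in sorted(sig.forbidden):
            lines.append(f"{sig.family}\t!{domain}\t0\t0")
    Path(path).write_text("\n".join(lines) + "\n")


def read_signatures(path: str | Path) -> list[ArchitectureSignature]:
    blocks: dict[str, dict] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        family, domain, lo, hi = line.split("\t")
        if family not in blocks:
            blocks[family] = {"req": [], "forbidden": set()}
            order.append(family)
        if domain.startswith("!"):
            blocks[family]["forbidden"].add(domain[1:])
        else:
            blocks[family]["req"].append(
                (domain, int(lo), None if hi == "*" else int(hi))
            )
    return [
        ArchitectureSignature(
            fam, blocks[fam]["req"], frozenset(blocks[fam]["forbidden"])
        )
        for fam in order
    ]


# ---------------------------------------------------------------------------
# Operations


def filter_hits(hits: Iterable[DomainHitRow], e_threshold: float) -> list[DomainHitRow]:
    """Keep exactly the hits with E-value <= threshold, order preserved."""
    if e_threshold <= 0:
        raise ValidationError("e_threshold must be positive")
    hits = list(hits)
    kept = [h for h in hits if h.e_value <= e_threshold]
    log.info("filter_hits: %d -> %d at E <= %g", len(hits), len(kept), e_threshold)
    return kept


def _overlap(a: DomainHitRow, b: DomainHitRow) -> int:
    return max(0, min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1)


def _conflicts(a: DomainHitRow, b: DomainHitRow) -> bool:
    return _overlap(a, b) > 0.5 * min(a.length, b.length)


def resolve_overlaps(hits: Sequence[DomainHitRow]) -> list[DomainHitRow]:
    """Greedy best-first resolution of heavily overlapping hits on one gene.

    Hits are admitted in order of (e_value, env_start, domain_name); a hit
    is dropped if it overlaps an already-admitted hit by more than 50% of
    the shorter of the two.  Deterministic by construction.
    """
    ranked = sorted(hits, key=lambda h: (h.e_value, h.env_start, h.domain_name))
    kept: list[DomainHitRow] = []
    for hit in ranked:
        if not any(_conflicts(hit, k) for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.env_start, h.env_end, h.domain_name))
    return kept


def classify_gene(
    gene: GeneModel,
    signatures: Sequence[ArchitectureSignature] | None = None,
    config: RunConfig | None = None,
) -> FamilyAssignment:
    """Assign a gene to the most specific satisfied family signature.

    Expects hits already E-value-filtered (and optionally overlap-resolved).
    Specificity is the number of required domain types, which makes Jagged
    (4 types) win over Delta (3) and Delta over the Dll catch-all (1).
    Exact specificity ties between satisfied signatures are surfaced as an
    error, never resolved silently.
    """
    cfg = config or RunConfig()
    sigs = list(signatures) if signatures is not None else default_signatures(cfg)
    counts = gene.domain_counts()
    first_start = {}
    for hit in sorted(gene.hits, key=lambda h: h.env_start):
        first_start.setdefault(hit.domain_name, hit.env_start)

    satisfied = [s for s in sigs if s.matches(counts, first_start)]
    failure_reasons = [
        (s.family, reason)
        for s in sigs
        if not s.matches(counts, first_start)
        and any(counts.get(d, 0) for d, _, _ in s.requirements)
        for reason in s.unmet(counts, first_start)
    ]
    if not satisfied:
        return FamilyAssignment(gene.gene_id, "unassigned", dict(counts), failure_reasons)
    best = max(s.specificity for s in satisfied)
    winners = [s for s in satisfied if s.specificity == best]
    if len(winners) > 1:
        raise AmbiguousClassificationError(gene.gene_id, [s.family for s in winners])
    return FamilyAssignment(
        gene.gene_id, winners[0].family, dict(counts), failure_reasons
    )


def enumerate_dsl_instances(gene: GeneModel) -> list[str]:
    """Identifiers for each DSL domain instance in a gene.

    Multi-DSL genes get ``gene_id-k`` with k the 1-based rank of the hit by
    start coordinate; a single-DSL gene keeps the bare gene id.
    """
    dsl = sorted(
        (h for h in gene.hits if h.domain_name == "DSL"), key=lambda h: h.env_start
    )
    if not dsl:
        return []
    if len(dsl) == 1:
        return [gene.gene_id]
    return [f"{gene.gene_id}-{k}" for k in range(1, len(dsl) + 1)]


DSL_GROUPS = ("dsl_only", "dsl_tandem", "dsl_egf", "dsl_egf_other")

#: Domains that do not count as "other" when grouping DSL genes: the
#: core ligand scaffold (MNLL leader, TM anchor) and DSL/EGF themselves.
_DSL_CORE = {"DSL", "EGF", "MNLL", "TM"}


def dsl_group(gene: GeneModel) -> str:
    """Partition a DSL-family gene into one of four architecture groups.

    dsl_only: a single DSL and no EGF; dsl_tandem: DSL tandem repeats and
    no EGF; dsl_egf: DSL + EGF with no additional domain types beyond the
    core ligand scaffold; dsl_egf_other: DSL + EGF plus extra domain types
    (e.g. the VWC of Jagged).
    """
    counts = gene.domain_counts()
    n_dsl = counts.get("DSL", 0)
    if n_dsl == 0:
        raise ValidationError(f"{gene.gene_id}: dsl_group requires >= 1 DSL hit")
    has_egf = counts.get("EGF", 0) > 0
    if not has_egf:
        return "dsl_only" if n_dsl == 1 else "dsl_tandem"
    extra = set(counts) - _DSL_CORE
    return "dsl_egf_other" if extra else "dsl_egf"


def count_domains(
    genes: Iterable[GeneModel], domains_of_interest: set[str] | None = None
) -> pd.DataFrame:
    """Per-(species, domain) counts of retained hit instances.

    Returns a tidy table with columns species_id, domain_name, count.
    """
    tally: Counter = Counter()
    for gene in genes:
        for hit in gene.hits:
            if domains_of_interest is None or hit.domain_name in domains_of_interest:
                tally[(gene.species_id, hit.domain_name)] += 1
    rows = [
        {"species_id": sp, "domain_name": dom, "count": n}
        for (sp, dom), n in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["species_id", "domain_name", "count"])


def build_presence_absence(
    assignments: Sequence[tuple[FamilyAssignment, str]],
    species: Sequence[str],
    families: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence and gene-count matrices (families x species).

    ``assignments`` pairs each FamilyAssignment with its species id.
    Returns (presence 0/1 matrix, per-cell gene counts); the counts expose
    within-species duplications (e.g. the duplicated mollusc Delta).
    """
    counts = pd.DataFrame(0, index=list(families), columns=list(species), dtype=int)
    for assignment, sp in assignments:
        if assignment.family == "unassigned":
            continue
        if sp not in counts.columns:
            raise ValidationError(f"species {sp!r} not in declared species list")
        if assignment.family not in counts.index:
            raise ValidationError(
                f"family {assignment.family!r} not in declared family list"
            )
        counts.loc[assignment.family, sp] += 1
    presence = (counts > 0).astype(int)
    return presence, counts
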