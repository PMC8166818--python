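"""Premature-termination detection and mechanism typing for paralog pairs.

Given a reference paralog CDS (e.g. Delta1) and a derived paralog CDS
(e.g. the mollusc-specific Delta2), this module aligns the two coding
sequences, locates the derived paralog's first in-frame stop, and types
the mutation that caused it:

* ``insertion_stop`` — a single-base insertion whose inserted base is part
  of the new stop codon (the C. gigas pattern: an inserted G creating a
  terminal TGA);
* ``substitution_nonsense`` — a point substitution converting a sense
  codon into a stop (the L. gigantea pattern: TTA -> TGA);
* ``deletion_frameshift`` — a base deletion shifting the reading frame
  with a novel downstream stop (the M. yessoensis pattern);
* ``insertion_frameshift`` — the same via a frame-shifting insertion.

Alignment is global with affine gaps under a fixed, documented scheme
(match +2, mismatch -1, gap open -5, gap extend -1; a length-L gap costs
5 + (L-1)).  Gap runs are left-normalised after traceback (a gap slides
left while the reference base entering the run equals the one leaving it)
so that indel coordinates are canonical and reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .architecture import GeneModel
from .config import RunConfig
from .errors import ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code, written out rather than imported so the test
# suite can cross-check it against an independent implementation.
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG (ATA=I, ATG=M; AGT/AGC=S, AGA/AGG=R)
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate(cds: str) -> tuple[str, int | None]:
    """Translate a CDS in frame 0 under the standard genetic code.

    Stops at the first stop codon.  Returns ``(protein, stop_index)`` with
    ``stop_index`` the 1-based codon position of the stop, or ``None`` if
    no stop is reached.  Codons containing N translate to ``X`` and are
    never treated as stops.  A trailing partial codon is ignored.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValidationError("CDS shorter than one codon")
    protein = []
    for k in range(len(cds) // 3):
        codon = cds[3 * k : 3 * k + 3]
        if "N" in codon:
            protein.append("X")
            continue
        aa = CODON_TABLE.get(codon)
        if aa is None:
            raise ValidationError(f"illegal codon {codon!r} at codon {k + 1}")
        if aa == "*":
            return "".join(protein), k + 1
        protein.append(aa)
    return "".join(protein), None


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh, affine gaps)

MATCH = 2
MISMATCH = -1
GAP_OPEN = 5  # cost of the first base of a gap
GAP_EXTEND = 1  # cost of each further base

_NEG = -1e9


@dataclasses.dataclass
class ParalogPair:
    """A reference/derived paralog pair with CDSs (e.g. Delta1 vs Delta2)."""

    ref: GeneModel
    alt: GeneModel
    anchor_residue: str = "R"

    def __post_init__(self) -> None:
        for role, gene in (("ref", self.ref), ("alt", self.alt)):
            if gene.cds is None:
                raise ValidationError(f"{role} gene {gene.gene_id!r} has no CDS")
            seq = gene.cds.sequence.upper()
            if not seq.startswith("ATG"):
                raise ValidationError(f"{role} CDS does not begin with ATG")
            if seq[-3:] not in STOP_CODONS:
                raise ValidationError(f"{role} CDS does not end with a stop codon")
        ref_seq = self.ref.cds.sequence.upper()
        if len(ref_seq) % 3 == 0:
            _, stop = translate(ref_seq)
            if stop is not None and stop != len(ref_seq) // 3:
                raise ValidationError("ref CDS has an internal in-frame stop")


@dataclasses.dataclass
class CodonAlignment:
    """Gapped ref/alt nucleotide strings plus per-column classification."""

    ref_aln: str
    alt_aln: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.alt_aln):
            raise ValidationError("aligned rows differ in length")

    @property
    def columns(self) -> list[str]:
        """Per-column kind: match, substitution, insertion_in_alt, deletion_in_alt."""
        kinds = []
        for a, b in zip(self.ref_aln, self.alt_aln):
            if a == "-":
                kinds.append("insertion_in_alt")
            elif b == "-":
                kinds.append("deletion_in_alt")
            elif a == b:
                kinds.append("match")
            else:
                kinds.append("substitution")
        return kinds

    def degapped(self) -> tuple[str, str]:
        return self.ref_aln.replace("-", ""), self.alt_aln.replace("-", "")


def _gotoh_matrices(a: str, b: str):
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    M = np.full((n + 1, m + 1), _NEG)
    D = np.full((n + 1, m + 1), _NEG)  # gap in alt (consumes ref)
    I = np.full((n + 1, m + 1), _NEG)  # gap in ref (consumes alt)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = -GAP_OPEN - (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        I[0, j] = -GAP_OPEN - (j - 1) * GAP_EXTEND
    js = np.arange(m)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH).astype(float)
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], D[i - 1, :-1]), I[i - 1, :-1])
        M[i, 1:] = prev_best + sub
        D[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], I[i - 1, 1:]) - GAP_OPEN, D[i - 1, 1:] - GAP_EXTEND
        )
        # I[i, j] = max_{k < j} (max(M, D)[i, k] - GAP_OPEN - (j-1-k) * GAP_EXTEND)
        c = np.maximum(M[i, :-1], D[i, :-1]) - GAP_OPEN + js * GAP_EXTEND
        I[i, 1:] = np.maximum.accumulate(c) - js * GAP_EXTEND
    return M, D, I


def _traceback(a: str, b: str, M, D, I) -> tuple[str, str]:
    i, j = len(a), len(b)
    # State preference on exact score ties: diagonal, then deletion-in-alt,
    # then insertion-in-alt (ties are rare for these integer scores and are
    # made irrelevant for indel coordinates by left-normalisation below).
    scores = (M[i, j], D[i, j], I[i, j])
    state = int(np.argmax(scores))
    ra, rb = [], []
    while i > 0 or j > 0:
        if state == 0:
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            prev = (M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            target = M[i, j] - sub
            state = next(k for k in range(3) if abs(prev[k] - target) < 1e-6)
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            opts = (
                M[i - 1, j] - GAP_OPEN,
                D[i - 1, j] - GAP_EXTEND,
                I[i - 1, j] - GAP_OPEN,
            )
            state_next = next(k for k in range(3) if abs(opts[k] - D[i, j]) < 1e-6)
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
            state = state_next
        else:
            opts = (
                M[i, j - 1] - GAP_OPEN,
                D[i, j - 1] - GAP_OPEN,
                I[i, j - 1] - GAP_EXTEND,
            )
            state_next = next(k for k in range(3) if abs(opts[k] - I[i, j]) < 1e-6)
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
            state = state_next
    return "".join(reversed(ra)), "".join(reversed(rb))


def _left_normalize(ref_aln: str, alt_aln: str) -> tuple[str, str]:
    """Slide every gap run as far left as score-equivalence allows.

    A gap run in one row spanning columns [c1, c2] can shift one column
    left iff the other row's residue at c1-1 equals its residue at c2
    (the displaced residue pairs with an identical partner).  Iterating to
    a fixpoint yields the canonical leftmost placement, e.g. a deletion in
    a homopolymer run is always reported at the run's first base.
    """
    rows = [list(ref_aln), list(alt_aln)]
    changed = True
    while changed:
        changed = False
        for g, other in ((0, 1), (1, 0)):
            gap_row, res_row = rows[g], rows[other]
            c = 0
            ncol = len(gap_row)
            while c < ncol:
                if gap_row[c] != "-":
                    c += 1
                    continue
                c2 = c
                while c2 + 1 < ncol and gap_row[c2 + 1] == "-":
                    c2 += 1
                while (
                    c > 0
                    and gap_row[c - 1] != "-"
                    and res_row[c - 1] != "-"
                    and res_row[c - 1] == res_row[c2]
                ):
                    gap_row[c2] = gap_row[c - 1]
                    gap_row[c - 1] = "-"
                    c, c2 = c - 1, c2 - 1
                    changed = True
                c = c2 + 1
    return "".join(rows[0]), "".join(rows[1])


def align_cds(ref: str, alt: str) -> CodonAlignment:
    """Global affine-gap alignment of two CDSs with canonical gap placement."""
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValidationError("cannot align an empty sequence")
    M, D, I = _gotoh_matrices(ref, alt)
    score = max(M[-1, -1], D[-1, -1], I[-1, -1])
    ra, rb = _traceback(ref, alt, M, D, I)
    ra, rb = _left_normalize(ra, rb)
    aln = CodonAlignment(ra, rb, float(score))
    if aln.degapped() != (ref, alt):
        raise AssertionError("traceback does not reproduce input sequences")
    return aln


def align_paralogs(pair: ParalogPair) -> CodonAlignment:
    return align_cds(pair.ref.cds.sequence, pair.alt.cds.sequence)


# ---------------------------------------------------------------------------
# Mechanism classification


@dataclasses.dataclass
class Edit:
    """One difference between ref and alt in alt coordinates (0-based).

    For substitutions ``alt_pos`` is the substituted base; for insertions
    the first inserted base; for deletions the alt position immediately
    after the deleted ref bases (the gap's boundary in alt coordinates).
    """

    kind: str  # substitution | insertion | deletion
    alt_pos: int
    ref_pos: int
    length: int
    ref_bases: str
    alt_bases: str

    def describe(self) -> str:
        return f"{self.kind}@alt:{self.alt_pos + 1}({self.ref_bases or '-'}>{self.alt_bases or '-'})"


def edits_from_alignment(aln: CodonAlignment) -> list[Edit]:
    """Collapse alignment columns into substitution and indel-run edits."""
    edits: list[Edit] = []
    kinds = aln.columns
    ref_pos = alt_pos = 0
    c = 0
    ncol = len(kinds)
    while c < ncol:
        kind = kinds[c]
        if kind == "match":
            ref_pos += 1
            alt_pos += 1
            c += 1
        elif kind == "substitution":
            edits.append(
                Edit("substitution", alt_pos, ref_pos, 1, aln.ref_aln[c], aln.alt_aln[c])
            )
            ref_pos += 1
            alt_pos += 1
            c += 1
        else:
            c2 = c
            while c2 + 1 < ncol and kinds[c2 + 1] == kind:
                c2 += 1
            run = c2 - c + 1
            if kind == "insertion_in_alt":
                edits.append(
                    Edit("insertion", alt_pos, ref_pos, run, "", aln.alt_aln[c : c2 + 1])
                )
                alt_pos += run
            else:
                edits.append(
                    Edit("deletion", alt_pos, ref_pos, run, aln.ref_aln[c : c2 + 1], "")
                )
                ref_pos += run
            c = c2 + 1
    return edits


MECHANISMS = (
    "insertion_stop",
    "substitution_nonsense",
    "deletion_frameshift",
    "insertion_frameshift",
    "none",
)


@dataclasses.dataclass
class TruncationReport:
    pair_id: str
    premature: bool
    alt_stop_codon_index: int | None
    ref_length_codons: int
    mechanism: str
    causal_edit: Edit | None
    alternates: list[Edit]
    anchor_offset: int | None
    within_window: bool | None  # None = indeterminate (no anchor found)


def mechanism_of_stop(alt_cds: str, edits: Sequence[Edit]) -> tuple[str, Edit | None, list[Edit]]:
    """Type the mutation causing alt's first in-frame stop.

    Pure positional definition shared with the synthetic planter: the stop
    codon spans alt nucleotides [3(s-1), 3s); a substitution inside the
    span is nonsense, an insertion whose inserted bases overlap the span
    created the stop directly, otherwise the nearest upstream
    frame-shifting indel is causal.
    """
    _, stop = translate(alt_cds)
    if stop is None:
        raise ValidationError("alt CDS has no in-frame stop")
    lo, hi = 3 * (stop - 1), 3 * stop  # [lo, hi) in alt coordinates
    in_span_subs = [
        e for e in edits if e.kind == "substitution" and lo <= e.alt_pos < hi
    ]
    in_span_ins = [
        e
        for e in edits
        if e.kind == "insertion" and e.alt_pos < hi and e.alt_pos + e.length > lo
    ]
    # Everything at or upstream of the stop is a potential alternate cause.
    upstream = [e for e in edits if e.alt_pos < hi]
    if in_span_subs:
        causal = in_span_subs[0]
        return "substitution_nonsense", causal, [e for e in upstream if e is not causal]
    if in_span_ins:
        causal = in_span_ins[0]
        return "insertion_stop", causal, [e for e in upstream if e is not causal]
    # Frame-shifting indels whose effect reaches the stop codon: a deletion
    # boundary at or before the stop start, or an insertion ending there.
    shifts = [
        e
        for e in edits
        if e.length % 3
        and (
            (e.kind == "deletion" and e.alt_pos <= lo)
            or (e.kind == "insertion" and e.alt_pos + e.length <= lo)
        )
    ]
    if not shifts:
        raise ValidationError("premature stop with no causal edit in the alignment")
    causal = max(shifts, key=lambda e: e.alt_pos)  # nearest upstream wins
    mech = "deletion_frameshift" if causal.kind == "deletion" else "insertion_frameshift"
    return mech, causal, [e for e in upstream if e is not causal]


def _ref_codon_at_alt_stop(aln: CodonAlignment, alt_stop: int) -> int:
    """Reference codon position aligned with the alt stop codon start."""
    target = 3 * (alt_stop - 1) + 1  # 1-based alt coordinate of the stop's first base
    ref_pos = alt_pos = 0
    for a, b in zip(aln.ref_aln, aln.alt_aln):
        if a != "-":
            ref_pos += 1
        if b != "-":
            alt_pos += 1
        if alt_pos == target and b != "-":
            break
    return (max(ref_pos, 1) - 1) // 3 + 1


def classify_mechanism(
    pair: ParalogPair,
    alignment: CodonAlignment | None = None,
    config: RunConfig | None = None,
) -> TruncationReport:
    """Full truncation report for a paralog pair.

    Locates the derived paralog's first in-frame stop, types its cause
    from the alignment edits (nearest upstream frame-changing edit wins;
    every other upstream difference is reported as an alternate), and
    computes the offset from the last reference anchor residue (arginine
    by default) to the stop, checked against the configured 1-10 window.
    """
    cfg = config or RunConfig()
    aln = alignment or align_paralogs(pair)
    ref_cds = pair.ref.cds.sequence.upper()
    alt_cds = pair.alt.cds.sequence.upper()
    ref_prot, ref_stop = translate(ref_cds)
    alt_prot, alt_stop = translate(alt_cds)
    pair_id = f"{pair.ref.gene_id}|{pair.alt.gene_id}"
    premature = len(alt_prot) < len(ref_prot)
    if not premature:
        return TruncationReport(
            pair_id, False, alt_stop, len(ref_prot), "none", None, [], None, None
        )
    edits = edits_from_alignment(aln)
    mech, causal, alternates = mechanism_of_stop(alt_cds, edits)

    # Anchor offset: amino acids from the last ref anchor residue upstream
    # of the stop (in ref-frame coordinates) to the stop position.
    anchor = (pair.anchor_residue or cfg.anchor_residue).upper()
    stop_ref_codon = _ref_codon_at_alt_stop(aln, alt_stop)
    anchor_positions = [
        k + 1 for k, aa in enumerate(ref_prot[: stop_ref_codon - 1]) if aa == anchor
    ]
    if anchor_positions:
        anchor_offset = stop_ref_codon - anchor_positions[-1]
        within = cfg.window_lo <= anchor_offset <= cfg.window_hi
    else:
        anchor_offset, within = None, None
    return TruncationReport(
        pair_id,
        True,
        alt_stop,
        len(ref_prot),
        mech,
        causal,
        alternates,
        anchor_offset,
        within,
    )


def termination_window_check(report: TruncationReport, config: RunConfig | None = None) -> bool | None:
    """True iff the stop falls in the configured window after the anchor.

    Returns ``None`` (indeterminate, flagged) when no anchor residue was
    found upstream of the stop in the reference.
    """
    cfg = config or RunConfig()
    if not report.premature:
        raise ValidationError("window check requires a premature report")
    if report.anchor_offset is None:
        return None
    return cfg.window_lo <= report.anchor_offset <= cfg.window_hi
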