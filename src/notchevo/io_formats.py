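"""Readers and writers for every external format the pipeline touches.

Formats
-------
* FASTA (protein or CDS); the writer wraps at 60 columns, the reader
  accepts any wrapping.
* Newick trees (rooted; branch lengths and internal labels optional),
  backed by dendropy.
* Domain-hit tables: tab-separated, six fixed columns
  ``gene_id  domain_name  pfam_accession  env_start  env_end  e_value``
  with ``#`` comment lines.  Coordinates are 1-based inclusive residue
  positions, matching HMMER envelope coordinates.
* Expression matrices: tab-separated, first column gene ids, header row of
  developmental-stage labels, values nonnegative RPKM/FPKM.
* Presence/absence matrices: families x species, cells 0/1.

Parsers never silently drop records: anything that cannot be represented
raises :class:`~notchevo.errors.ParseError` (bad bytes, with a line or row
number) or :class:`~notchevo.errors.ValidationError` (invariant violation).
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .errors import ParseError, ValidationError

log = logging.getLogger("notchevo")

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*", "-"}
DNA_ALPHABET = set("ACGTN")


@dataclasses.dataclass
class SequenceRecord:
    """One FASTA record with a declared alphabet.

    ``alphabet`` is ``"protein"`` (20 standard letters plus X, * and the
    gap character for aligned input) or ``"dna"`` (A, C, G, T, N).
    """

    id: str
    description: str
    sequence: str
    alphabet: str  # "protein" | "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: illegal {self.alphabet} character(s) "
                + ", ".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class DomainHitRow:
    """One domain annotation on one protein (HMMER-style envelope)."""

    gene_id: str
    domain_name: str
    pfam_accession: str | None
    env_start: int
    env_end: int
    e_value: float

    def __post_init__(self) -> None:
        if self.env_start < 1:
            raise ValidationError(
                f"{self.gene_id}/{self.domain_name}: env_start must be >= 1"
            )
        if self.env_end < self.env_start:
            raise ValidationError(
                f"{self.gene_id}/{self.domain_name}: env_end < env_start"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"{self.gene_id}/{self.domain_name}: negative e_value"
            )

    @property
    def length(self) -> int:
        return self.env_end - self.env_start + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Parse a FASTA file, validating ids and residue alphabets.

    Raises ParseError (naming the line number) on malformed headers or
    illegal characters, and ValidationError on duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        sid, _, desc = header.partition(" ")
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sequence id {sid!r}")
        seen.add(sid)
        records.append(SequenceRecord(sid, desc, seq, alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                bad = set(line.upper()) - allowed
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal {alphabet} character(s) "
                        + ", ".join(sorted(bad))
                    )
                chunks.append(line.strip().upper())
    flush()
    log.info("read_fasta: %s -> %d records", path, len(records))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Newick


def _validate_tree(tree: dendropy.Tree, source: str) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"{source}: duplicate leaf label(s): {', '.join(dupes)}")
    tree.is_rooted = True
    return tree


def _get_tree(source: dict, name: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **source)
    except Exception as exc:  # dendropy raises several parse exception types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"{name}: duplicate leaf labels") from exc
        raise ParseError(f"{name}: not parseable as newick: {exc}") from exc
    return _validate_tree(tree, name)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree; duplicate leaf labels are rejected."""
    return _get_tree({"path": str(path)}, str(path))


def tree_from_string(newick: str) -> dendropy.Tree:
    return _get_tree({"data": newick}, "<string>")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_string(tree) + "\n")


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


# ---------------------------------------------------------------------------
# Domain-hit tables

DOMAIN_HIT_COLUMNS = (
    "gene_id",
    "domain_name",
    "pfam_accession",
    "env_start",
    "env_end",
    "e_value",
)


def read_domain_hits(path: str | Path) -> list[DomainHitRow]:
    """Read the 6-column tab-separated domain-hit dialect.

    Column order is fixed (see DOMAIN_HIT_COLUMNS); ``-`` in the accession
    column means "no accession"; ``#`` lines are comments.  An optional
    header row repeating the column names is tolerated and skipped.
    """
    rows: list[DomainHitRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if tuple(parts) == DOMAIN_HIT_COLUMNS:
                continue
            if len(parts) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            gene_id, domain, acc, start_s, end_s, ev_s = parts
            try:
                start, end = int(start_s), int(end_s)
                e_value = float(ev_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            try:
                rows.append(
                    DomainHitRow(
                        gene_id=gene_id,
                        domain_name=domain,
                        pfam_accession=None if acc in ("", "-") else acc,
                        env_start=start,
                        env_end=end,
                        e_value=e_value,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    log.info("read_domain_hits: %s -> %d rows", path, len(rows))
    return rows


def write_domain_hits(
    rows: Iterable[DomainHitRow], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("# coordinates are 1-based inclusive residue positions\n")
        fh.write("\t".join(DOMAIN_HIT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.domain_name}\t{r.pfam_accession or '-'}\t"
                f"{r.env_start}\t{r.env_end}\t{r.e_value:g}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_matrix(path: str | Path, unit: str = "RPKM"):
    """Read a genes x stages expression table into an ExpressionMatrix.

    Stage order is taken from the header and preserved; negative values and
    missing cells are rejected.
    """
    from .expression import ExpressionMatrix

    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    ncol = len(header)
    for i, line in enumerate(lines[1:], 2):
        if len(line.split("\t")) != ncol:
            raise ParseError(f"{path}: row {i} has ragged width")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing cells in expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    log.info("read_expression_matrix: %s -> %d genes x %d stages", path, *df.shape)
    return ExpressionMatrix(values=df, unit=unit)


def write_expression_matrix(matrix, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene", float_format="%g")


# ---------------------------------------------------------------------------
# Presence/absence matrices (families x species, 0/1)


def read_presence_absence(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing cells in presence/absence matrix")
    values = df.astype(int)
    if not values.isin((0, 1)).all().all():
        raise ValidationError(f"{path}: presence/absence cells must be 0 or 1")
    return values


def write_presence_absence(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="family")


# ---------------------------------------------------------------------------
# Generic TSV with provenance header


def write_table(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None, index: bool = False
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%g")


def read_table(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return pd.read_csv(io.StringIO("\n".join(lines)), sep="\t")
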