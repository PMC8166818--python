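"""Shared fixtures and helpers for the notchevo test suite."""

from __future__ import annotations

import pytest

from notchevo.architecture import GeneModel
from notchevo.io_formats import SequenceRecord
from notchevo.truncation import ParalogPair, translate


def gene_from_cds(gene_id: str, cds: str, species: str = "SYN") -> GeneModel:
    """Build a minimal GeneModel around a coding sequence."""
    protein, _ = translate(cds)
    return GeneModel(
        gene_id,
        species,
        SequenceRecord(gene_id, "", protein or "M", "protein"),
        SequenceRecord(f"{gene_id}_cds", "", cds, "dna"),
    )


def paralog_pair(ref_cds: str, alt_cds: str, anchor: str = "R") -> ParalogPair:
    return ParalogPair(
        gene_from_cds("ref", ref_cds), gene_from_cds("alt", alt_cds), anchor
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The packaged synthetic dataset, generated once per session."""
    from notchevo.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("fixtures") / "bundle"
    make_fixtures(seed=42, out_dir=out)
    return out
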