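"""Type the mutation behind a premature stop in a derived paralog.

Mirrors the duplicated mollusc Delta analysis: the derived paralog
(Delta2) is shorter than its reference (Delta1) because of a single
mutation near the reference terminus.  We plant each of the four
mechanisms in a clean reading frame and recover mechanism, coordinate
and the stop position from the codon alignment alone.
"""

from notchevo import (
    GeneModel,
    ParalogPair,
    PlantError,
    SequenceRecord,
    classify_mechanism,
    translate,
)
from notchevo.synthetic import MECHANISM_CHOICES, plant_truncation, random_cds


def as_gene(gene_id: str, cds: str) -> GeneModel:
    protein, _ = translate(cds)
    return GeneModel(
        gene_id, "Cgi",
        SequenceRecord(gene_id, "", protein, "protein"),
        SequenceRecord(f"{gene_id}_cds", "", cds, "dna"),
    )


ref_cds = random_cds(120, seed=4)

for mechanism in MECHANISM_CHOICES:
    # Not every codon admits every mechanism (e.g. a nonsense substitution
    # needs a codon one base away from a stop), so scan for a valid target.
    for target in range(35, 60):
        try:
            alt_cds, truth = plant_truncation(ref_cds, mechanism, target, seed=8)
            break
        except PlantError:
            continue
    pair = ParalogPair(as_gene("Delta1", ref_cds), as_gene("Delta2", alt_cds))
    report = classify_mechanism(pair)
    print(
        f"{mechanism:<22} recovered={report.mechanism:<22} "
        f"stop at codon {report.alt_stop_codon_index} of {report.ref_length_codons}, "
        f"edit {report.causal_edit.describe()}"
    )

# The recovered mechanism matches the planted one and the edit coordinate
# is exact (1-based position in the derived CDS).  The report also carries
# the offset from the last reference arginine to the stop, used to test
# whether truncations cluster 1-10 residues after the conserved anchor.
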