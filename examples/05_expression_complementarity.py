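"""Score developmental expression similarity and complementarity.

RPKM/FPKM values are only comparable as within-gene trends, so paralog
profiles are compared by Spearman rank correlation over ordered
developmental stages.  The fixture mirrors the bivalve ligand pattern:
Delta1 peaks early, Delta2 rises late (its complement), and Jagged
tracks Delta2.
"""

from notchevo import ExpressionMatrix, nearest_profile, profile_similarity, stage_peak_report
from notchevo.synthetic import mollusc_expression_matrix

values, _ = mollusc_expression_matrix(seed=0)
matrix = ExpressionMatrix(values, "RPKM")

comparison = profile_similarity(
    matrix.profile("Delta1"), matrix.profile("Delta2"),
    gene_a="Delta1", gene_b="Delta2",
)
print(f"Delta1 vs Delta2: rho={comparison.score:+.2f} -> {comparison.relation}")

ranking = nearest_profile("Jagged", ["Delta1", "Delta2"], matrix)
for c in ranking:
    print(f"Jagged vs {c.gene_b}: rho={c.score:+.2f} -> {c.relation}")

print(stage_peak_report(matrix).to_string(index=False))

# Delta1/Delta2 are complementary (rho <= -0.5); Jagged ranks closer to
# Delta2 than Delta1.  The peak table reports each gene's maximal stage
# and a (max+1)/(median+1) enrichment ratio on raw values.
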