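"""Place a gene family's origin and losses on a species tree.

The packaged mollusc case study: Delta2 is present in gastropods,
cephalopods and bivalves but absent from the chiton outgroup and from
three gastropods.  Dollo parsimony (one gain, minimal losses) places the
origin on the stem of Gastropoda+Cephalopoda+Bivalvia with three
independent single-branch losses.
"""

from notchevo import annotate_losses, dollo_reconstruct
from notchevo.synthetic import mollusc_presence_matrix, mollusc_tree

tree = mollusc_tree()
matrix, _ = mollusc_presence_matrix()

for family in ("Delta1", "Delta2", "Helt"):
    presence = {sp: int(matrix.loc[family, sp]) for sp in matrix.columns}
    history = dollo_reconstruct(tree, presence, family=family)
    origin = "root (or earlier)" if history.origin_at_root else (
        "+".join(sorted(history.gain_edge))
    )
    print(f"{family}: gain above [{origin}]")
    print(f"  losses ({history.n_losses}): {annotate_losses(history) or '-'}")

# Delta1 is everywhere, so its origin is at (or before) the root of the
# sampled taxa with no losses.  Delta2 gains once on the conchiferan stem
# and is lost three times, each on a terminal gastropod branch.  Helt is
# ancestral but lost twice within gastropods (once on an internal branch
# covering a whole subclade).
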