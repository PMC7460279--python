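"""Population structure: IBS/MDS at the individual level, Reynolds + NJ at
the breed level.

Two breed pairs in the study generator share a recent common frequency pool
(the Padovana/Polverara situation); the neighbor-joining tree on Reynolds
distances should place each pair as neighbors.
"""

from galdiv import (
    apply_qc,
    breed_average_mds,
    make_study_fixture,
    neighbor_joining,
    reynolds_distance,
    write_newick,
)

ds, _ = make_study_fixture(seed=7)
ds, _ = apply_qc(ds)

mds = breed_average_mds(ds, k=2)
print("breed-average MDS coordinates (first components):")
print(mds.coordinates.head(6).round(4).to_string())

reyn = reynolds_distance(ds)
print(f"\nReynolds theta range: {reyn.d[reyn.d > 0].min():.3f} .. "
      f"{reyn.d.max():.3f}")

tree = neighbor_joining(reyn)
for a, b in (("PPA", "PPC"), ("PPB", "PPN")):
    siblings = {t.name for t in tree.find(a).parent.children if t.is_tip()}
    print(f"{a} NJ neighbors: {sorted(siblings - {a})} "
          f"({'pairs with ' + b if b in siblings else 'does not pair'})")
print("\nNewick (truncated):", write_newick(tree)[:90], "...")
# Clade mates pair in the tree because their allele frequencies drifted from
# a shared intermediate pool, the same signal Reynolds distance is built for.
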