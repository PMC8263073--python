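"""Network-based statistics on a planted group difference.

Group A carries an intrathalamic correlation delta of +0.25 over the shared
baseline; NBS should isolate a supra-threshold component concentrated on
the 16 thalamic regions.
"""
from collections import Counter

import gaersnet as gn

atlas = gn.default_atlas()
base = gn.default_study_spec()
stronger = base.with_edge_delta("thalamus", "thalamus", 0.25)

group_a = [gn.correlation_matrix(ts) for ts in
           gn.generate_group_timeseries(atlas, stronger, 8, 900, seed=1)]
group_b = [gn.correlation_matrix(ts) for ts in
           gn.generate_group_timeseries(atlas, base, 8, 900, seed=2)]

res = gn.nbs_test(group_a, group_b, alpha=0.05, n_perm=1000, seed=3)
for comp in res.significant:
    groups = Counter(
        r.functional_group for r in atlas.regions if r.abbreviation in comp.nodes
    )
    print(f"{comp.direction}: {comp.n_nodes} nodes, {comp.n_edges} connections, "
          f"P = {comp.p_value:.4g}")
    print("  node composition:", dict(groups))
print("The A>B component should sit on the thalamus — the planted effect —")
print("with its permutation probability bounded below by 1/(n_perm + 1).")
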