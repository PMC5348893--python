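"""Simulate a two-locus spidroin family down a species tree with and
without terminal-only gene conversion, and show how the NJ tree of the
terminal regions flips from ortholog grouping to paralog grouping.

Run:  python examples/04_concerted_evolution.py
"""

import dendropy
import numpy as np

from spidrokit.phylo import global_align, neighbor_joining, p_distance
from spidrokit.synth import SpidroinSpec, evolve_family, terminal_regions

st = dendropy.Tree.get(data="((S1:0.03,S2:0.03):0.02,(S3:0.03,S4:0.03):0.02);",
                       schema="newick", preserve_underscores=True)
st.is_rooted = True
spec = SpidroinSpec(seed=0, repeat_copies=10)

for conv, label in [(0.0, "conversion OFF"), (300.0, "terminal-only conversion ON")]:
    seqs, log = evolve_family(spec, st, n_loci=2, root_divergence=0.08,
                              conversion_rate=conv, terminal_only=True, seed=7)
    terms = {}
    for sid, rec in seqs.items():
        n, r, c = terminal_regions(rec, 450, 300)
        terms[sid] = n.residues + c.residues
    ids = sorted(terms)
    dm = np.zeros((len(ids), len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dm[i, j] = dm[j, i] = p_distance(global_align(terms[ids[i]], terms[ids[j]]))
    tree = neighbor_joining(ids, dm, midpoint_root=True)
    print(f"\n{label} ({len(log.of_type('conversion'))} conversion events)")
    print(tree.as_ascii_plot(plot_metric="level"))

print("With conversion off, termini track the species history (orthologs "
      "cluster by locus); frequent terminal-only conversion homogenizes the "
      "two loci within each species, so paralogs become sisters — the "
      "signature concerted evolution leaves in real spidroin terminal "
      "domains while the repetitive regions stay divergent.")
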