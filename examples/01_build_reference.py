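"""Build a tRF candidate reference from a (simulated) tRNA gene set.

Every tRNA gene yields mature-end fragment candidates of 15-30 nt: 5'-tRFs
(mature prefixes), 3'-tRFs (mature suffixes ending in CCA) and 3'U-tRFs
(pre-tRNA trailer fragments ending in the poly-U tract). Identical
sequences from multi-copy families are merged into one named candidate.
"""

from collections import Counter

from trfscape import enumerate_trf_candidates
from trfscape.simulate import simulate_reference

genes, _records = simulate_reference(n_genes=20, seed=1)
candidates = enumerate_trf_candidates(genes, length_range=(15, 30))

per_class = Counter(c.trf_class for c in candidates)
print(f"{len(genes)} tRNA genes -> {len(candidates)} tRF candidates")
for cls, n in sorted(per_class.items()):
    print(f"  {cls:>14}: {n}")
merged = [c for c in candidates if len(c.parent_families) > 1]
print(f"candidates shared by several gene families: {len(merged)}")
print("example names:", ", ".join(c.name for c in candidates[:3]))
# Each 5'-tRF name encodes end (5'/3'/3'U), parent family and length, e.g.
# 5'-ArgACG-1-1-L15 is the 15 nt fragment from the 5' end of tRNA-ArgACG-1-1.
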