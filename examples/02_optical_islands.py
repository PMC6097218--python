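"""Optical map assembly and hybrid scaffolding into islands.

Simulates nick-label molecules (50x, 3% sizing noise, 10% missed labels,
1 false label / 100 kb) from a 1 Mb region, assembles a consensus map,
then orders three sequence scaffolds on it and sizes the gaps between them.
"""

import numpy as np

from finishkit import simulate as sim
from finishkit.optical import (AlignParams, align_digest_to_map,
                               assemble_optical_maps, build_islands,
                               digest_sequence)

SEED = 0

genome, _ = sim.simulate_genome(sim.GenomeConfig(length=1_000_000), SEED)
mols, truth = sim.simulate_optical_molecules(
    genome, sim.OpticalConfig(coverage=50), SEED + 1)
maps = assemble_optical_maps(mols, seed=SEED)
big = max(maps, key=lambda m: len(m.sites))
print(f"{len(mols)} molecules -> consensus map with {len(big.sites)} label "
      f"sites over {big.length/1e6:.2f} Mb ({len(truth['sites'])} true sites)")

# three scaffolds with 5 kb inter-scaffold gaps, middle one flipped
cuts = [(0, 300_000, "+"), (305_000, 640_000, "-"), (645_000, 1_000_000, "+")]
from finishkit.io import revcomp
scaffolds = []
for i, (s, e, orient) in enumerate(cuts):
    seq = genome[s:e]
    scaffolds.append(digest_sequence(seq if orient == "+" else revcomp(seq),
                                     seq_id=f"scf{i}"))
params = AlignParams(max_skip=6, threshold=1e-6, seed=SEED)
alignments = [a for d in scaffolds
              for a in [align_digest_to_map(d, big, params)] if a]
islands = build_islands(scaffolds, maps, alignments)
for isl in islands:
    comps = [(kind, name, orient) for kind, name, orient, *_ in isl.components]
    print(isl.island_id, comps)
    for g in isl.gaps:
        print(f"  gap {g['left']}|{g['right']}: {g['size']:.0f} bp "
              f"(sized={g['sized']}; truth 5000 bp)")
# the island orders and orients the scaffolds on the optical frame and
# sizes the sequence gaps from the label coordinates.
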