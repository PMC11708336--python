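"""Design a tiling spacer library and its synthesis oligos.

Builds a small synthetic phage genome, tiles 35-nt spacers every 2 nt on
both strands, and prints the library size plus one example oligo.
"""

from spacerscreen.design import LibraryDesignConfig, design_tiling_library
from spacerscreen.simulate import SimulationConfig, simulate_genome

cfg = SimulationConfig(
    seed=1, genome_length=4000,
    operon_plan=[("PE", 100, 1500, "+", 5.0), ("PL", 1500, 4000, "+", 15.0)],
)
genome = simulate_genome(cfg)
library = design_tiling_library(genome, LibraryDesignConfig(spacer_length=35, step=2))

rec, oligo = library.records[0], library.oligos[0]
print(f"genome: {genome.name}, {genome.length} nt")
print(f"library: {len(library)} spacers (both strands, every 2 nt)")
print(f"first spacer: [{rec.start},{rec.end}) strand {rec.strand}: {rec.sequence}")
print(f"its 90-nt oligo: {oligo}")
# The library size follows the closed form 2 * (floor((L - k)/step) + 1);
# every oligo is exactly 90 nt: priming + BsaI + repeat homology + spacer.
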