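"""In-silico BsaXI digestion of a genome.

Builds a small synthetic genome, scans both degenerate forms of the BsaXI
recognition motif, excises the 33-nt tags around every site and reports how
many tags are unique genome-wide — the loci usable as markers.
"""

from i2brad import extract_tags, find_unique_tags, scan_sites
from i2brad.simdata import SimConfig, generate_genome

genome, sites = generate_genome(
    SimConfig(seed=1, chromosome_lengths=(200_000,), n_planted_sites=None)
)
plus = sum(s.orientation == "plus_form" for s in sites)
minus = len(sites) - plus
print(f"genome: {sum(len(s) for s in genome.values()):,} bp")
print(f"BsaXI recognition sites: {len(sites)} ({plus} plus-form, {minus} minus-form)")

drops: dict = {}
tags = extract_tags(genome, sites, "BsaXI", drop_counter=drops)
find_unique_tags(tags)
n_unique = sum(1 for t in tags if t.unique)
print(f"extracted tags: {len(tags)} (33 nt each, {drops.get('out_of_bounds', 0)} "
      "dropped at sequence ends)")
print(f"unique tags: {n_unique} — candidate marker loci")
# Each site yields one uniform-length fragment; unique tags are the loci a
# read can be assigned to unambiguously.
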