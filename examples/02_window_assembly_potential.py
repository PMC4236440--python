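"""Assembly-potential windows: what a second enzyme adds.

Tiles a genome into 4000-bp windows (one expected EcoRI site each on
average) and classifies each window by recognition-site count: 0 sites
means a scaffold of that size could never be anchored, 1 allows anchoring
without orientation, 2+ allows oriented placement. Cross-tabulating EcoRI
with BsaXI shows how many EcoRI-dead windows the type IIB enzyme rescues.
"""

from i2brad import classify_windows, cross_tabulate, scan_sites, tile_windows
from i2brad.simdata import SimConfig, generate_genome

genome, _ = generate_genome(
    SimConfig(seed=2, chromosome_lengths=(2_000_000,), n_planted_sites=None)
)
ws = tile_windows({k: len(v) for k, v in genome.items()}, 4000)
classify_windows(
    ws, {"EcoRI": scan_sites(genome, "EcoRI"), "BsaXI": scan_sites(genome, "BsaXI")}
)
t = cross_tabulate(ws, "EcoRI", "BsaXI")
print(f"windows: {t['n_windows']}")
print(f"EcoRI marginals  zero/one/many: {t['marginal_a']}")
print(f"BsaXI marginals  zero/one/many: {t['marginal_b']}")
print(f"EcoRI=0 and BsaXI>1 (rescued, orientable): {t['a_zero_b_many']['count']}")
print(f"EcoRI=1 and BsaXI>0 (rescued, anchorable): {t['a_one_b_any']['count']}")
print(
    "windows with >= 2 combined sites: "
    f"{t['combined_ge2']['count']} ({t['combined_ge2']['fraction']:.1%})"
)
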