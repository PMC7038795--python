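"""Simulate a chromomere map and one microdissection read sample.

Builds a 90 Mb chromosome, tiles it with chromomeres (common 1.5-3.5 Mb,
marker 4-5 Mb), and simulates the mapped reads of one dissected chromomere
with PCR duplicates, contamination and spillover into its neighbors.
"""
from lbcmap import (
    ChromomereMapSpec,
    DissectionSimSpec,
    GenomeMap,
    generate_chromomere_map,
    simulate_dissection_sample,
)
from lbcmap.simulate import neighbors_in_map

genome = GenomeMap({"chr4": 90_000_000})
sites = generate_chromomere_map(ChromomereMapSpec(genome=genome, seed=7))
n_marker = sum(s.kind == "marker" for s in sites)
print(f"chromomere map: {len(sites)} chromomeres ({n_marker} marker)")

site = sites[10]
reads = simulate_dissection_sample(
    site.interval, neighbors_in_map(sites, 10),
    DissectionSimSpec(seed=1), genome, sample_id=site.chromomere_id,
)
inside = sum(
    1 for r in reads
    if site.interval.start <= r.interval.start < site.interval.end
)
print(f"dissected {site.chromomere_id}: true span {site.interval} "
      f"({site.interval.length/1e6:.2f} Mb)")
print(f"simulated {len(reads)} reads, {inside} starting inside the chromomere")
print("the remainder is contamination/spillover noise the border caller must reject")
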