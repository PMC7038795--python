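"""Gene density and repeat content of called chromomeres.

Common chromomeres are simulated gene-dense and repeat-poor, marker
chromomeres gene-poor and repeat-rich; the annotation step recovers that
contrast from the called intervals alone.
"""
from lbcmap import (
    ChromomereCall,
    ChromomereMapSpec,
    GenomeMap,
    annotate_chromomere,
    generate_chromomere_map,
    generate_gene_repeat_annotations,
)

genome = GenomeMap({"chr4": 60_000_000})
sites = generate_chromomere_map(
    ChromomereMapSpec(genome=genome, marker_fraction=0.25, seed=5)
)
genes, repeats = generate_gene_repeat_annotations(sites, seed=6)

print("chromomere    class    genes  genes/Mb  repeat_frac  label")
for site in sites[:10]:
    # use the true interval as a perfect call to isolate the annotation step
    call = ChromomereCall(site.chromomere_id, site.interval,
                          site.interval.length / 1e6, 0, 0, 1, False)
    profile = annotate_chromomere(call, genes, repeats)
    print(f"{site.chromomere_id}  {site.kind:7} {profile.gene_count:5d}  "
          f"{profile.gene_density:8.2f}  {profile.repeat_fraction:11.3f}  "
          f"{profile.class_label}")
print("marker chromomeres should be repeat_rich, common ones gene_rich")
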