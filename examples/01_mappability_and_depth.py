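"""Mappability maps and read-depth ratios on a toy reference.

Builds a small random genome containing one exact duplication, maps
k-mer uniqueness, and shows how the duplicated tract loses all uniquely
mappable read-start positions while the rest of the genome keeps them.
"""

import numpy as np

import copydepth as cd

rng = np.random.default_rng(0)
genome = "".join(rng.choice(list("ACGT"), size=30_000))
# paste an exact copy of [2000, 5000) at 20000 to create a repeat
genome = genome[:20_000] + genome[2_000:5_000] + genome[23_000:]
reference = {"chr1": genome}

kmap = cd.build_kmer_map(reference, k=21)
loci = [
    cd.Locus("unique_locus", "chr1", 8_000, 11_000),
    cd.Locus("repeat_locus", "chr1", 2_100, 4_900),
]
cd.annotate_loci(loci, reference, kmap)
for loc in loci:
    print(f"{loc.id}: u = {loc.u} unique 21-mer starts, GC = {loc.gc:.3f}")
# u is ~0 inside the duplicated tract: every interior k-mer occurs twice,
# so no read can be placed there unambiguously.

kept, excluded = cd.filter_low_mappability(loci, min_u=500)
print(f"kept {len(kept)}, excluded {len(excluded)} (fewer than 500 unique k-mers)")

# expected depth: a locus with u unique positions in a genome of G bases
# sampled by N reads expects E = u*N/G reads at baseline copy number.
E = cd.expected_depth(u=loci[0].u, N=60_000, G=len(genome))
print(f"expected baseline depth E = {E:.1f} reads; observed 0.5*E would mean "
      "a heterozygous deletion (ratio 0.5)")
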