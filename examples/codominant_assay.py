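"""In-silico codominant PCR assay for the deletion allele.

Two primer pairs in one (virtual) reaction: one inside the deleted region
(product only from the wild-type allele) and one flanking the junction
(product only from the deletion allele - on wild type the primers are too
far apart to amplify).  Heterozygotes show both bands.
"""

import seedless as sl
from seedless.deletion import reverse_complement

spec = sl.GenomeSpec(ref_length=80_000, deletion_interval=(30_000, 46_020),
                     seed=13)
reference, allele, truth = sl.simulate_genome_pair(spec)
s, e = truth.deleted_interval

del_fwd = reference.sequence[s - 220:s - 200]
del_rev = reverse_complement(reference.sequence[e + 200:e + 220])
wt_fwd = reference.sequence[s + 5_000:s + 5_020]
wt_rev = reverse_complement(reference.sequence[s + 5_330:s + 5_350])


def assay(name, templates):
    wt_band = any(sl.insilico_pcr(t, wt_fwd, wt_rev, max_amplicon=3000)
                  for t in templates)
    del_band = any(sl.insilico_pcr(t, del_fwd, del_rev, max_amplicon=3000)
                   for t in templates)
    call = sl.call_codominant(sl.BandPattern(name, wt_band, del_band))
    print(f"{name:12s} wt band: {str(wt_band):5s} del band: "
          f"{str(del_band):5s} -> {call.value}")
    return call


assay("wild-type", [reference.sequence])
assay("mutant", [allele])
assay("mixture", [reference.sequence, allele])

products = sl.insilico_pcr(allele, del_fwd, del_rev, max_amplicon=3000)
span = sl.insilico_pcr(reference.sequence, del_fwd, del_rev,
                       max_amplicon=10 ** 7)
print(f"\njunction amplicon from the deletion allele: {products[0].length} bp")
print(f"(= wild-type inter-primer span {span[0].length} bp minus the "
      f"{truth.length} bp deletion)")
print("\nThe three band patterns distinguish the two homozygotes and the "
      "heterozygote\nin a single reaction - usable for seedling-stage "
      "marker-assisted selection.")
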