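"""Discover a deletion from simulated short-read alignments.

Simulates a 100 kb wild-type reference carrying a 16,020 bp deletion in a
resequenced line, projects error-free 150 b reads of the deletion allele
onto the reference (junction-spanning reads become soft-clipped), then runs
the discovery pipeline: depth profile, coverage-gap detection, junction-read
collection, overlap assembly and deletion calling.
"""

import seedless as sl
from seedless.deletion import discover_deletion, junction_report

spec = sl.GenomeSpec(ref_length=100_000, deletion_interval=(40_000, 56_020),
                     seed=1)
reference, allele, truth = sl.simulate_genome_pair(spec)
alignments = sl.simulate_alignments(allele, reference, depth=20.0, seed=1)
print(f"simulated {len(alignments)} reads at 20x from the deletion allele")

depth = sl.depth_profile(alignments, reference)
(gap,) = sl.detect_gaps(depth, min_gap_len=1000)
print(f"coverage gap          : {gap.interval} "
      f"(flanking depth ~{gap.mean_flanking_depth:.1f}x)")

junction_reads = sl.collect_junction_reads(alignments, gap)
print(f"boundary-clipped reads: {len(junction_reads)}")

contig = sl.assemble_junction(junction_reads)
print(f"junction contig       : {len(contig.sequence)} bp "
      f"from {contig.support} reads")

call = sl.call_deletion(contig, reference)
print()
print(junction_report(call, reference))
print(f"\ntruth interval {truth.deleted_interval} recovered: "
      f"{call.deleted_interval == truth.deleted_interval}")
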