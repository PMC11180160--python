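"""Clean-deletion discovery from short-read alignments.

The signal for a large deletion in a resequenced line aligned to a wild-type
reference is twofold: a coverage gap (near-complete absence of aligning
reads over the deleted interval, barring repeat-mapped spikes) and
soft-clipped reads piling up at the two gap boundaries.  Reads clipped at
the boundaries span the novel junction; assembling them by exact
suffix-prefix overlap yields a junction contig whose maximal prefix and
suffix anchors on the reference delimit the deletion.  Flank identity at
the breakpoint (microhomology) makes the exact placement ambiguous; calls
are canonicalized by shifting the interval maximally leftward.

All coordinates are 0-based, half-open.  1-based (GenBank-style) coordinates
appear only in the human-readable report and the VCF record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .errors import (
    AmbiguousAnchorError,
    AnchorError,
    ComparabilityError,
    StructuralError,
)

__all__ = [
    "ReferenceSeq",
    "AlignedRead",
    "CoverageGap",
    "JunctionContig",
    "AssemblyFailure",
    "DeletionCall",
    "Amplicon",
    "depth_profile",
    "detect_gaps",
    "collect_junction_reads",
    "assemble_junction",
    "call_deletion",
    "discover_deletion",
    "junctions_identical",
    "insilico_pcr",
    "read_fasta",
    "read_sam",
    "write_sam",
    "write_deletion_vcf",
    "junction_report",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReferenceSeq:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise ValueError("empty reference sequence")
        if set(seq) - _VALID:
            raise ValueError("reference contains non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRead:
    """One plus-strand alignment with soft-clipped ends.

    clipped_prefix_len + aligned length + clipped_suffix_len == read length;
    the aligned span on the reference is [ref_start, ref_start + aligned len).
    """

    read_id: str
    ref_start: int
    sequence: str
    clipped_prefix_len: int = 0
    clipped_suffix_len: int = 0

    def __post_init__(self) -> None:
        if self.clipped_prefix_len < 0 or self.clipped_suffix_len < 0:
            raise ValueError("negative clip length")
        if self.aligned_length <= 0:
            raise ValueError("read has no aligned bases")

    @property
    def aligned_length(self) -> int:
        return len(self.sequence) - self.clipped_prefix_len - self.clipped_suffix_len

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.aligned_length

    @property
    def aligned_span(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


@dataclass(frozen=True)
class CoverageGap:
    interval: tuple[int, int]
    mean_flanking_depth: float
    internal_max_depth: int

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class JunctionContig:
    sequence: str
    support: int
    left_anchor: tuple[int, int] | None = None
    right_anchor: tuple[int, int] | None = None


@dataclass(frozen=True)
class AssemblyFailure:
    """Returned (not raised) when no overlap path joins the junction reads."""

    reason: str
    n_reads: int


@dataclass(frozen=True)
class DeletionCall:
    """A left-aligned deletion call on a named reference."""

    reference_name: str
    deleted_interval: tuple[int, int]
    inserted_sequence: str
    microhomology_len: int
    classification: str  # clean | with_insertion | with_duplication
    contig_junction: int | None = None  # junction index within the source contig
    contig_sequence: str | None = None

    @property
    def length(self) -> int:
        return self.deleted_interval[1] - self.deleted_interval[0]


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int  # half-open; length inclusive of both primer footprints
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# depth and gaps


def depth_profile(alignments: Iterable[AlignedRead],
                  reference: ReferenceSeq) -> np.ndarray:
    """Per-base count of reads whose aligned span covers each position.

    Soft-clipped portions do not contribute coverage.
    """
    n = len(reference)
    diff = np.zeros(n + 1, dtype=np.int64)
    for read in alignments:
        if read.ref_start < 0 or read.ref_end > n:
            raise StructuralError(
                f"read {read.read_id!r} aligns outside the reference "
                f"[{read.ref_start}, {read.ref_end}) vs length {n}")
        diff[read.ref_start] += 1
        diff[read.ref_end] -= 1
    return np.cumsum(diff[:-1])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True in a boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def detect_gaps(depth: np.ndarray, max_internal_depth: int = 2,
                min_gap_len: int = 100, max_spike_len: int = 500,
                flank_window: int = 1000) -> list[CoverageGap]:
    """Coverage gaps: maximal low-depth runs, tolerant of repeat spikes.

    A run is low where depth <= max_internal_depth.  Two low runs separated
    by a high-depth run strictly shorter than ``max_spike_len`` are merged
    (reads repeat-mapped inside a deletion produce such spikes).  Merged runs
    shorter than ``min_gap_len`` are discarded.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty depth profile")
    low_runs = _runs(depth <= max_internal_depth)
    merged: list[tuple[int, int]] = []
    for run in low_runs:
        if merged and run[0] - merged[-1][1] < max_spike_len:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    gaps = []
    for start, end in merged:
        if end - start < min_gap_len:
            continue
        flank = np.concatenate([depth[max(0, start - flank_window):start],
                                depth[end:end + flank_window]])
        mean_flank = float(flank.mean()) if flank.size else float("nan")
        gaps.append(CoverageGap(interval=(start, end),
                                mean_flanking_depth=mean_flank,
                                internal_max_depth=int(depth[start:end].max())))
    return gaps


def collect_junction_reads(alignments: Iterable[AlignedRead], gap: CoverageGap,
                           min_clip: int = 20, window: int = 100,
                           ) -> list[AlignedRead]:
    """Reads clipped at either gap boundary.

    Left-side reads end within ``window`` of the gap start with a clipped
    suffix of at least ``min_clip`` bases; right-side reads begin within
    ``window`` of the gap end with a clipped prefix of at least ``min_clip``.
    """
    picked = []
    for read in alignments:
        if (abs(read.ref_end - gap.start) <= window
                and read.clipped_suffix_len >= min_clip):
            picked.append(read)
        elif (abs(read.ref_start - gap.end) <= window
                and read.clipped_prefix_len >= min_clip):
            picked.append(read)
    return picked


# ---------------------------------------------------------------------------
# junction assembly


def _best_overlap(a: str, b: str, min_overlap: int, max_mismatch: int) -> int:
    """Longest suffix(a)/prefix(b) overlap >= min_overlap, else 0."""
    limit = min(len(a), len(b))
    if max_mismatch == 0:
        for k in range(limit, min_overlap - 1, -1):
            if a.endswith(b[:k]):
                return k
        return 0
    for k in range(limit, min_overlap - 1, -1):
        mism = sum(x != y for x, y in zip(a[-k:], b[:k]))
        if mism <= max_mismatch:
            return k
    return 0


def assemble_junction(reads: Sequence[AlignedRead] | Sequence[str] | Sequence[tuple[str, str]],
                      min_overlap: int = 20, max_mismatch: int = 0,
                      ) -> JunctionContig | AssemblyFailure:
    """Greedy overlap-layout-consensus over junction reads.

    Repeatedly merges the pair with the longest suffix-prefix overlap of at
    least ``min_overlap`` bases (exact by default); a read contained in
    another is absorbed.  Ties break lexicographically by read id.  Returns
    an :class:`AssemblyFailure` (never raises) when no single contig results.
    """
    items: dict[str, str] = {}
    for i, r in enumerate(reads):
        if isinstance(r, AlignedRead):
            items[r.read_id] = r.sequence
        elif isinstance(r, tuple):
            items[r[0]] = r[1]
        else:
            items[f"read_{i:04d}"] = str(r)
    n_input = len(items)
    if n_input < 2:
        return AssemblyFailure(reason="need at least two reads", n_reads=n_input)

    while len(items) > 1:
        best = None  # (overlap, id_a, id_b, merged_seq)
        ids = sorted(items)
        for ida in ids:
            for idb in ids:
                if ida == idb:
                    continue
                a, b = items[ida], items[idb]
                if max_mismatch == 0 and b in a:
                    cand = (len(b), ida, idb, a)
                else:
                    k = _best_overlap(a, b, min_overlap, max_mismatch)
                    if k == 0:
                        continue
                    cand = (k, ida, idb, a + b[k:])
                if best is None or cand[0] > best[0] or (
                        cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])):
                    best = cand
        if best is None:
            return AssemblyFailure(
                reason=f"no overlap >= {min_overlap} joins the remaining "
                       f"{len(items)} fragments", n_reads=n_input)
        _, ida, idb, merged_seq = best
        del items[idb]
        items[ida] = merged_seq
    (seq,) = items.values()
    return JunctionContig(sequence=seq, support=n_input)


# ---------------------------------------------------------------------------
# deletion calling


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def call_deletion(contig: JunctionContig | str, reference: ReferenceSeq,
                  min_anchor: int = 30) -> DeletionCall:
    """Anchor a junction contig on the reference and call the deletion.

    The maximal exact prefix match of the contig is the left anchor, the
    maximal exact suffix match the right anchor.  Contig bases between the
    anchors are inserted sequence; anchor overlap on the contig is
    microhomology.  Pure deletions are left-aligned (shifted maximally
    leftward through identical flanking bases); calls with inserted sequence
    are reported at the anchor boundary.
    """
    seq = contig.sequence if isinstance(contig, JunctionContig) else str(contig)
    seq = seq.upper()
    ref = reference.sequence
    c = len(seq)
    if c < 2 * min_anchor:
        raise AnchorError(f"contig shorter than two anchors ({c} < {2 * min_anchor})")

    # left anchor: the seed may occur at several loci; the anchor is the one
    # with the longest exact extension, ambiguous only on a tie
    left_hits = _find_all(ref, seq[:min_anchor])
    if not left_hits:
        raise AnchorError("left anchor not found on reference")
    best_left: list[tuple[int, int]] = []  # (extension L, start a)
    for a0 in left_hits:
        L0 = min_anchor
        while L0 < c and a0 + L0 < len(ref) and ref[a0 + L0] == seq[L0]:
            L0 += 1
        best_left.append((L0, a0))
    max_l = max(x[0] for x in best_left)
    top_left = [x for x in best_left if x[0] == max_l]
    if len(top_left) > 1:
        raise AmbiguousAnchorError(
            f"left anchor matches {len(top_left)} loci with {max_l} bases")
    L, a = top_left[0]

    right_hits = _find_all(ref, seq[-min_anchor:])
    if not right_hits:
        raise AnchorError("right anchor not found on reference")
    best_right: list[tuple[int, int]] = []  # (extension R, ref end e)
    for hit in right_hits:
        e0 = hit + min_anchor
        R0 = min_anchor
        while R0 < c and e0 - R0 - 1 >= 0 and ref[e0 - R0 - 1] == seq[c - R0 - 1]:
            R0 += 1
        best_right.append((R0, e0))
    max_r = max(x[0] for x in best_right)
    top_right = [x for x in best_right if x[0] == max_r]
    if len(top_right) > 1:
        raise AmbiguousAnchorError(
            f"right anchor matches {len(top_right)} loci with {max_r} bases")
    R, e = top_right[0]

    if e - R < a:
        raise StructuralError("anchors overlap on the reference beyond the contig")

    if L + R < c:  # inserted bases between anchors
        inserted = seq[L:c - R]
        start, end = a + L, e - R
        microhomology = 0
        junction = L
    else:
        microhomology = L + R - c
        inserted = ""
        # leftmost placement within the anchor-overlap ambiguity window
        junction = c - R
        start, end = a + junction, e - R
        if end < start:
            raise StructuralError("anchors overlap more than the contig length")
        # canonical left alignment through identical flanking bases
        while start > 0 and end > start and ref[start - 1] == ref[end - 1]:
            start -= 1
            end -= 1
            junction -= 1

    if not inserted:
        classification = "clean"
    else:
        k = len(inserted)
        if (ref[max(0, start - k):start] == inserted
                or ref[end:end + k] == inserted):
            classification = "with_duplication"
        else:
            classification = "with_insertion"

    return DeletionCall(reference_name=reference.name,
                        deleted_interval=(start, end),
                        inserted_sequence=inserted,
                        microhomology_len=microhomology,
                        classification=classification,
                        contig_junction=junction,
                        contig_sequence=seq)


def junctions_identical(call_a: DeletionCall, call_b: DeletionCall,
                        window: int = 200) -> tuple[bool, list[str]]:
    """Compare two deletion calls (interval, insertion, junction-window bases).

    The junction window is read from each call's source contig, ``window``
    bases either side of its junction point, compared over the overlap of the
    available flanks.  Returns (identical, mismatch report lines).
    """
    if call_a.reference_name != call_b.reference_name:
        raise ComparabilityError("calls are on different references")
    report: list[str] = []
    if call_a.deleted_interval != call_b.deleted_interval:
        report.append(f"deleted_interval differs: {call_a.deleted_interval} "
                      f"vs {call_b.deleted_interval}")
    if call_a.inserted_sequence != call_b.inserted_sequence:
        report.append("inserted_sequence differs")
    if (call_a.contig_sequence is not None and call_b.contig_sequence is not None
            and call_a.contig_junction is not None
            and call_b.contig_junction is not None):
        for label, side in (("left", -1), ("right", +1)):
            fa = _junction_flank(call_a, side, window)
            fb = _junction_flank(call_b, side, window)
            k = min(len(fa), len(fb))
            fa, fb = (fa[-k:], fb[-k:]) if side < 0 else (fa[:k], fb[:k])
            for i, (x, y) in enumerate(zip(fa, fb)):
                if x != y:
                    offset = i - k if side < 0 else i
                    report.append(f"junction window mismatch at {label} flank "
                                  f"offset {offset}: {x} vs {y}")
    return (len(report) == 0, report)


def _junction_flank(call: DeletionCall, side: int, window: int) -> str:
    j = call.contig_junction
    seq = call.contig_sequence
    ins = len(call.inserted_sequence)
    if side < 0:
        return seq[max(0, j - window):j]
    return seq[j + ins:j + ins + window]


def discover_deletion(alignments: Sequence[AlignedRead], reference: ReferenceSeq,
                      max_internal_depth: int = 2, min_gap_len: int = 100,
                      max_spike_len: int = 500, min_clip: int = 20,
                      min_overlap: int = 20, min_anchor: int = 30,
                      ) -> DeletionCall | AssemblyFailure:
    """Full pipeline: depth profile, gap detection, junction-read collection,
    overlap assembly and deletion calling.  Returns the call for the largest
    coverage gap, or an :class:`AssemblyFailure` describing why none could be
    characterized."""
    depth = depth_profile(alignments, reference)
    gaps = detect_gaps(depth, max_internal_depth=max_internal_depth,
                       min_gap_len=min_gap_len, max_spike_len=max_spike_len)
    if not gaps:
        return AssemblyFailure(reason="no coverage gap detected", n_reads=0)
    gap = max(gaps, key=len)
    junction_reads = collect_junction_reads(alignments, gap, min_clip=min_clip)
    contig = assemble_junction(junction_reads, min_overlap=min_overlap)
    if isinstance(contig, AssemblyFailure):
        return contig
    return call_deletion(contig, reference, min_anchor=min_anchor)


# ---------------------------------------------------------------------------
# in-silico PCR

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        return _find_all(template, primer)
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    if len(t) < len(p):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mism = (windows != p).sum(axis=1)
    return [int(i) for i in np.flatnonzero(mism <= max_mismatch)]


def insilico_pcr(template: str, forward_primer: str, reverse_primer: str,
                 max_amplicon: int = 3000, max_mismatch: int = 0) -> list[Amplicon]:
    """Predict PCR products on the plus strand of a template.

    The forward primer is matched as given; the reverse primer as its
    reverse complement downstream.  Amplicon lengths include both primer
    footprints.  An empty list is a valid result (no product).
    """
    template = template.upper()
    fwd = forward_primer.upper()
    rev = reverse_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 bases")
    rc = reverse_complement(rev)
    fwd_sites = _primer_sites(template, fwd, max_mismatch)
    rev_sites = _primer_sites(template, rc, max_mismatch)
    amplicons = []
    for f in fwd_sites:
        for r in rev_sites:
            if r < f + len(fwd):
                continue
            end = r + len(rc)
            if end - f <= max_amplicon:
                amplicons.append(Amplicon(start=f, end=end,
                                          sequence=template[f:end]))
    return sorted(amplicons, key=lambda a: (a.start, a.end))


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list[ReferenceSeq]:
    return [ReferenceSeq(name=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[ReferenceSeq], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i:i + 80] + "\n")


def read_sam(path) -> list[AlignedRead]:
    """Load plus-strand alignments from SAM; soft/hard clips from CIGAR."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            ct = aln.cigartuples or []
            pre = ct[0][1] if ct and ct[0][0] in (4, 5) else 0
            suf = ct[-1][1] if len(ct) > 1 and ct[-1][0] in (4, 5) else 0
            reads.append(AlignedRead(read_id=aln.query_name,
                                     ref_start=aln.reference_start,
                                     sequence=aln.query_sequence,
                                     clipped_prefix_len=pre,
                                     clipped_suffix_len=suf))
    return reads


def write_sam(alignments: Sequence[AlignedRead], reference: ReferenceSeq,
              path) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": reference.name, "LN": len(reference)}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for read in alignments:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.sequence
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = read.ref_start
            seg.mapping_quality = 60
            cigar = []
            if read.clipped_prefix_len:
                cigar.append((4, read.clipped_prefix_len))
            cigar.append((0, read.aligned_length))
            if read.clipped_suffix_len:
                cigar.append((4, read.clipped_suffix_len))
            seg.cigartuples = cigar
            seg.query_qualities = pysam.qualitystring_to_array(
                "I" * len(read.sequence))
            sam.write(seg)


def write_deletion_vcf(call: DeletionCall, reference: ReferenceSeq, path) -> None:
    """Emit the call as a minimal symbolic-ALT VCF record (SVTYPE=DEL)."""
    start, end = call.deleted_interval
    if start == 0:
        raise StructuralError("deletion at reference start has no anchor base")
    pos = start  # 1-based position of the base before the deletion
    ref_base = reference.sequence[start - 1]
    info = [f"SVTYPE=DEL", f"END={end}", f"SVLEN=-{call.length}",
            f"HOMLEN={call.microhomology_len}"]
    if call.inserted_sequence:
        info.append(f"INSSEQ={call.inserted_sequence}")
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={reference.name},length={len(reference)}>",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the deleted interval (1-based inclusive)">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Breakpoint microhomology length">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Inserted sequence at the junction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        f"{reference.name}\t{pos}\tDEL1\t{ref_base}\t<DEL>\t.\tPASS\t{';'.join(info)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def junction_report(call: DeletionCall, reference: ReferenceSeq,
                    context: int = 30) -> str:
    """Human-readable junction summary with 1-based coordinates."""
    start, end = call.deleted_interval
    left = reference.sequence[max(0, start - context):start]
    right = reference.sequence[end:end + context]
    lines = [
        f"reference         : {call.reference_name} ({len(reference)} bp)",
        f"deleted interval  : {start + 1}-{end} (1-based inclusive), "
        f"{call.length} bp",
        f"classification    : {call.classification}",
        f"microhomology     : {call.microhomology_len} bp",
        f"inserted sequence : {call.inserted_sequence or '-'}",
        f"junction          : ...{left}][{right}...",
    ]
    return "\n".join(lines)
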