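"""Attribution of collapsed reads to host and non-host references.

Mapping is exhaustive gapless (substitution-only) alignment of short reads
against reference sequences on both strands.  Reads with any host hit are
attributed to the host first; non-host genome lists are then pruned with a
shuffled-decoy comparison and a minimum recruited-read-length rule, loci are
built from overlapping hit positions, and multi-mapped read counts are
redistributed by an iterative proportional (EM-style) cross-mapping
correction anchored on uniquely mapping reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import revcomp, seq_to_array

DEFAULT_MAX_MISMATCHES = 2
MIN_RECRUIT_LEN = 25


@dataclass(frozen=True)
class MappingHit:
    sequence: str
    reference_id: str
    position: int  # 0-based start on the forward reference
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class Locus:
    reference_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    raw_count: float = 0.0
    corrected_count: float = 0.0

    @property
    def locus_id(self) -> str:
        return f"{self.reference_id}:{self.start}-{self.end}({self.strand})"


def _scan_one_strand(
    read: np.ndarray, ref: np.ndarray, max_mm: int
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and mismatch counts of all gapless matches of ``read`` in
    ``ref`` with at most ``max_mm`` substitutions."""
    L = read.size
    if ref.size < L:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(ref, L)
    mm = (windows != read).sum(axis=1)
    pos = np.nonzero(mm <= max_mm)[0]
    return pos, mm[pos]


def map_reads(
    sequences: Iterable[str],
    reference: Mapping[str, str],
    max_mm: int = DEFAULT_MAX_MISMATCHES,
) -> list[MappingHit]:
    """All substitution-only alignments of each sequence against each
    reference sequence, on both strands, with <= max_mm mismatches.

    Positions are 0-based starts on the forward reference strand; output
    order is deterministic (reference, position, strand, sequence).
    """
    if not reference or all(len(s) == 0 for s in reference.values()):
        raise ValueError("reference is empty")
    ref_arrays = {rid: seq_to_array(rseq) for rid, rseq in reference.items()}
    hits: list[MappingHit] = []
    for seq in sequences:
        fwd = seq_to_array(seq)
        rev = seq_to_array(revcomp(seq))
        for rid, ref in ref_arrays.items():
            pos, mm = _scan_one_strand(fwd, ref, max_mm)
            hits.extend(
                MappingHit(seq, rid, int(p), "+", int(m)) for p, m in zip(pos, mm)
            )
            pos, mm = _scan_one_strand(rev, ref, max_mm)
            hits.extend(
                MappingHit(seq, rid, int(p), "-", int(m)) for p, m in zip(pos, mm)
            )
    hits.sort(key=lambda h: (h.reference_id, h.position, h.strand, h.sequence))
    return hits


def attribute_host(
    sequences: Sequence[str], host_hits: Iterable[MappingHit]
) -> tuple[list[str], list[str]]:
    """Host-first partition: any sequence with at least one host hit is host,
    regardless of non-host hits.  Returns (host, nonhost) preserving input
    order; the partition is exhaustive and disjoint."""
    host_set = {h.sequence for h in host_hits}
    host = [s for s in sequences if s in host_set]
    nonhost = [s for s in sequences if s not in host_set]
    return host, nonhost


def shuffle_decoys(sequences: Sequence[str], seed: int) -> list[str]:
    """Per-sequence uniform permutation of nucleotides (composition and
    length distribution preserved)."""
    rng = np.random.default_rng(seed)
    out = []
    for seq in sequences:
        arr = np.array(list(seq))
        rng.shuffle(arr)
        out.append("".join(arr))
    return out


def decoy_filter(
    nonhost_sequences: Sequence[str],
    genomes: Mapping[str, str],
    seed: int,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    min_recruit_len: int = MIN_RECRUIT_LEN,
    require_long_read: bool = True,
    require_decoy_excess: bool = True,
) -> list[str]:
    """Prune candidate genomes by recruitment specificity.

    A genome is retained iff (a) it recruits at least one real read of
    length >= ``min_recruit_len`` and (b) it recruits strictly more real
    reads than shuffled-decoy reads.  Either criterion can be switched off.
    """
    if not genomes:
        return []
    decoys = shuffle_decoys(nonhost_sequences, seed)
    real_hits = map_reads(nonhost_sequences, genomes, max_mm)
    decoy_hits = map_reads(decoys, genomes, max_mm)
    retained = []
    for gid in genomes:
        real_seqs = {h.sequence for h in real_hits if h.reference_id == gid}
        decoy_seqs = {h.sequence for h in decoy_hits if h.reference_id == gid}
        if require_long_read and not any(len(s) >= min_recruit_len for s in real_seqs):
            continue
        if require_decoy_excess and len(real_seqs) <= len(decoy_seqs):
            continue
        retained.append(gid)
    return retained


def build_loci(
    hits: Sequence[MappingHit], counts: Mapping[str, int] | None = None
) -> list[Locus]:
    """Merge overlapping same-strand hits into maximal intervals.

    ``counts`` gives collapse counts per read sequence (default 1 each);
    ``raw_count`` sums the counts of distinct reads touching the locus.
    """
    counts = counts or {}
    by_key: dict[tuple[str, str], list[MappingHit]] = {}
    for h in hits:
        by_key.setdefault((h.reference_id, h.strand), []).append(h)
    loci: list[Locus] = []
    for (rid, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.position, h.sequence))
        cur_start = cur_end = None
        cur_reads: set[str] = set()
        for h in group:
            start, end = h.position, h.position + len(h.sequence)
            if cur_start is None:
                cur_start, cur_end, cur_reads = start, end, {h.sequence}
            elif start < cur_end:  # overlap
                cur_end = max(cur_end, end)
                cur_reads.add(h.sequence)
            else:
                loci.append(
                    Locus(rid, cur_start, cur_end, strand,
                          raw_count=float(sum(counts.get(s, 1) for s in cur_reads)))
                )
                cur_start, cur_end, cur_reads = start, end, {h.sequence}
        if cur_start is not None:
            loci.append(
                Locus(rid, cur_start, cur_end, strand,
                      raw_count=float(sum(counts.get(s, 1) for s in cur_reads)))
            )
    return loci


@dataclass
class CrossmapResult:
    corrected: dict[str, float]  # locus id -> corrected count
    n_iter: int
    converged: bool


def crossmap_correct(
    read_locus_incidence: Mapping[str, Sequence[str]],
    counts: Mapping[str, int],
    tol: float = 1e-6,
    max_iter: int = 100,
    pseudocount: float = 1.0,
) -> CrossmapResult:
    """Redistribute multi-mapped read counts across loci by iterative
    proportional allocation.

    Locus weights start from uniquely mapping reads; each multi-mapped
    read's count is then allocated across its loci proportional to the
    current weights, and locus totals are iterated to a fixed point
    (max change < tol).  Reads none of whose loci carry any unique
    evidence are split by a symmetric pseudocount.  Every read's
    allocation sums exactly to its count, so total counts are conserved.
    """
    reads = list(read_locus_incidence)
    locus_ids = sorted({l for ls in read_locus_incidence.values() for l in ls})
    unique = dict.fromkeys(locus_ids, 0.0)
    for r in reads:
        ls = read_locus_incidence[r]
        if len(ls) == 1:
            unique[ls[0]] += counts[r]
    multi = [r for r in reads if len(read_locus_incidence[r]) > 1]
    totals = dict(unique)
    for it in range(1, max_iter + 1):
        new = dict(unique)
        for r in multi:
            ls = read_locus_incidence[r]
            w = np.array([totals[l] for l in ls], dtype=float)
            if w.sum() <= 0:
                w = w + pseudocount
            share = counts[r] * w / w.sum()
            for l, s in zip(ls, share):
                new[l] += s
        delta = max(abs(new[l] - totals[l]) for l in locus_ids) if locus_ids else 0.0
        totals = new
        if delta < tol:
            return CrossmapResult(totals, it, True)
    return CrossmapResult(totals, max_iter, False)


def hits_to_sam(
    hits: Sequence[MappingHit], reference: Mapping[str, str]
) -> str:
    """Minimal SAM rendering of hits (QNAME/FLAG/RNAME/POS/MAPQ/CIGAR + NM)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rid, rseq in reference.items():
        lines.append(f"@SQ\tSN:{rid}\tLN:{len(rseq)}")
    for h in hits:
        flag = 0 if h.strand == "+" else 16
        seq = h.sequence if h.strand == "+" else revcomp(h.sequence)
        lines.append(
            f"{h.sequence}\t{flag}\t{h.reference_id}\t{h.position + 1}\t255\t"
            f"{len(h.sequence)}M\t*\t0\t0\t{seq}\t*\tNM:i:{h.mismatches}"
        )
    return "\n".join(lines) + "\n"


def loci_to_bed(loci: Sequence[Locus]) -> str:
    """BED6 (+ corrected count in column 7); BED coordinates stay 0-based."""
    lines = []
    for i, l in enumerate(sorted(loci, key=lambda x: (x.reference_id, x.start, x.strand)), 1):
        lines.append(
            f"{l.reference_id}\t{l.start}\t{l.end}\tlocus_{i}\t"
            f"{int(round(l.raw_count))}\t{l.strand}\t{l.corrected_count:.6g}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
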