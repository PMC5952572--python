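"""Read-level preprocessing of small RNA-seq libraries.

The stages run in a fixed order — recursive 3' adapter trimming, 5' N
clipping, quality filtering, collapsing of identical reads — and end in a
sequences x libraries count table.  Two retention modes exist for the table:
``study`` keeps sequences seen at least 30 times summed over all libraries
of the experiment, ``public`` (for screening external datasets of unknown
design) only removes singletons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import seq_to_array, seqs_to_matrix

DEFAULT_MIN_LEN = 15
DEFAULT_MIN_OVERLAP = 10
DEFAULT_TRIM_MISMATCHES = 1
STUDY_MIN_TOTAL = 30

#: Illumina TruSeq small RNA 3' adapter.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CONTROL_TYPES = frozenset({"mock", "eluate", "water", "no_template"})
SAMPLE_TYPES = frozenset({"plasma"}) | CONTROL_TYPES


@dataclass(frozen=True)
class LibraryMeta:
    """Descriptor of one sequencing library.

    ``type`` is one of plasma | mock | eluate | water | no_template; controls
    are everything but plasma.  ``volume_uL`` is the plasma input volume
    (zero for controls), ``column`` the spin-column production line
    (regular | ultraclean) and ``batch`` its batch label.
    """

    library_id: str
    type: str
    column: str = "regular"
    batch: str = "1"
    volume_uL: float = 0.0
    spikein_name: str | None = None
    spikein_copies_per_uL: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample type {self.type!r}")

    @property
    def is_control(self) -> bool:
        return self.type in CONTROL_TYPES


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with the number of identical raw reads."""

    sequence: str
    count: int


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------

def _find_adapter_start(seq: str, adapter: str, min_overlap: int, max_mismatch: int) -> int:
    """Earliest position where the adapter (or an adapter prefix reaching the
    read end, >= min_overlap) matches with <= max_mismatch substitutions.
    Returns -1 if absent."""
    n, alen = len(seq), len(adapter)
    exact = seq.find(adapter)
    # only positions before the exact full match could beat it
    end = exact if exact >= 0 else n - min_overlap + 1
    for p in range(0, end):
        overlap = min(alen, n - p)
        if overlap < min_overlap:
            break
        mm = 0
        for a, b in zip(seq[p : p + overlap], adapter):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return p
    return exact


def _trim_batch_equal_len(
    seqs: list[str], adapter: str, min_overlap: int, max_mismatch: int
) -> np.ndarray:
    """Vectorised adapter search for equal-length sequences.

    Returns per-read trim position (length of retained prefix; len(seq) when
    no acceptable adapter occurrence exists).
    """
    n = len(seqs)
    length = len(seqs[0])
    mat = seqs_to_matrix(seqs)
    ad = seq_to_array(adapter)
    trim = np.full(n, length, dtype=np.int64)
    unset = np.ones(n, dtype=bool)
    for p in range(0, length - min_overlap + 1):
        overlap = min(len(adapter), length - p)
        mm = (mat[:, p : p + overlap] != ad[:overlap]).sum(axis=1)
        hit = unset & (mm <= max_mismatch)
        trim[hit] = p
        unset &= ~hit
        if not unset.any():
            break
    return trim


def trim_adapters(
    reads: Sequence[tuple[str, str]],
    adapter_list: Sequence[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_TRIM_MISMATCHES,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[tuple[str, str]]:
    """Recursively remove 3' adapter occurrences from (sequence, quality) pairs.

    An occurrence is the earliest position where the adapter — or an adapter
    prefix running to the read end of at least ``min_overlap`` nt — matches
    with at most ``max_mismatch`` substitutions; the read is cut there and
    the search repeated until a full pass removes nothing.  Reads ending up
    shorter than ``min_len`` are discarded.
    """
    if not adapter_list:
        raise ValueError("adapter_list must not be empty")
    current = list(reads)
    while True:
        changed = False
        for adapter in adapter_list:
            # group equal-length reads for the vectorised path
            by_len: dict[int, list[int]] = {}
            for i, (s, _) in enumerate(current):
                by_len.setdefault(len(s), []).append(i)
            trims = np.array([len(s) for s, _ in current], dtype=np.int64)
            for length, idx in by_len.items():
                if length < min_overlap:
                    continue
                seqs = [current[i][0] for i in idx]
                if len(seqs) >= 64:
                    t = _trim_batch_equal_len(seqs, adapter, min_overlap, max_mismatch)
                else:
                    t = np.array(
                        [
                            p if (p := _find_adapter_start(s, adapter, min_overlap, max_mismatch)) >= 0 else length
                            for s in seqs
                        ],
                        dtype=np.int64,
                    )
                trims[idx] = t
            if (trims < np.array([len(s) for s, _ in current])).any():
                changed = True
                current = [
                    (s[:t], q[:t]) for (s, q), t in zip(current, trims)
                ]
        if not changed:
            break
    return [(s, q) for s, q in current if len(s) >= min_len]


# ---------------------------------------------------------------------------
# 5' N clipping and quality filtering
# ---------------------------------------------------------------------------

def clip_5prime_Ns(
    reads: Sequence[tuple[str, str]], min_len: int = DEFAULT_MIN_LEN
) -> list[tuple[str, str]]:
    """Remove leading N calls (internal Ns untouched); drop reads < min_len."""
    out = []
    for seq, qual in reads:
        k = len(seq) - len(seq.lstrip("N"))
        if len(seq) - k >= min_len:
            out.append((seq[k:], qual[k:]))
    return out


def quality_filter(
    reads: Sequence[tuple[str, str]], q_min: int = 30, p_min: float = 90.0
) -> list[tuple[str, str]]:
    """Keep reads in which >= p_min percent of bases have Phred quality >= q_min.

    Qualities are Phred+33 encoded; a quality string whose length differs
    from its sequence raises with the record index.
    """
    for i, (seq, qual) in enumerate(reads):
        if len(seq) != len(qual):
            raise ValueError(
                f"record {i}: quality length {len(qual)} != sequence length {len(seq)}"
            )
    if not reads:
        return []
    lengths = np.array([len(q) for _, q in reads], dtype=np.int64)
    allq = np.frombuffer("".join(q for _, q in reads).encode("ascii"), dtype=np.uint8)
    good = (allq >= q_min + 33).astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    n_good = np.add.reduceat(good, starts)
    keep = n_good * 100 >= p_min * lengths
    return [r for r, k in zip(reads, keep) if k]


# ---------------------------------------------------------------------------
# collapsing and count tables
# ---------------------------------------------------------------------------

def collapse(reads: Sequence[tuple[str, str]] | Sequence[str]) -> list[CollapsedRead]:
    """Collapse identical read sequences, keeping abundance.

    Accepts (sequence, quality) pairs or bare sequences.  Output is ordered
    by descending count, ties broken lexicographically; the counts sum to the
    number of input reads.
    """
    seqs = [r[0] if isinstance(r, tuple) else r for r in reads]
    counter = Counter(seqs)
    return [
        CollapsedRead(seq, n)
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def preprocess_library(
    reads: Sequence[tuple[str, str]],
    adapter_list: Sequence[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_TRIM_MISMATCHES,
    min_len: int = DEFAULT_MIN_LEN,
    q_min: int = 30,
    p_min: float = 90.0,
) -> list[CollapsedRead]:
    """Full per-library chain: trim -> clip 5' Ns -> quality filter -> collapse."""
    reads = trim_adapters(reads, adapter_list, min_overlap, max_mismatch, min_len)
    reads = clip_5prime_Ns(reads, min_len)
    reads = quality_filter(reads, q_min, p_min)
    return collapse(reads)


def collapsed_to_fasta(collapsed: Sequence[CollapsedRead], path) -> None:
    """Write collapsed reads as FASTA with ``>seq{i}_{count}`` headers
    (the conventional collapser output format)."""
    with open(path, "w") as fh:
        for i, cr in enumerate(collapsed, 1):
            fh.write(f">seq{i}_{cr.count}\n{cr.sequence}\n")


@dataclass
class CountTable:
    """Sequences x libraries matrix of collapsed-read counts.

    ``library_sizes`` are the retained read totals per library, recorded
    before any row filtering, and are the cpm denominators.
    """

    counts: pd.DataFrame  # index: sequence, columns: library_id
    metas: list[LibraryMeta]
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        ids = [m.library_id for m in self.metas]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate library ids")
        self.counts = self.counts.loc[:, ids]
        self.library_sizes = self.library_sizes.loc[ids]

    @property
    def library_ids(self) -> list[str]:
        return [m.library_id for m in self.metas]

    @property
    def cpm(self) -> pd.DataFrame:
        sizes = self.library_sizes.replace(0, np.nan)
        return self.counts.div(sizes, axis=1) * 1e6

    def meta_for(self, library_id: str) -> LibraryMeta:
        for m in self.metas:
            if m.library_id == library_id:
                return m
        raise KeyError(library_id)

    def control_ids(self) -> list[str]:
        return [m.library_id for m in self.metas if m.is_control]

    def plasma_ids(self) -> list[str]:
        return [m.library_id for m in self.metas if m.type == "plasma"]

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("sequence").to_csv(path, sep="\t")


def build_count_table(
    per_library: Iterable[tuple[LibraryMeta, Sequence[CollapsedRead]]] | Mapping[LibraryMeta, Sequence[CollapsedRead]],
    mode: str = "study",
    study_min_total: int = STUDY_MIN_TOTAL,
) -> CountTable:
    """Assemble collapsed per-library reads into a CountTable.

    ``study`` mode retains sequences whose summed count over all libraries is
    at least ``study_min_total`` (default 30); ``public`` mode removes
    singletons (total count <= 1).  Library sizes are recorded before the row
    filter so cpm stays on the retained-read scale.
    """
    if mode not in ("study", "public"):
        raise ValueError(f"mode must be 'study' or 'public', got {mode!r}")
    items = list(per_library.items()) if isinstance(per_library, Mapping) else list(per_library)
    metas = [meta for meta, _ in items]
    ids = [m.library_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library ids")
    columns = {
        meta.library_id: pd.Series(
            {cr.sequence: cr.count for cr in collapsed}, dtype="int64"
        )
        for meta, collapsed in items
    }
    counts = pd.DataFrame(columns).fillna(0).astype("int64")
    counts = counts.sort_index()
    sizes = counts.sum(axis=0).astype("int64")
    total = counts.sum(axis=1)
    if mode == "study":
        counts = counts.loc[total >= study_min_total]
    else:
        counts = counts.loc[total > 1]
    return CountTable(counts=counts, metas=metas, library_sizes=sizes)
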