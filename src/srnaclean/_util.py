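"""Small shared helpers: sequence canonicalisation and FASTA/FASTQ round trips."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def to_dna(sequence: str) -> str:
    """Canonicalise a nucleotide string to upper-case DNA (U -> T)."""
    return sequence.upper().replace("U", "T")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def seqs_to_matrix(seqs: list[str]) -> np.ndarray:
    """Pack equal-length sequences into a (n, L) uint8 matrix of ASCII codes."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return buf.reshape(len(seqs), length)


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ (optionally gzipped) into (id, sequence, quality) tuples."""
    with _open_text(path) as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {title.split()[0]: seq for title, seq in SimpleFastaParser(fh)}


def iter_chunks(n: int, chunk: int) -> Iterator[tuple[int, int]]:
    for start in range(0, n, chunk):
        yield start, min(start + chunk, n)
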