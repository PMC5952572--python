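"""Identification and quantification of reagent-derived contaminant sRNAs.

A packaged six-assay panel (sRNA sequence, qPCR primer, annealing
temperature) defines the confirmed spin-column contaminants.  Sequencing
reads are assigned to assays when they share a perfect-identity alignment of
at least 14 nt with the primer — reads may extend beyond the primer.
Sequences recurring in extraction-control libraries (mock extractions,
column eluates, water, no-template) are flagged as artefacts; absolute copy
numbers come from normalising to a spike-in of known concentration; and a
public-screening mode reports per-assay reads-per-million for any local
FASTQ.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import read_fastq, to_dna
from .preprocess import (
    CountTable,
    LibraryMeta,
    TRUSEQ_SMALL_RNA_ADAPTER,
    build_count_table,
    preprocess_library,
)

DEFAULT_MIN_OVERLAP = 14


@dataclass(frozen=True)
class ContaminantAssay:
    """One qPCR assay for a confirmed contaminant sRNA."""

    name: str
    srna_sequence: str
    primer_sequence: str
    annealing_temp_C: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "srna_sequence", to_dna(self.srna_sequence))
        object.__setattr__(self, "primer_sequence", to_dna(self.primer_sequence))


@dataclass(frozen=True)
class SpikeInSpec:
    """Synthetic spike-in RNA of known eluate concentration."""

    name: str
    sequence: str
    copies_per_uL_eluate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_dna(self.sequence))
        if self.copies_per_uL_eluate <= 0:
            raise ValueError("copies_per_uL_eluate must be > 0")


def longest_primer_match(sequence: str, primer: str) -> int:
    """Length of the longest primer substring occurring exactly in ``sequence``.

    Equals the longest common substring because the primer is the shorter
    partner; 100%-identity semantics by construction.
    """
    plen = len(primer)
    if not sequence or not plen:
        return 0
    for length in range(min(plen, len(sequence)), 0, -1):
        for start in range(plen - length + 1):
            if primer[start : start + length] in sequence:
                return length
    return 0


def load_assays(path: str | Path | None = None) -> list[ContaminantAssay]:
    """Load the assay panel TSV (columns name, srna_sequence, primer_sequence,
    annealing_temp_C); defaults to the packaged six-assay panel.

    Self-consistency is asserted at load: every primer must match its own
    sRNA sequence under the >= 14 nt perfect-identity rule.
    """
    if path is None:
        ref = importlib.resources.files("srnaclean").joinpath("data/contaminant_panel.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    assays = [
        ContaminantAssay(
            name=row["name"],
            srna_sequence=row["srna_sequence"],
            primer_sequence=row["primer_sequence"],
            annealing_temp_C=float(row["annealing_temp_C"]),
        )
        for _, row in df.iterrows()
    ]
    for a in assays:
        if longest_primer_match(a.srna_sequence, a.primer_sequence) < DEFAULT_MIN_OVERLAP:
            raise ValueError(
                f"assay {a.name!r}: primer does not match its own sRNA sequence"
            )
    return assays


def match_contaminants(
    sequences: Iterable[str],
    assays: Sequence[ContaminantAssay],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dict[str, str]:
    """Assign read sequences to contaminant assays.

    A sequence is assigned iff it shares a perfect-identity alignment of at
    least ``min_overlap`` nt with an assay's primer (the read may be longer
    than the primer).  Ties are broken by longest overlap, then assay order.
    Returns {sequence: assay name} for assigned sequences only.
    """
    out: dict[str, str] = {}
    for seq in sequences:
        dna = to_dna(seq)
        best_name, best_len = None, min_overlap - 1
        for a in assays:
            m = longest_primer_match(dna, a.primer_sequence)
            if m > best_len:
                best_name, best_len = a.name, m
        if best_name is not None:
            out[seq] = best_name
    return out


def flag_control_sequences(
    table: CountTable,
    presence_frac: float = 0.5,
    min_copies: int = 1,
    spike_sequences: Iterable[str] = (),
) -> set[str]:
    """Sequences recurring in extraction-control libraries.

    A sequence is flagged iff it is detected at >= ``min_copies`` in strictly
    more than ``presence_frac`` of the control libraries (mock, eluate,
    water, no_template).  Spike-in sequences are never flagged.  Raises when
    the table contains no control libraries — the pipeline requires
    extraction controls to be sequenced with the study samples.
    """
    controls = table.control_ids()
    if not controls:
        raise ValueError(
            "no control libraries in count table; extraction controls must be "
            "sequenced with the study samples"
        )
    sub = table.counts[controls]
    frac = (sub >= min_copies).sum(axis=1) / len(controls)
    flagged = set(sub.index[frac > presence_frac])
    return flagged - {to_dna(s) for s in spike_sequences} - set(spike_sequences)


def spikein_normalize(
    table: CountTable, spike: SpikeInSpec
) -> tuple[pd.DataFrame, list[str]]:
    """Absolute copies per uL eluate per sequence per library.

    copies(seq, lib) = count(seq)/count(spike) * copies_per_uL_eluate; the
    ratio is invariant to the cpm scaling.  Libraries in which the spike-in
    is not detected cannot be normalised: they are returned in the flagged
    list and their column is NaN, never silently zeroed.
    """
    spike_seq = spike.sequence
    if spike_seq in table.counts.index:
        spike_counts = table.counts.loc[spike_seq]
    else:
        spike_counts = pd.Series(0, index=table.counts.columns)
    flagged = [lib for lib in table.counts.columns if spike_counts[lib] == 0]
    denom = spike_counts.replace(0, np.nan)
    copies = table.counts.div(denom, axis=1) * spike.copies_per_uL_eluate
    return copies, flagged


def assay_rpm(
    table: CountTable, assays: Sequence[ContaminantAssay],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-assay reads-per-million table (assays x libraries) from a count
    table, using the primer-identity assignment rule."""
    assignment = match_contaminants(table.counts.index, assays, min_overlap)
    rpm = pd.DataFrame(0.0, index=[a.name for a in assays], columns=table.counts.columns)
    cpm = table.cpm
    for seq, name in assignment.items():
        rpm.loc[name] += cpm.loc[seq].fillna(0.0)
    return rpm


def screen_dataset(
    fastq: str | Path | Sequence[tuple[str, str]],
    assays: Sequence[ContaminantAssay],
    adapters: Sequence[str] = (TRUSEQ_SMALL_RNA_ADAPTER,),
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.Series:
    """Screen any local sRNA-seq FASTQ for the contaminant panel.

    Preprocessing runs in public mode (singleton removal); the result is
    rpm per assay over the retained reads of the library.
    """
    if isinstance(fastq, (str, Path)):
        try:
            records = read_fastq(fastq)
        except (OSError, ValueError) as exc:
            raise ValueError(f"cannot read FASTQ {fastq}: {exc}") from exc
        reads = [(seq, qual) for _, seq, qual in records]
        library_id = Path(str(fastq)).name
    else:
        reads = list(fastq)
        library_id = "library"
    collapsed = preprocess_library(reads, list(adapters))
    meta = LibraryMeta(library_id=library_id, type="plasma")
    table = build_count_table([(meta, collapsed)], mode="public")
    rpm = assay_rpm(table, assays, min_overlap)
    return rpm[library_id]


@dataclass
class DepletionReport:
    """Paired treated/untreated copy estimates summarised per assay."""

    fold_change: pd.Series
    percent_reduction: pd.Series
    mean_fold: float
    mean_reduction: float
    sd_reduction: float
    undefined: list[str]  # untreated == 0: no estimate
    infinite: list[str]  # treated == 0: complete depletion


def depletion_report(
    copies_treated: Mapping[str, float] | pd.Series,
    copies_untreated: Mapping[str, float] | pd.Series,
) -> DepletionReport:
    """Fold change and percent reduction of contaminant levels after a
    column clean-up treatment.

    fold = untreated/treated (infinite when treated is 0); reduction =
    (1 - treated/untreated) * 100; aggregates are mean +/- SD across assays.
    Pairs with untreated == 0 are undefined and flagged, not averaged.
    """
    treated = pd.Series(dict(copies_treated), dtype=float)
    untreated = pd.Series(dict(copies_untreated), dtype=float)
    common = [k for k in untreated.index if k in treated.index]
    treated, untreated = treated[common], untreated[common]
    undefined = [k for k in common if untreated[k] == 0]
    ok = [k for k in common if untreated[k] > 0]
    fold = untreated[ok] / treated[ok].replace(0, np.nan)
    infinite = [k for k in ok if treated[k] == 0]
    fold[infinite] = np.inf
    reduction = (1.0 - treated[ok] / untreated[ok]) * 100.0
    finite = fold.replace(np.inf, np.nan).dropna()
    return DepletionReport(
        fold_change=fold,
        percent_reduction=reduction,
        mean_fold=float(finite.mean()) if len(finite) else float("nan"),
        mean_reduction=float(reduction.mean()) if len(reduction) else float("nan"),
        sd_reduction=float(reduction.std(ddof=1)) if len(reduction) > 1 else 0.0,
        undefined=undefined,
        infinite=infinite,
    )
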