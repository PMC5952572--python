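"""Multi-criteria cascade nominating bona fide exogenous plasma sRNAs.

Sequences from the study count table pass through a fixed filter order:

1. drop sequences assigned to the confirmed contaminant panel;
2. drop sequences detected in more than 10% of the extraction controls
   (i.e. not absent from at least 90% of them);
3. drop sequences ever reaching 10 or more copies in ANY control;
4. keep sequences seen with more than 3 reads in more than 7 of the 28
   plasma libraries (both strict inequalities; the 7-of-28 rule rescales
   as the fraction 0.25 for other library totals);
5. drop low-complexity sequences (mononucleotide entropy / homopolymer);
6. drop sequences with any host-genome hit;
7. drop sequences whose best reference match is a genus commonly reported
   as a sequencing-kit contaminant.

Survivors are the candidate exogenous sequences; survivor sets are nested
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .attribution import MappingHit
from .preprocess import CountTable

#: Genera repeatedly reported as sequencing/extraction kit contaminants in
#: low-biomass studies (ultrapure-water and kit reagent surveys).
DEFAULT_KIT_GENERA = (
    "Ralstonia", "Burkholderia", "Bradyrhizobium", "Sphingomonas",
    "Methylobacterium", "Mesorhizobium", "Herbaspirillum", "Acinetobacter",
    "Pseudomonas", "Stenotrophomonas", "Delftia", "Comamonas",
    "Propionibacterium", "Cutibacterium", "Corynebacterium", "Escherichia",
    "Aquabacterium", "Variovorax", "Phyllobacterium", "Afipia",
)

STAGES = (
    "confirmed_contaminant",
    "control_presence",
    "control_copy_cap",
    "low_abundance",
    "low_complexity",
    "host_like",
    "kit_genus",
    "candidate",
)


@dataclass(frozen=True)
class CascadeParams:
    control_absence_frac: float = 0.90
    control_copy_cap: int = 10
    min_reads: int = 3
    min_libraries: int = 7
    library_total: int = 28
    complexity_threshold: float = 1.5  # bits per symbol
    kit_genera: tuple[str, ...] = DEFAULT_KIT_GENERA

    def __post_init__(self) -> None:
        if not (0 < self.control_absence_frac <= 1):
            raise ValueError("control_absence_frac must be in (0, 1]")
        for name in ("control_copy_cap", "min_reads", "min_libraries", "library_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def effective_min_libraries(self, n_plasma: int) -> float:
        """Strict library-count threshold rescaled to the actual design.

        Defaults give the 7-of-28 rule; other designs use the same fraction
        (7/28 = 0.25) of their plasma library count.
        """
        return self.min_libraries * n_plasma / self.library_total


def shannon_entropy(sequence: str) -> float:
    """Mononucleotide Shannon entropy in bits per symbol."""
    n = len(sequence)
    if n == 0:
        return 0.0
    ent = 0.0
    for base in set(sequence):
        p = sequence.count(base) / n
        ent -= p * math.log2(p)
    return ent


def longest_homopolymer(sequence: str) -> int:
    best = run = 0
    prev = ""
    for c in sequence:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def low_complexity(sequence: str, threshold: float = 1.5) -> bool:
    """Flag sequences with entropy below ``threshold`` bits or with a
    homopolymer covering at least two thirds of their length."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if shannon_entropy(sequence) < threshold:
        return True
    return longest_homopolymer(sequence) * 3 >= 2 * len(sequence)


@dataclass
class CascadeReport:
    """Per-sequence stage outcomes and per-stage survivor counts."""

    outcomes: pd.Series  # sequence -> stage of removal, or 'candidate'
    survivor_counts: dict[str, int]
    candidates: list[str]
    params: CascadeParams

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"outcome": self.outcomes})
        df.index.name = "sequence"
        return df


def _best_hits(hits: Iterable[MappingHit]) -> dict[str, MappingHit]:
    """Best hit per sequence: fewest mismatches, then longest overlap, then
    reference order (deterministic)."""
    best: dict[str, MappingHit] = {}
    for h in hits:
        cur = best.get(h.sequence)
        if cur is None or (h.mismatches, -len(h.sequence), h.reference_id) < (
            cur.mismatches, -len(cur.sequence), cur.reference_id
        ):
            best[h.sequence] = h
    return best


def run_cascade(
    table: CountTable,
    contaminant_set: Iterable[str],
    params: CascadeParams = CascadeParams(),
    host_sequences: Iterable[str] | None = None,
    best_hit_genus: Mapping[str, str] | None = None,
) -> CascadeReport:
    """Apply the candidate cascade to a study count table.

    ``contaminant_set`` holds the sequences assigned to the confirmed
    contaminant panel (plus any spike-ins); ``host_sequences`` the sequences
    with at least one host-genome hit; ``best_hit_genus`` maps a sequence to
    the genus of its best reference hit (sequences absent from the mapping
    are treated as having no hit).  When host or taxon evidence is not
    supplied the corresponding stage passes everything through.
    """
    plasma = table.plasma_ids()
    if not plasma:
        raise ValueError("count table contains no plasma libraries")
    controls = table.control_ids()
    if not controls:
        raise ValueError(
            "no control libraries in count table; extraction controls must be "
            "sequenced with the study samples"
        )
    contaminant_set = set(contaminant_set)
    host_set = set(host_sequences) if host_sequences is not None else set()
    genus_of = dict(best_hit_genus) if best_hit_genus is not None else {}
    kit = set(params.kit_genera)

    counts = table.counts
    ctrl = counts[controls]
    pls = counts[plasma]
    detect_frac = (ctrl >= 1).sum(axis=1) / len(controls)
    max_ctrl = ctrl.max(axis=1)
    n_abundant = (pls > params.min_reads).sum(axis=1)
    min_libs = params.effective_min_libraries(len(plasma))

    outcomes = {}
    survivors = list(counts.index)
    survivor_counts: dict[str, int] = {}

    def stage(name: str, drop) -> None:
        nonlocal survivors
        kept = []
        for seq in survivors:
            if drop(seq):
                outcomes[seq] = name
            else:
                kept.append(seq)
        survivors = kept
        survivor_counts[name] = len(survivors)

    # epsilon guards the strict comparison against float representation of
    # the 10%-of-controls threshold
    presence_cap = 1.0 - params.control_absence_frac + 1e-9
    stage("confirmed_contaminant", lambda s: s in contaminant_set)
    stage("control_presence", lambda s: detect_frac[s] > presence_cap)
    stage("control_copy_cap", lambda s: max_ctrl[s] >= params.control_copy_cap)
    stage("low_abundance", lambda s: not n_abundant[s] > min_libs)
    stage("low_complexity", lambda s: low_complexity(s, params.complexity_threshold))
    stage("host_like", lambda s: s in host_set)
    stage("kit_genus", lambda s: genus_of.get(s) in kit)

    for seq in survivors:
        outcomes[seq] = "candidate"
    survivor_counts["candidate"] = len(survivors)
    return CascadeReport(
        outcomes=pd.Series(outcomes).reindex(counts.index),
        survivor_counts=survivor_counts,
        candidates=survivors,
        params=params,
    )


def classify_candidates(
    candidates: Sequence[str],
    reference_hits: Iterable[MappingHit],
    ref_taxa: Mapping[str, tuple[str, str]],
    kit_genera: Iterable[str] = DEFAULT_KIT_GENERA,
) -> pd.DataFrame:
    """Assign provisional taxon labels to cascade candidates.

    ``ref_taxa`` maps reference id -> (taxon group, genus), where group is
    one of host/vertebrate/bacteria/fungi/plant.  The best hit (fewest
    mismatches, then longest overlap, ties broken toward removal) decides:
    host or vertebrate best hits are removed as potentially human, kit-genus
    best hits are removed as reagent artefacts, the rest are labelled with
    the best-hit taxon or 'unknown' when nothing matches.
    """
    hits = list(reference_hits)
    for h in hits:
        if h.reference_id not in ref_taxa:
            raise ValueError(f"reference {h.reference_id!r} has no taxon label")
    kit = set(kit_genera)

    def removal_rank(h: MappingHit) -> int:
        group, genus = ref_taxa[h.reference_id]
        if group in ("host", "vertebrate"):
            return 0
        if genus in kit:
            return 1
        return 2

    best: dict[str, MappingHit] = {}
    for h in hits:
        cur = best.get(h.sequence)
        key = (h.mismatches, -len(h.sequence), removal_rank(h), h.reference_id)
        if cur is None or key < (
            cur.mismatches, -len(cur.sequence), removal_rank(cur), cur.reference_id
        ):
            best[h.sequence] = h

    rows = []
    for seq in candidates:
        h = best.get(seq)
        if h is None:
            rows.append((seq, "kept", "unknown", ""))
            continue
        group, genus = ref_taxa[h.reference_id]
        if group in ("host", "vertebrate"):
            rows.append((seq, "removed_host", group, genus))
        elif genus in kit:
            rows.append((seq, "removed_kit_genus", group, genus))
        else:
            rows.append((seq, "kept", group, genus))
    return pd.DataFrame(rows, columns=["sequence", "status", "taxon_group", "genus"])
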