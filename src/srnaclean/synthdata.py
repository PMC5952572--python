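"""Synthetic references, sequencing libraries and qPCR curves.

The generator emulates the design of a plasma titration experiment with
extraction controls: reagent contaminants sit on the spin column at a fixed
copy number per column, sample-borne RNA scales with the plasma input
volume, and a synthetic spike-in of known concentration enables absolute
quantification.  Because contaminant copies are per column while endogenous
copies are per microlitre, the inverse relationship between contaminant
relative abundance (cpm) and input volume is emergent rather than
hard-coded.

All randomness is driven by explicit integer seeds; identical (config,
seed) pairs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import random_dna, revcomp
from .exogenous import low_complexity
from .preprocess import (
    CollapsedRead,
    CountTable,
    LibraryMeta,
    TRUSEQ_SMALL_RNA_ADAPTER,
    build_count_table,
)

# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

#: The six confirmed column-contaminant sRNA sequences (DNA alphabet) and the
#: hsa-miR-486-5p spike-in used for absolute normalisation.
CONFIRMED_CONTAMINANTS: dict[str, str] = {
    "sRNA 1": "CTAACAGACCGAGGACTTGAAT",
    "sRNA 2": "ACGGACAAGAATAGGCTTCGGCT",
    "sRNA 3": "GCCTTGGTTGTAGGATCTGT",
    "sRNA 4": "GCCAGCATCAGTTCGGTGTG",
    "sRNA 5": "GAGAGTAGGACGTTGCCAGGTT",
    "sRNA 6": "TTGAAGGGTCGTTCGAGACCAGGACGTTGATAGGCTGGGTG",
}

SPIKE_IN_NAME = "hsa-miR-486-5p"
SPIKE_IN_SEQUENCE = "TCCTGTACTGAGCTGCCCCGAG"

#: Per-column contaminant copy numbers calibrated so that a 100 uL plasma
#: extraction on a regular column reproduces the observed per-sequence cpm
#: levels (tens of thousands of cpm for the most abundant contaminant).
DEFAULT_CONTAMINANT_COPIES: dict[str, float] = {
    "sRNA 1": 7200.0,
    "sRNA 2": 1700.0,
    "sRNA 3": 1750.0,
    "sRNA 4": 1450.0,
    "sRNA 5": 830.0,
    "sRNA 6": 730.0,
}


@dataclass(frozen=True)
class ReferenceConfig:
    """Sizes of the synthetic reference universe."""

    host_length: int = 50_000
    n_host_srnas: int = 40
    host_srna_len: tuple[int, int] = (18, 25)
    include_confirmed_panel: bool = True
    n_extra_contaminants: int = 0
    extra_contaminant_len: tuple[int, int] = (19, 24)
    n_exogenous: int = 5
    exogenous_len: tuple[int, int] = (20, 24)
    nonhost_genome_length: int = 8_000


@dataclass
class ReferenceSet:
    """Synthetic reference universe for one simulated experiment.

    ``host_srnas`` are planted loci (exact substrings of the host genome);
    ``host_srna_weights`` is the relative expression profile of the simulated
    plasma sample.  ``nonhost_genomes`` embed the contaminant and exogenous
    panels so attribution and taxonomy steps can be exercised;
    ``nonhost_taxa`` labels each with (taxon group, genus).
    """

    host_genome: dict[str, str]
    host_srnas: dict[str, str]
    host_srna_weights: dict[str, float]
    contaminant_panel: dict[str, str]
    exogenous_panel: dict[str, str]
    spike_in: tuple[str, str]
    nonhost_genomes: dict[str, str]
    nonhost_taxa: dict[str, tuple[str, str]]

    def all_planted(self) -> dict[str, str]:
        out = dict(self.host_srnas)
        out.update(self.contaminant_panel)
        out.update(self.exogenous_panel)
        out[self.spike_in[0]] = self.spike_in[1]
        return out


def _draw_distinct(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    forbidden: set[str],
    host: str,
    max_tries: int = 50,
) -> list[str]:
    """Random sequences distinct from each other, from ``forbidden`` and not
    exact substrings of the host genome (either strand).

    Low-complexity draws are rejected: the planted panels stand in for
    genuine biological sRNAs, which the analysis must be able to tell apart
    from degenerate artefact sequences.
    """
    host_rc = revcomp(host)
    out: list[str] = []
    for _ in range(n):
        for _ in range(max_tries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = random_dna(rng, length)
            if seq in forbidden or seq in out or seq in host or seq in host_rc:
                continue
            if low_complexity(seq, threshold=1.6):
                continue
            out.append(seq)
            break
        else:
            raise RuntimeError("could not draw a collision-free sequence")
    return out


def make_references(config: ReferenceConfig, seed: int) -> ReferenceSet:
    """Deterministically generate a ReferenceSet for (config, seed).

    The contaminant panel includes the six confirmed column contaminants
    verbatim when ``config.include_confirmed_panel`` is set.  If a panel sequence
    collides with the host genome at exact-match level the host genome is
    regenerated; persistent collision is a hard error.
    """
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        host = random_dna(rng, config.host_length)
        host_rc = revcomp(host)
        panel = dict(CONFIRMED_CONTAMINANTS) if config.include_confirmed_panel else {}
        if any(s in host or s in host_rc for s in panel.values()):
            continue
        if SPIKE_IN_SEQUENCE in host or SPIKE_IN_SEQUENCE in host_rc:
            continue
        forbidden = set(panel.values()) | {SPIKE_IN_SEQUENCE}
        try:
            extras = _draw_distinct(
                rng, config.n_extra_contaminants, config.extra_contaminant_len, forbidden, host
            )
            for i, seq in enumerate(extras, 1):
                panel[f"extra_contaminant_{i}"] = seq
            forbidden |= set(extras)
            exo = _draw_distinct(
                rng, config.n_exogenous, config.exogenous_len, forbidden, host
            )
        except RuntimeError:
            continue
        exo_panel = {f"exo_{i}": s for i, s in enumerate(exo, 1)}

        # plant host sRNA loci as genome substrings with distinct sequences
        host_srnas: dict[str, str] = {}
        seen: set[str] = set(panel.values()) | set(exo) | {SPIKE_IN_SEQUENCE}
        tries = 0
        while len(host_srnas) < config.n_host_srnas and tries < 50 * config.n_host_srnas:
            tries += 1
            length = int(rng.integers(config.host_srna_len[0], config.host_srna_len[1] + 1))
            pos = int(rng.integers(0, config.host_length - length))
            seq = host[pos : pos + length]
            if seq in seen or "N" in seq:
                continue
            host_srnas[f"host_srna_{len(host_srnas) + 1}"] = seq
            seen.add(seq)
        if len(host_srnas) < config.n_host_srnas:
            continue

        # lognormal expression profile for the plasma sample
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(host_srnas))
        weights = raw / raw.sum()
        host_srna_weights = {
            name: float(w) for name, w in zip(host_srnas, weights)
        }

        nonhost_genomes, nonhost_taxa = _embed_nonhost_genomes(
            rng, config, panel, exo_panel
        )
        return ReferenceSet(
            host_genome={"host_chr1": host},
            host_srnas=host_srnas,
            host_srna_weights=host_srna_weights,
            contaminant_panel=panel,
            exogenous_panel=exo_panel,
            spike_in=(SPIKE_IN_NAME, SPIKE_IN_SEQUENCE),
            nonhost_genomes=nonhost_genomes,
            nonhost_taxa=nonhost_taxa,
        )
    raise RuntimeError("reference generation failed: persistent host/panel collisions")


def _embed_nonhost_genomes(
    rng: np.random.Generator,
    config: ReferenceConfig,
    panel: Mapping[str, str],
    exo_panel: Mapping[str, str],
) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
    """Two labelled non-host genomes: one (a known kit-contaminant genus)
    carrying the contaminant panel, one carrying the exogenous panel."""

    def embed(background_len: int, inserts: Sequence[str]) -> str:
        g = list(random_dna(rng, background_len))
        slot = background_len // (len(inserts) + 1) if inserts else background_len
        for i, ins in enumerate(inserts, 1):
            pos = i * slot - len(ins) // 2
            g[pos : pos + len(ins)] = list(ins)
        return "".join(g)

    genomes = {
        "Ralstonia_sp": embed(config.nonhost_genome_length, list(panel.values())),
        "Lactobacillus_sp": embed(config.nonhost_genome_length, list(exo_panel.values())),
    }
    taxa = {
        "Ralstonia_sp": ("bacteria", "Ralstonia"),
        "Lactobacillus_sp": ("bacteria", "Lactobacillus"),
    }
    return genomes, taxa


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesign:
    """Composition model of one simulated library.

    Expected fragment pool: ``endogenous_copies_per_uL * V`` (split by the
    reference set's expression profile) + per-contaminant copies per column
    + ``exogenous_copies_per_uL * V`` per planted exogenous sequence
    + spike-in copies when the metadata says so.  Reads are drawn
    multinomially from the pool.
    """

    meta: LibraryMeta
    total_reads: int
    seed: int
    endogenous_copies_per_uL: float = 2000.0
    contaminant_copies_per_column: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_COPIES)
    )
    exogenous_copies_per_uL: float = 0.08
    carryover_contaminant_copies: float = 0.0
    eluate_volume_uL: float = 14.0
    error_rate: float = 0.001
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    read_length: int = 75
    low_quality_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.adapter:
            raise ValueError("adapter must be set")
        for name, v in (
            ("endogenous_copies_per_uL", self.endogenous_copies_per_uL),
            ("exogenous_copies_per_uL", self.exogenous_copies_per_uL),
            ("carryover_contaminant_copies", self.carryover_contaminant_copies),
            ("error_rate", self.error_rate),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.contaminant_copies_per_column.values()):
            raise ValueError("contaminant copies must be >= 0")


def fragment_pool(design: LibraryDesign, refs: ReferenceSet) -> pd.DataFrame:
    """Expected copy number per fragment species for this library.

    Returns a DataFrame indexed by species name with columns
    (sequence, category, copies); category is one of
    host | contaminant | exogenous | spike_in.
    """
    m = design.meta
    rows: list[tuple[str, str, str, float]] = []
    if m.type == "plasma":
        v = m.volume_uL
        for name, seq in refs.host_srnas.items():
            rows.append(
                (name, seq, "host", refs.host_srna_weights[name] * design.endogenous_copies_per_uL * v)
            )
        for name, seq in refs.contaminant_panel.items():
            rows.append((name, seq, "contaminant", design.contaminant_copies_per_column.get(name, 0.0)))
        for name, seq in refs.exogenous_panel.items():
            rows.append((name, seq, "exogenous", design.exogenous_copies_per_uL * v))
    elif m.type in ("mock", "eluate"):
        for name, seq in refs.contaminant_panel.items():
            rows.append((name, seq, "contaminant", design.contaminant_copies_per_column.get(name, 0.0)))
    else:  # water / no_template: carry-over only
        total = sum(design.contaminant_copies_per_column.values())
        if total > 0 and design.carryover_contaminant_copies > 0:
            for name, seq in refs.contaminant_panel.items():
                frac = design.contaminant_copies_per_column.get(name, 0.0) / total
                rows.append((name, seq, "contaminant", design.carryover_contaminant_copies * frac))
    if m.spikein_copies_per_uL > 0:
        rows.append(
            (refs.spike_in[0], refs.spike_in[1], "spike_in", m.spikein_copies_per_uL * design.eluate_volume_uL)
        )
    df = pd.DataFrame(rows, columns=["species", "sequence", "category", "copies"])
    return df.set_index("species")


def simulate_counts(design: LibraryDesign, refs: ReferenceSet) -> pd.DataFrame:
    """Multinomial draw of read counts per fragment species (the error-free
    collapsed view of the library).

    Returns the pool DataFrame with a ``count`` column; zero-count species
    are dropped.  Raises when the pool is empty but total_reads > 0.
    """
    pool = fragment_pool(design, refs)
    total_copies = pool["copies"].sum() if len(pool) else 0.0
    if design.total_reads > 0 and total_copies <= 0:
        raise ValueError(
            f"library {design.meta.library_id}: empty fragment pool with total_reads > 0"
        )
    rng = np.random.default_rng(design.seed)
    if design.total_reads == 0 or total_copies <= 0:
        pool = pool.assign(count=0)
        return pool[pool["count"] > 0]
    p = (pool["copies"] / total_copies).to_numpy()
    counts = rng.multinomial(design.total_reads, p)
    pool = pool.assign(count=counts)
    return pool[pool["count"] > 0].copy()


def simulate_collapsed(design: LibraryDesign, refs: ReferenceSet) -> list[CollapsedRead]:
    """The error-free collapsed view of a simulated library: the multinomial
    species counts as CollapsedRead records (descending count, ties
    lexicographic) — what preprocessing of an error-free FASTQ yields."""
    counts = simulate_counts(design, refs)
    return [
        CollapsedRead(row["sequence"], int(row["count"]))
        for _, row in counts.sort_values(
            ["count", "sequence"], ascending=[False, True]
        ).iterrows()
    ]


def simulate_study_table(
    refs: ReferenceSet,
    seed: int,
    total_reads: int = 200_000,
    mode: str = "study",
    **study_kwargs,
) -> CountTable:
    """Full study design rendered directly as a count table (error-free
    collapsed view), for fast end-to-end analyses."""
    designs = simulate_study(refs, seed, total_reads=total_reads, **study_kwargs)
    return build_count_table(
        [(d.meta, simulate_collapsed(d, refs)) for d in designs], mode=mode
    )


_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
_CODE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution errors on an ASCII uint8 matrix."""
    if error_rate <= 0 or mat.size == 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    n = int(mask.sum())
    if n == 0:
        return mat
    codes = _BASE_CODES[mat[mask]]
    shift = rng.integers(1, 4, size=n)
    mat = mat.copy()
    mat[mask] = _CODE_BASES[(codes + shift) % 4]
    return mat


def simulate_library(
    design: LibraryDesign, refs: ReferenceSet
) -> list[tuple[str, str, str]]:
    """Simulate FASTQ records (id, sequence, quality) for one library.

    Each read is its sRNA insert (with substitution errors at
    ``error_rate``) followed by the 3' adapter, padded by cycling the
    adapter out to ``read_length`` and truncated to it.  Qualities are
    constant Q36 except for an optional fraction of reads given low-quality
    bases to exercise the quality filter.  Read ids carry the originating
    species for truth tracking.
    """
    counts = simulate_counts(design, refs)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    L = design.read_length
    pad = (design.adapter * (L // len(design.adapter) + 2)).encode("ascii")
    pieces: list[np.ndarray] = []
    ids: list[str] = []
    for species, row in counts.iterrows():
        c = int(row["count"])
        insert = row["sequence"].encode("ascii")
        ins = np.tile(np.frombuffer(insert, dtype=np.uint8), (c, 1))
        ins = _mutate(ins, design.error_rate, rng)
        tail = np.frombuffer(pad[: max(0, L - ins.shape[1])], dtype=np.uint8)
        full = np.concatenate([ins, np.tile(tail, (c, 1))], axis=1)[:, :L]
        pieces.append(full)
        ids.extend(f"{design.meta.library_id}:{species}:{i}" for i in range(c))
    if not pieces:
        return []
    mat = np.concatenate(pieces, axis=0)
    order = rng.permutation(mat.shape[0])
    mat = mat[order]
    ids = [ids[i] for i in order]

    qual_mat = np.full(mat.shape, ord("E"), dtype=np.uint8)  # Q36
    if design.low_quality_frac > 0:
        bad_reads = rng.random(mat.shape[0]) < design.low_quality_frac
        bad_bases = rng.random(mat.shape) < 0.2
        qual_mat[bad_reads[:, None] & bad_bases] = ord("#")  # Q2

    seq_blob = mat.tobytes().decode("ascii")
    qual_blob = qual_mat.tobytes().decode("ascii")
    return [
        (rid, seq_blob[i * L : (i + 1) * L], qual_blob[i * L : (i + 1) * L])
        for i, rid in enumerate(ids)
    ]


# ---------------------------------------------------------------------------
# titration and study designs
# ---------------------------------------------------------------------------

TITRATION_VOLUMES_UL = (45.0, 100.0, 225.0, 500.0, 1115.0)
DEFAULT_ULTRACLEAN_FACTOR = 60.0

#: Replicates per titration volume giving 14 libraries per column type and
#: 28 plasma libraries over the two column types (replication is deliberately
#: unequal at the highest volume).
STUDY_REPLICATES: dict[float, int] = {45.0: 3, 100.0: 3, 225.0: 3, 500.0: 3, 1115.0: 2}


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def simulate_titration(
    volumes: Sequence[float],
    column_types: Sequence[str],
    refs: ReferenceSet,
    base_design: LibraryDesign,
    seed: int,
    replicates: int | Mapping[float, int] = 2,
    ultraclean_factor: float = DEFAULT_ULTRACLEAN_FACTOR,
) -> list[LibraryDesign]:
    """Library designs for a plasma input-volume titration.

    One design per (volume, column type, replicate); ultra-clean columns get
    all contaminant copy numbers divided by ``ultraclean_factor``.  Per-library
    seeds derive deterministically from the master seed.
    """
    if not volumes:
        raise ValueError("volumes must be non-empty")
    rep_of = (lambda v: replicates[v]) if isinstance(replicates, Mapping) else (lambda v: replicates)
    combos = [
        (float(v), col, r)
        for col in column_types
        for v in volumes
        for r in range(1, rep_of(float(v)) + 1)
    ]
    if len(set(combos)) != len(combos):
        raise ValueError("duplicate (volume, column, replicate) identifiers")
    seeds = _child_seeds(seed, len(combos))
    designs = []
    for (v, col, r), s in zip(combos, seeds):
        cont = dict(base_design.contaminant_copies_per_column)
        if col == "ultraclean":
            cont = {k: c / ultraclean_factor for k, c in cont.items()}
        meta = LibraryMeta(
            library_id=f"plasma_V{v:g}_{col}_r{r}",
            type="plasma",
            column=col,
            batch=col[0],
            volume_uL=v,
            seed=s,
        )
        designs.append(replace(base_design, meta=meta, seed=s, contaminant_copies_per_column=cont))
    return designs


def make_control_designs(
    refs: ReferenceSet,
    base_design: LibraryDesign,
    seed: int,
    n_mock: int = 6,
    n_eluate: int = 4,
    n_water: int = 1,
    n_no_template: int = 1,
    spikein_copies_per_uL: float = 40_000.0,
    column: str = "regular",
) -> list[LibraryDesign]:
    """Extraction-control designs: mock extractions and column eluates carry
    the spike-in at the stated concentration; water and no-template controls
    default to zero reads (no carry-over)."""
    specs = (
        [("mock", i, True) for i in range(1, n_mock + 1)]
        + [("eluate", i, True) for i in range(1, n_eluate + 1)]
        + [("water", i, False) for i in range(1, n_water + 1)]
        + [("no_template", i, False) for i in range(1, n_no_template + 1)]
    )
    seeds = _child_seeds(seed, len(specs))
    designs = []
    for (ctype, i, spiked), s in zip(specs, seeds):
        meta = LibraryMeta(
            library_id=f"{ctype}_{i}",
            type=ctype,
            column=column,
            batch=column[0],
            volume_uL=0.0,
            spikein_name=SPIKE_IN_NAME if spiked else None,
            spikein_copies_per_uL=spikein_copies_per_uL if spiked else 0.0,
            seed=s,
        )
        reads = base_design.total_reads if spiked else (
            base_design.total_reads if base_design.carryover_contaminant_copies > 0 else 0
        )
        designs.append(replace(base_design, meta=meta, seed=s, total_reads=reads))
    return designs


def simulate_study(
    refs: ReferenceSet,
    seed: int,
    total_reads: int = 200_000,
    column_types: Sequence[str] = ("regular", "ultraclean"),
    ultraclean_factor: float = DEFAULT_ULTRACLEAN_FACTOR,
    **design_kwargs,
) -> list[LibraryDesign]:
    """Full study design: the five-volume titration on both column types
    (28 plasma libraries) plus 12 extraction controls."""
    base = LibraryDesign(
        meta=LibraryMeta(library_id="template", type="plasma", volume_uL=100.0),
        total_reads=total_reads,
        seed=0,
        **design_kwargs,
    )
    s1, s2 = _child_seeds(seed, 2)
    designs = simulate_titration(
        TITRATION_VOLUMES_UL, column_types, refs, base, s1,
        replicates=STUDY_REPLICATES, ultraclean_factor=ultraclean_factor,
    )
    designs += make_control_designs(refs, base, s2)
    return designs


def metadata_frame(designs: Iterable[LibraryDesign]) -> pd.DataFrame:
    """Per-library metadata table (one row per design)."""
    rows = []
    for d in designs:
        m = d.meta
        rows.append(
            dict(
                library_id=m.library_id, type=m.type, column=m.column, batch=m.batch,
                volume_uL=m.volume_uL, spikein_name=m.spikein_name or "",
                spikein_copies_per_uL=m.spikein_copies_per_uL, seed=d.seed,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR curve simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrCurveParams:
    """Four-parameter sigmoid amplification model.

    Fluorescence at cycle c is baseline + amplitude / (1 + exp(-(c - mid)/width))
    with mid = midpoint_1copy - log10(copies) * cycles_per_decade, where
    cycles_per_decade = ln(10)/ln(1 + efficiency).  Perfect doubling
    (efficiency 1) gives 3.3219 cycles per decade.
    """

    baseline: float = 0.5
    amplitude: float = 10.0
    width: float = 1.0
    midpoint_1copy: float = 38.0
    efficiency: float = 1.0
    n_cycles: int = 40

    @property
    def cycles_per_decade(self) -> float:
        return float(np.log(10.0) / np.log1p(self.efficiency))

    def midpoint(self, copies: float) -> float:
        return self.midpoint_1copy - np.log10(copies) * self.cycles_per_decade


@dataclass
class AmplificationCurveSet:
    """One fluorescence trace per reaction, plus the true input copies."""

    cycles: np.ndarray
    fluorescence: np.ndarray  # (n_reactions, n_cycles)
    true_copies: np.ndarray
    noise_sd: float
    params: QpcrCurveParams

    def __len__(self) -> int:
        return self.fluorescence.shape[0]


def simulate_qpcr(
    true_copies_list: Sequence[float],
    curve_params: QpcrCurveParams = QpcrCurveParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AmplificationCurveSet:
    """Simulate amplification curves for a list of input copy numbers.

    noise_sd = 0 gives the analytic sigmoids; reactions with copies <= 0
    produce a flat baseline (no amplification)."""
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, curve_params.n_cycles + 1, dtype=float)
    traces = []
    for copies in true_copies_list:
        if copies <= 0:
            f = np.full_like(cycles, curve_params.baseline)
        else:
            mid = curve_params.midpoint(copies)
            f = curve_params.baseline + curve_params.amplitude / (
                1.0 + np.exp(-(cycles - mid) / curve_params.width)
            )
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=f.shape)
        traces.append(f)
    return AmplificationCurveSet(
        cycles=cycles,
        fluorescence=np.array(traces),
        true_copies=np.asarray(true_copies_list, dtype=float),
        noise_sd=noise_sd,
        params=curve_params,
    )
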