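"""Synthetic multi-copy genomes, communities, and CCS-like amplicon reads.

The generator emulates the data the phasing pipeline consumes: genomes
carrying C polymorphic 16S gene copies (substitutions and rare indels
between copies), mixtures of strains/species at chosen abundances, and
full-length circular-consensus-like reads with independent substitution
errors plus deletion errors whose probability grows with homopolymer
run length.  Every read carries complete provenance (source genome,
source copy, explicit error events), so ground truth is available to
every downstream test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compare import GeneCopySet
from .profiles import homopolymer_runs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error model for CCS-like long amplicon reads.

    ``deletion_rate_base`` applies at homopolymer run length 1; each
    extra run base multiplies the deletion probability by
    ``homopolymer_factor`` (capped at 0.5).  Substitutions and
    insertions are independent per base.  Defaults approximate
    multi-pass consensus reads: ~0.5% substitutions, rarer indels.
    """

    substitution_rate: float = 0.005
    insertion_rate: float = 0.001
    deletion_rate_base: float = 0.002
    homopolymer_factor: float = 2.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate",
                     "deletion_rate_base"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.homopolymer_factor <= 0:
            raise ValueError("homopolymer_factor must be positive")

    def deletion_prob(self, run_length: np.ndarray) -> np.ndarray:
        p = self.deletion_rate_base * \
            self.homopolymer_factor ** (run_length - 1.0)
        return np.minimum(p, 0.5)


ERROR_FREE = ErrorModel(substitution_rate=0.0, insertion_rate=0.0,
                        deletion_rate_base=0.0, homopolymer_factor=1.0)


@dataclass
class ReadProvenance:
    """Ground truth for one simulated read."""

    read_id: str
    genome_id: str
    copy_index: int
    # events on source-copy coordinates, applied in order:
    # ('del', pos, None) / ('sub', pos, new_base) / ('ins', pos, base)
    # with 1-based pos; insertions occur after the source position.
    events: list[tuple[str, int, str | None]] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Generator ledger: genomes, planted variants, abundances, provenance."""

    genomes: list[GeneCopySet]
    planted_variants: dict[str, list[tuple[int, list[int]]]]
    abundances: dict[str, float]
    reads: list[ReadProvenance] = field(default_factory=list)

    def genome(self, genome_id: str) -> GeneCopySet:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


def random_gene(length: int = 1500, seed: int | np.random.Generator = 0,
                gc: float = 0.54) -> str:
    """A random nucleotide sequence with 16S-like length and GC content."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_gene_copy_set(base: str, C: int, n_snp_loci: int,
                       copies_per_locus: Sequence[int] | None = None,
                       n_indels: int = 0,
                       seed: int | np.random.Generator = 0,
                       genome_id: str = "genome",
                       ) -> tuple[GeneCopySet, SyntheticTruth]:
    """Plant intragenomic polymorphisms into C copies of a base gene.

    Each of the ``n_snp_loci`` loci receives a substitution in exactly
    ``copies_per_locus[i]`` of the C copies (never the reference copy,
    copy 0, so the planted fraction k/C is directly observable on the
    reference coordinates).  ``n_indels`` single-base deletions are
    additionally planted in non-reference copies at distinct positions.
    The returned truth table records every placement.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if copies_per_locus is None:
        copies_per_locus = [max(1, C // 2)] * n_snp_loci
    if len(copies_per_locus) != n_snp_loci:
        raise ValueError("copies_per_locus must have one entry per locus")
    if any(not 1 <= k <= C - 1 for k in copies_per_locus):
        raise ValueError("each locus must hit between 1 and C-1 copies")
    L = len(base)
    needed = n_snp_loci + n_indels
    if needed > L - 2:
        raise ValueError("more loci than available positions")
    # keep loci off the sequence ends so alignments stay unambiguous
    positions = rng.choice(np.arange(2, L), size=needed, replace=False)
    snp_positions = np.sort(positions[:n_snp_loci])
    indel_positions = positions[n_snp_loci:]

    copies = [list(base.upper()) for _ in range(C)]
    planted: list[tuple[int, list[int]]] = []
    for pos, k in zip(snp_positions, copies_per_locus):
        carriers = sorted(rng.choice(np.arange(1, C), size=k, replace=False))
        old = base[pos].upper()
        alt = rng.permutation([b for b in "ACGT" if b != old])[0]
        for c in carriers:
            copies[c][pos] = alt
        planted.append((int(pos) + 1, [int(c) for c in carriers]))
    for pos in indel_positions:
        c = int(rng.integers(1, C))
        copies[c][pos] = ""
    gcs = GeneCopySet(genome_id=genome_id,
                      copies=["".join(c) for c in copies],
                      reference_copy_index=0)
    truth = SyntheticTruth(genomes=[gcs],
                           planted_variants={genome_id: planted},
                           abundances={genome_id: 1.0})
    return gcs, truth


def _simulate_read(copy_codes: np.ndarray, runs: np.ndarray,
                   model: ErrorModel, rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[tuple[str, int, str | None]]]:
    """Apply the error model to one source copy; return read codes + events."""
    L = copy_codes.size
    deleted = rng.random(L) < model.deletion_prob(runs)
    substituted = (~deleted) & (rng.random(L) < model.substitution_rate)
    inserted = rng.random(L) < model.insertion_rate
    events: list[tuple[str, int, str | None]] = []
    out = np.empty(L + int(inserted.sum()), dtype=np.uint8)
    n = 0
    hot = np.flatnonzero(deleted | substituted | inserted)
    prev = 0
    for pos in hot:
        seg = copy_codes[prev:pos]
        out[n:n + seg.size] = _BASES[seg]
        n += seg.size
        p1 = int(pos) + 1
        if deleted[pos]:
            events.append(("del", p1, None))
        else:
            code = copy_codes[pos]
            if substituted[pos]:
                code = (code + rng.integers(1, 4)) % 4
                events.append(("sub", p1, chr(_BASES[code])))
            out[n] = _BASES[code]
            n += 1
        if inserted[pos]:
            ins = rng.integers(0, 4)
            events.append(("ins", p1, chr(_BASES[ins])))
            out[n] = _BASES[ins]
            n += 1
        prev = int(pos) + 1
    seg = copy_codes[prev:]
    out[n:n + seg.size] = _BASES[seg]
    n += seg.size
    return out[:n], events


def replay_events(source: str,
                  events: Sequence[tuple[str, int, str | None]]) -> str:
    """Reconstruct a read from its source copy and provenance events."""
    out: list[str] = []
    ev_by_pos: dict[int, list[tuple[str, str | None]]] = {}
    for kind, pos, base in events:
        ev_by_pos.setdefault(pos, []).append((kind, base))
    for i, ref_base in enumerate(source.upper(), start=1):
        here = ev_by_pos.get(i, [])
        kinds = dict(here)
        if "del" in kinds:
            pass
        elif "sub" in kinds:
            out.append(kinds["sub"])
        else:
            out.append(ref_base)
        if "ins" in kinds:
            out.append(kinds["ins"])
    return "".join(out)


def simulate_ccs_reads(truth: SyntheticTruth, n_reads: int,
                       model: ErrorModel = ErrorModel(),
                       seed: int | np.random.Generator = 0,
                       ) -> list[tuple[str, str]]:
    """Draw CCS-like reads from the truth's genomes; record provenance.

    Source genomes are sampled by abundance, source copies uniformly
    within a genome (equal rrn operon dosage).  Reads are full-length
    copies of the gene with independently applied errors; provenance is
    appended to ``truth.reads``.  Returns ``(read_id, sequence)`` pairs.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    genome_ids = [g.genome_id for g in truth.genomes]
    weights = np.array([truth.abundances[g] for g in genome_ids], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    copy_cache = {
        g.genome_id: [(np.frombuffer(c.upper().encode(), dtype=np.uint8),
                       homopolymer_runs(c))
                      for c in g.copies]
        for g in truth.genomes
    }
    code_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code_of[ord(b)] = i
    reads: list[tuple[str, str]] = []
    start = len(truth.reads)
    g_draw = rng.choice(len(genome_ids), size=n_reads, p=weights)
    for i, gi in enumerate(g_draw):
        genome = truth.genomes[gi]
        ci = int(rng.integers(0, genome.copy_count))
        codes, runs = copy_cache[genome.genome_id][ci]
        read_codes, events = _simulate_read(code_of[codes], runs, model, rng)
        read_id = f"read{start + i:06d}"
        reads.append((read_id, read_codes.tobytes().decode("ascii")))
        truth.reads.append(ReadProvenance(read_id=read_id,
                                          genome_id=genome.genome_id,
                                          copy_index=ci, events=events))
    return reads


def make_community(genomes: Sequence[GeneCopySet],
                   abundances: Sequence[float], n_reads: int,
                   model: ErrorModel = ErrorModel(),
                   seed: int | np.random.Generator = 0,
                   planted_variants: dict | None = None,
                   ) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Pool reads from several genomes at the given relative abundances."""
    if len(genomes) != len(abundances):
        raise ValueError("one abundance per genome required")
    ab = np.asarray(abundances, dtype=float)
    if abs(ab.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    truth = SyntheticTruth(
        genomes=list(genomes),
        planted_variants=planted_variants or {},
        abundances={g.genome_id: float(a) for g, a in zip(genomes, ab)})
    reads = simulate_ccs_reads(truth, n_reads, model, seed)
    return reads, truth


# ---------------------------------------------------------------------------
# mock-community pooling arithmetic

BP_MASS_GRAMS = 1.096e-21  # mean mass of one DNA base pair


@dataclass
class CommunityDesign:
    """Pooling design: (species_id, genome_size_bp, predicted 16S copies)."""

    members: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for sid, n, c in self.members:
            if n <= 0:
                raise ValueError(f"{sid}: genome size must be positive")
            if c < 1:
                raise ValueError(f"{sid}: copy number must be >= 1")


def genome_dna_mass(n_bp: int | float) -> float:
    """Mass of one genome's DNA in grams: m = n * 1.096e-21 g/bp."""
    if n_bp < 0:
        raise ValueError("genome size must be non-negative")
    return float(n_bp) * BP_MASS_GRAMS


def pooled_mass_for_copies(design: CommunityDesign,
                           target_copies: float) -> dict[str, float]:
    """DNA mass per member delivering the same number of 16S copies.

    ``target_copies / copy_number`` genomes of each member are needed,
    so mass_i = target_copies / copy_number_i * genome_dna_mass(n_i).
    """
    if target_copies <= 0:
        raise ValueError("target_copies must be positive")
    return {sid: target_copies / c * genome_dna_mass(n)
            for sid, n, c in design.members}


# ---------------------------------------------------------------------------
# synthetic species databases for region-resolution benchmarking

def make_species_database(n_species: int, base: str | None = None,
                          length: int = 1500,
                          variable_windows: Sequence[tuple[int, int]] = (),
                          n_variable_sites: int = 20,
                          conserved: Sequence[tuple[int, str]] = (),
                          seed: int | np.random.Generator = 0,
                          ) -> list[tuple[str, str]]:
    """Species-representative gene set with localized discriminating sites.

    Starting from one base gene (random unless given), each species
    receives ``n_variable_sites`` private substitutions drawn only from
    the union of ``variable_windows`` (1-based inclusive spans); with no
    windows the whole gene is variable.  ``conserved`` plants shared
    motifs (e.g. primer-binding sites) at fixed 1-based offsets in every
    species.  Returns ``(species_id, sequence)`` pairs.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if base is None:
        base = random_gene(length, rng)
    base = base.upper()
    L = len(base)
    blocked = np.zeros(L, dtype=bool)
    planted = list(base)
    for off, motif in conserved:
        if off < 1 or off - 1 + len(motif) > L:
            raise ValueError("conserved motif outside the gene")
        planted[off - 1:off - 1 + len(motif)] = list(motif.upper())
        blocked[off - 1:off - 1 + len(motif)] = True
    base = "".join(planted)
    if variable_windows:
        allowed = np.zeros(L, dtype=bool)
        for a, b in variable_windows:
            allowed[a - 1:b] = True
    else:
        allowed = np.ones(L, dtype=bool)
    allowed &= ~blocked
    pool = np.flatnonzero(allowed)
    if n_variable_sites > pool.size:
        raise ValueError("not enough variable positions")
    db = []
    for s in range(n_species):
        sites = rng.choice(pool, size=n_variable_sites, replace=False)
        seq = list(base)
        for p in sites:
            old = seq[p]
            seq[p] = rng.permutation([b for b in "ACGT" if b != old])[0]
        db.append((f"species{s:03d}", "".join(seq)))
    return db
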