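"""Seeded simulator for gene models and per-tissue clone sets with planted RDDs.

The generator emulates the study design the pipeline is built for: for each
gene, 10-20 near-identical Sanger cDNA clones per tissue per individual, a
mutation-free gDNA clone set, a Poisson RDD load per clone that is elevated
in the pheromone gland, an A>G-dominated 12-class substitution spectrum,
and rare single-base insertions and 1..12-base contiguous deletions.

Planted events are spaced >= 10 bases apart within a clone and are only
planted in left-canonical positions (a deletion or insertion that could
slide left into an equivalent placement is redrawn), so every event is
unambiguously recoverable by left-normalising alignment.  Every applied
event is recorded in a ground-truth manifest.

This module also provides deterministic builders for engineered worked
examples (in-frame motif deletions, late-stop frameshifts) used to check
the effect classifier against printed variant-table scenarios.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effects import apply_events_to_cdna
from .rdd_caller import RDDEvent
from .seq_core import (GeneModel, TranscriptRef, STANDARD_TABLE,
                       read_fasta, read_gff3, reverse_complement,
                       write_fasta, write_gff3)

logger = logging.getLogger("rddkit")

SUBSTITUTION_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
                        "G>A", "G>C", "G>T", "T>A", "T>C", "T>G")

#: Substitution class weights patterned on the observed clone-set spectrum
#: (A>G-dominated, with T>C, G>A, C>T and G>T next); the seven remaining
#: classes get a small uniform weight.
DEFAULT_SPECTRUM = {"A>G": 116.0, "T>C": 48.0, "G>A": 41.0, "C>T": 30.0,
                    "G>T": 19.0}
_DEFAULT_WEIGHTS = tuple(DEFAULT_SPECTRUM.get(c, 6.0) for c in SUBSTITUTION_CLASSES)

DEFAULT_TISSUES = (("antennae", 0.8), ("legs", 0.8), ("head", 0.8),
                   ("wings", 0.8), ("pheromone_gland", 0.8))

PHEROMONE_GLAND = "pheromone_gland"

_SENSE_CODONS = sorted(STANDARD_TABLE.forward)
_BASES = "ACGT"


class SimConfigError(ValueError):
    """The simulation configuration is internally infeasible."""


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    ``tissues`` is a list of (name, lambda) pairs: the per-clone Poisson RDD
    rate for that tissue; the pheromone gland's rate is multiplied by
    ``pheromone_gland_multiplier`` (tissue RDD loads were reported two to
    three times higher there).  ``spectrum_weights`` orders the 12
    substitution classes as in :data:`SUBSTITUTION_CLASSES`.
    """

    seed: int = 0
    n_genes: int = 4
    exons_per_gene: tuple = (1, 3)          # inclusive range
    orf_codons: tuple = (90, 115)           # native protein length range
    exon_len: tuple = (80, 400)             # minimum / maximum exon length
    intron_len: tuple = (60, 300)
    tissues: tuple = DEFAULT_TISSUES
    pheromone_gland_multiplier: float = 3.0
    clones_per_tissue: int = 10
    gdna_clones: int = 10
    n_individuals: int = 5
    spectrum_weights: tuple = _DEFAULT_WEIGHTS
    p_insertion: float = 0.05
    p_deletion: float = 0.05
    max_del_len: int = 12
    min_event_spacing: int = 10
    error_rate: float = 0.0                 # optional uniform error channel

    def __post_init__(self):
        if sum(self.spectrum_weights) <= 0:
            raise SimConfigError("spectrum weights must sum to > 0")
        if len(self.spectrum_weights) != 12:
            raise SimConfigError("12 substitution class weights required")
        for p in (self.p_insertion, self.p_deletion, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError("probabilities must lie in [0, 1]")
        if self.p_insertion + self.p_deletion > 1.0:
            raise SimConfigError("p_insertion + p_deletion must be <= 1")
        if any(lam < 0 for _, lam in self.tissues):
            raise SimConfigError("RDD rates must be >= 0")
        if self.pheromone_gland_multiplier < 1.0:
            raise SimConfigError("pheromone gland multiplier must be >= 1")

    def rate(self, tissue: str) -> float:
        for name, lam in self.tissues:
            if name == tissue:
                mult = (self.pheromone_gland_multiplier
                        if name == PHEROMONE_GLAND else 1.0)
                return lam * mult
        raise SimConfigError(f"unknown tissue {tissue!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("exons_per_gene", "orf_codons", "exon_len", "intron_len",
                    "spectrum_weights"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "tissues" in d:
            d["tissues"] = tuple((t[0], float(t[1])) for t in d["tissues"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = [list(t) for t in self.tissues]
        for key in ("exons_per_gene", "orf_codons", "exon_len", "intron_len",
                    "spectrum_weights"):
            d[key] = list(d[key])
        return d


@dataclass
class CloneSequence:
    """One sequenced cDNA or gDNA clone."""

    clone_id: str
    gene_id: str
    tissue: str
    individual: str
    source: str          # cDNA | gDNA
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.clone_id}: empty sequence")
        if self.source not in ("cDNA", "gDNA"):
            raise ValueError(f"{self.clone_id}: source must be cDNA or gDNA")


@dataclass
class TruthManifest:
    """Ground truth of every planted event."""

    events: list = field(default_factory=list)  # dicts: clone_id, gene_id, kind, pos, ref_allele, alt_allele

    def add(self, clone_id, gene_id, kind, pos, ref_allele, alt_allele):
        self.events.append(dict(clone_id=clone_id, gene_id=gene_id, kind=kind,
                                pos=int(pos), ref_allele=ref_allele,
                                alt_allele=alt_allele))

    def extend(self, other: "TruthManifest"):
        self.events.extend(other.events)

    def __len__(self):
        return len(self.events)

    def keys(self):
        """Comparable event keys: (clone_id, kind, pos, ref, alt)."""
        return {(e["clone_id"], e["kind"], e["pos"], e["ref_allele"],
                 e["alt_allele"]) for e in self.events}


# ---------------------------------------------------------------------------
# random sequence helpers
# ---------------------------------------------------------------------------

def _random_bases(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_sense_codons(rng, n: int) -> list:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n)
    return [_SENSE_CODONS[i] for i in idx]


def make_coding_transcript(rng, n_codons: int, orf_offset: int = 0,
                           utr3_len: int = 20, codon_overrides: dict | None = None,
                           gene_id: str = "toy") -> TranscriptRef:
    """Random amplicon with a clean ORF: ATG, ``n_codons`` sense codons, stop.

    ``codon_overrides`` maps 1-based residue indices to fixed codons (used to
    pin motifs such as His-87 or a DKIP block to known positions).
    """
    codons = _random_sense_codons(rng, n_codons)
    codons[0] = "ATG"
    for res, codon in (codon_overrides or {}).items():
        if not 1 <= res <= n_codons:
            raise ValueError(f"override residue {res} outside ORF")
        codons[res - 1] = codon
    cdna = _random_bases(rng, orf_offset) + "".join(codons) + "TAA" \
        + _random_bases(rng, utr3_len)
    return TranscriptRef(gene_id=gene_id, cdna=cdna, orf_offset=orf_offset)


# ---------------------------------------------------------------------------
# gene simulation
# ---------------------------------------------------------------------------

def simulate_gene(config: SimConfig, rng, gene_index: int = 0):
    """One random gene model plus its spliced coding reference.

    The spliced cDNA always contains a complete ORF (no internal stop, one
    terminal stop); exon counts fall within the configured range; a
    minus-strand layout is drawn half the time.
    """
    gene_id = f"gene{gene_index + 1:02d}"
    n_codons = int(rng.integers(config.orf_codons[0], config.orf_codons[1] + 1))
    orf_offset = int(rng.integers(0, 49))
    utr3 = int(rng.integers(10, 61))
    ref = make_coding_transcript(rng, n_codons, orf_offset=orf_offset,
                                 utr3_len=utr3, gene_id=gene_id)
    cdna = ref.cdna

    lo, hi = config.exons_per_gene
    n_exons = int(rng.integers(lo, hi + 1))
    min_exon = config.exon_len[0]
    if n_exons * min_exon > len(cdna):
        raise SimConfigError(
            f"{gene_id}: cannot split {len(cdna)} bases into {n_exons} exons "
            f"of >= {min_exon} bases")
    # cut the cdna into n_exons pieces, each >= min_exon
    slack = len(cdna) - n_exons * min_exon
    cuts = np.sort(rng.integers(0, slack + 1, size=n_exons - 1)) if n_exons > 1 else []
    lengths = []
    prev = 0
    for c in cuts:
        lengths.append(min_exon + int(c) - prev)
        prev = int(c)
    lengths.append(min_exon + slack - prev)

    flank = int(rng.integers(30, 120))
    scaffold_parts = [_random_bases(rng, flank)]
    exons = []
    pos = flank
    offset_in_cdna = 0
    repeats = []
    for k, length in enumerate(lengths):
        exons.append((pos + 1, pos + length))
        scaffold_parts.append(cdna[offset_in_cdna:offset_in_cdna + length])
        offset_in_cdna += length
        pos += length
        if k < len(lengths) - 1:
            ilen = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            intron = _random_bases(rng, ilen)
            # avoid creating a spurious exon boundary signal; purely decorative
            scaffold_parts.append(intron)
            if rng.random() < 0.3:
                repeats.append((f"retroposon{len(repeats) + 1}",
                                (pos + 10, min(pos + ilen - 10, pos + 60))))
            pos += ilen
    scaffold_parts.append(_random_bases(rng, flank))
    scaffold = "".join(scaffold_parts)

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        L = len(scaffold)
        scaffold = reverse_complement(scaffold)
        exons = sorted((L - e + 1, L - s + 1) for s, e in exons)
        repeats = [(lab, (L - e + 1, L - s + 1)) for lab, (s, e) in repeats]

    model = GeneModel(gene_id=gene_id, scaffold_id=f"scaffold_{gene_id}",
                      strand=strand, exons=exons, scaffold_seq=scaffold,
                      repeats=repeats)
    return model, ref


# ---------------------------------------------------------------------------
# clone simulation
# ---------------------------------------------------------------------------

def _spacing_ok(intervals, start, end, spacing):
    return all(start > e + spacing or end < s - spacing for s, e in intervals)


def _draw_events(ref: TranscriptRef, config: SimConfig, rng, n_events: int):
    """Draw ``n_events`` planted events for one clone, >= spacing apart and
    left-canonical; returns None when placement fails (caller retries)."""
    L = len(ref.cdna)
    cdna = ref.cdna
    weights = np.asarray(config.spectrum_weights, dtype=float)
    weights = weights / weights.sum()
    base_positions = {b: [i + 1 for i, c in enumerate(cdna) if c == b]
                      for b in _BASES}
    p_sub = 1.0 - config.p_insertion - config.p_deletion
    intervals = []
    drawn = []
    for _ in range(n_events):
        u = rng.random()
        kind = ("substitution" if u < p_sub
                else "insertion" if u < p_sub + config.p_insertion
                else "deletion")
        placed = False
        if kind == "substitution":
            # class first (so class fractions follow the weights), then a
            # position among bases of that class's source
            cls = SUBSTITUTION_CLASSES[int(rng.choice(12, p=weights))]
            src, dst = cls[0], cls[2]
        for _ in range(60):
            if kind == "substitution":
                candidates = base_positions[src]
                if not candidates:
                    break
                pos = candidates[int(rng.integers(0, len(candidates)))]
                if not _spacing_ok(intervals, pos, pos, config.min_event_spacing):
                    continue
                drawn.append(("substitution", pos, src, dst))
                intervals.append((pos, pos))
                placed = True
                break
            if kind == "insertion":
                if L < 4:
                    break
                pos = int(rng.integers(2, L - 1))       # anchor base, 2..L-2
                base = _BASES[int(rng.integers(0, 4))]
                if base == cdna[pos - 1]:               # left-shiftable: redraw
                    continue
                if not _spacing_ok(intervals, pos, pos + 1, config.min_event_spacing):
                    continue
                drawn.append(("insertion", pos, "", base))
                intervals.append((pos, pos + 1))
                placed = True
                break
            # deletion
            d = 1 if rng.random() < 0.75 else int(rng.integers(2, config.max_del_len + 1))
            if L - d < 3:
                break
            pos = int(rng.integers(2, L - d + 1))       # keep pos >= 2, end <= L
            if cdna[pos - 2] == cdna[pos + d - 2]:      # left-shiftable: redraw
                continue
            if not _spacing_ok(intervals, pos, pos + d - 1, config.min_event_spacing):
                continue
            drawn.append(("deletion", pos, cdna[pos - 1:pos + d - 1], ""))
            intervals.append((pos, pos + d - 1))
            placed = True
            break
        if not placed:
            return None
    return drawn


def simulate_clone_set(ref: TranscriptRef, tissue: str, config: SimConfig, rng,
                       individual: str | None = None, clone_offset: int = 0):
    """cDNA clones for one gene in one tissue plus their truth manifest.

    Per-clone event counts are Poisson with the tissue's configured rate
    (pheromone gland multiplied up); events are substitutions, single-base
    insertions and contiguous deletions per the configured probabilities.
    """
    lam = config.rate(tissue)
    clones = []
    manifest = TruthManifest()
    for k in range(config.clones_per_tissue):
        indiv = individual or f"F{(k % config.n_individuals) + 1}"
        clone_id = f"{ref.gene_id}-{tissue}-{clone_offset + k + 1}"
        n_events = int(rng.poisson(lam))
        drawn = None
        for _ in range(200):
            drawn = _draw_events(ref, config, rng, n_events)
            if drawn is not None:
                break
        if drawn is None:
            raise SimConfigError(
                f"cannot place {n_events} events >= {config.min_event_spacing} "
                f"bases apart on a {len(ref.cdna)}-base reference; lower the rate")
        events = [RDDEvent(clone_id=clone_id, gene_id=ref.gene_id, tissue=tissue,
                           individual=indiv, kind=kind, pos=pos,
                           ref_allele=ra, alt_allele=aa)
                  for kind, pos, ra, aa in drawn]
        seq = apply_events_to_cdna(ref, events)
        if config.error_rate > 0:
            seq = _apply_error_channel(seq, config.error_rate, rng)
        for ev in events:
            manifest.add(clone_id, ref.gene_id, ev.kind, ev.pos,
                         ev.ref_allele, ev.alt_allele)
        clones.append(CloneSequence(clone_id=clone_id, gene_id=ref.gene_id,
                                    tissue=tissue, individual=indiv,
                                    source="cDNA", seq=seq))
    return clones, manifest


def _apply_error_channel(seq: str, rate: float, rng) -> str:
    """Uniform substitution noise (not recorded in the manifest)."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = _BASES[int(rng.integers(0, 4))]
    return "".join(out)


def simulate_gdna_clones(ref: TranscriptRef, config: SimConfig):
    """Mutation-free gDNA clone set (the genomic template shows no variation)."""
    return [CloneSequence(clone_id=f"{ref.gene_id}-gDNA-{k + 1}",
                          gene_id=ref.gene_id, tissue="gDNA",
                          individual=f"F{(k % config.n_individuals) + 1}",
                          source="gDNA", seq=ref.cdna)
            for k in range(config.gdna_clones)]


@dataclass
class SimulatedDataset:
    genes: list          # (GeneModel, TranscriptRef) pairs
    clones: list         # CloneSequence, cDNA and gDNA
    manifest: TruthManifest
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full seeded dataset: genes, per-tissue cDNA clones, gDNA clones, truth."""
    rng = np.random.default_rng(config.seed)
    genes = [simulate_gene(config, rng, i) for i in range(config.n_genes)]
    clones = []
    manifest = TruthManifest()
    for _, ref in genes:
        for tissue, _lam in config.tissues:
            cset, m = simulate_clone_set(ref, tissue, config, rng)
            clones.extend(cset)
            manifest.extend(m)
        clones.extend(simulate_gdna_clones(ref, config))
    logger.info("simulated %d genes, %d clones, %d planted events",
                len(genes), len(clones), len(manifest))
    return SimulatedDataset(genes=genes, clones=clones, manifest=manifest,
                            config=config)


def draw_random_events(ref: TranscriptRef, config: SimConfig, rng,
                       n_events: int, clone_id: str = "clone",
                       tissue: str = "tissue", individual: str = "F1") -> list:
    """``n_events`` random planted events on ``ref`` as :class:`RDDEvent` s.

    Same placement rules as the clone simulator (spacing, left-canonical);
    raises :class:`SimConfigError` when placement is infeasible.
    """
    for _ in range(200):
        drawn = _draw_events(ref, config, rng, n_events)
        if drawn is not None:
            return [RDDEvent(clone_id=clone_id, gene_id=ref.gene_id,
                             tissue=tissue, individual=individual, kind=kind,
                             pos=pos, ref_allele=ra, alt_allele=aa)
                    for kind, pos, ra, aa in drawn]
    raise SimConfigError(f"cannot place {n_events} events on a "
                         f"{len(ref.cdna)}-base reference")


def manifest_to_events(manifest: TruthManifest, clones) -> list:
    """Planted truth as :class:`RDDEvent` s with tissue/individual labels."""
    meta = {c.clone_id: c for c in clones}
    events = []
    for e in manifest.events:
        c = meta[e["clone_id"]]
        events.append(RDDEvent(clone_id=e["clone_id"], gene_id=e["gene_id"],
                               tissue=c.tissue, individual=c.individual,
                               kind=e["kind"], pos=e["pos"],
                               ref_allele=e["ref_allele"],
                               alt_allele=e["alt_allele"]))
    return events


# ---------------------------------------------------------------------------
# engineered worked examples
# ---------------------------------------------------------------------------

_MOTIF_CODONS = {"D": "GAT", "K": "AAA", "I": "ATT", "P": "CCA", "Y": "TAT",
                 "V": "GTT", "C": "TGT", "L": "CTG", "G": "GGA", "H": "CAT"}


def engineer_motif_deletion(rng, native_len: int, del_start: int, del_end: int,
                            motif: str, orf_offset: int = 0,
                            gene_id: str = "toy") -> tuple:
    """Transcript with ``motif`` pinned at residues del_start..del_end plus the
    in-frame deletion event removing exactly those codons.

    Returns ``(TranscriptRef, (pos, deleted_bases))``.  The construction
    guarantees the deletion is left-canonical and that the residue following
    the motif differs from its first residue, so the first affected residue
    is ``del_start``.
    """
    if len(motif) != del_end - del_start + 1:
        raise ValueError("motif length must match the residue span")
    overrides = {del_start + i: _MOTIF_CODONS[aa] for i, aa in enumerate(motif)}
    for _ in range(1000):
        ref = make_coding_transcript(rng, native_len, orf_offset=orf_offset,
                                     utr3_len=20, codon_overrides=overrides,
                                     gene_id=gene_id)
        prot = ref.native_protein
        if del_end < native_len and prot[del_end] == motif[0]:
            continue                       # first-diff anchor would move right
        pos = orf_offset + 3 * (del_start - 1) + 1
        deleted = ref.cdna[pos - 1:pos - 1 + 3 * len(motif)]
        if ref.cdna[pos - 2] == deleted[-1]:
            continue                       # deletion could slide left
        return ref, (pos, deleted)
    raise RuntimeError("could not engineer motif deletion example")


def engineer_late_frameshift(rng, native_len: int = 111, shift_res: int = 87,
                             target_len: int = 129, orf_offset: int = 48,
                             gene_id: str = "toy") -> tuple:
    """Transcript where deleting the first base of a His codon at
    ``shift_res`` shifts the frame past the native stop, yielding a variant
    of exactly ``target_len`` residues.

    Returns ``(TranscriptRef, (pos, deleted_base))`` with pos the 1-based
    cDNA position of the deleted base.
    """
    if target_len <= native_len:
        raise ValueError("late frameshift must lengthen the protein")
    head_codons = _random_sense_codons(rng, shift_res - 1)
    head_codons[0] = "ATG"
    while head_codons[-1][-1] == "C":      # keep the C-deletion left-canonical
        head_codons[-1] = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
    extra = target_len - shift_res + 1     # shifted codons to read through
    tail_needed = 1 + 3 * extra + 3        # 'AT' + tail read in the new frame
    n_native_tail = native_len - shift_res # native codons after the His
    utr3 = max(tail_needed - (3 * n_native_tail + 3), 0) + 12
    for _ in range(200000):
        tail = "".join(_random_sense_codons(rng, n_native_tail)) + "TAA" \
            + _random_bases(rng, utr3)
        # variant frame: codon shift_res = 'AT' + tail[0], then tail[1:] in threes
        shifted = "AT" + tail
        ok = True
        for j in range(extra):
            codon = shifted[3 * j:3 * j + 3]
            if codon in STANDARD_TABLE.stop_codons:
                ok = False
                break
        stop_codon = shifted[3 * extra:3 * extra + 3]
        if not ok or stop_codon not in STANDARD_TABLE.stop_codons:
            continue
        coding = "".join(head_codons) + "CAT" + tail
        cdna = _random_bases(rng, orf_offset) + coding
        ref = TranscriptRef(gene_id=gene_id, cdna=cdna, orf_offset=orf_offset)
        if ref.native_len_aa != native_len:
            continue
        pos = orf_offset + 3 * (shift_res - 1) + 1
        return ref, (pos, "C")
    raise RuntimeError("could not engineer late-frameshift example")


def engineer_early_frameshift_insertion(rng, native_len: int = 111,
                                        shift_res: int = 90, base: str = "A",
                                        target_len: int = 102,
                                        orf_offset: int = 48,
                                        gene_id: str = "toy") -> tuple:
    """Transcript where inserting ``base`` after the second base of codon
    ``shift_res`` frameshifts to a premature stop at ``target_len`` + 1.

    Returns ``(TranscriptRef, (pos, inserted_base))``; pos is the anchor base
    (the base after which the insertion occurs).
    """
    if target_len >= native_len:
        raise ValueError("early frameshift must shorten the protein")
    extra = target_len - shift_res + 1
    for _ in range(200000):
        ref = make_coding_transcript(rng, native_len, orf_offset=orf_offset,
                                     utr3_len=20, codon_overrides={shift_res: "CCT"},
                                     gene_id=gene_id)
        pos = orf_offset + 3 * (shift_res - 1) + 2   # after codon's 2nd base
        if ref.cdna[pos - 1] == base:                # left-shiftable: redraw
            continue
        var = ref.cdna[:pos] + base + ref.cdna[pos:]
        # shifted frame from codon shift_res onward
        start = orf_offset + 3 * (shift_res - 1)
        ok = True
        for j in range(extra):
            codon = var[start + 3 * j:start + 3 * j + 3]
            if len(codon) < 3 or codon in STANDARD_TABLE.stop_codons:
                ok = False
                break
        stop = var[start + 3 * extra:start + 3 * extra + 3]
        if not ok or stop not in STANDARD_TABLE.stop_codons:
            continue
        return ref, (pos, base)
    raise RuntimeError("could not engineer early-frameshift example")


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(genes, clones, manifest: TruthManifest, out_dir,
                  config: SimConfig | None = None) -> dict:
    """Write FASTA/GFF3/TSV/JSON files; re-reading reproduces the inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [c.clone_id for c in clones]
    if len(set(ids)) != len(ids):
        raise ValueError("clone_id collision in dataset")
    if not clones:
        warnings.warn("writing an empty clone list", stacklevel=2)
        logger.warning("writing an empty clone list to %s", out)

    scaffolds = {m.scaffold_id: m.scaffold_seq for m, _ in genes}
    write_fasta(out / "scaffolds.fasta", scaffolds)
    write_gff3(out / "genes.gff3", [m for m, _ in genes])
    write_fasta(out / "transcripts.fasta",
                {r.gene_id: r.cdna for _, r in genes},
                {r.gene_id: f"orf_offset={r.orf_offset}" for _, r in genes})
    for source in ("cDNA", "gDNA"):
        subset = {c.clone_id: c.seq for c in clones if c.source == source}
        write_fasta(out / f"clones_{source.lower()}.fasta", subset)
    meta = pd.DataFrame(
        [(c.clone_id, c.gene_id, c.tissue, c.individual, c.source)
         for c in clones],
        columns=["clone_id", "gene_id", "tissue", "individual", "source"])
    meta.to_csv(out / "clones.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump({"events": manifest.events}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if config is not None:
        with open(out / "simconfig.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return {"dir": str(out), "n_clones": len(clones), "n_events": len(manifest)}


def read_dataset(in_dir):
    """Read a dataset directory back into (genes, clones, manifest)."""
    d = Path(in_dir)
    scaffolds = read_fasta(d / "scaffolds.fasta")
    models = read_gff3(d / "genes.gff3", scaffolds)
    from Bio import SeqIO
    refs = {}
    for rec in SeqIO.parse(str(d / "transcripts.fasta"), "fasta"):
        offset = 0
        for tok in rec.description.split():
            if tok.startswith("orf_offset="):
                offset = int(tok.split("=", 1)[1])
        refs[rec.id] = TranscriptRef(gene_id=rec.id, cdna=str(rec.seq).upper(),
                                     orf_offset=offset)
    genes = [(m, refs[m.gene_id]) for m in models]
    meta = pd.read_csv(d / "clones.tsv", sep="\t")
    seqs = {}
    for source in ("cdna", "gdna"):
        path = d / f"clones_{source}.fasta"
        if path.exists():
            seqs.update(read_fasta(path))
    clones = [CloneSequence(clone_id=row.clone_id, gene_id=row.gene_id,
                            tissue=row.tissue, individual=row.individual,
                            source=row.source, seq=seqs[row.clone_id])
              for row in meta.itertuples()]
    manifest = TruthManifest()
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            manifest.events = json.load(fh)["events"]
    return genes, clones, manifest
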