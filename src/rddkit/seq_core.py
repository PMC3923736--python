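"""Sequence primitives shared by every pipeline stage.

Gene models live on a genomic scaffold in 1-based inclusive coordinates;
the spliced transcript (the Sanger amplicon) carries an explicit reading
frame offset (``orf_offset``), because the cloned amplicons do not always
start at the initiator codon.  All positions reported downstream are
1-based on the amplicon; internal slicing is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight, seq3

logger = logging.getLogger("rddkit")

NUCLEOTIDES = frozenset("ACGT")

#: Water mass added once per peptide chain (average, Da).
WATER_DA = 18.0153


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise AlphabetError(f"{what} contains non-ACGT characters: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# codon table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonTable:
    """Standard genetic code: 64 codons, exactly 3 stops."""

    forward: dict
    stop_codons: frozenset

    @classmethod
    def standard(cls) -> "CodonTable":
        tab = _BioCodonTable.unambiguous_dna_by_id[1]
        return cls(forward=dict(tab.forward_table),
                   stop_codons=frozenset(tab.stop_codons))

    def aa(self, codon: str) -> str:
        """Amino acid for a codon, '*' for a stop codon."""
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]


STANDARD_TABLE = CodonTable.standard()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene on a genomic scaffold.

    ``exons`` are (start, end) 1-based inclusive scaffold positions, sorted
    and non-overlapping, given on the forward scaffold strand; for a minus
    strand gene the spliced transcript is reverse-complemented.
    ``repeats`` is decorative annotation (e.g. retroposon intervals).
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list
    scaffold_seq: str
    repeats: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"{self.gene_id}: bad exon ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if prev_end > len(self.scaffold_seq):
            raise IndexError(
                f"{self.gene_id}: exon end {prev_end} outside scaffold "
                f"of length {len(self.scaffold_seq)}")


@dataclass
class TranscriptRef:
    """The spliced coding reference (amplicon) for one gene.

    ``orf_offset`` counts the bases before the first base of codon 1;
    ``native_stop_base`` is the 1-based position of the first base of the
    native stop codon on the amplicon.
    """

    gene_id: str
    cdna: str
    orf_offset: int
    native_protein: str = ""
    native_len_aa: int = 0
    native_stop_base: int = 0

    def __post_init__(self):
        _check_alphabet(self.cdna, f"{self.gene_id} cdna")
        if self.orf_offset < 0:
            raise ValueError("orf_offset must be >= 0")
        if len(self.cdna) < self.orf_offset + 3:
            raise ValueError("cdna too short for the stated orf_offset")
        protein, stop_found = translate_orf(self.cdna, self.orf_offset)
        if not stop_found:
            raise ValueError(f"{self.gene_id}: no stop codon in frame")
        if self.native_protein and self.native_protein != protein:
            raise ValueError(f"{self.gene_id}: native_protein does not match "
                             "translation of cdna")
        self.native_protein = protein
        self.native_len_aa = len(protein)
        self.native_stop_base = self.orf_offset + 3 * len(protein) + 1


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def splice_transcript(model: GeneModel) -> str:
    """Concatenate exon subsequences in transcript order.

    Minus-strand genes are reverse-complemented after concatenation, so the
    result is always the coding strand 5'->3'.
    """
    parts = [model.scaffold_seq[start - 1:end] for start, end in model.exons]
    spliced = "".join(parts)
    if model.strand == "-":
        spliced = reverse_complement(spliced)
    return spliced


def translate_orf(seq: str, offset: int, table: CodonTable = STANDARD_TABLE):
    """Translate consecutive codons from ``offset`` up to the first stop.

    Returns ``(protein, stop_found)``.  A trailing partial codon is ignored;
    ``stop_found`` is True iff a stop codon was actually reached.
    """
    _check_alphabet(seq)
    if offset >= len(seq):
        raise ValueError(f"offset {offset} not inside sequence of length {len(seq)}")
    residues = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in table.stop_codons:
            return "".join(residues), True
        residues.append(table.forward[codon])
    return "".join(residues), False


_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


def protein_mass(protein: str) -> float:
    """Average molecular mass of a peptide in Da (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - _AA20
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    return molecular_weight(protein, seq_type="protein", monoisotopic=False)


def protein_mass_kda(protein: str) -> float:
    """Mass in kDa rounded to 2 decimals, as printed in variant tables."""
    return round(protein_mass(protein) / 1000.0, 2)


def aa3(residue: str) -> str:
    """Three-letter residue code ('H' -> 'His', '*' -> 'Ter')."""
    return seq3(residue)


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records, descriptions=None) -> None:
    """Write {id: sequence} (plus optional {id: description}) as FASTA."""
    descriptions = descriptions or {}
    recs = [SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
            for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_gff3(path, models) -> None:
    """Write gene models (gene + exon features, 1-based inclusive) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            span = (model.exons[0][0], model.exons[-1][1])
            fh.write("\t".join([
                model.scaffold_id, "rddkit", "gene", str(span[0]), str(span[1]),
                ".", model.strand, ".", f"ID={model.gene_id}"]) + "\n")
            for k, (start, end) in enumerate(model.exons, 1):
                fh.write("\t".join([
                    model.scaffold_id, "rddkit", "exon", str(start), str(end),
                    ".", model.strand, ".",
                    f"ID={model.gene_id}.exon{k};Parent={model.gene_id}"]) + "\n")
            for label, (start, end) in model.repeats:
                fh.write("\t".join([
                    model.scaffold_id, "rddkit", "repeat_region",
                    str(start), str(end), ".", model.strand, ".",
                    f"ID={model.gene_id}.{label};Parent={model.gene_id}"]) + "\n")


def read_gff3(path, scaffolds) -> list:
    """Read gene models back from GFF3 given {scaffold_id: sequence}."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        repeats = []
        for child in db.children(gene, order_by="start"):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "repeat_region":
                label = child.id.split(".", 1)[-1]
                repeats.append((label, (child.start, child.end)))
        models.append(GeneModel(
            gene_id=gene.id, scaffold_id=gene.seqid, strand=gene.strand,
            exons=sorted(exons), scaffold_seq=scaffolds[gene.seqid],
            repeats=repeats))
    return models
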