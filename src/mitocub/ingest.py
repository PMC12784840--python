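"""GenBank mitogenome ingestion: parsing, CDS extraction, codonization.

Protein-coding genes are cut from the annotated genome, minus-strand genes
are reverse-complemented to sense orientation, complete (TAA/TAG) or
incomplete (T / TA, completed by polyadenylation in vivo) stop codons are
trimmed and recorded, and the remaining sequence is split into codons under
the invertebrate mitochondrial code.  The annotation is trusted: no
re-annotation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import TABLE5, STOP, CodonTable5, UntranslatableCodonError

log = logging.getLogger(__name__)

#: Canonical labels of the 13 metazoan mitochondrial protein-coding genes.
CANONICAL_PCGS = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

# GenBank /gene and /product labelling varies wildly between submitters.
_GENE_SYNONYMS = {
    "coi": "cox1", "co1": "cox1", "cox1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "cox2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "cox3": "cox3", "coxiii": "cox3",
    "cytb": "cytb", "cob": "cytb", "cytochromeb": "cytb", "cyb": "cytb",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "nd1": "nad1", "nad1": "nad1", "nd2": "nad2", "nad2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nd4": "nad4", "nad4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L",
    "nd5": "nad5", "nad5": "nad5", "nd6": "nad6", "nad6": "nad6",
}


class GenBankParseError(ValueError):
    """The file is not a readable single-record GenBank flat file."""


class NoCDSError(ValueError):
    """Record carries no protein-coding genes."""


class FrameError(ValueError):
    """CDS length after stop trimming is not a multiple of three."""


class InternalStopError(ValueError):
    """A stop codon occurs before the annotated end of a CDS."""


class UnknownGeneError(ValueError):
    """A CDS gene label cannot be mapped to a canonical PCG name."""


@dataclass(frozen=True)
class Feature:
    """One annotated feature; coordinates are GenBank 1-based inclusive.

    ``segments`` lists (start, end) pairs in transcription order so that a
    single feature wrapping the circular origin can be represented as two
    segments.
    """

    kind: str                      # CDS | tRNA | rRNA | D-loop
    segments: tuple                # ((start_1based, end_1based), ...)
    strand: int                    # +1 / -1
    gene: str
    codon_start: int = 1

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def span(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)


@dataclass(frozen=True)
class GenomeRecord:
    accession: str
    organism: str
    sequence: str                  # uppercase A/C/G/T (ambiguity preserved)
    features: tuple = ()

    def __post_init__(self):
        if not self.sequence:
            raise GenBankParseError("empty genome sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.segments:
                if not (1 <= s <= e <= n):
                    raise GenBankParseError(
                        f"feature {f.gene!r} interval {s}..{e} outside 1..{n}"
                    )

    def count(self, kind: str) -> int:
        return sum(1 for f in self.features if f.kind == kind)

    @property
    def gc_fraction(self) -> float:
        gc = sum(self.sequence.count(b) for b in "GC")
        return gc / len(self.sequence)

    @property
    def at_fraction(self) -> float:
        at = sum(self.sequence.count(b) for b in "AT")
        return at / len(self.sequence)


@dataclass(frozen=True)
class GeneSequence:
    """One extracted protein-coding gene, sense strand, stop removed."""

    gene_name: str
    species: str
    strand: int
    codons: tuple                  # trinucleotides, start codon included
    start_codon: str
    stop_note: str                 # complete_TAA | complete_TAG | incomplete_T | incomplete_TA
    cds_span: int = 0              # annotated span in bp (for frame audit)

    def __post_init__(self):
        if not self.codons:
            raise ValueError(f"{self.gene_name}: empty codon list")
        for c in self.codons:
            if len(c) != 3 or any(b not in "ACGT" for b in c):
                raise ValueError(f"{self.gene_name}: malformed codon {c!r}")

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


def normalize_gene_name(label: str) -> str:
    key = label.replace("-", "").replace("_", "").replace(" ", "").lower()
    try:
        return _GENE_SYNONYMS[key]
    except KeyError:
        raise UnknownGeneError(f"cannot map gene label {label!r} to a canonical PCG name") from None


def parse_genbank(path) -> GenomeRecord:
    """Parse a single-record GenBank flat file into a :class:`GenomeRecord`.

    CDS, tRNA, rRNA and D-loop/control-region features are retained with
    their strands, labels and ``codon_start`` qualifiers; coordinates are
    kept 1-based inclusive exactly as annotated.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad syntax
        raise GenBankParseError(f"{path}: not a valid single-record GenBank file: {exc}") from exc

    feats = []
    for f in record.features:
        if f.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        gene = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("product", [None])[0]
            or f.type
        )
        codon_start = int(f.qualifiers.get("codon_start", ["1"])[0])
        segments = tuple(
            sorted(
                ((int(part.start) + 1, int(part.end)) for part in f.location.parts),
                key=lambda se: se[0],
            )
        )
        strand = -1 if f.location.strand == -1 else 1
        feats.append(Feature(f.type, segments, strand, gene, codon_start))

    if not any(f.kind == "CDS" for f in feats):
        raise NoCDSError(f"{path}: no protein-coding genes in record")

    return GenomeRecord(
        accession=record.id or record.name,
        organism=record.annotations.get("organism", record.description),
        sequence=str(record.seq).upper(),
        features=tuple(feats),
    )


def translate_codon(codon: str, code: CodonTable5 = TABLE5) -> str:
    """Table-5 translation of one codon; stops return ``"*"``."""
    return code.translate(codon)


def _raw_cds(record: GenomeRecord, feat: Feature) -> str:
    parts = [record.sequence[s - 1:e] for s, e in feat.segments]
    seq = "".join(parts)
    if feat.strand == -1:
        seq = str(Seq(seq).reverse_complement())
    if feat.codon_start > 1:
        seq = seq[feat.codon_start - 1:]
    return seq


def codonize_cds(seq: str, gene: str, code: CodonTable5 = TABLE5):
    """Split a sense-strand CDS into codons, trimming the stop suffix.

    Returns (codons, stop_note).  A trailing TAA/TAG is a complete stop; a
    trailing single T or TA over a frame remainder is an incomplete stop
    completed by polyadenylation and is treated like a complete one.
    """
    rem = len(seq) % 3
    if rem == 0 and len(seq) >= 3 and seq[-3:] in code.stop_codons:
        body, note = seq[:-3], f"complete_{seq[-3:]}"
    elif rem == 1 and seq.endswith("T"):
        body, note = seq[:-1], "incomplete_T"
    elif rem == 2 and seq.endswith("TA"):
        body, note = seq[:-2], "incomplete_TA"
    else:
        body, note = seq, None

    if len(body) % 3 != 0:
        raise FrameError(f"{gene}: CDS length {len(seq)} has no complete or T/TA stop suffix")
    if note is None:
        # annotated CDS with neither a stop nor a partial stop; tolerated but logged
        log.warning("%s: CDS carries no stop suffix; treating span as coding", gene)
        note = "none"

    codons = tuple(body[i:i + 3] for i in range(0, len(body), 3))
    for i, c in enumerate(codons):
        if any(b not in "ACGT" for b in c):
            raise UntranslatableCodonError(c)
        if code.translate(c) == STOP:
            raise InternalStopError(f"{gene}: internal stop codon {c} at codon index {i}")
    return codons, note


def extract_pcgs(record: GenomeRecord, code: CodonTable5 = TABLE5,
                 drop_ambiguous: bool = True):
    """Extract all annotated CDS as :class:`GeneSequence` objects.

    Genes containing non-ACGT bases are dropped with a logged warning when
    ``drop_ambiguous`` (deterministic statistics over guessed bases).
    """
    genes = []
    for feat in record.features:
        if feat.kind != "CDS":
            continue
        name = normalize_gene_name(feat.gene)
        raw = _raw_cds(record, feat)
        try:
            codons, note = codonize_cds(raw, name, code)
        except UntranslatableCodonError as exc:
            if drop_ambiguous:
                log.warning("%s/%s: dropped (ambiguous base in codon %s)",
                            record.organism, name, exc.codon)
                continue
            raise
        genes.append(GeneSequence(
            gene_name=name,
            species=record.organism,
            strand=feat.strand,
            codons=codons,
            start_codon=codons[0],
            stop_note=note,
            cds_span=feat.span,
        ))
    if not genes:
        raise NoCDSError(f"{record.accession}: no usable protein-coding genes")
    return genes


def write_gene_fasta(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.species.replace(' ', '_')}|{g.gene_name}\n{g.sequence}\n")


def write_gene_inventory(genes, path) -> None:
    """TSV inventory: species, gene, strand, length (codons), start, stop note."""
    with open(path, "w") as fh:
        fh.write("species\tgene\tstrand\tn_codons\tstart_codon\tstop_note\n")
        for g in genes:
            fh.write(f"{g.species}\t{g.gene_name}\t{'+' if g.strand == 1 else '-'}\t"
                     f"{len(g.codons)}\t{g.start_codon}\t{g.stop_note}\n")
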