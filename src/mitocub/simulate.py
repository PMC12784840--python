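"""Synthetic AT-rich circular mitogenomes with controlled codon usage.

The generator emulates the features of invertebrate (arachnid-style)
mitochondrial genomes that the analysis stages depend on: a single circular
record carrying 13 protein-coding CDS on both strands, translation-table-5
coding, atypical start codons (ATT/ATA/TTG), incomplete stop codons (a
trailing T or TA completed by polyadenylation), and A+T-rich composition.

Codons are drawn i.i.d.: an amino acid from a composition vector, then a
codon within the synonymous family with weight proportional to ``theta``
for G/C-ending codons and ``1 - theta`` for A/T-ending codons.  Because
every table-5 family contains equally many G/C- and A/T-ending codons, the
implied GC3s of the model is exactly ``theta``, which makes parameter
recovery testable in closed form.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetic_code import TABLE5, CodonTable5
from .ingest import GeneSequence

#: Amino-acid composition mimicking AT-rich arthropod mitochondria
#: (elevated Leu/Ile/Phe/Ser/Met).
DEFAULT_AA_COMPOSITION = {
    "L": 0.15, "I": 0.10, "F": 0.09, "S": 0.11, "M": 0.06,
    "N": 0.05, "T": 0.05, "G": 0.06, "V": 0.05, "A": 0.04,
    "K": 0.04, "Y": 0.04, "W": 0.02, "P": 0.03, "H": 0.02,
    "Q": 0.02, "E": 0.02, "D": 0.02, "R": 0.02, "C": 0.01,
}

#: Default GC3 bias; chosen to sit in the GC3s range typical of arachnid
#: mitochondrial protein-coding genes.
DEFAULT_THETA = 0.265

#: Typical gene lengths (codons), strands and termination for a 13-PCG
#: arachnid-like mitogenome; nad1/nad4/nad4L/nad5 ride the minus strand and
#: cox2/nad4 end in incomplete stops.
DEFAULT_GENE_PLAN = (
    ("cox1",  512, +1, "ATT", "TAA"),
    ("cox2",  227, +1, "ATG", "T"),
    ("atp8",   52, +1, "ATT", "TAA"),
    ("atp6",  220, +1, "ATG", "TAA"),
    ("cox3",  263, +1, "ATG", "TAG"),
    ("nad3",  113, +1, "ATA", "TAA"),
    ("nad5",  551, -1, "ATT", "TAA"),
    ("nad4",  437, -1, "ATG", "TA"),
    ("nad4L",  91, -1, "ATA", "TAA"),
    ("nad6",  144, +1, "ATT", "TAA"),
    ("cytb",  370, +1, "TTG", "TAG"),
    ("nad1",  307, -1, "TTG", "TAA"),
    ("nad2",  320, +1, "ATA", "TAA"),
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SpecError(ValueError):
    """Invalid synthetic-genome specification."""


@dataclass(frozen=True)
class GeneSpec:
    name: str
    length: int                    # codons, start included, stop excluded
    strand: int
    start_codon: str = "ATG"
    stop: str = "TAA"              # TAA | TAG | T | TA

    def __post_init__(self):
        if self.length < 10:
            raise SpecError(f"{self.name}: gene length must be >= 10 codons")
        if self.start_codon not in {"ATG", "ATT", "ATA", "TTG", "GTG"}:
            raise SpecError(f"{self.name}: invalid start codon {self.start_codon}")
        if self.stop not in {"TAA", "TAG", "T", "TA"}:
            raise SpecError(f"{self.name}: invalid stop variant {self.stop}")
        if self.strand not in (1, -1):
            raise SpecError(f"{self.name}: strand must be +1/-1")

    @property
    def stop_note(self) -> str:
        return f"complete_{self.stop}" if len(self.stop) == 3 else f"incomplete_{self.stop}"


@dataclass(frozen=True)
class SyntheticSpec:
    species: str
    genes: tuple = tuple(GeneSpec(n, l, s, st, sp) for n, l, s, st, sp in DEFAULT_GENE_PLAN)
    aa_composition: dict = field(default_factory=lambda: dict(DEFAULT_AA_COMPOSITION))
    theta: float = DEFAULT_THETA
    family_weights: dict | None = None   # aa -> {codon: weight}; overrides theta
    seed: int = 0

    def __post_init__(self):
        tot = sum(self.aa_composition.values())
        if abs(tot - 1.0) > 1e-9:
            raise SpecError(f"amino-acid composition sums to {tot}, not 1")
        if not 0.0 < self.theta < 1.0:
            raise SpecError(f"theta must lie in (0, 1), got {self.theta}")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic quantities implied by a spec's weight model."""

    species: str
    codon_probs: dict              # sense codon -> emission probability
    implied_rscu: dict             # analyzed codon -> RSCU implied by weights
    implied_gc3s: float
    gene_tallies: dict = field(default_factory=dict)  # gene -> {codon: count}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "species": self.species,
                "codon_probs": self.codon_probs,
                "implied_rscu": self.implied_rscu,
                "implied_gc3s": self.implied_gc3s,
                "gene_tallies": self.gene_tallies,
            }, fh, indent=1)


def family_codon_weights(spec: SyntheticSpec, code: CodonTable5 = TABLE5) -> dict:
    """Normalized within-family codon weights for every amino acid."""
    out = {}
    for aa, fam in code.families.items():
        fam = sorted(fam)
        if spec.family_weights and aa in spec.family_weights:
            w = np.array([spec.family_weights[aa].get(c, 0.0) for c in fam], float)
        else:
            w = np.array([spec.theta if c[2] in "GC" else 1.0 - spec.theta for c in fam])
        if w.sum() <= 0:
            raise SpecError(f"all-zero codon weights in family {aa}")
        out[aa] = dict(zip(fam, w / w.sum()))
    return out


def ground_truth_stats(spec: SyntheticSpec, code: CodonTable5 = TABLE5) -> GroundTruth:
    """RSCU and GC3s implied analytically by the weight model."""
    weights = family_codon_weights(spec, code)
    probs = {}
    for aa, p_aa in spec.aa_composition.items():
        for c, w in weights[aa].items():
            probs[c] = p_aa * w

    implied_rscu = {}
    for aa, fam in code.synonymous_families.items():
        for c in sorted(fam):
            implied_rscu[c] = len(fam) * weights[aa][c]

    syn_mass = gc3_mass = 0.0
    for aa in code.synonymous_families:
        p_aa = spec.aa_composition.get(aa, 0.0)
        syn_mass += p_aa
        gc3_mass += p_aa * sum(w for c, w in weights[aa].items() if c[2] in "GC")
    return GroundTruth(
        species=spec.species,
        codon_probs=probs,
        implied_rscu=implied_rscu,
        implied_gc3s=gc3_mass / syn_mass if syn_mass else float("nan"),
    )


def sample_gene(gene: GeneSpec, spec: SyntheticSpec, rng: np.random.Generator,
                code: CodonTable5 = TABLE5):
    """Draw one gene; returns (GeneSequence, codon tally).

    The start codon is placed verbatim; the remaining ``length - 1`` codons
    are i.i.d. amino-acid-then-codon draws.  No stop can be emitted in frame
    because stops belong to no family.
    """
    weights = family_codon_weights(spec, code)
    aas = sorted(spec.aa_composition)
    p_aa = np.array([spec.aa_composition[a] for a in aas])

    aa_draws = rng.choice(len(aas), size=gene.length - 1, p=p_aa)
    body = np.empty(gene.length - 1, dtype=object)
    for idx in np.unique(aa_draws):
        fam = weights[aas[idx]]
        cs = list(fam)
        w = np.array([fam[c] for c in cs])
        mask = aa_draws == idx
        picks = rng.choice(len(cs), size=int(mask.sum()), p=w)
        body[mask] = [cs[i] for i in picks]
    codons = [gene.start_codon, *body.tolist()]

    tally: dict = {}
    for c in codons:
        tally[c] = tally.get(c, 0) + 1
    gs = GeneSequence(
        gene_name=gene.name, species=spec.species, strand=gene.strand,
        codons=tuple(codons), start_codon=gene.start_codon,
        stop_note=gene.stop_note,
        cds_span=3 * gene.length + len(gene.stop),
    )
    return gs, tally


def sample_mutational_gene(name: str, length: int, theta: float,
                           rng: np.random.Generator,
                           code: CodonTable5 = TABLE5,
                           species: str = "mutation-model") -> GeneSequence:
    """Gene under a pure mutation-pressure model: codons i.i.d. over all
    sense codons with weight ``prod(theta if base in GC else 1-theta)`` over
    the three positions.  All positions then share the same GC pressure, the
    regime where a neutrality slope near 1 is expected."""
    sense = list(code.sense_codons)
    w = np.array([
        np.prod([theta if b in "GC" else 1.0 - theta for b in c]) for c in sense
    ])
    w /= w.sum()
    draws = rng.choice(len(sense), size=length, p=w)
    return GeneSequence(
        gene_name=name, species=species, strand=1,
        codons=tuple(sense[i] for i in draws),
        start_codon=sense[draws[0]], stop_note="complete_TAA",
        cds_span=3 * length + 3,
    )


def _genbank_lines(accession: str, organism: str, seq: str, features) -> str:
    n = len(seq)
    lines = [
        f"LOCUS       {accession:<16}{n:>12} bp    DNA     circular INV 01-JAN-2026",
        f"DEFINITION  {organism} mitochondrion, complete genome (synthetic).",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
        f"SOURCE      {organism}",
        f"  ORGANISM  {organism}",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{n}",
        f"                     /organism=\"{organism}\"",
        "                     /mol_type=\"genomic DNA\"",
    ]
    for name, start, end, strand in features:
        loc = f"{start}..{end}" if strand == 1 else f"complement({start}..{end})"
        lines += [
            f"     CDS             {loc}",
            f"                     /gene=\"{name}\"",
            "                     /codon_start=1",
            "                     /transl_table=5",
        ]
    lines.append("ORIGIN")
    low = seq.lower()
    for i in range(0, n, 60):
        chunk = low[i:i + 60]
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def synthesize_genome(spec: SyntheticSpec, out_path=None, code: CodonTable5 = TABLE5):
    """Emit one circular GenBank record plus its ground truth.

    Returns (genbank text, GroundTruth).  Genes are laid out in spec order
    separated by short random A/T spacers; minus-strand genes are stored
    reverse-complemented in the genome with ``complement(..)`` locations, so
    parsing + extraction round-trips the emitted codon lists exactly.
    """
    rng = np.random.default_rng(spec.seed)
    truth = ground_truth_stats(spec, code)
    tallies = {}

    chunks = []
    features = []
    pos = 0  # 0-based running genome length

    def spacer():
        nonlocal pos
        k = int(rng.integers(5, 30))
        s = "".join("AT"[i] for i in rng.integers(0, 2, size=k))
        chunks.append(s)
        pos += k

    spacer()
    for gene in spec.genes:
        gs, tally = sample_gene(gene, spec, rng, code)
        tallies[gene.name] = tally
        dna = gs.sequence + gene.stop
        if gene.strand == -1:
            dna = _revcomp(dna)
        start = pos + 1
        end = pos + len(dna)
        features.append((gene.name, start, end, gene.strand))
        chunks.append(dna)
        pos = end
        spacer()

    seq = "".join(chunks)
    accession = f"SYN{zlib.crc32(spec.species.encode()) % 10 ** 6:06d}"
    text = _genbank_lines(accession, spec.species, seq, features)
    truth = GroundTruth(truth.species, truth.codon_probs, truth.implied_rscu,
                        truth.implied_gc3s, tallies)
    if out_path is not None:
        Path(out_path).write_text(text)
        truth.to_json(str(out_path) + ".truth.json")
    return text, truth


def default_cohort(n_species: int = 7, seed: int = 0, thetas=None):
    """Specs for a cohort of synthetic species with distinct GC3 biases,
    spanning the low-GC3s band seen in AT-rich mitogenomes."""
    if thetas is None:
        thetas = np.linspace(0.18, 0.42, n_species)
    if len(thetas) != n_species:
        raise SpecError("need one theta per species")
    return [
        SyntheticSpec(
            species=f"Synthospila species{chr(ord('A') + i)}",
            theta=float(t),
            seed=seed + 1000 * (i + 1),
        )
        for i, t in enumerate(thetas)
    ]
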