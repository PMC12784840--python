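"""Codon counting, RSCU, and positional nucleotide composition.

RSCU (relative synonymous codon usage) for codon *c* in a synonymous family
*F* with *n(F)* members and total family count *N(F)*:

    RSCU(c) = count(c) * n(F) / N(F)

so RSCU = 1 means the codon is used exactly as often as expected under
uniform synonymous usage.  Stop codons never enter the counts; Met and Trp
codons are tallied but carry no RSCU (their amino acids are excluded from
synonymous-site statistics by convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genetic_code import TABLE5, CodonTable5, EXCLUDED_AA

#: RSCU preference classes and their thresholds: a codon is strongly
#: preferred above 1.6, rarely used below 0.6, neutral in between
#: (boundaries inclusive on the neutral side).
RSCU_PREFERRED = 1.6
RSCU_RARE = 0.6

FOURFOLD_AA = frozenset({"V", "P", "T", "A", "G", "R"})


@dataclass(frozen=True)
class CodonCounts:
    """Codon tally for one unit (a gene, or a species' concatenated PCGs)."""

    label: str
    counts: dict
    total: int

    def __post_init__(self):
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not match count map")


@dataclass(frozen=True)
class RSCUProfile:
    """RSCU values and preference classes; codons of absent families are
    missing (``None``), which is distinct from RSCU = 0 in a present family."""

    label: str
    rscu: dict          # codon -> float | None
    classes: dict       # codon -> preferred | neutral | rare | undefined


@dataclass(frozen=True)
class CompositionStats:
    """Positional GC content and synonymous third-position base counts.

    GC1/GC2/GC3 run over every retained codon (start codon included, stops
    already removed upstream).  GC3s and the A3s/T3s/G3s/C3s tallies run
    only over codons of synonymously variable amino acids (Met/Trp
    excluded).  Fourfold-restricted third-position tallies are carried for
    parity-rule analysis.
    """

    label: str
    gc1: float
    gc2: float
    gc3: float
    gc3s: float | None
    a3s: int
    t3s: int
    g3s: int
    c3s: int
    ff_a3: int = 0
    ff_t3: int = 0
    ff_g3: int = 0
    ff_c3: int = 0
    at_fraction: float = 0.0
    n_codons: int = 0

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def count_codons(genes, scope: str = "per_gene", code: CodonTable5 = TABLE5):
    """Tally codons per gene or pooled over each species.

    Parameters
    ----------
    genes : list of GeneSequence
    scope : {"per_gene", "per_species_concatenated"}

    Stop codons cannot occur (extraction removes them), so every tallied
    codon is a sense codon.
    """
    if not genes:
        raise ValueError("empty gene list")
    if scope == "per_gene":
        units = [(f"{g.species}|{g.gene_name}", [g]) for g in genes]
    elif scope == "per_species_concatenated":
        by_species: dict = {}
        for g in genes:
            by_species.setdefault(g.species, []).append(g)
        units = list(by_species.items())
    else:
        raise ValueError(f"unknown scope {scope!r}")

    out = []
    for label, gs in units:
        tally: dict = {}
        for g in gs:
            for c in g.codons:
                tally[c] = tally.get(c, 0) + 1
        out.append(CodonCounts(label=label, counts=tally, total=sum(tally.values())))
    return out


def classify_rscu(rscu: float) -> str:
    """Three-class preference scheme; 0.6 and 1.6 are themselves neutral."""
    if rscu < 0:
        raise ValueError(f"RSCU cannot be negative: {rscu}")
    if rscu > RSCU_PREFERRED:
        return "preferred"
    if rscu < RSCU_RARE:
        return "rare"
    return "neutral"


def compute_rscu(counts: CodonCounts, code: CodonTable5 = TABLE5) -> RSCUProfile:
    """RSCU per analyzed codon; families with zero observations are missing."""
    rscu: dict = {}
    classes: dict = {}
    for aa, family in code.synonymous_families.items():
        n_f = len(family)
        total = sum(counts.counts.get(c, 0) for c in family)
        for c in sorted(family):
            if total == 0:
                rscu[c] = None
                classes[c] = "undefined"
            else:
                val = counts.counts.get(c, 0) * n_f / total
                rscu[c] = val
                classes[c] = classify_rscu(val)
    return RSCUProfile(label=counts.label, rscu=rscu, classes=classes)


def positional_composition(gene, code: CodonTable5 = TABLE5) -> CompositionStats:
    """GC by codon position plus synonymous third-position base tallies.

    ``gc3s`` is ``None`` (undefined, never silently 0) when the gene holds
    only Met/Trp codons.
    """
    codons = gene.codons
    if not codons:
        raise ValueError(f"{gene.gene_name}: no codons")

    n = len(codons)
    gc_pos = [0, 0, 0]
    at_total = 0
    for c in codons:
        for i, b in enumerate(c):
            if b in "GC":
                gc_pos[i] += 1
            else:
                at_total += 1

    syn = {"A": 0, "T": 0, "G": 0, "C": 0}
    ff = {"A": 0, "T": 0, "G": 0, "C": 0}
    n_syn = 0
    for c in codons:
        aa = code.translate(c)
        if aa in code.synonymous_families:
            syn[c[2]] += 1
            n_syn += 1
            if aa in FOURFOLD_AA:
                ff[c[2]] += 1

    gc3s = (syn["G"] + syn["C"]) / n_syn if n_syn else None

    return CompositionStats(
        label=f"{gene.species}|{gene.gene_name}",
        gc1=gc_pos[0] / n,
        gc2=gc_pos[1] / n,
        gc3=gc_pos[2] / n,
        gc3s=gc3s,
        a3s=syn["A"], t3s=syn["T"], g3s=syn["G"], c3s=syn["C"],
        ff_a3=ff["A"], ff_t3=ff["T"], ff_g3=ff["G"], ff_c3=ff["C"],
        at_fraction=at_total / (3 * n),
        n_codons=n,
    )


def write_rscu_table(profiles, counts_by_label, path, code: CodonTable5 = TABLE5) -> None:
    """Long-format TSV: unit, codon, amino acid, count, RSCU, class."""
    with open(path, "w") as fh:
        fh.write("unit\tcodon\tamino_acid\tcount\trscu\tclass\n")
        for p in profiles:
            cc = counts_by_label[p.label]
            for codon in sorted(p.rscu, key=lambda c: (code.forward[c], c)):
                val = p.rscu[codon]
                fh.write(f"{p.label}\t{codon}\t{code.forward[codon]}\t"
                         f"{cc.counts.get(codon, 0)}\t"
                         f"{'' if val is None else f'{val:.6f}'}\t{p.classes[codon]}\n")


def write_composition_table(stats, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tn_codons\tGC1\tGC2\tGC12\tGC3\tGC3s\t"
                 "A3s\tT3s\tG3s\tC3s\tAT\n")
        for s in stats:
            gc3s = "" if s.gc3s is None else f"{s.gc3s:.6f}"
            fh.write(f"{s.label}\t{s.n_codons}\t{s.gc1:.6f}\t{s.gc2:.6f}\t"
                     f"{s.gc12:.6f}\t{s.gc3:.6f}\t{gc3s}\t"
                     f"{s.a3s}\t{s.t3s}\t{s.g3s}\t{s.c3s}\t{s.at_fraction:.6f}\n")
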