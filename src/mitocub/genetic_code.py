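"""The invertebrate mitochondrial genetic code (NCBI translation table 5).

Relative to the standard code, table 5 reassigns AGA/AGG from Arg to Ser,
ATA from Ile to Met, and TGA from stop to Trp.  The consequences that matter
for codon-usage statistics:

* Ile is two-fold degenerate (ATT/ATC only);
* Ser is one eight-fold family (TCN plus AGT/AGC/AGA/AGG);
* Arg is the four-fold CGN family;
* Met (ATA/ATG) and Trp (TGA/TGG) each have two codons, but by the analysis
  convention used here they are excluded from every synonymous-site
  statistic, mirroring how most mitochondrial codon-bias studies treat them;
* only TAA and TAG remain as stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable as _BioCodonTable

BASES = "ACGT"
ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))

#: Amino acids whose codons never enter synonymous-site statistics.
EXCLUDED_AA = frozenset({"M", "W"})

STOP = "*"


@dataclass(frozen=True)
class CodonTable5:
    """Immutable view of translation table 5 plus derived family structure.

    Attributes
    ----------
    forward : dict
        codon -> one-letter amino acid; stop codons map to ``"*"``.
    families : dict
        amino acid -> frozenset of codons, for every amino acid *including*
        Met and Trp (callers consult :attr:`synonymous_families` for the
        statistics-eligible subset).
    synonymous_families : dict
        Same, restricted to amino acids with >=2 codons and not in
        :data:`EXCLUDED_AA`.
    stop_codons : frozenset
        {TAA, TAG}.
    start_codons : frozenset
        Starts permitted when validating annotated CDS.
    """

    forward: dict = field(default_factory=dict)
    families: dict = field(default_factory=dict)
    synonymous_families: dict = field(default_factory=dict)
    stop_codons: frozenset = frozenset()
    start_codons: frozenset = frozenset()

    def translate(self, codon: str) -> str:
        """Translate one codon; returns ``"*"`` for TAA/TAG.

        Raises
        ------
        UntranslatableCodonError
            If the codon contains a non-ACGT character (ambiguity codes are
            never guessed).
        """
        codon = codon.upper()
        try:
            return self.forward[codon]
        except KeyError:
            raise UntranslatableCodonError(codon) from None

    def family_of(self, codon: str):
        """Return (amino acid, synonymous family set) or (aa, None) if the
        codon's amino acid is excluded from synonymous statistics."""
        aa = self.translate(codon)
        if aa == STOP:
            return aa, None
        return aa, self.synonymous_families.get(aa)

    def is_synonymous_site_codon(self, codon: str) -> bool:
        """True if the codon contributes to GC3s / A3s / ENC statistics."""
        aa = self.translate(codon)
        return aa in self.synonymous_families

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in ALL_CODONS if self.forward[c] != STOP)

    @property
    def analyzed_codons(self) -> tuple:
        """The codons carried in RSCU tables: sense codons minus Met/Trp."""
        return tuple(
            c for c in ALL_CODONS
            if self.forward[c] != STOP and self.forward[c] not in EXCLUDED_AA
        )

    def degeneracy_classes(self) -> dict:
        """Map family size k -> list of amino acids with that degeneracy.

        Under table 5 with Met/Trp excluded: ten 2-fold, six 4-fold, one
        6-fold (Leu) and one 8-fold (Ser) amino acids.
        """
        out: dict = {}
        for aa, fam in self.synonymous_families.items():
            out.setdefault(len(fam), []).append(aa)
        return {k: sorted(v) for k, v in sorted(out.items())}


class UntranslatableCodonError(ValueError):
    """Codon contains a base outside A/C/G/T."""

    def __init__(self, codon: str):
        self.codon = codon
        super().__init__(f"cannot translate codon {codon!r}: non-ACGT base")


def _build_table5() -> CodonTable5:
    bio = _BioCodonTable.unambiguous_dna_by_id[5]
    forward = {c: bio.forward_table[c] for c in ALL_CODONS if c not in bio.stop_codons}
    forward.update({c: STOP for c in bio.stop_codons})

    families: dict = {}
    for codon, aa in forward.items():
        if aa != STOP:
            families.setdefault(aa, set()).add(codon)
    families = {aa: frozenset(cs) for aa, cs in families.items()}
    synonymous = {
        aa: cs for aa, cs in families.items()
        if len(cs) >= 2 and aa not in EXCLUDED_AA
    }
    return CodonTable5(
        forward=forward,
        families=families,
        synonymous_families=synonymous,
        stop_codons=frozenset(bio.stop_codons),
        start_codons=frozenset({"ATG", "ATT", "ATA", "TTG", "GTG"}),
    )


#: The shared table instance used across the package.
TABLE5 = _build_table5()

assert len(TABLE5.forward) == 64
assert TABLE5.forward["AGA"] == "S" and TABLE5.forward["AGG"] == "S"
assert TABLE5.forward["ATA"] == "M" and TABLE5.forward["TGA"] == "W"
assert TABLE5.stop_codons == {"TAA", "TAG"}
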