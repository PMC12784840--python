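"""Fetch the seven published mygalomorph mitogenome records into data/genbank/.

Requires network access to NCBI; run once, then the reference-genome
acceptance checks and the acceptance script can use the real records:

    python scripts/fetch_genbank.py [--email you@example.org]

The tarantula reference record is fetched by accession; the six companion
species are resolved by organism name + "complete mitochondrial genome".
"""

import argparse
import sys
import time
from pathlib import Path

from Bio import Entrez

ACCESSIONS = ["NC_062668"]
SPECIES = [
    "Cyriopagopus hainanus",
    "Cyriopagopus schmidti",
    "Atypus karschi",
    "Calisoga longitarsis",
    "Phyxioschema suthepium",
    "Bothriocyrtum californicum",
]
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "genbank"


def fetch_by_accession(acc: str) -> str:
    with Entrez.efetch(db="nucleotide", id=acc, rettype="gb", retmode="text") as h:
        return h.read()


def resolve_species(name: str) -> str:
    term = f'"{name}"[Organism] AND mitochondrion[Filter] AND complete genome[Title]'
    with Entrez.esearch(db="nucleotide", term=term, retmax=5) as h:
        ids = Entrez.read(h)["IdList"]
    if not ids:
        raise SystemExit(f"no complete mitogenome found for {name!r}")
    return ids[0]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--email", default="mitocub@example.org",
                    help="contact email passed to NCBI Entrez")
    args = ap.parse_args()
    Entrez.email = args.email
    OUT_DIR.mkdir(parents=True, exist_ok=True)

    for acc in ACCESSIONS:
        text = fetch_by_accession(acc)
        (OUT_DIR / f"{acc}.gb").write_text(text)
        print(f"wrote {OUT_DIR / f'{acc}.gb'}")
        time.sleep(0.4)

    for name in SPECIES:
        uid = resolve_species(name)
        text = fetch_by_accession(uid)
        slug = name.replace(" ", "_")
        (OUT_DIR / f"{slug}.gb").write_text(text)
        print(f"wrote {OUT_DIR / f'{slug}.gb'}")
        time.sleep(0.4)


if __name__ == "__main__":
    sys.exit(main())
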