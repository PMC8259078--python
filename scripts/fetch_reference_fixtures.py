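"""Extract the vendored reference-gene fixtures from an SGD R64 genome copy.

The fixtures in ``src/aidscan/data/reference_genes.fasta`` are the CDS of
SPT15 (YER148W), URA3 (YEL021W) and ADE1 (YAR015W) with 40 nt of genomic
flank on each side, taken from the S. cerevisiae R64 reference annotation
(SGD GenBank chromosome files).  This script documents and reproduces the
extraction; it needs a local copy of the R64 chromosome GenBank files (e.g.
the ``Saccharomyces_cerevisiae.zip`` bundled with the ``pygenome`` wheel, or
files downloaded from SGD) and is not required at test or analysis time —
the repository already vendors its output, with sha256 checksums recorded in
``src/aidscan/data/checksums.json``.

Usage:  python scripts/fetch_reference_fixtures.py <dir-with-chrNN.gb>
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

from Bio import SeqIO

TARGETS = {  # locus tag -> (chromosome file, standard name)
    "YER148W": ("chr05.gb", "SPT15"),
    "YEL021W": ("chr05.gb", "URA3"),
    "YAR015W": ("chr01.gb", "ADE1"),
}
FLANK = 40


def extract(genome_dir: Path) -> dict[str, dict]:
    out = {}
    cache: dict[str, object] = {}
    for locus, (chrom, gene) in TARGETS.items():
        if chrom not in cache:
            cache[chrom] = SeqIO.read(str(genome_dir / chrom), "genbank")
        rec = cache[chrom]
        feature = next(
            f for f in rec.features
            if f.type == "CDS" and locus in f.qualifiers.get("locus_tag", [])
        )
        s, e = int(feature.location.start), int(feature.location.end)
        if feature.location.strand == 1:
            up = str(rec.seq[s - FLANK : s])
            cds = str(rec.seq[s:e])
            dn = str(rec.seq[e : e + FLANK])
        else:
            up = str(rec.seq[e : e + FLANK].reverse_complement())
            cds = str(rec.seq[s:e].reverse_complement())
            dn = str(rec.seq[s - FLANK : s].reverse_complement())
        out[locus] = {"gene": gene, "upstream": up, "cds": cds, "downstream": dn}
    return out


def main():
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    genes = extract(Path(sys.argv[1]))
    data_dir = Path(__file__).resolve().parents[1] / "src/aidscan/data"
    lines = []
    for locus in TARGETS:
        g = genes[locus]
        seq = g["upstream"] + g["cds"] + g["downstream"]
        lines.append(
            f">{locus} gene={g['gene']} upstream_flank={len(g['upstream'])} "
            f"downstream_flank={len(g['downstream'])} assembly=R64 source=SGD"
        )
        lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    text = "\n".join(lines) + "\n"
    (data_dir / "reference_genes.fasta").write_text(text)
    sums = {
        "reference_genes.fasta": hashlib.sha256(text.encode()).hexdigest(),
        "per_gene_cds_sha256": {
            locus: hashlib.sha256(genes[locus]["cds"].encode()).hexdigest()
            for locus in TARGETS
        },
    }
    (data_dir / "checksums.json").write_text(json.dumps(sums, indent=1))
    print(json.dumps(sums, indent=1))


if __name__ == "__main__":
    main()
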