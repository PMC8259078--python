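"""Vendored reference fixtures.

``reference_genes.fasta`` carries the three S. cerevisiae genes used
throughout (SPT15/YER148W, URA3/YEL021W, ADE1/YAR015W) as sense-strand CDS
plus 40-nt genomic flanks, extracted from the SGD R64 genome annotation (see
``scripts/fetch_reference_fixtures.py``); sha256 checksums are recorded in
``checksums.json``.

``spt15_mutant_catalogue.synthetic.tsv`` is a synthetic reconstruction of
the catalogue of base-edited SPT15 mutant strains: the reported amino-acid
labels (A140G, A101P/V102I, ...) inverted to nucleotide changes under the
editing-window constraint.  It stands in for the original sequencing-derived
table, which is not redistributable here; synonymous bystander edits present
in the original data are not recoverable from the labels and are absent.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from ..sequence import CodingSequence, load_fasta

_GENES = {"SPT15": "YER148W", "URA3": "YEL021W", "ADE1": "YAR015W"}


def _data_path(name: str):
    return resources.files(__package__) / name


def available_genes() -> tuple[str, ...]:
    return tuple(_GENES)


def load_reference(gene: str = "SPT15", flank: int = 23) -> CodingSequence:
    """Load a vendored reference gene, trimming flanks to ``flank`` nt."""
    try:
        sysname = _GENES[gene.upper()]
    except KeyError:
        raise KeyError(f"unknown gene {gene!r}; available: {sorted(_GENES)}") from None
    with resources.as_file(_data_path("reference_genes.fasta")) as path:
        records = load_fasta(path)
    by_id = {cs.id: cs for cs in records}
    return by_id[sysname].with_flanks(flank)


def mutant_catalogue() -> pd.DataFrame:
    """Per-base rows of the synthetic SPT15 mutant-strain reconstruction."""
    with resources.as_file(_data_path("spt15_mutant_catalogue.synthetic.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def checksums() -> dict:
    with resources.as_file(_data_path("checksums.json")) as path:
        return json.loads(path.read_text())
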