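"""Stop-codon (gene-disruption) designs for URA3 and ADE1, plus the codon rule.

A single C->T edit can create a premature stop only from a handful of
codons: brute force over the codon table shows these are CGA, CAG and CAA
when the edited C is on the coding strand, and TGG (read CCA on the
antisense strand) when it is on the antisense strand.  Both gene targets are
then scanned for editing-window designs that truncate the protein.

Writes results/stop_designs.tsv and results/stop_rule.json.
"""

import json
from pathlib import Path

import pandas as pd

from aidscan import design_stop_targets, scan_pams, single_ct_stop_gain_codons
from aidscan.data import load_reference

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    sense, antisense = single_ct_stop_gain_codons()
    print("Single C->T stop-gain rule (brute force over all 64 codons):")
    print(f"  editable on the coding strand:    {sorted(sense)}")
    print(f"  editable on the antisense strand: {sorted(antisense)} "
          "(reads CCA on the antisense strand)")
    rows = []
    counts = {}
    for gene in ("URA3", "ADE1", "SPT15"):
        cs = load_reference(gene, flank=23)
        designs = design_stop_targets(cs, scan_pams(cs))
        counts[gene] = len(designs)
        for d in designs:
            rows.append(
                {
                    "gene": gene,
                    "site_id": d.site.site_id,
                    "strand": d.site.strand,
                    "guide": d.site.protospacer,
                    "cds_annotation": d.outcome.cds_annotation,
                    "protein_annotation": d.outcome.protein_annotation,
                    "truncation_residue": d.truncation_residue,
                    "stop_type": d.stop_type,
                }
            )
        print(f"  {gene}: {len(designs)} single-C->T truncation designs "
              f"(earliest at residue "
              f"{min((d.truncation_residue for d in designs), default='-')})")
    pd.DataFrame(rows).to_csv(RESULTS / "stop_designs.tsv", sep="\t", index=False)
    (RESULTS / "stop_rule.json").write_text(
        json.dumps(
            {
                "sense_stop_gain_codons": sorted(sense),
                "antisense_stop_gain_codons": sorted(antisense),
                "n_designs": counts,
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
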