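# aidscan

Target-site scanning, codon-consequence prediction and colony genotyping for
cytosine base editing of coding sequences.

Cytosine base editors such as Target-AID (a Cas9 D10A nickase fused to the
PmCDA1 deaminase and a uracil-glycosylase inhibitor) convert cytosines to
thymines — with minority C→G and C→A products — inside a fixed *editing
window* of the protospacer: positions −20 to −13 counted upstream of the NGG
PAM, where −1 abuts the PAM. Designing a mutagenesis campaign against a gene
therefore reduces to a sequence-analysis problem: find every protospacer+PAM
occurrence on both strands of the coding sequence, locate the window
cytosines (a cytosine on the antisense strand reads G on the coding strand),
and ask what each permitted substitution does to the affected codon —
synonymous, missense, stop-gain (only CGA/CAG/CAA on the coding strand and
TGG via the antisense CCA can become TAA/TAG/TGA by a single C→T), or start
loss. `aidscan` implements that design loop end to end, plus the read-out
side: calling substitutions and protein changes in colony amplicons against
the reference, estimating the editing efficiency *k/n* (edited colonies over
sequenced colonies) with a Wilson 95% interval, and the induction/glucose
colony-count viability ratio. A seeded simulator generates random in-frame
CDSs and edited colony read sets so the whole pipeline is testable without
external data.

The package is organised as a library (`src/aidscan/`) driven by numbered
analysis scripts (`analysis/01…04`) that reproduce the headline numbers for
the *S. cerevisiae* genes it ships as fixtures: *SPT15* (YER148W, the
TATA-binding protein, 723 bp / 240 residues), *URA3* and *ADE1*.

## Worked example

```python
from aidscan import scan_pams, coverage_report, design_stop_targets
from aidscan.data import load_reference

spt15 = load_reference("SPT15", flank=23)   # CDS + 23 nt genomic flank per side
sites = scan_pams(spt15)                    # NGG, 20-nt protospacer, both strands
rep = coverage_report(spt15, sites, alphabet=("T", "G", "A"))
print(len(sites), rep.targetable_C_sense, rep.targetable_C_antisense,
      rep.n_nonsynonymous_positions)
```

prints `69 31 36 56`: 69 target sites whose windows make 31 of the 130
coding-strand cytosines and 36 of the 159 antisense cytosines targetable
(some substitution changes the protein), reaching missense changes at 56
distinct residue positions. Stop designs are one call away:

```python
for d in design_stop_targets(spt15, sites)[:2]:
    print(d.site.site_id, d.outcome.cds_annotation,
          d.outcome.protein_annotation, d.stop_type)
```

prints the two SPT15 truncation designs, `000084- c.77G>A W26* amber` and
`000084- c.78G>A W26* opal` — both edit the antisense CCA of codon W26.

The same operations are exposed on the command line
(`aidscan scan|design|genotype|simulate|report`); every table and JSON
output carries a header with the tool version, config hash and input
checksums.

## Analysis scripts

- `analysis/01_scan_spt15_coverage.py` — SPT15 scan and cytosine coverage,
  with a sensitivity grid over substitution alphabet, flank length and
  consequence rule.
- `analysis/02_stop_designs.py` — the brute-forced single-C→T stop-gain
  codon rule and truncation designs for URA3, ADE1 and SPT15.
- `analysis/03_mutant_catalogue.py` — reprocesses the SPT15 mutant-strain
  catalogue (a synthetic reconstruction, see `src/aidscan/data/__init__.py`)
  through the consequence engine and tallies the substitution spectrum.
- `analysis/04_genotyping_simulation.py` — end-to-end genotyping validation
  on simulated colonies: label recovery, efficiency estimation and Wilson
  interval coverage.

Each writes its tables under `results/`.

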