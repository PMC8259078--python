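# Methods

## Model

A cytosine base editor is modelled as a purely positional machine: given a
protospacer of length 20 immediately 5' of an NGG PAM (IUPAC patterns and
other lengths are configurable), cytosines at PAM-relative offsets −20..−13
(the PAM-distal eight bases; −1 abuts the PAM) can be substituted. The
canonical product is C→T; the editor also produces minority C→G and C→A
outcomes, so the substitution alphabet is a configurable subset of {T, G, A}.
No positional activity profile is modelled inside the window — the window is
binary — and no bystander-penalty or guide-activity scoring is attempted.

Sites are enumerated on both strands of `upstream_flank + cds +
downstream_flank`. A '−'-strand site edits cytosines that read G on the
coding strand; its window occupies the mirror-image coordinates (for a PAM
at reference positions 1..3 the window is 16..23). Only sites whose
protospacer and PAM lie fully inside the available reference are reported:
how much genomic flank to admit is a parameter (default 23 nt per side, one
protospacer+PAM length, so that any window able to touch the CDS is seen);
with no flanks a warning is logged and scanning is effectively restricted to
in-CDS sites.

Consequences are classified per codon by table-1 translation: SYNONYMOUS,
MISSENSE, NONSENSE (alt codon in {TAA, TAG, TGA}, ref not a stop),
START_LOSS (initiator ATG destroyed; overrides missense), and MIXED for one
allele touching several codons with differing classes. Allele enumeration
per site takes every subset of 1..k window cytosines (default k=1) times
every alphabet assignment; the count obeys the closed form
Σ_k C(m,k)·|A|^k and a configurable cap guards against combinatorial
explosion. Edits to flank positions carry no codon change and are classed
NONCODING — an addition to the class vocabulary needed once windows may
straddle CDS boundaries.

Stop designs are restricted to single C→T edits, the chemistry the class of
editor is defined by; brute force over the codon table shows the editable
codons are exactly CGA/CAG/CAA (coding strand) and TGG (antisense strand,
where the editor sees CCA). Designs on the terminal stop codon are excluded
and each design reports its truncation residue and stop identity
(opal/amber/ochre).

A cytosine is *targetable* when any allowed single substitution at it is
nonsynonymous; coverage statistics deduplicate by reference position
(overlapping windows otherwise double-count) and also report the per-site
counts. Residue-position coverage aggregates the positions reachable by a
missense change.

## Genotyping

Colony amplicons are aligned to the reference with a global pairwise
alignment (match +1, mismatch −1, gap open −5, gap extend −1; end gaps free
on both sides so partial amplicons align to their covered region). The
scores are pinned for determinism; amplicons are near-identical to the
reference so calls are insensitive to them. Any internal gap marks the
colony uncallable — the editor's outcomes are substitutions, and an indel
more likely reflects a failed read — and uncallable colonies are excluded
from both numerator and denominator of the efficiency estimate by default
(a flag counts them as "edited-other"). Mixed-peak traces are out of scope;
inputs are basecalled sequences. Efficiency is k/n with a Wilson 95%
interval (statsmodels); viability is the induction/glucose colony ratio,
reported as-is with a warning when it exceeds 1.

## Synthetic data

`random_cds` draws internal codons base-wise with P(G)=P(C)=g/2, rejecting
stop codons; because the rejected codons are AT-rich, the per-base
probability g is calibrated by root finding so that the *conditional* GC
content equals the requested target (realized GC at 3 kb is within ±0.03).
Sequences start ATG and end with a stop drawn by base composition.
`simulate_edited_colonies` applies a prescribed change set to each colony
with a Bernoulli edit probability and overlays substitution-only sequencing
errors; truth records are kept for scoring. All randomness flows from a
single seed (numpy default_rng), so identical configs are byte-identical.
What the simulator does **not** emulate: real editor outcome heterogeneity
(partial edits, bystander patterns varying by window position), indel
byproducts, chromatogram noise, or colony cross-contamination — so passing
tests demonstrate correctness of the calling and estimation machinery, not
performance on messy real traces.

## Fixtures

The three study genes (SPT15/YER148W, URA3/YEL021W, ADE1/YAR015W) are
vendored as FASTA (CDS + 40-nt flanks) extracted from the SGD R64 genome
annotation; sha256 checksums are recorded and
`scripts/fetch_reference_fixtures.py` documents the extraction. The SPT15
mutant catalogue is a **synthetic reconstruction** (`*.synthetic.tsv`): the
reported mutant protein labels were inverted to nucleotide changes under the
constraint that all edits of a strain read C on one strand inside a single
NGG-site window, taking the minimal change set with a canonical-chemistry
tie-break (T before G before A). All 35 nonsynonymous labels are uniquely
recoverable this way (38 bases: 18 C→T, 18 C→G, 2 C→A); the one synonymous
label in the published list (R238R) is provably unreachable by cytosine
editing and is treated as a typo for R238K. Synonymous bystander co-edits in
the original sequencing data leave no trace in protein labels and are
therefore absent from the reconstruction.

## Known discrepancies with the externally reported figures

Two reported figures are not reproduced, and the corresponding acceptance
tests are deliberately left failing rather than loosened:

- **Coverage (24.6% / 21.4% / 50 positions).** Under the stated rules — the
  −20..−13 window, both strands, nonsynonymous consequence — no point of the
  sensitivity grid (alphabet {T} vs {T,G,A} × flank 0/23/40 nt × any
  nonsynonymous vs missense-only; window-convention shifts were also probed)
  lands on the reported triple. The closest principled configuration
  (alphabet {T,G,A}, any nonsynonymous) gives 23.8% / 22.6% / 56. The
  original site selection was manual, and its exact counting rule does not
  appear to follow any single consistent convention. A consistency check
  that does hold: every residue position realized by the reported mutants
  lies inside the predicted nonsynonymous position set.
- **Catalogue tallies (36 strains / 49 bases / 28 C→T, 19 C→G, 2 C→A).**
  The reconstruction necessarily undercounts: it recovers 35 strains and the
  38 label-determined bases. The missing bases are unrecoverable synonymous
  bystanders; fabricating them to hit the reported spectrum would make the
  fixture worthless as a test input.

## Problem sizes and defaults

Defaults: PAM NGG, protospacer 20 nt, window (−20, −13), alphabet {T}
(canonical chemistry) with {T,G,A} used for coverage statistics (the
realized spectrum), max multiplicity 1, flank 23 nt, alignment scores as
above, Wilson at 95%. Analysis and acceptance runs use 500 simulated
colonies at edit probability 0.3 and 2000 replicates of n=32 for interval
coverage — sizes at which binomial Monte-Carlo error is a few tenths of a
percent and the full suite runs in seconds.
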