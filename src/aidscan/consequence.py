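"""Edited-allele enumeration, codon consequence classification and coverage.

The editor chemistry deaminates cytosines: the canonical product is C->T, with
minority C->G and C->A outcomes.  An edit on the '-' strand manifests on the
sense strand as the complementary change (antisense C->T reads G->A on sense).

Consequence classes follow the usual variant vocabulary: SYNONYMOUS,
MISSENSE, NONSENSE (stop gain), START_LOSS (initiator ATG destroyed), MIXED
(one allele touching several codons with differing classes) and NONCODING
(all changes in the flanks).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from math import comb
from typing import Iterable, Sequence

import pandas as pd

from .scanner import EditableCytosine, TargetSite, find_editable_cytosines, in_cds
from .sequence import (
    CodingSequence,
    CodonTable,
    STANDARD_TABLE,
    complement_base,
)

CANONICAL_ALPHABET = ("T",)
OBSERVED_ALPHABET = ("T", "G", "A")  # realized editor spectrum, majority first

STOP_NAMES = {"TGA": "opal", "TAG": "amber", "TAA": "ochre"}


class Consequence(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    START_LOSS = "START_LOSS"
    MIXED = "MIXED"
    NONCODING = "NONCODING"


class OutcomeCapExceeded(RuntimeError):
    """Projected outcome count exceeds the configured cap.

    Lower ``max_multiplicity`` or shrink the alphabet.
    """


def classify_consequence(
    ref_codon: str,
    alt_codon: str,
    table: CodonTable = STANDARD_TABLE,
    codon_index: int = 0,
) -> Consequence:
    """Classify a single codon change.

    START_LOSS (initiator ATG replaced, codon_index 1) overrides MISSENSE;
    NONSENSE requires the reference codon not to be a stop already.
    """
    ref_aa = table.aa(ref_codon)
    alt_aa = table.aa(alt_codon)
    if alt_aa == ref_aa:
        return Consequence.SYNONYMOUS
    if alt_aa == "*":
        return Consequence.NONSENSE
    if codon_index == 1 and ref_codon == "ATG" and alt_codon != "ATG":
        return Consequence.START_LOSS
    return Consequence.MISSENSE


@dataclass(frozen=True)
class EditOutcome:
    """One predicted edited allele for one target site."""

    site_id: str
    # (1-based reference position, ref base on sense, alt base on sense)
    changes: tuple[tuple[int, str, str], ...]
    # (window offset, alt base on the edited strand)
    edited_strand_changes: tuple[tuple[int, str], ...]
    codon_changes: tuple[tuple[int, str, str], ...]
    consequence: Consequence
    protein_annotation: str
    cds_annotation: str
    per_codon_classes: tuple[Consequence, ...] = field(default=())

    @property
    def multiplicity(self) -> int:
        return len(self.changes)


def _protein_annotation(
    table: CodonTable, codon_changes: Sequence[tuple[int, str, str]]
) -> str:
    parts = []
    for idx, ref_codon, alt_codon in codon_changes:
        parts.append(f"{table.aa(ref_codon)}{idx}{table.aa(alt_codon)}")
    return "/".join(parts)


def _cds_annotation(changes_in_cds: Sequence[tuple[int, str, str]]) -> str:
    parts = [f"{p}{r}>{a}" for p, r, a in changes_in_cds]
    if not parts:
        return "."
    if len(parts) == 1:
        return f"c.{parts[0]}"
    return "c.[" + ";".join(parts) + "]"


def build_outcome(
    cs: CodingSequence,
    site_id: str,
    edits: Sequence[tuple[EditableCytosine, str]],
) -> EditOutcome:
    """Construct the allele produced by editing the given cytosines.

    ``edits`` pairs each editable cytosine with its substitution product on
    the edited strand (one of T, G, A).
    """
    table = cs.codon_table
    changes = []
    strand_changes = []
    cds_changes = []  # (cds_position, sense ref, sense alt)
    for ec, alt in sorted(edits, key=lambda e: e[0].ref_coordinate.position):
        if alt not in ("T", "G", "A"):
            raise ValueError(f"invalid substitution product {alt!r}")
        sense_ref = ec.sense_base
        sense_alt = alt if ec.edited_strand == "+" else complement_base(alt)
        changes.append((ec.ref_coordinate.position, sense_ref, sense_alt))
        strand_changes.append((ec.window_offset, alt))
        if ec.ref_coordinate.in_cds:
            cds_changes.append((ec.ref_coordinate.cds_position, sense_ref, sense_alt))
    # apply to the CDS and collect codon-level changes
    cds = list(cs.cds)
    for pos, ref, alt in cds_changes:
        assert cds[pos - 1] == ref
        cds[pos - 1] = alt
    mutant = "".join(cds)
    codon_changes = []
    classes = []
    touched = sorted({(p - 1) // 3 for p, _, _ in cds_changes})
    for ci in touched:
        ref_codon = cs.cds[ci * 3 : ci * 3 + 3]
        alt_codon = mutant[ci * 3 : ci * 3 + 3]
        codon_changes.append((ci + 1, ref_codon, alt_codon))
        classes.append(classify_consequence(ref_codon, alt_codon, table, ci + 1))
    if not codon_changes:
        consequence = Consequence.NONCODING
    elif len(set(classes)) == 1:
        consequence = classes[0]
    else:
        consequence = Consequence.MIXED
    return EditOutcome(
        site_id=site_id,
        changes=tuple(changes),
        edited_strand_changes=tuple(strand_changes),
        codon_changes=tuple(codon_changes),
        consequence=consequence,
        protein_annotation=_protein_annotation(table, codon_changes) or ".",
        cds_annotation=_cds_annotation(cds_changes),
        per_codon_classes=tuple(classes),
    )


def projected_outcome_count(m: int, alphabet_size: int, max_multiplicity: int) -> int:
    """Closed form sum_k C(m,k) * |alphabet|^k for k = 1..max_multiplicity."""
    return sum(comb(m, k) * alphabet_size**k for k in range(1, max_multiplicity + 1))


def enumerate_outcomes(
    cs: CodingSequence,
    ec_set: Iterable[EditableCytosine],
    alphabet: Sequence[str] = CANONICAL_ALPHABET,
    max_multiplicity: int = 1,
    cap: int = 200_000,
) -> list[EditOutcome]:
    """Enumerate all edited alleles per site.

    For each site, every subset of 1..max_multiplicity window cytosines is
    edited, each cytosine to each alphabet base.  Ordering is deterministic:
    by site, multiplicity, edited positions, then alphabetical products.
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if max_multiplicity < 1:
        raise ValueError("max_multiplicity must be >= 1")
    by_site: dict[str, list[EditableCytosine]] = {}
    for ec in ec_set:
        by_site.setdefault(ec.site_id, []).append(ec)
    total = sum(
        projected_outcome_count(len(v), len(alphabet), max_multiplicity)
        for v in by_site.values()
    )
    if total > cap:
        raise OutcomeCapExceeded(
            f"projected {total} outcomes exceed cap {cap}; lower max_multiplicity"
        )
    out: list[EditOutcome] = []
    alph = sorted(alphabet)
    for site_id in sorted(by_site):
        ecs = sorted(by_site[site_id], key=lambda e: e.ref_coordinate.position)
        for k in range(1, max_multiplicity + 1):
            for combo in itertools.combinations(ecs, k):
                for alts in itertools.product(alph, repeat=k):
                    out.append(build_outcome(cs, site_id, list(zip(combo, alts))))
    out.sort(
        key=lambda o: (
            o.changes[0][0] if o.changes else 0,
            o.multiplicity,
            tuple(a for _, a in o.edited_strand_changes),
            o.site_id,
        )
    )
    return out


# ---------------------------------------------------------------------------
# stop-codon (truncation) designs


@dataclass(frozen=True)
class StopDesign:
    site: TargetSite
    outcome: EditOutcome
    truncation_residue: int
    stop_type: str  # opal / amber / ochre


def single_ct_stop_gain_codons(
    table: CodonTable = STANDARD_TABLE,
) -> tuple[set[str], set[str]]:
    """Brute-force the codons convertible to a stop by one C->T edit.

    Returns (sense-editable codons, antisense-editable codons): a sense edit
    changes a codon C to T directly; an antisense edit changes a codon G to A.
    """
    sense, antisense = set(), set()
    bases = "ACGT"
    for codon in map("".join, itertools.product(bases, repeat=3)):
        if table.aa(codon) == "*":
            continue
        for i, b in enumerate(codon):
            if b == "C":
                alt = codon[:i] + "T" + codon[i + 1 :]
                if table.aa(alt) == "*":
                    sense.add(codon)
            if b == "G":
                alt = codon[:i] + "A" + codon[i + 1 :]
                if table.aa(alt) == "*":
                    antisense.add(codon)
    return sense, antisense


def design_stop_targets(
    cs: CodingSequence,
    sites: Sequence[TargetSite],
) -> list[StopDesign]:
    """Single-C->T designs that convert a non-stop codon to TAA/TAG/TGA.

    Edits to the terminal stop codon are excluded; each design reports the
    truncation residue index and the stop identity (opal/amber/ochre).
    """
    ecs = in_cds(find_editable_cytosines(cs, sites))
    last_codon = cs.n_codons if cs.protein().endswith("*") else None
    designs = []
    site_by_id = {s.site_id: s for s in sites}
    for outcome in enumerate_outcomes(cs, ecs, alphabet=("T",), max_multiplicity=1):
        if outcome.consequence is not Consequence.NONSENSE:
            continue
        codon_index, _, alt_codon = outcome.codon_changes[0]
        if last_codon is not None and codon_index == last_codon:
            continue
        designs.append(
            StopDesign(
                site=site_by_id[outcome.site_id],
                outcome=outcome,
                truncation_residue=codon_index,
                stop_type=STOP_NAMES[alt_codon],
            )
        )
    return designs


# ---------------------------------------------------------------------------
# nonsynonymous designs and coverage


def select_nonsynonymous_targets(
    cs: CodingSequence,
    sites: Sequence[TargetSite],
    alphabet: Sequence[str] = OBSERVED_ALPHABET,
    max_multiplicity: int = 1,
    include_nonsense: bool = False,
    include_start_loss: bool = False,
) -> list[tuple[TargetSite, EditOutcome]]:
    """Outcomes whose consequence is missense (or MIXED containing missense).

    NONSENSE and START_LOSS outcomes are excluded by default, mirroring a
    design goal of amino acid substitutions rather than truncations.
    """
    ecs = in_cds(find_editable_cytosines(cs, sites))
    site_by_id = {s.site_id: s for s in sites}
    keep = {Consequence.MISSENSE}
    if include_nonsense:
        keep.add(Consequence.NONSENSE)
    if include_start_loss:
        keep.add(Consequence.START_LOSS)
    selected = []
    for outcome in enumerate_outcomes(cs, ecs, alphabet, max_multiplicity):
        classes = set(outcome.per_codon_classes)
        if classes & keep:
            if not include_nonsense and outcome.consequence is Consequence.NONSENSE:
                continue
            if not include_start_loss and outcome.consequence is Consequence.START_LOSS:
                continue
            selected.append((site_by_id[outcome.site_id], outcome))
    return selected


def affected_residue_positions(
    designs: Iterable[tuple[TargetSite, EditOutcome]],
    classes: frozenset = frozenset({Consequence.MISSENSE}),
) -> set[int]:
    """Residue indices touched by a per-codon class in ``classes``."""
    positions = set()
    for _, outcome in designs:
        for (idx, _, _), cls in zip(outcome.codon_changes, outcome.per_codon_classes):
            if cls in classes:
                positions.add(idx)
    return positions


@dataclass(frozen=True)
class CoverageReport:
    """Per-strand cytosine coverage of an editing-window scan.

    A cytosine is *targetable* when it lies in the editing window of at least
    one site on its strand and at least one allowed substitution of it is
    nonsynonymous.  Counts are deduplicated per reference position; the
    per-site (duplicated) counts are carried alongside for transparency.
    """

    total_C_sense: int
    total_C_antisense: int
    targetable_C_sense: int
    targetable_C_antisense: int
    fraction_sense: float
    fraction_antisense: float
    nonsynonymous_positions: frozenset[int]
    n_nonsynonymous_positions: int
    targetable_C_sense_per_site: int = 0
    targetable_C_antisense_per_site: int = 0

    def as_dict(self) -> dict:
        d = {
            "total_C_sense": self.total_C_sense,
            "total_C_antisense": self.total_C_antisense,
            "targetable_C_sense": self.targetable_C_sense,
            "targetable_C_antisense": self.targetable_C_antisense,
            "fraction_sense": self.fraction_sense,
            "fraction_antisense": self.fraction_antisense,
            "n_nonsynonymous_positions": self.n_nonsynonymous_positions,
            "nonsynonymous_positions": sorted(self.nonsynonymous_positions),
            "targetable_C_sense_per_site": self.targetable_C_sense_per_site,
            "targetable_C_antisense_per_site": self.targetable_C_antisense_per_site,
        }
        return d


def coverage_report(
    cs: CodingSequence,
    sites: Sequence[TargetSite],
    alphabet: Sequence[str] = OBSERVED_ALPHABET,
    nonsynonymous_classes: frozenset = frozenset(
        {Consequence.MISSENSE, Consequence.NONSENSE, Consequence.START_LOSS}
    ),
) -> CoverageReport:
    """Coverage statistics for single-cytosine edits within the CDS.

    Totals count cytosines within the CDS on each strand (a sense G is an
    antisense C).  A position is targetable when any single allowed
    substitution at it yields a consequence in ``nonsynonymous_classes``;
    the missense residue-position set is aggregated from the same outcomes.
    """
    total_sense = cs.cds.count("C")
    total_anti = cs.cds.count("G")
    ecs = in_cds(find_editable_cytosines(cs, sites))
    targetable: dict[str, set[int]] = {"+": set(), "-": set()}
    per_site: dict[str, int] = {"+": 0, "-": 0}
    missense_positions: set[int] = set()
    for outcome in enumerate_outcomes(cs, ecs, alphabet, max_multiplicity=1):
        (pos, sense_ref, _), = outcome.changes
        # the edited strand is the one where the base reads C
        strand = "+" if sense_ref == "C" else "-"
        cls = outcome.per_codon_classes[0] if outcome.per_codon_classes else None
        if cls in nonsynonymous_classes:
            targetable[strand].add(pos)
        if cls is Consequence.MISSENSE:
            missense_positions.add(outcome.codon_changes[0][0])
    # per-site (duplicated) counts: unique (site, position) pairs that are targetable
    seen_pairs: set[tuple[str, int]] = set()
    for ec in ecs:
        key = (ec.ref_coordinate.position, ec.edited_strand)
        if key[0] in targetable[ec.edited_strand]:
            pair = (ec.site_id, ec.ref_coordinate.position)
            if pair not in seen_pairs:
                seen_pairs.add(pair)
                per_site[ec.edited_strand] += 1
    return CoverageReport(
        total_C_sense=total_sense,
        total_C_antisense=total_anti,
        targetable_C_sense=len(targetable["+"]),
        targetable_C_antisense=len(targetable["-"]),
        fraction_sense=len(targetable["+"]) / total_sense if total_sense else 0.0,
        fraction_antisense=len(targetable["-"]) / total_anti if total_anti else 0.0,
        nonsynonymous_positions=frozenset(missense_positions),
        n_nonsynonymous_positions=len(missense_positions),
        targetable_C_sense_per_site=per_site["+"],
        targetable_C_antisense_per_site=per_site["-"],
    )


# ---------------------------------------------------------------------------
# guide oligo design


@dataclass(frozen=True)
class OverhangConfig:
    """Cloning overhangs appended around the 20-nt guide in each oligo."""

    forward_5: str = ""
    forward_3: str = ""
    reverse_5: str = ""
    reverse_3: str = ""


@dataclass(frozen=True)
class GuideDesign:
    site_id: str
    guide_20nt: str
    forward_oligo: str
    reverse_oligo: str
    intended_outcomes: tuple[EditOutcome, ...] = ()

    def reconstruct_insert(self, overhangs: OverhangConfig) -> str:
        """Cassette insert implied by the oligo pair: overhang+guide+overhang."""
        return overhangs.forward_5 + self.guide_20nt + overhangs.forward_3


def design_guide_oligos(
    site: TargetSite,
    overhangs: OverhangConfig = OverhangConfig(),
    intended_outcomes: Sequence[EditOutcome] = (),
    guide_len: int = 20,
) -> GuideDesign:
    """Embed the 20-nt guide (the site protospacer) in a cloning oligo pair.

    The forward oligo carries the guide sense; the reverse oligo carries its
    reverse complement, each flanked by the configured overhangs.
    """
    from .sequence import reverse_complement

    guide = site.protospacer
    if len(guide) != guide_len:
        raise ValueError(f"guide length {len(guide)} != required {guide_len}")
    fwd = overhangs.forward_5 + guide + overhangs.forward_3
    rev = overhangs.reverse_5 + reverse_complement(guide) + overhangs.reverse_3
    return GuideDesign(
        site_id=site.site_id,
        guide_20nt=guide,
        forward_oligo=fwd,
        reverse_oligo=rev,
        intended_outcomes=tuple(intended_outcomes),
    )


# ---------------------------------------------------------------------------
# mutation-table reprocessing

MUTATION_TABLE_COLUMNS = ["strain_id", "cds_position", "edited_strand", "ref_base", "alt_base"]


def annotate_mutation_table(
    cs: CodingSequence,
    rows: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Recompute protein annotations and substitution tallies from a mutant table.

    Input: one row per edited base with columns ``strain_id``, ``cds_position``
    (1-based on the sense CDS), ``edited_strand`` ('+'/'-'), ``ref_base`` and
    ``alt_base`` given on the *edited* strand (ref must read C there).  Rows
    failing validation are reported per row, not fatally.

    Returns the per-strain annotated table and a tally dict with the
    substitution spectrum (C>T / C>G / C>A on the edited strand), the number
    of strains, edited bases, and distinct mutated base positions.
    """
    table = cs.codon_table
    required = set(MUTATION_TABLE_COLUMNS)
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"mutation table lacks columns: {sorted(missing)}")
    spectrum: Counter = Counter()
    row_errors: list[tuple[int, str]] = []
    strains: dict[str, list[tuple[int, str, str]]] = {}
    positions: set[int] = set()
    n_bases = 0
    for i, row in rows.iterrows():
        pos = int(row.cds_position)
        strand = str(row.edited_strand)
        ref = str(row.ref_base).upper()
        alt = str(row.alt_base).upper()
        if not 1 <= pos <= len(cs.cds):
            row_errors.append((i, f"cds_position {pos} out of range"))
            continue
        sense_base = cs.cds[pos - 1]
        edited_ref = sense_base if strand == "+" else complement_base(sense_base)
        if ref != "C" or edited_ref != "C":
            row_errors.append(
                (i, f"base at cds position {pos} reads {edited_ref} on strand {strand}, not C")
            )
            continue
        sense_alt = alt if strand == "+" else complement_base(alt)
        spectrum[f"C>{alt}"] += 1
        n_bases += 1
        positions.add(pos)
        strains.setdefault(str(row.strain_id), []).append((pos, sense_base, sense_alt))
    records = []
    for strain_id, subs in strains.items():
        cds = list(cs.cds)
        for pos, ref, alt in subs:
            cds[pos - 1] = alt
        mutant = "".join(cds)
        ann_parts = []
        classes = []
        for ci in sorted({(p - 1) // 3 for p, _, _ in subs}):
            ref_codon = cs.cds[ci * 3 : ci * 3 + 3]
            alt_codon = mutant[ci * 3 : ci * 3 + 3]
            cls = classify_consequence(ref_codon, alt_codon, table, ci + 1)
            classes.append(cls.value)
            ann_parts.append(f"{table.aa(ref_codon)}{ci + 1}{table.aa(alt_codon)}")
        records.append(
            {
                "strain_id": strain_id,
                "n_bases": len(subs),
                "cds_changes": ";".join(f"{p}{r}>{a}" for p, r, a in sorted(subs)),
                "protein_annotation": "/".join(ann_parts),
                "classes": "/".join(classes),
            }
        )
    annotated = pd.DataFrame(
        records,
        columns=["strain_id", "n_bases", "cds_changes", "protein_annotation", "classes"],
    )
    tallies = {
        "n_strains": len(strains),
        "n_bases": n_bases,
        "n_distinct_positions": len(positions),
        "C>T": spectrum.get("C>T", 0),
        "C>G": spectrum.get("C>G", 0),
        "C>A": spectrum.get("C>A", 0),
        "row_errors": row_errors,
    }
    return annotated, tallies
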