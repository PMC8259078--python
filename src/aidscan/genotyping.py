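"""Colony amplicon genotyping, mutation efficiency and cell viability.

Colonies are genotyped by sequencing a PCR amplicon over the target region
and comparing it to the reference.  Base-editor outcomes are substitutions,
so reads containing insertions or deletions are flagged uncallable rather
than interpreted.  Mutation efficiency is the fraction of sequenced colonies
carrying an edit (edited colonies over total sequenced colonies), reported
with a Wilson 95% confidence interval; cell viability is the colony count on
induction (galactose+raffinose) plates divided by the count on glucose
plates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from statsmodels.stats.proportion import proportion_confint

from .consequence import Consequence, classify_consequence
from .sequence import CodingSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentScores:
    """Pinned for determinism; amplicons are near-identical to the reference."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


DEFAULT_SCORES = AlignmentScores()


def _aligner(scores: AlignmentScores) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    # amplicons may cover only part of the reference (and vice versa):
    # end gaps on both sides are free, internal gaps penalized
    for attr, legacy in (
        ("open_left_insertion_score", "target_left_open_gap_score"),
        ("extend_left_insertion_score", "target_left_extend_gap_score"),
        ("open_right_insertion_score", "target_right_open_gap_score"),
        ("extend_right_insertion_score", "target_right_extend_gap_score"),
        ("open_left_deletion_score", "query_left_open_gap_score"),
        ("extend_left_deletion_score", "query_left_extend_gap_score"),
        ("open_right_deletion_score", "query_right_open_gap_score"),
        ("extend_right_deletion_score", "query_right_extend_gap_score"),
    ):
        try:
            setattr(aligner, attr, 0.0)
        except AttributeError:  # older biopython
            setattr(aligner, legacy, 0.0)
    return aligner


def align_amplicon(
    reference: str,
    observed: str,
    scores: AlignmentScores = DEFAULT_SCORES,
):
    """Global alignment of an observed amplicon against the reference.

    Reference end gaps are free, so a shorter amplicon aligns to its covered
    region.  Tie-breaking is deterministic: the first optimal alignment in
    biopython's canonical order (leftmost gap placement) is returned.
    """
    if not reference or not observed:
        raise ValueError("reference and observed must be non-empty")
    return _aligner(scores).align(reference, observed)[0]


@dataclass(frozen=True)
class ObservedGenotype:
    """Substitutions and protein changes called from one colony amplicon."""

    colony_id: str
    substitutions: tuple[tuple[int, str, str], ...]  # (cds_position, ref, alt)
    protein_changes: tuple[tuple[int, str, str], ...]  # (residue, ref_aa, alt_aa)
    label: str
    callable: bool
    reject_reason: str | None = None
    flank_substitutions: tuple[tuple[int, str, str], ...] = ()  # reference coords


def apply_substitutions(
    cs: CodingSequence, substitutions: Iterable[tuple[int, str, str]]
) -> str:
    """Reference sequence with (cds_position, ref, alt) substitutions applied."""
    ref = list(cs.reference)
    for pos, ref_base, alt_base in substitutions:
        idx = cs.cds_start + pos - 1
        if not cs.cds_start <= idx < cs.cds_end:
            raise ValueError(f"cds position {pos} out of range")
        if ref[idx] != ref_base:
            raise ValueError(
                f"reference base at cds position {pos} is {ref[idx]}, not {ref_base}"
            )
        ref[idx] = alt_base
    return "".join(ref)


def call_genotype(
    cs: CodingSequence,
    observed: str,
    colony_id: str = "colony",
    scores: AlignmentScores = DEFAULT_SCORES,
    min_overlap: int = 30,
) -> ObservedGenotype:
    """Call substitutions and protein changes for one colony amplicon.

    Any insertion or deletion in the aligned region makes the colony
    uncallable.  The label '/'-joins protein changes in ascending residue
    order; synonymous changes are listed in c. notation; an edit-free callable
    colony is labelled WT.
    """
    observed = observed.upper()
    if len(observed) < min_overlap:
        raise ValueError(
            f"{colony_id}: observed length {len(observed)} below minimum overlap {min_overlap}"
        )
    alignment = align_amplicon(cs.reference, observed, scores)
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) != 1:
        return ObservedGenotype(
            colony_id=colony_id,
            substitutions=(),
            protein_changes=(),
            label="uncallable",
            callable=False,
            reject_reason="alignment contains an insertion or deletion",
        )
    (t0, t1), (q0, _) = t_blocks[0], q_blocks[0]
    if t1 - t0 < min_overlap:
        return ObservedGenotype(
            colony_id=colony_id,
            substitutions=(),
            protein_changes=(),
            label="uncallable",
            callable=False,
            reject_reason=f"aligned overlap {t1 - t0} below minimum {min_overlap}",
        )
    ref = cs.reference
    subs_cds: list[tuple[int, str, str]] = []
    subs_flank: list[tuple[int, str, str]] = []
    for k in range(t1 - t0):
        r, o = ref[t0 + k], observed[q0 + k]
        if r != o:
            idx = t0 + k
            coord = cs.coordinate(idx)
            if coord.in_cds:
                subs_cds.append((coord.cds_position, r, o))
            else:
                subs_flank.append((coord.position, r, o))
    protein_changes: list[tuple[int, str, str]] = []
    label_parts: list[str] = []
    if subs_cds:
        mutant = apply_substitutions(cs, subs_cds)
        mut_cds = mutant[cs.cds_start : cs.cds_end]
        table = cs.codon_table
        for ci in sorted({(p - 1) // 3 for p, _, _ in subs_cds}):
            ref_codon = cs.cds[ci * 3 : ci * 3 + 3]
            alt_codon = mut_cds[ci * 3 : ci * 3 + 3]
            cls = classify_consequence(ref_codon, alt_codon, table, ci + 1)
            if cls is Consequence.SYNONYMOUS:
                for p, r, a in subs_cds:
                    if (p - 1) // 3 == ci:
                        label_parts.append(f"c.{p}{r}>{a}")
            else:
                ref_aa, alt_aa = table.aa(ref_codon), table.aa(alt_codon)
                protein_changes.append((ci + 1, ref_aa, alt_aa))
                label_parts.append(f"{ref_aa}{ci + 1}{alt_aa}")
    label = "/".join(label_parts) if label_parts else "WT"
    return ObservedGenotype(
        colony_id=colony_id,
        substitutions=tuple(subs_cds),
        protein_changes=tuple(protein_changes),
        label=label,
        callable=True,
        flank_substitutions=tuple(subs_flank),
    )


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Edited-colony fraction with a Wilson 95% interval."""

    n_edited: int
    n_total: int
    point: float
    ci_low: float
    ci_high: float


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(low), float(high)


def mutation_efficiency(
    genotypes: Sequence[ObservedGenotype],
    target_changes: Sequence[tuple[int, str, str]] | None = None,
    include_uncallable: bool = False,
) -> EfficiencyEstimate:
    """Fraction of colonies carrying the target edit (or any edit).

    By default only callable (substitution-only) colonies enter numerator and
    denominator.  With ``target_changes`` given, a colony counts as edited
    when its substitutions include all of the target (cds_position, ref, alt)
    changes; otherwise any non-WT callable colony counts.  With
    ``include_uncallable`` uncallable colonies are counted in the denominator
    and as "edited-other" in the numerator.
    """
    callable_gts = [g for g in genotypes if g.callable]
    pool = list(genotypes) if include_uncallable else callable_gts
    if not pool or not callable_gts:
        raise ValueError("no callable genotypes")
    n_total = len(pool)
    n_edited = 0
    for g in pool:
        if not g.callable:
            n_edited += 1  # edited-other: an indel is still an editing event
        elif target_changes is not None:
            if set(target_changes) <= set(g.substitutions):
                n_edited += 1
        elif g.substitutions:
            n_edited += 1
    point = n_edited / n_total
    low, high = wilson_interval(n_edited, n_total)
    return EfficiencyEstimate(
        n_edited=n_edited, n_total=n_total, point=point, ci_low=low, ci_high=high
    )


def cell_viability(colonies_induction: int, colonies_glucose: int) -> float:
    """Colonies on induction (galactose+raffinose) over colonies on glucose."""
    if colonies_glucose < 1:
        raise ValueError("glucose plate colony count must be >= 1")
    ratio = colonies_induction / colonies_glucose
    if ratio > 1:
        logger.warning("cell viability %.3f exceeds 1; reported as-is", ratio)
    return ratio


GENOTYPE_COLUMNS = [
    "colony_id", "callable", "label", "n_substitutions",
    "cds_changes", "protein_changes", "reject_reason",
]


def genotypes_to_table(genotypes: Sequence[ObservedGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        rows.append(
            (
                g.colony_id,
                g.callable,
                g.label,
                len(g.substitutions),
                ";".join(f"{p}{r}>{a}" for p, r, a in g.substitutions) or ".",
                ";".join(f"{r}{i}{a}" for i, r, a in g.protein_changes) or ".",
                g.reject_reason or ".",
            )
        )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
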