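"""Synthetic data: random in-frame CDSs and simulated edited-colony read sets.

The simulator emulates the data a colony-sequencing experiment produces: a
reference CDS, a set of colony amplicons in which a Bernoulli fraction of
colonies carries a prescribed window edit, and optional substitution-only
sequencing errors (the consensus of a Sanger read has no indel error mode
worth modelling here).  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .sequence import CodingSequence, write_fasta

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    cds_length: int = 300
    gc_target: float = 0.4
    n_colonies: int = 10
    edit_probability: float = 0.5
    # explicit change set: (cds_position, ref_base, alt_base) on the sense strand
    outcome_changes: tuple[tuple[int, str, str], ...] = ()
    error_rate: float = 0.0

    def __post_init__(self):
        if self.cds_length < 6 or self.cds_length % 3:
            raise ValueError("cds_length must be >= 6 and a multiple of 3")
        for name in ("gc_target", "edit_probability", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _base_probs(gc: float) -> np.ndarray:
    # order A, C, G, T
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _conditional_gc(x: float) -> float:
    """Realized GC of a random codon conditioned on not being a stop codon."""
    p = _base_probs(x)

    def pc(codon):
        return np.prod([p[BASES.index(b)] for b in codon])

    stop_mass = sum(pc(s) for s in STOPS)
    stop_gc = sum(pc(s) * sum(b in "GC" for b in s) for s in STOPS)
    return (3 * x - stop_gc) / (3 * (1 - stop_mass))


def _solve_gc(target: float) -> float:
    """Per-base G+C probability whose stop-rejected codons average ``target`` GC."""
    if target <= 0.0 or target >= 1.0:
        return target
    f = lambda x: _conditional_gc(x) - target
    lo, hi = 1e-9, 1 - 1e-9
    if f(lo) > 0:
        return 0.0
    if f(hi) < 0:
        return 1.0
    return float(brentq(f, lo, hi, xtol=1e-12))


def random_cds(
    length: int,
    gc_target: float = 0.4,
    seed: int = 0,
    id: str = "synthetic_cds",
) -> CodingSequence:
    """Random in-frame CDS: starts ATG, ends with a stop, no internal stop.

    Internal codons are drawn base-wise at a G+C probability calibrated (by
    root finding on the stop-rejection bias) so the realized GC content
    matches ``gc_target`` in expectation.  Deterministic given the seed.
    """
    if length < 6 or length % 3:
        raise ValueError("length must be >= 6 and a multiple of 3")
    rng = np.random.default_rng(seed)
    p = _base_probs(_solve_gc(gc_target))
    n_internal = length // 3 - 2
    codons = []
    while len(codons) < n_internal:
        draw = rng.choice(list(BASES), size=3, p=p)
        codon = "".join(draw)
        if codon not in STOPS:
            codons.append(codon)
    # terminal stop drawn among TAA/TAG/TGA proportional to base composition
    stop_weights = []
    pb = _base_probs(gc_target)
    for s in STOPS:
        stop_weights.append(np.prod([pb[BASES.index(b)] for b in s]))
    stop_weights = np.array(stop_weights) / sum(stop_weights)
    stop = STOPS[rng.choice(3, p=stop_weights)]
    return CodingSequence(id=id, cds="ATG" + "".join(codons) + stop)


@dataclass(frozen=True)
class SimulatedColony:
    colony_id: str
    sequence: str
    edited: bool
    truth_changes: tuple[tuple[int, str, str], ...]
    n_errors: int


def simulate_edited_colonies(
    cs: CodingSequence,
    config: SimulationConfig,
) -> list[SimulatedColony]:
    """Simulate colony amplicons over the full reference of ``cs``.

    Each colony carries the configured outcome with probability
    ``edit_probability``; per-base substitution errors are then applied at
    ``error_rate`` (uniform among the three other bases).  Truth records are
    retained for scoring the genotype caller.
    """
    rng = np.random.default_rng(config.seed)
    ref = cs.reference
    for pos, ref_base, _ in config.outcome_changes:
        idx = cs.cds_start + pos - 1
        if not cs.cds_start <= idx < cs.cds_end:
            raise ValueError(f"outcome cds position {pos} out of range")
        if ref[idx] != ref_base:
            raise ValueError(
                f"outcome ref base at cds position {pos} is {ref[idx]}, not {ref_base}"
            )
    colonies = []
    width = len(str(max(config.n_colonies, 1)))
    for i in range(config.n_colonies):
        edited = bool(rng.random() < config.edit_probability)
        seq = list(ref)
        truth = ()
        if edited:
            for pos, ref_base, alt_base in config.outcome_changes:
                seq[cs.cds_start + pos - 1] = alt_base
            truth = tuple(config.outcome_changes)
        n_err = 0
        if config.error_rate > 0:
            err_mask = rng.random(len(seq)) < config.error_rate
            for j in np.flatnonzero(err_mask):
                alternatives = [b for b in BASES if b != seq[j]]
                seq[j] = alternatives[rng.integers(3)]
                n_err += 1
        colonies.append(
            SimulatedColony(
                colony_id=f"colony_{i + 1:0{width}d}",
                sequence="".join(seq),
                edited=edited,
                truth_changes=truth,
                n_errors=n_err,
            )
        )
    return colonies


def write_colony_set(
    outdir: str | Path,
    cs: CodingSequence,
    colonies: Sequence[SimulatedColony],
) -> dict[str, Path]:
    """Write reference FASTA, colony FASTA and a truth TSV; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_path = outdir / "reference.fasta"
    write_fasta(ref_path, [cs])
    colonies_path = outdir / "colonies.fasta"
    with open(colonies_path, "w") as fh:
        for c in colonies:
            fh.write(f">{c.colony_id}\n{c.sequence}\n")
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["colony_id", "edited", "changes", "n_errors"])
        for c in colonies:
            writer.writerow(
                [
                    c.colony_id,
                    int(c.edited),
                    ";".join(f"{p}{r}>{a}" for p, r, a in c.truth_changes) or ".",
                    c.n_errors,
                ]
            )
    return {"reference": ref_path, "colonies": colonies_path, "truth": truth_path}
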