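"""Protospacer/PAM scanning and deaminase editing-window mapping.

A cytosine base editor acts on cytosines located in a fixed window at the
PAM-distal end of the protospacer.  Window positions are counted upstream of
the PAM: offset -1 abuts the PAM, offset -20 is the 5' terminus of a 20-nt
protospacer.  The default window is -20..-13 (8 bases), the region where
Target-AID (nCas9-PmCDA1) deaminates cytosines.

Sites are found on both strands of the reference; a site on the '-' strand
edits cytosines that read G on the sense strand.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequence import CodingSequence, ReferenceCoordinate, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-20, -13)
DEFAULT_PROTOSPACER_LEN = 20
DEFAULT_PAM = "NGG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(seq: str, pattern: str) -> bool:
    """Exact-length match of a nucleotide string against an IUPAC pattern."""
    if len(seq) != len(pattern):
        return False
    try:
        return all(base in IUPAC[p] for base, p in zip(seq, pattern))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in pattern") from None


@dataclass(frozen=True)
class TargetSite:
    """One protospacer+PAM occurrence with its editing window.

    Spans are 0-based half-open on the reference.  ``protospacer`` and ``pam``
    read 5'->3' on the site strand; ``window_offsets`` are the PAM-relative
    offsets covered by the window (ascending, e.g. -20..-13).
    """

    site_id: str
    strand: str
    protospacer: str
    pam: str
    protospacer_span: tuple[int, int]
    pam_span: tuple[int, int]
    window_span: tuple[int, int]
    window_offsets: tuple[int, ...]
    unique_protospacer: bool = True

    def window_ref_index(self, offset: int) -> int:
        """0-based reference index of a PAM-relative window offset."""
        lo, hi = min(self.window_offsets), max(self.window_offsets)
        if not lo <= offset <= hi:
            raise ValueError(f"offset {offset} outside window {lo}..{hi}")
        if self.strand == "+":
            return self.pam_span[0] + offset
        return self.pam_span[1] - 1 - offset  # offset < 0: higher coordinates


@dataclass(frozen=True)
class EditableCytosine:
    """A window position reading C on the site strand."""

    site_id: str
    window_offset: int
    edited_strand: str
    ref_coordinate: ReferenceCoordinate
    sense_base: str  # 'C' on '+' sites, 'G' on '-' sites


def scan_pams(
    cs: CodingSequence,
    pam_pattern: str = DEFAULT_PAM,
    protospacer_len: int = DEFAULT_PROTOSPACER_LEN,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[TargetSite]:
    """Find every full-length protospacer+PAM occurrence on both strands.

    Only sites whose protospacer and PAM lie entirely inside the available
    reference (flanks included) are reported; a reference shorter than
    ``protospacer_len + len(pam)`` yields an empty list.  Sites are sorted by
    reference start of the protospacer, then strand ('+' before '-'), and the
    site id is a deterministic function of coordinates and strand.
    """
    if not cs.upstream_flank and not cs.downstream_flank:
        logger.warning(
            "%s: no flanks supplied; scanning restricted to fully in-CDS sites", cs.id
        )
    return scan_reference(cs.reference, pam_pattern, protospacer_len, window)


def scan_reference(
    ref: str,
    pam_pattern: str = DEFAULT_PAM,
    protospacer_len: int = DEFAULT_PROTOSPACER_LEN,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[TargetSite]:
    """Scan a raw reference string (no CDS framing required)."""
    _validate_window(window, protospacer_len)
    plen = len(pam_pattern)
    n = len(ref)
    sites: list[TargetSite] = []
    for i in range(n - plen + 1):
        word = ref[i : i + plen]
        # '+' strand: protospacer immediately 5' of the PAM
        if i >= protospacer_len and iupac_match(word, pam_pattern):
            proto = ref[i - protospacer_len : i]
            sites.append(
                _make_site("+", proto, word, i - protospacer_len, i, plen, window)
            )
        # '-' strand: PAM reads 5'->3' on the reverse complement; on the sense
        # strand it appears as revcomp(pattern) with the protospacer 3' of it
        if i + plen + protospacer_len <= n and iupac_match(
            reverse_complement(word), pam_pattern
        ):
            proto = reverse_complement(ref[i + plen : i + plen + protospacer_len])
            sites.append(
                _make_site(
                    "-", proto, reverse_complement(word), i, i + plen, plen, window
                )
            )
    sites.sort(key=lambda s: (s.protospacer_span[0], 0 if s.strand == "+" else 1))
    counts = Counter(s.protospacer for s in sites)
    sites = [
        s if counts[s.protospacer] == 1
        else _replace_unique(s, False)
        for s in sites
    ]
    return sites


def _replace_unique(site: TargetSite, flag: bool) -> TargetSite:
    import dataclasses

    return dataclasses.replace(site, unique_protospacer=flag)


def _make_site(
    strand: str,
    proto: str,
    pam: str,
    a: int,
    b: int,
    plen: int,
    window: tuple[int, int],
) -> TargetSite:
    lo, hi = window
    if strand == "+":
        proto_span = (a, b)
        pam_span = (b, b + plen)
        win_span = (b + lo, b + hi + 1)
    else:
        pam_span = (a, b)
        proto_span = (b, b + len(proto))
        win_span = (b - 1 - hi, b - lo)
    site_id = f"{proto_span[0] + 1:06d}{strand}"
    return TargetSite(
        site_id=site_id,
        strand=strand,
        protospacer=proto,
        pam=pam,
        protospacer_span=proto_span,
        pam_span=pam_span,
        window_span=win_span,
        window_offsets=tuple(range(lo, hi + 1)),
    )


def _validate_window(window: tuple[int, int], protospacer_len: int) -> None:
    lo, hi = window
    if not (lo <= hi <= -1):
        raise ValueError(f"window {window} must satisfy lo <= hi <= -1")
    if lo < -protospacer_len:
        raise ValueError(
            f"window {window} extends beyond the {protospacer_len}-nt protospacer"
        )


def window_positions(
    cs: CodingSequence,
    site: TargetSite,
    window: tuple[int, int] | None = None,
) -> list[ReferenceCoordinate]:
    """Reference coordinates of the window bases, in ascending reference order.

    For '-' strand sites the PAM-distal end of the window lies at higher
    reference coordinates.
    """
    offsets = site.window_offsets if window is None else tuple(range(window[0], window[1] + 1))
    if window is not None:
        _validate_window(window, len(site.protospacer))
    idx = sorted(site.window_ref_index(o) for o in offsets)
    return [cs.coordinate(i) for i in idx]


def find_editable_cytosines(
    cs: CodingSequence,
    sites: Iterable[TargetSite],
) -> list[EditableCytosine]:
    """One record per (site, window offset) whose base reads C on the site strand.

    Overlapping sites yield duplicate reference positions (distinct site_id);
    use :func:`dedupe_by_position` for a per-position view.
    """
    ref = cs.reference
    out: list[EditableCytosine] = []
    for site in sites:
        for offset in site.window_offsets:
            i = site.window_ref_index(offset)
            if not 0 <= i < len(ref):
                continue
            base = ref[i]
            wanted = "C" if site.strand == "+" else "G"
            if base == wanted:
                out.append(
                    EditableCytosine(
                        site_id=site.site_id,
                        window_offset=offset,
                        edited_strand=site.strand,
                        ref_coordinate=cs.coordinate(i),
                        sense_base=base,
                    )
                )
    return out


def dedupe_by_position(
    ecs: Iterable[EditableCytosine],
) -> dict[tuple[int, str], EditableCytosine]:
    """Deduplicated view keyed by (1-based reference position, strand)."""
    out: dict[tuple[int, str], EditableCytosine] = {}
    for ec in ecs:
        out.setdefault((ec.ref_coordinate.position, ec.edited_strand), ec)
    return out


def in_cds(ecs: Iterable[EditableCytosine]) -> list[EditableCytosine]:
    return [ec for ec in ecs if ec.ref_coordinate.in_cds]


# ---------------------------------------------------------------------------
# tabular / BED export

SITE_COLUMNS = [
    "site_id", "strand", "protospacer", "pam",
    "protospacer_start", "protospacer_end",
    "pam_start", "pam_end", "window_start", "window_end",
    "unique_protospacer",
]

EDITABLE_COLUMNS = [
    "site_id", "window_offset", "edited_strand", "position",
    "cds_position", "codon_index", "codon_offset", "sense_base",
]


def sites_to_table(sites: Sequence[TargetSite]) -> pd.DataFrame:
    rows = [
        (
            s.site_id, s.strand, s.protospacer, s.pam,
            s.protospacer_span[0] + 1, s.protospacer_span[1],
            s.pam_span[0] + 1, s.pam_span[1],
            s.window_span[0] + 1, s.window_span[1],
            s.unique_protospacer,
        )
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def editable_to_table(ecs: Sequence[EditableCytosine]) -> pd.DataFrame:
    rows = [
        (
            ec.site_id, ec.window_offset, ec.edited_strand,
            ec.ref_coordinate.position, ec.ref_coordinate.cds_position,
            ec.ref_coordinate.codon_index, ec.ref_coordinate.codon_offset,
            ec.sense_base,
        )
        for ec in ecs
    ]
    return pd.DataFrame(rows, columns=EDITABLE_COLUMNS)


def sites_to_bed(sites: Sequence[TargetSite], chrom: str) -> str:
    """BED6 of protospacer, PAM and window spans (0-based half-open, score 0)."""
    lines = []
    for s in sites:
        for kind, (a, b) in (
            ("protospacer", s.protospacer_span),
            ("pam", s.pam_span),
            ("window", s.window_span),
        ):
            lines.append(f"{chrom}\t{a}\t{b}\t{s.site_id}_{kind}\t0\t{s.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
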