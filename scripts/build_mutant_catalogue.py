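"""Rebuild the synthetic SPT15 mutant catalogue fixture.

The original per-strain sequencing table behind the 36 reported SPT15
base-edited mutants is not redistributable here, so the fixture
``src/aidscan/data/spt15_mutant_catalogue.synthetic.tsv`` is a synthetic
reconstruction: each reported protein label (e.g. A140G, A101P/V102I) is
inverted to the nucleotide change set that produces it under the editor's
constraints — every edited base must read C on one strand, all edits of a
strain must fall inside a single NGG-site editing window (-20..-13) on that
strand, and no other codon may change.  When several change sets qualify,
the minimal one is taken, tie-broken by the editor's product frequency
(T, then G, then A) and then by position.

Labels that are unreachable by cytosine editing (the reported "R238R" — a
synonymous label, presumably a typo for R238K) are listed in the output
header comment and omitted from the rows.  Synonymous bystander edits in the
original data leave no trace in the labels and are necessarily absent.

Run from the repository root:  python scripts/build_mutant_catalogue.py
"""

from __future__ import annotations

import itertools
from pathlib import Path

from aidscan import find_editable_cytosines, in_cds, scan_pams
from aidscan.consequence import build_outcome
from aidscan.data import load_reference

# strain labels as reported for the 36 SPT15 mutants (batch annotations dropped)
REPORTED_LABELS = [
    "A2V", "A2D", "R6C", "R6G", "E9K", "P20L", "P20R", "W26S", "W26C",
    "T38I", "T38S", "S42N", "D56E", "P65L", "V71I", "V71L",
    "A101P/V102I", "V102L", "S118L", "T124S", "T124I", "A140G",
    "R141K", "R141T", "A150P", "A150T", "P169A", "G174V", "P187A",
    "P191C", "M197I", "L214F", "L214V", "R238K", "R238T", "R238R",
]

ALT_PREFERENCE = "TGA"  # canonical product first, then the minority products


def parse_label(label: str) -> list[tuple[int, str, str]]:
    out = []
    for part in label.split("/"):
        out.append((int(part[1:-1]), part[0], part[-1]))
    return out


def reconstruct(cs, labels):
    sites = scan_pams(cs)
    ecs = in_cds(find_editable_cytosines(cs, sites))
    by_site: dict[str, list] = {}
    for ec in ecs:
        by_site.setdefault(ec.site_id, []).append(ec)
    table = cs.codon_table
    found, unreachable = {}, []
    for label in labels:
        want = sorted(parse_label(label))
        candidates = []
        for site_id, site_ecs in by_site.items():
            site_ecs = sorted(site_ecs, key=lambda e: e.ref_coordinate.position)
            for k in (1, 2, 3):
                for combo in itertools.combinations(site_ecs, k):
                    for alts in itertools.product(ALT_PREFERENCE, repeat=k):
                        outcome = build_outcome(cs, site_id, list(zip(combo, alts)))
                        got = sorted(
                            (idx, table.aa(r), table.aa(a))
                            for idx, r, a in outcome.codon_changes
                            if table.aa(r) != table.aa(a)
                        )
                        # synonymous labels (X -> X) must match a synonymous change
                        if not got and outcome.codon_changes and all(w[1] == w[2] for w in want):
                            got = sorted(
                                (idx, table.aa(r), table.aa(a))
                                for idx, r, a in outcome.codon_changes
                            )
                        extra_codons = len(outcome.codon_changes) - len(
                            {idx for idx, _, _ in got}
                        )
                        if got == want and extra_codons == 0:
                            candidates.append(list(zip(combo, alts)))
        if not candidates:
            unreachable.append(label)
            continue
        candidates.sort(
            key=lambda edits: (
                len(edits),
                tuple(ALT_PREFERENCE.index(alt) for _, alt in edits),
                tuple(ec.ref_coordinate.position for ec, _ in edits),
            )
        )
        found[label] = candidates[0]
    return found, unreachable


def main():
    cs = load_reference("SPT15", flank=23)
    found, unreachable = reconstruct(cs, REPORTED_LABELS)
    out = Path(__file__).resolve().parents[1] / (
        "src/aidscan/data/spt15_mutant_catalogue.synthetic.tsv"
    )
    lines = [
        "# synthetic reconstruction of the SPT15 base-edited mutant catalogue",
        "# nucleotide changes inferred from reported protein labels under",
        "# single-site editing-window constraints; synonymous bystander edits",
        "# are not recoverable and absent; ref/alt are on the edited strand",
        f"# unreachable_labels={','.join(unreachable) or 'none'}",
        "strain_id\treported_label\tcds_position\tedited_strand\tref_base\talt_base",
    ]
    for label, edits in found.items():
        for ec, alt in edits:
            lines.append(
                f"{label}\t{label}\t{ec.ref_coordinate.cds_position}\t"
                f"{ec.edited_strand}\tC\t{alt}"
            )
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}: {len(found)} strains, "
          f"{sum(len(v) for v in found.values())} edited bases; "
          f"unreachable: {unreachable or 'none'}")


if __name__ == "__main__":
    main()
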