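"""Splice-junction classification and Dollo-parsimony gain placement.

Spliceosomal introns almost universally begin with GT (donor) and end with AG
(acceptor). Given per-species aligned intron slices, this module classifies
each junction as canonical, non-canonical, absent, or unknown, assembles a
junction-by-species state matrix, and places the origination of each junction
on a phylogeny under Dollo parsimony: a single gain on the stem branch of the
smallest clade containing every species carrying the junction, with any
carrier-free known-state leaves inside that clade counted as implied losses.

Input slices are assumed pre-oriented on the transcribed strand; no
reverse-complementing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import dendropy
import pandas as pd

STATES = ("present_canonical", "present_noncanonical", "absent", "unknown")


@dataclass(frozen=True)
class JunctionCall:
    """Donor/acceptor dinucleotide state of one junction in one species."""

    junction_id: str
    species: str
    donor: str
    acceptor: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        for dinuc in (self.donor, self.acceptor):
            if dinuc and (len(dinuc) != 2 or set(dinuc) - set("ACGTN")):
                raise ValueError(f"invalid dinucleotide {dinuc!r}")


def classify_junction(junction_id: str, species: str, intron_slice: str) -> JunctionCall:
    """Classify one species' intron slice by its terminal dinucleotides.

    The slice must span the whole intron (both termini); '-' gaps are allowed.
    canonical iff donor == GT and acceptor == AG; any other ungapped pair is
    present_noncanonical with the pair recorded; a gapped or N terminus, or a
    slice with fewer than 4 ungapped bases, is unknown; an entirely gapped
    slice is absent.
    """
    s = intron_slice.upper()
    if set(s) - set("ACGTN-"):
        raise ValueError("intron slice must be over A/C/G/T/N/-")
    ungapped = s.replace("-", "")
    if not ungapped:
        return JunctionCall(junction_id, species, "", "", "absent")
    if len(ungapped) < 4:
        return JunctionCall(junction_id, species, "", "", "unknown")
    donor, acceptor = s[:2], s[-2:]
    if "-" in donor or "-" in acceptor or "N" in donor or "N" in acceptor:
        return JunctionCall(junction_id, species, "", "", "unknown")
    state = (
        "present_canonical"
        if donor == "GT" and acceptor == "AG"
        else "present_noncanonical"
    )
    return JunctionCall(junction_id, species, donor, acceptor, state)


def build_junction_matrix(calls: Iterable[JunctionCall]) -> pd.DataFrame:
    """Junction x species state matrix; missing cells are 'unknown'.

    Duplicate (junction, species) calls with conflicting states raise.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("at least one junction call required")
    seen: dict[tuple[str, str], str] = {}
    for c in calls:
        key = (c.junction_id, c.species)
        if key in seen and seen[key] != c.state:
            raise ValueError(
                f"conflicting duplicate call for junction {c.junction_id!r} "
                f"in {c.species!r}: {seen[key]} vs {c.state}"
            )
        seen[key] = c.state
    junctions = sorted({j for j, _ in seen})
    species = sorted({s for _, s in seen})
    if len(species) < 2:
        raise ValueError("at least two species required")
    mat = pd.DataFrame("unknown", index=junctions, columns=species)
    for (j, s), state in seen.items():
        mat.loc[j, s] = state
    return mat


@dataclass(frozen=True)
class GainResult:
    """Dollo placement of a junction gain on a tree."""

    gained: bool
    branch: frozenset[str]  # leaves of the clade whose stem carries the gain
    losses: int
    ambiguous: bool

    def describe(self) -> str:
        if not self.gained:
            return "no gain (no species carries the junction)"
        leaves = "+".join(sorted(self.branch))
        flag = " [ambiguous]" if self.ambiguous else ""
        return f"stem of ({leaves}), {self.losses} implied losses{flag}"


def _leaf_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label if leaf.taxon else str(leaf)


def infer_gain_branch(
    states: Mapping[str, str],
    tree: dendropy.Tree,
    criterion: str = "canonical_only",
) -> GainResult:
    """Place a single junction gain on the tree under Dollo parsimony.

    ``states`` maps species to a junction state; every named species must be
    a tree leaf (tree leaves without a call are treated as unknown).
    ``criterion`` selects which states count as carrying the junction:
    ``canonical_only`` counts only present_canonical, ``any_present`` also
    counts present_noncanonical. Unknown-state species impose no constraint
    and never create losses. When several branches are equally parsimonious
    (possible only through unknown-state leaves) the most rootward one is
    reported and the result is flagged ambiguous.
    """
    if criterion == "canonical_only":
        targets_states = {"present_canonical"}
    elif criterion == "any_present":
        targets_states = {"present_canonical", "present_noncanonical"}
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    leaf_labels = {_leaf_label(l) for l in tree.leaf_node_iter()}
    unknown_species = set(states) - leaf_labels
    if unknown_species:
        raise ValueError(f"species not in tree: {sorted(unknown_species)}")
    carriers = {sp for sp, st in states.items() if st in targets_states}
    known_absent = {
        sp
        for sp, st in states.items()
        if st not in targets_states and st != "unknown"
    }
    if not carriers:
        return GainResult(False, frozenset(), 0, False)
    best: Optional[tuple[int, int, frozenset[str]]] = None
    n_best = 0
    for node in tree.preorder_node_iter():
        clade = frozenset(_leaf_label(l) for l in node.leaf_iter())
        if not carriers <= clade:
            continue
        cost = len(clade & known_absent)
        key = (cost, -len(clade))
        if best is None or key < (best[0], best[1]):
            best = (cost, -len(clade), clade)
            n_best = 1
        elif cost == best[0]:
            n_best += 1
    assert best is not None
    return GainResult(True, best[2], best[0], n_best > 1)


def gain_report(
    matrix: pd.DataFrame, tree: dendropy.Tree, criterion: str = "canonical_only"
) -> pd.DataFrame:
    """Dollo gain placement for every junction row of a state matrix."""
    rows = []
    for junction_id, row in matrix.iterrows():
        res = infer_gain_branch(row.to_dict(), tree, criterion)
        rows.append(
            {
                "junction_id": junction_id,
                "gained": res.gained,
                "gain_clade": "+".join(sorted(res.branch)),
                "implied_losses": res.losses,
                "ambiguous": res.ambiguous,
            }
        )
    return pd.DataFrame(rows)
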