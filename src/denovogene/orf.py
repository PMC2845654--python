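"""ORF discovery and cross-species frame-disabler / enabler analysis.

Given a transcript and an alignment of orthologous genomic sequence from
several species against a designated reference, this module finds open
reading frames, projects the reference CDS onto every other species, reports
frame-disrupting features (premature stop codons and frameshifting indels) in
non-reference lineages, and identifies focal-lineage "enabler" substitutions
that removed an ancestral disabler — the signature of a de novo ORF that
exists only on the focal branch.

Codon indices are 1-based over the amino acids of the reference ORF; the stop
codon is index n_codons + 1, matching the "amino acid position k" convention
used when describing such events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .popgen import is_stop, translate_codon

_DNA = set("ACGTN-")


@dataclass(frozen=True)
class OrthologAlignment:
    """Gapped, equal-length orthologous sequences with a designated reference."""

    species: tuple[str, ...]
    rows: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        if len(self.species) != len(self.rows):
            raise ValueError("one row per species required")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            for name, row in zip(self.species, self.rows):
                if len(row) != len(self.rows[0]):
                    raise ValueError(
                        f"ragged alignment: row {name!r} has length {len(row)}, "
                        f"expected {len(self.rows[0])}"
                    )
        if self.reference not in self.species:
            raise ValueError(f"reference {self.reference!r} not among species")
        for name, row in zip(self.species, self.rows):
            bad = set(row) - _DNA
            if bad:
                raise ValueError(f"row {name!r} contains invalid symbols {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def ungapped(self, species: str) -> str:
        return self.row(species).replace("-", "")


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated, stop-terminated reading frame.

    ``n_codons`` counts amino acids (stop excluded); ``cds_len_bp`` includes
    the stop codon, so cds_len_bp == 3 * (n_codons + 1).
    """

    start: int
    n_codons: int
    cds_len_bp: int
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.cds_len_bp != 3 * (self.n_codons + 1):
            raise ValueError("cds_len_bp must equal 3*(n_codons + 1)")
        if self.start < 0 or self.n_codons < 1:
            raise ValueError("invalid ORF coordinates")

    @property
    def end(self) -> int:
        """Exclusive end offset in the transcript (past the stop codon)."""
        return self.start + self.cds_len_bp


@dataclass(frozen=True)
class DisablerEvent:
    """A frame-disrupting feature in a non-reference species."""

    species: str
    kind: str  # premature_stop | frameshift
    codon_index: int
    detail: str  # observed codon, or "+k"/"-k" net indel with phase
    compensated: bool = False


@dataclass(frozen=True)
class EnablerSubstitution:
    """A focal-lineage change that removed an ancestral disabler."""

    codon_index: int
    ancestral: str
    derived: str
    removes: str  # premature_stop | frameshift

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived states must differ")


def scan_orfs(
    transcript: str, min_codons: int, include_ambiguous: bool = False
) -> list[Orf]:
    """All ATG-initiated, stop-terminated ORFs in the three forward frames.

    Returns ORFs with at least ``min_codons`` amino acids, sorted by length
    descending with ties broken by the 5'-most start. An ORF whose span
    contains an N is flagged ambiguous and excluded unless requested.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = transcript.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("transcript must be over A/C/G/T/N")
    found: list[Orf] = []
    from bisect import bisect_right

    for frame in range(3):
        # positions of in-frame stops, scanned once per frame
        stop_positions = [
            p for p in range(frame, len(seq) - 2, 3) if is_stop(seq[p : p + 3])
        ]
        for p in range(frame, len(seq) - 2, 3):
            if seq[p : p + 3] != "ATG":
                continue
            si = bisect_right(stop_positions, p)
            nxt = stop_positions[si] if si < len(stop_positions) else None
            if nxt is None:
                continue
            n_codons = (nxt - p) // 3
            if n_codons < min_codons:
                continue
            ambiguous = "N" in seq[p : nxt + 3]
            found.append(Orf(start=p, n_codons=n_codons, cds_len_bp=nxt + 3 - p, ambiguous=ambiguous))
    if not include_ambiguous:
        found = [o for o in found if not o.ambiguous]
    return sorted(found, key=lambda o: (-o.n_codons, o.start))


@dataclass(frozen=True)
class CodonAlignment:
    """One reference codon as seen in one species.

    ``bases`` are the species characters aligned to the three reference codon
    columns (may include '-'); ``insertions`` lists (after_offset, bases) for
    species bases sitting in columns where the reference is gapped, attached
    after base ``after_offset`` (0..2) of this codon.
    """

    ref_codon: str
    bases: str
    insertions: tuple[tuple[int, str], ...] = ()

    @property
    def net_indel(self) -> int:
        return sum(len(b) for _, b in self.insertions) - self.bases.count("-")

    def render(self) -> str:
        """Codon string with insertion bases interleaved (e.g. 'GGAA')."""
        out = []
        for i, b in enumerate(self.bases):
            out.append(b)
            for off, ins in self.insertions:
                if off == i:
                    out.append(ins)
        return "".join(out)

    def state(self) -> tuple[str, tuple[tuple[int, str], ...]]:
        return (self.bases, self.insertions)


@dataclass(frozen=True)
class CdsProjection:
    """Per-species view of the reference CDS through the alignment."""

    reference: str
    species: tuple[str, ...]
    n_codons: int
    codons: Mapping[str, tuple[CodonAlignment, ...]]
    missing: frozenset[str]

    def events_possible(self, sp: str) -> bool:
        return sp not in self.missing


def project_cds(aln: OrthologAlignment, orf: Orf) -> CdsProjection:
    """Project the reference ORF onto every species row.

    The ORF is given in ungapped reference coordinates. For each species the
    bases aligned to each reference codon's columns are collected, and bases
    in columns where the reference row is gapped are recorded as insertions
    attached to the codon position they follow. A species whose row is
    entirely gapped across the CDS is flagged missing.
    """
    ref_row = aln.row(aln.reference)
    ref_cols = [i for i, c in enumerate(ref_row) if c != "-"]
    if orf.end > len(ref_cols):
        raise ValueError("ORF extends beyond the reference row's ungapped span")
    n_total = orf.n_codons + 1  # amino acids + stop
    cds_cols = ref_cols[orf.start : orf.end]
    codons: dict[str, tuple[CodonAlignment, ...]] = {}
    missing = set()
    for sp in aln.species:
        row = aln.row(sp)
        per_codon: list[CodonAlignment] = []
        any_base = False
        for ci in range(n_total):
            cols = cds_cols[3 * ci : 3 * ci + 3]
            bases = "".join(row[c] for c in cols)
            ref_codon = "".join(ref_row[c] for c in cols)
            ins: list[tuple[int, str]] = []
            for off in range(3):
                col = cols[off]
                nxt = cds_cols[3 * ci + off + 1] if 3 * ci + off + 1 < len(cds_cols) else None
                stop_at = nxt if nxt is not None else col + 1
                if stop_at > col + 1:
                    chunk = "".join(
                        row[c] for c in range(col + 1, stop_at) if row[c] != "-"
                    )
                    if chunk:
                        ins.append((off, chunk))
            if bases.strip("-") or ins:
                any_base = True
            per_codon.append(CodonAlignment(ref_codon, bases, tuple(ins)))
        codons[sp] = tuple(per_codon)
        if not any_base:
            missing.add(sp)
    return CdsProjection(
        reference=aln.reference,
        species=aln.species,
        n_codons=orf.n_codons,
        codons=codons,
        missing=frozenset(missing),
    )


def detect_disablers(projection: CdsProjection) -> dict[str, list[DisablerEvent]]:
    """Frame-disrupting features per species relative to the reference ORF.

    Premature stops are reported at every in-frame stop codon before the
    reference stop; a codon is only read while the cumulative net indel
    length upstream is 0 mod 3 (after an uncompensated frameshift the frame
    is undefined and stop calls are suppressed). Frameshifts are reported at
    every codon whose net indel length is not 0 mod 3; if the species' total
    net indel over the CDS restores frame, its frameshift events are flagged
    compensated. Codons containing N are excluded from stop calls.
    """
    out: dict[str, list[DisablerEvent]] = {}
    for sp in projection.species:
        events: list[DisablerEvent] = []
        if sp in projection.missing:
            out[sp] = events
            continue
        net = 0
        shifts: list[DisablerEvent] = []
        for ci, codon in enumerate(projection.codons[sp], start=1):
            if ci > projection.n_codons:
                break  # reference stop codon: not a site for premature events
            in_frame = net % 3 == 0
            if (
                in_frame
                and "-" not in codon.bases
                and "N" not in codon.bases
                and is_stop(codon.bases)
                and not is_stop(codon.ref_codon)
            ):
                events.append(
                    DisablerEvent(sp, "premature_stop", ci, codon.bases)
                )
            delta = codon.net_indel
            if delta % 3 != 0:
                ev = DisablerEvent(
                    sp,
                    "frameshift",
                    ci,
                    f"{delta:+d} (phase {(net + delta) % 3})",
                )
                events.append(ev)
                shifts.append(ev)
            net += delta
        if shifts and net % 3 == 0:
            compensated = [
                DisablerEvent(e.species, e.kind, e.codon_index, e.detail, True)
                for e in shifts
            ]
            events = [
                compensated[shifts.index(e)] if e in shifts else e for e in events
            ]
        out[sp] = sorted(events, key=lambda e: e.codon_index)
    return out


def _ancestral_state(
    projection: CdsProjection, ci0: int, focal: str
) -> Optional[CodonAlignment]:
    """Majority codon state among non-focal species; ties yield None."""
    states = []
    for sp in projection.species:
        if sp == focal or sp in projection.missing:
            continue
        states.append(projection.codons[sp][ci0])
    if not states:
        return None
    counts = Counter(c.state() for c in states)
    ranked = counts.most_common()
    # strict majority: more than half the votes, so ties and mere
    # pluralities leave the ancestral state unknown
    if 2 * ranked[0][1] <= len(states):
        return None
    winner = ranked[0][0]
    ref_codon = states[0].ref_codon
    return CodonAlignment(ref_codon, winner[0], winner[1])


def infer_enablers(
    aln: OrthologAlignment,
    projection: CdsProjection,
    focal: Optional[str] = None,
) -> list[EnablerSubstitution]:
    """Focal-lineage substitutions that removed an ancestral disabler.

    The ancestral state at each codon is the strict majority (more than half)
    among non-focal species; a tie or mere plurality leaves the state unknown
    and the position is skipped. A
    position is an enabler when the ancestral state would be a disabler of
    the reference frame (a stop codon, or a frame-shifting indel) while the
    focal state is not.
    """
    focal = focal or projection.reference
    others = [
        sp for sp in projection.species if sp != focal and sp not in projection.missing
    ]
    if not others:
        raise ValueError("all non-focal species are missing over the CDS")
    if len(others) < 2:
        raise ValueError("need at least 2 non-focal species to vote an ancestral state")
    enablers: list[EnablerSubstitution] = []
    for ci0 in range(projection.n_codons):  # amino-acid codons only
        anc = _ancestral_state(projection, ci0, focal)
        if anc is None:
            continue
        foc = projection.codons[focal][ci0]
        if anc.state() == foc.state():
            continue
        anc_is_stop = (
            "-" not in anc.bases and "N" not in anc.bases and is_stop(anc.bases)
        )
        foc_is_stop = (
            "-" not in foc.bases and "N" not in foc.bases and is_stop(foc.bases)
        )
        if anc_is_stop and not foc_is_stop:
            slots = sorted({off for off, _ in anc.insertions + foc.insertions})
            enablers.append(
                EnablerSubstitution(
                    codon_index=ci0 + 1,
                    ancestral=_render_with_slots(anc, slots),
                    derived=_render_with_slots(foc, slots),
                    removes="premature_stop",
                )
            )
            continue
        if anc.net_indel % 3 != 0 and foc.net_indel % 3 == 0:
            slots = _union_slots(anc, foc)
            enablers.append(
                EnablerSubstitution(
                    codon_index=ci0 + 1,
                    ancestral=_render_with_slots(anc, slots),
                    derived=_render_with_slots(foc, slots),
                    removes="frameshift",
                )
            )
    return enablers


def _union_slots(*codons: CodonAlignment) -> list[tuple[int, int]]:
    """Insertion slots (after_offset, length) present in any of the codons."""
    slots: dict[int, int] = {}
    for c in codons:
        for off, bases in c.insertions:
            slots[off] = max(slots.get(off, 0), len(bases))
    return sorted(slots.items())


def _render_with_slots(codon: CodonAlignment, slots) -> str:
    """Render a codon padding absent insertion slots with '-' (e.g. 'G-AA')."""
    if slots and isinstance(slots[0], int):  # plain offsets, length 1 each
        slots = [(s, 1) for s in slots]
    mine = dict(codon.insertions)
    out = []
    for i, b in enumerate(codon.bases):
        out.append(b)
        for off, width in slots:
            if off == i:
                ins = mine.get(off, "")
                out.append(ins + "-" * (width - len(ins)))
    return "".join(out)


def classify_variation(aln: OrthologAlignment, orf: Orf) -> pd.DataFrame:
    """Per-codon divergence table versus the reference.

    For every non-reference species and every amino-acid codon that differs
    from the reference, reports the kind of change: ``synonymous``,
    ``nonsynonymous`` (any amino-acid change, including multi-hit codons and
    stop gains), or ``indel`` when gaps or insertions make the codon
    incomparable base-by-base. Codons containing N are skipped as uncertain.
    """
    projection = project_cds(aln, orf)
    rows = []
    for sp in aln.species:
        if sp == aln.reference or sp in projection.missing:
            continue
        for ci0 in range(orf.n_codons):
            codon = projection.codons[sp][ci0]
            if codon.bases == codon.ref_codon and not codon.insertions:
                continue
            if "N" in codon.bases or "N" in codon.ref_codon:
                continue
            if "-" in codon.bases or codon.insertions:
                kind = "indel"
            else:
                ref_aa = translate_codon(codon.ref_codon)
                other_aa = translate_codon(codon.bases)
                kind = "synonymous" if ref_aa == other_aa else "nonsynonymous"
            rows.append(
                {
                    "species": sp,
                    "codon_index": ci0 + 1,
                    "ref_codon": codon.ref_codon,
                    "other_codon": codon.render(),
                    "kind": kind,
                }
            )
    return pd.DataFrame(rows, columns=["species", "codon_index", "ref_codon", "other_codon", "kind"])
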