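"""Synthetic inputs for every pipeline stage: coalescent population samples,
ortholog alignments with planted evolutionary events, and screen fixtures.

The coalescent simulator follows the standard neutral model with time in
units of 2N generations: with k lineages the waiting time to the next
coalescence is exponential with rate k(k-1)/2, and infinite-sites mutations
fall on branches as a Poisson process of rate theta/2 per lineage per unit
time. ``theta`` is therefore the region-scaled population mutation rate,
the same parameterisation as the segregating-sites recursion in
:mod:`denovogene.popgen`, so the two are directly comparable oracles.

``evolve_orthologs`` grows an alignment down a phylogeny from an annotated
ancestral sequence under Jukes-Cantor background substitution (no background
indels) and applies planted events — substitutions, premature stops,
frameshifting indels, junction gains/losses — on named branches. The
generative alignment is exact by construction and a truth table of every
planted event per leaf is returned alongside it.

Background substitutions are rejected when they would create or destroy an
in-frame stop codon (read in the reference frame) or touch an annotated
junction dinucleotide, so planted events are provably the only frame- or
junction-relevant differences between species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np

from .formats import GeneModel, GenomicInterval
from .orf import OrthologAlignment
from .popgen import SnpRecord, is_stop
from .screen import (
    AssociationStudy,
    GeneAnnotation,
    LinkageStudy,
    SnpAssociation,
)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# neutral coalescent


@dataclass(frozen=True)
class CoalescentSample:
    """One infinite-sites coalescent sample.

    ``sites`` holds (position in [0,1), derived allele count) pairs sorted by
    position; ``total_tree_length`` is in units of 2N generations.
    """

    n: int
    theta: float
    seed: Optional[int]
    sites: tuple[tuple[float, int], ...]
    total_tree_length: float

    @property
    def n_segregating(self) -> int:
        return len(self.sites)


def _coalescent_branches(n: int, rng: np.random.Generator):
    """Branch (leaf count, length) pairs of one random genealogy.

    Returns (counts, lengths, total_length). Every branch below the MRCA is
    included; derived-allele counts of mutations on a branch equal its
    subtended leaf count.
    """
    exp = rng.exponential(size=n - 1)
    u = rng.random(size=2 * (n - 1))
    birth = [0.0] * n
    leaves = [1] * n
    lens = np.empty(2 * n - 2)
    cnts = np.empty(2 * n - 2, dtype=np.int64)
    t = 0.0
    out = 0
    ui = 0
    for k in range(n, 1, -1):
        t += exp[n - k] * 2.0 / (k * (k - 1))
        i = int(u[ui] * k)
        ui += 1
        b1, c1 = birth[i], leaves[i]
        birth[i], leaves[i] = birth[k - 1], leaves[k - 1]  # swap-remove
        j = int(u[ui] * (k - 1))
        ui += 1
        b2, c2 = birth[j], leaves[j]
        lens[out] = t - b1
        cnts[out] = c1
        lens[out + 1] = t - b2
        cnts[out + 1] = c2
        out += 2
        birth[j], leaves[j] = t, c1 + c2
    return cnts, lens, float(lens.sum())


def simulate_coalescent(
    n: int,
    theta: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CoalescentSample:
    """Draw one neutral infinite-sites sample of n chromosomes.

    Mutations are Poisson with mean theta/2 x branch length per branch and
    placed uniformly on [0, 1); each mutation's derived count is the leaf
    count subtended by its branch. Fully reproducible from ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    cnts, lens, total = _coalescent_branches(n, rng)
    muts = rng.poisson(theta / 2.0 * lens)
    sites = []
    for m, c in zip(muts, cnts):
        if m:
            for pos in rng.random(int(m)):
                sites.append((float(pos), int(c)))
    sites.sort()
    return CoalescentSample(n, theta, seed, tuple(sites), total)


def sample_segregating_counts(
    n: int, theta: float, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised draws of S over many replicates (topology-free).

    S depends on the genealogy only through its total length
    L = sum_k k T_k, so replicates can be drawn without building trees:
    S ~ Poisson(theta/2 x L). Distributionally identical to counting sites
    from :func:`simulate_coalescent` (checked in the test suite).
    """
    ks = np.arange(n, 1, -1)
    waits = rng.exponential(
        scale=2.0 / (ks * (ks - 1)), size=(reps, n - 1)
    )
    totals = waits @ ks
    return rng.poisson(theta / 2.0 * totals)


def simulate_popgen_region(
    lengths: Mapping[str, int],
    theta_per_site: Mapping[str, float],
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    locus_id: str = "sim",
) -> list[SnpRecord]:
    """Simulated SNP table over consecutive site-class blocks.

    For each class the number of segregating sites and their derived counts
    come from one coalescent genealogy at region rate theta_per_site x l;
    positions are distinct and uniform within the class's coordinate block.
    A class with rate 0 yields no SNPs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records: list[SnpRecord] = []
    offset = 0
    for cls, l in lengths.items():
        l = int(l)
        if l <= 0:
            raise ValueError(f"length for class {cls!r} must be > 0")
        rate = theta_per_site.get(cls, 0.0)
        if rate > 0:
            cnts, lens, _ = _coalescent_branches(n, rng)
            muts = rng.poisson(rate * l / 2.0 * lens)
            derived = np.repeat(cnts, muts)
            S = len(derived)
            if S > l:
                raise ValueError(
                    f"class {cls!r}: drew {S} segregating sites for only {l} bp"
                )
            positions = rng.choice(l, size=S, replace=False)
            order = np.argsort(positions)
            for pos, d in zip(positions[order], derived[order]):
                ref, alt = rng.choice(list(_BASES), size=2, replace=False)
                records.append(
                    SnpRecord(
                        position=offset + int(pos),
                        ref=str(ref),
                        alt=str(alt),
                        alt_count=int(d),
                        n_chromosomes=n,
                        site_class=cls,
                        locus_id=locus_id,
                    )
                )
        offset += l
    return records


# ---------------------------------------------------------------------------
# ortholog alignments with planted events


@dataclass(frozen=True)
class PlantedEventSpec:
    """One planted evolutionary event on a named branch.

    ``branch`` is a leaf name (terminal branch), an iterable of leaf names
    (the stem branch of their smallest containing clade), or ``"root"`` (the
    ancestral sequence itself, inherited by every leaf). ``kind`` is one of
    substitution | premature_stop | frameshift_indel | junction_gain |
    junction_loss. ``location`` is a 1-based codon index for codon events or
    a junction id. ``payload``: replacement codon for substitutions (default
    TAG for premature stops), "+BASES" / "-k" for insertions and deletions,
    or "DD,AA" donor/acceptor dinucleotides for junction events.
    """

    branch: Union[str, tuple[str, ...], frozenset]
    kind: str
    location: Union[int, str]
    payload: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (
            "substitution",
            "premature_stop",
            "frameshift_indel",
            "junction_gain",
            "junction_loss",
        ):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if isinstance(self.branch, (list, tuple, set, frozenset)):
            object.__setattr__(self, "branch", frozenset(self.branch))

    @property
    def indel_delta(self) -> int:
        if self.kind != "frameshift_indel":
            return 0
        if self.payload.startswith("-"):
            return -int(self.payload[1:])
        return len(self.payload.lstrip("+"))


@dataclass(frozen=True)
class AncestralLocus:
    """The root sequence with its feature map.

    ``orf_start`` is the 0-based offset of the reference ORF's ATG in the
    root sequence; ``orf_codons`` its amino-acid count. ``junctions`` maps a
    junction id to the 0-based offsets of the donor and acceptor
    dinucleotides (each spanning two bases, donor at the intron 5' end).
    """

    seq: str
    orf_start: Optional[int] = None
    orf_codons: Optional[int] = None
    junctions: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if set(self.seq) - set(_BASES):
            raise ValueError("root sequence must be over A/C/G/T")
        if self.orf_start is not None:
            if self.orf_codons is None:
                raise ValueError("orf_codons required with orf_start")
            end = self.orf_start + 3 * (self.orf_codons + 1)
            if end > len(self.seq):
                raise ValueError("ORF extends beyond the root sequence")


@dataclass(frozen=True)
class OrthologTruth:
    """Ground truth of planted events, per leaf."""

    disablers: Mapping[str, tuple[tuple[str, int], ...]]  # species -> (kind, codon)
    enablers: tuple[tuple[int, str], ...]  # (codon, removes) on the focal leaf
    junction_states: Mapping[str, Mapping[str, str]]  # junction -> species -> state
    junction_gain_branch: Mapping[str, frozenset]  # junction -> gained clade leaves


@dataclass(frozen=True)
class EvolvedFixture:
    alignment: OrthologAlignment
    truth: OrthologTruth
    ref_columns: tuple[int, ...]  # root-sequence index -> alignment column


def _resolve_branch(tree: dendropy.Tree, spec) -> dendropy.Node:
    if isinstance(spec, str):
        if spec == "root":
            return tree.seed_node
        for leaf in tree.leaf_node_iter():
            if leaf.taxon and leaf.taxon.label == spec:
                return leaf
        raise ValueError(f"branch leaf {spec!r} not in tree")
    taxa = [tree.taxon_namespace.get_taxon(lbl) for lbl in spec]
    if any(t is None for t in taxa):
        raise ValueError(f"branch clade {sorted(spec)} has taxa missing from tree")
    node = tree.mrca(taxa=taxa)
    if node is None:
        raise ValueError(f"no MRCA for clade {sorted(spec)}")
    return node


def _leaf_labels(node: dendropy.Node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def evolve_orthologs(
    tree: dendropy.Tree,
    root: AncestralLocus,
    events: Sequence[PlantedEventSpec],
    background_rate: float = 0.0,
    seed: Optional[int] = None,
    reference: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> EvolvedFixture:
    """Evolve a generative ortholog alignment with planted events.

    Sequences descend the tree under Jukes-Cantor substitution at
    ``background_rate`` expected substitutions per site per unit branch
    length (branches without lengths count as length 1); planted events are
    applied on their branches after background mutation, so they override it.
    Insertions open gap columns in all other rows; the returned alignment is
    the true generative alignment. ``reference`` names the focal leaf
    (defaults to the first leaf) used for codon coordinates and enabler truth.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree.is_rooted = True  # branch resolution treats the seed node as root
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    reference = reference or leaves[0]
    if reference not in leaves:
        raise ValueError(f"reference {reference!r} is not a leaf")

    # conflicting events: same branch + same location
    node_of = {id(ev): _resolve_branch(tree, ev.branch) for ev in events}
    seen: dict[tuple[int, object], str] = {}
    for ev in events:
        key = (id(node_of[id(ev)]), ev.location)
        if key in seen and seen[key] != ev.kind:
            raise ValueError(
                f"conflicting events at location {ev.location!r} on one branch: "
                f"{seen[key]} vs {ev.kind}"
            )
        seen.setdefault(key, ev.kind)

    # global columns: root positions plus one block per insertion event
    L = len(root.seq)
    insertions = [
        ev for ev in events if ev.kind == "frameshift_indel" and ev.indel_delta > 0
    ]

    def codon_cols_start(codon: int) -> int:
        assert root.orf_start is not None
        return root.orf_start + 3 * (codon - 1)

    columns: list[tuple[str, object]] = [("ref", i) for i in range(L)]
    for ev in insertions:
        after = codon_cols_start(int(ev.location))  # after first base of codon
        idx = next(
            i for i, c in enumerate(columns) if c == ("ref", after)
        )
        block = [("ins", (id(ev), k)) for k in range(ev.indel_delta)]
        columns[idx + 1 : idx + 1] = block
    col_of_ref = {c[1]: i for i, c in enumerate(columns) if c[0] == "ref"}
    ins_cols = {
        id(ev): [i for i, c in enumerate(columns) if c[0] == "ins" and c[1][0] == id(ev)]
        for ev in insertions
    }

    root_row = ["-"] * len(columns)
    for i, c in enumerate(columns):
        if c[0] == "ref":
            root_row[i] = root.seq[c[1]]

    # columns protected from background substitution: junction dinucleotides
    junction_cols = set()
    for d, a in root.junctions.values():
        junction_cols.update(col_of_ref[p] for p in (d, d + 1, a, a + 1))
    cds_codon_cols: list[tuple[int, ...]] = []
    if root.orf_start is not None:
        for ci in range(root.orf_codons + 1):  # amino acids + stop
            p = root.orf_start + 3 * ci
            cds_codon_cols.append(tuple(col_of_ref[p + k] for k in range(3)))
    codon_of_col = {
        col: ci for ci, cols in enumerate(cds_codon_cols) for col in cols
    }

    events_by_node: dict[int, list[PlantedEventSpec]] = {}
    for ev in events:
        events_by_node.setdefault(id(node_of[id(ev)]), []).append(ev)

    def apply_event(row: list[str], ev: PlantedEventSpec) -> None:
        if ev.kind in ("substitution", "premature_stop"):
            codon = int(ev.location)
            payload = ev.payload or ("TAG" if ev.kind == "premature_stop" else "")
            if len(payload) != 3 or set(payload) - set(_BASES):
                raise ValueError(f"codon payload must be 3 bases, got {payload!r}")
            for k, col in enumerate(cds_codon_cols[codon - 1]):
                row[col] = payload[k]
        elif ev.kind == "frameshift_indel":
            if ev.indel_delta > 0:
                payload = ev.payload.lstrip("+")
                for col, base in zip(ins_cols[id(ev)], payload):
                    row[col] = base
            else:
                # deletions start after the codon's first base, the same slot
                # insertions occupy, so a deletion exactly reverts a rootward
                # insertion at the same location
                start_col = cds_codon_cols[int(ev.location) - 1][0] + 1
                k = -ev.indel_delta
                for col in range(start_col, len(row)):
                    if k == 0:
                        break
                    if row[col] != "-":
                        row[col] = "-"
                        k -= 1
        elif ev.kind in ("junction_gain", "junction_loss"):
            d, a = root.junctions[str(ev.location)]
            if ev.payload:
                donor, acceptor = ev.payload.split(",")
            elif ev.kind == "junction_gain":
                donor, acceptor = "GT", "AG"
            else:
                donor, acceptor = "CT", "AG"  # default loss: break the donor
            for off, base in enumerate(donor):
                row[col_of_ref[d + off]] = base
            for off, base in enumerate(acceptor):
                row[col_of_ref[a + off]] = base

    def mutate(row: list[str], blen: float) -> None:
        if background_rate <= 0 or blen <= 0:
            return
        p_change = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * background_rate * blen))
        hits = np.nonzero(rng.random(len(row)) < p_change)[0]
        for col in hits:
            old = row[col]
            if old == "-" or col in junction_cols:
                continue
            choices = [b for b in _BASES if b != old]
            new = choices[int(rng.integers(3))]
            ci = codon_of_col.get(int(col))
            if ci == 0:
                continue  # the ORF start codon is preserved in every lineage
            if ci is not None:
                cols3 = cds_codon_cols[ci]
                before = "".join(row[c] for c in cols3)
                after = "".join(
                    new if c == col else row[c] for c in cols3
                )
                if "-" not in before and (is_stop(before) or is_stop(after)):
                    continue
            row[int(col)] = new

    # descend the tree
    rows: dict[str, list[str]] = {}
    root_working = list(root_row)
    for ev in events_by_node.get(id(tree.seed_node), []):
        apply_event(root_working, ev)

    def descend(node: dendropy.Node, row: list[str]) -> None:
        for child in node.child_nodes():
            crow = list(row)
            mutate(crow, child.edge.length if child.edge.length is not None else 1.0)
            for ev in events_by_node.get(id(child), []):
                apply_event(crow, ev)
            if child.is_leaf():
                rows[child.taxon.label] = crow
            else:
                descend(child, crow)

    descend(tree.seed_node, root_working)

    aln = OrthologAlignment(
        species=tuple(leaves),
        rows=tuple("".join(rows[l]) for l in leaves),
        reference=reference,
    )

    truth = _build_truth(tree, root, events, node_of, reference, leaves)
    ref_columns = tuple(col_of_ref[i] for i in range(L))
    return EvolvedFixture(alignment=aln, truth=truth, ref_columns=ref_columns)


def _junction_state_of(seq: str, d: int, a: int) -> str:
    donor, acceptor = seq[d : d + 2], seq[a : a + 2]
    return (
        "present_canonical"
        if donor == "GT" and acceptor == "AG"
        else "present_noncanonical"
    )


def _build_truth(tree, root, events, node_of, reference, leaves) -> OrthologTruth:
    """Replay planted events along each root-to-leaf path."""
    path_events: dict[str, list[PlantedEventSpec]] = {l: [] for l in leaves}
    # events ordered root-to-tip along each path; preorder gives that order
    ordered_nodes = list(tree.preorder_node_iter())
    order_of = {id(n): i for i, n in enumerate(ordered_nodes)}
    for leaf in leaves:
        applicable = [
            ev for ev in events if leaf in _leaf_labels(node_of[id(ev)])
        ]
        applicable.sort(key=lambda ev: order_of[id(node_of[id(ev)])])
        path_events[leaf] = applicable

    disablers: dict[str, tuple] = {}
    enablers: list[tuple[int, str]] = []
    junction_states: dict[str, dict[str, str]] = {
        j: {} for j in root.junctions
    }
    gain_branch: dict[str, frozenset] = {}

    for ev in events:
        if ev.kind == "junction_gain":
            gain_branch[str(ev.location)] = _leaf_labels(node_of[id(ev)])

    for leaf in leaves:
        stop_at: dict[int, bool] = {}
        net_at: dict[int, int] = {}
        jstate: dict[str, str] = {
            j: _junction_state_of(root.seq, d, a)
            for j, (d, a) in root.junctions.items()
        }
        for ev in path_events[leaf]:
            if ev.kind == "premature_stop":
                stop_at[int(ev.location)] = True
            elif ev.kind == "substitution":
                codon = int(ev.location)
                was_stop = stop_at.get(codon, False)
                now_stop = is_stop(ev.payload)
                stop_at[codon] = now_stop
                if leaf == reference and was_stop and not now_stop:
                    enablers.append((codon, "premature_stop"))
            elif ev.kind == "frameshift_indel":
                codon = int(ev.location)
                before = net_at.get(codon, 0)
                after = before + ev.indel_delta
                net_at[codon] = after
                if leaf == reference and before % 3 != 0 and after % 3 == 0:
                    enablers.append((codon, "frameshift"))
            elif ev.kind == "junction_gain":
                jstate[str(ev.location)] = "present_canonical"
            elif ev.kind == "junction_loss":
                jstate[str(ev.location)] = "present_noncanonical"
        evs = [("premature_stop", c) for c, on in sorted(stop_at.items()) if on]
        evs += [
            ("frameshift", c) for c, net in sorted(net_at.items()) if net % 3 != 0
        ]
        disablers[leaf] = tuple(sorted(evs, key=lambda e: e[1]))
        for j, st in jstate.items():
            junction_states[j][leaf] = st

    return OrthologTruth(
        disablers=disablers,
        enablers=tuple(enablers),
        junction_states=junction_states,
        junction_gain_branch=gain_branch,
    )


# ---------------------------------------------------------------------------
# screen fixture


@dataclass(frozen=True)
class ScreenFixture:
    genes: tuple[GeneModel, ...]
    gwas: tuple[AssociationStudy, ...]
    linkage: tuple[LinkageStudy, ...]
    annotations: Mapping[str, GeneAnnotation]
    truth: tuple[str, ...]  # gene ids satisfying all four filters


def make_screen_fixture(seed: Optional[int] = None, n_genes: int = 8) -> ScreenFixture:
    """A randomized convergence-screen fixture with known candidates.

    Generates ``n_genes`` genes on one chromosome, two association studies
    and two linkage studies. A random subset of 1-3 genes is planted to
    satisfy all four filters (each with one SNP significant in *both* GWAS,
    inside *both* linkage regions, with a complete homologue-free ORF);
    every other gene fails at least one filter in a randomly chosen way.
    """
    if n_genes < 5:
        raise ValueError("fixture requires at least 5 genes")
    rng = np.random.default_rng(seed)
    chrom = "chr20"
    alpha = 1e-4
    gene_len = 4000
    spacing = 10000
    genes = []
    for i in range(n_genes):
        start = 1000 + i * spacing
        exon1 = GenomicInterval(chrom, start, start + 1500)
        exon2 = GenomicInterval(chrom, start + 2500, start + gene_len)
        cds = GenomicInterval(chrom, start + 300, start + 3400)
        genes.append(
            GeneModel(gene_id=f"G{i + 1}", exons=(exon1, exon2), cds=cds, complete=True)
        )

    n_planted = int(rng.integers(1, 4))
    planted_idx = sorted(rng.choice(n_genes, size=n_planted, replace=False).tolist())
    planted = {genes[i].gene_id for i in planted_idx}

    failure_modes = ("gwas", "linkage", "orf", "homolog")
    ann: dict[str, GeneAnnotation] = {}
    fail_of: dict[str, str] = {}
    for g in genes:
        if g.gene_id in planted:
            ann[g.gene_id] = GeneAnnotation(True, True)
            continue
        mode = failure_modes[int(rng.integers(len(failure_modes)))]
        fail_of[g.gene_id] = mode
        ann[g.gene_id] = GeneAnnotation(
            orf_complete=mode != "orf", homolog_free=mode != "homolog"
        )

    study_records: dict[str, list[SnpAssociation]] = {"gwasA": [], "gwasB": []}
    linkage_regions: dict[str, list[GenomicInterval]] = {"linkA": [], "linkB": []}
    snp_counter = 0
    for g in genes:
        span = g.span()
        # the associated SNP sits in the 3'UTR-side of the span
        pos = span.end - int(rng.integers(50, 400))
        snp_counter += 1
        snp_id = f"rs{snp_counter:05d}"
        mode = fail_of.get(g.gene_id)
        sig_p = lambda: float(10 ** rng.uniform(-8, -5))
        null_p = lambda: float(10 ** rng.uniform(-3, -0.01))
        if g.gene_id in planted:
            study_records["gwasA"].append(SnpAssociation(snp_id, chrom, pos, sig_p()))
            study_records["gwasB"].append(SnpAssociation(snp_id, chrom, pos, sig_p()))
        elif mode == "gwas":
            # significant in only one study: convergence fails
            study_records["gwasA"].append(SnpAssociation(snp_id, chrom, pos, sig_p()))
            study_records["gwasB"].append(SnpAssociation(snp_id, chrom, pos, null_p()))
        else:
            study_records["gwasA"].append(SnpAssociation(snp_id, chrom, pos, sig_p()))
            study_records["gwasB"].append(SnpAssociation(snp_id, chrom, pos, sig_p()))
        # linkage coverage
        for lk in ("linkA", "linkB"):
            if g.gene_id in planted or mode != "linkage" or lk == "linkA":
                linkage_regions[lk].append(
                    GenomicInterval(chrom, max(0, span.start - 500), span.end + 500)
                )
    # background noise SNPs outside every gene span
    for _ in range(10):
        snp_counter += 1
        pos = int(rng.integers(n_genes * spacing + 5000, n_genes * spacing + 9000))
        for st in study_records.values():
            st.append(
                SnpAssociation(f"rs{snp_counter:05d}", chrom, pos, float(10 ** rng.uniform(-8, -0.01)))
            )

    gwas = tuple(
        AssociationStudy(sid, tuple(recs), alpha) for sid, recs in study_records.items()
    )
    linkage = tuple(
        LinkageStudy(sid, tuple(regs)) for sid, regs in linkage_regions.items()
    )
    return ScreenFixture(
        genes=tuple(genes),
        gwas=gwas,
        linkage=linkage,
        annotations=ann,
        truth=tuple(sorted(planted)),
    )
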