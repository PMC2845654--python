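"""Convergence screen for candidate genes and LD-based SNP prioritisation.

The screen surfaces genes supported independently by *every* supplied
association study and *every* linkage study, that also carry a complete ORF
with no identifiable homologues in other species — the filter that isolates
species-specific de novo protein-coding candidates from hypothesis-free
genetic mapping data. The LD half ranks SNPs in strong linkage
disequilibrium (r^2 above a threshold) with an index SNP, putting exonic
(including UTR) SNPs ahead of intronic/intergenic ones as the more plausible
causative variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .formats import GeneModel, GenomicInterval

EXONIC_FEATURES = {"exon", "CDS", "UTR", "UTR5", "UTR3", "3UTR", "5UTR"}


class SnpAssociation(NamedTuple):
    snp_id: str
    chrom: str
    pos: int  # 0-based
    p_value: float


@dataclass(frozen=True)
class AssociationStudy:
    """One association study: SNP p-values plus its significance threshold."""

    study_id: str
    records: tuple[SnpAssociation, ...]
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "records", tuple(SnpAssociation(*r) for r in self.records)
        )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for r in self.records:
            if not (0 < r.p_value <= 1):
                raise ValueError(f"p-value out of (0, 1] for {r.snp_id}")

    def significant_in(self, span: GenomicInterval) -> list[SnpAssociation]:
        return [
            r
            for r in self.records
            if r.chrom == span.chrom
            and span.start <= r.pos < span.end
            and r.p_value < self.alpha
        ]


@dataclass(frozen=True)
class LinkageStudy:
    """One linkage analysis: the genomic regions it implicates."""

    study_id: str
    regions: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.regions:
            raise ValueError("linkage study requires at least one region")

    def supports(self, span: GenomicInterval) -> bool:
        return any(span.overlaps(r) for r in self.regions)


@dataclass(frozen=True)
class GeneAnnotation:
    orf_complete: bool
    homolog_free: bool


@dataclass(frozen=True)
class CandidateGene:
    """A gene with the four evidence flags of the convergence screen."""

    gene: GeneModel
    gwas_convergent: bool
    linkage_supported: bool
    orf_complete: bool
    homolog_free: bool
    supporting_snps: tuple[str, ...] = ()

    @property
    def is_candidate(self) -> bool:
        return (
            self.gwas_convergent
            and self.linkage_supported
            and self.orf_complete
            and self.homolog_free
        )


def screen_candidates(
    genes: Iterable[GeneModel],
    gwas: Sequence[AssociationStudy],
    linkage: Sequence[LinkageStudy],
    annotations: Mapping[str, Union[GeneAnnotation, tuple[bool, bool]]],
    mode: str = "any_snp",
    promoter_pad: int = 0,
) -> list[CandidateGene]:
    """Genes significant in every GWAS and every linkage study, with a
    complete, homologue-free ORF.

    The gene span is the transcript extent including UTRs (optionally padded
    upstream/downstream by ``promoter_pad``). In ``any_snp`` mode each GWAS
    may be satisfied by a different SNP inside the span; in ``same_snp`` mode
    one common SNP must be significant in every GWAS. Only genes passing all
    four filters are returned.
    """
    if mode not in ("any_snp", "same_snp"):
        raise ValueError(f"unknown mode {mode!r}")
    if not gwas or not linkage:
        raise ValueError("at least one study of each kind is required")
    out = []
    for gene in genes:
        if gene.gene_id not in annotations:
            raise ValueError(f"gene {gene.gene_id!r} missing annotation flags")
        ann = annotations[gene.gene_id]
        if not isinstance(ann, GeneAnnotation):
            ann = GeneAnnotation(*ann)
        span = gene.span(promoter_pad)
        per_study = [
            {r.snp_id for r in study.significant_in(span)} for study in gwas
        ]
        if mode == "any_snp":
            convergent = all(per_study)
            snps: set[str] = set().union(*per_study) if convergent else set()
        else:
            common = set.intersection(*per_study) if per_study else set()
            convergent = bool(common)
            snps = common
        linked = all(study.supports(span) for study in linkage)
        cand = CandidateGene(
            gene=gene,
            gwas_convergent=convergent,
            linkage_supported=linked,
            orf_complete=ann.orf_complete,
            homolog_free=ann.homolog_free,
            supporting_snps=tuple(sorted(snps)),
        )
        if cand.is_candidate:
            out.append(cand)
    return out


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Phased haplotypes x SNPs, alleles coded 0/1."""

    snp_ids: tuple[str, ...]
    matrix: np.ndarray
    positions: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=int)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if mat.ndim != 2 or mat.shape[1] != len(self.snp_ids):
            raise ValueError("matrix must be haplotypes x len(snp_ids)")
        if not np.isin(mat, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    def column(self, snp_id: str) -> np.ndarray:
        return self.matrix[:, self.snp_ids.index(snp_id)]


def ld_r2(haps: HaplotypeMatrix, index_snp: str) -> pd.Series:
    """r^2 of every SNP with the index SNP, from haplotype frequencies.

    r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B)) with D = p_AB - p_A p_B. The index
    SNP must be polymorphic; a monomorphic comparison SNP has undefined r^2
    and is reported as NaN (missing).
    """
    a = haps.column(index_snp)
    p_a = a.mean()
    if p_a in (0.0, 1.0):
        raise ValueError(f"index SNP {index_snp!r} is monomorphic")
    values = {}
    for snp in haps.snp_ids:
        b = haps.column(snp)
        p_b = b.mean()
        if p_b in (0.0, 1.0):
            values[snp] = np.nan
            continue
        p_ab = np.mean(a * b)
        d = p_ab - p_a * p_b
        values[snp] = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return pd.Series(values, name=f"r2_vs_{index_snp}")


def prioritize_causative(
    ld: pd.Series,
    annotations: Mapping[str, str],
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Rank SNPs in strong LD with the index, exonic/UTR first.

    SNPs with r^2 >= threshold (NaNs excluded) are partitioned into exonic
    (including UTR) versus intronic/intergenic by their annotated feature;
    exonic SNPs rank first, and within each partition ranking is by r^2
    descending. Every linked SNP must carry a feature annotation.
    """
    linked = ld.dropna()
    linked = linked[linked >= r2_threshold]
    rows = []
    for snp, r2 in linked.items():
        if snp not in annotations:
            raise ValueError(f"SNP {snp!r} has no feature annotation")
        feature = annotations[snp]
        exonic = feature in EXONIC_FEATURES
        rows.append({"snp_id": snp, "r2": float(r2), "feature": feature, "exonic": exonic})
    rows.sort(key=lambda r: (not r["exonic"], -r["r2"], r["snp_id"]))
    return pd.DataFrame(rows, columns=["snp_id", "r2", "feature", "exonic"])
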