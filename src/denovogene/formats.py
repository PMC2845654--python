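"""Readers and writers for the external formats the pipeline consumes.

No science lives here. All coordinates are stored internally 0-based
half-open (BED arithmetic); formats with 1-based positions (SNP and
association tables, RepeatMasker .out) are converted exactly once, on read,
and converted back on write.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .orf import OrthologAlignment
from .popgen import ClassDiversity, DiversityReport, SegSiteDist, SnpRecord

_STRANDS = {"+", "-", "."}

# repeat classes RepeatMasker emits; unknown tokens are kept with a warning
_KNOWN_REPEAT_CLASSES = {
    "SINE", "LINE", "LTR", "DNA", "RC", "Retroposon", "Simple_repeat",
    "Low_complexity", "Satellite", "rRNA", "scRNA", "snRNA", "srpRNA",
    "tRNA", "RNA", "Unknown",
}

SNP_TSV_COLUMNS = [
    "locus_id", "pos_1based", "ref", "alt", "alt_count", "n_chromosomes", "site_class",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: ordered exons plus the genomic span of its CDS."""

    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[GenomicInterval] = None
    strand: str = "+"
    complete: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ValueError("gene model requires at least one exon")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError("exons must lie on one chromosome")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons must be sorted and non-overlapping")
        if self.cds is not None:
            if self.cds.chrom != self.exons[0].chrom:
                raise ValueError("CDS must lie on the exon chromosome")
            if not any(
                e.start <= self.cds.start < e.end for e in self.exons
            ) or not any(e.start < self.cds.end <= e.end for e in self.exons):
                raise ValueError("CDS endpoints must fall inside exons")
            if self.complete and self.spliced_cds_length() % 3 != 0:
                raise ValueError("complete CDS must have spliced length divisible by 3")

    def span(self, promoter_pad: int = 0) -> GenomicInterval:
        """Transcript extent including UTRs, optionally padded both sides."""
        start = max(0, self.exons[0].start - promoter_pad)
        end = self.exons[-1].end + promoter_pad
        return GenomicInterval(self.exons[0].chrom, start, end, self.strand, self.gene_id)

    def spliced_cds_intervals(self) -> list[GenomicInterval]:
        if self.cds is None:
            raise ValueError(f"gene {self.gene_id!r} has no CDS")
        pieces = []
        for e in self.exons:
            lo = max(e.start, self.cds.start)
            hi = min(e.end, self.cds.end)
            if hi > lo:
                pieces.append(GenomicInterval(e.chrom, lo, hi, self.strand))
        return pieces

    def spliced_cds_length(self) -> int:
        return sum(iv.length for iv in self.spliced_cds_intervals())


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]


def read_tracks(path: Union[str, Path], format: str, *, reference: Optional[str] = None):
    """Read one external file; the format is declared, never sniffed.

    Supported formats and return types:

    - ``fasta``: list of (name, sequence)
    - ``aligned-fasta``: :class:`~denovogene.orf.OrthologAlignment`
      (``reference`` defaults to the first record)
    - ``newick``: ``dendropy.Tree``
    - ``bed``: list of :class:`GenomicInterval` (BED is already 0-based)
    - ``repeatmasker-out``: list of :class:`GenomicInterval` labelled with the
      repeat class/family (1-based inclusive coordinates converted)
    - ``snp-tsv``: list of :class:`~denovogene.popgen.SnpRecord` (1-based
      positions converted)
    - ``assoc-tsv``: DataFrame [snp_id, chrom, pos, p_value], pos 0-based
    - ``haplotype-tsv``: (hap_ids, snp_ids, 0/1 ndarray)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "fasta":
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if format == "aligned-fasta":
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no records in {path}")
        width = len(records[0][1])
        for name, seq in records:
            if len(seq) != width:
                raise ValueError(
                    f"ragged alignment in {path}: record {name!r} has length "
                    f"{len(seq)}, expected {width}"
                )
        species = tuple(name for name, _ in records)
        rows = tuple(seq for _, seq in records)
        return OrthologAlignment(species, rows, reference or species[0])
    if format == "newick":
        return dendropy.Tree.get(path=str(path), schema="newick")
    if format == "bed":
        out = []
        for ln in _read_lines(path):
            f = ln.split()
            if len(f) < 3:
                raise ValueError(f"malformed BED line: {ln!r}")
            label = f[3] if len(f) > 3 and f[3] != "." else ""
            strand = f[5] if len(f) > 5 and f[5] in _STRANDS else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, label))
        return out
    if format == "repeatmasker-out":
        out = []
        with open(path) as fh:
            lines = fh.readlines()
        for ln in lines[3:]:  # 3 header lines
            f = ln.split()
            if not f:
                continue
            query, begin, end = f[4], int(f[5]), int(f[6])
            classfam = f[10]
            cls = classfam.split("/")[0]
            if cls not in _KNOWN_REPEAT_CLASSES:
                warnings.warn(
                    f"unknown repeat class token {cls!r} in {path.name}; record kept",
                    stacklevel=2,
                )
            out.append(GenomicInterval(query, begin - 1, end, ".", classfam))
        return out
    if format == "snp-tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = set(SNP_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"SNP table missing columns {sorted(missing)}")
        return [
            SnpRecord(
                position=int(r.pos_1based) - 1,
                ref=str(r.ref),
                alt=str(r.alt),
                alt_count=int(r.alt_count),
                n_chromosomes=int(r.n_chromosomes),
                site_class=str(r.site_class),
                locus_id=str(r.locus_id),
            )
            for r in df.itertuples()
        ]
    if format == "assoc-tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        needed = {"snp_id", "chrom", "pos_1based", "p_value"}
        if not needed <= set(df.columns):
            raise ValueError(f"association table missing columns {sorted(needed - set(df.columns))}")
        out = df[["snp_id", "chrom", "pos_1based", "p_value"]].copy()
        out["pos"] = out.pop("pos_1based").astype(int) - 1
        return out[["snp_id", "chrom", "pos", "p_value"]]
    if format == "haplotype-tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        mat = df.to_numpy(dtype=int)
        return list(df.index.astype(str)), list(df.columns.astype(str)), mat
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# report writing with round-trip readers


def write_report(records: Any, path: Union[str, Path], format: str = "tsv") -> None:
    """Serialise internal record types to TSV or JSON.

    Handles :class:`~denovogene.popgen.DiversityReport`,
    :class:`~denovogene.popgen.SegSiteDist`, and lists of
    :class:`~denovogene.popgen.SnpRecord` or :class:`GenomicInterval`.
    ``read_report`` inverts every writer exactly.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(records), fh, indent=1)
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(records, DiversityReport):
        df = records.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# n_chromosomes={records.n_chromosomes}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
        return
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records) if not isinstance(records, (list, tuple)) else records
    if all(isinstance(r, SnpRecord) for r in records) and records:
        rows = [
            {
                "locus_id": r.locus_id,
                "pos_1based": r.position + 1,
                "ref": r.ref,
                "alt": r.alt,
                "alt_count": r.alt_count,
                "n_chromosomes": r.n_chromosomes,
                "site_class": r.site_class,
            }
            for r in records
        ]
        pd.DataFrame(rows, columns=SNP_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if not records:  # header-only SNP table by convention
        pd.DataFrame(columns=SNP_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if all(isinstance(r, GenomicInterval) for r in records):
        with open(path, "w") as fh:
            for r in records:
                # '.' is BED's empty-name placeholder
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label or '.'}\t0\t{r.strand}\n")
        return
    raise TypeError(f"don't know how to serialise {type(records[0])} records to TSV")


_TYPE_REGISTRY = {
    "SegSiteDist": SegSiteDist,
    "DiversityReport": DiversityReport,
    "ClassDiversity": ClassDiversity,
    "SnpRecord": SnpRecord,
    "GenomicInterval": GenomicInterval,
}


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(o) for o in obj]
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"__type__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = _to_jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    raise TypeError(f"cannot serialise {type(obj)}")


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, list):
        return [_from_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=float)
        if "__type__" in obj:
            cls = _TYPE_REGISTRY[obj["__type__"]]
            kwargs = {k: _from_jsonable(v) for k, v in obj.items() if k != "__type__"}
            if cls is DiversityReport:
                kwargs["rows"] = tuple(kwargs["rows"])
            return cls(**kwargs)
        return {k: _from_jsonable(v) for k, v in obj.items()}
    return obj


def read_report(path: Union[str, Path], format: str = "json", kind: Optional[str] = None):
    """Read back a report written by :func:`write_report`.

    JSON reports reconstruct the original objects from their embedded type
    tags. TSV reports need ``kind``: ``diversity`` or ``snp``.
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return _from_jsonable(json.load(fh))
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if kind == "diversity":
        n = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# n_chromosomes="):
                n = int(first.split("=")[1])
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        rows = tuple(
            ClassDiversity(
                site_class=str(r.Locus),
                length=int(r.Length),
                n_segregating=int(r.S),
                theta_per_site=float(r.theta_per_site),
                pi_per_site=float(r.pi_per_site),
            )
            for r in df.itertuples()
        )
        return DiversityReport(n_chromosomes=n if n is not None else 0, rows=rows)
    if kind == "snp":
        return read_tracks(path, "snp-tsv")
    raise ValueError("TSV read_report requires kind='diversity' or 'snp'")


def write_aligned_fasta(aln: OrthologAlignment, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.species, aln.rows):
            fh.write(f">{name}\n{row}\n")


def write_newick(tree: dendropy.Tree, path: Union[str, Path]) -> None:
    tree.write(path=str(path), schema="newick")
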