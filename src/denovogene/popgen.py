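"""Population-genetics statistics for a resequenced locus.

Implements the per-site-class polymorphism summaries used to test whether a
putative coding region is under purifying selection: Watterson's theta and
nucleotide diversity per functional site class, Nei-Gojobori partitioning of a
CDS into synonymous and nonsynonymous sites, sliding-window diversity, and the
neutral-coalescent distribution of the number of segregating sites computed by
Hudson's recursion, from which a lower-tail constraint p-value is derived.

All estimators take the number of sampled *chromosomes* n (two per diploid
individual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

SITE_CLASSES = ("CDS_syn", "CDS_nonsyn", "UTR5", "UTR3", "intron", "flank")

_CODON_TABLE = unambiguous_dna_by_id[1]  # standard nuclear code
_STOPS = frozenset(_CODON_TABLE.stop_codons)  # {'TAA', 'TAG', 'TGA'}
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard code; stops return '*'."""
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE.forward_table[codon]


def is_stop(codon: str) -> bool:
    return codon.upper() in _STOPS


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic segregating site with its derived/alternate allele count.

    ``position`` is 0-based within the locus; TSV input/output uses 1-based
    positions, converted exactly once at the file boundary.
    """

    position: int
    ref: str
    alt: str
    alt_count: int
    n_chromosomes: int
    site_class: str
    locus_id: str = "locus"

    def __post_init__(self) -> None:
        if not (0 < self.alt_count < self.n_chromosomes):
            raise ValueError(
                f"alt_count must lie strictly between 0 and n_chromosomes; "
                f"got {self.alt_count}/{self.n_chromosomes} at position {self.position}"
            )
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass(frozen=True)
class ClassDiversity:
    """One row of a per-site-class diversity report."""

    site_class: str
    length: int
    n_segregating: int
    theta_per_site: float
    pi_per_site: float


@dataclass(frozen=True)
class DiversityReport:
    """Per-class polymorphism summary (S, Watterson theta/site, pi/site)."""

    n_chromosomes: int
    rows: tuple[ClassDiversity, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Locus": r.site_class,
                    "Length": r.length,
                    "S": r.n_segregating,
                    "theta_per_site": r.theta_per_site,
                    "pi_per_site": r.pi_per_site,
                }
                for r in self.rows
            ]
        )


def harmonic_number(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i (the Watterson denominator for n = m+1)."""
    if m < 1:
        raise ValueError("harmonic number requires m >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(n_segregating: int, length_bp: int, n_chromosomes: int) -> float:
    """Watterson's estimator of the per-site population mutation rate.

    theta_hat = S / (a_{n-1} * l) with a_{n-1} = sum_{i=1}^{n-1} 1/i.
    """
    if n_chromosomes < 2:
        raise ValueError("Watterson's estimator requires n >= 2 chromosomes")
    if length_bp < 1:
        raise ValueError("length must be >= 1 bp")
    if n_segregating < 0:
        raise ValueError("S must be >= 0")
    if n_segregating == 0:
        return 0.0
    return n_segregating / (harmonic_number(n_chromosomes - 1) * length_bp)


def nucleotide_diversity(
    snps: Iterable[SnpRecord], length_bp: int, n_chromosomes: int
) -> float:
    """Per-site nucleotide diversity (average pairwise differences / site).

    Uses the unbiased sample estimator: per segregating site with derived
    frequency p, heterozygosity 2 p (1-p) n/(n-1); summed and divided by the
    surveyed length. Equivalent to counting differing chromosome pairs over
    all C(n,2) pairs.
    """
    if length_bp < 1:
        raise ValueError("length must be >= 1 bp")
    snps = list(snps)
    if not snps:
        return 0.0
    positions = [s.position for s in snps]
    if len(set(positions)) != len(positions):
        raise ValueError("SNP positions must be distinct within one class")
    n = n_chromosomes
    for s in snps:
        if s.n_chromosomes != n:
            raise ValueError("all SNP records must share the same sample size n")
    total = 0.0
    for s in snps:
        p = s.alt_count / n
        total += 2.0 * p * (1.0 - p) * n / (n - 1)
    return total / length_bp


def count_sites_ng(cds: str) -> tuple[float, float]:
    """Nei-Gojobori fractional synonymous / nonsynonymous site counts.

    Each codon position contributes f/3 synonymous sites, where f is the
    number of the three possible single-base changes at that position that
    preserve the encoded amino acid (changes to or from a stop codon never
    count as synonymous). The two totals sum exactly to the CDS length.

    The final codon may be a stop codon (its sites are counted with 'stop'
    treated as the conserved state); internal stops are rejected.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if any(b not in _BASES for b in cds):
        raise ValueError("CDS must contain only A/C/G/T")
    n_codons = len(cds) // 3
    syn = 0.0
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if is_stop(codon) and ci < n_codons - 1:
            raise ValueError(f"internal stop codon {codon} at codon {ci + 1}")
        aa = translate_codon(codon)
        for pos in range(3):
            f = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if translate_codon(mutant) == aa:
                    f += 1
            syn += f / 3.0
    return syn, float(len(cds)) - syn


@dataclass(frozen=True)
class SegSiteDist:
    """Distribution P_n(s) of the number of segregating sites.

    ``theta`` is the region-scaled population mutation rate; ``probs[s]`` is
    the exact probability that s sites segregate in a sample of ``n``
    chromosomes under the neutral infinite-sites coalescent; ``tail_mass`` is
    the probability beyond the truncation point.
    """

    n: int
    theta: float
    probs: np.ndarray = field(repr=False)
    tail_mass: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegSiteDist):
            return NotImplemented
        return (
            self.n == other.n
            and self.theta == other.theta
            and self.tail_mass == other.tail_mass
            and np.array_equal(self.probs, other.probs)
        )

    @property
    def s_max(self) -> int:
        return len(self.probs) - 1

    def mean(self) -> float:
        """Truncated mean sum_s s * P_n(s); converges to theta * a_{n-1}."""
        return float(np.arange(len(self.probs)) @ self.probs)

    def cdf(self, s: int) -> float:
        """P(S <= s), exact for s within the truncation."""
        if s < 0:
            return 0.0
        s = min(s, self.s_max)
        return float(self.probs[: s + 1].sum())


def _recursion_probs(n: int, theta: float, s_max: int) -> np.ndarray:
    """P_n(0..s_max) by convolving per-level geometric mutation counts.

    While k ancestral lineages remain, the number of mutations is geometric:
    Q_k(i) = ((k-1)/(k-1+theta)) * (theta/(k-1+theta))^i, and
    P_k(s) = sum_i Q_k(i) P_{k-1}(s-i) with P_2 = Q_2. Truncation at s_max is
    exact for all s <= s_max because the convolution never consults higher
    terms.
    """
    i = np.arange(s_max + 1)
    k = 2
    probs = ((k - 1) / (k - 1 + theta)) * (theta / (k - 1 + theta)) ** i
    for k in range(3, n + 1):
        q = ((k - 1) / (k - 1 + theta)) * (theta / (k - 1 + theta)) ** i
        probs = np.convolve(q, probs)[: s_max + 1]
    return probs


def segsite_distribution(
    n: int, theta: float, s_max: Optional[int] = None
) -> SegSiteDist:
    """Exact distribution of the number of segregating sites (Hudson recursion).

    Parameters
    ----------
    n : sampled chromosomes (>= 2).
    theta : region-scaled population mutation rate (> 0).
    s_max : optional truncation point. When omitted, the distribution is
        truncated at the smallest s_max whose cumulative mass reaches
        1 - 1e-12; ``tail_mass`` carries the remainder.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if s_max is not None:
        if s_max < 0:
            raise ValueError("s_max must be >= 0")
        probs = _recursion_probs(n, theta, s_max)
        return SegSiteDist(n, theta, probs, float(1.0 - probs.sum()))

    # auto truncation: start past mean + 12 sd and grow until the target mass
    # 1 - 1e-12 is captured, then trim to the smallest sufficient s_max
    per_level_mean = theta / np.arange(1, n)
    mean = per_level_mean.sum()
    var = (per_level_mean + per_level_mean**2).sum()
    guess = int(np.ceil(mean + 12.0 * np.sqrt(var))) + 30
    target = 1.0 - 1e-12
    while True:
        probs = _recursion_probs(n, theta, guess)
        cum = np.cumsum(probs)
        if cum[-1] >= target:
            cut = int(np.searchsorted(cum, target))
            probs = probs[: cut + 1]
            return SegSiteDist(n, theta, probs, float(1.0 - probs.sum()))
        guess *= 2


def hudson_constraint_test(
    s_obs: int,
    length_bp: int,
    theta_null_per_site: float,
    n_chromosomes: int,
    inclusive: bool = True,
) -> float:
    """Lower-tail constraint test on the observed number of segregating sites.

    Computes P(S <= s_obs) (or P(S < s_obs) with ``inclusive=False``) under
    the neutral segregating-sites distribution with region-scaled rate
    theta = theta_null_per_site * length_bp. A small p indicates fewer
    polymorphisms than the null rate predicts, i.e. selective constraint.
    """
    if s_obs < 0:
        raise ValueError("s_obs must be >= 0")
    if length_bp < 1:
        raise ValueError("length must be >= 1 bp")
    theta = theta_null_per_site * length_bp
    upto = s_obs if inclusive else s_obs - 1
    if upto < 0:
        return 0.0
    dist = segsite_distribution(n_chromosomes, theta, s_max=upto)
    return float(dist.probs.sum())


def sliding_diversity(
    snps: Iterable[SnpRecord],
    locus_length: int,
    window: int = 100,
    step: int = 25,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity along a locus.

    Windows tile from position 0 with the given step; the last window is
    truncated at the locus end and its true length is used. Returns a frame
    with columns ``start``, ``end``, ``midpoint``, ``pi_per_site``.
    """
    if window > locus_length:
        raise ValueError("window must not exceed the locus length")
    if step < 1:
        raise ValueError("step must be >= 1")
    snps = list(snps)
    n = snps[0].n_chromosomes if snps else 2
    rows = []
    start = 0
    while start < locus_length:
        end = min(start + window, locus_length)
        inside = [s for s in snps if start <= s.position < end]
        pi = nucleotide_diversity(inside, end - start, n) if inside else 0.0
        rows.append(
            {"start": start, "end": end, "midpoint": (start + end) / 2.0, "pi_per_site": pi}
        )
        if end == locus_length:
            break
        start += step
    return pd.DataFrame(rows)


def per_class_report(
    snps: Iterable[SnpRecord],
    lengths: Mapping[str, int],
    n_chromosomes: int,
) -> DiversityReport:
    """Per-site-class polymorphism report (S, theta/site, pi/site).

    ``lengths`` maps each site class to its surveyed length in bp; every SNP's
    class must be present. Classes with no SNPs report S = 0 and zero rates.
    """
    for cls, l in lengths.items():
        if l <= 0:
            raise ValueError(f"length for class {cls!r} must be > 0")
    by_class: dict[str, list[SnpRecord]] = {cls: [] for cls in lengths}
    for s in snps:
        if s.site_class not in lengths:
            raise ValueError(f"SNP site class {s.site_class!r} absent from lengths")
        by_class[s.site_class].append(s)
    rows = []
    for cls, l in lengths.items():
        records = by_class[cls]
        S = len(records)
        rows.append(
            ClassDiversity(
                site_class=cls,
                length=int(l),
                n_segregating=S,
                theta_per_site=watterson_theta(S, int(l), n_chromosomes),
                pi_per_site=nucleotide_diversity(records, int(l), n_chromosomes),
            )
        )
    return DiversityReport(n_chromosomes=n_chromosomes, rows=tuple(rows))
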