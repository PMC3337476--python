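"""Mutation spectra, synonymous-codon classification, and usage vectors.

Substitutions are classified at the base-*pair* level, collapsing the two
strand descriptions of the same event (C→T on the forward strand and G→A on
the reverse describe one G·C→A·T change). Synonymous status of a codon
change is determined under the standard bacterial genetic code, and each
synonymous change is assigned a usage *vector* — whether it moves from a
more-used codon toward a less-used one ("down"), the reverse ("up"), or
between similarly used codons — relative to a codon usage table.

"Similarly often used" has no canonical definition; here it is a ratio band:
codons whose within-family usage fractions differ by less than a factor
``rho`` (default 1.5) count as similar. The band is configurable and its
choice is reported alongside the tallies.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .io_formats import (
    BACTERIAL_CODE,
    CodonUsageTable,
    Genome,
    MutationRecord,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Strand-collapsed substitution classes
# ---------------------------------------------------------------------------

class SubstitutionClass(enum.Enum):
    """The six strand-collapsed base-pair substitution classes."""

    GC_TO_AT = "GC>AT"
    GC_TO_TA = "GC>TA"
    GC_TO_CG = "GC>CG"
    AT_TO_GC = "AT>GC"
    AT_TO_CG = "AT>CG"
    AT_TO_TA = "AT>TA"

    @property
    def is_transition(self) -> bool:
        return self in (SubstitutionClass.GC_TO_AT, SubstitutionClass.AT_TO_GC)

    @property
    def from_gc_pair(self) -> bool:
        return self.value.startswith("GC")


# forward-strand (ref, alt) -> class; the complementary pair maps identically
_CLASS_OF: dict[tuple[str, str], SubstitutionClass] = {
    ("G", "A"): SubstitutionClass.GC_TO_AT,
    ("C", "T"): SubstitutionClass.GC_TO_AT,
    ("G", "T"): SubstitutionClass.GC_TO_TA,
    ("C", "A"): SubstitutionClass.GC_TO_TA,
    ("G", "C"): SubstitutionClass.GC_TO_CG,
    ("C", "G"): SubstitutionClass.GC_TO_CG,
    ("A", "G"): SubstitutionClass.AT_TO_GC,
    ("T", "C"): SubstitutionClass.AT_TO_GC,
    ("A", "C"): SubstitutionClass.AT_TO_CG,
    ("T", "G"): SubstitutionClass.AT_TO_CG,
    ("A", "T"): SubstitutionClass.AT_TO_TA,
    ("T", "A"): SubstitutionClass.AT_TO_TA,
}


def collapse_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Class of the base-pair change for a forward-strand ref→alt event."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    try:
        return _CLASS_OF[(ref, alt)]
    except KeyError:
        raise ValueError(f"invalid substitution {ref}->{alt}") from None


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts of mutations per strand-collapsed substitution class."""

    counts: dict[SubstitutionClass, int]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def gc_to_at_or_ta(self) -> int:
        """Grouped G/C→A/T count: G·C→A·T plus G·C→T·A."""
        return (
            self.counts[SubstitutionClass.GC_TO_AT]
            + self.counts[SubstitutionClass.GC_TO_TA]
        )

    @property
    def transitions(self) -> int:
        return sum(n for c, n in self.counts.items() if c.is_transition)


def summarize_spectrum(records: Sequence[MutationRecord]) -> SpectrumSummary:
    tally = Counter(collapse_substitution(r.ref_base, r.alt_base) for r in records)
    return SpectrumSummary({c: tally.get(c, 0) for c in SubstitutionClass})


# ---------------------------------------------------------------------------
# Codon changes and usage vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding span on the genome, 1-based inclusive coordinates.

    ``start`` <= ``end`` always; for a minus-strand gene the coding sequence
    is the reverse complement of genome[start..end], so the first codon sits
    at the ``end`` coordinate. The span length must be a multiple of 3.
    """

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"gene {self.name}: length not a multiple of 3")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class CodonStatus(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


@dataclass(frozen=True)
class CodonChange:
    codon_before: str
    codon_after: str

    def __post_init__(self) -> None:
        diff = sum(a != b for a, b in zip(self.codon_before, self.codon_after))
        if len(self.codon_before) != 3 or len(self.codon_after) != 3 or diff != 1:
            raise ValueError(
                f"{self.codon_before}->{self.codon_after} is not a single-base codon change"
            )

    @property
    def aa_before(self) -> str:
        return BACTERIAL_CODE[self.codon_before]

    @property
    def aa_after(self) -> str:
        return BACTERIAL_CODE[self.codon_after]

    @property
    def status(self) -> CodonStatus:
        if self.aa_before == "*":
            raise ValueError("status undefined for a change starting at a stop codon")
        if self.aa_after == "*":
            return CodonStatus.NONSENSE
        if self.aa_before == self.aa_after:
            return CodonStatus.SYNONYMOUS
        return CodonStatus.MISSENSE


def codon_change_of(
    record: MutationRecord, genome: Genome, gene: GeneAnnotation
) -> CodonChange:
    """Codon change induced by a substitution inside a gene.

    Codons are read in the coding orientation: for a minus-strand gene the
    genome window is reverse-complemented before translation.
    """
    if not gene.contains(record.position):
        raise ValueError(
            f"record {record.id} at {record.position} outside gene "
            f"{gene.name} ({gene.start}..{gene.end})"
        )
    if gene.strand == "+":
        offset = record.position - gene.start  # 0-based within CDS
    else:
        offset = gene.end - record.position
    codon_index = offset // 3
    within = offset % 3
    if gene.strand == "+":
        codon_start = gene.start + 3 * codon_index  # genome coordinate
        before = "".join(genome.base(codon_start + i) for i in range(3))
        after = before[:within] + record.alt_base + before[within + 1 :]
    else:
        codon_end = gene.end - 3 * codon_index
        fwd = "".join(genome.base(codon_end - 2 + i) for i in range(3))
        before = revcomp(fwd)
        alt_coding = record.alt_base.translate(_COMPLEMENT)
        after = before[:within] + alt_coding + before[within + 1 :]
    for codon in (before, after):
        if any(b not in "ACGT" for b in codon):
            raise ValueError(f"codon {codon!r} contains a masked/invalid base")
    if before[within] != (
        record.ref_base if gene.strand == "+" else record.ref_base.translate(_COMPLEMENT)
    ):
        raise ValueError(
            f"record {record.id}: genome codon {before} inconsistent with ref base"
        )
    return CodonChange(before, after)


class UsageVector(enum.Enum):
    DOWN = "down"      # more-used -> less-used
    SIMILAR = "similar"
    UP = "up"          # less-used -> more-used


def usage_vector(
    change: CodonChange, table: CodonUsageTable, rho: float = 1.5
) -> UsageVector:
    """Direction of a synonymous change relative to codon usage.

    ``down`` iff u(before) > rho·u(after); ``up`` iff u(after) > rho·u(before);
    otherwise ``similar``. ``rho`` must exceed 1.
    """
    if rho <= 1:
        raise ValueError("rho must be > 1")
    if change.status is not CodonStatus.SYNONYMOUS:
        raise ValueError(f"usage vector undefined for {change.status.value} change")
    u_before = table.fraction(change.codon_before)
    u_after = table.fraction(change.codon_after)
    if u_before > rho * u_after:
        return UsageVector.DOWN
    if u_after > rho * u_before:
        return UsageVector.UP
    return UsageVector.SIMILAR


@dataclass(frozen=True)
class VectorTally:
    down: int
    similar: int
    up: int
    rho: float
    n_synonymous: int = field(default=0)


def tally_usage_vectors(
    changes: Sequence[CodonChange], table: CodonUsageTable, rho: float = 1.5
) -> VectorTally:
    """Tally down/similar/up over the synonymous subset of ``changes``."""
    syn = [c for c in changes if c.status is CodonStatus.SYNONYMOUS]
    vecs = Counter(usage_vector(c, table, rho) for c in syn)
    return VectorTally(
        down=vecs.get(UsageVector.DOWN, 0),
        similar=vecs.get(UsageVector.SIMILAR, 0),
        up=vecs.get(UsageVector.UP, 0),
        rho=rho,
        n_synonymous=len(syn),
    )


# ---------------------------------------------------------------------------
# Regional vs genomic G+C composition
# ---------------------------------------------------------------------------

def binomial_two_tailed(k: int, n: int, p: float, method: str = "doubling") -> float:
    """Exact two-tailed binomial P for ``k`` successes in ``n`` at null ``p``.

    ``doubling`` (default): twice the smaller of P(X<=k), P(X>=k), capped at 1.
    ``minlike``: sum of all outcomes with likelihood <= that of ``k``
    (the scipy ``binomtest`` convention).
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if method == "doubling":
        lower = stats.binom.cdf(k, n, p)
        upper = stats.binom.sf(k - 1, n, p)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "minlike":
        return float(stats.binomtest(k, n, p).pvalue)
    raise ValueError(f"unknown method {method!r}")


def gc_composition_test(
    observed_gc: int, n: int, genomic_p: float, method: str = "doubling"
) -> float:
    """Two-tailed exact binomial test of a region's G+C count against the
    genomic G+C proportion."""
    return binomial_two_tailed(observed_gc, n, genomic_p, method=method)
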