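"""Mutation-rate arithmetic for mutation-accumulation (MA) experiments.

A point rate is mutations observed divided by (cumulative generations ×
target sites); multiplying by genome size gives a per-genome per-generation
rate; multiplying that by generations elapsed and by coding / synonymous
fractions gives expected substitution-class counts. All values are kept at
full float precision; rounding to the 2 significant figures customary in
print happens only in :func:`format_rate` at report time.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RateEstimate:
    """Per-bp per-generation rate from counts over a mutational target."""

    num_mutations: int
    cumulative_generations: float
    target_sites: float

    @property
    def rate_per_bp_per_gen(self) -> float:
        return self.num_mutations / (self.cumulative_generations * self.target_sites)


@dataclass(frozen=True)
class GenomeRate:
    rate_per_bp_per_gen: float
    genome_size: int

    @property
    def rate_per_genome_per_gen(self) -> float:
        return self.rate_per_bp_per_gen * self.genome_size


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected substitutions over an experiment, split by functional class."""

    genome_rate: float
    generations: float
    coding_fraction: float
    synonymous_fraction: float

    @property
    def total(self) -> float:
        return self.genome_rate * self.generations

    @property
    def coding(self) -> float:
        return self.total * self.coding_fraction

    @property
    def synonymous(self) -> float:
        return self.coding * self.synonymous_fraction


#: Fraction of the genome that is protein-coding (overridable default).
DEFAULT_CODING_FRACTION = 0.86
#: Fraction of coding-sequence substitutions that are synonymous.
DEFAULT_SYNONYMOUS_FRACTION = 0.25


def point_rate(m: int, generations: float, sites: float) -> RateEstimate:
    """Rate = m / (generations × sites), exact, no internal rounding."""
    if m < 0:
        raise ValueError("mutation count must be non-negative")
    if generations <= 0 or sites <= 0:
        raise ValueError("generations and sites must be positive")
    return RateEstimate(m, generations, sites)


def per_genome_rate(rate: RateEstimate | float, genome_size: int) -> GenomeRate:
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    r = rate.rate_per_bp_per_gen if isinstance(rate, RateEstimate) else float(rate)
    return GenomeRate(r, genome_size)


def expected_class_counts(
    genome_rate: float,
    generations: float,
    coding_fraction: float = DEFAULT_CODING_FRACTION,
    synonymous_fraction: float = DEFAULT_SYNONYMOUS_FRACTION,
) -> ExpectedCounts:
    for name, f in (("coding", coding_fraction), ("synonymous", synonymous_fraction)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} fraction must lie in [0, 1]")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return ExpectedCounts(genome_rate, generations, coding_fraction, synonymous_fraction)


def fold_difference(a: float, b: float) -> float:
    """How many fold larger ``a`` is than ``b``."""
    if b <= 0:
        raise ZeroDivisionError("reference rate must be positive")
    return a / b


def format_rate(value: float, sig: int = 2) -> str:
    """Display rounding to ``sig`` significant figures (e.g. '8.9e-11')."""
    if value == 0:
        return "0"
    return f"{value:.{sig - 1}e}"


def round_sig(value: float, sig: int) -> float:
    """Round to ``sig`` significant figures (report-time only)."""
    if value == 0:
        return 0.0
    return float(f"{value:.{sig - 1}e}")
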