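"""Flanking-base context profiles and the replicated goodness-of-fit G-test.

For each mutated site the ±``flank`` window (default −5..+5) is scanned and
the number of mutations with a G or C at each offset is counted. Under the
null that local composition around mutated sites matches the regional G+C
proportion *p*, each offset's count O is Binomial(n, p) with n the number of
contributing mutations.

The replicated decomposition treats each flanking offset as one replicate of
a two-class goodness-of-fit test and partitions the total statistic

    G_T = Σ_i G_i            (k df)

into a pooled component G_P = G(ΣO_i, k·n, p) with 1 df — overall excess or
deficit of G/C across the window — and a heterogeneity component
G_H = G_T − G_P with k−1 df — differences among offsets. By construction
G_T = G_P + G_H exactly.

The mutated site itself (offset 0) is profiled but excluded from the test by
default: its base composition is constrained by the mutation classes
themselves, and the decomposition then runs on k = 10 flanking replicates
(9 heterogeneity df). A flag includes it. Boundary mutations whose window
leaves a linear genome are skipped entirely (not truncated), keeping n equal
across offsets as the decomposition assumes; circular genomes wrap instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import Genome, MutationRecord
from .spectra_codon import binomial_two_tailed


# ---------------------------------------------------------------------------
# Context extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContextProfile:
    """Per-offset G/C counts over a set of mutations.

    ``counts`` maps each offset −flank..+flank to the number of mutations
    whose base at that offset is G or C; offset 0 uses the pre-mutation
    (reference) base. ``skipped`` lists record ids excluded because their
    window crossed the end of a linear genome or contained a masked base.
    """

    counts: dict[int, int]
    n: int
    p: float
    flank: int
    skipped: list[str] = field(default_factory=list)

    @property
    def offsets(self) -> list[int]:
        return sorted(self.counts)

    @property
    def expected_per_offset(self) -> float:
        """Expected G/C count per offset: n × p."""
        return self.n * self.p

    def test_counts(self, include_center: bool = False) -> list[int]:
        """Counts entering the replicated test, center excluded by default."""
        return [self.counts[o] for o in self.offsets if include_center or o != 0]


def extract_context(
    genome: Genome,
    records: Sequence[MutationRecord],
    flank: int = 5,
    p: float | None = None,
) -> ContextProfile:
    """Count G/C occupancy at each offset in ±``flank`` windows around
    mutated sites.

    ``p`` is the expected G/C proportion attached to the profile; defaults to
    the genome-wide G+C fraction but should be the regional value when the
    mutations come from a single locus.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    offsets = list(range(-flank, flank + 1))
    counts = {o: 0 for o in offsets}
    skipped: list[str] = []
    n = 0
    for r in records:
        if genome.topology == "linear" and (
            r.position - flank < 1 or r.position + flank > genome.length
        ):
            skipped.append(r.id)
            continue
        window = {o: genome.base(r.position + o) for o in offsets}
        window[0] = r.ref_base  # pre-mutation state, always
        if any(b not in "ACGT" for b in window.values()):
            skipped.append(r.id)
            continue
        n += 1
        for o in offsets:
            if window[o] in "GC":
                counts[o] += 1
    if n == 0:
        raise ValueError("all records were skipped; no context to profile")
    return ContextProfile(
        counts=counts,
        n=n,
        p=genome.gc_fraction if p is None else p,
        flank=flank,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# G statistics
# ---------------------------------------------------------------------------

def g_gof(O: int, n: int, p: float) -> float:
    """Two-class goodness-of-fit G statistic (1 df).

    G = 2[O ln(O/np) + (n−O) ln((n−O)/n(1−p))], with 0·ln(0/·) = 0.
    """
    if not 0 <= O <= n:
        raise ValueError("O must lie in [0, n]")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    O = float(O)
    n = float(n)
    term1 = O * math.log(O / (n * p)) if O > 0 else 0.0
    term2 = (n - O) * math.log((n - O) / (n * (1 - p))) if n - O > 0 else 0.0
    return 2.0 * (term1 + term2)


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0:
        raise ValueError("x must be >= 0")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(x, df))


def williams_correct(G: float, n: float, a: int = 2, nu: int = 1) -> float:
    """Williams small-sample correction: G / q, q = 1 + (a²−1)/(6·n·ν)."""
    if n <= 0:
        raise ValueError("n must be positive")
    q = 1.0 + (a**2 - 1) / (6.0 * n * nu)
    return G / q


def per_position_binomial(O: int, n: int, p: float, method: str = "doubling") -> float:
    """Exact two-tailed binomial P for one offset (alternative to the G tail)."""
    return binomial_two_tailed(O, n, p, method=method)


# ---------------------------------------------------------------------------
# Replicated decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofDecomposition:
    """Replicated goodness-of-fit decomposition over k offset replicates."""

    offsets: list[int]
    per_position_G: list[float]
    G_P: float
    G_H: float
    G_T: float
    df_P: int
    df_H: int
    df_T: int
    p_P: float
    p_H: float
    p_T: float
    per_position_p: list[float]
    n: int
    p_expected: float
    williams_applied: bool = False
    per_position_test: str = "g"


def replicated_gof(
    counts: Sequence[int],
    n: int,
    p: float,
    offsets: Sequence[int] | None = None,
    williams: bool = False,
    per_position_test: str = "g",
) -> GofDecomposition:
    """Decompose the total G over k replicate offsets into pooled and
    heterogeneity components.

    ``counts`` are the per-offset G/C counts, each out of the same ``n``
    mutations; ``p`` is the expected G/C proportion. With ``williams=True``
    the Williams correction divides each statistic before its tail
    probability is computed (off by default).
    """
    k = len(counts)
    if k < 2:
        raise ValueError("need at least 2 replicate offsets")
    if offsets is None:
        offsets = list(range(k))
    per_g = [g_gof(O, n, p) for O in counts]
    G_T = float(sum(per_g))
    G_P = g_gof(int(sum(counts)), k * n, p)
    G_H = G_T - G_P
    if williams:
        per_g_rep = [williams_correct(g, n, 2, 1) for g in per_g]
        G_P_rep = williams_correct(G_P, k * n, 2, 1)
        G_T_rep = williams_correct(G_T, k * n, 2, k)
        G_H_rep = williams_correct(G_H, k * n, 2, k - 1)
    else:
        per_g_rep, G_P_rep, G_H_rep, G_T_rep = per_g, G_P, G_H, G_T
    if per_position_test == "g":
        per_p = [chi2_sf(g, 1) for g in per_g_rep]
    elif per_position_test == "binomial":
        per_p = [per_position_binomial(int(O), n, p) for O in counts]
    else:
        raise ValueError(f"unknown per-position test {per_position_test!r}")
    return GofDecomposition(
        offsets=list(offsets),
        per_position_G=per_g_rep,
        G_P=G_P_rep,
        G_H=G_H_rep,
        G_T=G_T_rep,
        df_P=1,
        df_H=k - 1,
        df_T=k,
        p_P=chi2_sf(G_P_rep, 1),
        p_H=chi2_sf(G_H_rep, k - 1),
        p_T=chi2_sf(G_T_rep, k),
        per_position_p=per_p,
        n=n,
        p_expected=p,
        williams_applied=williams,
        per_position_test=per_position_test,
    )


def context_gof(
    profile: ContextProfile,
    include_center: bool = False,
    williams: bool = False,
    per_position_test: str = "g",
) -> GofDecomposition:
    """Run the replicated decomposition on a context profile."""
    offs = [o for o in profile.offsets if include_center or o != 0]
    counts = [profile.counts[o] for o in offs]
    return replicated_gof(
        counts,
        profile.n,
        profile.p,
        offsets=offs,
        williams=williams,
        per_position_test=per_position_test,
    )


# ---------------------------------------------------------------------------
# Null simulation (calibration)
# ---------------------------------------------------------------------------

def pooled_test_type1_error(
    n: int,
    p: float,
    k: int = 10,
    replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the pooled G test under the binomial null.

    Draws k offset counts ~ Binomial(n, p) per replicate, computes G_P on the
    pooled count, and returns the fraction rejected at ``alpha``. Vectorized:
    the pooled count is Binomial(k·n, p) directly.
    """
    rng = np.random.default_rng(seed)
    pooled = rng.binomial(k * n, p, size=replicates)
    crit = stats.chi2.isf(alpha, 1)
    rejected = 0
    for O in pooled:
        if g_gof(int(O), k * n, p) > crit:
            rejected += 1
    return rejected / replicates
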