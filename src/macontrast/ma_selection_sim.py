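"""Serial-bottleneck mutation-accumulation simulator and selection inference.

The regime emulated is daily serial dilution: a culture grows ~100-fold to
saturation (log2(100) ≈ 6.64 generations per cycle), then a fixed bottleneck
of N_b cells (default 5×10⁶) is transferred to fresh medium. Within-day
growth is treated as deterministic — at ≥5×10⁶ cells, growth-phase drift is
negligible next to transfer sampling — so selection acts through the
relative-fitness frequency update

    f' = f(1+s)^g / (f(1+s)^g + 1 − f)

per cycle of g generations, and drift acts only at the bottleneck, where the
transferred mutant count is Binomial(N_b, f').

A new mutation enters as a single cell at a bottleneck (f₀ = 1/N_b). Its
retention probability over a horizon of cycles, relative to the neutral
case, quantifies how much purifying selection depresses the apparent
mutation-accumulation rate; inverting that ratio curve estimates the average
selection coefficient implied by an observed rate depression. All stochastic
operations take explicit seeds and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class RegimeSpec:
    """Serial-dilution experimental design constants."""

    bottleneck_cells: int = 5_000_000
    growth_factor: float = 100.0
    total_generations: float = 40_000.0

    def __post_init__(self) -> None:
        if self.bottleneck_cells < 1:
            raise ValueError("bottleneck must be at least one cell")
        if self.growth_factor <= 1:
            raise ValueError("growth factor must exceed 1")

    @property
    def generations_per_cycle(self) -> float:
        return math.log2(self.growth_factor)

    @property
    def cycles(self) -> float:
        return self.total_generations / self.generations_per_cycle


def growth_update(f: float, s: float, g: float):
    """Deterministic within-day frequency update over g generations.

    Accepts scalars or numpy arrays of frequencies.
    """
    if 1 + s <= 0:
        raise ValueError("1+s must be positive")
    w = (1.0 + s) ** g
    # group (1 - f) so the endpoints f = 0 and f = 1 are exact
    return f * w / (f * w + (1.0 - f))


def bottleneck_sample(f, n_b: int, rng: np.random.Generator):
    """Binomial transfer sampling: returns X/N_b with X ~ Binomial(N_b, f)."""
    return rng.binomial(n_b, f) / n_b


# ---------------------------------------------------------------------------
# Lineage retention
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetentionResult:
    probability: float
    mc_se: float
    replicates: int
    cycles: int
    s: float
    seed: int


def _simulate_retention(
    s: float, regime: RegimeSpec, cycles: int, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Final frequencies of `replicates` lineages started at f0 = 1/N_b."""
    g = regime.generations_per_cycle
    n_b = regime.bottleneck_cells
    f = np.full(replicates, 1.0 / n_b)
    alive = np.ones(replicates, dtype=bool)
    for _ in range(cycles):
        fa = growth_update(f[alive], s, g)
        f[alive] = rng.binomial(n_b, fa) / n_b
        alive = f > 0.0
        if not alive.any():
            break
    return f


def retention_probability(
    s: float,
    regime: RegimeSpec | None = None,
    horizon: float = 400.0,
    replicates: int = 10_000,
    seed: int = 0,
) -> RetentionResult:
    """Fraction of lineages (single founder cell at a bottleneck) still
    present after ``horizon`` generations of growth+bottleneck cycles.

    "Present" means at least one copy in the bottleneck sample. The Monte
    Carlo standard error is the binomial SE of the retained fraction.
    """
    regime = regime or RegimeSpec()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cycles = int(horizon / regime.generations_per_cycle)
    if cycles < 1:
        raise ValueError("horizon shorter than one growth+bottleneck cycle")
    rng = np.random.default_rng(seed)
    final = _simulate_retention(s, regime, cycles, replicates, rng)
    p_hat = float(np.mean(final > 0))
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / replicates) / replicates)
    return RetentionResult(p_hat, se, replicates, cycles, s, seed)


@dataclass(frozen=True)
class DepressionRatio:
    ratio: float
    infinite: bool
    retention_neutral: RetentionResult
    retention_selected: RetentionResult
    mc_se: float


def rate_depression_ratio(
    s: float,
    regime: RegimeSpec | None = None,
    horizon: float = 400.0,
    replicates: int = 10_000,
    seed: int = 0,
) -> DepressionRatio:
    """Fold depression of mutant retention: retention(0) / retention(s).

    Both legs are simulated from the same seed (common random numbers), so
    the ratio at s = 0 is exactly 1 and the comparison is variance-reduced.
    """
    r0 = retention_probability(0.0, regime, horizon, replicates, seed)
    rs = retention_probability(s, regime, horizon, replicates, seed)
    if rs.probability == 0.0:
        return DepressionRatio(math.inf, True, r0, rs, math.inf)
    ratio = r0.probability / rs.probability
    # independent-leg delta-method SE; conservative given the shared seed
    rel = math.sqrt(
        (r0.mc_se / r0.probability) ** 2 + (rs.mc_se / rs.probability) ** 2
    )
    return DepressionRatio(ratio, False, r0, rs, ratio * rel)


# ---------------------------------------------------------------------------
# Inversion: selection coefficient from an observed rate depression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionEstimate:
    s_hat: float
    mc_se: float
    replicates: int
    seed: int
    observed_ratio: float | None = None
    bracket: tuple[float, float] | None = None


def infer_selection_coefficient(
    observed_ratio: float,
    regime: RegimeSpec | None = None,
    horizon: float = 400.0,
    replicates: int = 20_000,
    seed: int = 0,
    tol: float = 1e-4,
    s_min: float = -0.5,
) -> SelectionEstimate:
    """Selection coefficient whose simulated retention-depression ratio
    matches ``observed_ratio``.

    Bisects s over [s_min, 0]; every ratio evaluation reuses the same seed,
    making the Monte-Carlo ratio curve a fixed, monotone function of s so
    that bisection is well posed. The reported standard error propagates the
    ratio's Monte Carlo error through the local slope of the curve.
    """
    regime = regime or RegimeSpec()
    if observed_ratio < 1:
        raise ValueError("observed ratio must be >= 1")
    if observed_ratio == 1.0:
        return SelectionEstimate(0.0, 0.0, replicates, seed, observed_ratio, (0.0, 0.0))

    def ratio_at(s: float) -> DepressionRatio:
        return rate_depression_ratio(s, regime, horizon, replicates, seed)

    lo, hi = s_min, 0.0  # ratio(lo) >= observed >= ratio(hi)=1
    d_lo = ratio_at(lo)
    if not d_lo.infinite and d_lo.ratio < observed_ratio:
        raise ValueError(
            f"ratio {observed_ratio} not achievable by s >= {s_min} "
            f"at this horizon (max simulated {d_lo.ratio:.3g})"
        )
    d_mid = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        d_mid = ratio_at(mid)
        if d_mid.infinite or d_mid.ratio >= observed_ratio:
            lo = mid
        else:
            hi = mid
    s_hat = 0.5 * (lo + hi)
    # local slope of the ratio curve for error propagation
    delta = max(10 * tol, abs(s_hat) * 0.05)
    r_minus = ratio_at(s_hat - delta)
    r_plus = ratio_at(min(s_hat + delta, 0.0))
    d_hat = d_mid if d_mid is not None else ratio_at(s_hat)
    if r_minus.infinite or abs(s_hat + delta) < 1e-12:
        slope = abs((r_minus.ratio if not r_minus.infinite else observed_ratio * 2) - 1) / delta
    else:
        slope = abs(r_minus.ratio - r_plus.ratio) / (2 * delta)
    mc_se = (d_hat.mc_se / slope) if slope > 0 else abs(s_hat)
    mc_se = max(mc_se, tol)
    return SelectionEstimate(
        s_hat, float(mc_se), replicates, seed, observed_ratio, (lo, hi)
    )


# ---------------------------------------------------------------------------
# Reconstruction controls: mixture trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureTrajectory:
    """Mutant frequency observed at successive growth+bottleneck cycles."""

    cycles: list[int]
    frequencies: list[float]
    true_s: float | None = None
    generations_per_cycle: float = field(default=math.log2(100.0))

    def __post_init__(self) -> None:
        if len(self.cycles) != len(self.frequencies):
            raise ValueError("cycles and frequencies differ in length")
        if any(b <= a for a, b in zip(self.cycles, self.cycles[1:])):
            raise ValueError("cycle indices must be strictly increasing")
        if any(not 0 <= f <= 1 for f in self.frequencies):
            raise ValueError("frequencies must lie in [0, 1]")


def simulate_mixture_trajectory(
    f0: float,
    s: float,
    n_cycles: int,
    regime: RegimeSpec | None = None,
    seed: int | None = None,
) -> MixtureTrajectory:
    """Simulate a reconstruction control started from an artificial mixture.

    With ``seed=None`` the trajectory is the deterministic growth update
    alone (no bottleneck noise); otherwise binomial transfer sampling is
    applied each cycle.
    """
    regime = regime or RegimeSpec()
    g = regime.generations_per_cycle
    rng = None if seed is None else np.random.default_rng(seed)
    f = f0
    cyc, freqs = [0], [f0]
    for c in range(1, n_cycles + 1):
        f = growth_update(f, s, g)
        if rng is not None:
            f = bottleneck_sample(f, regime.bottleneck_cells, rng)
        cyc.append(c)
        freqs.append(float(f))
    return MixtureTrajectory(cyc, freqs, true_s=s, generations_per_cycle=g)


def fit_selection_from_mixture(
    trajectory: MixtureTrajectory, g: float | None = None
) -> SelectionEstimate:
    """Estimate s from a mixture trajectory by logit-linear regression.

    Under the growth model, ln(f/(1−f)) is linear in cumulative generations
    with slope ln(1+s); the least-squares slope is inverted to s. Points at
    exactly 0 or 1 carry no information about s and are dropped.
    """
    g = trajectory.generations_per_cycle if g is None else g
    pts = [
        (c * g, math.log(f / (1 - f)))
        for c, f in zip(trajectory.cycles, trajectory.frequencies)
        if 0.0 < f < 1.0
    ]
    if len(pts) < 2:
        raise ValueError("need at least 2 interior-frequency points to fit s")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, _ = np.polyfit(x, y, 1)
    resid = y - (slope * x + np.mean(y - slope * x))
    if len(pts) > 2:
        se_slope = math.sqrt(
            float(np.sum(resid**2)) / (len(pts) - 2) / float(np.sum((x - x.mean()) ** 2))
        )
    else:
        se_slope = 0.0
    s_hat = math.expm1(slope)
    return SelectionEstimate(
        s_hat=float(s_hat),
        mc_se=float(se_slope * (1.0 + s_hat)),  # delta method through exp
        replicates=len(pts),
        seed=-1,
    )
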