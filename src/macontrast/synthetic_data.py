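"""Synthetic genomes, genes, mutation tables, and MA count data.

Every generator takes an explicit seed and produces data whose statistical
structure is fully known, so each pipeline stage can be tested for parameter
recovery without external data:

* genomes are i.i.d. base sequences with a configurable G+C fraction;
* genes sample codons within each synonymous family proportional to a
  supplied usage table, so codon-usage-vector tallies have a known target;
* planted mutations draw their site with weight exp(β·c), where c is the
  G/C count in the ±flank window around the site (center excluded) — β = 0
  is exactly the uniform null the context G-test assumes, and β > 0 creates
  the G/C-rich-neighborhood hypermutability alternative;
* MA line counts are Poisson with mean rate × generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import (
    BACTERIAL_CODE,
    CodonUsageTable,
    Genome,
    MutationRecord,
    SENSE_CODONS,
)
from .spectra_codon import GeneAnnotation, SubstitutionClass, revcomp

CLASS_ORDER = list(SubstitutionClass)

#: alt base for each (strand-collapsed class, forward-strand ref base)
_ALT_OF: dict[tuple[SubstitutionClass, str], str] = {
    (SubstitutionClass.GC_TO_AT, "G"): "A",
    (SubstitutionClass.GC_TO_AT, "C"): "T",
    (SubstitutionClass.GC_TO_TA, "G"): "T",
    (SubstitutionClass.GC_TO_TA, "C"): "A",
    (SubstitutionClass.GC_TO_CG, "G"): "C",
    (SubstitutionClass.GC_TO_CG, "C"): "G",
    (SubstitutionClass.AT_TO_GC, "A"): "G",
    (SubstitutionClass.AT_TO_GC, "T"): "C",
    (SubstitutionClass.AT_TO_CG, "A"): "C",
    (SubstitutionClass.AT_TO_CG, "T"): "G",
    (SubstitutionClass.AT_TO_TA, "A"): "T",
    (SubstitutionClass.AT_TO_TA, "T"): "A",
}


@dataclass(frozen=True)
class SynthSpec:
    """Bundle of generator parameters for a full synthetic dataset."""

    genome_length: int = 100_000
    gc_fraction: float = 0.508
    n_genes: int = 10
    gene_length_codons: int = 100
    n_mutations: int = 23
    spectrum_probs: tuple[float, ...] = (
        0.45, 0.15, 0.05, 0.15, 0.05, 0.15,
    )  # over CLASS_ORDER
    context_beta: float = 0.0
    flank: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum_probs) - 1.0) > 1e-9:
            raise ValueError("spectrum probabilities must sum to 1")
        if len(self.spectrum_probs) != len(CLASS_ORDER):
            raise ValueError("need one probability per substitution class")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")
        if min(self.genome_length, self.n_genes, self.gene_length_codons) < 1:
            raise ValueError("lengths must be positive")


def make_genome(
    length: int, p: float, seed: int, identifier: str = "synthetic"
) -> Genome:
    """i.i.d. genome with P(G)=P(C)=p/2 and P(A)=P(T)=(1−p)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = rng.choice(
        np.array(list("GCAT")),
        size=length,
        p=[p / 2, p / 2, (1 - p) / 2, (1 - p) / 2],
    )
    return Genome(identifier=identifier, sequence="".join(bases))


# ---------------------------------------------------------------------------
# Genes with usage-biased codon sampling
# ---------------------------------------------------------------------------

def _families(table: CodonUsageTable) -> dict[str, tuple[list[str], list[float]]]:
    fams: dict[str, tuple[list[str], list[float]]] = {}
    for codon in sorted(table.frequencies):
        aa = BACTERIAL_CODE[codon]
        fams.setdefault(aa, ([], []))
        fams[aa][0].append(codon)
        fams[aa][1].append(table.family_fractions[codon])
    return fams


def sample_codons(
    n: int, usage_table: CodonUsageTable, rng: np.random.Generator
) -> list[str]:
    """Sample n sense codons: amino acid uniform over available families,
    codon within family proportional to usage fractions."""
    fams = _families(usage_table)
    aas = sorted(fams)
    if not aas:
        raise ValueError("usage table has no codon families")
    picks = rng.choice(len(aas), size=n)
    out = []
    for i in picks:
        codons, fracs = fams[aas[i]]
        out.append(codons[rng.choice(len(codons), p=np.asarray(fracs) / sum(fracs))])
    return out


def make_genes(
    n_genes: int,
    gene_length_codons: int,
    usage_table: CodonUsageTable,
    seed: int,
    intergenic: int = 50,
    gc_fraction: float = 0.508,
) -> tuple[Genome, list[GeneAnnotation]]:
    """Genome of usage-biased coding genes separated by i.i.d. spacers.

    Each gene is ATG + sampled sense codons + TAA; strands alternate so both
    orientations are exercised. Returns the assembled genome and one
    annotation per gene (1-based inclusive coordinates).
    """
    if gene_length_codons < 2:
        raise ValueError("genes need at least 2 codons")
    rng = np.random.default_rng(seed)

    def spacer(k: int) -> str:
        p = gc_fraction
        return "".join(
            rng.choice(
                np.array(list("GCAT")),
                size=k,
                p=[p / 2, p / 2, (1 - p) / 2, (1 - p) / 2],
            )
        )

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0
    for i in range(n_genes):
        parts.append(spacer(intergenic))
        pos += intergenic
        body = sample_codons(gene_length_codons - 2, usage_table, rng)
        cds = "ATG" + "".join(body) + "TAA"
        strand = "+" if i % 2 == 0 else "-"
        start = pos + 1
        end = pos + len(cds)
        parts.append(cds if strand == "+" else revcomp(cds))
        annotations.append(GeneAnnotation(f"gene{i + 1}", start, end, strand))
        pos = end
    parts.append(spacer(intergenic))
    return Genome("synthetic-genes", "".join(parts)), annotations


# ---------------------------------------------------------------------------
# Planted mutations with context-dependent site weights
# ---------------------------------------------------------------------------

def plant_mutations(
    genome: Genome,
    n: int,
    spectrum_probs: Sequence[float],
    beta: float = 0.0,
    flank: int = 5,
    seed: int = 0,
) -> list[MutationRecord]:
    """Plant n substitutions with context-weighted sites and a known spectrum.

    The n substitution classes are drawn first, Multinomial(n,
    ``spectrum_probs``) over the six strand-collapsed classes — so
    summarize_spectrum recovers ``spectrum_probs`` directly. Each class then
    receives a site drawn (without replacement) from the sites whose
    reference base matches the class's starting pair, with probability
    ∝ exp(β·c_i), where c_i is the G/C count in the ±flank window around
    site i, the center excluded — matching the context test's
    center-exclusion convention. β = 0 is the uniform null. Under linear
    topology only sites with a complete window are eligible. The alt base
    follows deterministically from class + reference base, so every record
    validates against the genome by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = np.asarray(spectrum_probs, dtype=float)
    if probs.shape != (6,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("spectrum_probs must be 6 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_gc = np.isin(seq, [b"G", b"C"])

    kernel = np.ones(2 * flank + 1)
    kernel[flank] = 0.0  # center excluded from c(site)
    if genome.topology == "circular":
        ext = np.concatenate([is_gc[-flank:], is_gc, is_gc[:flank]])
        c = np.convolve(ext.astype(float), kernel, mode="valid")
        eligible = np.arange(genome.length)
    else:
        c = np.convolve(is_gc.astype(float), kernel, mode="same")
        eligible = np.arange(flank, genome.length - flank)
    if len(eligible) == 0:
        raise ValueError("no eligible sites (genome shorter than window)")

    class_counts = rng.multinomial(n, probs)
    n_gc_needed = int(class_counts[:3].sum())
    n_at_needed = int(class_counts[3:].sum())

    chosen: list[tuple[int, SubstitutionClass]] = []
    for pair_is_gc, needed, class_idx in (
        (True, n_gc_needed, (0, 1, 2)),
        (False, n_at_needed, (3, 4, 5)),
    ):
        if needed == 0:
            continue
        pool = eligible[is_gc[eligible] == pair_is_gc]
        if len(pool) < needed:
            pair = "G·C" if pair_is_gc else "A·T"
            raise ValueError(f"only {len(pool)} eligible {pair} sites for {needed} mutations")
        logw = beta * c[pool]
        w = np.exp(logw - logw.max())
        sites = rng.choice(pool, size=needed, replace=False, p=w / w.sum())
        labels = [CLASS_ORDER[i] for i in class_idx for _ in range(class_counts[i])]
        chosen.extend(zip((int(x) for x in sites), labels))

    records: list[MutationRecord] = []
    for j, (idx, klass) in enumerate(sorted(chosen)):
        ref = genome.sequence[idx]
        alt = _ALT_OF[(klass, ref)]
        records.append(
            MutationRecord(id=f"m{j + 1}", position=idx + 1, ref_base=ref, alt_base=alt)
        )
    return records


def simulate_ma_counts(
    rate_per_genome: float, T: float, n_lines: int, seed: int = 0
) -> np.ndarray:
    """Per-line mutation counts: independent Poisson(rate × T) draws."""
    if rate_per_genome < 0 or T < 0:
        raise ValueError("rate and generations must be non-negative")
    if n_lines < 1:
        raise ValueError("need at least one line")
    rng = np.random.default_rng(seed)
    return rng.poisson(rate_per_genome * T, size=n_lines)


def uniform_usage_table(overrides: dict[str, float] | None = None) -> CodonUsageTable:
    """Complete 61-codon usage table, uniform within families unless
    overridden. Convenience for tests and synthetic gene generation."""
    freqs = {c: 1.0 for c in SENSE_CODONS}
    if overrides:
        freqs.update({k.upper().replace("U", "T"): v for k, v in overrides.items()})
    return CodonUsageTable(freqs)
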