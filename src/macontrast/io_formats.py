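"""Input/output layer: genomes, mutation tables, codon usage tables, reports.

Coordinate convention used throughout the package: positions are 1-based,
inclusive, on the forward strand (conventional GenBank numbering).

File formats
------------
* Genome: standard FASTA (multi-line records allowed), read via Biopython.
* Mutation table: TSV with header; required columns ``id``, ``position``,
  ``ref``, ``alt``; optional columns ``gene``, ``codon_before``,
  ``codon_after``, ``strand`` are preserved.
* Codon usage table: TSV with header ``codon``, ``aa``, ``freq``; frequencies
  may be per-thousand or relative — they are normalized internally to
  within-synonymous-family fractions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

VALID_BASES = frozenset("ACGT")

#: Standard bacterial/archaeal genetic code (NCBI translation table 11),
#: as a codon -> amino-acid mapping with '*' for stop.
_table11 = CodonTable.unambiguous_dna_by_id[11]
BACTERIAL_CODE: Mapping[str, str] = {
    **dict(_table11.forward_table),
    **{c: "*" for c in _table11.stop_codons},
}
SENSE_CODONS: frozenset[str] = frozenset(
    c for c, aa in BACTERIAL_CODE.items() if aa != "*"
)


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


class ValidationError(ValueError):
    """Raised when mutation records contradict the attached genome."""

    def __init__(self, message: str, offending_ids: Sequence[str] = ()):
        super().__init__(message)
        self.offending_ids = list(offending_ids)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A validated nucleotide sequence with linear or circular topology.

    ``sequence`` holds uppercase A/C/G/T only (ambiguity codes are either
    rejected at read time or masked to ``N`` and excluded downstream).
    """

    identifier: str
    sequence: str
    topology: str = "linear"  # {"linear", "circular"}

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not self.sequence:
            raise FormatError("empty genome sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def base(self, position: int) -> str:
        """Base at a 1-based forward-strand coordinate (wraps if circular)."""
        if self.topology == "circular":
            return self.sequence[(position - 1) % self.length]
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]


def read_fasta(
    path: str | Path,
    name: str | None = None,
    topology: str = "linear",
    ambiguity: str = "reject",
) -> Genome:
    """Read one genome record from a FASTA file.

    Parameters
    ----------
    name
        Record id to select; by default the first record is used.
    ambiguity
        ``"reject"`` (default) fails on non-ACGT characters, reporting the
        first offending position; ``"mask"`` replaces them with ``N``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = SeqIO.parse(str(path), "fasta")
    chosen = None
    for rec in records:
        if name is None or rec.id == name:
            chosen = rec
            break
    if chosen is None:
        raise FormatError(
            f"no FASTA record {'named ' + name if name else ''} in {path}"
        )
    seq = str(chosen.seq).upper()
    if not seq:
        raise FormatError(f"record {chosen.id!r} in {path} is empty")
    bad = [i for i, b in enumerate(seq) if b not in VALID_BASES]
    if bad:
        if ambiguity == "reject":
            raise FormatError(
                f"non-ACGT character {seq[bad[0]]!r} at position {bad[0] + 1} "
                f"in record {chosen.id!r} (and {len(bad) - 1} more)"
            )
        if ambiguity == "mask":
            chars = list(seq)
            for i in bad:
                chars[i] = "N"
            seq = "".join(chars)
        else:
            raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
    return Genome(identifier=chosen.id, sequence=seq, topology=topology)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Mutation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """One observed base substitution on the forward strand."""

    id: str
    position: int  # 1-based
    ref_base: str
    alt_base: str
    gene: str | None = None
    codon_before: str | None = None
    codon_after: str | None = None
    strand_of_gene: str | None = None  # "+" or "-"

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"record {self.id}: ref equals alt ({self.ref_base})")
        for b in (self.ref_base, self.alt_base):
            if b not in VALID_BASES:
                raise ValueError(f"record {self.id}: invalid base {b!r}")
        if self.position < 1:
            raise ValueError(f"record {self.id}: position must be >= 1")


_REQUIRED_COLUMNS = ("id", "position", "ref", "alt")
_OPTIONAL_COLUMNS = ("gene", "codon_before", "codon_after", "strand")


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a TSV mutation table into records, preserving file order.

    Every input row is either accepted or raises with its row number —
    rows are never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[MutationRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        rid = d["id"]
        if rid in seen:
            raise FormatError(f"{path}: duplicate id {rid!r} at row {row_no}")
        seen.add(rid)
        try:
            pos = int(d["position"])
        except ValueError:
            raise FormatError(
                f"{path}: unparsable position {d['position']!r} at row {row_no}"
            ) from None
        opt = {k: (d.get(k) or None) for k in _OPTIONAL_COLUMNS}
        try:
            records.append(
                MutationRecord(
                    id=rid,
                    position=pos,
                    ref_base=d["ref"].upper(),
                    alt_base=d["alt"].upper(),
                    gene=opt["gene"],
                    codon_before=opt["codon_before"],
                    codon_after=opt["codon_after"],
                    strand_of_gene=opt["strand"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {row_no}: {exc}") from None
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "position": r.position,
                "ref": r.ref_base,
                "alt": r.alt_base,
                "gene": r.gene or "",
                "codon_before": r.codon_before or "",
                "codon_after": r.codon_after or "",
                "strand": r.strand_of_gene or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def validate_against_genome(
    records: Sequence[MutationRecord], genome: Genome
) -> list[MutationRecord]:
    """Check that each record's reference base matches the genome.

    Returns the records unchanged when all pass; raises
    :class:`ValidationError` listing every offending id otherwise.
    Idempotent: validating the returned list again is a no-op.
    """
    mismatches: list[str] = []
    for r in records:
        if not 1 <= r.position <= genome.length:
            mismatches.append(f"{r.id} (position {r.position} outside genome)")
            continue
        actual = genome.base(r.position)
        if actual != r.ref_base:
            mismatches.append(
                f"{r.id} (genome has {actual} at {r.position}, table says {r.ref_base})"
            )
    if mismatches:
        raise ValidationError(
            f"{len(mismatches)} of {len(records)} records contradict the genome: "
            + "; ".join(mismatches),
            offending_ids=[m.split(" ")[0] for m in mismatches],
        )
    return list(records)


# ---------------------------------------------------------------------------
# Codon usage tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonUsageTable:
    """Codon -> usage frequency, with derived within-family fractions.

    A "family" is the set of sense codons translating to one amino acid under
    the bacterial genetic code. Input frequencies may be on any common scale
    (per-thousand, percent, relative); only within-family ratios matter.
    """

    frequencies: Mapping[str, float]
    family_fractions: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        freqs = {c.upper().replace("U", "T"): float(v) for c, v in self.frequencies.items()}
        for codon, v in freqs.items():
            if codon not in BACTERIAL_CODE:
                raise FormatError(f"unknown codon {codon!r}")
            if BACTERIAL_CODE[codon] == "*":
                raise FormatError(f"stop codon {codon!r} has no usage frequency")
            if v < 0 or math.isnan(v):
                raise FormatError(f"negative/NaN frequency for {codon!r}")
        object.__setattr__(self, "frequencies", freqs)
        totals: dict[str, float] = {}
        for codon, v in freqs.items():
            aa = BACTERIAL_CODE[codon]
            totals[aa] = totals.get(aa, 0.0) + v
        fractions: dict[str, float] = {}
        for codon, v in freqs.items():
            tot = totals[BACTERIAL_CODE[codon]]
            if tot <= 0:
                raise FormatError(
                    f"family of {codon!r} ({BACTERIAL_CODE[codon]}) sums to zero"
                )
            fractions[codon] = v / tot
        object.__setattr__(self, "family_fractions", fractions)

    @property
    def is_complete(self) -> bool:
        return set(self.frequencies) == SENSE_CODONS

    def require_complete(self) -> "CodonUsageTable":
        if not self.is_complete:
            missing = sorted(SENSE_CODONS - set(self.frequencies))
            raise FormatError(f"usage table missing {len(missing)} sense codons: {missing[:5]}...")
        return self

    def fraction(self, codon: str) -> float:
        codon = codon.upper().replace("U", "T")
        if codon not in self.family_fractions:
            raise KeyError(f"codon {codon!r} not in usage table")
        return self.family_fractions[codon]


def read_usage_table(path: str | Path) -> CodonUsageTable:
    """Read a TSV codon usage table (columns codon, aa, freq); must cover all
    61 sense codons."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"codon": str, "freq": float})
    for col in ("codon", "freq"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    table = CodonUsageTable(dict(zip(df["codon"], df["freq"])))
    return table.require_complete()


def write_usage_table(table: CodonUsageTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"codon": c, "aa": BACTERIAL_CODE[c], "freq": v}
        for c, v in sorted(table.frequencies.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int):
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def to_plain(results) -> dict:
    """Convert a result dataclass (or mapping) to plain JSON-ready types."""
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        d = dataclasses.asdict(results)
    elif isinstance(results, Mapping):
        d = dict(results)
    else:
        raise TypeError(f"cannot serialize {type(results).__name__}")
    return _round_floats(json.loads(json.dumps(d, default=_json_default)), 6)


def _json_default(o):
    import enum

    import numpy as np

    if isinstance(o, enum.Enum):
        return o.value
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o).__name__}")


def write_report(results, path: str | Path, format: str = "json") -> Path:
    """Write a stage result to JSON (nested) or TSV (flat key/value).

    Field order is deterministic; floats are emitted at 6 significant digits.
    """
    path = Path(path)
    plain = to_plain(results)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(plain, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "tsv":
        flat = _flatten(plain)
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in flat:
                fh.write(f"{k}\t{v}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _flatten(obj, prefix: str = "") -> list[tuple[str, object]]:
    out: list[tuple[str, object]] = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.extend(_flatten(v, f"{prefix}{k}." if prefix else f"{k}."))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            out.extend(_flatten(v, f"{prefix}{i}."))
    else:
        out.append((prefix.rstrip("."), obj))
    return out
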