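"""Codon-level primitives.

The standard genetic code (translation table 1), a fixed canonical ordering
of the 64 codons, CDS cleaning/framing, and per-CDS codon counting into the
64-dimensional percentage vectors that every downstream stage consumes.

Stop codons are ordinary features here: they are counted, they enter the
percentage denominator, and the stop "family" (symbol ``*``) is treated like
any synonymous family. Extremophile codon preference analyses report stop
codons among their significant and harmonised codons, so excluding them
would silently change every percentage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

DNA_BASES = "ACGT"

#: Canonical ordering of the 64 codons: alphabetical, AAA .. TTT.
#: Every matrix/vector in the package uses this column order.
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(DNA_BASES, repeat=3)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_SYMBOL = "*"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid (stops map to ``*``); 61 sense + 3 stop.
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
CODON_TO_AA.update({c: STOP_SYMBOL for c in _standard.stop_codons})

#: amino-acid symbol (incl. ``*``) -> frozenset of synonymous codons.
#: The family sets partition the 64 codons.
FAMILIES: dict[str, frozenset[str]] = {}
for _codon in CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_codon], set()).add(_codon)  # type: ignore[arg-type]
FAMILIES = {aa: frozenset(cs) for aa, cs in FAMILIES.items()}

#: The 20 proteinogenic amino acids, sorted.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(a for a in FAMILIES if a != STOP_SYMBOL))

STOP_CODONS: frozenset[str] = FAMILIES[STOP_SYMBOL]


class CdsError(ValueError):
    """A coding sequence could not be turned into a valid codon list."""


def is_valid_codon(codon: str) -> bool:
    return codon in CODON_INDEX


def clean_and_frame(
    raw_sequence: str,
    policy: str = "exclude",
    record_id: str | None = None,
) -> list[str]:
    """Normalise a raw nucleotide sequence and chunk it into frame-0 codons.

    Cleaning: whitespace removed, uppercased, RNA ``U`` mapped to ``T``.
    The frame always starts at the first base (full-length CDS assumption);
    1-2 trailing leftover bases are dropped with a logged warning.

    Parameters
    ----------
    policy:
        ``"exclude"`` (default) drops codons containing any non-ACGT
        character from counting (logged); ``"strict"`` rejects the record.

    Raises
    ------
    CdsError
        Empty sequence, no valid codon left, or an ambiguous codon under
        ``"strict"``.
    """
    if policy not in ("exclude", "strict"):
        raise ValueError(f"unknown cleaning policy {policy!r}")
    name = record_id or "<unnamed>"
    seq = "".join(raw_sequence.split()).upper().replace("U", "T")
    if not seq:
        raise CdsError(f"record {name}: empty sequence")
    leftover = len(seq) % 3
    if leftover:
        log.warning(
            "record %s: dropping %d trailing base(s) (length %d not a multiple of 3)",
            name, leftover, len(seq),
        )
        seq = seq[: len(seq) - leftover]
    codons: list[str] = []
    n_excluded = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in CODON_INDEX:
            codons.append(codon)
        elif policy == "strict":
            raise CdsError(
                f"record {name}: ambiguous codon {codon!r} at position {i} (strict mode)"
            )
        else:
            n_excluded += 1
    if n_excluded:
        log.warning("record %s: excluded %d ambiguous codon(s)", name, n_excluded)
    if not codons:
        raise CdsError(f"record {name}: no valid codons after cleaning")
    return codons


@dataclass
class CdsRecord:
    """One coding sequence with its cleaned codon list and class label."""

    id: str
    raw_sequence: str
    codons: list[str] = field(default_factory=list)
    class_label: str = ""
    organism: str | None = None

    @classmethod
    def from_sequence(
        cls,
        id: str,
        raw_sequence: str,
        class_label: str = "",
        organism: str | None = None,
        policy: str = "exclude",
    ) -> "CdsRecord":
        codons = clean_and_frame(raw_sequence, policy=policy, record_id=id)
        return cls(id=id, raw_sequence=raw_sequence, codons=codons,
                   class_label=class_label, organism=organism)


@dataclass(frozen=True)
class CodonFrequencyVector:
    """Counts and percentages over the 64 codons in canonical order.

    ``percentages[i] == 100 * counts[i] / total_codons``; the denominator is
    the number of valid codons counted, stop codons included.
    """

    counts: np.ndarray
    total_codons: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(counts.sum()) != self.total_codons:
            raise ValueError("sum(counts) must equal total_codons")
        if self.total_codons <= 0:
            raise ValueError("total_codons must be positive")

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.total_codons

    def percentage_of(self, codon: str) -> float:
        return float(self.percentages[CODON_INDEX[codon]])


def count_codons(codons: list[str]) -> CodonFrequencyVector:
    """Count a codon list into a :class:`CodonFrequencyVector`.

    Counts are additive across concatenated lists; percentages are the
    count-weighted mean of the parts.
    """
    if not codons:
        raise ValueError("cannot count an empty codon list")
    counts = np.zeros(64, dtype=np.int64)
    for codon in codons:
        try:
            counts[CODON_INDEX[codon]] += 1
        except KeyError:
            raise CdsError(f"invalid codon {codon!r}") from None
    return CodonFrequencyVector(counts=counts, total_codons=len(codons))


def counts_from_indices(indices: np.ndarray) -> CodonFrequencyVector:
    """Vectorised counting from canonical codon indices (generator fast path)."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("cannot count an empty codon list")
    counts = np.bincount(indices, minlength=64).astype(np.int64)
    return CodonFrequencyVector(counts=counts, total_codons=int(indices.size))


def translate(codons: list[str]) -> str:
    """Standard-code translation; stop codons render as ``*``."""
    try:
        return "".join(CODON_TO_AA[c] for c in codons)
    except KeyError as exc:
        raise CdsError(f"invalid codon {exc.args[0]!r}") from None
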