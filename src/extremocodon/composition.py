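"""Nucleotide-composition labels of codons and cross-class codon harmony.

A codon is AT-rich when at least two of its three bases are A or T, GC-rich
otherwise; the two labels partition the 64 codons (base counts sum to 3).
The ending label depends solely on the third (wobble) position: A/T-ending
vs G/C-ending — the GC3 dichotomy.

Composition summaries are computed over a "preferred" codon set (the
strictly positive contributors of one comparison); the harmony table crosses
those sets over the six extremophile classes to find codons shared by
several classes and codons favoured by none.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codon_model import CODONS, is_valid_codon

AT_RICH = "AT_RICH"
GC_RICH = "GC_RICH"
AT_END = "AT_END"
GC_END = "GC_END"

#: The six extremophile classes of the paired comparisons.
EXTREMOPHILE_CLASSES = (
    "thermophile", "psychrophile", "acidophile",
    "alkaliphile", "halophile", "barophile",
)


def classify_richness(codon: str) -> str:
    """AT_RICH if >= 2 of the 3 bases are A or T, else GC_RICH."""
    if not is_valid_codon(codon):
        raise ValueError(f"invalid codon {codon!r}")
    at = sum(base in "AT" for base in codon)
    return AT_RICH if at >= 2 else GC_RICH


def classify_ending(codon: str) -> str:
    """AT_END or GC_END by the third (wobble) base alone."""
    if not is_valid_codon(codon):
        raise ValueError(f"invalid codon {codon!r}")
    return AT_END if codon[2] in "AT" else GC_END


@dataclass(frozen=True)
class CompositionSummary:
    """Composition percentages of one preferred-codon set.

    Each pair of percentages sums to 100 (the labels are exhaustive and
    mutually exclusive).
    """

    preferred_set: frozenset[str]
    pct_at_rich: float
    pct_gc_rich: float
    pct_at_end: float
    pct_gc_end: float

    def to_dict(self) -> dict:
        return {
            "preferred_codons": sorted(self.preferred_set),
            "n_preferred": len(self.preferred_set),
            "pct_at_rich": self.pct_at_rich,
            "pct_gc_rich": self.pct_gc_rich,
            "pct_at_end": self.pct_at_end,
            "pct_gc_end": self.pct_gc_end,
        }


def composition_summary(preferred: set[str] | frozenset[str]) -> CompositionSummary:
    """Percentage of AT-/GC-rich and A/T-/G/C-ending codons in a set."""
    if not preferred:
        raise ValueError("preferred codon set is empty")
    preferred = frozenset(preferred)
    for codon in preferred:
        if not is_valid_codon(codon):
            raise ValueError(f"invalid codon {codon!r}")
    n = len(preferred)
    n_at_rich = sum(classify_richness(c) == AT_RICH for c in preferred)
    n_at_end = sum(classify_ending(c) == AT_END for c in preferred)
    return CompositionSummary(
        preferred_set=preferred,
        pct_at_rich=100.0 * n_at_rich / n,
        pct_gc_rich=100.0 * (n - n_at_rich) / n,
        pct_at_end=100.0 * n_at_end / n,
        pct_gc_end=100.0 * (n - n_at_end) / n,
    )


@dataclass
class HarmonyTable:
    """Codon x extremophile-class membership with shared counts.

    ``shared_count[codon]`` is the number of classes whose preferred set
    contains the codon (0..6); ``never_preferred`` lists codons absent from
    every supplied class set.
    """

    membership: pd.DataFrame      # 64 rows x class columns, bool
    shared_count: pd.Series       # 64 entries
    never_preferred: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        out = self.membership.copy()
        out.insert(0, "codon", out.index)
        out["shared_count"] = self.shared_count
        return out.reset_index(drop=True)

    def shared_in(self, k: int) -> list[str]:
        """Codons preferred by exactly k classes."""
        return sorted(self.shared_count.index[self.shared_count == k])


def harmony_table(preferred_by_class: dict[str, set[str]]) -> HarmonyTable:
    """Cross the preferred-codon sets of up to six extremophile classes.

    Class labels must come from :data:`EXTREMOPHILE_CLASSES`; an unknown
    label is an error rather than a silently added column.
    """
    unknown = set(preferred_by_class) - set(EXTREMOPHILE_CLASSES)
    if unknown:
        raise ValueError(
            f"unknown extremophile class label(s): {sorted(unknown)}; "
            f"expected a subset of {EXTREMOPHILE_CLASSES}"
        )
    classes = [c for c in EXTREMOPHILE_CLASSES if c in preferred_by_class]
    for cls in classes:
        for codon in preferred_by_class[cls]:
            if not is_valid_codon(codon):
                raise ValueError(f"class {cls!r}: invalid codon {codon!r}")
    membership = pd.DataFrame(
        {cls: [c in preferred_by_class[cls] for c in CODONS] for cls in classes},
        index=list(CODONS),
    )
    shared = membership.sum(axis=1) if classes else pd.Series(0, index=list(CODONS))
    never = sorted(shared.index[shared == 0])
    return HarmonyTable(membership=membership, shared_count=shared,
                        never_preferred=never)
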