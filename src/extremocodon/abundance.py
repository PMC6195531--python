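"""Relative abundance of significant codons, 1-9 preference ranking,
extreme-codon identification, and normalized per-pair data-point series.

The statistics, in the field's notation:

* per-codon class means over the N pairs,
  ``mean_e = (1/N) * sum_i (alpha_e)_i`` and likewise ``mean_ne``;
* the mean difference ``alpha_j = mean_e - mean_ne`` per significant codon;
* relative abundance ``beta_rel = alpha_j / alpha_max`` where ``alpha_max``
  is, by default, the maximum *absolute* difference over the significant
  set — that convention bounds beta_rel in [-1, 1] and preserves its sign.
  The literal signed maximum (which leaves beta_rel unbounded below when
  the largest difference is positive) is available via
  ``alpha_max_mode="signed"``;
* ratio weights ``xi = mean_e / mean_ne`` per significant codon, min-max
  scaled onto the 1-9 interval:
  ``W = ((xi - min xi) / (max xi - min xi)) * 8 + 1``,
  with integer ranks by round-half-up. Rank 9 = most extremophile-preferred
  codon, rank 1 = least.

Positive beta_rel marks a codon as a "positive contributor" to the
extremophile class; those sets feed the composition and harmony analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_model import CODON_INDEX
from .dataset_io import PairedDataset
from .significance import SignificantCodonSet

log = logging.getLogger(__name__)


@dataclass
class AbundanceResult:
    """Per-significant-codon means, differences and relative abundances."""

    dataset_label: str
    codons: list[str]       # significant codons, canonical order
    mean_e: np.ndarray      # % units
    mean_ne: np.ndarray     # % units
    diff: np.ndarray        # alpha_j = mean_e - mean_ne
    alpha_max: float
    beta_rel: np.ndarray    # unitless
    alpha_max_mode: str = "absolute"

    def positive_contributors(self) -> list[str]:
        """Codons with strictly positive relative abundance."""
        return [c for c, b in zip(self.codons, self.beta_rel) if b > 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": self.codons, "mean_e": self.mean_e, "mean_ne": self.mean_ne,
             "diff": self.diff, "beta_rel": self.beta_rel}
        )


def relative_abundance(
    paired: PairedDataset,
    sigset: SignificantCodonSet,
    alpha_max_mode: str = "absolute",
) -> AbundanceResult:
    """Compute relative abundance for every significant codon.

    ``alpha_max_mode``: ``"absolute"`` (default) normalises by
    ``max_j |alpha_j|``; ``"signed"`` uses the literal ``max_j alpha_j``.
    If the maximum is zero (all class means identical) every beta_rel is
    defined as 0 with a warning.
    """
    if alpha_max_mode not in ("absolute", "signed"):
        raise ValueError(f"unknown alpha_max_mode {alpha_max_mode!r}")
    if not sigset.codons:
        raise ValueError(
            f"dataset {paired.dataset_label!r}: empty significant set, "
            "relative abundance is undefined"
        )
    cols = [CODON_INDEX[c] for c in sigset.codons]
    mean_e = paired.matrix_e[:, cols].mean(axis=0)
    mean_ne = paired.matrix_ne[:, cols].mean(axis=0)
    diff = mean_e - mean_ne
    alpha_max = float(np.max(np.abs(diff)) if alpha_max_mode == "absolute"
                      else np.max(diff))
    if alpha_max == 0.0:
        log.warning("dataset %s: all mean differences are zero; "
                    "beta_rel set to 0 for every codon", paired.dataset_label)
        beta_rel = np.zeros_like(diff)
    else:
        beta_rel = diff / alpha_max
    return AbundanceResult(
        dataset_label=paired.dataset_label,
        codons=list(sigset.codons),
        mean_e=mean_e, mean_ne=mean_ne, diff=diff,
        alpha_max=alpha_max, beta_rel=beta_rel,
        alpha_max_mode=alpha_max_mode,
    )


@dataclass
class RankTable:
    """Ratio weights and their 1-9 interval-scale ranks."""

    dataset_label: str
    codons: list[str]
    xi: np.ndarray             # ratio weights mean_e / mean_ne
    W: np.ndarray              # continuous scale values in [1, 9]
    rank: np.ndarray           # integers in {1..9}
    alpha_min: float           # min xi
    beta_max: float            # max xi
    pseudocount_codons: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.codons)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": self.codons, "xi": self.xi, "W": self.W, "rank": self.rank}
        )


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5).astype(int)


def rank_codons(abundance: AbundanceResult) -> RankTable:
    """Map ratio weights onto the 1-9 preference scale.

    xi_i = mean_e / mean_ne per significant codon. A zero denominator gets a
    pseudocount of half the smallest nonzero mean percentage in the table
    (both classes pooled), and the codon is flagged. When every xi is equal
    the scale is degenerate and all ranks are set to 5 with a warning.
    """
    mean_e = np.array(abundance.mean_e, dtype=float)
    mean_ne = np.array(abundance.mean_ne, dtype=float)
    pooled = np.concatenate([mean_e, mean_ne])
    nonzero = pooled[pooled > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1.0
    pseudo_codons = [c for c, d in zip(abundance.codons, mean_ne) if d == 0]
    if pseudo_codons:
        log.warning(
            "dataset %s: zero counterpart mean for %s; using pseudocount %g",
            abundance.dataset_label, pseudo_codons, pseudo,
        )
    denom = np.where(mean_ne == 0, pseudo, mean_ne)
    numer = np.where(mean_e == 0, pseudo, mean_e) if (mean_e == 0).any() else mean_e
    xi = numer / denom
    alpha_min, beta_max = float(xi.min()), float(xi.max())
    if beta_max == alpha_min:
        log.warning("dataset %s: all ratio weights equal (%g); every rank set to 5",
                    abundance.dataset_label, beta_max)
        W = np.full_like(xi, 5.0)
    else:
        W = (xi - alpha_min) / (beta_max - alpha_min) * 8.0 + 1.0
    return RankTable(
        dataset_label=abundance.dataset_label,
        codons=list(abundance.codons),
        xi=xi, W=W, rank=_round_half_up(W),
        alpha_min=alpha_min, beta_max=beta_max,
        pseudocount_codons=pseudo_codons,
    )


def extreme_codons(ranks: RankTable) -> tuple[str, str]:
    """The highest- and lowest-ranked codons (max/min W).

    Exact ties are broken lexicographically on the codon string, so the
    result is deterministic.
    """
    if ranks.n == 0:
        raise ValueError("rank table is empty")
    w_max, w_min = ranks.W.max(), ranks.W.min()
    highest = min(c for c, w in zip(ranks.codons, ranks.W) if w == w_max)
    lowest = min(c for c, w in zip(ranks.codons, ranks.W) if w == w_min)
    return highest, lowest


@dataclass
class DataPointSeries:
    """Per-pair percentages of one codon, normalized to [0, 1] by the
    global maximum over both classes."""

    codon: str
    dataset_label: str
    pair_ids: list[str]
    values_e: np.ndarray
    values_ne: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pair_id": self.pair_ids, "score_e": self.values_e,
             "score_ne": self.values_ne}
        )


def datapoint_series(paired: PairedDataset, codon: str) -> DataPointSeries:
    """Normalized per-pair scores of one codon across both classes.

    Raw percentages are divided by the maximum raw value over the union of
    both classes, so the largest data-point is exactly 1. If every raw value
    is zero the series is all zeros (no division) with a warning.
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    j = CODON_INDEX[codon]
    raw_e = paired.matrix_e[:, j].astype(float)
    raw_ne = paired.matrix_ne[:, j].astype(float)
    top = max(raw_e.max(initial=0.0), raw_ne.max(initial=0.0))
    if top == 0.0:
        log.warning("dataset %s: codon %s absent from every CDS; "
                    "data-point series is all zeros", paired.dataset_label, codon)
        values_e, values_ne = raw_e, raw_ne
    else:
        values_e, values_ne = raw_e / top, raw_ne / top
    return DataPointSeries(
        codon=codon, dataset_label=paired.dataset_label,
        pair_ids=list(paired.pair_ids),
        values_e=values_e, values_ne=values_ne,
    )
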