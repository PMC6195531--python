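"""Per-codon significance filtering with the two-sample Kolmogorov-Smirnov test.

For each of the 64 codons, the N extremophile percentages are compared
against the N counterpart percentages with the (unpaired) two-sample KS
test; codons with p < alpha (default 0.05) form the significant set. The
set size M is the normaliser used later by the relative-abundance maximum.

No multiple-testing correction is applied by default — the raw per-codon
threshold is the field's convention for this screen — but Benjamini-
Hochberg can be switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import CODONS
from .dataset_io import PairedDataset

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class KsResult:
    codon: str
    D: float
    p_value: float
    significant: bool


@dataclass
class SignificantCodonSet:
    """All 64 per-codon KS results plus the ordered significant subset."""

    dataset_label: str
    alpha: float
    codons: list[str]          # significant, canonical order
    results: list[KsResult]    # all 64, canonical order

    @property
    def n_significant(self) -> int:
        return len(self.codons)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": [r.codon for r in self.results],
                "D": [r.D for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )


def ks_two_sample(
    sample_a, sample_b, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and p-value.

    D is the supremum absolute difference of the two empirical CDFs. The
    p-value is asymptotic by default; ``method="exact"`` switches to the
    exact null distribution (sensible for n <= 25), ``"auto"`` lets scipy
    choose. Two samples that are constant at the same value are identical
    distributions: (D, p) = (0, 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    if a.std() == 0 and b.std() == 0 and a[0] == b[0]:
        return 0.0, 1.0
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def filter_significant(
    paired: PairedDataset,
    alpha: float = DEFAULT_ALPHA,
    method: str = "asymp",
    bh_correct: bool = False,
) -> SignificantCodonSet:
    """Run the per-codon KS screen over a paired dataset.

    Requires N >= 2 pairs. Significance is strict: p < alpha. ``alpha >= 1``
    disables the filter entirely (every codon is flagged, including those
    with p exactly 1). With ``bh_correct`` the Benjamini-Hochberg adjusted
    p-values are thresholded instead.
    """
    if paired.n_pairs < 2:
        raise ValueError(
            f"dataset {paired.dataset_label!r}: need >= 2 pairs for the KS "
            f"screen, got {paired.n_pairs}"
        )
    Ds, ps = [], []
    for j in range(64):
        D, p = ks_two_sample(paired.matrix_e[:, j], paired.matrix_ne[:, j],
                             method=method)
        Ds.append(D)
        ps.append(p)
    ps_eff = np.asarray(ps)
    if bh_correct:
        ps_eff = stats.false_discovery_control(ps_eff, method="bh")
    flags = np.ones(64, dtype=bool) if alpha >= 1.0 else ps_eff < alpha
    results = [
        KsResult(codon=CODONS[j], D=Ds[j], p_value=ps[j], significant=bool(flags[j]))
        for j in range(64)
    ]
    significant = [CODONS[j] for j in range(64) if flags[j]]
    log.info("dataset %s: %d/64 codons significant at alpha=%g%s",
             paired.dataset_label, len(significant), alpha,
             " (BH-corrected)" if bh_correct else "")
    return SignificantCodonSet(
        dataset_label=paired.dataset_label,
        alpha=alpha,
        codons=significant,
        results=results,
    )
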