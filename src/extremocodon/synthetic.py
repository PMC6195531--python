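"""Synthetic paired-CDS generator.

Emulates homologous extremophile / counterpart gene pairs: both members of a
pair encode the *same* amino-acid sequence, but each class draws its
synonymous codons from its own per-family probability profile. Known biases
(e.g. AGG enriched and CAA depleted in a thermophile-like class) are
injected by shifting probability mass within a synonymous family, so the
generator's ground truth is exact and every downstream detection claim can
be checked against it.

Codon positions are independent — there is no dinucleotide autocorrelation
and no amino-acid divergence between pair members; see the methods note for
what that does and does not emulate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_model import (
    AMINO_ACIDS,
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    FAMILIES,
    STOP_SYMBOL,
    CdsRecord,
)
from .dataset_io import PairManifest, PairedDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassCodonProfile:
    """Per-amino-acid synonymous-codon choice probabilities for one class.

    ``probs[aa]`` is a mapping codon -> probability over that family
    (non-negative, summing to 1). The stop family (symbol ``*``) is included
    so full-length CDS with a terminal stop can be generated.
    """

    probs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for aa, fam in self.probs.items():
            if aa not in FAMILIES:
                raise ValueError(f"unknown amino-acid symbol {aa!r}")
            if set(fam) != set(FAMILIES[aa]):
                raise ValueError(f"family {aa}: codons {sorted(fam)} do not match "
                                 f"{sorted(FAMILIES[aa])}")
            vals = np.array(list(fam.values()), dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"family {aa}: probabilities must be >=0 and sum to 1")

    @classmethod
    def uniform(cls) -> "ClassCodonProfile":
        """Uniform within every synonymous family (incl. stop)."""
        return cls({aa: {c: 1.0 / len(fam) for c in sorted(fam)}
                    for aa, fam in FAMILIES.items()})

    def prob(self, codon: str) -> float:
        return self.probs[CODON_TO_AA[codon]][codon]


@dataclass(frozen=True)
class BiasSpec:
    """Shift ``delta`` of within-family probability mass toward (+) or away
    from (-) ``codon``; the rest of the family is renormalised
    proportionally."""

    codon: str
    delta: float

    def __post_init__(self) -> None:
        if self.codon not in CODON_INDEX:
            raise ValueError(f"invalid codon {self.codon!r}")


def make_profiles(
    background: ClassCodonProfile, biases: list[BiasSpec]
) -> ClassCodonProfile:
    """Apply bias specs to a background profile.

    The target codon's probability moves by ``delta``; the remaining mass is
    redistributed proportionally among the other codons of the same family.
    A delta that would push any probability outside [0, 1] is an error —
    nothing is clipped silently.
    """
    probs = {aa: dict(fam) for aa, fam in background.probs.items()}
    for bias in biases:
        aa = CODON_TO_AA[bias.codon]
        fam = probs[aa]
        target = fam[bias.codon] + bias.delta
        if not (0.0 <= target <= 1.0):
            raise ValueError(
                f"bias {bias.delta:+g} on {bias.codon} pushes its probability "
                f"to {target:g}, outside [0, 1]"
            )
        others = {c: p for c, p in fam.items() if c != bias.codon}
        rest_old = sum(others.values())
        rest_new = 1.0 - target
        if rest_old == 0.0 and rest_new > 0.0:
            raise ValueError(
                f"bias on {bias.codon}: cannot redistribute mass, "
                f"all other {aa}-family codons have probability 0"
            )
        scale = rest_new / rest_old if rest_old > 0 else 0.0
        new_fam = {c: p * scale for c, p in others.items()}
        new_fam[bias.codon] = target
        if any(p < -1e-12 or p > 1.0 + 1e-12 for p in new_fam.values()):
            raise ValueError(f"bias on {bias.codon} produced an invalid distribution")
        probs[aa] = {c: min(max(p, 0.0), 1.0) for c, p in new_fam.items()}
    return ClassCodonProfile(probs)


def thermophile_like_biases(delta: float = 0.3) -> list[BiasSpec]:
    """The canonical strong-bias condition: AGG enriched within the Arg
    family and CAA depleted within the Gln family."""
    return [BiasSpec("AGG", +delta), BiasSpec("CAA", -delta)]


def uniform_aa_profile() -> dict[str, float]:
    return {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}


@dataclass
class SyntheticConfig:
    """Generation conditions for one paired dataset.

    ``gene_length`` is in codons and excludes the terminal stop codon that is
    appended when ``include_stop`` is on (the default, mirroring full-length
    CDS). ``seed`` fully determines the output.
    """

    n_pairs: int = 100
    gene_length: int = 300
    aa_profile: dict[str, float] = field(default_factory=uniform_aa_profile)
    profile_e: ClassCodonProfile = field(default_factory=ClassCodonProfile.uniform)
    profile_ne: ClassCodonProfile = field(default_factory=ClassCodonProfile.uniform)
    include_stop: bool = True
    seed: int = 0
    dataset_label: str = "SYN"
    class_e: str = "extremophile"
    class_ne: str = "non-extremophile"

    def __post_init__(self) -> None:
        errors = []
        if self.n_pairs < 1:
            errors.append(f"n_pairs must be >= 1 (got {self.n_pairs})")
        if self.gene_length < 10:
            errors.append(f"gene_length must be >= 10 codons (got {self.gene_length})")
        probs = np.array([self.aa_profile.get(aa, 0.0) for aa in AMINO_ACIDS])
        if set(self.aa_profile) - set(AMINO_ACIDS):
            errors.append("aa_profile contains unknown amino-acid symbols")
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            errors.append("aa_profile probabilities must be >= 0 and sum to 1")
        if errors:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(errors))


def _family_arrays(profile: ClassCodonProfile) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """family symbol -> (codon indices, probabilities), deterministic order."""
    out = {}
    for aa, fam in profile.probs.items():
        codons = sorted(fam)
        out[aa] = (
            np.array([CODON_INDEX[c] for c in codons], dtype=np.int64),
            np.array([fam[c] for c in codons], dtype=float),
        )
    return out


def _encode(aa_matrix: np.ndarray, profile: ClassCodonProfile,
            rng: np.random.Generator) -> np.ndarray:
    """Sample codon indices for a matrix of amino-acid indices (rows = genes).

    Positions are filled family by family, which is equivalent to sampling
    each position independently but needs only one RNG call per family.
    """
    fam_arrays = _family_arrays(profile)
    out = np.empty(aa_matrix.shape, dtype=np.int64)
    for ai, aa in enumerate(AMINO_ACIDS + (STOP_SYMBOL,)):
        mask = aa_matrix == ai
        n = int(mask.sum())
        if n == 0:
            continue
        idx, p = fam_arrays[aa]
        out[mask] = rng.choice(idx, size=n, p=p)
    return out


def generate_pair(
    aa_sequence: str,
    profile_e: ClassCodonProfile,
    profile_ne: ClassCodonProfile,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Encode one amino-acid sequence under both class profiles.

    Each position is encoded independently by sampling a codon from the
    class profile's family vector, so ``translate(cds_e) ==
    translate(cds_ne) == aa_sequence`` by construction.
    """
    symbols = AMINO_ACIDS + (STOP_SYMBOL,)
    lookup = {aa: i for i, aa in enumerate(symbols)}
    try:
        aa_idx = np.array([[lookup[a] for a in aa_sequence]], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid amino-acid symbol {exc.args[0]!r}") from None
    cds_e = "".join(CODONS[i] for i in _encode(aa_idx, profile_e, rng)[0])
    cds_ne = "".join(CODONS[i] for i in _encode(aa_idx, profile_ne, rng)[0])
    return cds_e, cds_ne


def generate_records(
    config: SyntheticConfig,
) -> tuple[list[CdsRecord], list[CdsRecord], PairManifest, dict]:
    """Generate all pairs of a dataset in memory.

    Returns the extremophile-class records, the counterpart records, the
    pair manifest linking them, and a ground-truth dict recording the
    profiles and each codon's expected percentage displacement.
    """
    rng = np.random.default_rng(config.seed)
    L = config.gene_length + (1 if config.include_stop else 0)
    aa_probs = np.array([config.aa_profile[aa] for aa in AMINO_ACIDS])
    aa_matrix = rng.choice(len(AMINO_ACIDS), size=(config.n_pairs, config.gene_length),
                           p=aa_probs)
    if config.include_stop:
        stop_col = np.full((config.n_pairs, 1), len(AMINO_ACIDS), dtype=np.int64)
        aa_matrix = np.hstack([aa_matrix, stop_col])
    codons_e = _encode(aa_matrix, config.profile_e, rng)
    codons_ne = _encode(aa_matrix, config.profile_ne, rng)

    records_e, records_ne, rows = [], [], []
    for i in range(config.n_pairs):
        eid = f"{config.dataset_label}_e_{i:04d}"
        nid = f"{config.dataset_label}_ne_{i:04d}"
        seq_e = "".join(CODONS[j] for j in codons_e[i])
        seq_ne = "".join(CODONS[j] for j in codons_ne[i])
        records_e.append(CdsRecord(id=eid, raw_sequence=seq_e,
                                   codons=[CODONS[j] for j in codons_e[i]],
                                   class_label=config.class_e))
        records_ne.append(CdsRecord(id=nid, raw_sequence=seq_ne,
                                    codons=[CODONS[j] for j in codons_ne[i]],
                                    class_label=config.class_ne))
        rows.append((f"pair_{i:04d}", eid, nid))
    manifest = PairManifest(dataset_label=config.dataset_label, rows=rows)
    truth = ground_truth(config)
    return records_e, records_ne, manifest, truth


def expected_percentage(codon: str, config: SyntheticConfig, which: str = "e") -> float:
    """Closed-form expected percentage of ``codon`` in one class.

    For a sense codon: 100 * p_aa(aa) * p_class(codon | family), diluted by
    the appended stop codon when ``include_stop`` is on. Stop codons get
    100 * p_class(stop | stop family) * 1 / (L + 1).
    """
    profile = config.profile_e if which == "e" else config.profile_ne
    aa = CODON_TO_AA[codon]
    L = config.gene_length
    total = L + (1 if config.include_stop else 0)
    if aa == STOP_SYMBOL:
        if not config.include_stop:
            return 0.0
        return 100.0 * profile.prob(codon) / total
    return 100.0 * config.aa_profile[aa] * profile.prob(codon) * L / total


def ground_truth(config: SyntheticConfig) -> dict:
    """Expected per-codon percentages and displacements for every codon
    whose class probabilities differ."""
    displaced = {}
    for codon in CODONS:
        e = expected_percentage(codon, config, "e")
        ne = expected_percentage(codon, config, "ne")
        if not np.isclose(e, ne):
            displaced[codon] = {"expected_pct_e": e, "expected_pct_ne": ne,
                                "expected_displacement": e - ne}
    return {
        "dataset_label": config.dataset_label,
        "n_pairs": config.n_pairs,
        "gene_length": config.gene_length,
        "include_stop": config.include_stop,
        "seed": config.seed,
        "displaced_codons": displaced,
    }


def generate_paired_dataset(config: SyntheticConfig) -> tuple[PairedDataset, dict]:
    """Generate a dataset and assemble its paired percentage matrices.

    Counts codons directly from the sampled codon indices, skipping
    sequence-string construction; the RNG call sequence is identical to
    :func:`generate_records`, so for the same config the matrices are
    bit-identical to counting the written FASTA records.
    """
    rng = np.random.default_rng(config.seed)
    aa_probs = np.array([config.aa_profile[aa] for aa in AMINO_ACIDS])
    aa_matrix = rng.choice(len(AMINO_ACIDS), size=(config.n_pairs, config.gene_length),
                           p=aa_probs)
    if config.include_stop:
        stop_col = np.full((config.n_pairs, 1), len(AMINO_ACIDS), dtype=np.int64)
        aa_matrix = np.hstack([aa_matrix, stop_col])
    codons_e = _encode(aa_matrix, config.profile_e, rng)
    codons_ne = _encode(aa_matrix, config.profile_ne, rng)
    total = aa_matrix.shape[1]
    matrix_e = np.vstack([np.bincount(row, minlength=64) for row in codons_e])
    matrix_ne = np.vstack([np.bincount(row, minlength=64) for row in codons_ne])
    paired = PairedDataset(
        dataset_label=config.dataset_label,
        pair_ids=[f"pair_{i:04d}" for i in range(config.n_pairs)],
        matrix_e=100.0 * matrix_e / total,
        matrix_ne=100.0 * matrix_ne / total,
    )
    return paired, ground_truth(config)


def generate_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic dataset to disk.

    Emits two FASTA files (one per class), the pair-manifest TSV consumable
    by :mod:`extremocodon.dataset_io` unchanged, and a ground-truth JSON.
    Same config (incl. seed) -> byte-identical outputs.
    """
    from .dataset_io import write_fasta, write_manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_e, records_ne, manifest, truth = generate_records(config)
    paths = {
        "fasta_e": outdir / f"{config.dataset_label}_extremophile.fasta",
        "fasta_ne": outdir / f"{config.dataset_label}_counterpart.fasta",
        "manifest": outdir / f"{config.dataset_label}_pairs.tsv",
        "ground_truth": outdir / f"{config.dataset_label}_ground_truth.json",
    }
    write_fasta(records_e, paths["fasta_e"])
    write_fasta(records_ne, paths["fasta_ne"])
    write_manifest(manifest, paths["manifest"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("synthetic dataset %s: %d pairs written to %s",
             config.dataset_label, config.n_pairs, outdir)
    return paths
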