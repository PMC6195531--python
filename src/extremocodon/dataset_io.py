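"""Reading CDS FASTA and pair manifests, assembling paired feature matrices,
and writing tabular/JSON outputs.

Pairing is explicit: a manifest TSV (columns ``pair_id``, ``ext_id``,
``ctl_id``) names which extremophile CDS is homologous to which counterpart
CDS. Homology search itself is out of scope — the manifest is the contract.

All tables are TSV with a header row, UTF-8, ``.`` decimal separator;
structured reports are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_model import CODONS, CdsRecord, count_codons

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("pair_id", "ext_id", "ctl_id")


class DatasetError(ValueError):
    """Raised for malformed FASTA/manifest inputs or unresolvable ids."""


def read_fasta(
    path: str | Path,
    class_label: str = "",
    policy: str = "exclude",
) -> dict[str, CdsRecord]:
    """Parse a (wrapped or unwrapped) multi-record FASTA into CdsRecords.

    The header token before the first whitespace is the record id.
    Duplicate ids and records that fail cleaning are reported by id.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"FASTA file not found: {path}")
    records: dict[str, CdsRecord] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in records:
            raise DatasetError(f"duplicate record id {entry.id!r} in {path}")
        records[entry.id] = CdsRecord.from_sequence(
            id=entry.id,
            raw_sequence=str(entry.seq),
            class_label=class_label,
            policy=policy,
        )
    if not records:
        raise DatasetError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[CdsRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.raw_sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


@dataclass
class PairManifest:
    """Links each extremophile CDS id to its counterpart id under a pair id."""

    dataset_label: str
    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        pair_ids = [r[0] for r in self.rows]
        dupes = {p for p in pair_ids if pair_ids.count(p) > 1}
        if dupes:
            raise DatasetError(f"duplicate pair_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)


def load_manifest(path: str | Path, dataset_label: str = "") -> PairManifest:
    """Read a pair-manifest TSV (header: pair_id, ext_id, ctl_id)."""
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"manifest file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"manifest {path} is empty") from None
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetError(f"manifest {path} missing column(s): {sorted(missing)}")
    if df.empty:
        raise DatasetError(f"manifest {path} has no rows")
    if df[list(MANIFEST_COLUMNS)].isna().any().any():
        raise DatasetError(f"manifest {path} has empty cells")
    rows = [tuple(r) for r in df[list(MANIFEST_COLUMNS)].itertuples(index=False)]
    return PairManifest(dataset_label=dataset_label, rows=rows)


def write_manifest(manifest: PairManifest, path: str | Path) -> None:
    df = pd.DataFrame(manifest.rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


@dataclass
class PairedDataset:
    """N homologous pairs x 64 codon percentages for the two classes.

    Row i of ``matrix_e`` and ``matrix_ne`` both correspond to
    ``pair_ids[i]``; columns follow the canonical codon order. N is the
    number of protein pairs in the comparing dataset — the denominator of
    the per-codon mean percentages.
    """

    dataset_label: str
    pair_ids: list[str]
    matrix_e: np.ndarray
    matrix_ne: np.ndarray

    def __post_init__(self) -> None:
        self.matrix_e = np.asarray(self.matrix_e, dtype=float)
        self.matrix_ne = np.asarray(self.matrix_ne, dtype=float)
        n = len(self.pair_ids)
        if self.matrix_e.shape != (n, 64) or self.matrix_ne.shape != (n, 64):
            raise DatasetError(
                f"matrices must be ({n}, 64); got {self.matrix_e.shape} "
                f"and {self.matrix_ne.shape}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def build_paired_dataset(
    manifest: PairManifest, records: dict[str, CdsRecord]
) -> PairedDataset:
    """Assemble the N x 64 percentage matrices from a manifest and records.

    Deterministic: same inputs give bit-identical matrices.
    """
    rows_e, rows_ne = [], []
    for pair_id, ext_id, ctl_id in manifest.rows:
        for rid in (ext_id, ctl_id):
            if rid not in records:
                raise DatasetError(
                    f"pair {pair_id!r}: record id {rid!r} not found in FASTA"
                )
        rows_e.append(count_codons(records[ext_id].codons).percentages)
        rows_ne.append(count_codons(records[ctl_id].codons).percentages)
    return PairedDataset(
        dataset_label=manifest.dataset_label,
        pair_ids=[r[0] for r in manifest.rows],
        matrix_e=np.vstack(rows_e),
        matrix_ne=np.vstack(rows_ne),
    )


def frequency_table(records: dict[str, CdsRecord]) -> pd.DataFrame:
    """Per-record codon percentage table (rows = records, columns = codons)."""
    data = {rid: count_codons(r.codons).percentages for rid, r in records.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(CODONS))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
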