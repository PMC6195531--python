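"""End-to-end orchestration: run every analysis stage over one or more
paired datasets and write the full artifact bundle.

A run is reproducible from config + inputs + seed. Each dataset entry is
either loaded from FASTA + manifest or simulated by the synthetic
generator; stages run in the reporting order significance -> abundance ->
ranking -> extremes -> composition -> data-points -> weighting ->
classification -> rules, with a cross-dataset harmony table when more than
one dataset carries an extremophile class. Every stage writes its table to
the output directory, so any downstream stage can be resumed from disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import abundance as ab
from . import composition as comp
from . import dataset_io as dio
from . import ml
from . import significance as sig
from . import synthetic as syn

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and dataset label."""

    def __init__(self, stage: str, dataset: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for dataset {dataset!r}: {cause}")
        self.stage = stage
        self.dataset = dataset
        self.cause = cause


@dataclass
class DatasetSpec:
    """One comparing dataset: real files or a simulation block."""

    label: str
    extremophile_class: str | None = None
    fasta_e: str | None = None
    fasta_ne: str | None = None
    manifest: str | None = None
    simulate: dict | None = None

    def validate(self) -> None:
        has_files = all((self.fasta_e, self.fasta_ne, self.manifest))
        if bool(self.simulate) == has_files:
            raise ValueError(
                f"dataset {self.label!r}: provide either fasta_e/fasta_ne/"
                f"manifest or a simulate block (exactly one)"
            )
        if self.extremophile_class is not None and \
                self.extremophile_class not in comp.EXTREMOPHILE_CLASSES:
            raise ValueError(
                f"dataset {self.label!r}: unknown extremophile class "
                f"{self.extremophile_class!r}"
            )


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    outdir: str = "extremocodon_out"
    seed: int = 0
    alpha: float = sig.DEFAULT_ALPHA
    ks_method: str = "asymp"
    bh_correct: bool = False
    alpha_max_mode: str = "absolute"
    ml_models: list[str] = field(default_factory=lambda: ["knn", "tree"])
    ml_params: dict = field(default_factory=dict)
    train_frac: float = 0.7
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        ml_block = raw.pop("ml", {})
        datasets = [
            DatasetSpec(
                label=d["label"],
                extremophile_class=d.get("class"),
                fasta_e=d.get("fasta_e"),
                fasta_ne=d.get("fasta_ne"),
                manifest=d.get("manifest"),
                simulate=d.get("simulate"),
            )
            for d in raw.pop("datasets", [])
        ]
        cfg = cls(
            datasets=datasets,
            outdir=raw.pop("outdir", "extremocodon_out"),
            seed=int(raw.pop("seed", 0)),
            alpha=float(raw.pop("alpha", sig.DEFAULT_ALPHA)),
            ks_method=raw.pop("ks_method", "asymp"),
            bh_correct=bool(raw.pop("bh_correct", False)),
            alpha_max_mode=raw.pop("alpha_max_mode", "absolute"),
            ml_models=ml_block.get("models", ["knn", "tree"]),
            ml_params={k: v for k, v in ml_block.items() if k != "models"},
            train_frac=float(ml_block.get("train_frac", 0.7)),
            log_level=raw.pop("log_level", "INFO"),
        )
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        if not cfg.datasets:
            raise ValueError("config lists no datasets")
        for d in cfg.datasets:
            d.validate()
        return cfg


def _load_paired(spec: DatasetSpec, seed: int, outdir: Path) -> dio.PairedDataset:
    if spec.simulate is not None:
        blk = dict(spec.simulate)
        biases = [syn.BiasSpec(b["codon"], float(b["delta"]))
                  for b in blk.pop("biases", [])]
        profile_e = syn.make_profiles(syn.ClassCodonProfile.uniform(), biases)
        cfg = syn.SyntheticConfig(
            n_pairs=int(blk.pop("n_pairs", 100)),
            gene_length=int(blk.pop("gene_length", 300)),
            seed=int(blk.pop("seed", seed)),
            profile_e=profile_e,
            include_stop=bool(blk.pop("include_stop", True)),
            dataset_label=spec.label,
        )
        if blk:
            raise ValueError(f"unknown simulate key(s): {sorted(blk)}")
        syn.generate_dataset(cfg, outdir / "synthetic")
        paired, _ = syn.generate_paired_dataset(cfg)
        return paired
    records = dio.read_fasta(spec.fasta_e, class_label="extremophile")
    records.update(dio.read_fasta(spec.fasta_ne, class_label="counterpart"))
    manifest = dio.load_manifest(spec.manifest, dataset_label=spec.label)
    return dio.build_paired_dataset(manifest, records)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage for every dataset; returns the artifact manifest.

    If a dataset's significant set is empty the pipeline stops after the
    significance stage for that dataset with a clear message in the
    manifest. Any stage error aborts the run, naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"datasets": {}, "seed": config.seed}
    preferred_by_class: dict[str, set[str]] = {}

    for spec in config.datasets:
        label = spec.label
        ddir = outdir / label.replace("/", "_")
        ddir.mkdir(parents=True, exist_ok=True)
        entry: dict = {}
        artifacts["datasets"][label] = entry

        def _stage(name, fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError(name, label, exc) from exc

        paired = _stage("load", lambda: _load_paired(spec, config.seed, ddir))
        sigset = _stage("significance", lambda: sig.filter_significant(
            paired, alpha=config.alpha, method=config.ks_method,
            bh_correct=config.bh_correct))
        path = ddir / "significance.tsv"
        dio.write_table(sigset.to_dataframe(), path)
        entry["significance"] = str(path)
        entry["n_significant"] = sigset.n_significant
        if not sigset.codons:
            msg = (f"dataset {label}: no codon significant at "
                   f"alpha={config.alpha}; downstream stages skipped")
            log.warning(msg)
            entry["stopped_after"] = "significance"
            entry["message"] = msg
            continue

        abres = _stage("abundance", lambda: ab.relative_abundance(
            paired, sigset, alpha_max_mode=config.alpha_max_mode))
        path = ddir / "abundance.tsv"
        dio.write_table(abres.to_dataframe(), path)
        entry["abundance"] = str(path)

        ranks = _stage("ranking", lambda: ab.rank_codons(abres))
        path = ddir / "ranks.tsv"
        dio.write_table(ranks.to_dataframe(), path)
        entry["ranks"] = str(path)

        highest, lowest = _stage("extremes", lambda: ab.extreme_codons(ranks))
        path = ddir / "extreme_codons.json"
        dio.write_json({"highest": highest, "lowest": lowest}, path)
        entry["extreme_codons"] = str(path)

        positives = abres.positive_contributors()
        entry["positive_contributors"] = positives
        if positives:
            summary = _stage("composition",
                             lambda: comp.composition_summary(set(positives)))
            path = ddir / "composition.json"
            dio.write_json(summary.to_dict(), path)
            entry["composition"] = str(path)
            if spec.extremophile_class:
                preferred_by_class[spec.extremophile_class] = set(positives)
        else:
            log.warning("dataset %s: no positive contributors; "
                        "composition skipped", label)

        for codon in dict.fromkeys((highest, lowest)):
            series = _stage("datapoints",
                            lambda c=codon: ab.datapoint_series(paired, c))
            path = ddir / f"datapoints_{codon}.tsv"
            dio.write_table(series.to_dataframe(), path)
            entry.setdefault("datapoints", {})[codon] = str(path)

        table = _stage("features", lambda: ml.FeatureTable.from_paired(paired, sigset))
        wm = _stage("weighting", lambda: ml.attribute_weights(table))
        path = ddir / "attribute_weights.tsv"
        dio.write_table(wm.to_dataframe(), path)
        entry["attribute_weights"] = str(path)
        counts = ml.support_counts(wm)
        path = ddir / "support_counts.tsv"
        dio.write_table(counts.to_dataframe(), path)
        entry["support_counts"] = str(path)

        split = ml.SplitSpec(train_frac=config.train_frac, seed=config.seed)
        reports = []
        for model in config.ml_models:
            params = dict(config.ml_params.get(model, {}))
            report = _stage(f"classify:{model}", lambda m=model, p=params:
                            ml.train_eval(table, m, split, **p))
            reports.append(report.to_dict())
        path = ddir / "classifier_reports.json"
        dio.write_json(reports, path)
        entry["classifier_reports"] = str(path)

        # final interpretable tree refit on all rows for rule extraction
        def _rules():
            params = dict(config.ml_params.get("tree", {}))
            from sklearn.tree import DecisionTreeClassifier
            clf = DecisionTreeClassifier(
                criterion=ml.CRITERION_MAP[params.get("criterion", "infogain")],
                max_depth=params.get("max_depth", 5),
                random_state=config.seed,
            )
            clf.fit(table.X.to_numpy(), table.y.to_numpy())
            return ml.extract_rules(clf, list(table.X.columns))

        rules = _stage("rules", _rules)
        path = ddir / "rules.txt"
        path.write_text(ml.render_rules(rules) + "\n", encoding="utf-8")
        entry["rules"] = str(path)

    if len(preferred_by_class) > 1:
        harmony = comp.harmony_table(preferred_by_class)
        path = outdir / "harmony.tsv"
        dio.write_table(harmony.to_dataframe(), path)
        artifacts["harmony"] = str(path)

    manifest_path = outdir / "artifacts.json"
    dio.write_json(artifacts, manifest_path)
    artifacts["manifest"] = str(manifest_path)
    return artifacts
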