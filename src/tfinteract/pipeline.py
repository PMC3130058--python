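"""End-to-end training pipeline and its serializable run configuration.

The pipeline mirrors a full interaction-prediction study: evidence-type
filtering of the positive pairs, redundancy filtering, negative-set
completion, featurization, a stratified split into k + 1 groups (k for
cross-validated wrapper selection, one held out as a completely blind test
set), greedy forward selection under the preserved folds, a final fit of
the QDA model on all k training groups restricted to the best feature
prefix, and an evaluation of that model on the blind group.

Every run writes its effective configuration (including all seeds) next to
its outputs, so two runs from the same configuration are bitwise identical.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from . import dataset as ds
from .aaindex import filter_complete, parse_aaindex1
from .errors import TFInteractError
from .features import (MASS_CONVENTION, pair_feature_matrix, read_fasta,
                       write_feature_matrix)
from .metrics import (UndefinedMetricWarning, confusion, mean_metric_sets,
                      metric_set, report_table)
from .qda import QDAModel, fit_qda, predict
from .selection import (FoldAssignment, best_subset, forward_select,
                        make_stratified_folds)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    fasta: str
    aaindex: str
    pairs: str
    outdir: str
    allowed_mi_types: tuple[str, ...] = tuple(sorted(ds.DEFAULT_MI_TYPES))
    mi_filter: bool = True
    identity_threshold: float = 0.8
    k: int = 10
    max_features: int = 150
    ridge: float = 1e-6
    criterion: str = "accuracy"
    seed: int = 0
    n_negative_per_class: int | None = None
    candidate_pool: list[int] | None = None

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["allowed_mi_types"] = list(d["allowed_mi_types"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise TFInteractError(f"unknown config keys: {sorted(unknown)}")
        if "allowed_mi_types" in d:
            d["allowed_mi_types"] = tuple(d["allowed_mi_types"])
        return cls(**d)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())


def _log_stage(stage: str, n_in: int, n_out: int) -> None:
    logger.info("%s: %d -> %d", stage, n_in, n_out)


def prepare_dataset(config: RunConfig, sequences, records
                    ) -> ds.InteractionSet:
    """MI-type filter, redundancy filter, and negative-set completion."""
    positives = [r for r in records if r.label == "positive"]
    negatives = [r for r in records if r.label == "negative"]
    if config.mi_filter:
        kept = ds.filter_by_mi_type(positives,
                                    frozenset(config.allowed_mi_types))
        _log_stage("mi-type filter (positives)", len(positives), len(kept))
        positives = kept
    universe = set(sequences)
    pos_set = ds.InteractionSet(list(positives), universe=universe)
    pos_set, removed = ds.redundancy_filter(pos_set, sequences,
                                            config.identity_threshold)
    _log_stage("redundancy filter (positives)",
               len(positives), len(pos_set.records))
    if not negatives:
        if config.n_negative_per_class is None:
            raise TFInteractError(
                "pair table has no negatives and n_negative_per_class "
                "is not set")
        known_partners: dict[str, set] = {i: set() for i in universe}
        for r in pos_set.records:
            known_partners[r.first_id].add(r.second_id)
            known_partners[r.second_id].add(r.first_id)
        negatives = ds.generate_negative_set(
            universe, known_partners, config.n_negative_per_class,
            config.seed, positives=pos_set.pair_keys(), sequences=sequences)
        _log_stage("negative generation", 0, len(negatives))
    return ds.InteractionSet(pos_set.records + list(negatives),
                             universe=universe), removed


@dataclass
class PipelineResult:
    config: RunConfig
    trace: "object"
    best_features: list[int]
    model: QDAModel
    cv_report: "object"
    blind_metrics: "object"
    n_blind: int


def run_pipeline(config: RunConfig) -> PipelineResult:
    sequences = read_fasta(config.fasta)
    with open(config.aaindex) as fh:
        entries = parse_aaindex1(fh)
    table = filter_complete(entries)
    _log_stage("property filter", len(entries), table.size)
    records = ds.read_pairs_tsv(config.pairs, sequences=sequences)
    iset, removed = prepare_dataset(config, sequences, records)
    pairs = [(r.first_id, r.second_id) for r in iset.records]
    labels = np.array([r.label for r in iset.records])
    X = pair_feature_matrix(pairs, sequences, table).to_numpy()
    _log_stage("featurization (pairs)", len(records), X.shape[0])

    # k + 1 stratified groups: folds 1..k train/CV, group k+1 is blind.
    groups = make_stratified_folds(labels, config.k + 1, config.seed)
    blind = groups.test_mask(config.k + 1)
    cv_idx = np.flatnonzero(~blind)
    folds = FoldAssignment(fold_of=groups.fold_of[cv_idx], k=config.k,
                           seed=config.seed)
    trace = forward_select(X[cv_idx], labels[cv_idx], folds,
                           max_features=config.max_features,
                           ridge=config.ridge,
                           candidate_pool=config.candidate_pool,
                           criterion=config.criterion)
    best = best_subset(trace)
    _log_stage("forward selection (features)", len(trace.candidate_pool),
               len(best))
    model = fit_qda(X[cv_idx][:, best], labels[cv_idx], ridge=config.ridge,
                    feature_indices=list(best),
                    property_accessions=table.accessions,
                    mass_convention=MASS_CONVENTION)
    cv_report = report_table(trace.steps[len(best) - 1].per_fold_metrics,
                             trace.steps[len(best) - 1].mean_metrics)
    y_blind = labels[blind]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedMetricWarning)
        blind_metrics = metric_set(
            confusion(y_blind, predict(model, X[blind][:, best])))
    result = PipelineResult(config=config, trace=trace, best_features=best,
                            model=model, cv_report=cv_report,
                            blind_metrics=blind_metrics,
                            n_blind=int(blind.sum()))

    os.makedirs(config.outdir, exist_ok=True)
    config.write(os.path.join(config.outdir, "config.yaml"))
    trace.to_dataframe().to_csv(os.path.join(config.outdir, "trace.tsv"),
                                sep="\t", index=False)
    with open(os.path.join(config.outdir, "trace.json"), "w") as fh:
        fh.write(trace.to_json())
    model.save(os.path.join(config.outdir, "model.json"))
    cv_report.to_csv(os.path.join(config.outdir, "cv_metrics.tsv"), sep="\t")
    ds.removals_to_frame(removed).to_csv(
        os.path.join(config.outdir, "redundancy_removals.tsv"),
        sep="\t", index=False)
    import pandas as pd
    pd.DataFrame([{"n_blind": result.n_blind,
                   **{k: (None if v is None else round(v, 2))
                      for k, v in blind_metrics.as_dict().items()}}]).to_csv(
        os.path.join(config.outdir, "blind_metrics.tsv"), sep="\t",
        index=False)
    return result


def featurize_to_files(config: RunConfig) -> str:
    """The featurize command body: pair matrix TSV + annotation JSON."""
    sequences = read_fasta(config.fasta)
    with open(config.aaindex) as fh:
        table = filter_complete(parse_aaindex1(fh))
    records = ds.read_pairs_tsv(config.pairs, sequences=sequences)
    pairs = [(r.first_id, r.second_id) for r in records]
    df = pair_feature_matrix(pairs, sequences, table)
    os.makedirs(config.outdir, exist_ok=True)
    matrix_path = os.path.join(config.outdir, "features.tsv")
    write_feature_matrix(df, table, matrix_path,
                         os.path.join(config.outdir, "annotation.json"))
    config.write(os.path.join(config.outdir, "config.yaml"))
    return matrix_path
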