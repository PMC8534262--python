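"""End-to-end study pipeline: recordings -> epochs -> features -> benchmark.

The autoencoder is the only feature transform that is *fitted*; it is
trained on the training-split subjects only and then applied to everyone,
which the audit log records.  Spectral, wavelet and network features are
per-subject computations with nothing to fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import autoencoder as ae
from . import classify, network, preprocess, spectral, wavelet
from .containers import EpochSet, Recording


@dataclass
class StudyConfig:
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    ae: ae.AEConfig = field(default_factory=ae.AEConfig)
    include_ae: bool = True
    graph_density: float = 0.2
    select_features: bool = True
    k: int = 50
    train_frac: float = 0.8
    folds: int = 10
    n_iter: int = 32
    seed: int = 0


def preprocess_cohort(
    recordings: list[Recording], config: preprocess.PreprocessConfig | None = None
) -> tuple[list[EpochSet], list[preprocess.PipelineLog]]:
    epoch_sets, logs = [], []
    for rec in recordings:
        es, log = preprocess.run_pipeline(rec, config)
        epoch_sets.append(es)
        logs.append(log)
    return epoch_sets, logs


def subject_features(
    epochs: EpochSet,
    graph_density: float = 0.2,
    ae_model: ae.AEModel | None = None,
) -> dict[str, float]:
    """All per-subject features from one artifact-screened epoch set."""
    bands = spectral.classifier_bands()
    row: dict[str, float] = {}
    row.update(
        spectral.band_power(epochs, spectral.default_bands(epochs.fs)).feature_row()
    )
    row.update(wavelet.subband_features(epochs))
    row.update(network.network_features(epochs, bands, density=graph_density))
    if ae_model is not None:
        row.update(ae.latent_features(ae_model, epochs))
    return row


def build_feature_table(
    epoch_sets: list[EpochSet],
    graph_density: float = 0.2,
    ae_model: ae.AEModel | None = None,
) -> pd.DataFrame:
    rows = {
        es.subject_id: subject_features(es, graph_density, ae_model)
        for es in epoch_sets
    }
    labels = {es.subject_id: es.group for es in epoch_sets}
    return classify.make_table(rows, labels)


@dataclass
class StudyResult:
    report: classify.BenchmarkReport
    table: pd.DataFrame
    logs: list[preprocess.PipelineLog]
    ae_model: ae.AEModel | None = None


def run_study(
    recordings: list[Recording],
    mode: str = "binary",
    config: StudyConfig | None = None,
) -> StudyResult:
    """Preprocess, extract all four feature families, benchmark the models."""
    config = config or StudyConfig()
    epoch_sets, logs = preprocess_cohort(recordings, config.preprocess)

    labels = {es.subject_id: es.group for es in epoch_sets}
    label_table = pd.DataFrame(
        {classify.LABEL_COLUMN: pd.Series(labels)}
    )
    if mode == "binary":
        label_table[classify.LABEL_COLUMN] = classify.binarize_labels(
            label_table[classify.LABEL_COLUMN]
        ).values
    train_ids, test_ids = classify.stratified_split(
        label_table, train_frac=config.train_frac, seed=config.seed
    )

    ae_model = None
    audit = {}
    if config.include_ae:
        cfg = config.ae
        if cfg.window_len != epoch_sets[0].n_times:
            raise ValueError(
                "autoencoder window_len must equal the epoch length "
                f"({epoch_sets[0].n_times} samples)"
            )
        train_sets = [es for es in epoch_sets if es.subject_id in set(train_ids)]
        ae_model = ae.train_autoencoder(train_sets, cfg)
        audit["ae_trained_on"] = ae_model.trained_on

    table = build_feature_table(
        epoch_sets, graph_density=config.graph_density, ae_model=ae_model
    )
    report = classify.run_benchmark(
        table,
        mode=mode,
        select_features=config.select_features,
        k=config.k,
        folds=config.folds,
        seed=config.seed,
        n_iter=config.n_iter,
        split=(train_ids, test_ids),
        audit=audit,
    )
    return StudyResult(report=report, table=table, logs=logs, ae_model=ae_model)
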