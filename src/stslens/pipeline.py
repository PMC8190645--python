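"""End-to-end orchestration: simulate -> featurize -> represent -> probe
-> rsa -> reweight -> report.

Each stage reads and writes only the documented on-disk formats (TSV
pairs/predictions, HDF5 activations/representations, CSV results), so
stages are independently re-runnable: disabling a stage whose outputs
already exist leaves downstream stages working from the stored files.
A JSON manifest records the config hash, the derived per-stage seeds,
the package version and a SHA-256 checksum of every output, and one
root seed fixes every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    Corpus,
    ModelSpec,
    PredictionSet,
    ValidationError,
    count_tokens,
    read_activations_h5,
    read_pairs_tsv,
    read_predictions_tsv,
    write_activations_h5,
    write_pairs_tsv,
    write_predictions_tsv,
)
from .features import (
    FEATURE_NAMES,
    feature_table,
    loss_feature_correlations,
)
from .probing import decode_all, rank_top, select_layers
from .representations import (
    REPRESENTATION_NAMES,
    SCALAR_REPRESENTATIONS,
    build_all,
    read_representations_h5,
    write_representations_h5,
)
from .rsa import (
    RDM,
    feature_rdm,
    ground_truth_rdm,
    layerwise_reweight,
    nnls_reweight,
    rdm_spearman,
    representation_rdm,
)
from .seeding import child_seed
from .synthetic import (
    BiasConfig,
    CorpusConfig,
    Planting,
    generate_activations,
    generate_corpus,
    generate_predictions,
)

logger = logging.getLogger("stslens.pipeline")

STAGES = ("simulate", "featurize", "represent", "probe", "rsa", "reweight", "report")

ENSEMBLE_NAME = "mean_score"

CONFIG_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PredictionModelConfig:
    name: str
    overlap_bias_strength: float = 1.0
    additive_bias: float = 0.0
    noise_sd: float = 0.3

    @property
    def bias(self) -> BiasConfig:
        return BiasConfig(
            overlap_bias_strength=self.overlap_bias_strength,
            additive_bias=self.additive_bias,
            noise_sd=self.noise_sd,
        )


@dataclass(frozen=True)
class ActivationModelConfig:
    name: str
    n_layers: int = 12
    hidden_dim: int = 64
    layout: str = "cls_first"
    background_sd: float = 1.0
    plantings: tuple[Planting, ...] = ()

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            name=self.name,
            n_layers=self.n_layers,
            hidden_dim=self.hidden_dim,
            layout=self.layout,
        )


@dataclass(frozen=True)
class RunConfig:
    """Root configuration; serializes losslessly to/from YAML.

    Every stage seed derives from the single root ``seed``; unknown
    config keys are rejected rather than ignored.
    """

    seed: int = 0
    version: int = CONFIG_VERSION
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    prediction_models: tuple[PredictionModelConfig, ...] = (
        PredictionModelConfig("sim-bert", 1.1, 0.05, 0.40),
        PredictionModelConfig("sim-biobert", 0.9, 0.00, 0.30),
        PredictionModelConfig("sim-clinicalbert", 0.9, -0.05, 0.30),
        PredictionModelConfig("sim-dsbert", 0.8, 0.00, 0.28),
        PredictionModelConfig("sim-xlnet", 1.3, 0.05, 0.35),
    )
    activation_models: tuple[ActivationModelConfig, ...] = (
        ActivationModelConfig(
            name="virtual-12",
            n_layers=12,
            hidden_dim=64,
            layout="cls_first",
            plantings=(
                Planting(6, "sent_avg_difference", 2.0, 0.5),
                Planting(10, "cls", 2.0, 0.5),
            ),
        ),
        ActivationModelConfig(
            name="virtual-24",
            n_layers=24,
            hidden_dim=64,
            layout="cls_last",
            plantings=(
                Planting(18, "max_reps_concat", 2.0, 0.5),
                Planting(2, "avg_sent_cosine_dist", 2.0, 0.1),
            ),
        ),
    )
    probe_folds: int = 10
    rsa_folds: int = 10
    include_text_features: bool = True
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if self.version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {self.version}")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "version": self.version,
            "seed": self.seed,
            "corpus": enc(self.corpus),
            "prediction_models": enc(self.prediction_models),
            "activation_models": enc(self.activation_models),
            "probe_folds": self.probe_folds,
            "rsa_folds": self.rsa_folds,
            "include_text_features": self.include_text_features,
            "stages": list(self.stages),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        def build(dc_type, data, context):
            if not isinstance(data, Mapping):
                raise ConfigError(f"{context}: expected a mapping")
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(data) - names
            if unknown:
                raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
            return dc_type(**data)

        known = {
            "version", "seed", "corpus", "prediction_models",
            "activation_models", "probe_folds", "rsa_folds",
            "include_text_features", "stages",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")

        kwargs: dict = {k: raw[k] for k in known & set(raw)}
        if "corpus" in kwargs:
            corpus_raw = dict(kwargs["corpus"])
            if "score_levels" in corpus_raw:
                corpus_raw["score_levels"] = tuple(corpus_raw["score_levels"])
            kwargs["corpus"] = build(CorpusConfig, corpus_raw, "corpus")
        if "prediction_models" in kwargs:
            kwargs["prediction_models"] = tuple(
                build(PredictionModelConfig, m, f"prediction_models[{i}]")
                for i, m in enumerate(kwargs["prediction_models"])
            )
        if "activation_models" in kwargs:
            models = []
            for i, m in enumerate(kwargs["activation_models"]):
                m = dict(m)
                plantings = tuple(
                    build(Planting, p, f"activation_models[{i}].plantings")
                    for p in m.pop("plantings", [])
                )
                mc = build(
                    ActivationModelConfig,
                    m,
                    f"activation_models[{i}]",
                )
                models.append(dataclasses.replace(mc, plantings=plantings))
            kwargs["activation_models"] = tuple(models)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, Mapping):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(canon).hexdigest()


# ---------------------------------------------------------------------------
# ensemble + evaluation


def mean_score(predictions: Sequence[PredictionSet]) -> PredictionSet:
    """Per-pair arithmetic mean across models (the ensemble prediction)."""
    if not predictions:
        raise ValidationError("no prediction sets to average")
    ids = set(predictions[0].predictions)
    for ps in predictions[1:]:
        if set(ps.predictions) != ids:
            raise ValidationError(
                f"{ps.model_name} covers different pair ids than "
                f"{predictions[0].model_name}"
            )
    ordered = sorted(ids)
    stacked = np.vstack([ps.aligned(ordered) for ps in predictions])
    means = stacked.mean(axis=0)
    return PredictionSet(
        model_name=ENSEMBLE_NAME,
        predictions=dict(zip(ordered, means.astype(float))),
    )


@dataclass
class EvaluationReport:
    """Per-model Pearson r vs gold plus the inter-model correlation matrix."""

    model_pearson: dict[str, float]
    inter_model: pd.DataFrame
    ensemble_pearson: float

    def to_dict(self) -> dict:
        return {
            "model_pearson": {k: self.model_pearson[k] for k in sorted(self.model_pearson)},
            "ensemble_pearson": self.ensemble_pearson,
            "inter_model": {
                "models": list(self.inter_model.index),
                "matrix": self.inter_model.to_numpy().tolist(),
            },
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant prediction vector; Pearson r undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_predictions(
    predictions: Sequence[PredictionSet], gold: Mapping[str, float]
) -> EvaluationReport:
    """Pearson r of each model (and the ensemble) against gold scores,
    plus the model x model prediction correlation matrix."""
    ids = sorted(gold)
    y = np.array([gold[i] for i in ids])
    named = {ps.model_name: ps.aligned(ids) for ps in predictions}
    members = [n for n in named if n != ENSEMBLE_NAME]
    per_model = {name: _pearson(vec, y) for name, vec in named.items()}
    mat = np.eye(len(members))
    for i, a in enumerate(members):
        for j, b in enumerate(members):
            if i < j:
                mat[i, j] = mat[j, i] = _pearson(named[a], named[b])
    ensemble_r = per_model.get(ENSEMBLE_NAME, float("nan"))
    return EvaluationReport(
        model_pearson=per_model,
        inter_model=pd.DataFrame(mat, index=members, columns=members),
        ensemble_pearson=ensemble_r,
    )


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(outdir: Path, cfg: RunConfig) -> list[Path]:
    seed = child_seed(cfg.seed, "simulate")
    logger.info("simulate: seed=%d", seed)
    corpus = generate_corpus(cfg.corpus, seed)
    files = [outdir / "train.tsv", outdir / "test.tsv"]
    write_pairs_tsv(corpus.train, files[0])
    write_pairs_tsv(corpus.test, files[1])

    predsets = [
        generate_predictions(corpus, m.bias, child_seed(seed, m.name), m.name)
        for m in cfg.prediction_models
    ]
    predsets.append(mean_score(predsets))
    pred_path = outdir / "predictions.tsv"
    write_predictions_tsv(predsets, pred_path)
    files.append(pred_path)

    for m in cfg.activation_models:
        acts = generate_activations(
            corpus.test,
            m.spec,
            plantings=m.plantings,
            seed=child_seed(seed, "activations", m.name),
            background_sd=m.background_sd,
        )
        path = outdir / f"activations_{m.name}.h5"
        write_activations_h5(acts, path)
        files.append(path)
    return files


def _load_test(outdir: Path):
    return read_pairs_tsv(outdir / "test.tsv")


def _stage_featurize(outdir: Path, cfg: RunConfig) -> list[Path]:
    logger.info("featurize: seed=%d (deterministic stage)", cfg.seed)
    train = read_pairs_tsv(outdir / "train.tsv")
    test = _load_test(outdir)
    vocab = count_tokens(train)
    preds = read_predictions_tsv(outdir / "predictions.tsv")[ENSEMBLE_NAME]
    rows = feature_table(test, vocab, preds.predictions)
    corr = loss_feature_correlations(rows)
    f1, f2 = outdir / "features.csv", outdir / "correlations.csv"
    rows.to_csv(f1, index=False)
    corr.to_csv(f2, index=False)
    return [f1, f2]


def _stage_represent(outdir: Path, cfg: RunConfig) -> list[Path]:
    files = []
    for m in cfg.activation_models:
        acts = read_activations_h5(outdir / f"activations_{m.name}.h5", m.name)
        layers = select_layers(acts.model.n_layers)
        table = build_all(acts, layers, REPRESENTATION_NAMES)
        path = outdir / f"representations_{m.name}.h5"
        write_representations_h5(table, path)
        files.append(path)
    return files


def _stage_probe(outdir: Path, cfg: RunConfig) -> list[Path]:
    seed = child_seed(cfg.seed, "probe")
    logger.info("probe: seed=%d folds=%d", seed, cfg.probe_folds)
    gold = {p.pair_id: p.score for p in _load_test(outdir)}
    frames = []
    for m in cfg.activation_models:
        table = read_representations_h5(
            outdir / f"representations_{m.name}.h5", m.name
        )
        frames.append(decode_all(table, gold, folds=cfg.probe_folds, seed=seed))
    results = pd.concat(frames, ignore_index=True)
    f1, f2 = outdir / "probe_results.csv", outdir / "probe_top.csv"
    results.to_csv(f1, index=False)
    rank_top(results, 10).to_csv(f2, index=False)
    return [f1, f2]


def _text_feature_rdms(outdir: Path) -> list[RDM]:
    feats = pd.read_csv(outdir / "features.csv", dtype={"pair_id": str})
    feats = feats.sort_values("pair_id")
    ids = list(feats["pair_id"])
    return [
        feature_rdm(ids, feats[name].to_numpy(), name) for name in FEATURE_NAMES
    ]


def _representation_rdms(table, ids) -> dict[tuple[str, int], RDM]:
    out = {}
    for (rep, layer), mat in table.values.items():
        metric = "abs_diff" if rep in SCALAR_REPRESENTATIONS else "cosine"
        out[(rep, layer)] = representation_rdm(
            ids,
            mat if metric == "cosine" else mat.ravel(),
            metric=metric,
            source=f"representation({table.model_name},{rep},L{layer})",
        )
    return out


def _stage_rsa(outdir: Path, cfg: RunConfig) -> list[Path]:
    test = sorted(_load_test(outdir), key=lambda p: p.pair_id)
    ids = [p.pair_id for p in test]
    target = ground_truth_rdm(ids, [p.score for p in test])
    rows = []
    for m in cfg.activation_models:
        table = read_representations_h5(
            outdir / f"representations_{m.name}.h5", m.name
        )
        if table.pair_ids != ids:
            raise ValidationError(f"{m.name}: representation rows misaligned")
        for (rep, layer), rdm in sorted(_representation_rdms(table, ids).items()):
            rows.append(
                {
                    "model_name": m.name,
                    "rep_name": rep,
                    "layer": layer,
                    "spearman": rdm_spearman(rdm, target),
                }
            )
    path = outdir / "rsa_basic.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _stage_reweight(outdir: Path, cfg: RunConfig) -> list[Path]:
    seed = child_seed(cfg.seed, "reweight")
    logger.info("reweight: seed=%d folds=%d", seed, cfg.rsa_folds)
    test = sorted(_load_test(outdir), key=lambda p: p.pair_id)
    ids = [p.pair_id for p in test]
    target = ground_truth_rdm(ids, [p.score for p in test])
    text_rdms = _text_feature_rdms(outdir) if cfg.include_text_features else []
    text_rdms = [r for r in text_rdms if not r.degenerate]

    fit_rows, layer_frames = [], []
    for m in cfg.activation_models:
        table = read_representations_h5(
            outdir / f"representations_{m.name}.h5", m.name
        )
        rep_rdms = _representation_rdms(table, ids)
        candidates = [rep_rdms[key] for key in sorted(rep_rdms)] + text_rdms
        fit = nnls_reweight(candidates, target, folds=cfg.rsa_folds, seed=seed)
        for name, raw, norm in zip(
            fit.candidates, fit.raw_weights, fit.normalized_weights
        ):
            fit_rows.append(
                {
                    "model_name": m.name,
                    "candidate": name,
                    "raw_weight": float(raw),
                    "normalized_weight": float(norm),
                    "cv_spearman": fit.cv_spearman,
                    "train_spearman": fit.train_spearman,
                    "folds": fit.folds,
                    "seed": fit.seed,
                }
            )
        by_layer = {
            layer: [rep_rdms[(rep, layer)] for rep in table.rep_names]
            for layer in table.layers
        }
        ltable, _ = layerwise_reweight(
            by_layer, target, folds=cfg.rsa_folds, seed=seed
        )
        ltable.insert(0, "model_name", m.name)
        layer_frames.append(ltable)

    f1, f2 = outdir / "rsa_fit.csv", outdir / "rsa_layerwise.csv"
    pd.DataFrame(fit_rows).to_csv(f1, index=False)
    pd.concat(layer_frames, ignore_index=True).to_csv(f2, index=False)
    return [f1, f2]


def _stage_report(outdir: Path, cfg: RunConfig) -> list[Path]:
    test = _load_test(outdir)
    gold = {p.pair_id: p.score for p in test}
    predsets = list(read_predictions_tsv(outdir / "predictions.tsv").values())
    report = evaluate_predictions(predsets, gold)
    path = outdir / "evaluation_report.json"
    path.write_text(
        json.dumps(report.to_dict(), sort_keys=True, indent=2), encoding="utf-8"
    )
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "represent": _stage_represent,
    "probe": _stage_probe,
    "rsa": _stage_rsa,
    "reweight": _stage_reweight,
    "report": _stage_report,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the enabled stages in dependency order; write manifest.json.

    Returns the manifest.  A stage failure aborts the run with a
    ``StageError`` naming the stage; outputs written so far are kept and
    a marker file is left under ``failed/``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    manifest: dict = {
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "package_version": __version__,
        "stage_seeds": {s: child_seed(config.seed, s) for s in config.stages},
        "stages": {},
    }
    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        logger.info("running stage %s", stage)
        try:
            files = _STAGE_FUNCS[stage](outdir, config)
        except Exception as err:
            faildir = outdir / "failed"
            faildir.mkdir(exist_ok=True)
            (faildir / f"{stage}.txt").write_text(str(err), encoding="utf-8")
            raise StageError(stage, err) from err
        manifest["stages"][stage] = {
            f.name: _sha256(f) for f in sorted(files)
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2), encoding="utf-8"
    )
    return manifest
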