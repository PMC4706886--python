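"""End-to-end orchestration: preprocess -> topomaps -> select -> features -> CV.

`PipelineConfig` gathers every stage knob; `featurize_study` turns a
recording + event table + layout into a labeled question-vector table; and
`run_pipeline` reads a study from disk, featurizes it (with a
content-addressed cache of the expensive featurization stage), runs
repeated cross-validation, and returns a JSON-serializable report embedding
the configuration and input hashes so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_preprocess as iop
from .classify import LabeledDataset, SVMConfig, fold_accuracies, repeated_cv
from .errors import ParameterError, PipelineStageError
from .features import aggregate_feature_matrix, feature_set, sequence_feature_matrix
from .selection import select_discriminant_topomaps
from .topomap import DEFAULT_GRID_SIZE, epoch_to_topomaps

log = logging.getLogger("eegmem")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage knobs of one system, serializable to/from YAML."""

    band_low_hz: float = 1.0
    band_high_hz: float = 48.0
    channels: tuple[str, ...] | None = None  # None = keep all
    grid_size: int = DEFAULT_GRID_SIZE
    n_topomaps: int = 150
    pair_keep: str = "later"
    blocks_per_side: int = 16
    features: tuple[str, ...] = ("mean", "standard_deviation")
    n_selected_features: int | None = 500
    selection_scope: str = "per-fold"
    folds: int = 10
    repeats: int = 1
    seed: int = 0
    svm: SVMConfig = field(default_factory=SVMConfig)

    def __post_init__(self):
        feature_set(self.features)  # validates names
        if self.blocks_per_side not in (4, 8, 16, 32):
            raise ParameterError("blocks_per_side must be one of 4, 8, 16, 32")
        if self.grid_size % self.blocks_per_side:
            raise ParameterError("blocks_per_side must divide grid_size")
        if self.n_topomaps < 1:
            raise ParameterError("n_topomaps must be >= 1")
        if isinstance(self.svm, dict):
            object.__setattr__(self, "svm", SVMConfig(**self.svm))
        if self.channels is not None:
            object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "features", tuple(self.features))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels) if self.channels else None
        d["features"] = list(self.features)
        d["svm"] = {
            "C_grid": list(self.svm.C_grid),
            "gamma_grid": list(self.svm.gamma_grid),
            "inner_folds": self.svm.inner_folds,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "svm" in d and isinstance(d["svm"], dict):
            svm = dict(d["svm"])
            for k in ("C_grid", "gamma_grid"):
                if k in svm:
                    svm[k] = tuple(svm[k])
            d["svm"] = SVMConfig(**svm)
        for k in ("channels", "features"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def featurize_question(
    rec: iop.EEGRecording,
    events: iop.EventTable,
    layout: iop.ElectrodeLayout,
    question_id: str,
    config: PipelineConfig,
) -> np.ndarray:
    """One question's 4s-dimensional feature vector from a *filtered* recording."""
    epoch = iop.extract_question_epoch(rec, events, question_id)
    seq = epoch_to_topomaps(epoch, layout, config.grid_size, question_id=question_id)
    n_sel = min(config.n_topomaps, len(seq) - 1)
    seq = select_discriminant_topomaps(seq, n_sel, keep=config.pair_keep)
    fm = sequence_feature_matrix(seq, config.blocks_per_side, config.features)
    return aggregate_feature_matrix(fm).values


def featurize_study(
    rec: iop.EEGRecording,
    events: iop.EventTable,
    layout: iop.ElectrodeLayout,
    config: PipelineConfig,
) -> LabeledDataset:
    """Filter, epoch, render, select, and featurize every question."""
    rec = iop.bandpass_filter(rec, config.band_low_hz, config.band_high_hz)
    if config.channels is not None:
        rec = iop.select_channels(rec, config.channels)
        layout_rows = [layout.channel_ids.index(c) for c in config.channels]
        layout = iop.ElectrodeLayout(
            tuple(config.channels),
            layout.positions[layout_rows],
            head_radius=layout.head_radius,
        )
    vectors, labels = [], []
    for i, qid in enumerate(events.question_ids):
        vectors.append(featurize_question(rec, events, layout, qid, config))
        labels.append(events.labels[i])
        log.debug("featurized %s (%d/%d)", qid, i + 1, len(events))
    return LabeledDataset(np.vstack(vectors), np.asarray(labels), events.question_ids)


def dataset_to_frame(data: LabeledDataset) -> pd.DataFrame:
    p = data.features.shape[1]
    df = pd.DataFrame(data.features, columns=[f"f{i}" for i in range(p)])
    df.insert(0, "question_id", data.question_ids)
    df.insert(1, "label", data.labels)
    return df


def frame_to_dataset(df: pd.DataFrame) -> LabeledDataset:
    cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    return LabeledDataset(
        df[cols].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=int),
        tuple(str(q) for q in df["question_id"]),
    )


# ---------------------------------------------------------------------------
# Full pipeline with featurization cache
# ---------------------------------------------------------------------------

_FEATURE_KNOBS = (
    "band_low_hz",
    "band_high_hz",
    "channels",
    "grid_size",
    "n_topomaps",
    "pair_keep",
    "blocks_per_side",
    "features",
)


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _feature_cache_key(config: PipelineConfig, input_hashes: dict) -> str:
    knobs = {k: config.to_dict()[k] for k in _FEATURE_KNOBS}
    blob = json.dumps({"knobs": knobs, "inputs": input_hashes}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, data_dir, cache_dir=None
) -> dict:
    """Execute the whole system on a study directory and report CV results.

    ``data_dir`` must hold ``recording.dat`` + ``recording.json``,
    ``events.csv`` and ``layout.csv``.  When ``cache_dir`` is given, the
    featurized question table is cached there keyed by the input hashes and
    the feature-affecting configuration, so classifier-side knobs can be
    re-run without re-rendering topomaps.
    """
    data_dir = Path(data_dir)
    paths = {
        "recording": data_dir / "recording.dat",
        "recording_meta": data_dir / "recording.json",
        "events": data_dir / "events.csv",
        "layout": data_dir / "layout.csv",
    }
    for name, p in paths.items():
        if not p.exists():
            raise PipelineStageError("load", FileNotFoundError(f"{name} file {p}"))
    input_hashes = {name: _file_sha256(p) for name, p in paths.items()}

    def stage(name, fn, *args, **kw):
        try:
            log.info("stage %s", name)
            return fn(*args, **kw)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    rec = stage("load", iop.read_recording, paths["recording"], paths["recording_meta"])
    events = stage("load", iop.read_events, paths["events"], rec.sampling_rate)
    layout = stage("load", iop.read_layout, paths["layout"])

    cache_file = None
    data = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = _feature_cache_key(config, input_hashes)
        cache_file = cache_dir / f"features-{key}.csv"
        if cache_file.exists():
            log.info("featurization cache hit: %s", cache_file.name)
            data = frame_to_dataset(pd.read_csv(cache_file))
    if data is None:
        data = stage("featurize", featurize_study, rec, events, layout, config)
        if cache_file is not None:
            dataset_to_frame(data).to_csv(cache_file, index=False)

    results = stage(
        "evaluate",
        repeated_cv,
        data,
        repeats=config.repeats,
        folds=config.folds,
        cfg=config.svm,
        seed=config.seed,
        n_selected_features=config.n_selected_features,
        selection_scope=config.selection_scope,
    )
    accs = fold_accuracies(results)
    return {
        "config": config.to_dict(),
        "input_hashes": input_hashes,
        "n_questions": len(data),
        "cv": [r.to_dict() for r in results],
        "accuracies": [float(a) for a in accs],
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)) if accs.size > 1 else 0.0,
        "mean_auc": float(np.mean([r.mean_auc for r in results])),
    }
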