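"""End-to-end orchestration: denoise -> layers -> features -> classify ->
seeds -> brightness transform -> graph cut -> morphology -> evaluate.

The library splits the workflow into a training entry point (fit the
AdaBoost false-positive filter, optionally tune the energy weights, on
volumes with reference masks) and an application entry point that runs a
saved model on new volumes. Both are deterministic for a fixed
configuration and seed; every intermediate is persisted next to the final
mask together with a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .boost import StrongClassifier, filter_regions, make_labels, train
from .denoise import DiffusionParams, mcde_filter
from .evaluate import SegmentationMetrics, compute_metrics
from .features import extract_all_features
from .io import (
    ContractError,
    OctVolume,
    RegionMask,
    read_mask,
    read_volume,
    write_mask,
    write_surfaces,
    write_volume,
)
from .layers import LayerParams, estimate_bm, initial_ped_mask, segment_layers
from .pedcut import (
    EnergyWeights,
    SeedError,
    brightness_transform,
    build_shape_prior,
    estimate_weights,
    graph_cut,
    make_seeds,
    postprocess,
)

log = logging.getLogger("pedseg")

__all__ = [
    "PipelineParams",
    "RunConfig",
    "StageError",
    "VolumeResult",
    "segment_volume",
    "train_model",
    "run_pipeline",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineParams:
    """All stage parameters of the framework in one serializable bundle."""

    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    layers: LayerParams = field(default_factory=LayerParams)
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    c_fg: float = 0.143
    c_bg: float = 1.143
    c_recon: float = 0.200
    c_close: float = 0.700
    overlap_threshold: float = 0.5
    boost_rounds: int = 50

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        d = dict(d)
        for key, typ in (
            ("diffusion", DiffusionParams),
            ("layers", LayerParams),
            ("weights", EnergyWeights),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


@dataclass
class VolumeResult:
    """Everything the pipeline computes for one volume."""

    surfaces: dict
    initial_mask: RegionMask
    refined_mask: RegionMask
    final_mask: RegionMask
    metrics: SegmentationMetrics | None = None


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, exc) from exc
            log.info("stage %-12s %6.2f s", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def _prepare_cut(bright: OctVolume, refined: RegionMask,
                 params: "PipelineParams"):
    """Seeds, shape prior and solve domain for the graph cut.

    The cut is solved on the bounding box of all seeds; beyond it (far
    outside the background-seed boxes) everything is background.
    """
    from .pedcut import SeedSet

    seeds = make_seeds(refined, params.c_fg, params.c_bg)
    where = np.nonzero(seeds.foreground | seeds.background)
    box = tuple(slice(int(w.min()), int(w.max()) + 1) for w in where)
    sub_seeds = SeedSet(seeds.foreground[box], seeds.background[box])
    prior = build_shape_prior(RegionMask(refined.mask[box]))
    return bright.data[box], sub_seeds, prior, box


def segment_volume(volume: OctVolume, clf: StrongClassifier | None,
                   params: PipelineParams | None = None,
                   truth: RegionMask | None = None,
                   retina: RegionMask | None = None) -> VolumeResult:
    """Run the full segmentation pipeline on one volume.

    Without a classifier the initial regions pass through unfiltered (used
    during training). With ``truth`` given, overlap metrics are computed
    against it (``retina`` defaults to the ILM-BM slab of the segmented
    surfaces).
    """
    params = params or PipelineParams()
    nz = volume.shape[2]

    den = _stage("denoise")(mcde_filter)(volume, params.diffusion)
    surfaces = _stage("layers")(segment_layers)(den, params.layers)
    surfaces["BM"] = estimate_bm(surfaces["RPE_FLOOR"])
    initial = initial_ped_mask(surfaces["RPE_FLOOR"], surfaces["BM"], nz)

    @_stage("classify")
    def _classify():
        if clf is None or not initial.mask.any():
            return initial
        regions, feats = extract_all_features(den.data, initial.mask, surfaces)
        return filter_regions(initial, regions, feats, clf)

    refined = _classify()

    @_stage("graphcut")
    def _cut():
        if not refined.mask.any():
            return RegionMask(np.zeros_like(refined.mask))
        bright = brightness_transform(den, surfaces)
        try:
            data, sub_seeds, prior, box = _prepare_cut(bright, refined, params)
            cut = graph_cut(data, sub_seeds, prior, params.weights)
        except SeedError:
            log.warning("degenerate seeds; keeping refined mask")
            return refined
        full = np.zeros_like(refined.mask)
        full[box] = cut.mask
        return RegionMask(full)

    final = _stage("morphology")(postprocess)(_cut(), params.c_recon,
                                              params.c_close)

    metrics = None
    if truth is not None:
        if retina is None:
            from .io import slab_mask

            ilm_minus = dataclasses.replace(surfaces["ILM"])
            ilm_minus.heights = surfaces["ILM"].heights - 1
            retina = RegionMask(slab_mask(ilm_minus, surfaces["BM"], nz))
            retina.mask |= truth.mask
        metrics = compute_metrics(final, truth, retina)
    return VolumeResult(surfaces, initial, refined, final, metrics)


def train_model(volumes_and_truths, params: PipelineParams | None = None,
                tune_weights: bool = False
                ) -> tuple[StrongClassifier, PipelineParams]:
    """Fit the false-positive filter (and optionally the energy weights).

    ``volumes_and_truths`` is a sequence of ``(OctVolume, RegionMask)``
    pairs. Candidate regions from each volume's initial segmentation are
    labeled positive when at least ``overlap_threshold`` of their pixels
    overlap the truth, and an AdaBoost ensemble is trained on the pooled
    feature matrix.
    """
    params = params or PipelineParams()
    feats, labels = [], []
    tuning_cases = []
    for volume, truth in volumes_and_truths:
        den = mcde_filter(volume, params.diffusion)
        surfaces = segment_layers(den, params.layers)
        surfaces["BM"] = estimate_bm(surfaces["RPE_FLOOR"])
        initial = initial_ped_mask(surfaces["RPE_FLOOR"], surfaces["BM"],
                                   volume.shape[2])
        regions, fv = extract_all_features(den.data, initial.mask, surfaces)
        if not regions:
            continue
        feats.append(fv)
        labels.append(make_labels(regions, truth.mask, params.overlap_threshold))
        if tune_weights and truth.mask.any():
            tuning_cases.append((den, surfaces, initial, truth))
    if not feats:
        raise ContractError("no candidate regions found in the training set")
    X = np.vstack(feats)
    y = np.concatenate(labels)
    clf = train(X, y, params.boost_rounds)

    if tune_weights and tuning_cases:
        cases = []
        for den, surfaces, initial, truth in tuning_cases:
            regions, fv = extract_all_features(den.data, initial.mask, surfaces)
            refined = filter_regions(initial, regions, fv, clf)
            if not refined.mask.any():
                continue
            bright = brightness_transform(den, surfaces)
            try:
                data, seeds, prior, box = _prepare_cut(bright, refined, params)
            except SeedError:
                continue
            cases.append((data, seeds, prior, truth.mask[box]))
        if cases:
            params = dataclasses.replace(
                params, weights=estimate_weights(cases, params.weights)
            )
    return clf, params


@dataclass
class RunConfig:
    """File-level configuration of a pipeline run."""

    inputs: list[str]
    output_dir: str
    classifier: str | None = None
    truths: list[str] | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["params"] = PipelineParams.from_dict(raw.get("params", {}))
        return cls(**raw)

    def validate(self) -> None:
        for p in list(self.inputs) + list(self.truths or []):
            if not Path(p).exists():
                raise ContractError(f"input file does not exist: {p}")
        if self.classifier is None:
            raise ContractError(
                "classify mode needs a classifier file; train one first"
            )
        if not Path(self.classifier).exists():
            raise ContractError(f"classifier file does not exist: {self.classifier}")
        if self.truths is not None and len(self.truths) != len(self.inputs):
            raise ContractError("one truth mask per input volume required")


def run_pipeline(config: RunConfig) -> list[VolumeResult]:
    """Apply a trained model to every configured volume, persisting outputs.

    Per volume ``<stem>/`` receives surfaces.csv and the initial, refined
    and final masks; a ``manifest.json`` (parameters, package version,
    seed) and, when truths are given, a ``metrics.csv`` with one row per
    volume plus an aggregate row, are written to the output directory.
    """
    config.validate()
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    clf = StrongClassifier.from_json(config.classifier)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "classifier": str(config.classifier),
        "params": config.params.to_dict(),
        "inputs": list(config.inputs),
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=1))

    results = []
    rows = []
    for i, path in enumerate(config.inputs):
        volume = read_volume(path)
        truth = read_mask(config.truths[i]) if config.truths else None
        res = segment_volume(volume, clf, config.params, truth=truth)
        vdir = out_root / Path(path).stem
        vdir.mkdir(exist_ok=True)
        write_surfaces(res.surfaces, vdir / "surfaces.csv")
        write_mask(res.initial_mask, vdir / "initial_mask.tif")
        write_mask(res.refined_mask, vdir / "refined_mask.tif")
        write_mask(res.final_mask, vdir / "final_mask.tif")
        results.append(res)
        if res.metrics is not None:
            rows.append({"volume": Path(path).stem, **res.metrics.as_percent()})

    if rows:
        import pandas as pd

        df = pd.DataFrame(rows)
        agg = df.drop(columns="volume").mean().to_dict()
        df = pd.concat(
            [df, pd.DataFrame([{"volume": "mean", **agg}])], ignore_index=True
        )
        df.to_csv(out_root / "metrics.csv", index=False)
    return results
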