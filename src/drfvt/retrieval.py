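"""Feature extraction pipeline, index building, and sketch queries.

The database side processes every labelled projection-view silhouette
through the configured feature pipeline and stores the resulting radial
feature vectors per model; a query sketch is processed with the *same*
configuration and models are ranked by the Euclidean distance

    D(X, Y) = sqrt(sum_i (x_i - y_i)^2)

between its feature vector and each model's views.  A model's score is
the minimum distance over its views (a sketch depicts one viewpoint), and
ties are broken lexicographically by model id for reproducibility.  The
index records a configuration fingerprint so that query-time parameters
(sampling length N, dimensionality M, FVT flag, method) must match the
parameters the index was built with.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptor
from .contour import Contour, contour_to_signal, trace_outline
from .features import FeatureVector, fvt, maxc_select, radial_feature
from .images import fill_strokes, load_silhouette

__all__ = [
    "PipelineConfig",
    "ModelRecord",
    "RankedResult",
    "RetrievalIndex",
    "ConfigMismatchError",
    "euclidean_distance",
    "feature_from_signal",
    "compute_feature",
    "build_index",
    "query",
    "rank_feature",
]

logger = logging.getLogger(__name__)


class ConfigMismatchError(ValueError):
    """Query feature parameters do not match the index configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters fixing the feature-extraction pipeline.

    ``n_samples`` (N) is the even outline resampling length;
    ``n_coefficients`` (M) the retained descriptor dimensionality;
    ``method`` selects the low-frequency reconstruction pipeline ("dr")
    or the highest-curvature baseline ("maxc"); ``use_fvt`` applies the
    min-anchored cyclic shift.  The image options control binarization
    and stroke-to-region preprocessing.
    """

    n_samples: int = 256
    n_coefficients: int = 32
    use_fvt: bool = True
    method: str = "dr"
    threshold: int = 127
    invert: bool = False
    closing_radius: int = 1
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("dr", "maxc"):
            raise ValueError("method must be 'dr' or 'maxc'")

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class ModelRecord:
    """All view features of one database model."""

    model_id: str
    category: str
    view_ids: list[str]
    views: list[FeatureVector]


@dataclass
class RankedResult:
    """Models ordered by ascending distance to a query feature."""

    query_id: str
    entries: list[tuple[str, float]]


def euclidean_distance(x: FeatureVector, y: FeatureVector) -> float:
    """Euclidean distance between two feature vectors of equal length."""
    if len(x.r) != len(y.r):
        raise ValueError(f"feature length mismatch: {len(x.r)} vs {len(y.r)}")
    if x.fvt_applied != y.fvt_applied:
        raise ValueError("cannot compare FVT and non-FVT feature vectors")
    return float(np.linalg.norm(np.asarray(x.r) - np.asarray(y.r)))


def feature_from_signal(signal: np.ndarray,
                        config: PipelineConfig) -> FeatureVector:
    """Low-frequency ("dr") feature of a complex outline signal.

    Runs DFT -> invariance normalization -> truncation to M -> inverse
    DFT -> radial feature (-> FVT).  Used by the image pipeline after
    tracing/resampling, and directly by rasterization-free tests.
    """
    coeffs = descriptor.dft(signal)
    norm = descriptor.normalize(coeffs)
    desc = descriptor.truncate(norm, config.n_coefficients)
    feat = radial_feature(descriptor.reconstruct(desc))
    return fvt(feat) if config.use_fvt else feat


def _feature_from_contour(contour: Contour,
                          config: PipelineConfig) -> FeatureVector:
    if config.method == "dr":
        signal = contour_to_signal(contour, config.n_samples)
        return feature_from_signal(signal, config)
    points = maxc_select(contour, config.n_coefficients)
    feat = radial_feature(points)
    return fvt(feat) if config.use_fvt else feat


def compute_feature(image, config: PipelineConfig) -> FeatureVector:
    """Full image-to-feature pipeline.

    ``image`` is a path (PNG/PGM) or a binary array; it is binarized,
    stroke-filled, traced, and fed to the configured feature pipeline.
    """
    if isinstance(image, (str, Path)):
        mask = load_silhouette(image, threshold=config.threshold,
                               invert=config.invert)
    else:
        mask = np.asarray(image).astype(bool)
    mask = fill_strokes(mask, closing_radius=config.closing_radius,
                        fill_holes=config.fill_holes)
    return _feature_from_contour(trace_outline(mask), config)


@dataclass
class RetrievalIndex:
    """Searchable per-model feature store with its build configuration."""

    config: PipelineConfig
    records: list[ModelRecord] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_views(self) -> int:
        return sum(len(r.views) for r in self.records)

    def categories(self) -> dict[str, str]:
        """Mapping model_id -> category."""
        return {r.model_id: r.category for r in self.records}

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "models": [
                {
                    "model_id": r.model_id,
                    "category": r.category,
                    "views": [
                        {
                            "view_id": vid,
                            "r": [float(v) for v in fv.r],
                            "centroid": [fv.centroid[0], fv.centroid[1]],
                            "fvt": fv.fvt_applied,
                            "k": fv.k,
                        }
                        for vid, fv in zip(r.view_ids, r.views)
                    ],
                }
                for r in self.records
            ],
        }
        return json.dumps(payload, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RetrievalIndex":
        obj = json.loads(text)
        index = cls(config=PipelineConfig(**obj["config"]))
        for rec in obj["models"]:
            views = [
                FeatureVector(r=np.array(v["r"], dtype=float),
                              centroid=tuple(v["centroid"]),
                              fvt_applied=bool(v["fvt"]), k=v["k"])
                for v in rec["views"]
            ]
            index.records.append(ModelRecord(
                model_id=rec["model_id"], category=rec["category"],
                view_ids=[v["view_id"] for v in rec["views"]], views=views))
        return index

    @classmethod
    def load(cls, path) -> "RetrievalIndex":
        return cls.from_json(Path(path).read_text())

    def features_to_csv(self, path) -> None:
        """Dump all view features as CSV rows: id, category, view, M, fvt, r_1..r_M."""
        rows = []
        for rec in self.records:
            for vid, fv in zip(rec.view_ids, rec.views):
                row = {"model_id": rec.model_id, "category": rec.category,
                       "view_id": vid, "M": len(fv.r),
                       "fvt": int(fv.fvt_applied)}
                row.update({f"r_{t + 1}": fv.r[t] for t in range(len(fv.r))})
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def build_index(manifest, config: PipelineConfig,
                base_dir=None) -> RetrievalIndex:
    """Build a retrieval index from a labelled view manifest.

    ``manifest`` is a CSV path or DataFrame with columns ``model_id,
    category, view_id, image_path`` (paths resolved against ``base_dir``,
    defaulting to the manifest's directory).  Rows whose image cannot be
    processed are recorded in ``index.errors`` and skipped; an empty
    manifest, or one with no processable row, is an error.
    """
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        table = pd.read_csv(manifest_path)
        if base_dir is None:
            base_dir = manifest_path.parent
    else:
        table = manifest
        if base_dir is None:
            base_dir = Path(".")
    base_dir = Path(base_dir)
    if len(table) == 0:
        raise ValueError("empty manifest")

    index = RetrievalIndex(config=config)
    by_model: dict[str, ModelRecord] = {}
    for row in table.itertuples(index=False):
        key = f"{row.model_id}/{row.view_id}"
        try:
            feat = compute_feature(base_dir / row.image_path, config)
        except Exception as exc:  # per-row tolerance, index still built
            logger.warning("skipping %s: %s", key, exc)
            index.errors.append((key, str(exc)))
            continue
        rec = by_model.get(row.model_id)
        if rec is None:
            rec = ModelRecord(model_id=str(row.model_id),
                              category=str(row.category),
                              view_ids=[], views=[])
            by_model[row.model_id] = rec
            index.records.append(rec)
        rec.view_ids.append(str(row.view_id))
        rec.views.append(feat)
    if not index.records:
        raise ValueError("no manifest row could be processed")
    return index


def rank_feature(feature: FeatureVector, index: RetrievalIndex,
                 top_k: int | None = None,
                 query_id: str = "query") -> RankedResult:
    """Rank index models against a precomputed query feature.

    The feature must match the index configuration (same M, same FVT
    flag); a model's distance is the minimum over its views; ties break
    by model id; ``top_k`` beyond the index size is clamped.
    """
    cfg = index.config
    if len(feature.r) != cfg.n_coefficients:
        raise ConfigMismatchError(
            f"query feature has M={len(feature.r)}, "
            f"index was built with M={cfg.n_coefficients}")
    if feature.fvt_applied != cfg.use_fvt:
        raise ConfigMismatchError(
            "query feature FVT flag does not match the index configuration")
    scored = sorted(
        ((min(euclidean_distance(feature, v) for v in rec.views),
          rec.model_id) for rec in index.records))
    entries = [(mid, dist) for dist, mid in scored]
    if top_k is not None:
        entries = entries[:top_k]
    return RankedResult(query_id=query_id, entries=entries)


def query(image, index: RetrievalIndex, top_k: int | None = None,
          query_id: str = "query") -> RankedResult:
    """Rank index models against a sketch image (path or binary array)."""
    feature = compute_feature(image, index.config)
    return rank_feature(feature, index, top_k=top_k, query_id=query_id)
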