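"""The OA vector and the B-score.

The OA vector is the line in flattened shape space passing through the mean
shape of a non-OA reference group and the mean shape of an OA group.  The
B-score of a shape is its signed orthogonal projection onto this line,
measured from the non-OA mean (the origin, B-score 0) in units of one sample
standard deviation of the non-OA group's own projections, positive toward
the OA mean.  By construction the defining non-OA sample has B-score mean 0
and sample SD 1.

:class:`BScoreModel` is the estimator that fits the vector from two labelled
groups (per sex by default) and converts shapes to scores; helpers
reconstruct the shape at a given B-score and map the resulting per-triangle
percentage area change.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .shapes import CorrespondedShape, MeshTopology, group_mean

__all__ = [
    "BScoreModel",
    "build_oa_vector",
    "compute_bscore",
    "nonoa_limits",
    "shape_at_bscore",
    "area_change_map",
    "triangle_areas",
    "select_groups_by_klg",
]

NONOA_LABELS = frozenset({0, "0", "nonoa", "non-oa", "non_oa", False})
OA_LABELS = frozenset({1, "1", "oa", True})


def _as_group_flag(label) -> int:
    key = label.lower() if isinstance(label, str) else label
    if key in NONOA_LABELS:
        return 0
    if key in OA_LABELS:
        return 1
    raise ValueError(f"unrecognised group label {label!r}; expected non-OA/OA")


class BScoreModel(BaseEstimator, TransformerMixin):
    """Fit the OA vector from labelled groups and score shapes along it.

    Parameters
    ----------
    pooled_direction : bool, default False
        If True, a single direction is computed from the sex-pooled group
        means while origins and SD units stay sex-specific.  The fully
        sex-specific model is the default.

    Attributes
    ----------
    models_ : dict mapping sex to a dict with keys ``origin`` (flattened
        non-OA mean), ``direction`` (unit vector toward the OA mean),
        ``sigma`` (non-OA sample SD along the direction, the B-score unit,
        mm), ``n_nonoa`` and ``n_oa``.
    n_points_ : vertex count of the fitted cohort.
    """

    def __init__(self, pooled_direction: bool = False):
        self.pooled_direction = pooled_direction

    def fit(self, shapes: Sequence[CorrespondedShape], y) -> "BScoreModel":
        """Fit per-sex OA vectors.

        ``y`` labels each shape non-OA (0/"nonoa") or OA (1/"oa").  Shapes
        must already sit in one common (Procrustes) frame.
        """
        shapes = list(shapes)
        flags = [_as_group_flag(label) for label in y]
        if len(flags) != len(shapes):
            raise ValueError("y must label every shape")
        if not shapes:
            raise ValueError("no shapes to fit")
        n_points = shapes[0].n_points
        if any(s.n_points != n_points for s in shapes):
            raise ValueError("mismatched n_points across cohort")

        sexes = sorted({s.sex for s in shapes})
        groups: dict[str, dict[int, list[CorrespondedShape]]] = {
            sex: {0: [], 1: []} for sex in sexes}
        for s, flag in zip(shapes, flags):
            groups[s.sex][flag].append(s)
        for sex in sexes:
            if not groups[sex][0]:
                raise ValueError(f"empty non-OA group for sex {sex!r}")
            if not groups[sex][1]:
                raise ValueError(f"empty OA group for sex {sex!r}")
            if len(groups[sex][0]) < 2:
                raise ValueError(f"non-OA group for sex {sex!r} needs >= 2 members")

        pooled_direction = None
        if self.pooled_direction:
            nonoa_mean = group_mean([s for s, f in zip(shapes, flags) if f == 0])
            oa_mean = group_mean([s for s, f in zip(shapes, flags) if f == 1])
            delta = oa_mean - nonoa_mean
            norm = float(np.linalg.norm(delta))
            if norm == 0.0:
                raise ValueError("pooled OA and non-OA means coincide")
            pooled_direction = delta / norm

        self.models_ = {}
        for sex in sexes:
            origin = group_mean(groups[sex][0])
            if pooled_direction is None:
                delta = group_mean(groups[sex][1]) - origin
                norm = float(np.linalg.norm(delta))
                if norm == 0.0:
                    raise ValueError(f"OA and non-OA means coincide for sex {sex!r}")
                direction = delta / norm
            else:
                direction = pooled_direction
            proj = np.array([(s.vector - origin) @ direction for s in groups[sex][0]])
            sigma = float(np.std(proj, ddof=1))
            if sigma == 0.0:
                raise ValueError(f"zero non-OA spread along the OA vector for sex {sex!r}")
            self.models_[sex] = {
                "origin": origin,
                "direction": direction,
                "sigma": sigma,
                "n_nonoa": len(groups[sex][0]),
                "n_oa": len(groups[sex][1]),
            }
        self.n_points_ = n_points
        return self

    def score_shape(self, shape: CorrespondedShape) -> float:
        """B-score of one shape (units: non-OA SDs, positive toward OA)."""
        check_is_fitted(self, "models_")
        if shape.sex not in self.models_:
            raise ValueError(f"sex {shape.sex!r} absent from fitted model "
                             f"(has {sorted(self.models_)})")
        if shape.n_points != self.n_points_:
            raise ValueError(f"shape {shape.shape_id!r} has {shape.n_points} points, "
                             f"model expects {self.n_points_}")
        m = self.models_[shape.sex]
        return float((shape.vector - m["origin"]) @ m["direction"] / m["sigma"])

    def transform(self, shapes: Sequence[CorrespondedShape]) -> np.ndarray:
        return np.array([self.score_shape(s) for s in shapes])

    # -- persistence --------------------------------------------------

    def to_json(self, path) -> None:
        check_is_fitted(self, "models_")
        doc = {
            "format": "bscore-oa-vector-model",
            "version": 1,
            "n_points": int(self.n_points_),
            "pooled_direction": bool(self.pooled_direction),
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "sexes": {},
        }
        digest = hashlib.sha256()
        for sex in sorted(self.models_):
            m = self.models_[sex]
            digest.update(m["origin"].tobytes())
            digest.update(m["direction"].tobytes())
            doc["sexes"][sex] = {
                "origin": m["origin"].tolist(),
                "direction": m["direction"].tolist(),
                "sigma": m["sigma"],
                "n_nonoa": m["n_nonoa"],
                "n_oa": m["n_oa"],
            }
        doc["model_hash"] = digest.hexdigest()
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "BScoreModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "bscore-oa-vector-model":
            raise ValueError(f"{path} is not an OA-vector model file")
        model = cls(pooled_direction=doc.get("pooled_direction", False))
        model.models_ = {}
        for sex, m in doc["sexes"].items():
            model.models_[sex] = {
                "origin": np.asarray(m["origin"], dtype=float),
                "direction": np.asarray(m["direction"], dtype=float),
                "sigma": float(m["sigma"]),
                "n_nonoa": int(m["n_nonoa"]),
                "n_oa": int(m["n_oa"]),
            }
        model.n_points_ = int(doc["n_points"])
        return model


def build_oa_vector(nonoa: Sequence[CorrespondedShape], oa: Sequence[CorrespondedShape],
                    pooled_direction: bool = False) -> BScoreModel:
    """Fit a :class:`BScoreModel` from explicit non-OA and OA shape groups."""
    shapes = list(nonoa) + list(oa)
    y = [0] * len(list(nonoa)) + [1] * len(list(oa))
    return BScoreModel(pooled_direction=pooled_direction).fit(shapes, y)


def compute_bscore(shape: CorrespondedShape, model: BScoreModel) -> float:
    return model.score_shape(shape)


def nonoa_limits(level: float = 0.95) -> tuple[float, float]:
    """Symmetric non-OA reference range in B-score units.

    The non-OA group has B-score mean 0 and SD 1 by construction, so its
    central ``level`` interval under normality is plus/minus the standard
    normal quantile at (1+level)/2 — the familiar +-1.96 at 95%.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    q = float(stats.norm.ppf((1 + level) / 2))
    return (-q, q)


def shape_at_bscore(b: float, model: BScoreModel, sex: str) -> CorrespondedShape:
    """Shape on the OA vector at B-score ``b`` for the given sex."""
    check_is_fitted(model, "models_")
    if not np.isfinite(b):
        raise ValueError(f"B-score must be finite, got {b}")
    if sex not in model.models_:
        raise ValueError(f"sex {sex!r} absent from model")
    m = model.models_[sex]
    vec = m["origin"] + float(b) * m["sigma"] * m["direction"]
    return CorrespondedShape.from_vector(vec, shape_id=f"bscore={b:g}", sex=sex)


def triangle_areas(coords: np.ndarray, topology: MeshTopology) -> np.ndarray:
    """Per-face triangle areas via the cross-product formula."""
    faces = topology.faces
    a = coords[faces[:, 0]]
    edge1 = coords[faces[:, 1]] - a
    edge2 = coords[faces[:, 2]] - a
    return 0.5 * np.linalg.norm(np.cross(edge1, edge2), axis=1)


def area_change_map(b: float, model: BScoreModel, topology: MeshTopology,
                    sex: str) -> np.ndarray:
    """Percent area change of each triangle between B-score 0 and ``b``.

    This is the numeric form of the severity heat map: red regions of the
    rendered figure correspond to faces with large positive values, i.e.
    local surface growth (osteophyte-like change at the cartilage-plate rim).
    """
    origin_shape = shape_at_bscore(0.0, model, sex)
    topology.validate_for(origin_shape.n_points)
    area0 = triangle_areas(origin_shape.coords, topology)
    zero = np.flatnonzero(area0 == 0.0)
    if zero.size:
        raise ValueError(f"zero-area faces on the origin shape: {zero.tolist()}")
    area_b = triangle_areas(shape_at_bscore(b, model, sex).coords, topology)
    return 100.0 * (area_b - area0) / area0


def select_groups_by_klg(klg_table, min_grade_oa: int = 2):
    """Split knees into OA / non-OA groups from longitudinal KLG readings.

    ``klg_table`` maps knee id to a sequence of KLG readings over time.
    A knee is OA if every reading is >= ``min_grade_oa`` and non-OA if every
    reading is 0; knees meeting neither definition belong to neither group.
    Returns ``(nonoa_ids, oa_ids)`` preserving the table's iteration order.
    """
    nonoa_ids, oa_ids = [], []
    for knee_id, readings in klg_table.items():
        readings = list(readings)
        if not readings:
            continue
        if all(g == 0 for g in readings):
            nonoa_ids.append(knee_id)
        elif all(g >= min_grade_oa for g in readings):
            oa_ids.append(knee_id)
    return nonoa_ids, oa_ids
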