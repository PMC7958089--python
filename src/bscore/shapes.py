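"""Corresponded point-set shapes, rigid alignment and shape PCA.

A cohort of knees is represented as a list of :class:`CorrespondedShape`
objects sharing a fixed anatomical correspondence: vertex ``i`` of one femur
is the same anatomical location as vertex ``i`` of every other femur.  On
this substrate the module provides side mirroring, generalized Procrustes
alignment (GPA) into a common frame, group mean shapes, and a point
distribution model (PCA on the aligned coordinates).

Alignment is rigid by default (rotation + translation, no scaling): real
osteoarthritic shape change includes genuine size increase of the articular
surfaces, which similarity alignment would remove.  A ``scaling`` flag is
available for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CorrespondedShape",
    "MeshTopology",
    "AlignmentResult",
    "mirror_to_reference_side",
    "kabsch",
    "GeneralizedProcrustes",
    "generalized_procrustes",
    "group_mean",
    "ShapePCA",
    "fit_pca_model",
]

SIDES = ("left", "right")
SEXES = ("male", "female")


@dataclass(frozen=True)
class CorrespondedShape:
    """One subject-knee's corresponded 3D vertex coordinates (mm).

    Vertex order *is* the anatomical correspondence and is never permuted
    by any operation in this package (mirroring applies the explicit
    left-right correspondence map, identity by default).
    """

    shape_id: str
    coords: np.ndarray  # (n_points, 3), mm
    side: str = "right"
    sex: str = "female"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(
                f"coords must be (n_points, 3); got {coords.shape} for {self.shape_id!r}"
            )
        if coords.shape[0] < 4:
            raise ValueError(f"need at least 4 corresponded points, got {coords.shape[0]}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in shape {self.shape_id!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Flattened 3*n_points coordinate vector (row-major: x0,y0,z0,x1,...)."""
        return self.coords.ravel()

    def with_coords(self, coords: np.ndarray, **kwargs) -> "CorrespondedShape":
        return replace(self, coords=np.asarray(coords, dtype=float), **kwargs)

    @staticmethod
    def from_vector(vector: np.ndarray, shape_id: str, side: str = "right",
                    sex: str = "female") -> "CorrespondedShape":
        vector = np.asarray(vector, dtype=float)
        if vector.ndim != 1 or vector.size % 3:
            raise ValueError("vector length must be a multiple of 3")
        return CorrespondedShape(shape_id, vector.reshape(-1, 3), side=side, sex=sex)


@dataclass(frozen=True)
class MeshTopology:
    """Triangle face list shared by all shapes of a cohort (0-based indices)."""

    faces: np.ndarray  # (n_faces, 3) int

    def __post_init__(self) -> None:
        faces = np.asarray(self.faces, dtype=int)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError(f"faces must be (n_faces, 3); got {faces.shape}")
        if faces.min(initial=0) < 0:
            raise ValueError("negative vertex index in face list")
        degenerate = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) \
            | (faces[:, 0] == faces[:, 2])
        if degenerate.any():
            raise ValueError(
                f"degenerate faces (repeated vertex) at indices {np.flatnonzero(degenerate).tolist()}"
            )
        object.__setattr__(self, "faces", faces)

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate_for(self, n_points: int) -> None:
        if self.faces.size and self.faces.max() >= n_points:
            raise ValueError(
                f"face index {self.faces.max()} out of range for {n_points} points"
            )


@dataclass
class AlignmentResult:
    """Output of generalized Procrustes alignment.

    Each aligned shape equals a rigid (or similarity) transform of its input:
    ``aligned = scale * input @ rotation.T + translation``.
    """

    shapes: list  # aligned CorrespondedShape
    rotations: list  # (3,3) per shape
    translations: list  # (3,) per shape
    scales: list  # float per shape (1.0 when scaling disabled)
    mean: np.ndarray  # (n_points, 3), centred at origin
    n_iter: int
    mean_change: float


def mirror_to_reference_side(shape: CorrespondedShape,
                             correspondence_map: np.ndarray | None = None
                             ) -> CorrespondedShape:
    """Bring a shape into the right-knee convention.

    Left shapes are reflected about the x=0 plane and re-indexed by the
    left-to-right vertex correspondence map (``new[i] = reflected[map[i]]``);
    the identity map (default) suits synthetic cohorts whose template is
    built symmetric in correspondence.  Right shapes pass through unchanged.
    """
    if shape.side == "right":
        return shape
    if shape.side != "left":  # pragma: no cover - dataclass already validates
        raise ValueError(f"unknown side {shape.side!r}")
    reflected = shape.coords.copy()
    reflected[:, 0] = -reflected[:, 0]
    if correspondence_map is not None:
        cmap = np.asarray(correspondence_map, dtype=int)
        if sorted(cmap.tolist()) != list(range(shape.n_points)):
            raise ValueError("correspondence_map must be a permutation of vertex indices")
        reflected = reflected[cmap]
    return shape.with_coords(reflected, side="right")


def kabsch(source: np.ndarray, target: np.ndarray, scaling: bool = False
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid (optionally similarity) superposition.

    Returns ``(rotation, translation, scale)`` such that
    ``scale * source @ rotation.T + translation`` best fits ``target``.
    The rotation is proper (det = +1).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have identical shapes")
    c_s = source.mean(axis=0)
    c_t = target.mean(axis=0)
    src = source - c_s
    tgt = target - c_t
    ss = float(np.sum(src * src))
    if ss <= 0.0:
        raise ValueError("degenerate shape: all points coincident")
    h = src.T @ tgt
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d]) if source.shape[1] == 3 else np.ones(source.shape[1])
    if source.shape[1] == 3:
        rot = vt.T @ np.diag(diag) @ u.T
        trace = float(np.sum(s * diag))
    else:
        rot = vt.T @ u.T
        trace = float(np.sum(s))
    scale = trace / ss if scaling else 1.0
    trans = c_t - scale * rot @ c_s
    return rot, trans, scale


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Iterative generalized Procrustes alignment into a common frame.

    ``fit`` aligns the training cohort to its evolving mean shape, recentred
    at the origin each iteration, until the mean changes by less than ``tol``
    (Frobenius norm, mm) or ``max_iter`` is reached.  ``transform`` performs
    ordinary Procrustes superposition of further shapes onto the fitted mean.

    Parameters
    ----------
    scaling : bool, default False
        Allow a per-shape similarity scale.  Off by default because OA shape
        change includes real size change that scaling would erase.
    tol : float, default 1e-8
        Convergence tolerance on the Frobenius norm of the mean-shape change.
    max_iter : int, default 100

    Attributes
    ----------
    mean_ : (n_points, 3) mean shape, centroid at the origin.
    n_iter_ : iterations run.
    mean_change_ : final mean-change norm.
    """

    def __init__(self, scaling: bool = False, tol: float = 1e-8, max_iter: int = 100):
        self.scaling = scaling
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, shapes: Sequence[CorrespondedShape], y=None) -> "GeneralizedProcrustes":
        self.fit_transform(shapes)
        return self

    def fit_transform(self, shapes: Sequence[CorrespondedShape], y=None) -> list:
        shapes = list(shapes)
        if not shapes:
            raise ValueError("need at least one shape")
        n_points = shapes[0].n_points
        bad = [s.shape_id for s in shapes if s.n_points != n_points]
        if bad:
            raise ValueError(f"mismatched n_points for shapes: {bad}")
        coords = np.stack([s.coords for s in shapes])
        for i, c in enumerate(coords):
            if float(np.sum((c - c.mean(axis=0)) ** 2)) <= 0.0:
                raise ValueError(f"degenerate shape (all points coincident): {shapes[i].shape_id!r}")

        # start from the centred cohort mean so an already-aligned cohort is
        # a fixed point (idempotence); fall back to the first shape when the
        # naive mean collapses (e.g. antipodal orientations)
        centred = coords - coords.mean(axis=1, keepdims=True)
        mean = centred.mean(axis=0)
        if float(np.sum(mean ** 2)) < 1e-12 * float(np.mean(np.sum(centred ** 2, axis=(1, 2)))):
            mean = centred[0]
        aligned = coords.copy()
        n_iter = 0
        change = np.inf
        for n_iter in range(1, self.max_iter + 1):
            for i in range(len(shapes)):
                rot, trans, scale = kabsch(coords[i], mean, scaling=self.scaling)
                aligned[i] = scale * coords[i] @ rot.T + trans
            new_mean = aligned.mean(axis=0)
            new_mean = new_mean - new_mean.mean(axis=0)
            change = float(np.linalg.norm(new_mean - mean))
            mean = new_mean
            if change < self.tol:
                break

        self.mean_ = mean
        self.n_iter_ = n_iter
        self.mean_change_ = change
        rotations, translations, scales, out = [], [], [], []
        for i, s in enumerate(shapes):
            rot, trans, scale = kabsch(coords[i], mean, scaling=self.scaling)
            rotations.append(rot)
            translations.append(trans)
            scales.append(scale)
            out.append(s.with_coords(scale * coords[i] @ rot.T + trans))
        self.rotations_ = rotations
        self.translations_ = translations
        self.scales_ = scales
        self.aligned_ = out
        return out

    def transform(self, shapes: Sequence[CorrespondedShape]) -> list:
        check_is_fitted(self, "mean_")
        out = []
        for s in shapes:
            if s.n_points != self.mean_.shape[0]:
                raise ValueError(f"shape {s.shape_id!r} has {s.n_points} points, "
                                 f"model expects {self.mean_.shape[0]}")
            rot, trans, scale = kabsch(s.coords, self.mean_, scaling=self.scaling)
            out.append(s.with_coords(scale * s.coords @ rot.T + trans))
        return out

    @property
    def result_(self) -> AlignmentResult:
        check_is_fitted(self, "mean_")
        return AlignmentResult(
            shapes=self.aligned_, rotations=self.rotations_,
            translations=self.translations_, scales=self.scales_,
            mean=self.mean_, n_iter=self.n_iter_, mean_change=self.mean_change_,
        )


def generalized_procrustes(shapes: Sequence[CorrespondedShape], scaling: bool = False,
                           tol: float = 1e-8, max_iter: int = 100) -> AlignmentResult:
    """Functional wrapper around :class:`GeneralizedProcrustes`."""
    gpa = GeneralizedProcrustes(scaling=scaling, tol=tol, max_iter=max_iter)
    gpa.fit(shapes)
    return gpa.result_


def group_mean(shapes: Sequence[CorrespondedShape]) -> np.ndarray:
    """Coordinate-wise arithmetic mean as a flattened shape vector."""
    shapes = list(shapes)
    if not shapes:
        raise ValueError("group_mean of empty shape list")
    n_points = shapes[0].n_points
    if any(s.n_points != n_points for s in shapes):
        raise ValueError("mismatched n_points in group")
    return np.mean([s.vector for s in shapes], axis=0)


class ShapePCA(BaseEstimator, TransformerMixin):
    """Point distribution model: PCA of flattened aligned shape vectors.

    Retains the smallest number of modes whose cumulative explained-variance
    fraction reaches ``variance_retained``.  Modes are unit-norm, ordered by
    decreasing eigenvalue, with the sign convention that each mode's
    largest-magnitude loading is positive.
    """

    def __init__(self, variance_retained: float = 0.98):
        self.variance_retained = variance_retained

    def fit(self, shapes: Sequence[CorrespondedShape], y=None) -> "ShapePCA":
        shapes = list(shapes)
        if len(shapes) < 2:
            raise ValueError("PCA requires at least 2 shapes")
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must be in (0, 1]")
        x = np.stack([s.vector for s in shapes])
        pca = PCA(n_components=min(x.shape[0] - 1, x.shape[1]))
        pca.fit(x)
        ratios = pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.variance_retained - 1e-12) + 1)
        k = min(k, len(ratios))
        components = pca.components_[:k].copy()
        for j in range(k):
            i_max = int(np.argmax(np.abs(components[j])))
            if components[j, i_max] < 0:
                components[j] = -components[j]
        self.mean_ = pca.mean_
        self.components_ = components
        self.eigenvalues_ = pca.explained_variance_[:k].copy()
        self.total_variance_ = float(pca.explained_variance_.sum())
        self.n_components_ = k
        return self

    def transform(self, shapes: Sequence[CorrespondedShape]) -> np.ndarray:
        check_is_fitted(self, "components_")
        x = np.stack([s.vector for s in shapes])
        return (x - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        return self.mean_ + np.asarray(scores, dtype=float) @ self.components_


def fit_pca_model(shapes: Sequence[CorrespondedShape],
                  variance_retained: float = 0.98) -> ShapePCA:
    """Functional wrapper: fit a :class:`ShapePCA` and return it."""
    return ShapePCA(variance_retained=variance_retained).fit(shapes)
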