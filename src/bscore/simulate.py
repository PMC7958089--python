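"""Synthetic corresponded femur-like cohorts with known ground truth.

Real cohorts of segmented, corresponded femur surfaces are not freely
shippable, so every analysis module here is exercised on simulated ones.
The generator emulates the statistical structure the method relies on, not
femoral anatomy:

* a latent OA *severity* per knee, drawn from a two-component mixture
  (non-OA component N(0, 1); OA component N(4, 1.5^2), OA fraction 0.4),
  correlated 0.6 between a person's two knees;
* a condyle-like template surface (a jittered ellipsoid) whose deformation
  grows linearly with severity — concentrated on a designated "rim" vertex
  band standing in for the cartilage-plate edge where osteophytic growth
  localises, with mild flattening elsewhere;
* additive per-sex shape offsets, individual PCA-style variation modes and
  i.i.d. Gaussian coordinate measurement noise;
* Kellgren-Lawrence grade as a cut-point discretisation of severity with a
  configurable misclassification rate, so each observed grade contains a
  wide range of true severities;
* symptom scores and TKR generated so that every threshold-exceedance
  probability is exactly inverse-logit(intercept + slope * severity).

All randomness flows from a single seed through per-component substreams,
so the output is bit-reproducible and adding subjects never perturbs
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.special import expit

from .outcomes import ClinicalRecord, DEFAULT_THRESHOLDS, SCALE_RANGES
from .repeatability import ScanPair
from .shapes import CorrespondedShape, MeshTopology

__all__ = [
    "SimulationConfig",
    "CohortData",
    "make_template",
    "deformation_field",
    "generate_cohort",
    "generate_repeat_scans",
    "simulate_score_pairs",
    "oa_group_labels",
]

DEFAULT_OUTCOME_COEFS = {
    # (intercept, slope) on the logit scale per unit latent severity; the
    # moderate defaults take risk from ~10% at severity -2 to ~60% at +7.
    "nrs_pain": {"moderate": (-1.619, 0.289), "severe": (-3.27, 0.31)},
    "womac_function": {"moderate": (-1.619, 0.289), "severe": (-3.27, 0.31)},
    "womac_pain": {"moderate": (-1.619, 0.289), "severe": (-3.27, 0.31)},
    "tkr": (-4.0, 0.5),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions."""

    n_subjects: int = 250
    seed: int = 0
    n_points: int = 120
    fraction_female: float = 0.5
    oa_fraction: float = 0.4
    nonoa_mean: float = 0.0
    nonoa_sd: float = 1.0
    oa_mean: float = 4.0
    oa_sd: float = 1.5
    knee_correlation: float = 0.6
    rim_fraction: float = 0.2
    rim_gain: float = 0.8        # mm of rim displacement per severity unit
    flatten_gain: float = 0.1    # mm of central flattening per severity unit
    sex_offset: float = 1.0      # rms mm of the male-female shape offset
    variation_sds: tuple = (1.0, 0.6, 0.3)  # mm, individual variation modes
    noise_sd: float = 0.1        # mm, i.i.d. coordinate measurement noise
    klg_cutpoints: tuple = (-0.5, 1.0, 2.5, 4.0)
    klg_misclassification: float = 0.2
    n_timepoints: int = 4
    outcome_coefs: dict = field(default_factory=lambda: {
        scale: (dict(v) if isinstance(v, dict) else v)
        for scale, v in DEFAULT_OUTCOME_COEFS.items()})

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.n_points < 12:
            raise ValueError("n_points must be at least 12")
        for name in ("nonoa_sd", "oa_sd", "rim_gain", "flatten_gain",
                     "sex_offset", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fraction_female", "oa_fraction", "klg_misclassification",
                     "rim_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1 <= self.knee_correlation <= 1:
            raise ValueError("knee_correlation must be in [-1, 1]")
        if any(s < 0 for s in self.variation_sds):
            raise ValueError("variation SDs must be non-negative")
        cuts = list(self.klg_cutpoints)
        if len(cuts) != 4 or sorted(cuts) != cuts or len(set(cuts)) != 4:
            raise ValueError("klg_cutpoints must be 4 strictly increasing values")
        if self.n_timepoints < 1:
            raise ValueError("need at least the baseline timepoint")


@dataclass
class CohortData:
    """Everything one simulated cohort produces.

    ``truth`` carries the latent state (severity, pre-misclassification KLG,
    true outcome probabilities) for recovery tests only; analysis code must
    never consume it.
    """

    shapes: list
    records: list
    truth: pd.DataFrame
    template: CorrespondedShape
    topology: MeshTopology
    rim_indices: np.ndarray
    config: SimulationConfig


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere points (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_template(n_points: int = 120, seed: int = 0,
                  rim_fraction: float = 0.2
                  ) -> tuple[CorrespondedShape, MeshTopology, np.ndarray]:
    """Closed condyle-like template surface with designated rim vertices.

    A unit Fibonacci sphere is stretched to ellipsoid semi-axes
    (40, 35, 25) mm — femoral-condyle scale — and given a small seeded
    jitter to break the spiral's symmetries.  Faces come from the convex
    hull, so the topology is closed and non-degenerate.  The rim set is the
    ``rim_fraction`` of vertices nearest the equatorial plane, the synthetic
    stand-in for the cartilage-plate edge.
    """
    if n_points < 12:
        raise ValueError(f"n_points must be at least 12, got {n_points}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pts = _fibonacci_sphere(n_points) * np.array([40.0, 35.0, 25.0])
    pts = pts + rng.normal(scale=0.3, size=pts.shape)
    topo = MeshTopology(ConvexHull(pts).simplices)
    n_rim = int(round(rim_fraction * n_points))
    rim = np.argsort(np.abs(pts[:, 2]))[:n_rim]
    shape = CorrespondedShape("template", pts, side="right", sex="female")
    return shape, topo, np.sort(rim)


def deformation_field(template: CorrespondedShape, rim_indices: np.ndarray,
                      rim_gain: float, flatten_gain: float) -> np.ndarray:
    """Per-severity-unit displacement field (mm): radial outward growth on
    the rim band, mild flattening toward the equatorial plane elsewhere."""
    coords = template.coords
    n = template.n_points
    fld = np.zeros((n, 3))
    rim_mask = np.zeros(n, dtype=bool)
    rim_mask[rim_indices] = True
    radial = coords[:, :2].copy()
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    fld[rim_mask, :2] = rim_gain * (radial / norms)[rim_mask]
    fld[~rim_mask, 2] = -flatten_gain * np.sign(coords[~rim_mask, 2])
    return fld


def _unit_rms_field(rng: np.random.Generator, n_points: int) -> np.ndarray:
    f = rng.normal(size=(n_points, 3))
    return f / np.sqrt(np.mean(f ** 2))


def _draw_scores(rng: np.random.Generator, severity: float, scale: str,
                 coefs: dict, n_timepoints: int) -> list:
    """Integer scores whose threshold exceedances follow the logistic model.

    One uniform draw per timepoint is mapped through the stacked severe /
    moderate exceedance probabilities, then a uniform integer is placed in
    the implied band, so P(score >= threshold) is exactly
    inverse-logit(intercept + slope * severity) for both thresholds.
    """
    lo, hi = SCALE_RANGES[scale]
    t_mod = DEFAULT_THRESHOLDS[scale]["moderate"]
    t_sev = DEFAULT_THRESHOLDS[scale]["severe"]
    a_m, b_m = coefs["moderate"]
    a_s, b_s = coefs["severe"]
    p_mod = expit(a_m + b_m * severity)
    p_sev = min(expit(a_s + b_s * severity), p_mod)
    scores = []
    for _ in range(n_timepoints):
        r = rng.uniform()
        if r < p_sev:
            scores.append(int(rng.integers(t_sev, hi + 1)))
        elif r < p_mod:
            scores.append(int(rng.integers(t_mod, t_sev)))
        else:
            scores.append(int(rng.integers(lo, t_mod)))
    return scores


def generate_cohort(config: SimulationConfig | None = None) -> CohortData:
    """Simulate shapes, clinical records and ground truth for one cohort.

    Each person contributes two knees (left and right) with correlated
    severity; left-knee geometry is stored reflected about x=0, so the
    analysis pipeline must mirror it back before modelling.
    """
    config = config or SimulationConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    template_ss, field_ss, subject_root = root.spawn(3)

    template, topology, rim = make_template(config.n_points,
                                            seed=config.seed,
                                            rim_fraction=config.rim_fraction)
    severity_field = deformation_field(template, rim, config.rim_gain,
                                       config.flatten_gain)
    field_rng = np.random.default_rng(field_ss)
    sex_field = _unit_rms_field(field_rng, config.n_points) * config.sex_offset
    modes = [_unit_rms_field(field_rng, config.n_points)
             for _ in config.variation_sds]

    shapes, records, truth_rows = [], [], []
    subject_seeds = subject_root.spawn(config.n_subjects)
    for i, sub_ss in enumerate(subject_seeds):
        rng = np.random.default_rng(sub_ss)
        person_id = f"P{i:04d}"
        sex = "female" if rng.uniform() < config.fraction_female else "male"
        is_oa = rng.uniform() < config.oa_fraction
        mean = config.oa_mean if is_oa else config.nonoa_mean
        sd = config.oa_sd if is_oa else config.nonoa_sd
        rho = config.knee_correlation
        z = rng.standard_normal(2)
        z2 = rho * z[0] + np.sqrt(max(0.0, 1 - rho * rho)) * z[1]
        severities = {"right": mean + sd * z[0], "left": mean + sd * z2}

        age = float(rng.normal(62.7, 9.45))
        bmi = float(rng.normal(30.3, 5.23))
        ethnicity = str(rng.choice(["white", "black", "other"], p=[0.8, 0.12, 0.08]))
        smoking = str(rng.choice(["never", "former", "current"], p=[0.5, 0.3, 0.2]))

        for side in ("right", "left"):
            s = float(severities[side])
            knee_id = f"{person_id}_{side[0].upper()}"
            coords = template.coords + s * severity_field
            if sex == "male":
                coords = coords + sex_field
            for mode, mode_sd in zip(modes, config.variation_sds):
                coords = coords + rng.normal(scale=mode_sd) * mode
            if config.noise_sd > 0:
                coords = coords + rng.normal(scale=config.noise_sd,
                                             size=coords.shape)
            if side == "left":
                coords = coords.copy()
                coords[:, 0] = -coords[:, 0]
            shapes.append(CorrespondedShape(knee_id, coords, side=side, sex=sex))

            true_klg = int(np.searchsorted(config.klg_cutpoints, s, side="right"))
            klg = true_klg
            if rng.uniform() < config.klg_misclassification:
                klg = int(np.clip(true_klg + rng.choice([-1, 1]), 0, 4))

            series = {scale: _draw_scores(rng, s, scale,
                                          config.outcome_coefs[scale],
                                          config.n_timepoints)
                      for scale in SCALE_RANGES}
            a_t, b_t = config.outcome_coefs["tkr"]
            p_tkr = float(expit(a_t + b_t * s))
            tkr = bool(rng.uniform() < p_tkr)

            records.append(ClinicalRecord(
                knee_id=knee_id, person_id=person_id, sex=sex, side=side,
                klg=klg, tkr=tkr,
                nrs_pain=series["nrs_pain"],
                womac_function=series["womac_function"],
                womac_pain=series["womac_pain"],
                covariates={
                    "age": age, "bmi": bmi, "ethnicity": ethnicity,
                    "alignment": float(rng.normal(0.0, 3.0)),
                    "prior_surgery": int(rng.uniform() < 0.1),
                    "nsaid": int(rng.uniform() < 0.3),
                    "smoking": smoking,
                },
            ))
            a_m, b_m = config.outcome_coefs["nrs_pain"]["moderate"]
            truth_rows.append({
                "knee_id": knee_id, "person_id": person_id, "severity": s,
                "true_klg": true_klg, "observed_klg": klg,
                "p_moderate_pain": float(expit(a_m + b_m * s)), "p_tkr": p_tkr,
            })

    truth = pd.DataFrame(truth_rows, columns=[
        "knee_id", "person_id", "severity", "true_klg", "observed_klg",
        "p_moderate_pain", "p_tkr"])
    return CohortData(shapes=shapes, records=records, truth=truth,
                      template=template, topology=topology, rim_indices=rim,
                      config=config)


def oa_group_labels(records: Sequence[ClinicalRecord], min_grade_oa: int = 2
                    ) -> dict:
    """Map knee_id -> group flag (0 non-OA, 1 OA, None neither) from KLG.

    With a single timepoint per knee this reduces the longitudinal
    definition (grade 0 at every visit vs >= 2 at every visit) to the
    baseline grade.
    """
    labels = {}
    for rec in records:
        if rec.klg == 0:
            labels[rec.knee_id] = 0
        elif rec.klg >= min_grade_oa:
            labels[rec.knee_id] = 1
        else:
            labels[rec.knee_id] = None
    return labels


def generate_repeat_scans(shapes: Sequence[CorrespondedShape], noise_sd: float,
                          seed: int = 0) -> list:
    """Duplicate each shape twice with fresh i.i.d. coordinate noise.

    Emulates same-day repeat imaging: both copies are the same underlying
    bone observed with independent measurement error.  Returns
    ``[(copy1, copy2), ...]`` in input order.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pairs = []
    for s in shapes:
        copies = []
        for k in (1, 2):
            noise = rng.normal(scale=noise_sd, size=s.coords.shape) \
                if noise_sd > 0 else 0.0
            copies.append(s.with_coords(s.coords + noise,
                                        shape_id=f"{s.shape_id}_scan{k}"))
        pairs.append(tuple(copies))
    return pairs


def simulate_score_pairs(n: int, error_sd: float, seed: int = 0,
                         truth_mean: float = 2.0, truth_sd: float = 2.5) -> list:
    """Repeat-measurement B-score pairs: truth + independent Gaussian error.

    Each knee has a fixed true B-score drawn from N(truth_mean, truth_sd^2);
    both measurements add independent N(0, error_sd^2) noise, the regime in
    which the Bland-Altman SDD converges to 1.96 * sqrt(2) * error_sd.
    """
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if error_sd < 0:
        raise ValueError("error_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    truths = rng.normal(truth_mean, truth_sd, size=n)
    errs = rng.normal(scale=error_sd, size=(n, 2)) if error_sd > 0 \
        else np.zeros((n, 2))
    return [ScanPair(f"K{i:05d}", float(t + e[0]), float(t + e[1]))
            for i, (t, e) in enumerate(zip(truths, errs))]
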