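"""Readers and writers for the package's plain-text interchange formats.

Shapes travel as ASCII PLY / OBJ meshes (via trimesh, vertex order
preserved — the order *is* the anatomical correspondence) or as a landmark
CSV (``shape_id,vertex_index,x,y,z`` plus optional ``sex``/``side``
columns), the canonical cross-language surface.  Mesh filenames follow the
``<id>_<sex>_<side>.ply`` convention so metadata survives without a
sidecar.  Clinical tables, scan pairs, B-scores and topology all use the
CSV dialects documented on their functions.  All writes are atomic
(temp file + rename).
"""

from __future__ import annotations

import contextlib
import csv
import glob as globlib
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .outcomes import ClinicalRecord, SCALE_RANGES
from .repeatability import ScanPair
from .shapes import CorrespondedShape, MeshTopology

__all__ = [
    "atomic_write",
    "write_shape_mesh", "read_shape_mesh",
    "write_landmark_csv", "read_landmark_csv",
    "read_shapes", "write_shapes",
    "write_topology_csv", "read_topology_csv",
    "write_clinical_csv", "read_clinical_csv",
    "write_bscores_csv", "read_bscores_csv",
    "write_pairs_csv", "read_pairs_csv",
]

_SCALE_PREFIX = {"nrs_pain": "nrs", "womac_function": "womacF",
                 "womac_pain": "womacA"}
_COVARIATE_COLUMNS = ("age", "ethnicity", "bmi", "alignment", "prior_surgery",
                      "nsaid", "smoking")


@contextlib.contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


# -- mesh formats ------------------------------------------------------

def shape_filename(shape: CorrespondedShape, ext: str = "ply") -> str:
    return f"{shape.shape_id}_{shape.sex}_{shape.side}.{ext}"


def _parse_mesh_filename(path) -> tuple[str, str, str]:
    stem = Path(path).stem
    parts = stem.split("_")
    if len(parts) < 3 or parts[-1] not in ("left", "right") \
            or parts[-2] not in ("male", "female"):
        raise ValueError(
            f"cannot parse sex/side from filename {Path(path).name!r}; "
            "expected '<id>_<sex>_<side>.<ext>'")
    return "_".join(parts[:-2]), parts[-2], parts[-1]


def write_shape_mesh(shape: CorrespondedShape, topology: MeshTopology, path) -> None:
    """Write one shape as ASCII PLY or OBJ (extension decides).

    Coordinates are written as double precision (%.17g), so a write/read
    cycle is lossless; the stock float32 PLY writers are not.
    """
    topology.validate_for(shape.n_points)
    path = Path(path)
    ext = path.suffix.lower()
    lines = []
    if ext == ".ply":
        lines += ["ply", "format ascii 1.0",
                  f"element vertex {shape.n_points}",
                  "property double x", "property double y", "property double z",
                  f"element face {topology.n_faces}",
                  "property list uchar int vertex_indices", "end_header"]
        lines += [" ".join("%.17g" % c for c in row) for row in shape.coords]
        lines += ["3 %d %d %d" % tuple(f) for f in topology.faces]
    elif ext == ".obj":
        lines += ["v %.17g %.17g %.17g" % tuple(row) for row in shape.coords]
        lines += ["f %d %d %d" % tuple(f + 1) for f in topology.faces]
    else:
        raise ValueError(f"unsupported mesh extension {path.suffix!r}")
    with atomic_write(path) as fh:
        fh.write("\n".join(lines) + "\n")


def read_shape_mesh(path, sex: str | None = None, side: str | None = None
                    ) -> tuple[CorrespondedShape, MeshTopology]:
    """Read one PLY/OBJ mesh, vertex order untouched."""
    path = Path(path)
    mesh = trimesh.load_mesh(str(path), process=False, maintain_order=True)
    if sex is None or side is None:
        shape_id, file_sex, file_side = _parse_mesh_filename(path)
        sex = sex or file_sex
        side = side or file_side
    else:
        shape_id = path.stem
    shape = CorrespondedShape(shape_id, np.asarray(mesh.vertices, dtype=float),
                              side=side, sex=sex)
    return shape, MeshTopology(np.asarray(mesh.faces, dtype=int))


# -- landmark CSV ------------------------------------------------------

def write_landmark_csv(shapes: Sequence[CorrespondedShape], path) -> None:
    """Landmark CSV: ``shape_id,vertex_index,x,y,z,sex,side``, 0-based, mm."""
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["shape_id", "vertex_index", "x", "y", "z", "sex", "side"])
        for s in shapes:
            for i, (x, y, z) in enumerate(s.coords):
                writer.writerow([s.shape_id, i, "%.17g" % x, "%.17g" % y,
                                 "%.17g" % z, s.sex, s.side])


def read_landmark_csv(path) -> list:
    """Read all shapes from a landmark CSV, preserving vertex order."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"shape_id", "vertex_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV {path} missing columns {sorted(missing)}")
    shapes = []
    for shape_id, grp in df.groupby("shape_id", sort=False):
        grp = grp.sort_values("vertex_index")
        if not np.array_equal(grp["vertex_index"].to_numpy(),
                              np.arange(len(grp))):
            raise ValueError(f"non-contiguous vertex indices for {shape_id!r}")
        sex = str(grp["sex"].iloc[0]) if "sex" in grp else "female"
        side = str(grp["side"].iloc[0]) if "side" in grp else "right"
        shapes.append(CorrespondedShape(
            str(shape_id), grp[["x", "y", "z"]].to_numpy(dtype=float),
            side=side, sex=sex))
    return shapes


def read_shapes(paths_or_glob, fmt: str | None = None) -> list:
    """Read a cohort of shapes from files or a glob pattern.

    Format is inferred from extensions unless ``fmt`` (``ply``/``obj``/
    ``landmark_csv``) is given.  Raises if vertex counts disagree, naming
    the offending files.
    """
    if isinstance(paths_or_glob, (str, Path)):
        paths = sorted(globlib.glob(str(paths_or_glob)))
        if not paths:
            paths = [str(paths_or_glob)]
    else:
        paths = [str(p) for p in paths_or_glob]
    shapes = []
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(p)
        ext = Path(p).suffix.lower()
        if fmt == "landmark_csv" or ext == ".csv":
            shapes.extend(read_landmark_csv(p))
        elif fmt in (None, "ply", "obj") and ext in (".ply", ".obj"):
            shapes.append(read_shape_mesh(p)[0])
        else:
            raise ValueError(f"unsupported shape file {p!r}")
    counts = {s.n_points for s in shapes}
    if len(counts) > 1:
        offenders = {s.shape_id: s.n_points for s in shapes}
        raise ValueError(f"inconsistent vertex counts across cohort: {offenders}")
    return shapes


def write_shapes(shapes: Sequence[CorrespondedShape], topology: MeshTopology,
                 out_dir, fmt: str = "ply") -> list:
    """Write each shape to ``out_dir`` using the filename convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in shapes:
        p = out_dir / shape_filename(s, ext=fmt)
        write_shape_mesh(s, topology, p)
        paths.append(p)
    return paths


# -- topology ----------------------------------------------------------

def write_topology_csv(topology: MeshTopology, path) -> None:
    """Face-list CSV ``v0,v1,v2`` (0-based)."""
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["v0", "v1", "v2"])
        writer.writerows(topology.faces.tolist())


def read_topology_csv(path) -> MeshTopology:
    df = pd.read_csv(path)
    return MeshTopology(df[["v0", "v1", "v2"]].to_numpy(dtype=int))


# -- clinical table ----------------------------------------------------

def write_clinical_csv(records: Sequence[ClinicalRecord], path) -> None:
    """One row per knee; score series in ``nrs_t0..``, ``womacF_t0..``,
    ``womacA_t0..`` columns; empty cell = missing."""
    n_t = max((len(r.series(s)) for r in records for s in SCALE_RANGES),
              default=0)
    header = ["knee_id", "person_id", "sex", "side", "klg", "tkr",
              *_COVARIATE_COLUMNS]
    for scale, prefix in _SCALE_PREFIX.items():
        header += [f"{prefix}_t{t}" for t in range(n_t)]
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [r.knee_id, r.person_id, r.sex, r.side, r.klg, int(r.tkr)]
            row += [r.covariates.get(c, "") for c in _COVARIATE_COLUMNS]
            for scale in _SCALE_PREFIX:
                series = r.series(scale)
                row += [("" if t >= len(series) or series[t] is None
                         else series[t]) for t in range(n_t)]
            writer.writerow(row)


def read_clinical_csv(path) -> list:
    """Read and validate the clinical table; errors carry the row number."""
    df = pd.read_csv(path)
    records = []
    for row_num, (_, row) in enumerate(df.iterrows(), start=2):
        series = {}
        for scale, prefix in _SCALE_PREFIX.items():
            cols = sorted((c for c in df.columns if c.startswith(f"{prefix}_t")),
                          key=lambda c: int(c.rsplit("t", 1)[1]))
            series[scale] = [None if pd.isna(row[c]) else float(row[c])
                             for c in cols]
        covariates = {}
        for c in _COVARIATE_COLUMNS:
            if c in df.columns and not pd.isna(row[c]):
                covariates[c] = row[c]
        try:
            records.append(ClinicalRecord(
                knee_id=str(row["knee_id"]), person_id=str(row["person_id"]),
                sex=str(row["sex"]), side=str(row["side"]),
                klg=int(row["klg"]), tkr=bool(int(row["tkr"])),
                nrs_pain=series["nrs_pain"],
                womac_function=series["womac_function"],
                womac_pain=series["womac_pain"],
                covariates=covariates))
        except ValueError as exc:
            raise ValueError(f"{path} row {row_num}: {exc}") from exc
    return records


# -- scores and pairs --------------------------------------------------

def write_bscores_csv(shapes: Sequence[CorrespondedShape],
                      bscores: Sequence[float], path) -> None:
    """B-score table: ``shape_id,sex,side,bscore``."""
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["shape_id", "sex", "side", "bscore"])
        for s, b in zip(shapes, bscores):
            writer.writerow([s.shape_id, s.sex, s.side, "%.17g" % float(b)])


def read_bscores_csv(path) -> dict:
    """Read a B-score table into a ``shape_id -> bscore`` mapping."""
    df = pd.read_csv(path, float_precision="round_trip")
    return dict(zip(df["shape_id"].astype(str), df["bscore"].astype(float)))


def write_pairs_csv(pairs: Sequence[ScanPair], path) -> None:
    """Repeat-scan pairs: ``shape_id,bscore_1,bscore_2,interval``."""
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["shape_id", "bscore_1", "bscore_2", "interval"])
        for p in pairs:
            writer.writerow([p.shape_id, "%.17g" % p.bscore_1,
                             "%.17g" % p.bscore_2, p.interval])


def read_pairs_csv(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [ScanPair(str(r.shape_id), float(r.bscore_1), float(r.bscore_2),
                     str(r.interval)) for r in df.itertuples()]
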