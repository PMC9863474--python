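"""Landmark anatomy and inter-landmark distance measurement.

The PAPVR ratio is built from two straight-line distances between three
anatomical reference points on a patient's 3D-reconstructed heart model:

* ``PV_CRANIAL_SUPERIOR_RIM`` — superior rim of the most cranial anomalous
  pulmonary vein,
* ``SVD_SUPERIOR_RIM`` — superior rim of the sinus venosus defect,
* ``AZYGOS_INFERIOR_RIM`` — inferior rim of the azygos vein.

Distances are point-to-point Euclidean distances in millimetres, computed in
a right-handed Cartesian frame. Geodesic (along-wall) distances are
deliberately not used: they would require the full vessel segmentation, which
is upstream of this package. Voxel/image-space coordinates are not accepted.

Landmarks may optionally be snapped to the nearest vertex of a triangulated
surface model (STL) before measurement; snapping is off by default and
measurements otherwise use the authored coordinates verbatim.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LandmarkName",
    "Landmark",
    "PatientAnatomy",
    "MeasurementSet",
    "SnapResult",
    "AnnotationError",
    "GeometryError",
    "MIN_SEPARATION_MM",
    "load_anatomy",
    "parse_annotation",
    "format_annotation",
    "write_anatomy",
    "snap_to_surface",
    "measure",
]

#: Two landmarks closer than this are treated as coincident (degenerate).
MIN_SEPARATION_MM = 1e-6


class LandmarkName(str, enum.Enum):
    """The three anatomical reference points of the PAPVR score."""

    PV_CRANIAL_SUPERIOR_RIM = "PV_CRANIAL_SUPERIOR_RIM"
    SVD_SUPERIOR_RIM = "SVD_SUPERIOR_RIM"
    AZYGOS_INFERIOR_RIM = "AZYGOS_INFERIOR_RIM"


class AnnotationError(ValueError):
    """Raised when a landmark annotation file violates the schema."""


class GeometryError(ValueError):
    """Raised for degenerate or invalid landmark geometry."""


def _as_position(value) -> np.ndarray:
    pos = np.asarray(value, dtype=float)
    if pos.shape != (3,):
        raise GeometryError(f"landmark position must be a 3-vector, got shape {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise GeometryError(f"landmark position must be finite, got {pos}")
    pos.setflags(write=False)
    return pos


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point, position in millimetres."""

    name: LandmarkName
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", LandmarkName(self.name))
        object.__setattr__(self, "position", _as_position(self.position))


@dataclass(frozen=True)
class PatientAnatomy:
    """Exactly one landmark per name for one patient, pairwise distinct.

    ``model_path`` optionally records the surface model the landmarks were
    annotated on; it is informational and never read implicitly.
    """

    patient_id: str
    landmarks: tuple[Landmark, ...]
    model_path: Path | None = None

    def __post_init__(self) -> None:
        lms = tuple(self.landmarks)
        object.__setattr__(self, "landmarks", lms)
        names = [lm.name for lm in lms]
        if len(names) != len(set(names)):
            raise GeometryError(f"duplicate landmark names for patient {self.patient_id!r}")
        missing = set(LandmarkName) - set(names)
        if missing:
            raise GeometryError(
                f"patient {self.patient_id!r} is missing landmark(s): "
                + ", ".join(sorted(m.value for m in missing))
            )
        for i, a in enumerate(lms):
            for b in lms[i + 1 :]:
                if float(np.linalg.norm(a.position - b.position)) <= MIN_SEPARATION_MM:
                    raise GeometryError(
                        f"landmarks {a.name.value} and {b.name.value} coincide "
                        f"for patient {self.patient_id!r}"
                    )

    def position(self, name: LandmarkName) -> np.ndarray:
        name = LandmarkName(name)
        for lm in self.landmarks:
            if lm.name is name:
                return lm.position
        raise KeyError(name)  # unreachable on a valid instance


@dataclass(frozen=True)
class MeasurementSet:
    """The two distances (mm) the PAPVR ratio is computed from.

    ``d_pv_svd``: most cranial anomalous PV to the superior rim of the sinus
    venosus defect. ``d_pv_azygos``: same PV to the inferior rim of the azygos
    vein (the normalising distance).
    """

    patient_id: str
    d_pv_svd: float
    d_pv_azygos: float

    def __post_init__(self) -> None:
        d1, d2 = float(self.d_pv_svd), float(self.d_pv_azygos)
        if not (math.isfinite(d1) and math.isfinite(d2)):
            raise GeometryError("distances must be finite")
        if d1 < 0 or d2 < 0:
            raise GeometryError("distances must be non-negative")
        if d1 + d2 <= 0:
            raise GeometryError(
                f"patient {self.patient_id!r}: both distances are zero; "
                "the PAPVR ratio is undefined"
            )
        object.__setattr__(self, "d_pv_svd", d1)
        object.__setattr__(self, "d_pv_azygos", d2)


# ---------------------------------------------------------------------------
# Landmark annotation files
#
# One strict key-value dialect. Blank lines and '#' comments are ignored.
#
#   patient_id <id>
#   landmark <NAME> <x> <y> <z>        (coordinates in mm, three lines total)
# ---------------------------------------------------------------------------


def parse_annotation(text: str, source: str = "<string>") -> PatientAnatomy:
    """Parse landmark annotation text into a :class:`PatientAnatomy`."""
    patient_id: str | None = None
    landmarks: list[Landmark] = []
    seen: set[LandmarkName] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        key = tokens[0]
        if key == "patient_id":
            if len(tokens) != 2:
                raise AnnotationError(f"{source}:{lineno}: expected 'patient_id <id>'")
            if patient_id is not None:
                raise AnnotationError(f"{source}:{lineno}: duplicate patient_id")
            patient_id = tokens[1]
        elif key == "landmark":
            if len(tokens) != 5:
                raise AnnotationError(
                    f"{source}:{lineno}: expected 'landmark <NAME> <x> <y> <z>'"
                )
            try:
                name = LandmarkName(tokens[1])
            except ValueError:
                raise AnnotationError(
                    f"{source}:{lineno}: unknown landmark name {tokens[1]!r}; "
                    f"expected one of {[n.value for n in LandmarkName]}"
                ) from None
            if name in seen:
                raise AnnotationError(
                    f"{source}:{lineno}: duplicate landmark {name.value}"
                )
            try:
                xyz = [float(t) for t in tokens[2:5]]
            except ValueError:
                raise AnnotationError(
                    f"{source}:{lineno}: non-numeric coordinate in {tokens[2:5]}"
                ) from None
            if not all(math.isfinite(v) for v in xyz):
                raise AnnotationError(f"{source}:{lineno}: non-finite coordinate")
            seen.add(name)
            landmarks.append(Landmark(name, xyz))
        else:
            raise AnnotationError(f"{source}:{lineno}: unknown key {key!r}")
    if patient_id is None:
        raise AnnotationError(f"{source}: missing patient_id record")
    missing = set(LandmarkName) - seen
    if missing:
        raise AnnotationError(
            f"{source}: missing landmark(s): "
            + ", ".join(sorted(m.value for m in missing))
        )
    try:
        return PatientAnatomy(patient_id=patient_id, landmarks=tuple(landmarks))
    except GeometryError as exc:
        raise AnnotationError(f"{source}: {exc}") from exc


def load_anatomy(path: str | Path) -> PatientAnatomy:
    """Load a landmark annotation file (see module docstring for the schema)."""
    path = Path(path)
    return parse_annotation(path.read_text(), source=str(path))


def format_annotation(anatomy: PatientAnatomy) -> str:
    """Serialise a :class:`PatientAnatomy` back to annotation text."""
    lines = [f"patient_id {anatomy.patient_id}"]
    for name in LandmarkName:
        x, y, z = (float(v) for v in anatomy.position(name))
        lines.append(f"landmark {name.value} {x!r} {y!r} {z!r}")
    return "\n".join(lines) + "\n"


def write_anatomy(anatomy: PatientAnatomy, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(format_annotation(anatomy))
    return path


# ---------------------------------------------------------------------------
# Surface snapping and measurement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnapResult:
    """Snapped anatomy plus per-landmark displacement (mm)."""

    anatomy: PatientAnatomy
    displacements: Mapping[LandmarkName, float]


def snap_to_surface(anatomy: PatientAnatomy, model) -> SnapResult:
    """Snap each landmark to the nearest vertex of a triangulated surface.

    Parameters
    ----------
    anatomy:
        The authored landmarks.
    model:
        A ``trimesh.Trimesh``, an ``(n, 3)`` vertex array, or a path to an STL
        file (millimetre units assumed).

    Returns
    -------
    SnapResult with the snapped anatomy and the Euclidean displacement each
    landmark moved. Raises :class:`GeometryError` if the mesh is empty or if
    two landmarks snap onto the same (or coincident) vertices, which indicates
    a degenerate annotation relative to the mesh resolution.
    """
    import trimesh
    from scipy.spatial import cKDTree

    if isinstance(model, (str, Path)):
        model = trimesh.load_mesh(str(model))
    if hasattr(model, "vertices"):
        vertices = np.asarray(model.vertices, dtype=float)
    else:
        vertices = np.asarray(model, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 3 or vertices.shape[0] == 0:
        raise GeometryError("surface model has no vertices")

    tree = cKDTree(vertices)
    snapped: list[Landmark] = []
    displacements: dict[LandmarkName, float] = {}
    for lm in anatomy.landmarks:
        dist, idx = tree.query(lm.position)
        snapped.append(Landmark(lm.name, vertices[idx]))
        displacements[lm.name] = float(dist)
    try:
        new_anatomy = PatientAnatomy(
            patient_id=anatomy.patient_id,
            landmarks=tuple(snapped),
            model_path=anatomy.model_path,
        )
    except GeometryError as exc:
        raise GeometryError(
            f"snapping produced coincident landmarks for patient "
            f"{anatomy.patient_id!r}: {exc}"
        ) from exc
    return SnapResult(anatomy=new_anatomy, displacements=displacements)


def measure(anatomy: PatientAnatomy) -> MeasurementSet:
    """Measure the two PAPVR-score distances (mm) from landmark geometry.

    ``d_pv_svd`` is the Euclidean distance PV ↔ SVD superior rim and
    ``d_pv_azygos`` the distance PV ↔ azygos inferior rim.
    """
    pv = anatomy.position(LandmarkName.PV_CRANIAL_SUPERIOR_RIM)
    svd = anatomy.position(LandmarkName.SVD_SUPERIOR_RIM)
    azygos = anatomy.position(LandmarkName.AZYGOS_INFERIOR_RIM)
    return MeasurementSet(
        patient_id=anatomy.patient_id,
        d_pv_svd=float(np.linalg.norm(pv - svd)),
        d_pv_azygos=float(np.linalg.norm(pv - azygos)),
    )
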