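"""Cohort collation and I/O.

The central currency of the package is the :class:`CohortSurface`: one
``N x V`` matrix holding a single scalar morphometry measure (thickness,
curvature, sulcal depth, area, gyrification) for every subject (row) at
every template vertex (column), columns ordered left hemisphere then right.
Extraction functions build it from per-subject files produced by standard
preprocessing pipelines; ``save_cohort``/``load_cohort`` round-trip it
through a single compressed portable container so analyses can run without
access to the original subject directories.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np

from .templates import TemplateRegistry, default_registry

__all__ = [
    "CohortSurface",
    "read_curv",
    "write_curv",
    "extract_freesurfer_cohort",
    "extract_hippunfold_cohort",
    "extract_fslr_cohort",
    "save_cohort",
    "load_cohort",
    "CurvFormatError",
    "CohortError",
]

logger = logging.getLogger(__name__)

CONTAINER_VERSION = "vertexstats-cohort-1"


class CurvFormatError(ValueError):
    """Malformed or unsupported FreeSurfer curv-format file."""


class CohortError(ValueError):
    """Inconsistent cohort construction (missing files, shape mismatch...)."""


@dataclass
class CohortSurface:
    """N-subjects x V-vertices morphometry matrix with metadata.

    ``left_count`` columns belong to the left hemisphere, the rest to the
    right.  ``session_ids`` is present for longitudinal cohorts stored in
    long format (one row per subject-session).
    """

    data: np.ndarray
    subject_ids: list[str]
    space_tag: str
    measure: str
    left_count: int
    session_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[0] != len(self.subject_ids):
            raise CohortError("row count does not match subject_ids")
        if self.session_ids is not None and len(self.session_ids) != self.data.shape[0]:
            raise CohortError("session_ids length does not match rows")
        if not 0 <= self.left_count <= self.data.shape[1]:
            raise CohortError("left_count out of range")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# FreeSurfer curv binary dialect

_CURV_MAGIC = b"\xff\xff\xff"


def read_curv(path: str | Path) -> np.ndarray:
    """Read a FreeSurfer "curv"-format per-vertex scalar file.

    Layout: 3 magic bytes ``FF FF FF``, then big-endian int32 vertex count,
    face count, and values-per-vertex (must be 1), then big-endian float32
    values.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 15:
        raise IOError(f"truncated curv file: {path}")
    if raw[:3] != _CURV_MAGIC:
        raise CurvFormatError(f"bad curv magic bytes in {path}")
    n_vertices, n_faces, vals_per_vertex = struct.unpack(">iii", raw[3:15])
    if vals_per_vertex != 1:
        raise CurvFormatError(
            f"unsupported curv dialect ({vals_per_vertex} values per vertex) in {path}"
        )
    expected = 15 + 4 * n_vertices
    if len(raw) < expected:
        raise IOError(
            f"truncated curv file {path}: {len(raw)} bytes, expected {expected}"
        )
    values = np.frombuffer(raw[15:expected], dtype=">f4").astype(np.float64)
    del n_faces
    return values


def write_curv(values: Sequence[float] | np.ndarray, path: str | Path) -> None:
    """Write per-vertex values in the curv dialect read by :func:`read_curv`."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("curv values must be finite")
    with open(path, "wb") as fh:
        fh.write(_CURV_MAGIC)
        fh.write(struct.pack(">iii", values.size, 0, 1))
        fh.write(values.astype(">f4").tobytes())


# ---------------------------------------------------------------------------
# extraction


def _hemi_lengths(space_tag: str, registry: TemplateRegistry) -> tuple[int, int]:
    return registry.hemi_counts(space_tag)


def extract_freesurfer_cohort(
    subjects_dir: str | Path,
    measure: str,
    space_tag: str,
    subject_list: Sequence[str] | None = None,
    registry: TemplateRegistry | None = None,
) -> CohortSurface:
    """Collate per-subject FreeSurfer morphometry into a cohort matrix.

    Expects ``<subjects_dir>/<subject>/surf/{lh,rh}.<measure>`` curv files
    already resampled to the target template.  Subjects are enumerated in
    lexicographic directory order unless ``subject_list`` fixes the order;
    directory entries lacking both hemisphere files are ignored (FreeSurfer
    subject directories contain non-subject entries such as ``fsaverage``).
    """
    registry = registry or default_registry
    subjects_dir = Path(subjects_dir)
    lc, rc = _hemi_lengths(space_tag, registry)

    if subject_list is None:
        candidates = sorted(p.name for p in subjects_dir.iterdir() if p.is_dir())
        subjects = [
            s
            for s in candidates
            if (subjects_dir / s / "surf" / f"lh.{measure}").exists()
            or (subjects_dir / s / "surf" / f"rh.{measure}").exists()
        ]
    else:
        subjects = list(subject_list)
    if not subjects:
        raise CohortError(f"no subjects with {measure} files under {subjects_dir}")

    rows = np.empty((len(subjects), lc + rc), dtype=np.float64)
    for i, subj in enumerate(subjects):
        for hemi, prefix, expected, sl in (
            ("lh", "left", lc, slice(0, lc)),
            ("rh", "right", rc, slice(lc, lc + rc)),
        ):
            fpath = subjects_dir / subj / "surf" / f"{hemi}.{measure}"
            if not fpath.exists():
                raise CohortError(
                    f"subject {subj!r}: missing {prefix}-hemisphere file {fpath}"
                )
            vals = read_curv(fpath)
            if vals.size != expected:
                raise CohortError(
                    f"subject {subj!r}: {hemi}.{measure} has {vals.size} vertices, "
                    f"expected {expected} for {space_tag}"
                )
            rows[i, sl] = vals
    return CohortSurface(rows, subjects, space_tag, measure, lc)


def _gifti_shape_values(path: Path) -> np.ndarray:
    import nibabel as nib
    from nibabel.nifti1 import intent_codes

    img = nib.load(str(path))
    if not img.darrays:
        raise CurvFormatError(f"GIFTI file {path} has no data arrays")
    da = img.darrays[0]
    if da.intent != intent_codes["NIFTI_INTENT_SHAPE"]:
        raise CurvFormatError(
            f"GIFTI file {path} is not a shape file (intent {da.intent})"
        )
    return np.asarray(da.data, dtype=np.float64)


def extract_hippunfold_cohort(
    subjects_dir: str | Path,
    measure: str,
    space_tag: str = "CIT168",
    registry: TemplateRegistry | None = None,
) -> CohortSurface:
    """Collate HippUnfold hippocampal GIFTI shape files, session-aware.

    Expects ``sub-*/[ses-*/]surf/*hemi-{L,R}*_{measure}.shape.gii``; one
    output row per subject-session (long format), columns left then right
    hippocampus.  A subject-session missing either hemisphere is skipped
    with a warning.
    """
    registry = registry or default_registry
    subjects_dir = Path(subjects_dir)
    lc, rc = _hemi_lengths(space_tag, registry)

    rows: list[np.ndarray] = []
    subj_ids: list[str] = []
    sess_ids: list[str] = []
    any_sessions = False

    for subj_dir in sorted(subjects_dir.glob("sub-*")):
        if not subj_dir.is_dir():
            continue
        ses_dirs = sorted(d for d in subj_dir.glob("ses-*") if d.is_dir())
        units = [(d, d.name) for d in ses_dirs] if ses_dirs else [(subj_dir, "")]
        any_sessions = any_sessions or bool(ses_dirs)
        for unit_dir, ses in units:
            hemi_vals = {}
            for hemi, expected in (("L", lc), ("R", rc)):
                matches = sorted(
                    (unit_dir / "surf").glob(f"*hemi-{hemi}*{measure}.shape.gii")
                )
                if not matches:
                    break
                vals = _gifti_shape_values(matches[0])
                if vals.size != expected:
                    raise CohortError(
                        f"{matches[0]}: {vals.size} vertices, expected {expected}"
                    )
                hemi_vals[hemi] = vals
            if len(hemi_vals) < 2:
                logger.warning(
                    "skipping %s %s: missing hemisphere %s file",
                    subj_dir.name, ses or "(no session)", measure,
                )
                continue
            rows.append(np.concatenate([hemi_vals["L"], hemi_vals["R"]]))
            subj_ids.append(subj_dir.name)
            sess_ids.append(ses)
    if not rows:
        raise CohortError(f"no usable subjects under {subjects_dir}")
    return CohortSurface(
        np.vstack(rows),
        subj_ids,
        space_tag,
        measure,
        lc,
        session_ids=sess_ids if any_sessions else None,
    )


def _default_cifti_reader(path: Path) -> np.ndarray:
    """Read a dense scalar file with nibabel and return the data row."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).ravel()


def extract_fslr_cohort(
    derivatives_dir: str | Path,
    measure: str,
    space_tag: str = "fsLR32k",
    reader: Callable[[Path], np.ndarray] | None = None,
    pattern: str | None = None,
    registry: TemplateRegistry | None = None,
) -> CohortSurface:
    """Collate fsLR32k dense scalar files (one file per subject, both hemispheres).

    Reading of the dense file format itself is delegated to ``reader``
    (default: nibabel); this function owns only the collation contract:
    lexicographic subject order, 64,984 columns left-then-right.
    """
    registry = registry or default_registry
    derivatives_dir = Path(derivatives_dir)
    lc, rc = _hemi_lengths(space_tag, registry)
    reader = reader or _default_cifti_reader
    pattern = pattern or f"*{measure}*.dscalar.nii"

    files = sorted(derivatives_dir.glob(pattern))
    if not files:
        raise CohortError(f"no {pattern} files under {derivatives_dir}")
    rows = np.empty((len(files), lc + rc), dtype=np.float64)
    ids = []
    for i, f in enumerate(files):
        try:
            vals = np.asarray(reader(f), dtype=np.float64).ravel()
        except Exception as exc:  # propagate with file name
            raise CohortError(f"reader failed on {f}: {exc}") from exc
        if vals.size != lc + rc:
            raise CohortError(
                f"{f}: {vals.size} vertices, expected {lc + rc} for {space_tag}"
            )
        rows[i] = vals
        ids.append(f.name.split("_")[0])
    return CohortSurface(rows, ids, space_tag, measure, lc)


# ---------------------------------------------------------------------------
# portable container

def save_cohort(c: CohortSurface, path: str | Path) -> None:
    """Write the cohort to a single compressed HDF5 container.

    The matrix is stored as float32 with gzip + byte-shuffle, which
    compresses spatially smooth morphometry well below raw size.
    """
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = CONTAINER_VERSION
        fh.attrs["space_tag"] = c.space_tag
        fh.attrs["measure"] = c.measure
        fh.attrs["left_count"] = c.left_count
        fh.create_dataset(
            "data",
            data=c.data.astype(np.float32),
            compression="gzip",
            compression_opts=6,
            shuffle=True,
            chunks=(min(c.n_subjects, 16), min(c.n_vertices, 8192)),
        )
        str_dt = h5py.string_dtype(encoding="utf-8")
        fh.create_dataset("subject_ids", data=np.array(c.subject_ids, dtype=object), dtype=str_dt)
        if c.session_ids is not None:
            fh.create_dataset(
                "session_ids", data=np.array(c.session_ids, dtype=object), dtype=str_dt
            )


def load_cohort(path: str | Path) -> CohortSurface:
    """Load a container written by :func:`save_cohort`."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"cannot open cohort container {path}: {exc}") from exc
    with fh:
        version = fh.attrs.get("format_version")
        if version != CONTAINER_VERSION:
            raise CohortError(
                f"incompatible container version {version!r} (expected {CONTAINER_VERSION!r})"
            )
        data = fh["data"][()].astype(np.float64)
        subject_ids = [s.decode() if isinstance(s, bytes) else s for s in fh["subject_ids"][()]]
        session_ids = None
        if "session_ids" in fh:
            session_ids = [
                s.decode() if isinstance(s, bytes) else s for s in fh["session_ids"][()]
            ]
        return CohortSurface(
            data,
            subject_ids,
            str(fh.attrs["space_tag"]),
            str(fh.attrs["measure"]),
            int(fh.attrs["left_count"]),
            session_ids=session_ids,
        )
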