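import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertexstats.cohort import (
    CohortError,
    CohortSurface,
    CurvFormatError,
    extract_freesurfer_cohort,
    extract_fslr_cohort,
    extract_hippunfold_cohort,
    load_cohort,
    read_curv,
    save_cohort,
    write_curv,
)
from vertexstats.templates import TemplateRegistry, hemisphere_pair, make_grid_mesh

# ---------------------------------------------------------------------------
# curv dialect


@given(
    st.lists(
        st.floats(-1e6, 1e6, allow_nan=False, width=32), min_size=0, max_size=200
    )
)
@settings(max_examples=50, deadline=None)
def test_curv_roundtrip_is_identity_at_float32(tmp_path_factory, values):
    path = tmp_path_factory.mktemp("curv") / "lh.thickness"
    write_curv(values, path)
    out = read_curv(path)
    np.testing.assert_array_equal(out, np.asarray(values, dtype=np.float32).astype(float))


def test_curv_roundtrip_large_random(tmp_path):
    rng = np.random.default_rng(0)
    values = rng.normal(size=100_000).astype(np.float32).astype(float)
    write_curv(values, tmp_path / "f")
    np.testing.assert_array_equal(read_curv(tmp_path / "f"), values)


def test_curv_matches_independent_reader(tmp_path):
    # nibabel's freesurfer morphometry reader as the independent oracle
    import nibabel as nib

    values = np.array([0.5, -1.25, 3.0])
    write_curv(values, tmp_path / "lh.curv")
    oracle = nib.freesurfer.read_morph_data(str(tmp_path / "lh.curv"))
    np.testing.assert_array_equal(oracle.astype(float), values)


def test_curv_reads_independent_writer(tmp_path):
    import nibabel as nib

    values = np.linspace(-2, 2, 33).astype(np.float32)
    nib.freesurfer.write_morph_data(str(tmp_path / "rh.sulc"), values)
    np.testing.assert_array_equal(read_curv(tmp_path / "rh.sulc"), values.astype(float))


def test_curv_error_taxonomy(tmp_path):
    bad_magic = tmp_path / "bad"
    bad_magic.write_bytes(b"\x00\x00\x00" + b"\x00" * 20)
    with pytest.raises(CurvFormatError):
        read_curv(bad_magic)

    write_curv([1.0, 2.0, 3.0], tmp_path / "ok")
    raw = (tmp_path / "ok").read_bytes()
    (tmp_path / "trunc").write_bytes(raw[:-4])
    with pytest.raises(IOError):
        read_curv(tmp_path / "trunc")

    # values-per-vertex != 1
    import struct

    weird = b"\xff\xff\xff" + struct.pack(">iii", 1, 0, 3) + b"\x00" * 12
    (tmp_path / "weird").write_bytes(weird)
    with pytest.raises(CurvFormatError):
        read_curv(tmp_path / "weird")

    with pytest.raises(ValueError):
        write_curv([np.nan], tmp_path / "nan")


def test_write_curv_empty_vector(tmp_path):
    write_curv([], tmp_path / "empty")
    assert read_curv(tmp_path / "empty").size == 0


# ---------------------------------------------------------------------------
# FreeSurfer extraction


def _make_subject(subjects_dir, name, lh, rh, measure="thickness"):
    d = subjects_dir / name / "surf"
    d.mkdir(parents=True)
    if lh is not None:
        write_curv(lh, d / f"lh.{measure}")
    if rh is not None:
        write_curv(rh, d / f"rh.{measure}")


@pytest.fixture()
def fs_dir(tmp_path):
    rng = np.random.default_rng(7)
    per_hemi = 42  # synthetic-ico1
    vals = {}
    for name in ("sub-b", "sub-a", "sub-c"):
        lh, rh = rng.normal(size=per_hemi), rng.normal(size=per_hemi)
        _make_subject(tmp_path, name, lh, rh)
        vals[name] = np.r_[lh, rh].astype(np.float32).astype(float)
    (tmp_path / "fsaverage").mkdir()  # non-subject entry must be ignored
    return tmp_path, vals


def test_freesurfer_collation_order_and_values(fs_dir):
    subjects_dir, vals = fs_dir
    c = extract_freesurfer_cohort(subjects_dir, "thickness", "synthetic-ico1")
    assert c.subject_ids == ["sub-a", "sub-b", "sub-c"]  # lexicographic
    assert c.data.shape == (3, 84)
    assert c.left_count == 42
    for i, s in enumerate(c.subject_ids):
        np.testing.assert_array_equal(c.data[i], vals[s])


def test_freesurfer_subject_list_reorders_rows(fs_dir):
    subjects_dir, vals = fs_dir
    order = ["sub-c", "sub-a"]
    c = extract_freesurfer_cohort(
        subjects_dir, "thickness", "synthetic-ico1", subject_list=order
    )
    assert c.subject_ids == order
    np.testing.assert_array_equal(c.data[0], vals["sub-c"])


def test_freesurfer_missing_hemisphere_names_subject(tmp_path):
    _make_subject(tmp_path, "sub-x", np.zeros(42), None)
    with pytest.raises(CohortError, match="sub-x"):
        extract_freesurfer_cohort(tmp_path, "thickness", "synthetic-ico1")


def test_freesurfer_wrong_length_is_shape_error(tmp_path):
    _make_subject(tmp_path, "sub-y", np.zeros(10), np.zeros(42))
    with pytest.raises(CohortError, match="expected 42"):
        extract_freesurfer_cohort(tmp_path, "thickness", "synthetic-ico1")


# ---------------------------------------------------------------------------
# HippUnfold extraction (GIFTI)


def _write_shape_gii(path, values, intent="NIFTI_INTENT_SHAPE"):
    import nibabel as nib

    da = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent=intent
    )
    nib.gifti.GiftiImage(darrays=[da]).to_filename(str(path))


@pytest.fixture()
def hipp_registry():
    reg = TemplateRegistry()
    left = make_grid_mesh(4, 5, hemisphere="left")
    right = make_grid_mesh(4, 5, hemisphere="right")
    reg.register("synthetic-hipp", left, right)
    return reg


def test_hippunfold_sessions_long_format(tmp_path, hipp_registry):
    rng = np.random.default_rng(3)
    for s in ("sub-01", "sub-02"):
        for ses in ("ses-1", "ses-2", "ses-3"):
            d = tmp_path / s / ses / "surf"
            d.mkdir(parents=True)
            for hemi in "LR":
                _write_shape_gii(
                    d / f"{s}_{ses}_hemi-{hemi}_thickness.shape.gii",
                    rng.normal(size=20),
                )
    c = extract_hippunfold_cohort(
        tmp_path, "thickness", space_tag="synthetic-hipp", registry=hipp_registry
    )
    assert c.data.shape == (6, 40)
    assert c.session_ids == ["ses-1", "ses-2", "ses-3"] * 2
    assert c.subject_ids == ["sub-01"] * 3 + ["sub-02"] * 3


def test_hippunfold_missing_session_skipped_with_warning(tmp_path, hipp_registry, caplog):
    for s, sessions in (("sub-01", ["ses-1", "ses-2"]), ("sub-02", ["ses-1"])):
        for ses in sessions:
            d = tmp_path / s / ses / "surf"
            d.mkdir(parents=True)
            for hemi in "LR":
                _write_shape_gii(d / f"hemi-{hemi}_thickness.shape.gii", np.ones(20))
    # sub-02 ses-2 absent entirely; also drop one hemisphere of sub-01 ses-2
    (tmp_path / "sub-01" / "ses-2" / "surf" / "hemi-R_thickness.shape.gii").unlink()
    import logging

    with caplog.at_level(logging.WARNING, logger="vertexstats.cohort"):
        c = extract_hippunfold_cohort(
            tmp_path, "thickness", space_tag="synthetic-hipp", registry=hipp_registry
        )
    assert c.data.shape == (2, 40)
    assert "sub-01" in caplog.text


def test_hippunfold_non_shape_intent_rejected(tmp_path, hipp_registry):
    d = tmp_path / "sub-01" / "ses-1" / "surf"
    d.mkdir(parents=True)
    for hemi in "LR":
        _write_shape_gii(
            d / f"hemi-{hemi}_thickness.shape.gii", np.ones(20),
            intent="NIFTI_INTENT_TIME_SERIES",
        )
    with pytest.raises(CurvFormatError, match="shape"):
        extract_hippunfold_cohort(
            tmp_path, "thickness", space_tag="synthetic-hipp", registry=hipp_registry
        )


# ---------------------------------------------------------------------------
# fsLR collation (delegated reader)


def test_fslr_collation_with_stub_reader(tmp_path):
    reg = TemplateRegistry()
    left, right = hemisphere_pair(1)
    reg.register("tiny-dense", left, right)
    known = {}
    rng = np.random.default_rng(1)
    for name in ("subA_thickness.dscalar.nii", "subB_thickness.dscalar.nii"):
        (tmp_path / name).write_bytes(b"stub")
        known[name] = rng.normal(size=84)

    c = extract_fslr_cohort(
        tmp_path, "thickness", space_tag="tiny-dense",
        reader=lambda p: known[p.name], registry=reg,
    )
    assert c.subject_ids == ["subA", "subB"]
    np.testing.assert_array_equal(c.data[0], known["subA_thickness.dscalar.nii"])


def test_fslr_mismatch_and_empty_errors(tmp_path):
    reg = TemplateRegistry()
    left, right = hemisphere_pair(1)
    reg.register("tiny-dense", left, right)
    with pytest.raises(CohortError):
        extract_fslr_cohort(tmp_path, "thickness", space_tag="tiny-dense", registry=reg)
    (tmp_path / "s_thickness.dscalar.nii").write_bytes(b"stub")
    with pytest.raises(CohortError, match="expected 84"):
        extract_fslr_cohort(
            tmp_path, "thickness", space_tag="tiny-dense",
            reader=lambda p: np.zeros(10), registry=reg,
        )


# ---------------------------------------------------------------------------
# container round trip


def test_container_roundtrip_identity(tmp_path, rng):
    data = rng.normal(size=(10, 84)).astype(np.float32).astype(float)
    c = CohortSurface(
        data, [f"s{i}" for i in range(10)], "synthetic-ico1", "thickness", 42,
        session_ids=["ses-1"] * 10,
    )
    save_cohort(c, tmp_path / "c.h5")
    back = load_cohort(tmp_path / "c.h5")
    np.testing.assert_array_equal(back.data, c.data)
    assert back.subject_ids == c.subject_ids
    assert back.session_ids == c.session_ids
    assert (back.space_tag, back.measure, back.left_count) == (
        "synthetic-ico1", "thickness", 42,
    )


def test_container_compresses_smooth_data(tmp_path):
    from vertexstats.ops import smooth_surface

    rng = np.random.default_rng(0)
    pair = hemisphere_pair(3)
    left, right = pair
    v = left.n_vertices + right.n_vertices
    c = CohortSurface(
        rng.normal(2.5, 0.3, size=(40, v)), [f"s{i}" for i in range(40)],
        "synthetic-ico3", "thickness", left.n_vertices,
    )
    smooth = smooth_surface(c, pair, fwhm=45.0)
    save_cohort(smooth, tmp_path / "c.h5")
    raw_bytes = smooth.data.astype(np.float32).nbytes
    assert (tmp_path / "c.h5").stat().st_size < 0.9 * raw_bytes


def test_container_version_mismatch(tmp_path):
    import h5py

    c = CohortSurface(np.zeros((2, 4)), ["a", "b"], "x", "m", 2)
    save_cohort(c, tmp_path / "c.h5")
    with h5py.File(tmp_path / "c.h5", "a") as fh:
        fh.attrs["format_version"] = "someone-elses-format"
    with pytest.raises(CohortError, match="version"):
        load_cohort(tmp_path / "c.h5")


def test_container_truncated_file(tmp_path):
    c = CohortSurface(np.zeros((2, 4)), ["a", "b"], "x", "m", 2)
    save_cohort(c, tmp_path / "c.h5")
    raw = (tmp_path / "c.h5").read_bytes()
    (tmp_path / "bad.h5").write_bytes(raw[: len(raw) // 4])
    with pytest.raises((IOError, CohortError)):
        load_cohort(tmp_path / "bad.h5")
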