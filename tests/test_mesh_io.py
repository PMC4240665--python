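"""Mesh reading, validation and vertex-spacing behaviour."""

import numpy as np
import pytest

from percmorph.mesh_io import (
    EmptyMeshError,
    SurfaceMesh,
    median_vertex_spacing,
    read_manifest,
    read_mesh,
    write_mesh,
)

SQUARE_VERTS = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.5], [0.0, 1.0, 0.5]]
)
SQUARE_FACES = np.array([[0, 1, 2], [0, 2, 3]])


def write_square_ply(path, extra_face=None):
    faces = list(SQUARE_FACES)
    if extra_face is not None:
        faces.append(extra_face)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(SQUARE_VERTS)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [" ".join(f"{c:.6f}" for c in v) for v in SQUARE_VERTS]
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_square_obj(path):
    lines = [f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}" for v in SQUARE_VERTS]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in SQUARE_FACES]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_square_stl(path):
    lines = ["solid patch"]
    for f in SQUARE_FACES:
        a, b, c = (SQUARE_VERTS[i] for i in f)
        lines.append("facet normal 0 0 1")
        lines.append("  outer loop")
        for v in (a, b, c):
            lines.append(f"    vertex {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
        lines.append("  endloop")
        lines.append("endfacet")
    lines.append("endsolid patch")
    path.write_text("\n".join(lines) + "\n")
    return path


def test_ply_round_trip(tmp_path):
    mesh = read_mesh(write_square_ply(tmp_path / "sq.ply"))
    assert mesh.n_vertices == 4 and mesh.n_faces == 2
    np.testing.assert_allclose(mesh.vertices, SQUARE_VERTS, atol=1e-6)


def test_format_equivalence(tmp_path):
    """The same patch written as PLY, OBJ and STL reads back with
    identical coordinates (STL duplicates vertices per facet)."""
    ply = read_mesh(write_square_ply(tmp_path / "sq.ply"))
    obj = read_mesh(write_square_obj(tmp_path / "sq.obj"))
    stl = read_mesh(write_square_stl(tmp_path / "sq.stl"))
    np.testing.assert_allclose(ply.vertices, obj.vertices, atol=1e-6)
    np.testing.assert_allclose(obj.faces, ply.faces)
    # STL: compare the set of face-corner coordinates
    def corners(m):
        return np.sort(m.vertices[m.faces].reshape(-1, 3), axis=0)

    np.testing.assert_allclose(corners(stl), corners(ply), atol=1e-6)


def test_degenerate_face_dropped(tmp_path, caplog):
    path = write_square_ply(tmp_path / "bad.ply", extra_face=[0, 1, 1])
    with caplog.at_level("INFO", logger="percmorph.mesh_io"):
        mesh = read_mesh(path)
    assert mesh.n_faces == 2
    assert "1 degenerate" in caplog.text


def test_zero_area_face_dropped(tmp_path):
    # collinear triangle (0,0)-(1,0)-(0.5,0): zero area
    path = tmp_path / "z.obj"
    path.write_text(
        "v 0 0 0\nv 1 0 0\nv 0.5 0 0\nv 0 1 0\nf 1 2 3\nf 1 2 4\n"
    )
    mesh = read_mesh(path)
    assert mesh.n_faces == 1


def test_all_faces_degenerate_raises(tmp_path):
    path = tmp_path / "e.obj"
    path.write_text("v 0 0 0\nv 1 0 0\nv 2 0 0\nf 1 2 3\n")
    with pytest.raises(EmptyMeshError):
        read_mesh(path)


def test_missing_file_raises():
    with pytest.raises(IOError):
        read_mesh("/nonexistent/mesh.ply")


def test_median_vertex_spacing_unit_square():
    """Unit square split into 2 triangles: unique edges 1,1,1,1,sqrt(2),
    median 1.0."""
    mesh = SurfaceMesh(vertices=SQUARE_VERTS * [1, 1, 0], faces=SQUARE_FACES)
    assert median_vertex_spacing(mesh) == pytest.approx(1.0)


def test_median_vertex_spacing_scale_and_rigid_invariance(rng):
    mesh = SurfaceMesh(vertices=SQUARE_VERTS, faces=SQUARE_FACES)
    s0 = median_vertex_spacing(mesh)
    scaled = SurfaceMesh(vertices=2 * SQUARE_VERTS, faces=SQUARE_FACES)
    assert median_vertex_spacing(scaled) == pytest.approx(2 * s0)
    theta = 0.7
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    moved = SurfaceMesh(
        vertices=SQUARE_VERTS @ rot.T + [5.0, -2.0, 3.0], faces=SQUARE_FACES
    )
    assert median_vertex_spacing(moved) == pytest.approx(s0, rel=1e-12)


def test_regular_grid_spacing():
    pitch = 0.4
    xs, ys = np.meshgrid(np.arange(5) * pitch, np.arange(5) * pitch)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])
    idx = np.arange(25).reshape(5, 5)
    faces = []
    for i in range(4):
        for j in range(4):
            faces.append([idx[i, j], idx[i, j + 1], idx[i + 1, j]])
            faces.append([idx[i, j + 1], idx[i + 1, j + 1], idx[i + 1, j]])
    mesh = SurfaceMesh(vertices=verts, faces=np.array(faces))
    assert median_vertex_spacing(mesh) == pytest.approx(pitch)


def test_write_read_preserves_geometry(tmp_path):
    mesh = SurfaceMesh(vertices=SQUARE_VERTS, faces=SQUARE_FACES)
    path = write_mesh(mesh, tmp_path / "out.ply")
    back = read_mesh(path)
    np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
    np.testing.assert_array_equal(back.faces, mesh.faces)


def test_invalid_meshes_rejected():
    with pytest.raises(ValueError):
        SurfaceMesh(vertices=SQUARE_VERTS, faces=np.array([[0, 1, 9]]))
    with pytest.raises(ValueError):
        SurfaceMesh(
            vertices=np.array([[0, 0, np.nan], [1, 0, 0], [0, 1, 0]]),
            faces=np.array([[0, 1, 2]]),
        )


def test_read_manifest(tmp_path):
    mf = tmp_path / "manifest.csv"
    mf.write_text(
        "specimen_id,path,group_label\n"
        "a,scans/a.ply,experimental\n"
        "b,/abs/b.ply,natural\n"
    )
    df = read_manifest(mf)
    assert list(df["specimen_id"]) == ["a", "b"]
    assert df["path"][0].endswith("scans/a.ply")
    assert df["path"][1] == "/abs/b.ply"
    bad = tmp_path / "bad.csv"
    bad.write_text("specimen_id,file\nx,y\n")
    with pytest.raises(ValueError):
        read_manifest(bad)
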