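import numpy as np
import pytest

from cardiomech import geometry
from cardiomech.fem import StrainProfile
from cardiomech.geometry import MeshError


def test_rectangle_outline_area():
    poly = geometry.build_synthetic_outline(100.0, 20.0, corner_rounding=0.0)
    assert geometry.polygon_area(poly) == pytest.approx(2000.0)


def test_rounded_outline_area_oracle():
    # stadium-like outline: rectangle minus 4 corner squares plus 4 quarter
    # circles of radius r = rounding * width
    L, W, c = 100.0, 20.0, 0.4
    r = c * W
    expected = L * W - (4.0 - np.pi) * r ** 2
    poly = geometry.build_synthetic_outline(L, W, c)
    assert geometry.polygon_area(poly) == pytest.approx(expected, rel=2e-3)


def test_outline_validation_errors():
    with pytest.raises(ValueError):
        geometry.build_synthetic_outline(10.0, 20.0)   # width > length
    with pytest.raises(ValueError):
        geometry.build_synthetic_outline(100.0, 20.0, corner_rounding=0.7)


def test_mesh_outline_basic_invariants():
    poly = geometry.build_synthetic_outline(60.0, 20.0, 0.4)
    mesh = geometry.mesh_outline(poly, 3.0)
    mesh.validate()
    areas = mesh.element_areas()
    assert np.all(areas > 0)
    assert np.sum(areas) == pytest.approx(geometry.polygon_area(poly), rel=0.02)
    # nodes span the bounding box
    assert mesh.nodes[:, 0].min() == pytest.approx(0.0, abs=1e-9)
    assert mesh.nodes[:, 0].max() == pytest.approx(60.0, abs=1e-9)


def test_mesh_refinement_increases_elements():
    poly = geometry.build_synthetic_outline(60.0, 20.0, 0.4)
    coarse = geometry.mesh_outline(poly, 5.0)
    fine = geometry.mesh_outline(poly, 2.5)
    assert fine.n_elements > 2.5 * coarse.n_elements


def test_rotated_mesh_preserves_areas_and_fibers(small_mesh):
    rot = small_mesh.rotated(0.7)
    assert np.allclose(rot.element_areas(), small_mesh.element_areas())
    assert np.allclose(np.linalg.norm(rot.fiber_direction, axis=1), 1.0)
    rot.validate()


def test_default_anchor_band(small_mesh):
    anchor = geometry.default_anchor(small_mesh, band_width=3.0)
    x = small_mesh.nodes[anchor] @ small_mesh.long_axis
    mid = 0.5 * (small_mesh.nodes[:, 0].min() + small_mesh.nodes[:, 0].max())
    assert len(anchor) > 0
    assert np.all(np.abs(x - mid) <= 1.5 + 1e-9)


def test_select_anchor_from_profile(small_mesh):
    pos = np.linspace(0.0, 60.0, 61)
    strain = -0.05 * np.ones(61)
    strain[25:36] = 0.001          # non-shortening band = adhesion site
    prof = StrainProfile(pos, strain)
    anchor = geometry.select_anchor(small_mesh, strain_profile=prof)
    x = small_mesh.nodes[anchor, 0]
    assert np.all((x >= 25.0 - 1e-9) & (x <= 35.0 + 1e-9))


def test_select_anchor_errors(small_mesh):
    prof = StrainProfile(np.linspace(0, 60, 10), -0.05 * np.ones(10))
    with pytest.raises(ValueError):
        geometry.select_anchor(small_mesh, strain_profile=prof)
    with pytest.raises(ValueError):
        geometry.select_anchor(small_mesh)


def test_linescan_helpers(small_mesh):
    ls = geometry.linescan_from_spacing(small_mesh, 0.28)
    assert np.allclose(np.diff(ls), 0.28)
    assert ls[0] == pytest.approx(small_mesh.nodes[:, 0].min())
    with pytest.raises(ValueError):
        geometry.sample_linescan(small_mesh, 1)


def test_msh_roundtrip(tmp_path, small_mesh):
    path = tmp_path / "cell.msh"
    geometry.write_mesh(small_mesh, path)
    back = geometry.read_mesh(path)
    assert np.allclose(back.nodes, small_mesh.nodes)
    assert np.array_equal(np.sort(back.triangles, axis=1),
                          np.sort(small_mesh.triangles, axis=1))
    back.validate()


def test_msh_rejects_non_triangles(tmp_path):
    text = ("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n4\n1 0 0 0\n2 1 0 0\n3 1 1 0\n4 0 1 0\n$EndNodes\n"
            "$Elements\n1\n1 3 2 0 1 1 2 3 4\n$EndElements\n")
    path = tmp_path / "quad.msh"
    path.write_text(text)
    with pytest.raises(MeshError, match="quadrangle"):
        geometry.read_mesh(path)


def test_msh_rejects_bad_version(tmp_path):
    path = tmp_path / "new.msh"
    path.write_text("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    with pytest.raises(MeshError, match="version"):
        geometry.read_mesh(path)


def test_vtk_export(tmp_path, small_mesh):
    path = tmp_path / "cell.vtk"
    geometry.write_vtk(small_mesh, path,
                       point_data={"ux": np.zeros(small_mesh.n_nodes)},
                       cell_data={"E": np.ones(small_mesh.n_elements)})
    text = path.read_text()
    assert "UNSTRUCTURED_GRID" in text
    assert f"POINTS {small_mesh.n_nodes} double" in text
    assert "SCALARS E double 1" in text
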