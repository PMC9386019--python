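import ast
import re

import numpy as np
import pytest

from wingmorph import segmentation
from wingmorph.corrugation import CorrugationParams, extract_sections, loft_surface
from wingmorph.errors import AssemblyError
from wingmorph.export import (MaterialConfig, build_model, make_sections,
                              model_from_json, model_mesh,
                              write_neutral_geometry, write_solver_script)
from wingmorph.morphometrics import pixels_to_cartesian, polygon_area
from wingmorph.simplify import rdp_simplify


@pytest.fixture(scope="module")
def boundaries10(seg10):
    return {r.id: rdp_simplify(r.boundary_chain, 1.0, closed=True,
                               source_id=r.id)
            for r in seg10.regions}


@pytest.fixture(scope="module")
def planar_model(seg10, boundaries10):
    return build_model(seg10, boundaries10, "two_section")


@pytest.fixture(scope="module")
def shell_model(seg10, boundaries10, wing10):
    sec_img = np.full(wing10.image.shape, 128, dtype=np.uint8)
    field = extract_sections(
        sec_img, CorrugationParams(n_sections=5, peak_height=6.0))
    surface = loft_surface(field, boundaries10[seg10.main.id].vertices,
                           image_height=wing10.image.shape[0])
    return build_model(seg10, boundaries10, "two_section", surface=surface)


class TestBuildModel:
    def test_two_section_grouping(self, planar_model, seg10):
        assert planar_model.sections.names == ["veins", "membranes"]
        assert len(planar_model.cells) == len(seg10.subdomains)
        assigned = set(planar_model.sections.mapping.values())
        assert assigned == {"veins", "membranes"}

    def test_multi_section_one_per_cell_plus_veins(self, seg10, boundaries10):
        model = build_model(seg10, boundaries10, "multi_section")
        assert len(model.sections.names) == len(seg10.subdomains) + 1

    def test_hole_cut_from_model(self, damaged_wing):
        dmg, hole_seed = damaged_wing
        res = segmentation.segment(dmg.image, hole_seeds=[hole_seed])
        boundaries = {r.id: rdp_simplify(r.boundary_chain, 1.0, closed=True)
                      for r in res.regions}
        model = build_model(res, boundaries, "two_section")
        assert len(model.holes) == 1
        assert len(model.cells) == len(res.subdomains)

    def test_missing_boundary_names_region(self, seg10, boundaries10):
        incomplete = dict(boundaries10)
        missing = seg10.subdomains[0].id
        del incomplete[missing]
        with pytest.raises(AssemblyError, match=str(missing)):
            build_model(seg10, incomplete, "two_section")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            make_sections("six_section", [1, 2])


class TestSolverScript:
    def test_planar_script_is_valid_python(self, planar_model):
        text = write_solver_script(planar_model)
        ast.parse(text)

    def test_two_section_script_has_exactly_two_assignments(self, planar_model):
        text = write_solver_script(planar_model)
        assert text.count("part.SectionAssignment(") == 2

    def test_multi_section_script_assignment_count(self, seg10, boundaries10):
        model = build_model(seg10, boundaries10, "multi_section")
        text = write_solver_script(model)
        assert text.count("part.SectionAssignment(") == len(seg10.subdomains) + 1

    def test_every_cell_partitioned_exactly_once(self, planar_model):
        text = write_solver_script(planar_model)
        for cid in planar_model.cells:
            starts = re.findall(rf"^cell_{cid} = \(", text, flags=re.M)
            assert len(starts) == 1

    def test_shell_script_loft_sections_and_single_path(self, shell_model):
        text = write_solver_script(shell_model)
        ast.parse(text)
        defs = re.findall(r"^loft_section_\d+ = ", text, flags=re.M)
        assert len(defs) == 5
        assert len(re.findall(r"^loft_path = ", text, flags=re.M)) == 1
        assert text.count("part.ShellLoft(") == 1

    def test_material_constants_written(self, planar_model):
        cfg = MaterialConfig()
        text = write_solver_script(planar_model, cfg)
        assert "1.500000e+08" in text
        assert "2.100000e+12" in text
        assert "0.003" in text

    def test_byte_deterministic(self, planar_model, tmp_path):
        p1, p2 = tmp_path / "a.py", tmp_path / "b.py"
        write_solver_script(planar_model, path=p1)
        write_solver_script(planar_model, path=p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestNeutralGeometry:
    def test_planar_obj_has_zero_z(self, planar_model, tmp_path):
        p = tmp_path / "m.obj"
        write_neutral_geometry(planar_model, p, grid_step=2)
        zs = [float(line.split()[3]) for line in p.read_text().splitlines()
              if line.startswith("v ")]
        assert zs and all(z == 0.0 for z in zs)

    def test_peak_zero_shell_identical_to_planar(self, seg10, boundaries10,
                                                 wing10):
        sec_img = np.full(wing10.image.shape, 255, dtype=np.uint8)
        field = extract_sections(
            sec_img, CorrugationParams(n_sections=4, peak_height=0.0))
        surface = loft_surface(field, boundaries10[seg10.main.id].vertices,
                               image_height=wing10.image.shape[0])
        shell = build_model(seg10, boundaries10, "two_section", surface=surface)
        planar = build_model(seg10, boundaries10, "two_section")
        mesh_s = model_mesh(shell)
        mesh_p = model_mesh(planar)
        np.testing.assert_array_equal(mesh_s.vertices, mesh_p.vertices)
        np.testing.assert_array_equal(mesh_s.faces, mesh_p.faces)
        assert (mesh_s.vertices[:, 2] == 0.0).all()

    def test_triangulated_area_matches_shoelace(self, seg10, boundaries10):
        model = build_model(seg10, boundaries10, "two_section")
        mesh = model_mesh(model, grid_step=1)
        v = mesh.vertices
        tri = v[mesh.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri_area = 0.5 * np.abs(cross).sum()
        h = model.image_height
        shoelace = polygon_area(model.outer)
        for hole in model.holes.values():
            shoelace -= polygon_area(hole)
        assert tri_area == pytest.approx(shoelace, rel=0.01)

    def test_obj_loadable_by_independent_reader(self, planar_model, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        p = tmp_path / "m.obj"
        write_neutral_geometry(planar_model, p, grid_step=2)
        mesh = trimesh.load(p, process=False)
        assert len(mesh.faces) > 0

    def test_stl_deterministic(self, planar_model, tmp_path):
        p1, p2 = tmp_path / "a.stl", tmp_path / "b.stl"
        write_neutral_geometry(planar_model, p1, grid_step=2)
        write_neutral_geometry(planar_model, p2, grid_step=2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_text().startswith("solid wing")

    def test_json_roundtrip_lossless(self, planar_model, tmp_path):
        p = tmp_path / "m.json"
        write_neutral_geometry(planar_model, p)
        rebuilt = model_from_json(p)
        np.testing.assert_array_equal(rebuilt.outer, planar_model.outer)
        assert set(rebuilt.cells) == set(planar_model.cells)
        for cid in planar_model.cells:
            np.testing.assert_array_equal(rebuilt.cells[cid],
                                          planar_model.cells[cid])
        assert rebuilt.sections.mapping == planar_model.sections.mapping
        assert rebuilt.dimensionality == planar_model.dimensionality

    def test_unknown_format_rejected(self, planar_model, tmp_path):
        with pytest.raises(ValueError):
            write_neutral_geometry(planar_model, tmp_path / "m.xyz")
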