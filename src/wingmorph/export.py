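"""Wing model assembly and solver-ready export.

A :class:`WingModel` bundles everything a finite-element preprocessor needs:
the outer boundary polygon, the cell partitions, hole cuts, a material
section assignment, and (for shell models) the corrugated surface.  Two
material groupings are supported:

* *two-section*: one section for all veins, one for all membranes (cells);
* *multi-section*: one section per cell plus one for the veins, so each
  cell can carry its own material.

Exports:

* a deterministic Abaqus-dialect Python script (sketch of the outer
  boundary, hole cuts, per-cell face partitions, shell-loft commands for 3D
  models, material/section definitions and one section assignment per
  section) — emitted as text and syntactically valid Python, never executed
  here;
* neutral OBJ / ASCII-STL meshes and a lossless JSON topology dump.

Both planar and shell meshes come from the same boundary-trimmed regular
grid triangulation, so a shell model with zero peak height exports exactly
the planar vertex set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corrugation import CorrugatedSurface, HeightField, loft_surface
from .errors import AssemblyError, DegenerateInputError
from .morphometrics import ScaleSpec

#: Validation constants for a hawkmoth (Manduca sexta) forewing bending test:
#: homogeneous Young's moduli for membranes and veins and the tip point load.
E_MEMBRANE_DEFAULT = 1.5e8   # N m^-2
E_VEIN_DEFAULT = 2.1e12      # N m^-2
TIP_LOAD_DEFAULT = 0.003     # N


@dataclass
class MaterialConfig:
    E_membrane: float = E_MEMBRANE_DEFAULT
    E_vein: float = E_VEIN_DEFAULT
    tip_load: float = TIP_LOAD_DEFAULT
    poisson: float = 0.3
    thickness: dict = field(default_factory=dict)  # section name -> thickness
    default_thickness: float = 1.0

    def __post_init__(self):
        if self.E_membrane <= 0 or self.E_vein <= 0:
            raise DegenerateInputError("Young's moduli must be positive")


@dataclass
class SectionAssignment:
    mode: str                 # 'two_section' | 'multi_section'
    names: list               # section names, veins first
    mapping: dict             # face id ('veins' or cell id) -> section name


@dataclass
class WingModel:
    dimensionality: str       # 'planar_2d' | 'shell_3d'
    outer: np.ndarray         # (n, 2) Cartesian (x, y)
    cells: dict               # cell id -> (k, 2) Cartesian polygon
    holes: dict               # region id -> (k, 2) Cartesian polygon
    sections: SectionAssignment
    surface: CorrugatedSurface | None = None
    scale: ScaleSpec | None = None
    image_height: int = 0
    # pixel-space copies retained for meshing (row, col)
    outer_px: np.ndarray | None = None
    cells_px: dict = field(default_factory=dict)
    holes_px: dict = field(default_factory=dict)


def make_sections(mode: str, cell_ids) -> SectionAssignment:
    """Build the section grouping for the given cells."""
    cell_ids = list(cell_ids)
    if mode == "two_section":
        names = ["veins", "membranes"]
        mapping = {"veins": "veins", **{cid: "membranes" for cid in cell_ids}}
    elif mode == "multi_section":
        names = ["veins"] + [f"cell_{cid}" for cid in cell_ids]
        mapping = {"veins": "veins", **{cid: f"cell_{cid}" for cid in cell_ids}}
    else:
        raise ValueError(f"unknown section mode {mode!r}")
    return SectionAssignment(mode=mode, names=names, mapping=mapping)


def build_model(seg_result, boundaries: dict, sections: SectionAssignment | str,
                surface: CorrugatedSurface | None = None,
                scale: ScaleSpec | None = None) -> WingModel:
    """Assemble a wing model from segmentation output.

    *boundaries* maps region id -> simplified boundary (its ``vertices`` in
    pixel coordinates); it must cover the main domain (id of
    ``seg_result.main``), every retained subdomain, and every discontinuity.
    Cell faces become membrane partitions; the vein face is the remainder of
    the main domain; discontinuities are cut out.
    """
    height = seg_result.shape[0]

    def verts_of(region):
        b = boundaries.get(region.id)
        if b is None:
            raise AssemblyError(
                f"missing simplified boundary for {region.kind} region {region.id}")
        return np.asarray(getattr(b, "vertices", b), dtype=float)

    def to_cart(chain_px):
        return np.stack([chain_px[:, 1], (height - 1) - chain_px[:, 0]], axis=1)

    outer_px = verts_of(seg_result.main)
    cells_px = {r.id: verts_of(r) for r in seg_result.subdomains}
    holes_px = {r.id: verts_of(r) for r in seg_result.discontinuities}
    if isinstance(sections, str):
        sections = make_sections(sections, sorted(cells_px))
    s = scale.length_per_pixel if scale else 1.0
    model = WingModel(
        dimensionality="shell_3d" if surface is not None else "planar_2d",
        outer=to_cart(outer_px) * s,
        cells={cid: to_cart(v) * s for cid, v in cells_px.items()},
        holes={hid: to_cart(v) * s for hid, v in holes_px.items()},
        sections=sections, surface=surface, scale=scale,
        image_height=height, outer_px=outer_px,
        cells_px=cells_px, holes_px=holes_px)
    return model


def model_mesh(model: WingModel, grid_step: int = 1) -> CorrugatedSurface:
    """Triangulated surface of the model (holes cut): the corrugated loft for
    shell models, the same grid at z = 0 for planar models."""
    if model.dimensionality == "shell_3d" and model.surface is not None:
        return model.surface
    flat = HeightField(
        sections=np.zeros((2, model.image_height)),
        section_positions=np.array([model.outer_px[:, 1].min(),
                                    model.outer_px[:, 1].max()]),
        peaks=np.zeros(2))
    return loft_surface(flat, model.outer_px, list(model.holes_px.values()),
                        image_height=model.image_height, grid_step=grid_step)


# ---------------------------------------------------------------------------
# Solver script emission
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _poly_lines(name: str, verts: np.ndarray) -> list:
    pts = ", ".join(f"({_fmt(x)}, {_fmt(y)})" for x, y in verts)
    return [f"{name} = ({pts})"]


def write_solver_script(model: WingModel, materials: MaterialConfig | None = None,
                        path=None) -> str:
    """Emit the model as an Abaqus-dialect Python script (text only).

    The script sketches the outer boundary, cuts holes, partitions cell
    faces, defines shell-loft sections and a linear loft path for 3D
    models, and assigns one material section per section name.  Output is
    byte-stable for identical input; it is never executed by this package.
    """
    materials = materials or MaterialConfig()
    sec = model.sections
    lines = [
        "# Wing finite-element model (generated)",
        "from abaqus import mdb",
        "from abaqusConstants import THREE_D, DEFORMABLE_BODY, MIDDLE_SURFACE",
        "",
        "model = mdb.models['Model-1']",
        "sketch = model.ConstrainedSketch(name='wing_outline', sheetSize=1000.0)",
    ]
    lines += _poly_lines("outer_boundary", model.outer)
    lines += [
        "for i in range(len(outer_boundary)):",
        "    sketch.Line(point1=outer_boundary[i],"
        " point2=outer_boundary[(i + 1) % len(outer_boundary)])",
        "part = model.Part(name='wing', dimensionality=THREE_D,"
        " type=DEFORMABLE_BODY)",
    ]
    fld = (model.surface.source_field
           if model.dimensionality == "shell_3d" and model.surface is not None
           else None)
    if fld is not None:
        lines += ["", "# shell loft: section curves joined along a linear path"]
        for i, (pos, curve) in enumerate(
                zip(fld.section_positions, fld.sections)):
            ys = (model.image_height - 1) - np.arange(len(curve), dtype=float)
            pts = ", ".join(
                f"({_fmt(pos)}, {_fmt(y)}, {_fmt(z)})"
                for y, z in zip(ys[::8], curve[::8]))
            lines.append(f"loft_section_{i} = ({pts})")
        lines.append(
            "loft_path = 'linear'  # straight path across the sections")
        all_secs = ", ".join(
            f"loft_section_{i}" for i in range(len(fld.sections)))
        lines.append(
            f"part.ShellLoft(loftsections=({all_secs}), paths=(loft_path,))")
    else:
        lines.append("part.BaseShell(sketch=sketch)")
    lines.append("")
    lines.append("# hole cuts")
    for hid in sorted(model.holes):
        name = f"hole_{hid}"
        lines += _poly_lines(name, model.holes[hid])
        lines += [
            f"cut = model.ConstrainedSketch(name='{name}', sheetSize=1000.0)",
            f"for i in range(len({name})):",
            f"    cut.Line(point1={name}[i], point2={name}[(i + 1) % len({name})])",
            f"part.Cut(sketch=cut)",
        ]
    lines.append("")
    lines.append("# cell partitions")
    for cid in sorted(model.cells):
        name = f"cell_{cid}"
        lines += _poly_lines(name, model.cells[cid])
        lines += [
            f"psk = model.ConstrainedSketch(name='partition_{cid}',"
            " sheetSize=1000.0)",
            f"for i in range(len({name})):",
            f"    psk.Line(point1={name}[i], point2={name}[(i + 1) % len({name})])",
            f"part.PartitionFaceBySketch(faces=part.faces, sketch=psk)",
        ]
    lines.append("")
    lines.append("# materials and sections")
    lines += [
        "mat_membrane = model.Material(name='membrane')",
        f"mat_membrane.Elastic(table=(({materials.E_membrane:.6e},"
        f" {materials.poisson}),))",
        "mat_vein = model.Material(name='vein')",
        f"mat_vein.Elastic(table=(({materials.E_vein:.6e},"
        f" {materials.poisson}),))",
        f"tip_load = {materials.tip_load}  # N, applied at the wing tip",
    ]
    for name in sec.names:
        mat = "vein" if name == "veins" else "membrane"
        thick = materials.thickness.get(name, materials.default_thickness)
        lines.append(
            f"model.HomogeneousShellSection(name='{name}', material='{mat}',"
            f" thickness={thick})")
    lines.append("")
    lines.append("# section assignments: one statement per section")
    for name in sec.names:
        faces = sorted((fid for fid, s in sec.mapping.items() if s == name),
                       key=str)
        regions = ", ".join(
            "'veins_face'" if fid == "veins" else f"'face_of_cell_{fid}'"
            for fid in faces)
        lines.append(
            f"part.SectionAssignment(region=({regions},),"
            f" sectionName='{name}', offsetType=MIDDLE_SURFACE)")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Neutral geometry
# ---------------------------------------------------------------------------

def write_neutral_geometry(model: WingModel, path, fmt: str = None,
                           grid_step: int = 1) -> None:
    """Write the model as OBJ, ASCII STL, or a lossless JSON topology dump.

    *fmt* defaults to the file suffix.  OBJ/STL carry the triangulated
    surface (z = 0 for planar models) in pixel-derived Cartesian
    coordinates; JSON carries the full polygon topology, physical scaling
    included, and round-trips through :func:`model_from_json`.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1]
    fmt = fmt.upper()
    if fmt == "JSON":
        with open(path, "w", newline="\n") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    mesh = model_mesh(model, grid_step=grid_step)
    if fmt == "OBJ":
        _write_obj(mesh, path)
    elif fmt == "STL":
        _write_stl_ascii(mesh, path)
    else:
        raise ValueError(f"unknown geometry format {fmt!r}")


def _write_obj(mesh: CorrugatedSurface, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("# wingmorph mesh\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def _write_stl_ascii(mesh: CorrugatedSurface, path) -> None:
    v = mesh.vertices
    with open(path, "w", newline="\n") as fh:
        fh.write("solid wing\n")
        for a, b, c in mesh.faces:
            n = np.cross(v[b] - v[a], v[c] - v[a])
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            fh.write(f"  facet normal {_fmt(n[0])} {_fmt(n[1])} {_fmt(n[2])}\n")
            fh.write("    outer loop\n")
            for i in (a, b, c):
                fh.write(f"      vertex {_fmt(v[i][0])} {_fmt(v[i][1])}"
                         f" {_fmt(v[i][2])}\n")
            fh.write("    endloop\n")
            fh.write("  endfacet\n")
        fh.write("endsolid wing\n")


def model_to_dict(model: WingModel) -> dict:
    return {
        "dimensionality": model.dimensionality,
        "image_height": model.image_height,
        "outer": model.outer.tolist(),
        "cells": {str(k): v.tolist() for k, v in model.cells.items()},
        "holes": {str(k): v.tolist() for k, v in model.holes.items()},
        "sections": {
            "mode": model.sections.mode,
            "names": model.sections.names,
            "mapping": {str(k): v for k, v in model.sections.mapping.items()},
        },
        "scale": ({"length_per_pixel": model.scale.length_per_pixel,
                   "unit": model.scale.unit} if model.scale else None),
        "outer_px": (model.outer_px.tolist()
                     if model.outer_px is not None else None),
        "cells_px": {str(k): v.tolist() for k, v in model.cells_px.items()},
        "holes_px": {str(k): v.tolist() for k, v in model.holes_px.items()},
    }


def model_from_json(path) -> WingModel:
    """Rebuild a model from a JSON topology dump (lossless round-trip for
    planar topology; the lofted surface is not serialised)."""
    with open(path) as fh:
        doc = json.load(fh)

    def intkey(d):
        return {("veins" if k == "veins" else int(k)): v for k, v in d.items()}

    sections = SectionAssignment(mode=doc["sections"]["mode"],
                                 names=list(doc["sections"]["names"]),
                                 mapping=intkey(doc["sections"]["mapping"]))
    scale = None
    if doc["scale"]:
        scale = ScaleSpec(doc["scale"]["length_per_pixel"], doc["scale"]["unit"])
    return WingModel(
        dimensionality=doc["dimensionality"],
        outer=np.asarray(doc["outer"], dtype=float),
        cells={int(k): np.asarray(v, dtype=float)
               for k, v in doc["cells"].items()},
        holes={int(k): np.asarray(v, dtype=float)
               for k, v in doc["holes"].items()},
        sections=sections, surface=None, scale=scale,
        image_height=doc["image_height"],
        outer_px=(np.asarray(doc["outer_px"], dtype=float)
                  if doc["outer_px"] is not None else None),
        cells_px={int(k): np.asarray(v, dtype=float)
                  for k, v in doc["cells_px"].items()},
        holes_px={int(k): np.asarray(v, dtype=float)
                  for k, v in doc["holes_px"].items()})
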