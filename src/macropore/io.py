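"""Mesh and field export: Gmsh MSH 2.2 (ASCII) and legacy VTK.

No external mesh-I/O library is used; the writers emit the standard
formats directly and a minimal MSH reader round-trips the package's own
meshes (named physical groups carry the region and boundary tags)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import DISC, FLUID
from .meshing import Mesh

_PHYS = {
    "fluid": 1,
    "disc": 2,
    "inlet": 11,
    "outlet": 12,
    "chamber_wall": 13,
    "disc_arc": 14,
    "channel_wall": 15,
}
_PHYS_INV = {v: k for k, v in _PHYS.items()}


def write_msh(mesh: Mesh, path) -> None:
    """Write the mesh as Gmsh MSH 2.2 with named physical groups for the
    two regions and all boundary/interface tags."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(_PHYS))]
    for name, num in sorted(_PHYS.items(), key=lambda kv: kv[1]):
        dim = 2 if name in ("fluid", "disc") else 1
        lines.append(f'{dim} {num} "{name}"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(len(mesh.points))]
    for i, (x, y) in enumerate(mesh.points, start=1):
        lines.append(f"{i} {x:.12g} {y:.12g} 0")
    lines.append("$EndNodes")

    elements = []
    for edges, tags in (
        (mesh.boundary_edges, mesh.boundary_tags),
        (mesh.interface_edges, mesh.interface_tags),
    ):
        for (a, b), t in zip(edges, tags):
            elements.append((1, _PHYS[t], (a + 1, b + 1)))
    for tri, reg in zip(mesh.triangles, mesh.region):
        name = "disc" if reg == DISC else "fluid"
        elements.append((2, _PHYS[name], tuple(int(v) + 1 for v in tri)))
    lines += ["$Elements", str(len(elements))]
    for i, (etype, phys, nodes) in enumerate(elements, start=1):
        lines.append(f"{i} {etype} 2 {phys} {phys} " + " ".join(map(str, nodes)))
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a mesh previously written by :func:`write_msh`."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    points = []
    tris, regions = [], []
    bedges, btags, iedges, itags = [], [], [], []
    for line in it:
        if line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                points.append((float(parts[1]), float(parts[2])))
            assert next(it) == "$EndNodes"
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                phys = int(parts[3])
                nodes = [int(v) - 1 for v in parts[3 + ntags :]]
                name = _PHYS_INV[phys]
                if etype == 1:
                    if name in ("disc_arc", "channel_wall"):
                        iedges.append(nodes)
                        itags.append(name)
                    else:
                        bedges.append(nodes)
                        btags.append(name)
                elif etype == 2:
                    tris.append(nodes)
                    regions.append(DISC if name == "disc" else FLUID)
            assert next(it) == "$EndElements"
    return Mesh(
        points=np.array(points),
        triangles=np.array(tris, dtype=int),
        region=np.array(regions, dtype=int),
        boundary_edges=np.array(bedges, dtype=int),
        boundary_tags=np.array(btags),
        interface_edges=(
            np.array(iedges, dtype=int) if iedges else np.empty((0, 2), dtype=int)
        ),
        interface_tags=np.array(itags),
        h_boundary=float("nan"),
        h_max=float("nan"),
        domain=None,
    )


def write_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Write the mesh and nodal scalar/vector fields as legacy ASCII VTK."""
    path = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        "macropore field snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.points)} double",
    ]
    for x, y in mesh.points:
        out.append(f"{x:.10g} {y:.10g} 0")
    m = len(mesh.triangles)
    out.append(f"CELLS {m} {4 * m}")
    for tri in mesh.triangles:
        out.append("3 " + " ".join(str(int(v)) for v in tri))
    out.append(f"CELL_TYPES {m}")
    out.extend(["5"] * m)
    out.append(f"CELL_DATA {m}")
    out.append("SCALARS region int 1")
    out.append("LOOKUP_TABLE default")
    out.extend(str(int(r)) for r in mesh.region)
    if point_data:
        out.append(f"POINT_DATA {len(mesh.points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.10g}" for v in arr)
            else:
                out.append(f"VECTORS {name} double")
                out.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr)
    path.write_text("\n".join(out) + "\n")
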