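"""Readers and writers for labeled tetrahedral meshes.

Three ASCII dialects are supported, chosen because they cover the common
export paths of segmentation/meshing pipelines:

* ``vtk`` — legacy ASCII VTK unstructured grid.  Region tags travel as the
  ``region`` cell scalar, named node sets as 0/1 point scalars named
  ``nset:<name>``, extra per-element fields as additional cell scalars.
* ``msh`` — Gmsh MSH 4.1.  One volume entity per region tag (entity tag ==
  physical tag == region tag); node sets travel as ``$NodeData`` views named
  ``nset:<name>`` (value 1 on members), per-element fields as
  ``$ElementData``.
* ``inp`` — minimal Abaqus INP: ``*NODE``, ``*ELEMENT TYPE=C3D4`` (one block
  per region, ``ELSET=REGION_<tag>``), native ``*NSET`` cards.  Per-element
  fields are encoded in ``** DEVFEA CELL_DATA`` comment blocks so they
  survive a round trip through this reader.

All dialects are 1-based on disk and 0-based in memory.  Only TET4 volume
cells are accepted; any other cell type is a hard error.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .mesh import TetMesh

__all__ = ["read_mesh", "write_mesh"]

_FORMATS = ("msh", "vtk", "inp")
_EXT_MAP = {".msh": "msh", ".vtk": "vtk", ".inp": "inp"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    try:
        return _EXT_MAP[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}")


def read_mesh(path: str | Path, format: str | None = None) -> TetMesh:
    """Read a labeled tetrahedral mesh, preserving region tags and node sets.

    ``format`` is one of ``{"msh", "vtk", "inp"}``; inferred from the file
    suffix when omitted.  Raises on non-tetrahedral cells and dangling node
    references (the latter via :class:`TetMesh` construction).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.is_file():
        raise FileNotFoundError(path)
    text = path.read_text()
    if fmt == "vtk":
        mesh, _ = _parse_vtk(text)
    elif fmt == "msh":
        mesh, _ = _parse_msh(text)
    else:
        mesh, _ = _parse_inp(text)
    return mesh


def read_mesh_with_data(path: str | Path, format: str | None = None):
    """Like :func:`read_mesh` but also return per-element scalar fields."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    parser = {"vtk": _parse_vtk, "msh": _parse_msh, "inp": _parse_inp}[fmt]
    return parser(text)


def write_mesh(
    mesh: TetMesh,
    path: str | Path,
    format: str | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a mesh (plus optional per-element scalar fields) to disk."""
    path = Path(path)
    fmt = _infer_format(path, format)
    cell_data = {
        name: np.asarray(vals, dtype=float) for name, vals in (cell_data or {}).items()
    }
    for name, vals in cell_data.items():
        if vals.shape != (mesh.n_elements,):
            raise ValueError(
                f"cell_data {name!r} has length {vals.shape}, expected ({mesh.n_elements},)"
            )
    writer = {"vtk": _write_vtk, "msh": _write_msh, "inp": _write_inp}[fmt]
    path.write_text(writer(mesh, cell_data))


# ---------------------------------------------------------------------------
# legacy VTK unstructured grid
# ---------------------------------------------------------------------------

def _write_vtk(mesh: TetMesh, cell_data: dict[str, np.ndarray]) -> str:
    out = [
        "# vtk DataFile Version 3.0",
        "devfea tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    out += [" ".join(f"{v:.17g}" for v in row) for row in mesh.node_coords]
    m = mesh.n_elements
    out.append(f"CELLS {m} {5 * m}")
    out += ["4 " + " ".join(str(i) for i in tet) for tet in mesh.tets]
    out.append(f"CELL_TYPES {m}")
    out += ["10"] * m
    out.append(f"CELL_DATA {m}")
    out.append("SCALARS region int 1")
    out.append("LOOKUP_TABLE default")
    out += [str(int(t)) for t in mesh.element_region]
    for name, vals in cell_data.items():
        out.append(f"SCALARS {name} double 1")
        out.append("LOOKUP_TABLE default")
        out += [f"{v:.17g}" for v in vals]
    if mesh.node_sets:
        out.append(f"POINT_DATA {mesh.n_nodes}")
        for name, idx in sorted(mesh.node_sets.items()):
            mask = np.zeros(mesh.n_nodes, dtype=int)
            mask[idx] = 1
            out.append(f"SCALARS nset:{name} int 1")
            out.append("LOOKUP_TABLE default")
            out += [str(v) for v in mask]
    return "\n".join(out) + "\n"


def _parse_vtk(text: str):
    lines = text.splitlines()
    # token stream below the 4-line header
    i = 0

    def next_nonempty():
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines):
            raise ValueError("truncated VTK file")
        line = lines[i]
        i += 1
        return line

    header = next_nonempty()
    if not header.startswith("# vtk DataFile"):
        raise ValueError("not a legacy VTK file")
    next_nonempty()  # title
    if next_nonempty().strip().upper() != "ASCII":
        raise ValueError("only ASCII VTK supported")
    if "UNSTRUCTURED_GRID" not in next_nonempty():
        raise ValueError("only unstructured grids supported")

    def read_numbers(count, dtype=float):
        vals: list = []
        nonlocal i
        while len(vals) < count:
            vals.extend(dtype(tok) for tok in next_nonempty().split())
        if len(vals) != count:
            raise ValueError("unexpected token count in VTK section")
        return vals

    coords = cells = types = region = None
    cell_fields: dict[str, np.ndarray] = {}
    node_sets: dict[str, np.ndarray] = {}
    section = None  # CELL_DATA / POINT_DATA context
    n_points = n_cells = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        key = stripped.split()[0].upper()
        if key == "POINTS":
            parts = next_nonempty().split()
            n_points = int(parts[1])
            coords = np.array(read_numbers(3 * n_points)).reshape(n_points, 3)
        elif key == "CELLS":
            parts = next_nonempty().split()
            n_cells, total = int(parts[1]), int(parts[2])
            raw = read_numbers(total, dtype=int)
            cells = []
            j = 0
            while j < len(raw):
                k = raw[j]
                cells.append(raw[j + 1 : j + 1 + k])
                j += 1 + k
        elif key == "CELL_TYPES":
            parts = next_nonempty().split()
            types = read_numbers(int(parts[1]), dtype=int)
        elif key in ("CELL_DATA", "POINT_DATA"):
            next_nonempty()
            section = key
        elif key == "SCALARS":
            parts = next_nonempty().split()
            name = parts[1]
            count = n_cells if section == "CELL_DATA" else n_points
            lookup = next_nonempty()
            if not lookup.strip().upper().startswith("LOOKUP_TABLE"):
                i -= 1  # lookup table line is optional
            vals = np.array(read_numbers(count))
            if section == "CELL_DATA":
                if name == "region":
                    region = vals.astype(np.int64)
                else:
                    cell_fields[name] = vals
            elif name.startswith("nset:"):
                node_sets[name[5:]] = np.nonzero(vals != 0)[0]
        elif key in ("VECTORS", "NORMALS"):
            next_nonempty()
            count = n_cells if section == "CELL_DATA" else n_points
            read_numbers(3 * count)
        else:
            i += 1  # skip unknown line

    if coords is None or cells is None or types is None:
        raise ValueError("VTK file missing POINTS/CELLS/CELL_TYPES")
    bad = [t for t in types if t != 10]
    if bad:
        raise ValueError(
            f"non-tetrahedral cells present (VTK cell types {sorted(set(bad))})"
        )
    tets = np.array(cells, dtype=np.int64)
    mesh = TetMesh(coords, tets, region, node_sets)
    return mesh, cell_fields


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1
# ---------------------------------------------------------------------------

def _write_msh(mesh: TetMesh, cell_data: dict[str, np.ndarray]) -> str:
    tags = [int(t) for t in mesh.region_tags()]
    lo = mesh.node_coords.min(axis=0) if mesh.n_nodes else np.zeros(3)
    hi = mesh.node_coords.max(axis=0) if mesh.n_nodes else np.zeros(3)
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$Entities",
           f"0 0 0 {len(tags)}"]
    for t in tags:
        out.append(
            " ".join(f"{v:.17g}" for v in (*lo, *hi)).join([f"{t} ", f" 1 {t} 0"])
        )
    out.append("$EndEntities")
    # single node block attached to the first volume entity
    n = mesh.n_nodes
    ent = tags[0] if tags else 1
    out += ["$Nodes", f"1 {n} 1 {n}", f"3 {ent} 0 {n}"]
    out += [str(i + 1) for i in range(n)]
    out += [" ".join(f"{v:.17g}" for v in row) for row in mesh.node_coords]
    out.append("$EndNodes")
    m = mesh.n_elements
    out += ["$Elements"]
    blocks = [(t, np.nonzero(mesh.element_region == t)[0]) for t in tags]
    out.append(f"{len(blocks)} {m} 1 {m}")
    eid = 1
    for t, idx in blocks:
        out.append(f"3 {t} 4 {len(idx)}")
        for e in idx:
            conn = " ".join(str(v + 1) for v in mesh.tets[e])
            out.append(f"{eid} {conn}")
            eid += 1
    out.append("$EndElements")
    for name, setidx in sorted(mesh.node_sets.items()):
        out += ["$NodeData", "1", f'"nset:{name}"', "1", "0.0", "3", "0", "1",
                str(len(setidx))]
        out += [f"{i + 1} 1" for i in setidx]
        out.append("$EndNodeData")
    # element order on disk is block order; remember the permutation
    perm = np.concatenate([idx for _, idx in blocks]) if blocks else np.array([], int)
    for name, vals in cell_data.items():
        out += ["$ElementData", "1", f'"{name}"', "1", "0.0", "3", "0", "1", str(m)]
        out += [f"{k + 1} {vals[perm[k]]:.17g}" for k in range(m)]
        out.append("$EndElementData")
    return "\n".join(out) + "\n"


def _parse_msh(text: str):
    sections: dict[str, list[list[str]]] = {}
    name = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$End"):
            name = None
        elif line.startswith("$"):
            name = line[1:]
            sections.setdefault(name, []).append([])
        elif name is not None:
            sections[name][-1].append(line)

    if "MeshFormat" not in sections:
        raise ValueError("not a Gmsh MSH file")
    version = sections["MeshFormat"][0][0].split()[0]
    if not version.startswith("4"):
        raise ValueError(f"only MSH 4.x supported, got version {version}")

    node_lines = sections.get("Nodes", [[]])[0]
    header = node_lines[0].split()
    n_blocks, n_nodes = int(header[0]), int(header[1])
    tag_to_idx: dict[int, int] = {}
    coords = np.empty((n_nodes, 3))
    pos = 1
    count = 0
    for _ in range(n_blocks):
        bh = node_lines[pos].split()
        nb = int(bh[3])
        pos += 1
        tags = [int(node_lines[pos + k]) for k in range(nb)]
        pos += nb
        for k in range(nb):
            xyz = [float(v) for v in node_lines[pos + k].split()[:3]]
            tag_to_idx[tags[k]] = count
            coords[count] = xyz
            count += 1
        pos += nb
    if count != n_nodes:
        raise ValueError("MSH node count mismatch")

    elem_lines = sections.get("Elements", [[]])[0]
    header = elem_lines[0].split()
    n_blocks = int(header[0])
    tets: list[list[int]] = []
    regions: list[int] = []
    pos = 1
    for _ in range(n_blocks):
        dim, ent, etype, nb = (int(v) for v in elem_lines[pos].split())
        pos += 1
        if etype != 4:
            raise ValueError(
                f"non-tetrahedral cells present (MSH element type {etype})"
            )
        for k in range(nb):
            parts = elem_lines[pos + k].split()
            tets.append([tag_to_idx[int(v)] for v in parts[1:5]])
            regions.append(ent)
        pos += nb

    node_sets: dict[str, np.ndarray] = {}
    cell_fields: dict[str, np.ndarray] = {}
    # data-section header: 1 string tag (name), 1 real tag (time), 3 integer
    # tags (step, components, entity count) -> entity count at line 7
    for block in sections.get("NodeData", []):
        dname = block[1].strip('"')
        nvals = int(block[7])
        members = [tag_to_idx[int(block[8 + k].split()[0])] for k in range(nvals)]
        if dname.startswith("nset:"):
            node_sets[dname[5:]] = np.array(sorted(members), dtype=np.int64)
    for block in sections.get("ElementData", []):
        dname = block[1].strip('"')
        nvals = int(block[7])
        vals = np.empty(nvals)
        for k in range(nvals):
            tag, v = block[8 + k].split()
            vals[int(tag) - 1] = float(v)
        cell_fields[dname] = vals

    mesh = TetMesh(coords, np.array(tets, dtype=np.int64),
                   np.array(regions, dtype=np.int64), node_sets)
    return mesh, cell_fields


# ---------------------------------------------------------------------------
# minimal Abaqus INP
# ---------------------------------------------------------------------------

def _write_inp(mesh: TetMesh, cell_data: dict[str, np.ndarray]) -> str:
    out = ["*HEADING", "devfea tetrahedral mesh", "*NODE"]
    for i, row in enumerate(mesh.node_coords):
        out.append(f"{i + 1}, " + ", ".join(f"{v:.17g}" for v in row))
    for t in mesh.region_tags():
        idx = np.nonzero(mesh.element_region == t)[0]
        out.append(f"*ELEMENT, TYPE=C3D4, ELSET=REGION_{int(t)}")
        for e in idx:
            out.append(f"{e + 1}, " + ", ".join(str(v + 1) for v in mesh.tets[e]))
    for name, setidx in sorted(mesh.node_sets.items()):
        out.append(f"*NSET, NSET={name}")
        members = [str(i + 1) for i in setidx]
        for k in range(0, len(members), 8):
            out.append(", ".join(members[k : k + 8]))
    for name, vals in cell_data.items():
        out.append(f"** DEVFEA CELL_DATA {name}")
        for e in range(mesh.n_elements):
            out.append(f"** {e + 1} {vals[e]:.17g}")
    return "\n".join(out) + "\n"


_INP_KEY_RE = re.compile(r"\*(\w+)", re.IGNORECASE)


def _parse_inp(text: str):
    nodes: dict[int, list[float]] = {}
    elements: list[tuple[int, list[int], int]] = []  # (id, conn, region)
    nsets: dict[str, list[int]] = {}
    cell_fields_raw: dict[str, dict[int, float]] = {}
    mode = None
    current_region = 0
    auto_region = 0
    current_nset: str | None = None
    current_field: str | None = None

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("** DEVFEA CELL_DATA"):
            current_field = line.split()[-1]
            cell_fields_raw[current_field] = {}
            mode = "celldata"
            continue
        if line.startswith("**"):
            if mode == "celldata" and current_field is not None:
                parts = line[2:].split()
                if len(parts) == 2:
                    cell_fields_raw[current_field][int(parts[0])] = float(parts[1])
            continue
        if line.startswith("*"):
            keyword = _INP_KEY_RE.match(line).group(1).upper()
            opts = {
                k.strip().upper(): v.strip()
                for k, v in (
                    p.split("=", 1) for p in line.split(",")[1:] if "=" in p
                )
            }
            if keyword == "NODE":
                mode = "node"
            elif keyword == "ELEMENT":
                etype = opts.get("TYPE", "").upper()
                if etype != "C3D4":
                    raise ValueError(
                        f"non-tetrahedral cells present (INP element type {etype or '?'})"
                    )
                elset = opts.get("ELSET", "")
                m = re.fullmatch(r"REGION_(\d+)", elset)
                if m:
                    current_region = int(m.group(1))
                else:
                    auto_region += 1
                    current_region = auto_region
                mode = "element"
            elif keyword == "NSET":
                current_nset = opts.get("NSET")
                if current_nset is None:
                    raise ValueError("*NSET card without NSET= name")
                nsets.setdefault(current_nset, [])
                mode = "nset"
            else:
                mode = None
            continue
        if mode == "node":
            parts = [p for p in line.replace(",", " ").split()]
            nodes[int(parts[0])] = [float(v) for v in parts[1:4]]
        elif mode == "element":
            parts = [int(p) for p in line.replace(",", " ").split()]
            if len(parts) != 5:
                raise ValueError("C3D4 element line must have 4 node references")
            elements.append((parts[0], parts[1:], current_region))
        elif mode == "nset" and current_nset is not None:
            nsets[current_nset] += [int(p) for p in line.replace(",", " ").split()]

    if not nodes or not elements:
        raise ValueError("INP file missing *NODE or *ELEMENT data")
    tag_sorted = sorted(nodes)
    tag_to_idx = {t: i for i, t in enumerate(tag_sorted)}
    coords = np.array([nodes[t] for t in tag_sorted])
    elements.sort(key=lambda e: e[0])
    eid_to_idx = {e[0]: k for k, e in enumerate(elements)}
    tets = np.array([[tag_to_idx[v] for v in conn] for _, conn, _ in elements],
                    dtype=np.int64)
    regions = np.array([r for _, _, r in elements], dtype=np.int64)
    node_sets = {
        name: np.array(sorted(tag_to_idx[t] for t in idx), dtype=np.int64)
        for name, idx in nsets.items()
    }
    cell_fields = {}
    for name, mapping in cell_fields_raw.items():
        vals = np.zeros(len(elements))
        for eid, v in mapping.items():
            vals[eid_to_idx[eid]] = v
        cell_fields[name] = vals
    mesh = TetMesh(coords, tets, regions, node_sets)
    return mesh, cell_fields
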