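"""Lossless mesh I/O through ASCII VTK unstructured-grid (.vtu) files.

One file carries the volume mesh (tet cells with a ``domain`` cell field),
the facet sets (appended triangle cells with a ``facet_set`` code field),
the long-axis frame (FieldData) and any per-element or per-node fields
(fat fractions, fiber vectors, potentials, displacements).  Standard VTK
viewers read these files directly; the facet-set name table is kept in an
XML comment that other tools ignore.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import CANONICAL_FACET_SETS, FACE_VERTICES, MeshError, TetMesh

_VTK_TET4 = 10
_VTK_TET10 = 24
_VTK_TRI = 5

__all__ = ["write_mesh", "read_mesh"]


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if a.dtype.kind == "f":
        return " ".join(f"{x:.17g}" for x in a.ravel())
    return " ".join(str(int(x)) for x in a.ravel())


def _data_array(name: str, arr: np.ndarray, ncomp: int | None = None) -> str:
    a = np.asarray(arr)
    vtype = "Float64" if a.dtype.kind == "f" else "Int64"
    comp = f' NumberOfComponents="{ncomp}"' if ncomp else ""
    return (
        f'<DataArray type="{vtype}" Name="{name}"{comp} format="ascii">\n'
        f"{_fmt(a)}\n</DataArray>\n"
    )


def write_mesh(
    mesh: TetMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write mesh + facet sets (+ optional fields) to an ASCII .vtu file.

    ``cell_data`` arrays are per-tet (length n_elems); ``point_data`` per
    node.  The mesh is validated first (orphan nodes, inverted elements).
    """
    mesh.validate()
    path = Path(path)
    set_names = list(mesh.facet_sets.keys())
    tris = (
        np.vstack([mesh.face_corner_nodes(mesh.facet_sets[n]) for n in set_names])
        if set_names
        else np.empty((0, 3), dtype=np.int64)
    )
    tri_codes = np.concatenate(
        [np.full(len(mesh.facet_sets[n]), i, dtype=np.int64) for i, n in enumerate(set_names)]
    ) if set_names else np.empty(0, dtype=np.int64)

    n_tet, n_tri = mesh.n_elems, tris.shape[0]
    npe = mesh.tet_conn.shape[1]
    conn = np.concatenate([mesh.tet_conn.ravel(), tris.ravel()])
    offsets = np.concatenate(
        [np.arange(1, n_tet + 1) * npe, n_tet * npe + np.arange(1, n_tri + 1) * 3]
    )
    types = np.concatenate(
        [
            np.full(n_tet, _VTK_TET10 if npe == 10 else _VTK_TET4),
            np.full(n_tri, _VTK_TRI),
        ]
    )

    pad = np.full(n_tri, -1, dtype=np.int64)
    cd_blocks = [
        _data_array("domain", np.concatenate([mesh.elem_domain, pad])),
        _data_array("facet_set", np.concatenate([np.full(n_tet, -1, dtype=np.int64), tri_codes])),
    ]
    for name, arr in (cell_data or {}).items():
        a = np.asarray(arr, dtype=float)
        if a.ndim == 1:
            cd_blocks.append(_data_array(name, np.concatenate([a, pad.astype(float)])))
        else:
            padv = np.full((n_tri, a.shape[1]), 0.0)
            cd_blocks.append(_data_array(name, np.vstack([a, padv]), ncomp=a.shape[1]))
    pd_blocks = []
    for name, arr in (point_data or {}).items():
        a = np.asarray(arr, dtype=float)
        pd_blocks.append(_data_array(name, a, ncomp=a.shape[1] if a.ndim > 1 else None))

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write(f"<!--myofat:facet_sets={','.join(set_names)}-->\n")
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write("<UnstructuredGrid>\n<FieldData>\n")
        fh.write(_data_array("long_axis", mesh.long_axis, ncomp=3))
        fh.write(_data_array("distal_point", mesh.distal_point, ncomp=3))
        fh.write("</FieldData>\n")
        fh.write(f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_tet + n_tri}">\n')
        fh.write("<Points>\n")
        fh.write(_data_array("Points", mesh.node_coords, ncomp=3))
        fh.write("</Points>\n<Cells>\n")
        fh.write(_data_array("connectivity", conn))
        fh.write(_data_array("offsets", offsets))
        fh.write(_data_array("types", types))
        fh.write("</Cells>\n<CellData>\n")
        for blk in cd_blocks:
            fh.write(blk)
        fh.write("</CellData>\n<PointData>\n")
        for blk in pd_blocks:
            fh.write(blk)
        fh.write("</PointData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def _parse_arrays(parent) -> dict[str, np.ndarray]:
    out = {}
    if parent is None:
        return out
    for da in parent.findall("DataArray"):
        dtype = float if da.get("type", "").startswith("Float") else np.int64
        text = da.text or ""
        arr = np.array(text.split(), dtype=float) if text.strip() else np.empty(0)
        if dtype is np.int64:
            arr = arr.astype(np.int64)
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            arr = arr.reshape(-1, ncomp)
        out[da.get("Name")] = arr
    return out


def read_mesh(
    path: str | Path, require_canonical: bool = True
) -> tuple[TetMesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read a .vtu written by :func:`write_mesh`.

    Returns ``(mesh, cell_data, point_data)``; per-tet cell fields are
    returned trimmed to the tet cells.  With ``require_canonical`` the six
    pipeline facet sets must all be present (error names the missing ones).
    """
    path = Path(path)
    text = path.read_text()
    set_names: list[str] = []
    marker = "myofat:facet_sets="
    if marker in text:
        seg = text.split(marker, 1)[1].split("-->", 1)[0].strip()
        set_names = [s for s in seg.split(",") if s]
    root = ET.fromstring(text.split("-->", 1)[-1] if "<!--" in text.split("<VTKFile")[0] else text)
    grid = root.find("UnstructuredGrid")
    fdata = _parse_arrays(grid.find("FieldData"))
    piece = grid.find("Piece")
    pts = _parse_arrays(piece.find("Points"))["Points"].reshape(-1, 3)
    cells = _parse_arrays(piece.find("Cells"))
    conn, offsets, types = cells["connectivity"], cells["offsets"], cells["types"]
    cdata = _parse_arrays(piece.find("CellData"))
    pdata = _parse_arrays(piece.find("PointData"))

    tet_mask = (types == _VTK_TET4) | (types == _VTK_TET10)
    tri_mask = types == _VTK_TRI
    starts = np.concatenate([[0], offsets[:-1]])
    npe = 10 if (types == _VTK_TET10).any() else 4
    tet_conn = np.vstack(
        [conn[s:e] for s, e, m in zip(starts, offsets, tet_mask) if m]
    ).reshape(-1, npe)
    tris = (
        np.vstack([conn[s:e] for s, e, m in zip(starts, offsets, tri_mask) if m]).reshape(-1, 3)
        if tri_mask.any()
        else np.empty((0, 3), dtype=np.int64)
    )

    domain = cdata.get("domain")
    if domain is None:
        raise MeshError("file has no 'domain' cell field")
    domain = domain[tet_mask].astype(np.int64)

    mesh = TetMesh(
        node_coords=pts,
        tet_conn=tet_conn,
        elem_domain=domain,
        long_axis=fdata.get("long_axis", np.array([0.0, 0.0, 1.0])).ravel(),
        distal_point=fdata.get("distal_point", np.zeros(3)).ravel(),
    )

    # rebuild facet sets as (elem, local_face) pairs; interface faces pick
    # the lowest-domain (muscle) side
    face_map: dict[tuple, tuple[int, int]] = {}
    all_tris = mesh.corners[:, FACE_VERTICES]
    for e in range(mesh.n_elems):
        for lf in range(4):
            key = tuple(sorted(all_tris[e, lf]))
            prev = face_map.get(key)
            if prev is None or domain[e] < domain[prev[0]]:
                face_map[key] = (e, lf)
    codes = cdata["facet_set"][tri_mask].astype(np.int64) if "facet_set" in cdata else None
    if codes is not None and len(set_names):
        for i, name in enumerate(set_names):
            sel = tris[codes == i]
            pairs = []
            for tri in sel:
                key = tuple(sorted(int(v) for v in tri))
                if key not in face_map:
                    raise MeshError(f"facet set {name!r} references a non-mesh face")
                pairs.append(face_map[key])
            mesh.facet_sets[name] = (
                np.array(pairs, dtype=np.int64) if pairs else np.empty((0, 2), dtype=np.int64)
            )
    if require_canonical:
        missing = [n for n in CANONICAL_FACET_SETS if n not in mesh.facet_sets]
        if missing:
            raise MeshError(f"missing facet sets: {missing}")
    cell_out = {
        k: (v[tet_mask] if v.shape[0] == types.shape[0] else v)
        for k, v in cdata.items()
        if k not in ("domain", "facet_set")
    }
    return mesh, cell_out, pdata
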