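"""Minimal legacy-VTK (ASCII ``vtk DataFile Version 3.0``) unstructured-grid IO.

Only the subset needed by this package is supported: tetrahedral cells
(VTK cell type 10), point data and cell data as SCALARS (float/int) or
VECTORS (float).  Files are plain text so meshes remain diff-able and
portable.
"""

from __future__ import annotations

import numpy as np

_CELL_TET = 10


def write_vtk(path, points, cells, point_data=None, cell_data=None, title="cardiotwin mesh"):
    """Write a tetrahedral unstructured grid to a legacy ASCII .vtk file.

    Parameters
    ----------
    points : (n, 3) float array, coordinates in mm.
    cells : (m, 4) int array of tetrahedron node indices.
    point_data, cell_data : dict of name -> (n,) or (n, 3) arrays.
    """
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title.replace("\n", " ") + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt="%.9g")
        fh.write(f"CELLS {len(cells)} {len(cells) * 5}\n")
        np.savetxt(fh, np.column_stack([np.full(len(cells), 4), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), _CELL_TET), fmt="%d")
        for keyword, data, n in (("POINT_DATA", point_data, len(points)),
                                 ("CELL_DATA", cell_data, len(cells))):
            if not data:
                continue
            fh.write(f"{keyword} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")
                else:
                    kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%d" if kind == "int" else "%.9g")


class _Cursor:
    def __init__(self, tokens):
        self.toks = tokens
        self.i = 0

    def peek(self):
        return self.toks[self.i].upper() if self.i < len(self.toks) else None

    def take(self, n=1):
        out = self.toks[self.i:self.i + n]
        self.i += n
        return out

    def take_array(self, n, dtype):
        return np.array(self.take(n), dtype=dtype)

    def seek(self, word):
        while self.i < len(self.toks) and self.toks[self.i].upper() != word:
            self.i += 1
        return self.i < len(self.toks)


def _read_attributes(cur, n, store):
    """Parse consecutive SCALARS/VECTORS entries."""
    while True:
        tok = cur.peek()
        if tok == "SCALARS":
            _, name, kind, _ncomp = cur.take(4)
            if cur.peek() == "LOOKUP_TABLE":
                cur.take(2)
            dtype = int if kind.lower() in ("int", "long", "short") else float
            store[name] = cur.take_array(n, dtype)
        elif tok == "VECTORS":
            _, name, _kind = cur.take(3)
            store[name] = cur.take_array(3 * n, float).reshape(n, 3)
        else:
            return


def read_vtk(path):
    """Read a legacy ASCII tetrahedral .vtk file written by :func:`write_vtk`.

    Returns ``(points, cells, point_data, cell_data)``.
    """
    with open(path) as fh:
        cur = _Cursor(fh.read().split())
    if not cur.seek("POINTS"):
        raise ValueError(f"{path}: no POINTS block")
    n_pts = int(cur.take(3)[1])
    points = cur.take_array(3 * n_pts, float).reshape(n_pts, 3)
    if not cur.seek("CELLS"):
        raise ValueError(f"{path}: no CELLS block")
    n_cells = int(cur.take(3)[1])
    raw = cur.take_array(5 * n_cells, int).reshape(n_cells, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError(f"{path}: only tetrahedral cells are supported")
    cells = raw[:, 1:]

    point_data, cell_data = {}, {}
    while cur.peek() is not None:
        tok = cur.peek()
        if tok == "POINT_DATA":
            cur.take(2)
            _read_attributes(cur, n_pts, point_data)
        elif tok == "CELL_DATA":
            cur.take(2)
            _read_attributes(cur, n_cells, cell_data)
        else:
            cur.take(1)
    return points, cells, point_data, cell_data
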