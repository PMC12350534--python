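"""Minimal PLY point-cloud reader/writer.

Supports ascii and binary-little-endian PLY with float32/float64 vertex
coordinates, optional nx/ny/nz normals and an optional uchar ``label``
channel whose code->name mapping travels in header comments
(``comment label <code> <name>``). Point order is preserved and a binary
write/read cycle round-trips bit-exact. Big-endian files are rejected
explicitly rather than silently misread; unknown elements are skipped with
a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import FormatError

__all__ = ["read_ply", "write_ply"]

_DTYPES = {
    "float": np.dtype("<f4"),
    "float32": np.dtype("<f4"),
    "double": np.dtype("<f8"),
    "float64": np.dtype("<f8"),
    "uchar": np.dtype("u1"),
    "uint8": np.dtype("u1"),
    "char": np.dtype("i1"),
    "int8": np.dtype("i1"),
    "short": np.dtype("<i2"),
    "ushort": np.dtype("<u2"),
    "int": np.dtype("<i4"),
    "int32": np.dtype("<i4"),
    "uint": np.dtype("<u4"),
    "uint32": np.dtype("<u4"),
}


def write_ply(path, points, normals=None, labels=None, binary: bool = True) -> None:
    """Write a point cloud.

    ``labels`` may be an array of strings; distinct values are coded as
    uchar with the mapping recorded in header comments.
    """
    pts = np.asarray(points, dtype="<f8")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FormatError(f"points must be (N, 3), got {pts.shape}")
    n = len(pts)
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0"]
    label_codes = None
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise FormatError("labels length mismatch")
        names = sorted(set(labels.tolist()))
        if len(names) > 255:
            raise FormatError("more than 255 distinct labels")
        label_codes = np.array([names.index(v) for v in labels.tolist()], dtype="u1")
        for code, name in enumerate(names):
            header.append(f"comment label {code} {name}")
    header.append(f"element vertex {n}")
    for prop in ("x", "y", "z"):
        header.append(f"property double {prop}")
    if normals is not None:
        normals = np.asarray(normals, dtype="<f8")
        if normals.shape != pts.shape:
            raise FormatError("normals shape mismatch")
        for prop in ("nx", "ny", "nz"):
            header.append(f"property double {prop}")
    if labels is not None:
        header.append("property uchar label")
    header.append("end_header")

    cols = [pts]
    if normals is not None:
        cols.append(normals)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [("xyz", "<f8", 3)]
            if normals is not None:
                fields.append(("n", "<f8", 3))
            if label_codes is not None:
                fields.append(("label", "u1"))
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["xyz"] = pts
            if normals is not None:
                rec["n"] = normals
            if label_codes is not None:
                rec["label"] = label_codes
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                parts = [f"{v:.17g}" for v in pts[i]]
                if normals is not None:
                    parts += [f"{v:.17g}" for v in normals[i]]
                if label_codes is not None:
                    parts.append(str(int(label_codes[i])))
                fh.write((" ".join(parts) + "\n").encode("ascii"))


def read_ply(path):
    """Read a point cloud.

    Returns ``(points, normals, labels)``; normals/labels are None when the
    file has no such properties.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    # -- header ----------------------------------------------------------
    end = data.find(b"end_header")
    if end < 0:
        raise FormatError(f"{path}: no end_header")
    header_bytes = data[: data.find(b"\n", end) + 1]
    body = data[len(header_bytes) :]
    lines = header_bytes.decode("ascii", errors="replace").splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}: line 1: missing 'ply' magic")
    fmt = None
    n_vertex = None
    props = []  # (name, dtype) for the vertex element
    label_names = {}
    current_element = None
    skipped = []
    for lineno, line in enumerate(lines[1:], start=2):
        tok = line.strip().split()
        if not tok or tok[0] == "end_header":
            continue
        if tok[0] == "comment":
            if len(tok) == 4 and tok[1] == "label":
                label_names[int(tok[2])] = tok[3]
            continue
        if tok[0] == "format":
            if tok[1] == "binary_big_endian":
                raise FormatError(f"{path}: line {lineno}: big-endian PLY is not supported")
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise FormatError(f"{path}: line {lineno}: unknown format {tok[1]!r}")
            fmt = tok[1]
        elif tok[0] == "element":
            current_element = tok[1]
            if tok[1] == "vertex":
                n_vertex = int(tok[2])
            else:
                skipped.append(tok[1])
        elif tok[0] == "property":
            if current_element != "vertex":
                continue
            if tok[1] == "list":
                raise FormatError(f"{path}: line {lineno}: list properties not supported")
            if tok[1] not in _DTYPES:
                raise FormatError(f"{path}: line {lineno}: unknown type {tok[1]!r}")
            props.append((tok[2], _DTYPES[tok[1]]))
        else:
            raise FormatError(f"{path}: line {lineno}: unexpected token {tok[0]!r}")
    if fmt is None or n_vertex is None:
        raise FormatError(f"{path}: header missing format or vertex element")
    if skipped:
        warnings.warn(f"{path}: skipping unknown PLY elements {skipped}")
    names = [p[0] for p in props]
    for needed in ("x", "y", "z"):
        if needed not in names:
            raise FormatError(f"{path}: vertex element lacks property {needed!r}")

    # -- body ------------------------------------------------------------
    rec_dtype = np.dtype([(name, dt) for name, dt in props])
    if fmt == "binary_little_endian":
        need = rec_dtype.itemsize * n_vertex
        if len(body) < need:
            raise FormatError(f"{path}: truncated body ({len(body)} < {need} bytes)")
        rec = np.frombuffer(body[:need], dtype=rec_dtype)
    else:
        text_rows = body.decode("ascii").split("\n")
        rows = [r.split() for r in text_rows if r.strip()][:n_vertex]
        if len(rows) < n_vertex:
            raise FormatError(f"{path}: expected {n_vertex} vertices, found {len(rows)}")
        rec = np.zeros(n_vertex, dtype=rec_dtype)
        arr = np.array(rows, dtype=object)
        for col, (name, dt) in enumerate(props):
            rec[name] = arr[:, col].astype(dt)

    pts = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    normals = None
    if all(k in names for k in ("nx", "ny", "nz")):
        normals = np.column_stack([rec["nx"], rec["ny"], rec["nz"]]).astype(float)
    labels = None
    if "label" in names:
        codes = rec["label"]
        if label_names:
            lut = np.array([label_names.get(i, str(i)) for i in range(256)])
            labels = lut[codes]
        else:
            labels = codes.copy()
    return pts, normals, labels
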