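"""Plain-text coordinate file formats.

Two layouts are supported for per-minimum coordinates:

* ``xyz`` — concatenated XYZ-like blocks: a bead-count line, a comment line
  (free text, conventionally carrying the energy), then one ``LABEL x y z``
  row per bead.
* ``flat`` — one line of 3N whitespace-separated numbers per structure.
"""
from __future__ import annotations

import numpy as np

from .geometry import as_coords

__all__ = ["read_xyz", "write_xyz", "read_flat_coords", "write_flat_coords",
           "read_coords", "write_coords"]

_FLOAT_FMT = "{:.17g}"


def write_xyz(path, frames) -> None:
    """Write structures as XYZ blocks.

    ``frames`` is an iterable of ``(labels, coords, comment)`` where
    ``labels`` is a per-bead sequence of element-column strings (a single
    string is broadcast to every bead).
    """
    with open(path, "w") as fh:
        for labels, coords, comment in frames:
            coords = as_coords(coords)
            n = coords.shape[0]
            if isinstance(labels, str) and len(labels) != n:
                labels = [labels] * n
            fh.write(f"{n}\n{comment}\n")
            for lab, (x, y, z) in zip(labels, coords):
                fh.write(f"{lab} {_FLOAT_FMT.format(x)} "
                         f"{_FLOAT_FMT.format(y)} {_FLOAT_FMT.format(z)}\n")


def read_xyz(path):
    """Read XYZ blocks; returns a list of ``(labels, coords, comment)``."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected a bead count, "
                             f"got {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise ValueError(f"{path}:{i + 1}: truncated block of {n} beads")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        labels, rows = [], []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{i + 3 + k}: expected 'LABEL x y z'")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        frames.append((labels, np.array(rows), comment))
        i += 2 + n
    return frames


def write_flat_coords(path, coords_list) -> None:
    with open(path, "w") as fh:
        for coords in coords_list:
            flat = as_coords(coords).ravel()
            fh.write(" ".join(_FLOAT_FMT.format(v) for v in flat) + "\n")


def read_flat_coords(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            vals = [float(v) for v in line.split()]
            if len(vals) % 3:
                raise ValueError(f"{path}:{lineno}: {len(vals)} values is not 3N")
            out.append(np.array(vals).reshape(-1, 3))
    return out


def read_coords(path, fmt: str = "auto"):
    """Read either coordinate layout; returns a list of (n, 3) arrays."""
    if fmt == "auto":
        with open(path) as fh:
            first = ""
            for line in fh:
                if line.strip():
                    first = line.strip()
                    break
        fmt = "xyz" if len(first.split()) == 1 else "flat"
    if fmt == "xyz":
        return [coords for _, coords, _ in read_xyz(path)]
    if fmt == "flat":
        return read_flat_coords(path)
    raise ValueError(f"unknown coordinates format {fmt!r}")


def write_coords(path, coords_list, fmt: str = "flat", labels="X",
                 comments=None) -> None:
    if fmt == "flat":
        write_flat_coords(path, coords_list)
    elif fmt == "xyz":
        if comments is None:
            comments = ["" for _ in coords_list]
        write_xyz(path, [(labels, c, com) for c, com in zip(coords_list, comments)])
    else:
        raise ValueError(f"unknown coordinates format {fmt!r}")
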