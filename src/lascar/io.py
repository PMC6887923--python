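"""File formats: NIfTI volumes, VTK/PLY shells, JSON and CSV artefacts.

Shells travel as legacy ASCII VTK polydata with named per-vertex scalar
arrays (``vertex_si``, ``include_mask``, ``vertex_area``) — written and
parsed here because no dependency of this package speaks that format —
or as PLY (geometry only, via trimesh) for viewers.  All round trips are
lossless for the arrays named above; lengths are millimetres throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .shellmap import AtrialShell, IntensityVolume


class ParseError(ValueError):
    """Malformed artefact file."""


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_nifti(vol: IntensityVolume, path) -> None:
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def read_nifti(path) -> IntensityVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in affine[:3, 3])
    return IntensityVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)


# ---------------------------------------------------------------------------
# shells: legacy ASCII VTK polydata with POINT_DATA arrays
# ---------------------------------------------------------------------------

def write_shell_vtk(shell: AtrialShell, path) -> None:
    p = Path(path)
    lines = ["# vtk DataFile Version 3.0", "atrial shell", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(shell.vertices)} float"]
    lines += [" ".join(f"{c:.8g}" for c in v) for v in shell.vertices]
    nf = len(shell.faces)
    lines.append(f"POLYGONS {nf} {4 * nf}")
    lines += ["3 " + " ".join(str(int(i)) for i in f) for f in shell.faces]
    lines.append(f"POINT_DATA {len(shell.vertices)}")
    arrays = {"include_mask": shell.include_mask.astype(int),
              "vertex_area": shell.vertex_area}
    if shell.vertex_si is not None:
        arrays["vertex_si"] = shell.vertex_si
    for name, arr in arrays.items():
        dtype = "int" if arr.dtype.kind in "iub" else "float"
        lines.append(f"SCALARS {name} {dtype} 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.10g}" if dtype == "float" else str(int(v)) for v in arr]
    p.write_text("\n".join(lines) + "\n")


def read_shell_vtk(path) -> AtrialShell:
    tokens = Path(path).read_text().split("\n")
    it = iter(enumerate(tokens))

    def fail(lineno, msg):
        raise ParseError(f"{path}:{lineno + 1}: {msg}")

    verts = faces = None
    arrays: dict[str, np.ndarray] = {}
    i = 0
    try:
        while i < len(tokens):
            line = tokens[i].strip()
            if line.startswith("POINTS"):
                n = int(line.split()[1])
                verts = np.array([[float(x) for x in tokens[i + 1 + k].split()]
                                  for k in range(n)])
                i += n + 1
            elif line.startswith("POLYGONS"):
                n = int(line.split()[1])
                faces = np.array([[int(x) for x in tokens[i + 1 + k].split()[1:]]
                                  for k in range(n)], dtype=np.int64)
                i += n + 1
            elif line.startswith("SCALARS"):
                name, kind = line.split()[1:3]
                if not tokens[i + 1].startswith("LOOKUP_TABLE"):
                    fail(i + 1, f"expected LOOKUP_TABLE after SCALARS {name}")
                n = len(verts)
                conv = float if kind == "float" else int
                arrays[name] = np.array(
                    [conv(tokens[i + 2 + k]) for k in range(n)])
                i += n + 2
            else:
                i += 1
    except (IndexError, ValueError) as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: truncated or malformed near line {i + 1}: "
                         f"{exc}") from exc
    if verts is None or faces is None:
        raise ParseError(f"{path}: missing POINTS or POLYGONS section")
    include = arrays.get("include_mask")
    return AtrialShell(verts, faces, arrays.get("vertex_si"),
                       None if include is None else include.astype(bool))


def write_shell_ply(shell: AtrialShell, path) -> None:
    shell.trimesh.export(str(path))


# ---------------------------------------------------------------------------
# JSON / CSV artefacts
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True)
                          + "\n")


def read_json(path):
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at offset {exc.pos}") from exc


def read_seed_points(path, shell: AtrialShell | None = None) -> dict:
    """Seed file: {"left": [...], "right": [...]} of vertex indices, or of
    mm points snapped to the nearest included vertex when a shell is given."""
    data = read_json(path)
    out = {}
    for side in ("left", "right"):
        if side not in data:
            raise ParseError(f"{path}: missing '{side}' seed list")
        entries = data[side]
        if entries and isinstance(entries[0], (list, tuple)):
            if shell is None:
                raise ValueError("mm seed points require a shell to snap to")
            idx = []
            inc = np.flatnonzero(shell.include_mask)
            for p in entries:
                d = np.linalg.norm(shell.vertices[inc] - np.asarray(p, float),
                                   axis=1)
                idx.append(int(inc[np.argmin(d)]))
            out[side] = np.asarray(idx)
        else:
            out[side] = np.asarray([int(i) for i in entries])
    return out


COHORT_CSV_COLUMNS = ["subject_id", "group", "true_burden", "true_width_left",
                      "true_width_right", "complete_left", "complete_right"]


def write_cohort_truth_csv(subjects, path) -> None:
    rows = []
    for s in subjects:
        gt = s.ground_truth
        rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "true_burden": gt.true_burden_fraction,
            "true_width_left": gt.true_width_per_loop["left"],
            "true_width_right": gt.true_width_per_loop["right"],
            "complete_left": gt.complete_left,
            "complete_right": gt.complete_right,
        })
    pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS).to_csv(path, index=False)


def write_records_csv(records, path) -> None:
    from dataclasses import asdict
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("complete_left", "complete_right", "complete_bilateral"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
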