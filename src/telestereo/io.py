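"""Standard-format I/O: PLY point clouds, image stacks, YAML configs.

PLY is the interchange format for clouds (ASCII primary, little-endian
binary accepted on read) so results open directly in common cloud
viewers; the per-point correlation is stored as a named float property
``score`` so quality thresholds remain reproducible downstream.  Unknown
float properties found on read are kept and exposed by name.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np
import yaml

from .camera import TelecentricCamera
from .fitting import PointCloud
from .synthetic import ImageStack

__all__ = [
    "PlyParseError",
    "read_ply",
    "write_ply",
    "read_stack",
    "write_stack",
    "write_manifest",
    "read_manifest",
]


class PlyParseError(ValueError):
    def __init__(self, msg: str, line: int | None = None):
        super().__init__(f"line {line}: {msg}" if line is not None else msg)
        self.line = line


_PLY_TYPES = {
    "float": ("f", 4, float), "float32": ("f", 4, float),
    "double": ("d", 8, float), "float64": ("d", 8, float),
    "uchar": ("B", 1, int), "uint8": ("B", 1, int),
    "char": ("b", 1, int), "int8": ("b", 1, int),
    "short": ("h", 2, int), "int16": ("h", 2, int),
    "ushort": ("H", 2, int), "uint16": ("H", 2, int),
    "int": ("i", 4, int), "int32": ("i", 4, int),
    "uint": ("I", 4, int), "uint32": ("I", 4, int),
}


def write_ply(cloud: PointCloud, path) -> None:
    """Write a cloud as ASCII PLY: x, y, z (+ color, + score)."""
    has_color = cloud.color is not None
    lines = [
        "ply",
        "format ascii 1.0",
        "comment telestereo point cloud (mm)",
        f"element vertex {len(cloud)}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if has_color:
        lines += ["property uchar red", "property uchar green",
                  "property uchar blue"]
    lines += ["property float score", "end_header"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        rgb = None
        if has_color:
            rgb = np.clip(np.rint(cloud.color * 255), 0, 255).astype(int)
        # scores are declared 'float' (32-bit): emit the float32 value at
        # full precision so a read-back reproduces it exactly
        score32 = cloud.score.astype(np.float32)
        for i, (p, s) in enumerate(zip(cloud.points, score32)):
            row = f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
            if has_color:
                row += f" {rgb[i, 0]} {rgb[i, 1]} {rgb[i, 2]}"
            fh.write(row + f" {s:.9g}\n")


def read_ply(path) -> PointCloud:
    """Read an ASCII or little-endian binary PLY into a PointCloud.

    Requires float x, y, z vertex properties.  A ``score`` property (or
    ``scalar_score`` as some viewers rename it) populates the quality
    channel; red/green/blue populate color; any other scalar properties
    are ignored for the cloud but parsed for consistency checks.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    # --- header ---
    try:
        header_end = data.index(b"end_header")
    except ValueError:
        raise PlyParseError("missing end_header") from None
    nl = data.index(b"\n", header_end)
    header = data[:nl].decode("ascii", errors="replace").splitlines()
    body = data[nl + 1:]
    if not header or header[0].strip() != "ply":
        raise PlyParseError("not a PLY file (missing 'ply' magic)", line=1)
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for ln, raw in enumerate(header[1:], start=2):
        tok = raw.strip().split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
            if fmt not in ("ascii", "binary_little_endian"):
                raise PlyParseError(f"unsupported format {fmt!r}", line=ln)
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                try:
                    n_vertex = int(tok[2])
                except (IndexError, ValueError):
                    raise PlyParseError("bad vertex count", line=ln) from None
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyParseError("list property on vertex unsupported",
                                    line=ln)
            if tok[1] not in _PLY_TYPES:
                raise PlyParseError(f"unknown property type {tok[1]!r}",
                                    line=ln)
            props.append((tok[2], tok[1]))
    if fmt is None:
        raise PlyParseError("missing format line")
    if n_vertex is None:
        raise PlyParseError("missing 'element vertex' declaration")
    names = [p[0] for p in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PlyParseError(f"vertex property {axis!r} missing")

    n_props = len(props)
    if fmt == "ascii":
        text = body.decode("ascii", errors="replace").splitlines()
        rows = [r for r in text if r.strip()]
        if len(rows) < n_vertex:
            raise PlyParseError(
                f"declared {n_vertex} vertices but found {len(rows)}",
                line=len(header) + 1 + len(rows))
        table = np.empty((n_vertex, n_props))
        hdr_lines = len(header) + 1
        for i in range(n_vertex):
            vals = rows[i].split()
            if len(vals) != n_props:
                raise PlyParseError(
                    f"expected {n_props} values, got {len(vals)}",
                    line=hdr_lines + i)
            try:
                table[i] = [float(v) for v in vals]
            except ValueError:
                raise PlyParseError("non-numeric vertex data",
                                    line=hdr_lines + i) from None
    else:
        fmt_str = "<" + "".join(_PLY_TYPES[t][0] for _, t in props)
        rec = struct.calcsize(fmt_str)
        if len(body) < rec * n_vertex:
            raise PlyParseError(
                f"binary body too short for {n_vertex} vertices")
        table = np.array(
            [struct.unpack_from(fmt_str, body, i * rec)
             for i in range(n_vertex)], dtype=float
        ).reshape(n_vertex, n_props)

    col = {name: table[:, i] for i, (name, _) in enumerate(props)}
    pts = np.column_stack([col["x"], col["y"], col["z"]])
    score = None
    for key in ("score", "scalar_score", "scalar_Score"):
        if key in col:
            score = np.clip(col[key], -1.0, 1.0)
            break
    color = None
    if all(k in col for k in ("red", "green", "blue")):
        color = np.column_stack([col["red"], col["green"], col["blue"]]) / 255.0
    gap = col.get("gap")
    return PointCloud(pts, score=score, color=color, gap=gap)


# ----------------------------------------------------------------------
# image stacks
# ----------------------------------------------------------------------

def _to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32))


def read_stack(path, camera_id: str | None = None) -> ImageStack:
    """Read a multi-page TIFF, or a directory of ordered PNG/TIFF frames.

    Integer frames are normalized to [0, 1] by their dtype's full range;
    float frames are taken as-is.  All frames must share one shape.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".png", ".tif", ".tiff"))
        )
        if not files:
            raise FileNotFoundError(f"no frames in {path}")
        frames = []
        for f in files:
            img = np.asarray(iio.imread(path / f))
            if img.ndim == 3:  # collapse RGB to luminance
                img = img.mean(axis=2).astype(img.dtype)
            frames.append(_to_unit(img))
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        arr = _to_unit(arr)
    return ImageStack(frames=arr, camera_id=camera_id or path.stem)


# ----------------------------------------------------------------------
# manifests / configs
# ----------------------------------------------------------------------

def write_manifest(path, cam1: TelecentricCamera, cam2: TelecentricCamera,
                   projector=None, seed: int | None = None,
                   extra: dict | None = None) -> None:
    doc = {"units": {"length": "mm", "angle": "deg"},
           "camera1": cam1.to_dict(), "camera2": cam2.to_dict()}
    if projector is not None:
        doc["projector"] = {
            "direction": [float(v) for v in projector.direction],
            "up": [float(v) for v in projector.up],
            "pattern_pitch_mm": float(projector.pattern_pitch),
        }
    if seed is not None:
        doc["seed"] = int(seed)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = dict(doc)
    if "camera1" in doc:
        out["camera1"] = TelecentricCamera.from_dict(doc["camera1"])
    if "camera2" in doc:
        out["camera2"] = TelecentricCamera.from_dict(doc["camera2"])
    return out
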