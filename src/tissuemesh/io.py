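"""Readers and writers: labeled images (TIFF, INR) and meshes (PLY, OBJ, VTK).

Conventions: image arrays are (z, y, x); world coordinates are in μm with the
same axis order, voxel centre at (index + 0.5) · voxel_size.  Mesh files use
the native x, y, z order of each format (so ``x = world[2]`` etc.); PLY and
VTK carry the per-triangle interface labels (two integer cell ids, exterior
= 0) and the per-vertex corner/surface/pinned flags, and a PLY round-trip is
lossless up to float precision.  OBJ cannot carry labels and drops them with
a warning.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

from .image_adjacency import SegmentedImage
from .stem import TissueMesh

logger = logging.getLogger(__name__)

__all__ = [
    "read_labeled_image",
    "write_labeled_image",
    "read_mesh",
    "write_mesh",
]


# ---------------------------------------------------------------------------
# labeled images
# ---------------------------------------------------------------------------


def read_labeled_image(path, voxel_size: Optional[Tuple[float, float, float]]
                       = None, background_label: int = 1) -> SegmentedImage:
    """Read a segmented 3D image from multi-page TIFF or INR.

    Voxel size comes from file metadata; a ``voxel_size`` argument overrides
    it, and its absence in both places is an error.  Non-integer pixel types
    are rejected — a segmentation is a label field.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta_vs = _tiff_voxel_size(tif)
    elif path.suffix.lower() in (".inr", ".inr.gz"):
        data, meta_vs = _read_inr(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(
            f"segmented image must have an integer pixel type, got "
            f"{data.dtype}")
    vs = voxel_size or meta_vs
    if vs is None:
        raise ValueError(
            f"{path}: no voxel size in metadata and no override given")
    return SegmentedImage(data.astype(np.int32), tuple(vs), background_label)


def _tiff_voxel_size(tif) -> Optional[Tuple[float, float, float]]:
    try:
        page = tif.pages[0]
        ij = tif.imagej_metadata or {}
        spacing = ij.get("spacing")
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if spacing is None or xres is None or yres is None:
            return None
        vx = xres.value[1] / xres.value[0]
        vy = yres.value[1] / yres.value[0]
        return (float(spacing), float(vy), float(vx))
    except Exception:
        return None


def write_labeled_image(image: SegmentedImage, path) -> None:
    """Write a segmented image; the round-trip restores labels exactly."""
    path = Path(path)
    vz, vy, vx = image.voxel_size
    if path.suffix.lower() in (".tif", ".tiff"):
        data = image.labels
        if data.min() >= 0 and data.max() < 2 ** 16:
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.int32)
        tifffile.imwrite(
            path, data, imagej=True,
            resolution=(1.0 / vx, 1.0 / vy),
            metadata={"spacing": vz, "unit": "um", "axes": "ZYX"})
    elif path.suffix.lower() == ".inr":
        _write_inr(image, path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def _write_inr(image: SegmentedImage, path) -> None:
    data = image.labels.astype(np.uint32)
    zdim, ydim, xdim = data.shape
    vz, vy, vx = image.voxel_size
    header = (
        f"#INRIMAGE-4#{{\n"
        f"XDIM={xdim}\nYDIM={ydim}\nZDIM={zdim}\nVDIM=1\n"
        f"TYPE=unsigned fixed\nPIXSIZE=32 bits\nCPU=decm\nSCALE=2**0\n"
        f"VX={vx}\nVY={vy}\nVZ={vz}\n")
    pad = 256 - len(header) - 4
    header += "\n" * pad + "##}\n"
    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        # INR is x-fastest, like our (z, y, x) C-order array
        f.write(data.astype("<u4").tobytes())


def _read_inr(path):
    with open(path, "rb") as f:
        header = f.read(256).decode("ascii", errors="replace")
        fields = {}
        for line in header.splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                fields[k.strip()] = v.strip()
        xdim, ydim, zdim = (int(fields[k]) for k in ("XDIM", "YDIM", "ZDIM"))
        pixsize = int(fields.get("PIXSIZE", "32 bits").split()[0])
        kind = fields.get("TYPE", "unsigned fixed")
        if "float" in kind:
            raise TypeError("INR file with float pixels is not a label image")
        dtype = {8: "u1", 16: "<u2", 32: "<u4", 64: "<u8"}[pixsize]
        if "signed" in kind and not kind.startswith("unsigned"):
            dtype = dtype.replace("u", "i")
        count = xdim * ydim * zdim
        data = np.frombuffer(f.read(), dtype=dtype, count=count)
        data = data.reshape(zdim, ydim, xdim)
        vs = None
        if all(k in fields for k in ("VX", "VY", "VZ")):
            vs = (float(fields["VZ"]), float(fields["VY"]),
                  float(fields["VX"]))
        return data, vs


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def write_mesh(mesh: TissueMesh, path, format: Optional[str] = None) -> None:
    """Write a tissue mesh as PLY (lossless), VTK legacy, or OBJ.

    PLY and VTK store the interface label pair per triangle and the
    corner/surface/pinned flags per vertex; OBJ stores geometry only and
    logs a warning about the dropped labels.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply(mesh, path)
    elif fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "obj":
        logger.warning("OBJ cannot store interface labels; they are dropped "
                       "(use PLY or VTK to keep them)")
        _write_obj(mesh, path)
    else:
        raise ValueError(
            f"unsupported mesh format {fmt!r}; use PLY or VTK for labelled "
            f"tissue meshes")


def read_mesh(path) -> TissueMesh:
    """Read a tissue mesh written by :func:`write_mesh` (PLY only)."""
    path = Path(path)
    if path.suffix.lower() != ".ply":
        raise ValueError("only PLY round-trips tissue meshes with labels")
    return _read_ply(path)


def _write_ply(mesh: TissueMesh, path) -> None:
    v = mesh.vertices
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write("comment tissuemesh; coordinates in um; "
                "file x,y,z = world x,y,z (array order z,y,x reversed)\n")
        f.write(f"element vertex {len(v)}\n")
        for name in ("x", "y", "z"):
            f.write(f"property double {name}\n")
        for name in ("is_corner", "is_surface", "pinned"):
            f.write(f"property uchar {name}\n")
        f.write(f"element face {mesh.n_triangles()}\n")
        f.write("property list uchar int vertex_indices\n")
        f.write("property int label1\nproperty int label2\n")
        f.write("end_header\n")
        for i in range(len(v)):
            f.write("%.17g %.17g %.17g %d %d %d\n" % (
                v[i, 2], v[i, 1], v[i, 0],
                int(mesh.is_corner[i]), int(mesh.is_surface[i]),
                int(mesh.pinned[i])))
        for ti in range(mesh.n_triangles()):
            a, b, c = (int(x) for x in mesh.triangles[ti])
            l1, l2 = (int(x) for x in mesh.tri_labels[ti])
            f.write(f"3 {a} {b} {c} {l1} {l2}\n")


def _read_ply(path) -> TissueMesh:
    with open(path) as f:
        line = f.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        vert_props = []
        element = None
        for line in f:
            line = line.strip()
            if line.startswith("element vertex"):
                n_vert = int(line.split()[-1])
                element = "vertex"
            elif line.startswith("element face"):
                n_face = int(line.split()[-1])
                element = "face"
            elif line.startswith("property") and element == "vertex":
                vert_props.append(line.split()[-1])
            elif line == "end_header":
                break
        verts = np.zeros((n_vert, 3))
        flags = np.zeros((n_vert, 3), dtype=bool)
        idx = {name: i for i, name in enumerate(vert_props)}
        for i in range(n_vert):
            parts = f.readline().split()
            x, y, z = (float(parts[idx[n]]) for n in ("x", "y", "z"))
            verts[i] = (z, y, x)
            for j, name in enumerate(("is_corner", "is_surface", "pinned")):
                if name in idx:
                    flags[i, j] = bool(int(parts[idx[name]]))
        tris = np.zeros((n_face, 3), dtype=np.int64)
        labels = np.zeros((n_face, 2), dtype=np.int64)
        for i in range(n_face):
            parts = f.readline().split()
            k = int(parts[0])
            if k != 3:
                raise ValueError("tissue meshes are triangular")
            tris[i] = [int(x) for x in parts[1:4]]
            if len(parts) >= 6:
                labels[i] = [int(parts[4]), int(parts[5])]
    return TissueMesh(verts, tris, labels, flags[:, 0], flags[:, 1],
                      flags[:, 2])


def _write_vtk(mesh: TissueMesh, path) -> None:
    v = mesh.vertices
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("tissuemesh triangular tissue mesh (um)\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(v)} double\n")
        for i in range(len(v)):
            f.write("%.17g %.17g %.17g\n" % (v[i, 2], v[i, 1], v[i, 0]))
        n = mesh.n_triangles()
        f.write(f"POLYGONS {n} {4 * n}\n")
        for ti in range(n):
            a, b, c = (int(x) for x in mesh.triangles[ti])
            f.write(f"3 {a} {b} {c}\n")
        f.write(f"CELL_DATA {n}\n")
        for col, name in ((0, "label1"), (1, "label2")):
            f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(x)) for x in mesh.tri_labels[:, col]))
            f.write("\n")
        f.write(f"POINT_DATA {len(v)}\n")
        for arr, name in ((mesh.is_corner, "is_corner"),
                          (mesh.is_surface, "is_surface"),
                          (mesh.pinned, "pinned")):
            f.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(x)) for x in arr))
            f.write("\n")


def _write_obj(mesh: TissueMesh, path) -> None:
    with open(path, "w") as f:
        f.write("# tissuemesh OBJ export (labels dropped)\n")
        for p in mesh.vertices:
            f.write("v %.17g %.17g %.17g\n" % (p[2], p[1], p[0]))
        for t in mesh.triangles:
            f.write("f %d %d %d\n" % (t[0] + 1, t[1] + 1, t[2] + 1))
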