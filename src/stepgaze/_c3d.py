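"""Minimal C3D point-data reader and writer (Intel byte order).

Covers the subset of the C3D standard needed to exchange labelled marker
trajectories: the 512-byte header, the parameter section (POINT group) and
the 3-D point data section in either floating-point or scaled-integer
representation.  No analog channels, no event section.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Sequence

import numpy as np

BLOCK = 512
PROC_INTEL = 84


class C3DError(ValueError):
    """Raised for files this reader cannot interpret."""


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_c3d_points(path: Path):
    """Return ``(labels, points, rate, units)`` from a C3D file.

    ``points`` has shape ``(n_frames, n_points, 3)`` in the file's native
    units and axes; invalid points (negative residual) are NaN.
    """
    data = path.read_bytes()
    if len(data) < BLOCK:
        raise C3DError(f"{path.name}: truncated file")
    param_block, magic = data[0], data[1]
    if magic != 0x50:
        raise C3DError(f"{path.name}: not a C3D file (magic {magic:#x})")

    n_points = struct.unpack_from("<H", data, 2)[0]
    first_frame = struct.unpack_from("<H", data, 6)[0]
    last_frame = struct.unpack_from("<H", data, 8)[0]
    scale = struct.unpack_from("<f", data, 12)[0]
    data_block = struct.unpack_from("<H", data, 16)[0]
    rate = struct.unpack_from("<f", data, 20)[0]
    n_frames = last_frame - first_frame + 1

    params = _read_params(data, param_block, path)
    labels = params.get(("POINT", "LABELS"))
    if labels is None:
        raise C3DError(f"{path.name}: POINT:LABELS missing (unlabelled points)")
    labels = [lab.strip() for lab in labels][:n_points]
    if any(not lab for lab in labels):
        raise C3DError(f"{path.name}: blank point label")
    units = params.get(("POINT", "UNITS"), "mm")
    if isinstance(units, list):
        units = units[0]
    if ("POINT", "SCALE") in params:
        scale = float(np.ravel(params[("POINT", "SCALE")])[0])
    if ("POINT", "RATE") in params:
        rate = float(np.ravel(params[("POINT", "RATE")])[0])

    off = (data_block - 1) * BLOCK
    if scale < 0:  # floating-point data
        raw = np.frombuffer(
            data, dtype="<f4", count=n_frames * n_points * 4, offset=off
        ).reshape(n_frames, n_points, 4)
        points = raw[:, :, :3].astype(float)
        residual = raw[:, :, 3]
    else:  # scaled 16-bit integer data
        raw = np.frombuffer(
            data, dtype="<i2", count=n_frames * n_points * 4, offset=off
        ).reshape(n_frames, n_points, 4)
        points = raw[:, :, :3].astype(float) * scale
        residual = raw[:, :, 3].astype(float)
    points = points.copy()
    points[residual < 0] = np.nan
    return labels, points, float(rate), str(units)


def _read_params(data: bytes, param_block: int, path: Path) -> dict:
    """Parse the parameter section into ``{(GROUP, PARAM): value}``."""
    off = (param_block - 1) * BLOCK
    proc = data[off + 3]
    if proc != PROC_INTEL:
        raise C3DError(f"{path.name}: unsupported processor type {proc}")
    pos = off + 4
    groups: dict[int, str] = {}
    raw_params: list[tuple[int, str, int]] = []  # (group_id, name, body_pos)

    while pos < len(data):
        n_name = struct.unpack_from("<b", data, pos)[0]
        if n_name == 0:
            break
        group_id = struct.unpack_from("<b", data, pos + 1)[0]
        name = data[pos + 2 : pos + 2 + abs(n_name)].decode("ascii")
        body = pos + 2 + abs(n_name)
        next_off = struct.unpack_from("<h", data, body)[0]
        if group_id < 0:
            groups[-group_id] = name
        else:
            raw_params.append((group_id, name, body + 2))
        if next_off == 0:
            break
        pos = body + next_off

    out: dict[tuple[str, str], object] = {}
    for group_id, name, body in raw_params:
        etype = struct.unpack_from("<b", data, body)[0]
        ndims = data[body + 1]
        dims = list(data[body + 2 : body + 2 + ndims])
        dpos = body + 2 + ndims
        count = int(np.prod(dims)) if dims else 1
        if etype == -1:  # characters
            width = dims[0] if dims else 1
            n_items = count // width if width else 0
            if ndims <= 1:
                value: object = data[dpos : dpos + count].decode("ascii")
            else:
                value = [
                    data[dpos + i * width : dpos + (i + 1) * width].decode(
                        "ascii"
                    )
                    for i in range(n_items)
                ]
        elif etype == 1:
            value = np.frombuffer(data, "<i1", count, dpos)
        elif etype == 2:
            value = np.frombuffer(data, "<i2", count, dpos)
        elif etype == 4:
            value = np.frombuffer(data, "<f4", count, dpos)
        else:
            continue
        gname = groups.get(group_id)
        if gname is not None:
            out[(gname.upper(), name.upper())] = value
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_c3d_points(
    path: Path,
    labels: Sequence[str],
    points: np.ndarray,
    rate: float,
    units: str = "m",
) -> None:
    """Write labelled points as a float-format Intel C3D file.

    ``points`` has shape ``(n_frames, n_points, 3)`` in ``units``; NaN
    samples are written with residual -1 (invalid).
    """
    points = np.asarray(points, dtype=float)
    n_frames, n_points, _ = points.shape
    if len(labels) != n_points:
        raise ValueError("labels/points mismatch")

    param = _build_param_section(labels, n_frames, rate, units)
    n_param_blocks = (len(param) + BLOCK - 1) // BLOCK
    param = param.ljust(n_param_blocks * BLOCK, b"\x00")
    # patch the parameter-block count now that it is known
    param = param[:2] + bytes([n_param_blocks]) + param[3:]
    data_block = 2 + n_param_blocks

    header = bytearray(BLOCK)
    header[0] = 2  # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)  # analog channels
    struct.pack_into("<H", header, 6, 1)  # first frame
    struct.pack_into("<H", header, 8, n_frames)
    struct.pack_into("<H", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # negative scale = float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 1)  # analog samples per frame
    struct.pack_into("<f", header, 20, float(rate))

    frames = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frames[:, :, :3] = np.nan_to_num(points, nan=0.0)
    invalid = np.isnan(points).any(axis=2)
    frames[:, :, 3] = np.where(invalid, -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param)
        fh.write(frames.tobytes())


def _param_entry(
    name: str, group_id: int, etype: int, dims: list[int], payload: bytes
) -> bytes:
    body = struct.pack("<bb", etype, len(dims)) + bytes(dims) + payload + b"\x00"
    entry = struct.pack("<bb", len(name), group_id) + name.encode("ascii")
    entry += struct.pack("<h", len(body) + 2) + body
    return entry


def _group_entry(name: str, group_id: int) -> bytes:
    entry = struct.pack("<bb", len(name), -group_id) + name.encode("ascii")
    entry += struct.pack("<h", 3) + b"\x00"
    return entry


def _build_param_section(
    labels: Sequence[str], n_frames: int, rate: float, units: str
) -> bytes:
    out = bytearray(struct.pack("<bbbb", 2, 0x50, 1, PROC_INTEL))
    gid = 1
    out += _group_entry("POINT", gid)
    out += _param_entry("USED", gid, 2, [], struct.pack("<h", len(labels)))
    out += _param_entry("FRAMES", gid, 2, [], struct.pack("<h", n_frames))
    out += _param_entry("SCALE", gid, 4, [], struct.pack("<f", -1.0))
    out += _param_entry("RATE", gid, 4, [], struct.pack("<f", float(rate)))
    out += _param_entry(
        "DATA_START", gid, 2, [], struct.pack("<h", 0)
    )  # patched implicitly via header; kept for readers that require it
    width = max(len(lab) for lab in labels)
    payload = b"".join(lab.ljust(width).encode("ascii") for lab in labels)
    out += _param_entry("LABELS", gid, -1, [width, len(labels)], payload)
    u = units.ljust(4).encode("ascii")
    out += _param_entry("UNITS", gid, -1, [len(u)], u)
    out += struct.pack("<bb", 0, 0)  # terminator
    return bytes(out)
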