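"""Reading and writing images in a generic SMV-style format.

SMV images carry a brace-delimited ASCII header (key=value; pairs,
padded to ``HEADER_BYTES``) followed by an unsigned 16-bit raster whose
byte order is declared by the ``BYTE_ORDER`` key.  This writer adds a
few custom keys (window origin, pedestal, seed, image kind) that the
reader returns in the image metadata; unknown keys are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulator import RawImage, Window

__all__ = ["read_image", "write_image"]

_KNOWN = {"HEADER_BYTES", "DIM", "BYTE_ORDER", "TYPE", "SIZE1", "SIZE2",
          "EXPOSURE_TIME", "KIND", "WINDOW_X0", "WINDOW_Y0", "PEDESTAL",
          "SEED"}


class SMVError(IOError):
    pass


def write_image(image: RawImage, path: str | Path,
                byte_order: str = "little_endian",
                extra_header: dict | None = None) -> None:
    """Write a raster + metadata as an SMV-style file (round-trip exact)."""
    if byte_order not in ("little_endian", "big_endian"):
        raise SMVError(f"unsupported BYTE_ORDER {byte_order!r}")
    data = np.ascontiguousarray(image.data, dtype=np.uint16)
    fields = {
        "DIM": 2,
        "BYTE_ORDER": byte_order,
        "TYPE": "unsigned_short",
        "SIZE1": data.shape[1],
        "SIZE2": data.shape[0],
        "EXPOSURE_TIME": image.exposure_s,
        "KIND": image.kind,
        "WINDOW_X0": image.window.x0,
        "WINDOW_Y0": image.window.y0,
    }
    if "seed" in image.meta:
        fields["SEED"] = image.meta["seed"]
    for k, v in image.meta.items():
        if k.upper() not in fields and k != "seed":
            fields[k.upper()] = v
    if extra_header:
        fields.update({k.upper(): v for k, v in extra_header.items()})
    body = "".join(f"{k}={v};\n" for k, v in fields.items())
    header_bytes = 512
    while len(body) + len(f"{{\nHEADER_BYTES={header_bytes};\n") + 2 > header_bytes:
        header_bytes *= 2
    header = f"{{\nHEADER_BYTES={header_bytes};\n{body}}}\n"
    header = header.ljust(header_bytes, " ").encode("ascii")
    dtype = "<u2" if byte_order == "little_endian" else ">u2"
    Path(path).write_bytes(header + data.astype(dtype).tobytes())


def read_image(path: str | Path) -> RawImage:
    """Read an SMV-style image; header keys land in ``image.meta``."""
    blob = Path(path).read_bytes()
    if not blob.startswith(b"{"):
        raise SMVError(f"{path}: not an SMV-style file (missing '{{')")
    end = blob.find(b"}")
    if end < 0:
        raise SMVError(f"{path}: unterminated header")
    fields: dict[str, str] = {}
    for line in blob[1:end].decode("ascii", errors="replace").splitlines():
        line = line.strip().rstrip(";")
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        header_bytes = int(fields["HEADER_BYTES"])
        size1 = int(fields["SIZE1"])
        size2 = int(fields["SIZE2"])
    except KeyError as exc:
        raise SMVError(f"{path}: missing mandatory header key {exc}") from exc
    if fields.get("TYPE", "unsigned_short") != "unsigned_short":
        raise SMVError(f"{path}: unsupported TYPE {fields.get('TYPE')!r}")
    order = fields.get("BYTE_ORDER", "little_endian")
    if order not in ("little_endian", "big_endian"):
        raise SMVError(f"{path}: unsupported BYTE_ORDER {order!r}")
    dtype = "<u2" if order == "little_endian" else ">u2"
    n_expected = size1 * size2 * 2
    raster = blob[header_bytes:header_bytes + n_expected]
    if len(raster) < n_expected:
        raise SMVError(f"{path}: truncated raster "
                       f"({len(raster)} of {n_expected} bytes)")
    data = np.frombuffer(raster, dtype=dtype).reshape(size2, size1)
    meta = {k: v for k, v in fields.items() if k not in _KNOWN}
    if "SEED" in fields:
        meta["seed"] = int(fields["SEED"])
    return RawImage(
        data=data.astype(np.uint16),
        window=Window(int(fields.get("WINDOW_X0", 0)),
                      int(fields.get("WINDOW_Y0", 0)), size1, size2),
        exposure_s=float(fields.get("EXPOSURE_TIME", 1.0)),
        kind=fields.get("KIND", "raw"),
        meta=meta,
    )
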