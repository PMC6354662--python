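"""Read/write 3-D volumes and masks: DICOM series (read+write), MetaImage, NIfTI.

The DICOM support is deliberately minimal: single-frame, uncompressed,
little-endian axial series with identity in-plane orientation — the shape
of data the segmentation pipeline consumes.  MetaImage (.mha, uncompressed,
local data) is the canonical persistence format; NIfTI goes through nibabel.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np

from .grid import Mask, Volume

__all__ = [
    "DicomError",
    "read_dicom_series",
    "write_dicom_series",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


class DicomError(ValueError):
    """Malformed or unsupported DICOM input."""


# ---------------------------------------------------------------------------
# DICOM: minimal single-series reader/writer (explicit/implicit VR little endian)
# ---------------------------------------------------------------------------

_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_IMPLICIT_LE = "1.2.840.10008.1.2"
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"  # secondary capture
_ROOT_UID = "2.25.424242"

_TAG_SERIES_UID = (0x0020, 0x000E)
_TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
_TAG_IPP = (0x0020, 0x0032)
_TAG_PIXEL_SPACING = (0x0028, 0x0030)
_TAG_SLICE_THICKNESS = (0x0018, 0x0050)
_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOCATED = (0x0028, 0x0100)
_TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
_TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
_TAG_RESCALE_SLOPE = (0x0028, 0x1053)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


def _read_elements(buf: bytes) -> dict[tuple[int, int], bytes]:
    """Parse a little-endian DICOM byte stream into {tag: raw value}."""
    pos = 0
    if len(buf) > 132 and buf[128:132] == b"DICM":
        pos = 132
    explicit = None
    out: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        # file meta group (0002) is always explicit VR
        meta = group == 0x0002
        if explicit is None and not meta:
            explicit = buf[pos + 4 : pos + 6].isalpha() and buf[pos + 4 : pos + 6].isupper()
        use_explicit = True if meta else bool(explicit)
        if use_explicit:
            vr = buf[pos + 4 : pos + 6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, pos + 8)
                vpos = pos + 12
            else:
                (length,) = struct.unpack_from("<H", buf, pos + 6)
                vpos = pos + 8
        else:
            vr = b""
            (length,) = struct.unpack_from("<I", buf, pos + 4)
            vpos = pos + 8
        if length == 0xFFFFFFFF:
            raise DicomError(
                f"undefined-length element ({group:04x},{elem:04x}) is not supported"
            )
        if vpos + length > n:
            raise DicomError(f"truncated element ({group:04x},{elem:04x})")
        out[(group, elem)] = buf[vpos : vpos + length]
        pos = vpos + length
    return out


def _decode_ds(raw: bytes) -> list[float]:
    text = raw.decode("ascii", errors="replace").strip("\x00 ")
    if not text:
        return []
    return [float(tok) for tok in text.split("\\")]


def _decode_us(raw: bytes) -> int:
    return struct.unpack("<H", raw[:2])[0]


def _require(elements: dict, tag: tuple[int, int], path, what: str) -> bytes:
    if tag not in elements:
        raise DicomError(f"{path}: missing required DICOM tag {what} {tag}")
    return elements[tag]


def read_dicom_series(directory_path) -> Volume:
    """Read one axial DICOM series from a directory into a :class:`Volume`.

    Slices are sorted by z position; spacing comes from PixelSpacing and the
    inter-slice gap; RescaleSlope/Intercept are applied.  Mixed series,
    missing spacing tags, and non-uniform slice gaps are rejected.
    """
    directory = Path(directory_path)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise DicomError(f"{directory}: no files found")

    slices = []
    for path in files:
        elements = _read_elements(path.read_bytes())
        if _TAG_PIXEL_DATA not in elements:
            continue  # not an image object
        series_uid = (
            elements.get(_TAG_SERIES_UID, b"").decode("ascii", "replace").strip("\x00 ")
        )
        spacing_raw = elements.get(_TAG_PIXEL_SPACING)
        if spacing_raw is None:
            raise DicomError(f"{path}: missing PixelSpacing (0028,0030)")
        row_sp, col_sp = _decode_ds(spacing_raw)[:2]
        ipp_raw = elements.get(_TAG_IPP)
        if ipp_raw is None:
            raise DicomError(f"{path}: missing ImagePositionPatient (0020,0032)")
        ipp = _decode_ds(ipp_raw)
        rows = _decode_us(_require(elements, _TAG_ROWS, path, "Rows"))
        cols = _decode_us(_require(elements, _TAG_COLS, path, "Columns"))
        bits = _decode_us(elements.get(_TAG_BITS_ALLOCATED, struct.pack("<H", 16)))
        if bits != 16:
            raise DicomError(f"{path}: only 16-bit pixel data supported, got {bits}")
        signed = _decode_us(
            elements.get(_TAG_PIXEL_REPRESENTATION, struct.pack("<H", 0))
        )
        slope_l = _decode_ds(elements.get(_TAG_RESCALE_SLOPE, b"1"))
        inter_l = _decode_ds(elements.get(_TAG_RESCALE_INTERCEPT, b"0"))
        slope = slope_l[0] if slope_l else 1.0
        intercept = inter_l[0] if inter_l else 0.0
        dtype = np.dtype("<i2") if signed else np.dtype("<u2")
        pix = np.frombuffer(elements[_TAG_PIXEL_DATA], dtype=dtype, count=rows * cols)
        pix = pix.reshape(rows, cols)
        slices.append(
            {
                "path": path,
                "series": series_uid,
                "ipp": ipp,
                "spacing": (col_sp, row_sp),
                "pixels": pix,
                "slope": slope,
                "intercept": intercept,
                "thickness": _decode_ds(elements.get(_TAG_SLICE_THICKNESS, b""))
                or [None],
            }
        )

    if not slices:
        raise DicomError(f"{directory}: no DICOM image files found")

    series_ids = sorted({s["series"] for s in slices})
    if len(series_ids) != 1:
        raise DicomError(
            f"{directory}: directory mixes {len(series_ids)} series: {series_ids}"
        )
    in_plane = {s["spacing"] for s in slices}
    if len(in_plane) != 1:
        raise DicomError(f"{directory}: inconsistent PixelSpacing across slices: {in_plane}")
    (sx, sy) = slices[0]["spacing"]

    slices.sort(key=lambda s: s["ipp"][2])
    zs = np.array([s["ipp"][2] for s in slices], dtype=float)
    if len(zs) > 1:
        gaps = np.diff(zs)
        sz = float(np.median(gaps))
        if sz <= 0:
            raise DicomError(f"{directory}: duplicate or non-increasing slice positions")
        if np.max(np.abs(gaps - sz)) > 1e-3 * max(1.0, sz):
            raise DicomError(
                f"{directory}: non-uniform slice gap (gaps range "
                f"{gaps.min():.6g}..{gaps.max():.6g} mm)"
            )
    else:
        sz = slices[0]["thickness"][0]
        if sz is None:
            raise DicomError(f"{directory}: single slice without SliceThickness")

    stack = np.stack([s["pixels"] for s in slices], axis=0)  # (z, row, col)
    slopes = {(s["slope"], s["intercept"]) for s in slices}
    if len(slopes) != 1:
        raise DicomError(f"{directory}: inconsistent rescale slope/intercept")
    slope, intercept = slices[0]["slope"], slices[0]["intercept"]
    data = stack.transpose(2, 1, 0)  # -> (x, y, z)
    if slope != 1.0 or intercept != 0.0:
        data = data.astype(np.float64) * slope + intercept
        if np.all(data == np.round(data)):
            data = data.astype(np.int32)
    else:
        data = data.astype(np.int32)

    ipp0 = slices[0]["ipp"]
    origin = (ipp0[0] - 0.5 * sx, ipp0[1] - 0.5 * sy, float(zs[0]) - 0.5 * sz)
    return Volume(np.ascontiguousarray(data), spacing=(sx, sy, float(sz)), origin=origin)


def _encode_element(tag: tuple[int, int], vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in (b"UI", b"CS", b"DS", b"IS", b"LO") else b" "
        if vr == b"UI":
            value = value[:-1] + b"\x00"
    head = struct.pack("<HH", *tag)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def _ds(*values: float) -> bytes:
    return "\\".join(f"{v:.10g}" for v in values).encode("ascii")


def write_dicom_series(volume: Volume, directory_path, *, series_number: int = 1) -> list[Path]:
    """Write a :class:`Volume` as an explicit-VR-LE axial DICOM series.

    Intensities are rounded to signed 16-bit; callers with float data should
    prefer :func:`write_volume`.  Returns the written file paths.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.asarray(volume.data)
    if np.issubdtype(data.dtype, np.floating):
        data = np.round(data)
    if data.min() < -32768 or data.max() > 32767:
        raise DicomError("intensities exceed the signed 16-bit range")
    data = data.astype("<i2")
    sx, sy, sz = volume.spacing
    series_uid = f"{_ROOT_UID}.{series_number}"
    study_uid = f"{_ROOT_UID}.0"
    paths = []
    nz = volume.shape[2]
    for k in range(nz):
        sop_uid = f"{series_uid}.{k + 1}"
        ipp = (
            volume.origin[0] + 0.5 * sx,
            volume.origin[1] + 0.5 * sy,
            volume.origin[2] + (k + 0.5) * sz,
        )
        pixels = np.ascontiguousarray(data[:, :, k].T)  # (row=y, col=x)
        body = b"".join(
            [
                _encode_element((0x0008, 0x0016), b"UI", _SC_SOP_CLASS.encode()),
                _encode_element((0x0008, 0x0018), b"UI", sop_uid.encode()),
                _encode_element((0x0018, 0x0050), b"DS", _ds(sz)),
                _encode_element((0x0020, 0x000D), b"UI", study_uid.encode()),
                _encode_element((0x0020, 0x000E), b"UI", series_uid.encode()),
                _encode_element((0x0020, 0x0013), b"IS", str(k + 1).encode()),
                _encode_element((0x0020, 0x0032), b"DS", _ds(*ipp)),
                _encode_element((0x0020, 0x0037), b"DS", _ds(1, 0, 0, 0, 1, 0)),
                _encode_element((0x0028, 0x0002), b"US", struct.pack("<H", 1)),
                _encode_element((0x0028, 0x0004), b"CS", b"MONOCHROME2"),
                _encode_element((0x0028, 0x0010), b"US", struct.pack("<H", pixels.shape[0])),
                _encode_element((0x0028, 0x0011), b"US", struct.pack("<H", pixels.shape[1])),
                _encode_element((0x0028, 0x0030), b"DS", _ds(sy, sx)),
                _encode_element((0x0028, 0x0100), b"US", struct.pack("<H", 16)),
                _encode_element((0x0028, 0x0101), b"US", struct.pack("<H", 16)),
                _encode_element((0x0028, 0x0102), b"US", struct.pack("<H", 15)),
                _encode_element((0x0028, 0x0103), b"US", struct.pack("<H", 1)),
                _encode_element((0x0028, 0x1052), b"DS", b"0"),
                _encode_element((0x0028, 0x1053), b"DS", b"1"),
                _encode_element(_TAG_PIXEL_DATA, b"OW", pixels.tobytes()),
            ]
        )
        meta_body = b"".join(
            [
                _encode_element((0x0002, 0x0001), b"OB", b"\x00\x01"),
                _encode_element((0x0002, 0x0002), b"UI", _SC_SOP_CLASS.encode()),
                _encode_element((0x0002, 0x0003), b"UI", sop_uid.encode()),
                _encode_element((0x0002, 0x0010), b"UI", _EXPLICIT_LE.encode()),
            ]
        )
        meta = _encode_element((0x0002, 0x0000), b"UL", struct.pack("<I", len(meta_body)))
        path = directory / f"slice_{k:04d}.dcm"
        path.write_bytes(b"\x00" * 128 + b"DICM" + meta + meta_body + body)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# MetaImage (.mha, uncompressed, local data)
# ---------------------------------------------------------------------------

_MET_TYPES = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_LONG": np.int64,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _write_mha(data: np.ndarray, spacing, origin, path: Path) -> None:
    dtype = np.dtype(data.dtype)
    if dtype not in _MET_NAMES:
        raise ValueError(f"dtype {dtype} not representable in MetaImage")
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        f"ElementSpacing = {spacing[0]:.17g} {spacing[1]:.17g} {spacing[2]:.17g}\n"
        f"Offset = {origin[0]:.17g} {origin[1]:.17g} {origin[2]:.17g}\n"
        f"ElementType = {_MET_NAMES[dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        # MetaImage raster order: x fastest
        fh.write(np.ascontiguousarray(data.T).tobytes())


def _read_mha(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    raw = path.read_bytes()
    fields: dict[str, str] = {}
    pos = 0
    while True:
        eol = raw.index(b"\n", pos)
        line = raw[pos:eol].decode("ascii")
        pos = eol + 1
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
        if key.strip() == "ElementDataFile":
            break
    if fields.get("ElementDataFile") != "LOCAL":
        raise ValueError(f"{path}: only LOCAL MetaImage data supported")
    if fields.get("CompressedData", "False") == "True":
        raise ValueError(f"{path}: compressed MetaImage not supported")
    shape = tuple(int(t) for t in fields["DimSize"].split())
    spacing = tuple(float(t) for t in fields["ElementSpacing"].split())
    origin = tuple(float(t) for t in fields.get("Offset", "0 0 0").split())
    dtype = np.dtype(_MET_TYPES[fields["ElementType"]])
    count = shape[0] * shape[1] * shape[2]
    data = np.frombuffer(raw[pos:], dtype=dtype, count=count)
    data = data.reshape(shape[::-1]).T  # stored x-fastest
    return np.ascontiguousarray(data), spacing, origin


# ---------------------------------------------------------------------------
# NIfTI via nibabel (LPS world kept by sign-flipping the RAS affine)
# ---------------------------------------------------------------------------


def _write_nifti(data: np.ndarray, spacing, origin, path: Path) -> None:
    import nibabel as nib

    sx, sy, sz = spacing
    ox, oy, oz = origin
    affine = np.array(
        [
            [-sx, 0, 0, -(ox + 0.5 * sx)],
            [0, -sy, 0, -(oy + 0.5 * sy)],
            [0, 0, sz, oz + 0.5 * sz],
            [0, 0, 0, 1],
        ]
    )
    nib.save(nib.Nifti1Image(data, affine), os.fspath(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    affine = img.affine
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned NIfTI volumes supported")
    diag = np.diag(affine[:3, :3])
    spacing = tuple(float(abs(d)) for d in diag)
    trans = affine[:3, 3]
    centre0 = (-trans[0] if diag[0] < 0 else trans[0],
               -trans[1] if diag[1] < 0 else trans[1],
               trans[2] if diag[2] > 0 else -trans[2])
    origin = tuple(float(c - 0.5 * s) for c, s in zip(centre0, spacing))
    data = np.asanyarray(img.dataobj)
    return np.ascontiguousarray(data), spacing, origin


# ---------------------------------------------------------------------------
# Public volume/mask persistence
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _dispatch(path) -> str:
    name = str(path)
    if name.endswith(".mha"):
        return "mha"
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    raise ValueError(
        f"unsupported volume format for {name!r} (expected .mha, .nii or .nii.gz)"
    )


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    if _dispatch(path) == "mha":
        _write_mha(volume.data, volume.spacing, volume.origin, path)
    else:
        _write_nifti(volume.data, volume.spacing, volume.origin, path)


def read_volume(path) -> Volume:
    path = Path(path)
    reader = _read_mha if _dispatch(path) == "mha" else _read_nifti
    data, spacing, origin = reader(path)
    return Volume(data, spacing=spacing, origin=origin)


def write_mask(mask: Mask, path) -> None:
    path = Path(path)
    data = mask.data.astype(np.uint8)
    if _dispatch(path) == "mha":
        _write_mha(data, mask.spacing, mask.origin, path)
    else:
        _write_nifti(data, mask.spacing, mask.origin, path)


def read_mask(path) -> Mask:
    path = Path(path)
    reader = _read_mha if _dispatch(path) == "mha" else _read_nifti
    data, spacing, origin = reader(path)
    if not np.isin(data, (0, 1)).all():
        raise ValueError(f"{path}: mask file contains values other than 0/1")
    return Mask(data.astype(bool), spacing=spacing, origin=origin)
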