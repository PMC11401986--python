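"""Reader/writer for a documented subset of the Illumina GTC container.

The on-disk layout follows the public little-endian table-of-contents
convention of GTC v3+: a 3-byte magic ``gtc``, a version byte, an int32
entry count, then ``(uint16 id, uint32 offset)`` TOC pairs pointing at the
payload blocks.  Only the entries this pipeline consumes are implemented:

====  =========================  =======================================
id    name                       payload
====  =========================  =======================================
1     NUM_SNPS                   int32
10    SAMPLE_NAME                length-prefixed UTF-8 string
400   NORMALIZATION_TRANSFORMS   int32 count; per transform int32 version
                                 + float64 offset_x, offset_y, scale_x,
                                 scale_y, shear, theta
410   TRANSFORM_INDICES          uint16 per record
1000  RAW_X                      uint16 per record
1001  RAW_Y                      uint16 per record
1002  GENOTYPES                  uint8 per record (0 NC, 1 AA, 2 AB, 3 BB)
1004  GENOTYPE_SCORES            float64 per record
====  =========================  =======================================

Transform parameters are stored at full double precision and the per-record
transform index is explicit (the vendor derives it from the manifest);
both choices keep write→read round trips bit-exact.  Unknown TOC ids are
skipped with a warning so files carrying extra vendor blocks still load.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np

from .errors import FormatError, IntegrityError, ParameterError
from .types import CODE_TO_GENOTYPE, GENOTYPE_CODES, GtcRecord, NormalizationTransform

MAGIC = b"gtc"
VERSION = 5

ID_NUM_SNPS = 1
ID_SAMPLE_NAME = 10
ID_NORMALIZATION_TRANSFORMS = 400
ID_TRANSFORM_INDICES = 410
ID_RAW_X = 1000
ID_RAW_Y = 1001
ID_GENOTYPES = 1002
ID_GENOTYPE_SCORES = 1004

_REQUIRED = (
    ID_NUM_SNPS, ID_NORMALIZATION_TRANSFORMS, ID_TRANSFORM_INDICES,
    ID_RAW_X, ID_RAW_Y, ID_GENOTYPES, ID_GENOTYPE_SCORES,
)


def _read_exact(buf: bytes, offset: int, n: int, what: str) -> bytes:
    if offset + n > len(buf):
        raise FormatError(
            f"truncated GTC file: need {n} bytes for {what} at offset "
            f"{offset}, file has {len(buf)}"
        )
    return buf[offset:offset + n]


def write_gtc(
    records: list[GtcRecord],
    transforms: list[NormalizationTransform],
    path: str | Path,
    sample_name: str = "",
) -> Path:
    """Serialize genotype records to a GTC-dialect file.

    Validates everything before any bytes are written; ``read_gtc`` on the
    result reproduces every record field exactly.
    """
    if not records:
        raise ParameterError("cannot write a GTC file with zero records")
    if not transforms:
        raise ParameterError("at least one normalization transform required")
    for r in records:
        if not 0 <= r.transform_index < len(transforms):
            raise ParameterError(
                f"record {r.snp_index}: transform index {r.transform_index} "
                f"outside [0, {len(transforms)})"
            )
        if r.gtype not in GENOTYPE_CODES:
            raise ParameterError(f"invalid genotype code {r.gtype!r}")
        if not (0 <= r.x_raw <= 0xFFFF and 0 <= r.y_raw <= 0xFFFF):
            raise ParameterError(
                f"record {r.snp_index}: raw intensity outside uint16 range"
            )

    n = len(records)
    name_bytes = sample_name.encode("utf-8")

    payloads: list[tuple[int, bytes]] = [
        (ID_NUM_SNPS, struct.pack("<i", n)),
        (ID_SAMPLE_NAME, struct.pack("<I", len(name_bytes)) + name_bytes),
        (
            ID_NORMALIZATION_TRANSFORMS,
            struct.pack("<i", len(transforms)) + b"".join(
                struct.pack(
                    "<i6d", 1, t.offset_x, t.offset_y, t.scale_x,
                    t.scale_y, t.shear, t.theta,
                )
                for t in transforms
            ),
        ),
        (
            ID_TRANSFORM_INDICES,
            np.array([r.transform_index for r in records],
                     dtype="<u2").tobytes(),
        ),
        (ID_RAW_X, np.array([r.x_raw for r in records], dtype="<u2").tobytes()),
        (ID_RAW_Y, np.array([r.y_raw for r in records], dtype="<u2").tobytes()),
        (
            ID_GENOTYPES,
            np.array([GENOTYPE_CODES[r.gtype] for r in records],
                     dtype="u1").tobytes(),
        ),
        (
            ID_GENOTYPE_SCORES,
            np.array([r.score for r in records], dtype="<f8").tobytes(),
        ),
    ]

    header_size = len(MAGIC) + 1 + 4 + 6 * len(payloads)
    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    out += struct.pack("<i", len(payloads))
    offset = header_size
    body = bytearray()
    for entry_id, blob in payloads:
        out += struct.pack("<HI", entry_id, offset)
        body += blob
        offset += len(blob)
    out += body

    path = Path(path)
    path.write_bytes(bytes(out))
    return path


def read_gtc(
    path: str | Path,
) -> tuple[dict, list[GtcRecord], list[NormalizationTransform]]:
    """Parse a GTC-dialect file.

    Returns ``(meta, records, transforms)`` where ``meta`` carries the
    sample name and declared SNP count.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 8:
        raise FormatError(f"file too short to be GTC ({len(buf)} bytes)")
    if buf[:3] != MAGIC:
        raise FormatError(
            f"bad magic bytes at offset 0: expected {MAGIC!r}, got {buf[:3]!r}"
        )
    version = buf[3]
    if version != VERSION:
        raise FormatError(f"unsupported GTC dialect version {version} at offset 3")
    (n_entries,) = struct.unpack_from("<i", buf, 4)
    if n_entries <= 0:
        raise FormatError(f"non-positive TOC entry count at offset 4")

    toc: dict[int, int] = {}
    pos = 8
    for _ in range(n_entries):
        raw = _read_exact(buf, pos, 6, "TOC entry")
        entry_id, offset = struct.unpack("<HI", raw)
        known = entry_id in _REQUIRED or entry_id == ID_SAMPLE_NAME
        if not known:
            warnings.warn(f"skipping unknown GTC TOC entry id {entry_id}")
        else:
            toc[entry_id] = offset
        pos += 6

    missing = [i for i in _REQUIRED if i not in toc]
    if missing:
        raise FormatError(f"GTC file missing required TOC entries {missing}")

    (n,) = struct.unpack("<i", _read_exact(buf, toc[ID_NUM_SNPS], 4, "NUM_SNPS"))
    if n <= 0:
        raise FormatError(f"non-positive SNP count {n}")

    sample_name = ""
    if ID_SAMPLE_NAME in toc:
        off = toc[ID_SAMPLE_NAME]
        (slen,) = struct.unpack("<I", _read_exact(buf, off, 4, "name length"))
        sample_name = _read_exact(buf, off + 4, slen, "sample name").decode("utf-8")

    off = toc[ID_NORMALIZATION_TRANSFORMS]
    (n_t,) = struct.unpack("<i", _read_exact(buf, off, 4, "transform count"))
    if n_t <= 0:
        raise FormatError(f"non-positive transform count {n_t}")
    transforms = []
    off += 4
    for _ in range(n_t):
        raw = _read_exact(buf, off, 4 + 6 * 8, "transform block")
        _, ox, oy, sx, sy, sh, th = struct.unpack("<i6d", raw)
        try:
            transforms.append(NormalizationTransform(
                offset_x=ox, offset_y=oy, theta=th, shear=sh,
                scale_x=sx, scale_y=sy,
            ))
        except ValueError as e:
            raise FormatError(f"invalid transform at offset {off}: {e}") from e
        off += len(raw)

    def _array(entry_id: int, dtype: str, what: str) -> np.ndarray:
        itemsize = np.dtype(dtype).itemsize
        raw = _read_exact(buf, toc[entry_id], n * itemsize, what)
        return np.frombuffer(raw, dtype=dtype)

    t_idx = _array(ID_TRANSFORM_INDICES, "<u2", "transform indices")
    x_raw = _array(ID_RAW_X, "<u2", "raw X")
    y_raw = _array(ID_RAW_Y, "<u2", "raw Y")
    gcodes = _array(ID_GENOTYPES, "u1", "genotypes")
    scores = _array(ID_GENOTYPE_SCORES, "<f8", "scores")

    bad = set(np.unique(gcodes)) - set(CODE_TO_GENOTYPE)
    if bad:
        raise FormatError(f"unknown genotype codes {sorted(bad)} in file")
    if t_idx.size and int(t_idx.max()) >= len(transforms):
        raise IntegrityError(
            f"transform index {int(t_idx.max())} exceeds transform count {len(transforms)}"
        )

    records = [
        GtcRecord(
            snp_index=i,
            gtype=CODE_TO_GENOTYPE[int(gcodes[i])],
            score=float(scores[i]),
            x_raw=int(x_raw[i]),
            y_raw=int(y_raw[i]),
            transform_index=int(t_idx[i]),
        )
        for i in range(n)
    ]
    meta = {"sample_name": sample_name, "n_snps": n}
    return meta, records, transforms
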