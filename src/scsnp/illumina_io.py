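"""Ingestion of the four array-metadata/data artifacts and table assembly.

A genotyping batch is described by four inputs: a SNP manifest, a
genotype-cluster file, a user sample sheet, and one GTC file per sample.
:func:`assemble_table` joins them into the long-format genotype table used
by every downstream stage — one row per (sample, SNP) carrying the called
genotype, the vendor GenCall score, and raw plus affine-normalized
two-channel intensities.

Manifest and cluster files are accepted in two dialects with identical
content: a TSV dialect (what the simulator emits) and a compact
little-endian binary subset.  The full vendor BPM/EGT layouts are not
reproduced; only the fields this pipeline consumes are carried.
"""

from __future__ import annotations

import csv
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParameterError
from .gtc import read_gtc
from .types import (
    ClusterDefinition,
    GenotypeCluster,
    ManifestRecord,
    NormalizationTransform,
    SampleSheetEntry,
)

MANIFEST_MAGIC = b"BPMS"
CLUSTER_MAGIC = b"EGTS"

#: canonical column order of the assembled genotype table
TABLE_COLUMNS = [
    "sample_id", "individual", "family", "Chr", "Name", "position",
    "intensity_only", "gtype", "score", "x_raw", "y_raw", "x", "y",
]


# ---------------------------------------------------------------------------
# manifest

def _detect_dialect(path: Path, magic: bytes) -> str:
    with open(path, "rb") as fh:
        head = fh.read(len(magic))
    return "binary" if head == magic else "tabular"


def read_manifest(path: str | Path, dialect: str = "auto") -> list[ManifestRecord]:
    """Read a SNP manifest; returns one record per marker, nothing filtered.

    Chromosome token ``"0"`` and copy-number ("cnv"-named or
    intensity-only) markers are preserved verbatim — filtering is a QC
    decision made later, not an ingestion one.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"empty manifest file: {path}")
    if dialect == "auto":
        dialect = _detect_dialect(path, MANIFEST_MAGIC)
    if dialect == "binary":
        records = _read_manifest_binary(path)
    elif dialect == "tabular":
        records = _read_manifest_tabular(path)
    else:
        raise ParameterError(f"unknown manifest dialect {dialect!r}")

    seen: set[str] = set()
    for r in records:
        if r.name in seen:
            raise IntegrityError(f"duplicate SNP name {r.name!r} in manifest")
        seen.add(r.name)
    return records


def _read_manifest_tabular(path: Path) -> list[ManifestRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"name", "chromosome", "position"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
    if "alleles" not in df.columns:
        df["alleles"] = "AB"
    if "intensity_only" not in df.columns:
        df["intensity_only"] = False
    return [
        ManifestRecord(
            name=str(row.name_), chromosome=str(row.chromosome),
            position=int(row.position), alleles=str(row.alleles),
            intensity_only=bool(row.intensity_only),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def _read_manifest_binary(path: Path) -> list[ManifestRecord]:
    buf = path.read_bytes()
    if buf[:4] != MANIFEST_MAGIC:
        raise FormatError(
            f"bad manifest magic at offset 0: expected {MANIFEST_MAGIC!r}, "
            f"got {buf[:4]!r}"
        )
    pos = 5  # magic + version byte
    (n,) = struct.unpack_from("<i", buf, pos)
    pos += 4
    records = []
    try:
        for _ in range(n):
            name, pos = _unpack_str(buf, pos)
            chrom, pos = _unpack_str(buf, pos)
            (position,) = struct.unpack_from("<I", buf, pos)
            pos += 4
            alleles = buf[pos:pos + 2].decode("ascii")
            pos += 2
            intensity_only = bool(buf[pos])
            pos += 1
            records.append(ManifestRecord(name, chrom, position, alleles,
                                          intensity_only))
    except struct.error as e:
        raise FormatError(f"truncated manifest at offset {pos}: {e}") from e
    return records


def write_manifest(records: list[ManifestRecord], path: str | Path,
                   dialect: str = "tabular") -> Path:
    path = Path(path)
    if dialect == "tabular":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["name", "chromosome", "position", "alleles",
                        "intensity_only"])
            for r in records:
                w.writerow([r.name, r.chromosome, r.position, r.alleles,
                            r.intensity_only])
    elif dialect == "binary":
        out = bytearray(MANIFEST_MAGIC)
        out.append(1)
        out += struct.pack("<i", len(records))
        for r in records:
            out += _pack_str(r.name) + _pack_str(r.chromosome)
            out += struct.pack("<I", r.position)
            out += r.alleles.encode("ascii")[:2].ljust(2, b"N")
            out.append(1 if r.intensity_only else 0)
        path.write_bytes(bytes(out))
    else:
        raise ParameterError(f"unknown manifest dialect {dialect!r}")
    return path


def _pack_str(s: str) -> bytes:
    b = s.encode("utf-8")
    return struct.pack("<H", len(b)) + b


def _unpack_str(buf: bytes, pos: int) -> tuple[str, int]:
    (n,) = struct.unpack_from("<H", buf, pos)
    pos += 2
    return buf[pos:pos + n].decode("utf-8"), pos + n


# ---------------------------------------------------------------------------
# cluster file

def read_cluster(path: str | Path, dialect: str = "auto") -> list[ClusterDefinition]:
    """Read per-SNP genotype-cluster statistics (AA/AB/BB in the MA plane)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"empty cluster file: {path}")
    if dialect == "auto":
        dialect = _detect_dialect(path, CLUSTER_MAGIC)
    if dialect == "tabular":
        defs = _read_cluster_tabular(path)
    elif dialect == "binary":
        defs = _read_cluster_binary(path)
    else:
        raise ParameterError(f"unknown cluster dialect {dialect!r}")
    return defs


def _read_cluster_tabular(path: Path) -> list[ClusterDefinition]:
    df = pd.read_csv(path, sep="\t")
    required = {"snp_name", "genotype", "mean_m", "mean_a", "sd_m", "sd_a"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cluster file {path} missing columns {sorted(missing)}")
    defs = []
    for snp, grp in df.groupby("snp_name", sort=False):
        clusters = {}
        for row in grp.itertuples(index=False):
            try:
                clusters[str(row.genotype)] = GenotypeCluster(
                    float(row.mean_m), float(row.mean_a),
                    float(row.sd_m), float(row.sd_a),
                )
            except ValueError as e:
                raise IntegrityError(f"SNP {snp!r}: {e}") from e
        try:
            defs.append(ClusterDefinition(str(snp), clusters))
        except ValueError as e:
            raise IntegrityError(str(e)) from e
    return defs


def _read_cluster_binary(path: Path) -> list[ClusterDefinition]:
    buf = path.read_bytes()
    if buf[:4] != CLUSTER_MAGIC:
        raise FormatError(
            f"bad cluster magic at offset 0: expected {CLUSTER_MAGIC!r}, "
            f"got {buf[:4]!r}"
        )
    pos = 5
    (n,) = struct.unpack_from("<i", buf, pos)
    pos += 4
    defs = []
    try:
        for _ in range(n):
            name, pos = _unpack_str(buf, pos)
            clusters = {}
            for g in ("AA", "AB", "BB"):
                mm, ma, sm, sa = struct.unpack_from("<4d", buf, pos)
                pos += 32
                try:
                    clusters[g] = GenotypeCluster(mm, ma, sm, sa)
                except ValueError as e:
                    raise IntegrityError(f"SNP {name!r}: {e}") from e
            defs.append(ClusterDefinition(name, clusters))
    except struct.error as e:
        raise FormatError(f"truncated cluster file at offset {pos}: {e}") from e
    return defs


def write_cluster(defs: list[ClusterDefinition], path: str | Path,
                  dialect: str = "tabular") -> Path:
    path = Path(path)
    if dialect == "tabular":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["snp_name", "genotype", "mean_m", "mean_a",
                        "sd_m", "sd_a"])
            for d in defs:
                for g in ("AA", "AB", "BB"):
                    c = d.clusters[g]
                    w.writerow([d.snp_name, g, repr(c.mean_m), repr(c.mean_a),
                                repr(c.sd_m), repr(c.sd_a)])
    elif dialect == "binary":
        out = bytearray(CLUSTER_MAGIC)
        out.append(1)
        out += struct.pack("<i", len(defs))
        for d in defs:
            out += _pack_str(d.snp_name)
            for g in ("AA", "AB", "BB"):
                c = d.clusters[g]
                out += struct.pack("<4d", c.mean_m, c.mean_a, c.sd_m, c.sd_a)
        path.write_bytes(bytes(out))
    else:
        raise ParameterError(f"unknown cluster dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# sample sheet

def read_samplesheet(path: str | Path,
                     check_paths: bool = True) -> list[SampleSheetEntry]:
    """Read the user sample sheet (plain headered CSV, or vendor-style with
    a ``[Data]`` section header; auto-detected).

    GTC paths are resolved relative to the sheet's directory and must exist
    when ``check_paths`` is true.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip().lower().startswith("[data]"):
            start = i + 1
            break
    rows = list(csv.DictReader(lines[start:]))
    if not rows:
        raise FormatError(f"sample sheet {path} has no data rows")
    fields = rows[0].keys()
    if "sample_id" not in fields:
        raise FormatError(f"sample sheet {path} missing 'sample_id' column")
    if "gtc_path" not in fields:
        raise FormatError(f"sample sheet {path} missing 'gtc_path' column")

    entries: list[SampleSheetEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        sid = row["sample_id"].strip()
        if sid in seen:
            raise IntegrityError(f"duplicate sample_id {sid!r} in sheet row {i}")
        seen.add(sid)
        gtc = Path(row["gtc_path"].strip())
        if not gtc.is_absolute():
            gtc = path.parent / gtc
        if check_paths and not gtc.exists():
            raise IntegrityError(
                f"sheet row {i} (sample {sid!r}): GTC path {gtc} does not exist"
            )
        individual = (row.get("individual") or "").strip() or sid
        family = (row.get("family") or "").strip() or None
        entries.append(SampleSheetEntry(sid, str(gtc), individual, family))
    return entries


def write_samplesheet(entries: list[SampleSheetEntry], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "gtc_path", "individual", "family"])
        for e in entries:
            w.writerow([e.sample_id, e.gtc_path, e.individual or "",
                        e.family or ""])
    return path


# ---------------------------------------------------------------------------
# normalization

def apply_normalization(x_raw, y_raw, t: NormalizationTransform):
    """Map raw two-channel intensities into normalized space.

    Four stages, in order: subtract the channel offsets; rotate by
    ``theta``; remove ``shear`` from the first coordinate; divide each
    coordinate by its scale.  Negative results are clamped to zero so the
    subsequent log transform stays defined.  Accepts scalars or arrays.
    """
    if not (t.scale_x > 0 and t.scale_y > 0):
        raise ParameterError("normalization scales must be strictly positive")
    x_raw = np.asarray(x_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    x1 = x_raw - t.offset_x
    y1 = y_raw - t.offset_y
    cos_t, sin_t = np.cos(t.theta), np.sin(t.theta)
    x2 = cos_t * x1 + sin_t * y1
    y2 = -sin_t * x1 + cos_t * y1
    x3 = x2 - t.shear * y2
    x = np.maximum(x3 / t.scale_x, 0.0)
    y = np.maximum(y2 / t.scale_y, 0.0)
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def invert_normalization(x, y, t: NormalizationTransform):
    """Algebraic inverse of :func:`apply_normalization` (no clamping).

    Used by the simulator to derive raw intensities from normalized ones;
    exact only for points whose forward image is strictly interior
    (nothing clamped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x3 = x * t.scale_x
    y2 = y * t.scale_y
    x2 = x3 + t.shear * y2
    cos_t, sin_t = np.cos(t.theta), np.sin(t.theta)
    x1 = cos_t * x2 - sin_t * y2
    y1 = sin_t * x2 + cos_t * y2
    xr = x1 + t.offset_x
    yr = y1 + t.offset_y
    if xr.ndim == 0:
        return float(xr), float(yr)
    return xr, yr


# ---------------------------------------------------------------------------
# assembly

def assemble_table(
    sheet: list[SampleSheetEntry],
    manifest: list[ManifestRecord],
    clusters: list[ClusterDefinition] | None = None,
) -> pd.DataFrame:
    """Load every sample's GTC and build the long-format genotype table.

    Result has one row per (sample, SNP) — ``len(sheet) * len(manifest)``
    rows — with normalized intensities computed through each record's own
    affine transform.  When cluster definitions are supplied they are
    validated for coverage of the manifest.
    """
    if not sheet:
        raise ParameterError("empty sample sheet")
    if not manifest:
        raise ParameterError("empty manifest")
    if clusters is not None:
        cluster_names = {c.snp_name for c in clusters}
        missing = [m.name for m in manifest if m.name not in cluster_names]
        if missing:
            raise IntegrityError(
                f"cluster file lacks definitions for {len(missing)} manifest "
                f"SNPs (first: {missing[:3]})"
            )

    names = np.array([m.name for m in manifest])
    chroms = np.array([m.chromosome for m in manifest])
    positions = np.array([m.position for m in manifest], dtype=np.int64)
    intensity_only = np.array([m.intensity_only for m in manifest], dtype=bool)

    frames = []
    for entry in sheet:
        _, records, transforms = read_gtc(entry.gtc_path)
        if len(records) != len(manifest):
            raise IntegrityError(
                f"sample {entry.sample_id!r}: GTC has {len(records)} records "
                f"but manifest lists {len(manifest)} SNPs"
            )
        x_raw = np.array([r.x_raw for r in records], dtype=float)
        y_raw = np.array([r.y_raw for r in records], dtype=float)
        t_idx = np.array([r.transform_index for r in records])
        x = np.empty_like(x_raw)
        y = np.empty_like(y_raw)
        for ti in np.unique(t_idx):
            mask = t_idx == ti
            x[mask], y[mask] = apply_normalization(
                x_raw[mask], y_raw[mask], transforms[ti]
            )
        frames.append(pd.DataFrame({
            "sample_id": entry.sample_id,
            "individual": entry.individual or entry.sample_id,
            "family": entry.family,
            "Chr": chroms,
            "Name": names,
            "position": positions,
            "intensity_only": intensity_only,
            "gtype": [r.gtype for r in records],
            "score": [r.score for r in records],
            "x_raw": x_raw,
            "y_raw": y_raw,
            "x": x,
            "y": y,
        }))
    table = pd.concat(frames, ignore_index=True)
    return table[TABLE_COLUMNS]
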