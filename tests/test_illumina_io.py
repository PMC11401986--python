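"""Manifest / cluster / sample-sheet readers, normalization, assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scsnp import (
    ClusterDefinition,
    FormatError,
    GenotypeCluster,
    IntegrityError,
    ManifestRecord,
    NormalizationTransform,
    ParameterError,
    apply_normalization,
    assemble_table,
    invert_normalization,
    read_cluster,
    read_manifest,
    read_samplesheet,
    write_cluster,
    write_manifest,
    write_samplesheet,
)
from scsnp.types import GtcRecord, SampleSheetEntry
from scsnp.gtc import write_gtc


# ---------------------------------------------------------------------------
# manifest

def test_manifest_loader_does_not_filter(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "name\tchromosome\tposition\talleles\tintensity_only\n"
        "rs1\t1\t100\tAB\tFalse\n"
        "rs2\t0\t0\tAB\tFalse\n"
        "cnvi1\t5\t500\tAB\tTrue\n"
    )
    records = read_manifest(path)
    assert [r.name for r in records] == ["rs1", "rs2", "cnvi1"]
    assert records[1].chromosome == "0"
    assert records[2].intensity_only


def test_empty_manifest_is_a_format_error(tmp_path):
    path = tmp_path / "empty.tsv"
    path.touch()
    with pytest.raises(FormatError, match="empty"):
        read_manifest(path)


def test_duplicate_snp_name_is_an_integrity_error(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("name\tchromosome\tposition\nrs1\t1\t1\nrs1\t2\t2\n")
    with pytest.raises(IntegrityError, match="rs1"):
        read_manifest(path)


@pytest.mark.parametrize("dialect", ["tabular", "binary"])
def test_manifest_round_trip(tmp_path, dialect):
    records = [
        ManifestRecord(f"rs{i}", str(1 + i % 22), i * 10, "AB", i % 7 == 0)
        for i in range(200)
    ]
    path = tmp_path / f"m.{dialect}"
    write_manifest(records, path, dialect=dialect)
    assert read_manifest(path, dialect=dialect) == records
    assert read_manifest(path) == records  # auto-detected


def test_binary_manifest_bad_magic(tmp_path):
    path = tmp_path / "bad.bin"
    path.write_bytes(b"NOPE" + bytes(20))
    with pytest.raises(FormatError, match="offset 0"):
        read_manifest(path, dialect="binary")


# ---------------------------------------------------------------------------
# cluster file

def _defs(n=2):
    return [
        ClusterDefinition(f"rs{i}", {
            g: GenotypeCluster(m, 10.0, 0.4, 0.3)
            for g, m in (("AA", 4.0), ("AB", 0.0), ("BB", -4.0))
        })
        for i in range(n)
    ]


@pytest.mark.parametrize("dialect", ["tabular", "binary"])
def test_cluster_round_trip(tmp_path, dialect):
    path = tmp_path / f"c.{dialect}"
    write_cluster(_defs(5), path, dialect=dialect)
    assert read_cluster(path) == _defs(5)


def test_cluster_missing_genotype_is_integrity_error(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text(
        "snp_name\tgenotype\tmean_m\tmean_a\tsd_m\tsd_a\n"
        "rs1\tAA\t4\t10\t0.4\t0.3\n"
        "rs1\tAB\t0\t10\t0.4\t0.3\n"
    )
    with pytest.raises(IntegrityError, match="rs1"):
        read_cluster(path)


def test_cluster_zero_dispersion_is_integrity_error(tmp_path):
    path = tmp_path / "c.tsv"
    rows = "".join(
        f"rs1\t{g}\t0\t10\t{sd}\t0.3\n"
        for g, sd in (("AA", 0.4), ("AB", 0.0), ("BB", 0.4))
    )
    path.write_text("snp_name\tgenotype\tmean_m\tmean_a\tsd_m\tsd_a\n" + rows)
    with pytest.raises(IntegrityError, match="positive"):
        read_cluster(path)


# ---------------------------------------------------------------------------
# sample sheet

def test_samplesheet_family_metadata(small_batch):
    _, paths, _ = small_batch
    entries = read_samplesheet(paths["samplesheet"])
    assert len(entries) == 6
    assert {e.family for e in entries} == {"F1", "F2"}


def test_default_preset_sheet_has_23_samples_two_families(preset_batch):
    _, paths, _ = preset_batch
    entries = read_samplesheet(paths["samplesheet"])
    assert len(entries) == 23
    assert {e.family for e in entries} == {"F1", "F2"}


def test_missing_gtc_path_names_the_row(tmp_path):
    sheet = tmp_path / "s.csv"
    sheet.write_text("sample_id,gtc_path\nS1,missing.gtc\n")
    with pytest.raises(IntegrityError, match="row 1.*S1"):
        read_samplesheet(sheet)


def test_sheet_without_family_column(tmp_path):
    gtc = tmp_path / "s1.gtc"
    write_gtc([GtcRecord(0, "AA", 0.9, 5, 5, 0)],
              [NormalizationTransform()], gtc)
    sheet = tmp_path / "s.csv"
    sheet.write_text("sample_id,gtc_path\nS1,s1.gtc\n")
    entries = read_samplesheet(sheet)
    assert entries[0].family is None
    assert entries[0].individual == "S1"


def test_duplicate_sample_id_is_integrity_error(tmp_path):
    sheet = tmp_path / "s.csv"
    sheet.write_text("sample_id,gtc_path\nS1,a.gtc\nS1,b.gtc\n")
    with pytest.raises(IntegrityError, match="duplicate"):
        read_samplesheet(sheet, check_paths=False)


def test_vendor_style_data_section_header(tmp_path):
    sheet = tmp_path / "s.csv"
    sheet.write_text("[Header]\njunk\n[Data]\nsample_id,gtc_path\nS1,a.gtc\n")
    entries = read_samplesheet(sheet, check_paths=False)
    assert entries[0].sample_id == "S1"


# ---------------------------------------------------------------------------
# normalization

def _normalize_oracle(x, y, t):
    """Independent step-by-step evaluation of the four affine stages."""
    x1, y1 = x - t.offset_x, y - t.offset_y
    x2 = math.cos(t.theta) * x1 + math.sin(t.theta) * y1
    y2 = -math.sin(t.theta) * x1 + math.cos(t.theta) * y1
    x3 = x2 - t.shear * y2
    return max(x3 / t.scale_x, 0.0), max(y2 / t.scale_y, 0.0)


def test_identity_transform_is_identity():
    assert apply_normalization(100.0, 50.0, NormalizationTransform()) == (100.0, 50.0)


def test_offsets_only():
    t = NormalizationTransform(offset_x=10, offset_y=5)
    assert apply_normalization(100.0, 50.0, t) == (90.0, 45.0)


def test_quarter_turn_rotation_with_clamp():
    t = NormalizationTransform(theta=math.pi / 2)
    x, y = apply_normalization(100.0, 50.0, t)
    assert x == pytest.approx(50.0)
    assert y == 0.0  # rotated second coordinate is -x, clamped


transform_strategy = st.builds(
    NormalizationTransform,
    offset_x=st.floats(-100, 100), offset_y=st.floats(-100, 100),
    theta=st.floats(-0.5, 0.5), shear=st.floats(-0.5, 0.5),
    scale_x=st.floats(0.1, 5.0), scale_y=st.floats(0.1, 5.0),
)


@given(
    transform_strategy,
    st.floats(0, 60000), st.floats(0, 60000),
)
def test_full_six_parameter_case_matches_stagewise_oracle(t, x, y):
    assert apply_normalization(x, y, t) == pytest.approx(
        _normalize_oracle(x, y, t), rel=1e-12, abs=1e-12
    )


@given(transform_strategy, st.floats(100, 60000), st.floats(100, 60000))
def test_normalization_invertible_for_interior_points(t, x, y):
    nx, ny = apply_normalization(x, y, t)
    if nx > 0 and ny > 0:  # nothing was clamped
        rx, ry = invert_normalization(nx, ny, t)
        assert rx == pytest.approx(x, rel=1e-9, abs=1e-6)
        assert ry == pytest.approx(y, rel=1e-9, abs=1e-6)


def test_non_positive_scale_rejected():
    with pytest.raises(ValueError):
        NormalizationTransform(scale_x=0.0)


# ---------------------------------------------------------------------------
# assembly

def _mini_batch(tmp_path, n_samples=2, n_snps=3):
    manifest = [ManifestRecord(f"rs{i}", "1", i) for i in range(n_snps)]
    entries = []
    for s in range(n_samples):
        records = [GtcRecord(i, "AA", 0.9, 100 + i, 50, 0) for i in range(n_snps)]
        gtc = tmp_path / f"S{s}.gtc"
        write_gtc(records, [NormalizationTransform(offset_x=10.0)], gtc)
        entries.append(SampleSheetEntry(f"S{s}", str(gtc), f"S{s}", "F1"))
    return entries, manifest


def test_assembly_cardinality(tmp_path):
    entries, manifest = _mini_batch(tmp_path)
    table = assemble_table(entries, manifest)
    assert len(table) == 2 * 3
    assert not table.duplicated(["sample_id", "Name"]).any()
    # normalized through the offset transform
    assert (table["x"] == table["x_raw"] - 10.0).all()


def test_snp_count_mismatch_names_sample(tmp_path):
    entries, manifest = _mini_batch(tmp_path)
    with pytest.raises(IntegrityError, match="S0"):
        assemble_table(entries, manifest + [ManifestRecord("rs99", "2", 9)])


def test_simulated_batch_assembles_to_samples_times_snps(small_batch):
    from scsnp import read_cluster, read_manifest, read_samplesheet

    cfg, paths, _ = small_batch
    table = assemble_table(
        read_samplesheet(paths["samplesheet"]),
        read_manifest(paths["manifest"]),
        read_cluster(paths["cluster"]),
    )
    assert len(table) == cfg.n_samples * cfg.n_snps
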