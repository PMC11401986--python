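"""Generative model of single-cell SNP-array batches under WGA noise.

Whole-genome amplification of a single cell's ~8 pg of DNA corrupts
genotypes in two characteristic ways: allele drop-out (ADO), where one
allele of a heterozygote fails to amplify and AB is called AA or BB, and
allele drop-in (ADI), where a homozygote is spuriously called AB — an
artifact that lands at low log-average intensity with a log-ratio near
zero.  The simulator draws true genotypes per family allele-frequency
profile, applies ADO/ADI/no-call corruption, places every observed call in
the (m, a) cluster of its observed genotype (ADI errors in their own
low-``a`` cloud), back-transforms to normalized intensities, inverts a
randomly drawn per-sample affine transform to get raw intensities, and
assigns GenCall-like scores from Beta distributions that are higher for
correct calls.  It emits a complete fixture set — manifest, cluster file,
sample sheet, one GTC per sample — plus a per-call ground-truth table, so
the whole pipeline is testable offline.

The default configuration emulates a batch of 23 haploid sperm cells from
two families with heavy ADI-induced spurious heterozygosity.  Haploid
templates have no heterozygote to drop an allele from; amplification
failure of the single allele is modelled as a no-call, so in haploid mode
``ado_rate`` adds to the no-call burden rather than producing ADO-class
errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, ParameterError
from .illumina_io import (
    invert_normalization,
    write_cluster,
    write_manifest,
    write_samplesheet,
)
from .gtc import write_gtc
from .ma import ma_to_intensities
from .thresholds import SHADOW_COLUMN, set_threshold
from .types import (
    ClusterDefinition,
    GenotypeCluster,
    GtcRecord,
    ManifestRecord,
    NormalizationTransform,
    SampleSheetEntry,
    SimulationConfig,
)

#: cloud used for records that end as no-calls (suboptimal signal)
_NC_GEOMETRY = {"mean": (0.0, 6.0), "sd": (2.5, 1.0)}


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_true_genotypes(rng: np.random.Generator, freqs: np.ndarray,
                         ploidy: str, n_samples: int) -> np.ndarray:
    """Genotype matrix (samples x SNPs) as strings; ``freqs`` is the B-allele
    frequency profile of the family."""
    n_snps = len(freqs)
    if ploidy == "haploid":
        b = rng.random((n_samples, n_snps)) < freqs
        return np.where(b, "BB", "AA")
    u = rng.random((n_samples, n_snps))
    p_aa = (1 - freqs) ** 2
    p_ab = 2 * freqs * (1 - freqs)
    out = np.full((n_samples, n_snps), "BB", dtype="<U2")
    out[u < p_aa + p_ab] = "AB"
    out[u < p_aa] = "AA"
    return out


def simulate_batch(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Generate a batch and write its fixture files under ``out_dir``.

    Returns ``(paths, truth)`` where ``paths`` maps artifact names
    (manifest, cluster, samplesheet, truth, config, and one entry per
    sample GTC) to files, and ``truth`` has one row per (sample, SNP) with
    ``true_gtype``, ``observed_gtype``, ``score`` and
    ``error_class`` in {correct, ADO, ADI, NC}.
    """
    geometry = dict(config.cluster_geometry)
    for key, geo in geometry.items():
        if not (geo["sd"][0] > 0 and geo["sd"][1] > 0):
            raise ParameterError(f"cluster {key!r}: dispersions must be positive")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (rng_manifest, rng_freq, rng_geno, rng_noise, rng_intensity,
     rng_score, rng_transform) = _streams(config.seed, 7)

    # --- manifest: informative "rs" markers plus intensity-only "cnvi" probes
    n_io = int(round(config.intensity_only_fraction * config.n_snps))
    io_flags = np.zeros(config.n_snps, dtype=bool)
    if n_io:
        io_flags[rng_manifest.choice(config.n_snps, size=n_io, replace=False)] = True
    chroms = rng_manifest.integers(1, 23, size=config.n_snps).astype(str)
    positions = np.sort(rng_manifest.integers(1, 250_000_000, size=config.n_snps))
    manifest = [
        ManifestRecord(
            name=(f"cnvi{i}" if io_flags[i] else f"rs{i}"),
            chromosome=("0" if io_flags[i] else chroms[i]),
            position=int(positions[i]),
            alleles="AB",
            intensity_only=bool(io_flags[i]),
        )
        for i in range(config.n_snps)
    ]

    # --- cluster file mirrors the generating geometry
    defs = [
        ClusterDefinition(m.name, {
            g: GenotypeCluster(geometry[g]["mean"][0], geometry[g]["mean"][1],
                               geometry[g]["sd"][0], geometry[g]["sd"][1])
            for g in ("AA", "AB", "BB")
        })
        for m in manifest
    ]

    # --- true genotypes per family allele-frequency profile
    sample_ids: list[str] = []
    families: list[str] = []
    true_rows = []
    for fam_name, fam_n in config.families:
        freqs = rng_freq.uniform(0.05, 0.95, size=config.n_snps)
        g = _draw_true_genotypes(rng_geno, freqs, config.ploidy, fam_n)
        for j in range(fam_n):
            sample_ids.append(f"{fam_name}_S{j + 1:02d}")
            families.append(fam_name)
            true_rows.append(g[j])
    true = np.stack(true_rows)                       # samples x snps
    true[:, io_flags] = "NC"                         # no genotype exists

    n_s, n_snp = true.shape
    observed = true.copy()
    error_class = np.full((n_s, n_snp), "correct", dtype="<U7")

    # --- ADO: heterozygous template loses one allele
    u = rng_noise.random((n_s, n_snp))
    is_ab = true == "AB"
    ado = is_ab & (u < config.ado_rate)
    flip = rng_noise.random((n_s, n_snp)) < 0.5
    observed[ado & flip] = "AA"
    observed[ado & ~flip] = "BB"
    error_class[ado] = "ADO"
    if config.ploidy == "haploid":
        # single-allele template: amplification failure -> no signal
        hap_nc = ~io_flags & (rng_noise.random((n_s, n_snp)) < config.ado_rate)
        observed[hap_nc] = "NC"
        error_class[hap_nc] = "NC"

    # --- ADI: homozygous template gains a spurious heterozygous call
    is_hom = np.isin(true, ("AA", "BB")) & (error_class == "correct")
    adi = is_hom & (rng_noise.random((n_s, n_snp)) < config.adi_rate)
    observed[adi] = "AB"
    error_class[adi] = "ADI"

    # --- baseline no-calls (low signal), overriding everything
    nc = rng_noise.random((n_s, n_snp)) < config.nc_rate
    nc |= io_flags[None, :]
    observed[nc] = "NC"
    error_class[nc] = "NC"

    # --- intensity features per observed call
    m_feat = np.empty((n_s, n_snp))
    a_feat = np.empty((n_s, n_snp))
    for key, mask in (
        ("AA", (observed == "AA")),
        ("AB", (observed == "AB") & (error_class != "ADI")),
        ("ADI", error_class == "ADI"),
        ("BB", observed == "BB"),
    ):
        geo = geometry[key]
        k = int(mask.sum())
        m_feat[mask] = rng_intensity.normal(geo["mean"][0], geo["sd"][0], k)
        a_feat[mask] = rng_intensity.normal(geo["mean"][1], geo["sd"][1], k)
    mask = observed == "NC"
    k = int(mask.sum())
    m_feat[mask] = rng_intensity.normal(_NC_GEOMETRY["mean"][0],
                                        _NC_GEOMETRY["sd"][0], k)
    a_feat[mask] = rng_intensity.normal(_NC_GEOMETRY["mean"][1],
                                        _NC_GEOMETRY["sd"][1], k)

    x_norm, y_norm = ma_to_intensities(m_feat, a_feat)

    # --- GenCall-like scores per error class
    scores = np.empty((n_s, n_snp))
    for cls, params in (
        ("correct", config.score_model["correct"]),
        ("ADO", config.score_model["error"]),
        ("ADI", config.score_model["error"]),
        ("NC", config.score_model["nc"]),
    ):
        mask = error_class == cls
        scores[mask] = rng_score.beta(params[0], params[1], int(mask.sum()))

    # --- per-sample affine transform; raw = inverse(normalized), quantized
    entries: list[SampleSheetEntry] = []
    paths: dict[str, Path] = {}
    truth_frames = []
    snp_names = np.array([m.name for m in manifest])
    for i, sid in enumerate(sample_ids):
        t = NormalizationTransform(
            offset_x=float(rng_transform.uniform(20, 120)),
            offset_y=float(rng_transform.uniform(20, 120)),
            theta=float(rng_transform.uniform(-0.08, 0.08)),
            shear=float(rng_transform.uniform(-0.05, 0.05)),
            scale_x=float(rng_transform.uniform(0.8, 1.2)),
            scale_y=float(rng_transform.uniform(0.8, 1.2)),
        )
        xr, yr = invert_normalization(x_norm[i], y_norm[i], t)
        xr = np.clip(np.rint(xr), 0, 0xFFFF).astype(int)
        yr = np.clip(np.rint(yr), 0, 0xFFFF).astype(int)
        records = [
            GtcRecord(
                snp_index=j, gtype=str(observed[i, j]),
                score=float(scores[i, j]), x_raw=int(xr[j]),
                y_raw=int(yr[j]), transform_index=0,
            )
            for j in range(n_snp)
        ]
        gtc_path = out_dir / f"{sid}.gtc"
        write_gtc(records, [t], gtc_path, sample_name=sid)
        paths[f"gtc:{sid}"] = gtc_path
        entries.append(SampleSheetEntry(sid, gtc_path.name, sid, families[i]))
        truth_frames.append(pd.DataFrame({
            "sample_id": sid,
            "individual": sid,
            "family": families[i],
            "Name": snp_names,
            "true_gtype": true[i],
            "observed_gtype": observed[i],
            "error_class": error_class[i],
            "score": scores[i],
        }))

    truth = pd.concat(truth_frames, ignore_index=True)

    paths["manifest"] = write_manifest(manifest, out_dir / "manifest.tsv")
    paths["cluster"] = write_cluster(defs, out_dir / "cluster.tsv")
    paths["samplesheet"] = write_samplesheet(entries, out_dir / "samplesheet.csv")
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    config_path = out_dir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump({
            "n_samples": config.n_samples, "n_snps": config.n_snps,
            "ploidy": config.ploidy,
            "families": [list(f) for f in config.families],
            "ado_rate": config.ado_rate, "adi_rate": config.adi_rate,
            "nc_rate": config.nc_rate,
            "intensity_only_fraction": config.intensity_only_fraction,
            "seed": config.seed,
        }, fh)
    paths["config"] = config_path
    return paths, truth


def truth_labels(table: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Boolean label per table row: called genotype equals the template
    genotype and is not a no-call.  Rows are matched on (sample_id, Name)."""
    merged = table.merge(
        truth[["sample_id", "Name", "true_gtype"]],
        on=["sample_id", "Name"], how="left", validate="one_to_one",
    )
    if merged["true_gtype"].isna().any():
        n = int(merged["true_gtype"].isna().sum())
        raise IntegrityError(f"{n} table rows have no matching truth record")
    return ((merged["gtype"] == merged["true_gtype"])
            & (merged["gtype"] != "NC")).set_axis(table.index)


def evaluate_against_truth(
    scored: pd.DataFrame,
    truth: pd.DataFrame,
    threshold: float,
    score_col: str = "rfgda_score",
) -> dict[str, float]:
    """Precision / recall of the retained call set after thresholding.

    A call is *retained* when it is non-NC after ``set_threshold``;
    it is *correct* when the originally called genotype equals the truth.
    Recall is relative to the correct calls in the unthresholded retained
    set, so threshold 0 gives recall 1.  Also reports the fraction of ADI
    calls surviving the threshold (``adi_retention``) and of correct calls
    (``correct_retention``).
    """
    merged = scored.merge(
        truth[["sample_id", "Name", "true_gtype", "error_class"]],
        on=["sample_id", "Name"], how="inner", validate="one_to_one",
    )
    if len(merged) != len(scored):
        raise IntegrityError(
            f"key mismatch: {len(scored)} scored rows, {len(merged)} matched"
        )
    thresholded = set_threshold(merged, score_col, threshold)
    original = thresholded[SHADOW_COLUMN]
    retained = thresholded["gtype"] != "NC"
    called = original != "NC"
    correct = (original == thresholded["true_gtype"]) & called
    adi = thresholded["error_class"] == "ADI"

    n_retained = int(retained.sum())
    n_correct_retained = int((retained & correct).sum())
    return {
        "precision": n_correct_retained / n_retained if n_retained else np.nan,
        "recall": n_correct_retained / int(correct.sum()) if correct.any() else np.nan,
        "adi_retention": float((retained & adi).sum() / adi.sum()) if adi.any() else np.nan,
        "correct_retention": (n_correct_retained / int(correct.sum())
                              if correct.any() else np.nan),
        "n_retained": float(n_retained),
    }


def ab_fraction_at_retention(
    table: pd.DataFrame, score_col: str, retention: float
) -> float:
    """AB share of the top-``retention`` fraction of called genotypes
    ranked by ``score_col`` (matched-call-rate comparison between scorers)."""
    if not 0 < retention <= 1:
        raise ParameterError(f"retention {retention} outside (0, 1]")
    called = table[table["gtype"] != "NC"]
    if called.empty:
        return np.nan
    n_keep = max(1, int(round(retention * len(called))))
    kept = called.nlargest(n_keep, score_col)
    return float((kept["gtype"] == "AB").mean())
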