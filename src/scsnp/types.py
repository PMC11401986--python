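"""Core value types shared across the pipeline.

All are plain frozen dataclasses; tabular data lives in pandas DataFrames
(see :mod:`scsnp.illumina_io` for the long-format genotype table contract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

GENOTYPES = ("NC", "AA", "AB", "BB")
#: integer codes used in the GTC-dialect binary files
GENOTYPE_CODES = {"NC": 0, "AA": 1, "AB": 2, "BB": 3}
CODE_TO_GENOTYPE = {v: k for k, v in GENOTYPE_CODES.items()}


@dataclass(frozen=True)
class ManifestRecord:
    """One SNP marker on the array.

    ``chromosome`` is kept verbatim as a string token; ``"0"`` marks probes
    with no genomic placement.  ``intensity_only`` flags copy-number probes
    that yield no genotype.
    """

    name: str
    chromosome: str
    position: int
    alleles: str = "AB"
    intensity_only: bool = False

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position for SNP {self.name!r}")


@dataclass(frozen=True)
class GenotypeCluster:
    """Centre and dispersion of one genotype cloud in the (m, a) plane."""

    mean_m: float
    mean_a: float
    sd_m: float
    sd_a: float

    def __post_init__(self) -> None:
        if not (self.sd_m > 0 and self.sd_a > 0):
            raise ValueError("cluster dispersions must be strictly positive")


@dataclass(frozen=True)
class ClusterDefinition:
    """Population-derived AA/AB/BB cluster statistics for one SNP."""

    snp_name: str
    clusters: dict[str, GenotypeCluster]  # keys exactly {"AA", "AB", "BB"}

    def __post_init__(self) -> None:
        if set(self.clusters) != {"AA", "AB", "BB"}:
            raise ValueError(
                f"SNP {self.snp_name!r}: need exactly AA/AB/BB clusters, "
                f"got {sorted(self.clusters)}"
            )


@dataclass(frozen=True)
class NormalizationTransform:
    """Six-parameter affine map from raw to normalized channel intensities.

    Applied in four stages: subtract offsets, rotate by ``theta``, remove
    ``shear`` from the first coordinate, divide by the per-axis scales.
    """

    offset_x: float = 0.0
    offset_y: float = 0.0
    theta: float = 0.0
    shear: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale_x > 0 and self.scale_y > 0):
            raise ValueError("scale_x and scale_y must be strictly positive")

    @property
    def is_identity(self) -> bool:
        return all(
            math.isclose(getattr(self, f), v, abs_tol=0.0)
            for f, v in (
                ("offset_x", 0.0), ("offset_y", 0.0), ("theta", 0.0),
                ("shear", 0.0), ("scale_x", 1.0), ("scale_y", 1.0),
            )
        )


@dataclass(frozen=True)
class GtcRecord:
    """One genotype call as stored in a GTC-dialect file."""

    snp_index: int
    gtype: str            # one of GENOTYPES
    score: float          # vendor GenCall score in [0, 1]
    x_raw: int            # raw channel intensities, uint16 range
    y_raw: int
    transform_index: int = 0

    def __post_init__(self) -> None:
        if self.gtype not in GENOTYPES:
            raise ValueError(f"invalid genotype {self.gtype!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.x_raw < 0 or self.y_raw < 0:
            raise ValueError("raw intensities must be non-negative")


@dataclass(frozen=True)
class SampleSheetEntry:
    """One sample in the user-provided sheet."""

    sample_id: str
    gtc_path: str
    individual: str | None = None
    family: str | None = None


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic single-cell array batch.

    Defaults emulate a batch of 23 haploid (sperm) single cells from two
    families amplified by multiple-displacement amplification: heavy
    allele drop-in (spurious heterozygosity at low log-average intensity)
    plus a baseline no-call rate.  ``ado_rate`` only acts on heterozygous
    templates; for haploid cells amplification failure of the single
    allele surfaces as a no-call instead.
    """

    n_samples: int = 23
    n_snps: int = 20_000
    ploidy: str = "haploid"                  # "haploid" | "diploid"
    families: tuple[tuple[str, int], ...] = (("F1", 12), ("F2", 11))
    ado_rate: float = 0.20
    adi_rate: float = 0.10
    nc_rate: float = 0.03
    intensity_only_fraction: float = 0.02
    seed: int = 0
    # per-genotype cluster geometry in (m, a) log2 space
    cluster_geometry: dict = field(default_factory=lambda: {
        "AA": {"mean": (4.0, 10.0), "sd": (0.45, 0.35)},
        "AB": {"mean": (0.0, 10.0), "sd": (0.45, 0.35)},
        "BB": {"mean": (-4.0, 10.0), "sd": (0.45, 0.35)},
        # drop-in artifact: m near zero at low log-average, inflated spread
        "ADI": {"mean": (0.0, 7.0), "sd": (0.9, 0.7)},
    })
    # Beta(alpha, beta) score models; correct calls mode ~0.8, errors ~0.45,
    # no-calls ~0.1 — discriminative but deliberately imperfect.
    score_model: dict = field(default_factory=lambda: {
        "correct": (9.0, 3.0),
        "error": (5.5, 6.5),
        "nc": (2.0, 10.0),
    })

    def __post_init__(self) -> None:
        for name in ("ado_rate", "adi_rate", "nc_rate",
                     "intensity_only_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        if sum(n for _, n in self.families) != self.n_samples:
            raise ValueError("family sample counts must sum to n_samples")
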