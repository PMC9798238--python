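"""Genome templates: chromosome dimensions, SNP placement and the bp<->cM map.

A :class:`GenomeTemplate` fixes the coordinate systems the simulator and the
mapping stages share. Physical coordinates are 1-based bp; genetic
coordinates are cM measured from the chromosome start. The default
recombination-rate map is uniform (a single linear bp->cM segment), but a
piecewise-linear map can be supplied through per-chromosome anchor arrays.

The default chromosome dimensions mirror a dense maize biparental map: ten
chromosomes, ~2.06 Gb and 2180.93 cM in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Per-chromosome (bp length, cM length, SNP count) of the maize RIL map the
# simulator emulates by default (chromosomes 1..10).
MAIZE_BP_LENGTHS = [
    301_476_924, 237_917_468, 232_245_527, 242_062_272, 217_959_525,
    169_407_836, 176_826_311, 175_377_492, 157_038_028, 149_632_204,
]
MAIZE_CM_LENGTHS = [
    360.88, 258.14, 233.27, 247.66, 204.27,
    183.40, 197.27, 192.74, 171.88, 131.41,
]
MAIZE_SNP_COUNTS = [
    10_773, 9_213, 10_214, 8_665, 6_335, 7_218, 6_923, 7_949, 5_402, 4_988,
]


class ConfigurationError(ValueError):
    """Invalid simulator or pipeline configuration."""


@dataclass
class GenomeTemplate:
    """Chromosome names/lengths, SNP positions, and the bp<->cM map.

    ``bp_anchors[chrom]`` / ``cm_anchors[chrom]`` are matched monotone arrays
    defining a piecewise-linear genetic map; the default is the two-point
    anchor ((0, L_bp), (0, L_cM)), i.e. a uniform recombination rate.
    """

    chrom_names: list[str]
    bp_lengths: dict[str, int]
    cm_lengths: dict[str, float]
    snp_positions: dict[str, np.ndarray]
    bp_anchors: dict[str, np.ndarray] = field(default_factory=dict)
    cm_anchors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chrom_names:
            if self.bp_lengths[chrom] <= 0:
                raise ConfigurationError(f"{chrom}: non-positive bp length")
            if self.cm_lengths[chrom] < 0:
                raise ConfigurationError(f"{chrom}: negative cM length")
            pos = np.asarray(self.snp_positions[chrom], dtype=np.int64)
            if pos.size and (pos.min() < 1 or pos.max() > self.bp_lengths[chrom]):
                raise ConfigurationError(f"{chrom}: SNP positions off chromosome")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ConfigurationError(f"{chrom}: SNP positions not strictly increasing")
            self.snp_positions[chrom] = pos
            if chrom not in self.bp_anchors:
                self.bp_anchors[chrom] = np.array([0.0, float(self.bp_lengths[chrom])])
                self.cm_anchors[chrom] = np.array([0.0, float(self.cm_lengths[chrom])])

    @property
    def total_cm(self) -> float:
        return float(sum(self.cm_lengths.values()))

    @property
    def total_bp(self) -> int:
        return int(sum(self.bp_lengths.values()))

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray:
        return np.interp(np.asarray(bp, dtype=float),
                         self.bp_anchors[chrom], self.cm_anchors[chrom])

    def cm_to_bp(self, chrom: str, cm) -> np.ndarray:
        """Inverse genetic map; on zero-cM chromosomes every cM maps to bp 0."""
        cma = self.cm_anchors[chrom]
        if cma[-1] <= 0:
            return np.zeros_like(np.asarray(cm, dtype=float))
        return np.interp(np.asarray(cm, dtype=float), cma, self.bp_anchors[chrom])

    def snp_cm(self, chrom: str) -> np.ndarray:
        return self.bp_to_cm(chrom, self.snp_positions[chrom])


def build_genome_template(
    n_chrom: int,
    bp_lengths,
    cm_lengths,
    n_snps_per_chrom,
    seed: int = 0,
    chrom_names: list[str] | None = None,
) -> GenomeTemplate:
    """Draw SNP positions uniformly without replacement on each chromosome.

    ``bp_lengths``, ``cm_lengths`` and ``n_snps_per_chrom`` may be scalars
    (shared by all chromosomes) or per-chromosome sequences of length
    ``n_chrom``.
    """

    def _expand(x, cast):
        if np.isscalar(x):
            return [cast(x)] * n_chrom
        x = list(x)
        if len(x) != n_chrom:
            raise ConfigurationError(
                f"expected {n_chrom} per-chromosome values, got {len(x)}"
            )
        return [cast(v) for v in x]

    bp = _expand(bp_lengths, int)
    cm = _expand(cm_lengths, float)
    counts = _expand(n_snps_per_chrom, int)
    if any(v <= 0 for v in bp):
        raise ConfigurationError("bp lengths must be positive")
    if any(v < 0 for v in cm):
        raise ConfigurationError("cM lengths must be non-negative")
    if any(c < 2 for c in counts):
        raise ConfigurationError("need at least 2 SNPs per chromosome")

    names = chrom_names or [f"chr{i + 1}" for i in range(n_chrom)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    snp_positions = {}
    for name, length, count in zip(names, bp, counts):
        if count > length:
            raise ConfigurationError(f"{name}: more SNPs than bp positions")
        pos = np.unique(rng.integers(1, length + 1, size=count))
        while pos.size < count:  # top up duplicates; rare for sparse SNPs
            extra = rng.integers(1, length + 1, size=count - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        snp_positions[name] = pos.astype(np.int64)
    return GenomeTemplate(
        chrom_names=names,
        bp_lengths=dict(zip(names, bp)),
        cm_lengths=dict(zip(names, cm)),
        snp_positions=snp_positions,
    )


def maize_template(seed: int = 0, snp_scale: float = 1.0) -> GenomeTemplate:
    """The default ten-chromosome maize-like template (~2,181 cM).

    ``snp_scale`` thins or densifies the per-chromosome SNP counts, keeping
    the chromosome dimensions fixed.
    """
    counts = [max(2, int(round(c * snp_scale))) for c in MAIZE_SNP_COUNTS]
    return build_genome_template(
        n_chrom=10,
        bp_lengths=MAIZE_BP_LENGTHS,
        cm_lengths=MAIZE_CM_LENGTHS,
        n_snps_per_chrom=counts,
        seed=seed,
    )
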