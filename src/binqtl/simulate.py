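"""Synthetic RIL populations with breakpoint truth and replicated phenotypes.

The generator emulates the data a genotyping-by-sequencing study of a
biparental recombinant inbred line (RIL) population produces after variant
calling: parental-origin SNP calls for a few hundred lines on ten
chromosomes, ~1% miscalls and a few percent missing data, residual
heterozygosity from a finite number of selfing generations, and a
multi-environment replicated quantitative trait controlled by several
additive QTLs.

Meioses place crossovers as a Poisson count with mean equal to the
chromosome's genetic length in Morgans, positions uniform on the cM scale
(no interference). Lines descend from the F1 by single-seed descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeTemplate
from .matrix import A, B, H, N, SNPCallMatrix

Hap = tuple[np.ndarray, np.ndarray]  # (segment end coords, labels in {0,1})


def _merge_equal(ends: np.ndarray, labels: np.ndarray) -> Hap:
    """Drop zero-length segments, then fuse adjacent equal-label segments."""
    if ends.size == 0:
        return ends, labels
    prev = np.concatenate([[np.minimum(ends[0], 0) * 0], ends[:-1]])
    keep = ends > prev
    ends, labels = ends[keep], labels[keep]
    keep = np.concatenate([labels[:-1] != labels[1:], [True]])
    return ends[keep], labels[keep]


def _splice(hapa: Hap, hapb: Hap, xo: np.ndarray, start: int, length: float) -> Hap:
    """Gamete from two haplotypes with crossovers at ``xo`` (cM coords)."""
    cut = np.unique(np.concatenate([xo, hapa[0], hapb[0], [length]]))
    cut = cut[(cut > 0) & (cut <= length)]
    lows = np.concatenate([[0.0], cut[:-1]])
    mids = (lows + cut) / 2.0
    parity = (np.searchsorted(xo, mids) + start) % 2
    la = hapa[1][np.searchsorted(hapa[0], mids)]
    lb = hapb[1][np.searchsorted(hapb[0], mids)]
    labels = np.where(parity == 0, la, lb).astype(np.int8)
    return _merge_equal(cut, labels)


def _meiosis(plant: tuple[Hap, Hap], cm_length: float, rng: np.random.Generator) -> Hap:
    hapa, hapb = plant
    internal = cm_length if cm_length > 0 else 1.0
    n_xo = rng.poisson(cm_length / 100.0)
    start = int(rng.integers(0, 2))
    if n_xo == 0:
        src = (hapa, hapb)[start]
        return src[0].copy(), src[1].copy()
    xo = np.sort(rng.uniform(0.0, internal, size=n_xo))
    return _splice(hapa, hapb, xo, start, internal)


def _diploid_segments(h1: Hap, h2: Hap) -> tuple[np.ndarray, np.ndarray]:
    """Merge two haplotypes into A/H/B segments (still on the cM scale)."""
    cut = np.unique(np.concatenate([h1[0], h2[0]]))
    lows = np.concatenate([[0.0], cut[:-1]])
    mids = (lows + cut) / 2.0
    l1 = h1[1][np.searchsorted(h1[0], mids)]
    l2 = h2[1][np.searchsorted(h2[0], mids)]
    labels = np.where(l1 == l2, np.where(l1 == 0, A, B), H).astype(np.int8)
    return _merge_equal(cut, labels)


@dataclass
class TrueGenome:
    """Ground-truth parental-origin mosaic of each simulated line.

    ``segments[chrom][i]`` is ``(ends_bp, labels)`` for line ``i``: segment
    ``k`` covers 1-based positions ``(ends_bp[k-1], ends_bp[k]]`` and carries
    label A, B or H. Segment boundaries other than the chromosome end are the
    true recombination breakpoints.
    """

    lines: list[str]
    chrom_lengths: dict[str, int]
    segments: dict[str, list[tuple[np.ndarray, np.ndarray]]]

    def junctions(self, chrom: str, line_idx: int) -> np.ndarray:
        """True breakpoint positions (bp) for one line on one chromosome."""
        return self.segments[chrom][line_idx][0][:-1]

    def n_breakpoints(self) -> np.ndarray:
        """True breakpoint count per line, summed over chromosomes."""
        counts = np.zeros(len(self.lines), dtype=int)
        for chrom in self.segments:
            for i, (ends, _) in enumerate(self.segments[chrom]):
                counts[i] += ends.size - 1
        return counts

    def n_crossovers(self) -> np.ndarray:
        """Per-line count of switches between successive homozygous labels.

        Residual-het tracts are skipped, so an A-H-B stretch counts as one
        crossover; this is the count the 2x map-expansion expectation for
        selfed RILs refers to.
        """
        counts = np.zeros(len(self.lines), dtype=int)
        for chrom in self.segments:
            for i, (_, labels) in enumerate(self.segments[chrom]):
                hom = labels[labels != H]
                if hom.size > 1:
                    counts[i] += int((hom[:-1] != hom[1:]).sum())
        return counts

    def het_fraction(self) -> float:
        """Length-weighted fraction of the genomes that is heterozygous."""
        het = total = 0.0
        for chrom, per_line in self.segments.items():
            for ends, labels in per_line:
                lengths = np.diff(np.concatenate([[0], ends]))
                het += lengths[labels == H].sum()
                total += ends[-1]
        return het / total if total else 0.0

    def label_at(self, chrom: str, line_idx: int, positions) -> np.ndarray:
        ends, labels = self.segments[chrom][line_idx]
        idx = np.searchsorted(ends, np.asarray(positions, dtype=np.int64), side="left")
        return labels[np.minimum(idx, labels.size - 1)]

    def majority_label(self, chrom: str, line_idx: int, start: int, end: int) -> int:
        """Label occupying most bp of the 0-based half-open window [start, end)."""
        ends, labels = self.segments[chrom][line_idx]
        lows = np.concatenate([[0], ends[:-1]])
        overlap = np.minimum(ends, end) - np.maximum(lows, start)
        overlap = np.clip(overlap, 0, None)
        weights = np.zeros(3)
        for code in (A, B, H):
            weights[code] = overlap[labels == code].sum()
        return int(np.argmax(weights))

    def to_bed(self, path) -> None:
        """Write segments as a BED-like table (0-based half-open)."""
        rows = []
        for chrom, per_line in self.segments.items():
            for i, (ends, labels) in enumerate(per_line):
                lows = np.concatenate([[0], ends[:-1]])
                for lo, hi, lab in zip(lows, ends, labels):
                    rows.append((chrom, int(lo), int(hi), self.lines[i], "ABH"[lab]))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "line", "genotype"]).to_csv(
            path, sep="\t", index=False
        )


def simulate_ril_population(
    template: GenomeTemplate,
    n_lines: int,
    selfing_generations: int = 6,
    seed: int = 0,
) -> tuple[TrueGenome, SNPCallMatrix]:
    """Simulate RILs by single-seed descent from the F1 of an A x B cross.

    ``selfing_generations`` counts meiosis rounds after the F1 (1 gives an
    F2, 6 the near-homozygous F7 typical of RIL panels). Returns the true
    genome mosaics and the error-free SNP call matrix read off them.
    """
    if selfing_generations < 1:
        raise ConfigurationError("selfing_generations must be >= 1")
    if n_lines < 1:
        raise ConfigurationError("n_lines must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    segments: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        c: [] for c in template.chrom_names
    }
    calls: dict[str, np.ndarray] = {}

    for chrom in template.chrom_names:
        cm_len = template.cm_lengths[chrom]
        bp_len = template.bp_lengths[chrom]
        internal = cm_len if cm_len > 0 else 1.0
        snp_pos = template.snp_positions[chrom]
        chrom_calls = np.empty((n_lines, snp_pos.size), dtype=np.int8)
        f1 = (
            (np.array([internal]), np.array([0], dtype=np.int8)),
            (np.array([internal]), np.array([1], dtype=np.int8)),
        )
        for i in range(n_lines):
            plant = f1
            for _ in range(selfing_generations):
                plant = (_meiosis(plant, cm_len, rng), _meiosis(plant, cm_len, rng))
            ends_cm, labels = _diploid_segments(*plant)
            # segment ends back to physical coordinates
            if cm_len > 0:
                ends_bp = np.round(template.cm_to_bp(chrom, ends_cm)).astype(np.int64)
            else:
                ends_bp = np.array([bp_len], dtype=np.int64)
                labels = labels[-1:]
            ends_bp[-1] = bp_len
            ends_bp, labels = _merge_equal(ends_bp, labels)
            segments[chrom].append((ends_bp, labels))
            idx = np.searchsorted(ends_bp, snp_pos, side="left")
            chrom_calls[i] = labels[np.minimum(idx, labels.size - 1)]
        calls[chrom] = chrom_calls

    truth = TrueGenome(
        lines=lines,
        chrom_lengths=dict(template.bp_lengths),
        segments=segments,
    )
    matrix = SNPCallMatrix(
        lines=lines,
        positions={c: template.snp_positions[c].copy() for c in template.chrom_names},
        calls=calls,
    )
    return truth, matrix


def corrupt_genotypes(
    matrix: SNPCallMatrix,
    error_rate: float,
    missing_rate: float,
    seed: int = 0,
) -> SNPCallMatrix:
    """Flip calls to a uniformly chosen other code, then mask to missing.

    Each non-missing call is independently replaced by one of the two other
    genotype codes with probability ``error_rate``, then set to N with
    probability ``missing_rate``. The input matrix is left unmodified.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = matrix.copy()
    for chrom in out.chroms:
        m = out.calls[chrom]
        observed = m != N
        if error_rate > 0:
            flip = observed & (rng.random(m.shape) < error_rate)
            offset = rng.integers(1, 3, size=m.shape, dtype=np.int8)
            m[flip] = (m[flip] + offset[flip]) % 3
        if missing_rate > 0:
            m[observed & (rng.random(m.shape) < missing_rate)] = N
    return out


# --------------------------------------------------------------------------
# Trait architecture and phenotypes


@dataclass
class TraitArchitecture:
    """Additive QTLs plus the variance structure of a multi-environment trial.

    Variances are on the trait-unit² scale: ``var_gy``/``var_gl``/``var_gly``
    are the genotype x year / x location / x year x location interaction
    components and ``var_e`` the plot residual. ``var_env`` and ``var_rep``
    are environment-mean and replicate-block components; they shift
    environment means but cancel from entry-mean heritability. ``var_g`` is
    the target genotypic variance implied by the QTL effects (informational —
    the genetic value of a line is always the raw sum of its QTL scores).
    """

    qtls: list[tuple[str, int, float]]
    var_gy: float = 0.1
    var_gl: float = 0.1
    var_gly: float = 0.2
    var_e: float = 0.15
    years: list = field(default_factory=lambda: [2018, 2019])
    locations: list = field(default_factory=lambda: ["L1", "L2"])
    reps: int = 3
    env_cells: list[tuple] | None = None  # subset of years x locations
    var_env: float = 0.25
    var_rep: float = 0.05
    intercept: float = 10.0
    var_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("var_gy", "var_gl", "var_gly", "var_e", "var_env", "var_rep"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.reps < 1 or not self.years or not self.locations:
            raise ConfigurationError("design counts must be >= 1")
        if self.env_cells is None:
            self.env_cells = list(product(self.years, self.locations))
        for y, loc in self.env_cells:
            if y not in self.years or loc not in self.locations:
                raise ConfigurationError(f"environment cell ({y},{loc}) not in design")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    def env_name(self, year, loc) -> str:
        return f"{loc}{year}"


def unbalanced_trial_environments() -> tuple[list, list, list[tuple]]:
    """The unbalanced three-environment layout: one location in two years
    plus a second location in one year."""
    years = [2018, 2019]
    locations = ["GZL", "HEB"]
    cells = [(2018, "GZL"), (2019, "GZL"), (2019, "HEB")]
    return years, locations, cells


def genetic_values(truth: TrueGenome, qtls) -> np.ndarray:
    """Sum of additive QTL scores per line; x = +1 (A), 0 (H), -1 (B)."""
    g = np.zeros(len(truth.lines))
    for chrom, pos, effect in qtls:
        if chrom not in truth.segments:
            raise ConfigurationError(f"QTL chromosome {chrom} not simulated")
        if not 1 <= pos <= truth.chrom_lengths[chrom]:
            raise ConfigurationError(f"QTL position {chrom}:{pos} off chromosome")
        for i in range(len(truth.lines)):
            lab = int(truth.label_at(chrom, i, [pos])[0])
            g[i] += effect * (1 if lab == A else -1 if lab == B else 0)
    return g


def architecture_for_h2(
    truth: TrueGenome,
    qtls,
    h2: float,
    profile: tuple[float, float, float, float] = (0.1, 0.1, 0.2, 0.15),
    **kwargs,
) -> TraitArchitecture:
    """Scale a noise profile so the entry-mean H² formula hits ``h2``.

    The realized genotypic variance of the simulated lines is computed from
    the QTL scores; the (gy, gl, gly, e) profile is then multiplied by a
    single factor so that ``var_g / (var_g + noise-on-entry-mean)`` equals
    the target for the architecture's Y x L x R design.
    """
    if not 0 < h2 < 1:
        raise ConfigurationError("h2 must be in (0, 1)")
    base = TraitArchitecture(qtls=qtls, **kwargs)
    var_g = float(np.var(genetic_values(truth, qtls), ddof=1))
    if var_g <= 0:
        raise ConfigurationError("QTLs give zero genetic variance; cannot tune H²")
    y, loc, r = base.n_years, base.n_locations, base.reps
    gy, gl, gly, e = profile
    d0 = gy / y + gl / loc + gly / (loc * y) + e / (loc * y * r)
    s = var_g * (1.0 / h2 - 1.0) / d0
    return TraitArchitecture(
        qtls=qtls,
        var_gy=s * gy,
        var_gl=s * gl,
        var_gly=s * gly,
        var_e=s * e,
        var_g=var_g,
        **kwargs,
    )


def simulate_phenotypes(
    truth: TrueGenome,
    arch: TraitArchitecture,
    seed: int = 0,
) -> pd.DataFrame:
    """One record per line x environment x replicate.

    value = intercept + genetic value + env + rep(env) + G x Y + G x L +
    G x Y x L + residual, with the interaction and residual deviations drawn
    normal with the architecture's variances.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(truth.lines)
    g = genetic_values(truth, arch.qtls)

    def _draw(var: float, size) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(var), size=size) if var > 0 else np.zeros(size)

    gy = {y: _draw(arch.var_gy, n) for y in arch.years}
    gl = {l: _draw(arch.var_gl, n) for l in arch.locations}
    gly = {cell: _draw(arch.var_gly, n) for cell in arch.env_cells}
    env_eff = {cell: float(_draw(arch.var_env, 1)[0]) for cell in arch.env_cells}
    rep_eff = {
        (cell, r): float(_draw(arch.var_rep, 1)[0])
        for cell in arch.env_cells
        for r in range(1, arch.reps + 1)
    }

    rows = []
    for cell in arch.env_cells:
        year, loc = cell
        env = arch.env_name(year, loc)
        line_mean = arch.intercept + g + gy[year] + gl[loc] + gly[cell] + env_eff[cell]
        for r in range(1, arch.reps + 1):
            resid = _draw(arch.var_e, n)
            values = line_mean + rep_eff[(cell, r)] + resid
            for i in range(n):
                rows.append((truth.lines[i], env, year, loc, r, values[i]))
    return pd.DataFrame(
        rows, columns=["line", "env", "year", "location", "rep", "value"]
    )
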