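"""Post-calling SNP filters for a biparental progeny genotype matrix.

The filters reproduce the standard screens applied to GBS calls before bin
calling: keep only SNPs where the two parents are homozygous for different
alleles, recode progeny by parental origin (alleles absent from both parents
are unscorable), drop SNPs with segregation distortion by a chi-square test
against the 1:1 RIL expectation, drop SNPs/lines with poor call rates, and
drop SNPs on unanchored scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import A, B, H, N, SNPCallMatrix


class NoInformativeMarkersError(ValueError):
    """No SNP distinguishes the two parents."""


class EmptyMatrixError(ValueError):
    """A filter removed all SNPs or all lines."""


@dataclass
class QCReport:
    """Counts removed per filter, written alongside the filtered matrix."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)  # name, removed, kept

    def add(self, name: str, removed: int, kept: int) -> None:
        self.steps.append((name, removed, kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "removed", "kept"])


def _alleles(genotype: str) -> tuple[str, str]:
    g = genotype.replace("/", "").replace("|", "").upper()
    if len(g) == 1:  # haploid-style shorthand
        g = g * 2
    if len(g) != 2:
        raise ValueError(f"cannot parse genotype {genotype!r}")
    return g[0], g[1]


def select_parental_informative(
    parent1_calls: pd.Series | dict,
    parent2_calls: pd.Series | dict,
) -> pd.DataFrame:
    """SNPs where both parents are homozygous for different alleles.

    Inputs map SNP identifiers to base genotypes (``"AA"``, ``"A/T"`` ...).
    Returns a frame indexed by SNP id with the parent-1 and parent-2 alleles
    of the retained (aa x bb) SNPs.
    """
    p1 = pd.Series(parent1_calls)
    p2 = pd.Series(parent2_calls)
    common = p1.index.intersection(p2.index)
    rows = {}
    for snp in common:
        a1, a2 = _alleles(str(p1[snp]))
        b1, b2 = _alleles(str(p2[snp]))
        if a1 == a2 and b1 == b2 and a1 != b1 and a1 != "N" and b1 != "N":
            rows[snp] = (a1, b1)
    if not rows:
        raise NoInformativeMarkersError(
            "no SNP has both parents homozygous for different alleles"
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=["allele1", "allele2"])


def encode_by_parent(
    progeny_alleles: pd.DataFrame,
    informative_snps: pd.DataFrame,
) -> pd.DataFrame:
    """Recode progeny base calls to A/B/H by parental origin.

    ``progeny_alleles`` is lines x SNPs of base genotypes. Alleles carried by
    neither parent are abnormal bases: the call becomes N. SNPs absent from
    the informative set are excluded.
    """
    snps = [s for s in progeny_alleles.columns if s in informative_snps.index]
    out = pd.DataFrame(index=progeny_alleles.index, columns=snps, dtype=object)
    for snp in snps:
        a, b = informative_snps.loc[snp, ["allele1", "allele2"]]
        for line in progeny_alleles.index:
            raw = progeny_alleles.at[line, snp]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                out.at[line, snp] = "N"
                continue
            g1, g2 = _alleles(str(raw))
            pair = {g1, g2}
            if pair == {a}:
                out.at[line, snp] = "A"
            elif pair == {b}:
                out.at[line, snp] = "B"
            elif pair == {a, b}:
                out.at[line, snp] = "H"
            else:
                out.at[line, snp] = "N"  # abnormal base
    return out


def segregation_chi2(matrix: SNPCallMatrix) -> dict[str, np.ndarray]:
    """Per-SNP chi-square p-value of A:B counts against 1:1 (H, N excluded)."""
    pvals = {}
    for chrom in matrix.chroms:
        m = matrix.calls[chrom]
        n_a = (m == A).sum(axis=0).astype(float)
        n_b = (m == B).sum(axis=0).astype(float)
        total = n_a + n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = (n_a - n_b) ** 2 / total
        p = stats.chi2.sf(chi2, df=1)
        p[total == 0] = 0.0  # zero informative calls: remove (logged by caller)
        pvals[chrom] = p
    return pvals


def filter_segregation(
    matrix: SNPCallMatrix,
    alpha: float = 0.001,
    continuity_correction: bool = False,
    report: QCReport | None = None,
) -> SNPCallMatrix:
    """Remove SNPs whose A:B segregation deviates from 1:1 at p < alpha."""
    keep = {}
    removed = kept = 0
    for chrom in matrix.chroms:
        m = matrix.calls[chrom]
        n_a = (m == A).sum(axis=0).astype(float)
        n_b = (m == B).sum(axis=0).astype(float)
        total = n_a + n_b
        diff = np.abs(n_a - n_b)
        if continuity_correction:
            diff = np.clip(diff - 1.0, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = diff**2 / total
        p = stats.chi2.sf(chi2, df=1)
        mask = (total > 0) & (p >= alpha)
        keep[chrom] = mask
        removed += int((~mask).sum())
        kept += int(mask.sum())
    if report is not None:
        report.add("segregation_chi2", removed, kept)
    return matrix.subset_snps(keep)


def filter_call_rate(
    matrix: SNPCallMatrix,
    min_snp_rate: float = 0.2,
    min_line_rate: float = 0.2,
    report: QCReport | None = None,
) -> SNPCallMatrix:
    """Drop low-call-rate SNPs first, then low-call-rate lines (fixed order)."""
    for name, rate in (("min_snp_rate", min_snp_rate), ("min_line_rate", min_line_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    snp_rates = matrix.snp_call_rate()
    keep = {c: snp_rates[c] >= min_snp_rate for c in matrix.chroms}
    out = matrix.subset_snps(keep)
    n_removed_snps = matrix.n_snps - out.n_snps
    line_mask = out.line_call_rate() >= min_line_rate
    n_removed_lines = int((~line_mask).sum())
    out = out.subset_lines(line_mask)
    if out.n_snps == 0 or out.n_lines == 0:
        raise EmptyMatrixError("call-rate filter removed all data")
    if report is not None:
        report.add("call_rate_snps", n_removed_snps, out.n_snps)
        report.add("call_rate_lines", n_removed_lines, out.n_lines)
    return out


def filter_chromosome_allowlist(
    matrix: SNPCallMatrix,
    allowed: list[str] | None = None,
    report: QCReport | None = None,
) -> SNPCallMatrix:
    """Drop SNPs on unanchored sequences (names outside the allow-list)."""
    if allowed is None:
        allowed = [f"chr{i}" for i in range(1, 11)]
    keep = {c: np.ones(matrix.positions[c].size, dtype=bool)
            for c in matrix.chroms if c in allowed}
    out = matrix.subset_snps(keep)
    if report is not None:
        report.add("scaffold_snps", matrix.n_snps - out.n_snps, out.n_snps)
    return out


def run_qc(
    matrix: SNPCallMatrix,
    alpha: float = 0.001,
    min_snp_rate: float = 0.2,
    min_line_rate: float = 0.2,
    allowed_chroms: list[str] | None = None,
) -> tuple[SNPCallMatrix, QCReport]:
    """Apply the full post-calling filter chain; returns matrix and report."""
    report = QCReport()
    out = matrix
    if allowed_chroms is not None:
        out = filter_chromosome_allowlist(out, allowed_chroms, report)
    out = filter_call_rate(out, min_snp_rate, min_line_rate, report)
    out = filter_segregation(out, alpha, report=report)
    if out.n_snps == 0:
        raise EmptyMatrixError("QC removed all SNPs")
    return out, report
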