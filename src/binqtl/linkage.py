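"""Recombination fractions between adjacent bins and the Kosambi genetic map.

Bin order is fixed by physical position. For a selfed RIL population the
observed fraction of discordant homozygous pairs between adjacent bins, R,
relates to the meiotic recombination fraction r by R = 2r/(1+2r); the Kosambi
map function d = 25·ln((1+2r)/(1−2r)) converts r to cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binmap import BinMap
from .matrix import A, B

R_CAP = 0.4999  # meiotic r is capped just below independence


def kosambi(r) -> np.ndarray | float:
    """Kosambi map distance in cM; requires 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d) -> np.ndarray | float:
    """Meiotic r from a Kosambi distance in cM: r = tanh(d/50)/2."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def ril_r_from_observed(R) -> np.ndarray | float:
    """Invert the selfed-RIL relation R = 2r/(1+2r); capped below 0.5."""
    R = np.asarray(R, dtype=float)
    r = np.where(R < 1.0, R / (2.0 * (1.0 - R)), np.inf)
    r = np.minimum(r, R_CAP)
    return float(r) if r.ndim == 0 else r


def observed_from_ril_r(r) -> np.ndarray | float:
    """Forward selfed-RIL relation R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def estimate_rf(geno_a: np.ndarray, geno_b: np.ndarray, min_pairs: int = 2):
    """Meiotic r between two bins from their line genotype codes.

    Only pairs where both bins are homozygous (A or B) are informative; H and
    N are excluded. Returns ``(r, n_pairs)``; r is ``None`` when fewer than
    ``min_pairs`` informative pairs exist.
    """
    a = np.asarray(geno_a)
    b = np.asarray(geno_b)
    hom = np.isin(a, (A, B)) & np.isin(b, (A, B))
    n = int(hom.sum())
    if n < min_pairs:
        return None, n
    discordant = int((a[hom] != b[hom]).sum())
    return float(ril_r_from_observed(discordant / n)), n


@dataclass
class GeneticMap:
    """Per-bin cM coordinates plus a per-chromosome summary table.

    ``table`` columns: chrom, bin_id, bp_start, bp_end, r_adjacent, d_cm,
    cum_cm (r_adjacent/d_cm refer to the interval to the PREVIOUS bin and are
    NaN for the first bin of a chromosome). Bins whose adjacent r was
    undefined were merged into their left neighbour and are absent.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    merged_bins: list[str]

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @property
    def total_cm(self) -> float:
        return float(self.summary.loc[self.summary["chrom"] == "Total", "cm"].iloc[0])

    def to_csv(self, path, summary_path=None) -> None:
        self.table.to_csv(path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, index=False)


def _interval_recombination(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval recombination numerators/denominators for one chromosome.

    For each line, consecutive informative (homozygous) bins are compared; a
    discordant pair whose bins are separated by a run of H/N calls apportions
    its single recombination event uniformly over the spanned intervals,
    while the line counts once toward every spanned interval's denominator.
    With no gaps this reduces to the plain adjacent-bin discordance count.
    """
    n_lines, m = geno.shape
    num = np.zeros(m - 1) if m > 1 else np.zeros(0)
    den_diff = np.zeros(m) if m > 1 else np.zeros(1)
    for i in range(n_lines):
        g = geno[i]
        inf = np.flatnonzero((g == A) | (g == B))
        if inf.size < 2:
            continue
        den_diff[inf[0]] += 1
        den_diff[inf[-1]] -= 1
        v = g[inf]
        disc = v[:-1] != v[1:]
        span = np.diff(inf)
        w = disc / span
        for k in np.flatnonzero(disc):
            num[inf[k] : inf[k + 1]] += w[k]
    den = np.cumsum(den_diff)[:-1] if m > 1 else np.zeros(0)
    return num, den


def build_map(binmap: BinMap, min_pairs: int = 2) -> GeneticMap:
    """Adjacent recombination fractions and cumulative Kosambi positions.

    Recombination events of lines with uninformative (H/N) calls between
    their nearest homozygous bins are apportioned across the spanned
    intervals, so residual heterozygosity and missing bins do not shorten the
    map. Intervals covered by fewer than ``min_pairs`` informative lines give
    no distance: the right bin is merged into the left one and logged.
    """
    rows = []
    summary_rows = []
    merged: list[str] = []
    for chrom in binmap.bins["chrom"].unique():
        sl = binmap.chrom_slice(chrom)
        sub = binmap.bins.iloc[sl].reset_index(drop=True)
        geno = binmap.genotypes[:, sl]
        num, den = _interval_recombination(geno)
        kept = [0]
        r_list = [np.nan]
        carry_num = 0.0
        carry_den = np.inf
        for j in range(1, len(sub)):
            carry_num += num[j - 1]
            carry_den = min(carry_den, den[j - 1])  # coverage of the merged stretch
            if carry_den < min_pairs:
                merged.append(str(sub.loc[j, "bin_id"]))
                continue
            R = min(carry_num / carry_den, 0.999)
            kept.append(j)
            r_list.append(float(ril_r_from_observed(R)))
            carry_num = 0.0
            carry_den = np.inf
        d = np.array([np.nan] + [kosambi(r) for r in r_list[1:]])
        cum = np.concatenate([[0.0], np.cumsum(d[1:])]) if len(kept) else np.array([])
        for idx, (j, r_adj) in enumerate(zip(kept, r_list)):
            rows.append(
                (
                    chrom,
                    sub.loc[j, "bin_id"],
                    int(sub.loc[j, "start"]),
                    int(sub.loc[j, "end"]),
                    r_adj,
                    d[idx],
                    cum[idx],
                )
            )
        intervals = len(kept) - 1
        total = float(cum[-1]) if len(kept) else 0.0
        summary_rows.append(
            (
                chrom,
                len(kept),
                total,
                total / intervals if intervals > 0 else 0.0,
                float(np.nanmax(d)) if intervals > 0 else 0.0,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "bin_id", "bp_start", "bp_end", "r_adjacent", "d_cm", "cum_cm"],
    )
    summary = pd.DataFrame(
        summary_rows, columns=["chrom", "n_markers", "cm", "mean_adjacent_cm", "max_gap_cm"]
    )
    n_markers = int(summary["n_markers"].sum())
    total_cm = float(summary["cm"].sum())
    intervals = n_markers - len(summary)
    summary.loc[len(summary)] = (
        "Total",
        n_markers,
        total_cm,
        total_cm / intervals if intervals > 0 else 0.0,
        float(summary["max_gap_cm"].max()),
    )
    return GeneticMap(table=table, summary=summary, merged_bins=merged)
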