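"""Composite interval mapping on the bin map.

The scan is Haley-Knott regression of line phenotypes on expected genotype
scores. At a genotyped bin the score is the observed call (+1 for A, -1 for
B, 0 for a residual heterozygote); at missing calls and pseudomarker
positions the score is the conditional expectation given the nearest
informative flanking bins under a two-state selfed-RIL Markov chain whose
interval recombination probabilities come from Kosambi-inverted map
distances. Cofactor bins chosen by forward selection absorb background QTL
variance; cofactors within an exclusion window of the test position are
dropped from both the null and the QTL model, so

    LOD(t) = (n/2) * log10(RSS0 / RSS1)

compares the cofactor-only model with the cofactor+score model. With no
cofactors the scan reduces to simple interval mapping. Genome-wide
significance comes from permutation of the phenotype across lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binmap import BinMap
from .linkage import GeneticMap, kosambi_inverse, observed_from_ril_r
from .matrix import A, B, H

_TINY = 1e-12


@dataclass
class ScanGrid:
    """Evaluation positions and per-line expected genotype scores."""

    chrom: np.ndarray      # str per position
    pos_cm: np.ndarray
    pos_bp: np.ndarray     # physical anchor (bin midpoint at markers)
    pos_bp_lo: np.ndarray  # outer physical extent of the position's bin
    pos_bp_hi: np.ndarray
    is_marker: np.ndarray  # True where the position is a genotyped bin
    bin_id: np.ndarray     # bin id at marker positions, "" elsewhere
    scores: np.ndarray     # n_lines x n_pos, in [-1, 1]
    lines: list[str]

    @property
    def n_pos(self) -> int:
        return self.pos_cm.size

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)


def _no_recomb_prob(d_cm: np.ndarray) -> np.ndarray:
    """P(same RIL genotype class across an interval of d cM)."""
    return 1.0 - observed_from_ril_r(kosambi_inverse(np.asarray(d_cm, dtype=float)))


def genotype_probs(
    gmap: GeneticMap,
    binmap: BinMap,
    grid_step: float | None = None,
) -> ScanGrid:
    """Expected genotype scores at bin markers (plus an optional cM grid).

    ``grid_step=None`` evaluates at marker positions only; otherwise
    pseudomarkers every ``grid_step`` cM are merged in.
    """
    bin_col = {b: j for j, b in enumerate(binmap.bins["bin_id"])}
    chrom_arrays, cm_arrays, bp_arrays, marker_arrays, id_arrays, score_arrays = (
        [], [], [], [], [], []
    )
    bp_lo_arrays, bp_hi_arrays = [], []
    n_lines = len(binmap.lines)
    for chrom in gmap.table["chrom"].unique():
        sub = gmap.chrom_table(chrom)
        m_cm = sub["cum_cm"].to_numpy(dtype=float)
        m_bp = ((sub["bp_start"] + sub["bp_end"]) / 2.0).to_numpy(dtype=float)
        ids = sub["bin_id"].to_numpy()
        cols = [bin_col[b] for b in ids]
        geno = binmap.genotypes[:, cols]

        if grid_step is not None and m_cm.size and m_cm[-1] > 0:
            pseudo = np.arange(0.0, m_cm[-1], grid_step)
            pos = np.unique(np.concatenate([m_cm, pseudo]))
        else:
            pos = m_cm.copy()
        # map eval positions onto markers where they coincide
        m_idx = np.searchsorted(m_cm, pos)
        m_idx_c = np.minimum(m_idx, m_cm.size - 1)
        at_marker = np.isclose(m_cm[m_idx_c], pos)
        marker_of_pos = np.where(at_marker, m_idx_c, -1)
        pos_bp = np.interp(pos, m_cm, m_bp) if m_cm.size > 1 else np.full(pos.size, m_bp[0] if m_bp.size else 0.0)
        # physical extent: the full bin at markers, the point at pseudomarkers
        m_lo = sub["bp_start"].to_numpy(dtype=float)
        m_hi = sub["bp_end"].to_numpy(dtype=float)
        pos_bp_lo = pos_bp.copy()
        pos_bp_hi = pos_bp.copy()
        at = marker_of_pos >= 0
        pos_bp_lo[at] = m_lo[marker_of_pos[at]]
        pos_bp_hi[at] = m_hi[marker_of_pos[at]]

        scores = np.zeros((n_lines, pos.size))
        for i in range(n_lines):
            g = geno[i]
            inf = np.flatnonzero((g == A) | (g == B))
            v = np.where(g == A, 1.0, -1.0)
            if inf.size == 0:
                continue
            inf_cm = m_cm[inf]
            li = np.searchsorted(inf_cm, pos, side="right") - 1
            ri = np.searchsorted(inf_cm, pos, side="left")
            has_l = li >= 0
            has_r = ri < inf.size
            dl = np.where(has_l, pos - inf_cm[np.clip(li, 0, None)], np.inf)
            dr = np.where(has_r, inf_cm[np.clip(ri, None, inf.size - 1)] - pos, np.inf)
            pl = _no_recomb_prob(np.where(np.isfinite(dl), dl, 0.0))
            pr = _no_recomb_prob(np.where(np.isfinite(dr), dr, 0.0))
            vl = v[inf[np.clip(li, 0, None)]]
            vr = v[inf[np.clip(ri, None, inf.size - 1)]]
            s = np.zeros(pos.size)
            both = has_l & has_r
            # two-state chain conditional on both flanks
            wa = np.where(vl > 0, pl, 1 - pl) * np.where(vr > 0, pr, 1 - pr)
            wb = np.where(vl < 0, pl, 1 - pl) * np.where(vr < 0, pr, 1 - pr)
            with np.errstate(invalid="ignore"):
                s_both = (wa - wb) / (wa + wb)
            s[both] = s_both[both]
            only_l = has_l & ~has_r
            s[only_l] = ((2 * pl - 1) * vl)[only_l]
            only_r = has_r & ~has_l
            s[only_r] = ((2 * pr - 1) * vr)[only_r]
            # observed calls are degenerate (H scores 0 additively)
            obs = marker_of_pos >= 0
            obs_idx = marker_of_pos[obs]
            g_obs = g[obs_idx]
            s_obs = s[obs]
            s_obs[g_obs == A] = 1.0
            s_obs[g_obs == B] = -1.0
            s_obs[g_obs == H] = 0.0
            s[obs] = s_obs
            scores[i] = s

        chrom_arrays.append(np.full(pos.size, chrom, dtype=object))
        cm_arrays.append(pos)
        bp_arrays.append(pos_bp)
        bp_lo_arrays.append(pos_bp_lo)
        bp_hi_arrays.append(pos_bp_hi)
        marker_arrays.append(marker_of_pos >= 0)
        id_arr = np.full(pos.size, "", dtype=object)
        id_arr[marker_of_pos >= 0] = ids[marker_of_pos[marker_of_pos >= 0]]
        id_arrays.append(id_arr)
        score_arrays.append(scores)

    return ScanGrid(
        chrom=np.concatenate(chrom_arrays),
        pos_cm=np.concatenate(cm_arrays),
        pos_bp=np.concatenate(bp_arrays),
        pos_bp_lo=np.concatenate(bp_lo_arrays),
        pos_bp_hi=np.concatenate(bp_hi_arrays),
        is_marker=np.concatenate(marker_arrays),
        bin_id=np.concatenate(id_arrays),
        scores=np.hstack(score_arrays),
        lines=list(binmap.lines),
    )


def select_cofactors(
    grid: ScanGrid,
    y: np.ndarray,
    n_cofactors: int = 5,
    alpha: float = 0.05,
    min_sep_cm: float = 10.0,
) -> list[int]:
    """Forward selection of marker cofactors by partial F-statistic.

    Greedily adds the marker most associated with the phenotype conditional
    on markers already chosen, stopping at ``n_cofactors`` or when the best
    candidate is not significant after Bonferroni correction for the number
    of candidate markers (so a pure-noise phenotype usually selects none).
    Candidates within ``min_sep_cm`` of a chosen cofactor on the same
    chromosome are excluded to avoid collinear sets.
    """
    if n_cofactors <= 0:
        return []
    y = np.asarray(y, dtype=float)
    n = y.size
    cand = np.flatnonzero(grid.is_marker)
    Xr = grid.scores[:, cand].copy()
    yr = y - y.mean()
    Xr = Xr - Xr.mean(axis=0)
    chosen: list[int] = []
    blocked = np.zeros(cand.size, dtype=bool)
    while len(chosen) < n_cofactors:
        norms = np.einsum("ij,ij->j", Xr, Xr)
        ok = (~blocked) & (norms > _TINY)
        if not ok.any():
            break
        rss0 = float(yr @ yr)
        if rss0 <= _TINY:
            break
        num = (Xr.T @ yr) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ok, num / (norms * rss0), 0.0)
        j = int(np.argmax(r2))
        dof = n - len(chosen) - 2
        if dof <= 0:
            break
        f = r2[j] / max(1.0 - r2[j], _TINY) * dof
        p = stats.f.sf(f, 1, dof)
        if p * cand.size >= alpha:
            break
        chosen.append(int(cand[j]))
        xj = Xr[:, j] / np.sqrt(norms[j])
        yr = yr - xj * (xj @ yr)
        Xr = Xr - np.outer(xj, xj @ Xr)
        same = grid.chrom[cand] == grid.chrom[cand[j]]
        near = np.abs(grid.pos_cm[cand] - grid.pos_cm[cand[j]]) <= min_sep_cm
        blocked |= same & near
    return chosen


def _retained_masks(
    grid: ScanGrid, cofactors: list[int], window_cm: float
) -> dict[tuple, np.ndarray]:
    """Group positions by which cofactors stay in the model there."""
    groups: dict[tuple, list[int]] = {}
    cof_chrom = [grid.chrom[c] for c in cofactors]
    cof_cm = [grid.pos_cm[c] for c in cofactors]
    for p in range(grid.n_pos):
        mask = tuple(
            not (cof_chrom[k] == grid.chrom[p] and abs(cof_cm[k] - grid.pos_cm[p]) <= window_cm)
            for k in range(len(cofactors))
        )
        groups.setdefault(mask, []).append(p)
    return {m: np.array(idx) for m, idx in groups.items()}


def _null_basis(n: int, cols: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of intercept + cofactor columns (rank-reduced)."""
    design = [np.ones((n, 1))]
    if cols is not None and cols.size:
        design.append(cols)
    D = np.hstack(design)
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-9 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def cim_scan(
    grid: ScanGrid,
    y: np.ndarray,
    cofactors: list[int] | None = None,
    window_cm: float = 10.0,
) -> np.ndarray:
    """LOD profile over the grid; cofactors near the test position drop out."""
    lods = _scan_matrix(grid, np.asarray(y, dtype=float)[:, None], cofactors, window_cm)
    return lods[:, 0]


def _scan_matrix(
    grid: ScanGrid,
    Y: np.ndarray,
    cofactors: list[int] | None,
    window_cm: float,
) -> np.ndarray:
    """LOD for each position x each phenotype column of Y (vectorized)."""
    cofactors = cofactors or []
    n = Y.shape[0]
    lods = np.zeros((grid.n_pos, Y.shape[1]))
    for mask, pos_idx in _retained_masks(grid, cofactors, window_cm).items():
        retained = [c for c, keep in zip(cofactors, mask) if keep]
        Q = _null_basis(n, grid.scores[:, retained] if retained else None)
        Yr = Y - Q @ (Q.T @ Y)
        rss0 = np.einsum("ij,ij->j", Yr, Yr)
        Xg = grid.scores[:, pos_idx]
        Xr = Xg - Q @ (Q.T @ Xg)
        norms = np.einsum("ij,ij->j", Xr, Xr)
        num = (Xr.T @ Yr) ** 2  # positions x phenotypes
        with np.errstate(divide="ignore", invalid="ignore"):
            num = np.where(norms[:, None] > _TINY, num / np.maximum(norms, _TINY)[:, None], 0.0)
            rss1 = np.maximum(rss0[None, :] - num, _TINY * np.maximum(rss0[None, :], 1.0))
            lod = 0.5 * n * np.log10(np.where(rss0 > _TINY, rss0 / rss1, 1.0))
        lods[pos_idx] = np.clip(np.nan_to_num(lod), 0.0, None)
    return lods


def permutation_max_lods(
    grid: ScanGrid,
    y: np.ndarray,
    cofactors: list[int] | None = None,
    window_cm: float = 10.0,
    n_perm: int = 1000,
    seed: int = 0,
    cofactor_policy: str = "fixed",
    n_cofactors: int = 5,
) -> np.ndarray:
    """Genome-wide maximum LOD for each phenotype permutation.

    Permutation i is drawn from an independent substream of ``seed`` so the
    set is reproducible regardless of batching. ``cofactor_policy='fixed'``
    keeps the observed-data cofactors; ``'reselect'`` redoes forward
    selection per permutation (slower).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    perms = np.empty((n, n_perm))
    for i in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        perms[:, i] = y[rng.permutation(n)]
    if cofactor_policy == "fixed":
        lods = _scan_matrix(grid, perms, cofactors, window_cm)
        return lods.max(axis=0)
    if cofactor_policy != "reselect":
        raise ValueError("cofactor_policy must be 'fixed' or 'reselect'")
    out = np.empty(n_perm)
    for i in range(n_perm):
        cof = select_cofactors(grid, perms[:, i], n_cofactors=n_cofactors)
        out[i] = _scan_matrix(grid, perms[:, i : i + 1], cof, window_cm).max()
    return out


def permutation_threshold(
    grid: ScanGrid,
    y: np.ndarray,
    cofactors: list[int] | None = None,
    window_cm: float = 10.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    cofactor_policy: str = "fixed",
) -> float:
    """Empirical (1 - alpha) quantile of the permutation max-LOD null."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    max_lods = permutation_max_lods(
        grid, y, cofactors, window_cm, n_perm, seed, cofactor_policy
    )
    return float(np.quantile(max_lods, 1.0 - alpha))  # type-7 interpolation


def support_interval(
    pos_cm: np.ndarray,
    pos_bp: np.ndarray,
    lod: np.ndarray,
    peak_idx: int,
    drop: float = 1.5,
    pos_bp_lo: np.ndarray | None = None,
    pos_bp_hi: np.ndarray | None = None,
) -> tuple[float, float, float, float, bool]:
    """LOD-drop support interval around a peak on one chromosome.

    Returns (cm_lo, cm_hi, bp_lo, bp_hi, clipped): the outermost span of
    chromosome positions with LOD >= peak - drop, expanded to the first
    flanking evaluation points below the cutoff (the convention of the
    standard lodint utility: secondary bumps within the drop widen the
    interval); ``clipped`` is True when the span runs into a chromosome end.
    When the flanking positions are bins, ``pos_bp_lo``/``pos_bp_hi`` supply
    their outer physical extents so the Mb interval spans the flanking bins
    entirely.
    """
    if pos_bp_lo is None:
        pos_bp_lo = pos_bp
    if pos_bp_hi is None:
        pos_bp_hi = pos_bp
    cutoff = lod[peak_idx] - drop
    above = np.flatnonzero(np.asarray(lod) >= cutoff)
    lo = int(above[0])
    hi = int(above[-1])
    clipped = False
    if lo > 0:
        lo -= 1  # first flanking point below the cutoff
    else:
        clipped = True
    if hi < lod.size - 1:
        hi += 1
    else:
        clipped = True
    return (
        float(pos_cm[lo]),
        float(pos_cm[hi]),
        float(pos_bp_lo[lo]),
        float(pos_bp_hi[hi]),
        clipped,
    )


def estimate_effects(x_peak: np.ndarray, y: np.ndarray, lod: float) -> tuple[float, float]:
    """(ADD, single-scan PVE) at a peak.

    ADD is half the A-class minus B-class difference, i.e. the regression
    coefficient of the phenotype on the expected genotype score (positive
    when the female-parent allele raises the trait). PVE = 100 * (1 -
    10^(-2 LOD / n)).
    """
    x = np.asarray(x_peak, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= _TINY:
        raise ValueError("peak genotype scores are constant; ADD undefined")
    add = float(xc @ (y - y.mean()) / denom)
    pve = 100.0 * (1.0 - 10.0 ** (-2.0 * lod / y.size))
    return add, pve


def fit_multi_qtl(
    grid: ScanGrid,
    peak_indices: list[int],
    y: np.ndarray,
    min_sep_cm: float = 1.0,
) -> pd.DataFrame:
    """Joint additive model over all peaks; PVE by drop-one R² difference.

    Peaks closer than ``min_sep_cm`` on one chromosome are merged (the one
    with the larger marginal correlation is kept).
    """
    y = np.asarray(y, dtype=float)
    if not peak_indices:
        return pd.DataFrame(columns=["peak_idx", "pve", "joint_r2"])
    kept: list[int] = []
    for p in sorted(set(peak_indices), key=lambda p: (grid.chrom[p], grid.pos_cm[p])):
        if kept and grid.chrom[kept[-1]] == grid.chrom[p] and (
            grid.pos_cm[p] - grid.pos_cm[kept[-1]] < min_sep_cm
        ):
            continue
        kept.append(p)

    def _r2(cols: list[int]) -> float:
        if not cols:
            return 0.0
        X = np.hstack([np.ones((y.size, 1)), grid.scores[:, cols]])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

    full = _r2(kept)
    rows = []
    for p in kept:
        others = [q for q in kept if q != p]
        rows.append((p, 100.0 * (full - _r2(others)), full))
    return pd.DataFrame(rows, columns=["peak_idx", "pve", "joint_r2"])


@dataclass
class QTLRecord:
    """One detected QTL in one environment/analysis."""

    name: str
    chrom: str
    env: str
    peak_cm: float
    peak_mb: float
    lod: float
    marker_lo: str
    marker_hi: str
    ci_lo_mb: float
    ci_hi_mb: float
    pve: float
    add: float
    ci_clipped: bool = False


@dataclass
class ScanResult:
    profile: pd.DataFrame  # chrom, pos_cm, pos_mb, lod
    threshold: float
    qtls: list[QTLRecord]
    cofactors: list[int]


def scan_trait(
    binmap: BinMap,
    gmap: GeneticMap,
    blue: pd.DataFrame,
    env: str = "BLUE",
    n_perm: int = 1000,
    alpha: float = 0.05,
    drop: float = 1.5,
    n_cofactors: int = 5,
    window_cm: float = 10.0,
    grid_step: float | None = None,
    seed: int = 0,
    cofactor_policy: str = "fixed",
    threshold: float | None = None,
) -> ScanResult:
    """Full CIM pass: cofactors, LOD profile, threshold, QTL records.

    ``blue`` must carry line/blue columns; lines are matched to the bin map
    by name. A precomputed ``threshold`` skips the permutation stage.
    """
    order = {ln: i for i, ln in enumerate(binmap.lines)}
    blue = blue[blue["line"].isin(order)].copy()
    blue = blue.sort_values("line", key=lambda s: s.map(order))
    if len(blue) < len(binmap.lines):
        raise ValueError("phenotype table does not cover all bin-map lines")
    y = blue["blue"].to_numpy(dtype=float)

    grid = genotype_probs(gmap, binmap, grid_step=grid_step)
    cof = select_cofactors(grid, y, n_cofactors=n_cofactors)
    lod = cim_scan(grid, y, cof, window_cm)
    if threshold is None:
        threshold = permutation_threshold(
            grid, y, cof, window_cm, n_perm, alpha, seed, cofactor_policy
        )

    qtls: list[QTLRecord] = []
    peak_indices: list[int] = []
    for chrom in pd.unique(grid.chrom):
        idx = grid.chrom_index(chrom)
        above = lod[idx] >= threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = np.concatenate([[0] if above[0] else [], edges[~above[edges]] + 1]).astype(int)
        ends = np.concatenate([edges[above[edges]], [idx.size - 1] if above[-1] else []]).astype(int)
        for s, e in zip(starts, ends):
            seg = idx[s : e + 1]
            peak = int(seg[np.argmax(lod[seg])])
            peak_indices.append(peak)

    multi = fit_multi_qtl(grid, peak_indices, y) if len(peak_indices) > 1 else None
    for peak in peak_indices:
        chrom = grid.chrom[peak]
        idx = grid.chrom_index(chrom)
        local = int(np.flatnonzero(idx == peak)[0])
        cm_lo, cm_hi, bp_lo, bp_hi, clipped = support_interval(
            grid.pos_cm[idx], grid.pos_bp[idx], lod[idx], local, drop,
            pos_bp_lo=grid.pos_bp_lo[idx], pos_bp_hi=grid.pos_bp_hi[idx],
        )
        add, pve = estimate_effects(grid.scores[:, peak], y, float(lod[peak]))
        if multi is not None:
            row = multi[multi["peak_idx"] == peak]
            if len(row):
                pve = float(row["pve"].iloc[0])
        markers = idx[grid.is_marker[idx]]
        m_lo = markers[np.searchsorted(grid.pos_cm[markers], cm_lo, side="left"):]
        m_hi = markers[: np.searchsorted(grid.pos_cm[markers], cm_hi, side="right")]
        qtls.append(
            QTLRecord(
                name="",
                chrom=str(chrom),
                env=env,
                peak_cm=float(grid.pos_cm[peak]),
                peak_mb=float(grid.pos_bp[peak]) / 1e6,
                lod=float(lod[peak]),
                marker_lo=str(grid.bin_id[m_lo[0]]) if m_lo.size else "",
                marker_hi=str(grid.bin_id[m_hi[-1]]) if m_hi.size else "",
                ci_lo_mb=bp_lo / 1e6,
                ci_hi_mb=bp_hi / 1e6,
                pve=float(pve),
                add=float(add),
                ci_clipped=clipped,
            )
        )
    profile = pd.DataFrame(
        {
            "chrom": grid.chrom,
            "pos_cm": grid.pos_cm,
            "pos_mb": grid.pos_bp / 1e6,
            "lod": lod,
        }
    )
    return ScanResult(profile=profile, threshold=float(threshold), qtls=qtls, cofactors=cof)
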