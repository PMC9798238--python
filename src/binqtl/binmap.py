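"""Sliding-window bin calling: genotype smoothing, breakpoints and 100-kb bins.

The raw per-SNP parental-origin calls of each line are scanned with a
15-SNP window (step one SNP, skipping missing calls). A window is called for
a parent when at least 11 of its 15 informative sites come from that parent,
otherwise heterozygous; adjacent equal window calls merge into blocks and
each block transition is a candidate recombination breakpoint. Population
bins are the maximal runs of 100-kb grid intervals containing no breakpoint
in any line; they are the markers of all downstream mapping.

A single true crossover unavoidably produces a short heterozygous window run
while the window slides across it (six windows for the 11/15 rule), so a
documented collapse step merges an H run of at most ``window`` windows
flanked by opposite homozygous blocks into one A<->B breakpoint before
breakpoints are counted, localized and gridded. Genuine residual-het tracts
span many more windows and keep their two flanking breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import A, B, H, N, SNPCallMatrix


@dataclass
class WindowCallTrack:
    """Ordered window calls for one line on one chromosome.

    ``first_snp``/``last_snp`` are original SNP indices of each window's
    extreme sites; ``obs_idx`` indexes the line's non-missing SNPs.
    """

    first_snp: np.ndarray
    last_snp: np.ndarray
    call: np.ndarray
    obs_idx: np.ndarray
    start_obs: np.ndarray  # window start offsets into obs_idx
    window: int

    @property
    def n_windows(self) -> int:
        return self.call.size


@dataclass
class LineBlocks:
    """Maximal runs of equal window calls, in original SNP index space.

    ``first_center``/``last_center`` are the center SNPs of the block's first
    and last windows (the sites the block call directly supports);
    ``zone_lo``/``zone_hi`` are the first SNP of the last window and the last
    SNP of the first window — the outer bounds within which the transition to
    the neighbouring block can physically lie.
    """

    call: np.ndarray       # int8 per block
    first_center: np.ndarray  # original SNP index of first supporting site
    last_center: np.ndarray
    n_windows: np.ndarray  # windows supporting each block
    zone_lo: np.ndarray    # first SNP of the block's LAST window
    zone_hi: np.ndarray    # last SNP of the block's FIRST window


@dataclass
class LineBreakpoints:
    """Breakpoint intervals between consecutive blocks of one line."""

    bp_low: np.ndarray
    bp_high: np.ndarray
    left_call: np.ndarray
    right_call: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bp_low + self.bp_high) / 2.0


def call_windows(
    codes: np.ndarray,
    window: int = 15,
    step: int = 1,
    majority: int = 11,
) -> WindowCallTrack:
    """Window calls over one line's SNP codes on one chromosome.

    Missing calls are skipped so every window holds ``window`` non-missing
    sites; H sites count toward neither parent. Chromosomes with fewer than
    ``window`` non-missing sites yield an empty track.
    """
    if not window >= majority >= window // 2 + 1:
        raise ValueError(
            f"need window >= majority >= window//2 + 1, got {window}/{majority}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    codes = np.asarray(codes, dtype=np.int8)
    obs_idx = np.flatnonzero(codes != N)
    vals = codes[obs_idx]
    n_obs = vals.size
    if n_obs < window:
        empty = np.empty(0, dtype=np.int64)
        return WindowCallTrack(
            empty, empty, empty.astype(np.int8), obs_idx, empty, window
        )
    ca = np.concatenate([[0], np.cumsum(vals == A)])
    cb = np.concatenate([[0], np.cumsum(vals == B)])
    starts = np.arange(0, n_obs - window + 1, step)
    n_a = ca[starts + window] - ca[starts]
    n_b = cb[starts + window] - cb[starts]
    call = np.full(starts.size, H, dtype=np.int8)
    call[n_a >= majority] = A
    call[n_b >= majority] = B
    return WindowCallTrack(
        first_snp=obs_idx[starts],
        last_snp=obs_idx[starts + window - 1],
        call=call,
        obs_idx=obs_idx,
        start_obs=starts,
        window=window,
    )


def merge_blocks(
    track: WindowCallTrack,
    positions: np.ndarray,
) -> tuple[LineBlocks, LineBreakpoints]:
    """Collapse equal adjacent window calls into blocks; record breakpoints.

    Each window supports its center SNP; the first/last blocks extend to the
    line's first/last non-missing SNP. The breakpoint between consecutive
    blocks spans from the last supporting SNP of the left block to the first
    supporting SNP of the right block (consecutive observed SNPs).
    """
    if track.n_windows == 0:
        empty = np.empty(0, dtype=np.int64)
        blocks = LineBlocks(empty.astype(np.int8), empty, empty, empty, empty, empty)
        return blocks, LineBreakpoints(
            empty, empty, empty.astype(np.int8), empty.astype(np.int8)
        )
    call = track.call
    change = np.flatnonzero(call[:-1] != call[1:])
    run_start = np.concatenate([[0], change + 1])
    run_end = np.concatenate([change, [call.size - 1]])
    half = track.window // 2
    centers = track.obs_idx[track.start_obs + half]  # each window's center site
    first_center = centers[run_start].copy()
    last_center = centers[run_end].copy()
    first_center[0] = track.obs_idx[0]
    last_center[-1] = track.obs_idx[-1]
    blocks = LineBlocks(
        call=call[run_start],
        first_center=first_center,
        last_center=last_center,
        n_windows=(run_end - run_start + 1).astype(np.int64),
        zone_lo=track.first_snp[run_end].astype(np.int64),
        zone_hi=track.last_snp[run_start].astype(np.int64),
    )
    left = centers[run_end[:-1]]
    right = centers[run_start[1:]]
    bps = LineBreakpoints(
        bp_low=positions[left].astype(np.int64),
        bp_high=positions[right].astype(np.int64),
        left_call=blocks.call[:-1].copy(),
        right_call=blocks.call[1:].copy(),
    )
    return blocks, bps


def collapse_het_artifacts(
    blocks: LineBlocks,
    max_run: int,
) -> LineBlocks:
    """Absorb short H blocks between opposite homozygous blocks.

    An H run of at most ``max_run`` windows flanked by A and B is the
    signature the sliding window leaves on a single crossover; it is removed
    so that the crossover is reported as one A<->B breakpoint.
    """
    call = list(blocks.call)
    first = list(blocks.first_center)
    last = list(blocks.last_center)
    nwin = list(blocks.n_windows)
    zlo = list(blocks.zone_lo)
    zhi = list(blocks.zone_hi)
    i = 1
    while i < len(call) - 1:
        if (
            call[i] == H
            and nwin[i] <= max_run
            and call[i - 1] != H
            and call[i + 1] != H
            and call[i - 1] != call[i + 1]
        ):
            del call[i], first[i], last[i], nwin[i], zlo[i], zhi[i]
        else:
            i += 1
    # fuse equal neighbours created by the deletion
    j = 1
    while j < len(call):
        if call[j] == call[j - 1]:
            last[j - 1] = last[j]
            nwin[j - 1] += nwin[j]
            zlo[j - 1] = zlo[j]
            del call[j], first[j], last[j], nwin[j], zlo[j], zhi[j]
        else:
            j += 1
    return LineBlocks(
        call=np.array(call, dtype=np.int8),
        first_center=np.array(first, dtype=np.int64),
        last_center=np.array(last, dtype=np.int64),
        n_windows=np.array(nwin, dtype=np.int64),
        zone_lo=np.array(zlo, dtype=np.int64),
        zone_hi=np.array(zhi, dtype=np.int64),
    )


def _refine_interval(
    codes: np.ndarray,
    lo_snp: int,
    hi_snp: int,
    left_call: int,
    right_call: int,
    pad: int,
) -> tuple[int, int]:
    """Tighten a transition zone using raw calls that match the flanks.

    Within the smoothed zone [lo_snp, hi_snp] the interval is narrowed to
    (last raw call equal to the left block, first raw call equal to the right
    block), padded by ``pad`` observed SNPs; if call errors invert the order
    the full zone is kept.
    """
    zone = np.arange(lo_snp, hi_snp + 1)
    zone = zone[codes[zone] != N]
    if zone.size == 0:
        return lo_snp, hi_snp
    left_match = zone[codes[zone] == left_call]
    right_match = zone[codes[zone] == right_call]
    if left_match.size == 0 or right_match.size == 0:
        return lo_snp, hi_snp
    lo, hi = int(left_match[-1]), int(right_match[0])
    if lo >= hi:
        return lo_snp, hi_snp
    if pad:
        lo_i = np.searchsorted(zone, lo) - pad
        hi_i = np.searchsorted(zone, hi) + pad
        lo = int(zone[max(lo_i, 0)])
        hi = int(zone[min(hi_i, zone.size - 1)])
    return lo, hi


def breakpoints_from_blocks(
    blocks: LineBlocks,
    codes: np.ndarray,
    positions: np.ndarray,
    refine: bool = True,
    pad: int = 1,
) -> LineBreakpoints:
    """Breakpoint intervals between consecutive blocks, optionally refined."""
    n = blocks.call.size
    if n <= 1:
        empty = np.empty(0, dtype=np.int64)
        return LineBreakpoints(empty, empty, empty.astype(np.int8), empty.astype(np.int8))
    lo_snp = blocks.zone_lo[:-1]
    hi_snp = blocks.zone_hi[1:]
    bp_low = np.empty(n - 1, dtype=np.int64)
    bp_high = np.empty(n - 1, dtype=np.int64)
    for k in range(n - 1):
        lo, hi = int(lo_snp[k]), int(hi_snp[k])
        if refine:
            lo, hi = _refine_interval(
                codes, lo, hi, int(blocks.call[k]), int(blocks.call[k + 1]), pad
            )
        bp_low[k] = positions[lo]
        bp_high[k] = positions[hi]
    return LineBreakpoints(
        bp_low=bp_low,
        bp_high=bp_high,
        left_call=blocks.call[:-1].copy(),
        right_call=blocks.call[1:].copy(),
    )


def detect_population_bins(
    midpoints: np.ndarray,
    chrom_length: int,
    grid: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin boundaries from all lines' breakpoint midpoints on a grid.

    Every grid interval containing at least one midpoint starts a new bin;
    returns 0-based half-open (starts, ends) tiling [0, chrom_length).
    """
    cells = np.unique((np.asarray(midpoints, dtype=np.int64) // grid) * grid)
    cells = cells[(cells > 0) & (cells < chrom_length)]
    starts = np.concatenate([[0], cells])
    ends = np.concatenate([cells, [chrom_length]])
    return starts.astype(np.int64), ends.astype(np.int64)


@dataclass
class BinMap:
    """Population-wide bins and the lines x bins genotype matrix."""

    lines: list[str]
    bins: pd.DataFrame  # columns: chrom, start, end, bin_id
    genotypes: np.ndarray  # int8, n_lines x n_bins

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_csv(self, geno_path, bed_path=None) -> None:
        from .matrix import CODE_CHARS

        df = pd.DataFrame(
            CODE_CHARS[self.genotypes],
            index=pd.Index(self.lines, name="line"),
            columns=self.bins["bin_id"],
        )
        df.to_csv(geno_path)
        if bed_path is not None:
            self.bins[["chrom", "start", "end", "bin_id"]].to_csv(
                bed_path, sep="\t", index=False, header=False
            )


@dataclass
class BreakpointSet:
    """All lines' breakpoint intervals in one long table."""

    table: pd.DataFrame  # line, chrom, bp_low, bp_high, left, right, midpoint

    def per_line_counts(self) -> pd.Series:
        return self.table.groupby("line").size()


def _genotype_line_bins(
    starts: np.ndarray,
    ends: np.ndarray,
    blocks: LineBlocks,
    bps: LineBreakpoints,
    codes: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Bin genotypes for one line on one chromosome."""
    n_bins = starts.size
    out = np.full(n_bins, N, dtype=np.int8)
    if blocks.call.size == 0:
        # too few informative SNPs for any window: direct majority per bin
        for j in range(n_bins):
            out[j] = _majority_call(codes, positions, starts[j], ends[j], None)
        return out
    if bps.bp_low.size == 0:
        out[:] = blocks.call[0]
        return out
    lows, highs = bps.bp_low, bps.bp_high
    # candidate overlapping interval for each bin
    cand = np.searchsorted(highs, starts, side="right")
    cand_clip = np.minimum(cand, lows.size - 1)
    overlaps = (cand < lows.size) & (lows[cand_clip] < ends) & (highs[cand_clip] > starts)
    # block index for non-overlapping bins: number of intervals fully left
    block_idx = np.searchsorted(highs, starts, side="right")
    clean = ~overlaps
    out[clean] = blocks.call[np.minimum(block_idx[clean], blocks.call.size - 1)]
    for j in np.flatnonzero(overlaps):
        k = cand[j]
        flank = None
        if blocks.call[k] == blocks.call[k + 1]:
            flank = int(blocks.call[k])
        out[j] = _majority_call(codes, positions, starts[j], ends[j], flank)
    return out


def _majority_call(codes, positions, start, end, flank_fill) -> int:
    i0 = np.searchsorted(positions, start + 1)
    i1 = np.searchsorted(positions, end, side="right")
    seg = codes[i0:i1]
    counts = np.array([(seg == A).sum(), (seg == B).sum(), (seg == H).sum()])
    if counts.sum() == 0:
        return flank_fill if flank_fill is not None else N
    top = counts.max()
    if (counts == top).sum() > 1:
        return N
    return int(np.argmax(counts))


def build_bin_map(
    matrix: SNPCallMatrix,
    window: int = 15,
    step: int = 1,
    majority: int = 11,
    grid: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    collapse: bool = True,
    refine: bool = True,
    pad: int = 1,
) -> tuple[BinMap, BreakpointSet]:
    """Full bin-calling pass over a population genotype matrix.

    Returns the population bin map and the (collapsed) breakpoint set used to
    place the bin boundaries. ``chrom_lengths`` defaults to each chromosome's
    last SNP position.
    """
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(matrix.positions[c][-1]) if matrix.positions[c].size else grid
            for c in matrix.chroms
        }
    all_blocks: dict[str, list[LineBlocks]] = {}
    all_bps: dict[str, list[LineBreakpoints]] = {}
    bp_rows = []
    for chrom in matrix.chroms:
        positions = matrix.positions[chrom]
        blocks_c, bps_c = [], []
        for i in range(matrix.n_lines):
            codes = matrix.calls[chrom][i]
            track = call_windows(codes, window=window, step=step, majority=majority)
            blocks, _ = merge_blocks(track, positions)
            if collapse:
                blocks = collapse_het_artifacts(blocks, max_run=window)
            bps = breakpoints_from_blocks(blocks, codes, positions, refine=refine, pad=pad)
            blocks_c.append(blocks)
            bps_c.append(bps)
            for k in range(bps.bp_low.size):
                bp_rows.append(
                    (
                        matrix.lines[i],
                        chrom,
                        int(bps.bp_low[k]),
                        int(bps.bp_high[k]),
                        "ABH"[bps.left_call[k]],
                        "ABH"[bps.right_call[k]],
                        (bps.bp_low[k] + bps.bp_high[k]) / 2.0,
                    )
                )
        all_blocks[chrom] = blocks_c
        all_bps[chrom] = bps_c

    bp_table = pd.DataFrame(
        bp_rows,
        columns=["line", "chrom", "bp_low", "bp_high", "left", "right", "midpoint"],
    )
    bin_frames = []
    geno_cols = []
    for chrom in matrix.chroms:
        mids = bp_table.loc[bp_table["chrom"] == chrom, "midpoint"].to_numpy()
        starts, ends = detect_population_bins(mids, chrom_lengths[chrom], grid=grid)
        bin_frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        geno = np.empty((matrix.n_lines, starts.size), dtype=np.int8)
        for i in range(matrix.n_lines):
            geno[i] = _genotype_line_bins(
                starts,
                ends,
                all_blocks[chrom][i],
                all_bps[chrom][i],
                matrix.calls[chrom][i],
                matrix.positions[chrom],
            )
        geno_cols.append(geno)
    bins = pd.concat(bin_frames, ignore_index=True)
    bins["bin_id"] = [f"mk{i + 1}" for i in range(len(bins))]
    genotypes = np.hstack(geno_cols) if geno_cols else np.empty((matrix.n_lines, 0), np.int8)
    return BinMap(lines=list(matrix.lines), bins=bins, genotypes=genotypes), BreakpointSet(
        table=bp_table
    )


def breakpoint_summary(breakpoints: BreakpointSet, lines: list[str] | None = None) -> dict:
    """Per-line counts, population total and mean breakpoints per line."""
    counts = breakpoints.per_line_counts()
    if lines is not None:
        counts = counts.reindex(lines, fill_value=0)
    total = int(counts.sum())
    mean = float(counts.mean()) if len(counts) else 0.0
    return {"per_line": counts, "total": total, "mean_per_line": mean}


# --------------------------------------------------------------------------
# Truth-based evaluation (synthetic data only)


def bin_genotype_accuracy(binmap: BinMap, truth) -> tuple[float, float]:
    """(accuracy over non-missing bin calls, fraction of calls missing).

    Truth for a bin is the label occupying most bp of the bin in the line's
    true mosaic.
    """
    correct = called = total = 0
    for chrom in truth.segments:
        sl = binmap.chrom_slice(chrom)
        sub = binmap.bins.iloc[sl]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        geno = binmap.genotypes[:, sl]
        for i in range(len(binmap.lines)):
            for j in range(starts.size):
                call = geno[i, j]
                total += 1
                if call == N:
                    continue
                called += 1
                if call == truth.majority_label(chrom, i, int(starts[j]), int(ends[j])):
                    correct += 1
    acc = correct / called if called else 0.0
    return acc, 1.0 - called / total if total else 0.0


def crossover_recovery(breakpoints: BreakpointSet, truth) -> float:
    """Fraction of true junctions covered by a breakpoint interval of the
    same line/chromosome."""
    hit = total = 0
    table = breakpoints.table
    grouped = {k: v for k, v in table.groupby(["line", "chrom"])}
    for chrom in truth.segments:
        for i, line in enumerate(truth.lines):
            junc = truth.junctions(chrom, i)
            if junc.size == 0:
                continue
            total += junc.size
            sub = grouped.get((line, chrom))
            if sub is None:
                continue
            lows = sub["bp_low"].to_numpy()
            highs = sub["bp_high"].to_numpy()
            for j in junc:
                if np.any((lows <= j) & (j <= highs)):
                    hit += 1
    return hit / total if total else 1.0
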