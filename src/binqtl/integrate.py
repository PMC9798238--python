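"""Merge per-environment QTL lists into consensus loci.

QTLs detected in different environments are the same locus when their
confidence intervals overlap or their peaks are within 20 Mb; merging is
single-linkage (chains merge), per chromosome, independent of input order.
Consensus loci are named by trait prefix and chromosome, with an ordinal
suffix by ascending peak position when a chromosome hosts more than one
locus (qPC2-1, qPC2-2, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import QTLRecord


@dataclass
class ConsensusQTL:
    name: str
    chrom: str
    members: list[QTLRecord]
    union_lo_mb: float
    union_hi_mb: float
    environments: list[str] = field(default_factory=list)

    @property
    def detection_count(self) -> int:
        return len(self.members)

    @property
    def stable(self) -> bool:
        """Detected in at least two environments/analyses."""
        return len(set(self.environments)) >= 2


def _chrom_label(chrom: str) -> str:
    m = re.search(r"(\d+)$", str(chrom))
    return m.group(1) if m else str(chrom)


def _mergeable(a: QTLRecord, b: QTLRecord, max_peak_gap_mb: float) -> bool:
    overlap = a.ci_lo_mb <= b.ci_hi_mb and b.ci_lo_mb <= a.ci_hi_mb
    return overlap or abs(a.peak_mb - b.peak_mb) <= max_peak_gap_mb


def merge_across_envs(
    qtl_lists: list[list[QTLRecord]],
    max_peak_gap_mb: float = 20.0,
    prefix: str = "PC",
) -> list[ConsensusQTL]:
    """Single-linkage clustering of QTL records under the merge predicate."""
    records = [q for lst in qtl_lists for q in lst]
    out: list[ConsensusQTL] = []
    for chrom in sorted({q.chrom for q in records}):
        recs = sorted(
            (q for q in records if q.chrom == chrom), key=lambda q: q.peak_mb
        )
        parent = list(range(len(recs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if _mergeable(recs[i], recs[j], max_peak_gap_mb):
                    parent[find(j)] = find(i)
        clusters: dict[int, list[QTLRecord]] = {}
        for i, rec in enumerate(recs):
            clusters.setdefault(find(i), []).append(rec)
        ordered = sorted(clusters.values(), key=lambda ms: min(m.peak_mb for m in ms))
        label = _chrom_label(chrom)
        for k, members in enumerate(ordered, start=1):
            name = (
                f"q{prefix}{label}"
                if len(ordered) == 1
                else f"q{prefix}{label}-{k}"
            )
            for m in members:
                m.name = name
            out.append(
                ConsensusQTL(
                    name=name,
                    chrom=chrom,
                    members=members,
                    union_lo_mb=min(m.ci_lo_mb for m in members),
                    union_hi_mb=max(m.ci_hi_mb for m in members),
                    environments=[m.env for m in members],
                )
            )
    return out


def report_table(consensus: list[ConsensusQTL]) -> pd.DataFrame:
    """One row per member record, sorted by chromosome then peak position."""
    rows = []
    for c in consensus:
        for m in sorted(c.members, key=lambda q: q.peak_mb):
            rows.append(
                (
                    c.name,
                    _chrom_label(c.chrom),
                    m.env,
                    f"{m.marker_lo}-{m.marker_hi}",
                    f"{m.ci_lo_mb:.2f}-{m.ci_hi_mb:.2f}",
                    round(m.pve, 2),
                    round(m.add, 2),
                    round(m.lod, 2),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["Name", "Chr", "Env", "Marker interval", "Interval (Mb)", "PVE", "ADD", "LOD"],
    )
    if len(df):
        df["_chr"] = pd.to_numeric(df["Chr"], errors="coerce")
        df = df.sort_values(["_chr", "Chr", "Interval (Mb)"]).drop(columns="_chr")
        df = df.reset_index(drop=True)
    return df
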