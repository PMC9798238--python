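"""Parental-origin genotype matrices.

Progeny of a biparental cross are coded by parental origin at each SNP:
``A`` (homozygous for the female-parent allele), ``B`` (homozygous for the
male-parent allele), ``H`` (heterozygous) and ``N`` (missing / unscorable).
Internally the four codes are small integers so per-chromosome call matrices
are plain ``int8`` numpy arrays of shape (lines, SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A, B, H, N = 0, 1, 2, 3
CODE_CHARS = np.array(["A", "B", "H", "N"])
_CHAR_TO_CODE = {"A": A, "B": B, "H": H, "N": N}
_GT_STRINGS = {A: "0/0", B: "1/1", H: "0/1", N: "./."}


@dataclass
class SNPCallMatrix:
    """Lines x SNPs parental-origin calls with 1-based physical positions.

    ``positions[chrom]`` is a strictly increasing ``int64`` array of 1-based
    bp coordinates; ``calls[chrom]`` is the matching ``int8`` matrix with one
    row per line.
    """

    lines: list[str]
    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions on {chrom} not strictly increasing")
            self.positions[chrom] = pos
            calls = np.asarray(self.calls[chrom], dtype=np.int8)
            if calls.shape != (len(self.lines), pos.size):
                raise ValueError(
                    f"call matrix on {chrom} has shape {calls.shape}, "
                    f"expected {(len(self.lines), pos.size)}"
                )
            if calls.size and (calls.min() < A or calls.max() > N):
                raise ValueError("call codes must be in {A,B,H,N}")
            self.calls[chrom] = calls

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_snps(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def copy(self) -> "SNPCallMatrix":
        return SNPCallMatrix(
            lines=list(self.lines),
            positions={c: p.copy() for c, p in self.positions.items()},
            calls={c: m.copy() for c, m in self.calls.items()},
        )

    def subset_snps(self, keep: dict[str, np.ndarray]) -> "SNPCallMatrix":
        """New matrix keeping, per chromosome, the boolean/index mask ``keep``."""
        positions, calls = {}, {}
        for chrom in self.chroms:
            mask = keep.get(chrom)
            if mask is None:
                continue
            positions[chrom] = self.positions[chrom][mask]
            calls[chrom] = self.calls[chrom][:, mask]
        return SNPCallMatrix(lines=list(self.lines), positions=positions, calls=calls)

    def subset_lines(self, keep: np.ndarray) -> "SNPCallMatrix":
        idx = np.asarray(keep)
        lines = [self.lines[i] for i in np.arange(self.n_lines)[idx]] \
            if idx.dtype == bool else [self.lines[i] for i in idx]
        return SNPCallMatrix(
            lines=lines,
            positions={c: p.copy() for c, p in self.positions.items()},
            calls={c: m[idx] for c, m in self.calls.items()},
        )

    def line_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per line, across all chromosomes."""
        total = self.n_snps
        if total == 0:
            return np.zeros(self.n_lines)
        nonmiss = sum((m != N).sum(axis=1) for m in self.calls.values())
        return np.asarray(nonmiss, dtype=float) / total

    def snp_call_rate(self) -> dict[str, np.ndarray]:
        """Fraction of non-missing calls per SNP, per chromosome."""
        n = max(self.n_lines, 1)
        return {c: (m != N).sum(axis=0) / n for c, m in self.calls.items()}

    # ------------------------------------------------------------------ IO

    def to_table(self, path, header_comment: str | None = None) -> None:
        """Write as TSV: chrom, pos, then one A/B/H/N column per line."""
        frames = []
        for chrom in self.chroms:
            df = pd.DataFrame(
                CODE_CHARS[self.calls[chrom].T], columns=self.lines
            )
            df.insert(0, "pos", self.positions[chrom])
            df.insert(0, "chrom", chrom)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "pos", *self.lines]
        )
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "SNPCallMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        lines = [c for c in df.columns if c not in ("chrom", "pos")]
        positions, calls = {}, {}
        for chrom, sub in df.groupby("chrom", sort=False):
            positions[chrom] = sub["pos"].to_numpy(np.int64)
            codes = sub[lines].to_numpy(str)
            calls[chrom] = np.vectorize(_CHAR_TO_CODE.__getitem__)(codes).T.astype(
                np.int8
            )
        return cls(lines=lines, positions=positions, calls=calls)

    def to_vcf(self, path) -> None:
        """Write calls as an uncompressed VCF (A→0/0, B→1/1, H→0/1, N→./.).

        REF/ALT are placeholder parental alleles; the substance carried by the
        file is the GT matrix with samples = lines.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=binqtl\n")
            for chrom in self.chroms:
                length = int(self.positions[chrom][-1]) if self.positions[chrom].size else 0
                fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.lines)
                + "\n"
            )
            for chrom in self.chroms:
                pos = self.positions[chrom]
                m = self.calls[chrom]
                for j in range(pos.size):
                    gts = "\t".join(_GT_STRINGS[int(c)] for c in m[:, j])
                    fh.write(f"{chrom}\t{pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path) -> "SNPCallMatrix":
        """Read a GT-coded VCF where 0/0→A, 1/1→B, het→H, missing→N."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        lines = list(vcf.samples)
        pos_acc: dict[str, list[int]] = {}
        call_acc: dict[str, list[np.ndarray]] = {}
        for var in vcf:
            gt = np.array(var.gt_types)  # 0=hom ref,1=het,2=unknown,3=hom alt
            codes = np.full(gt.shape, N, dtype=np.int8)
            codes[gt == 0] = A
            codes[gt == 3] = B
            codes[gt == 1] = H
            pos_acc.setdefault(var.CHROM, []).append(var.POS)
            call_acc.setdefault(var.CHROM, []).append(codes)
        positions = {c: np.array(v, dtype=np.int64) for c, v in pos_acc.items()}
        calls = {c: np.vstack(v).T.astype(np.int8) for c, v in call_acc.items()}
        return cls(lines=lines, positions=positions, calls=calls)
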