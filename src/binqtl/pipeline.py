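"""Structured configuration and the simulate -> ... -> merge pipeline driver.

Every stage parameter has a default matching the study conditions the
package emulates (275 lines, ten chromosomes, three environment-years with
three replicates, 15/11 window rule, 100-kb bins, 1000 permutations at
alpha 0.05, 1.5-LOD intervals, 20-Mb merging). A single global seed is
expanded into independent per-stage substreams. Re-running with the same
config and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .binmap import breakpoint_summary, build_bin_map
from .genome import (
    MAIZE_BP_LENGTHS,
    MAIZE_CM_LENGTHS,
    MAIZE_SNP_COUNTS,
    build_genome_template,
)
from .integrate import merge_across_envs, report_table
from .linkage import build_map
from .phenostats import env_correlations, fit_mixed_model, heritability
from .qc import run_qc
from .scan import scan_trait
from .simulate import (
    TraitArchitecture,
    architecture_for_h2,
    corrupt_genotypes,
    unbalanced_trial_environments,
    simulate_phenotypes,
    simulate_ril_population,
)

_FORBID = ConfigDict(extra="forbid")


class GenomeConfig(BaseModel):
    model_config = _FORBID
    n_chrom: int = 10
    bp_lengths: list[int] = Field(default_factory=lambda: list(MAIZE_BP_LENGTHS))
    cm_lengths: list[float] = Field(default_factory=lambda: list(MAIZE_CM_LENGTHS))
    n_snps_per_chrom: list[int] = Field(default_factory=lambda: list(MAIZE_SNP_COUNTS))


class QTLSpec(BaseModel):
    model_config = _FORBID
    chrom: str
    pos_bp: int
    effect: float


def _default_qtls() -> list[QTLSpec]:
    return [
        QTLSpec(chrom="chr1", pos_bp=12_000_000, effect=0.25),
        QTLSpec(chrom="chr2", pos_bp=17_150_000, effect=0.35),
        QTLSpec(chrom="chr5", pos_bp=95_000_000, effect=0.25),
        QTLSpec(chrom="chr7", pos_bp=134_000_000, effect=-0.30),
        QTLSpec(chrom="chr9", pos_bp=79_000_000, effect=-0.30),
    ]


class PopulationConfig(BaseModel):
    model_config = _FORBID
    n_lines: int = 275
    selfing_generations: int = 6
    error_rate: float = 0.01
    missing_rate: float = 0.05


class TraitConfig(BaseModel):
    model_config = _FORBID
    qtls: list[QTLSpec] = Field(default_factory=_default_qtls)
    h2: float = 0.81
    design: str = "unbalanced"  # 3 env-years; or "balanced" (2y x 2loc)
    reps: int = 3
    intercept: float = 10.0


class QCConfig(BaseModel):
    model_config = _FORBID
    alpha: float = 0.001
    min_snp_rate: float = 0.2
    min_line_rate: float = 0.2


class BinmapConfig(BaseModel):
    model_config = _FORBID
    window: int = 15
    step: int = 1
    majority: int = 11
    grid: int = 100_000


class ScanConfig(BaseModel):
    model_config = _FORBID
    n_perm: int = 1000
    alpha: float = 0.05
    drop: float = 1.5
    n_cofactors: int = 5
    window_cm: float = 10.0
    grid_step: float | None = None  # None scans at bin markers only


class MergeConfig(BaseModel):
    model_config = _FORBID
    max_gap_mb: float = 20.0


class PipelineConfig(BaseModel):
    model_config = _FORBID
    seed: int = 0
    trait_prefix: str = "PC"
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    trait: TraitConfig = Field(default_factory=TraitConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    binmap: BinmapConfig = Field(default_factory=BinmapConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    merge: MergeConfig = Field(default_factory=MergeConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    def param_hash(self) -> str:
        payload = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed (< 2^31)."""
    digest = hashlib.sha256(stage.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def _stamp(path: Path, stage: str, phash: str) -> None:
    """Prepend a self-describing header comment to a text artifact."""
    text = path.read_text()
    path.write_text(f"# binqtl stage={stage} params={phash}\n{text}")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> qc -> binmap -> geneticmap -> blue -> scan -> merge.

    Writes per-stage artifacts under ``out_dir`` and returns the run
    manifest (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = config.param_hash()
    log: list[dict] = []

    def _log(stage: str, **counts) -> None:
        log.append({"stage": stage, **counts})

    # --- simulate -----------------------------------------------------
    g = config.genome
    template = build_genome_template(
        g.n_chrom, g.bp_lengths, g.cm_lengths, g.n_snps_per_chrom,
        seed=stage_seed(config.seed, "genome"),
    )
    truth, clean = simulate_ril_population(
        template,
        config.population.n_lines,
        config.population.selfing_generations,
        seed=stage_seed(config.seed, "population"),
    )
    observed = corrupt_genotypes(
        clean,
        config.population.error_rate,
        config.population.missing_rate,
        seed=stage_seed(config.seed, "corrupt"),
    )
    qtls = [(q.chrom, q.pos_bp, q.effect) for q in config.trait.qtls]
    if config.trait.design == "unbalanced":
        years, locations, cells = unbalanced_trial_environments()
    else:
        years, locations, cells = [2018, 2019], ["L1", "L2"], None
    arch = architecture_for_h2(
        truth, qtls, config.trait.h2,
        years=years, locations=locations, env_cells=cells,
        reps=config.trait.reps, intercept=config.trait.intercept,
    )
    pheno = simulate_phenotypes(truth, arch, seed=stage_seed(config.seed, "phenotype"))
    observed.to_table(out / "genotypes.tsv", header_comment=f"binqtl stage=simulate params={phash}")
    truth.to_bed(out / "truth_segments.bed")
    pheno.to_csv(out / "phenotypes.csv", index=False)
    _log("simulate", lines=observed.n_lines, snps=observed.n_snps,
         records=len(pheno), true_breakpoints=int(truth.n_breakpoints().sum()))

    # --- qc -----------------------------------------------------------
    filtered, report = run_qc(
        observed,
        alpha=config.qc.alpha,
        min_snp_rate=config.qc.min_snp_rate,
        min_line_rate=config.qc.min_line_rate,
    )
    report.to_frame().to_csv(out / "qc_report.csv", index=False)
    _stamp(out / "qc_report.csv", "qc", phash)
    _log("qc", snps_in=observed.n_snps, snps_out=filtered.n_snps, lines=filtered.n_lines)

    # --- binmap --------------------------------------------------------
    chrom_lengths = {c: template.bp_lengths[c] for c in filtered.chroms}
    binmap, breakpoints = build_bin_map(
        filtered,
        window=config.binmap.window,
        step=config.binmap.step,
        majority=config.binmap.majority,
        grid=config.binmap.grid,
        chrom_lengths=chrom_lengths,
    )
    binmap.to_csv(out / "bin_genotypes.csv", bed_path=out / "bins.bed")
    _stamp(out / "bin_genotypes.csv", "binmap", phash)
    bp_summary = breakpoint_summary(breakpoints, lines=binmap.lines)
    _log("binmap", bins=binmap.n_bins, breakpoints=bp_summary["total"],
         mean_breakpoints_per_line=round(bp_summary["mean_per_line"], 2))

    # --- genetic map ----------------------------------------------------
    gmap = build_map(binmap)
    gmap.to_csv(out / "genetic_map.csv", summary_path=out / "map_summary.csv")
    _stamp(out / "genetic_map.csv", "geneticmap", phash)
    _log("geneticmap", markers=int(gmap.summary.iloc[-1]["n_markers"]),
         total_cm=round(gmap.total_cm, 2))

    # --- blue -----------------------------------------------------------
    blues, vc = fit_mixed_model(pheno)
    blues.to_csv(out / "blue.csv", index=False)
    _stamp(out / "blue.csv", "blue", phash)
    h2 = heritability(vc)
    corr = env_correlations(pheno)
    corr.to_csv(out / "env_correlations.csv")
    _log("blue", lines=len(blues), h2=round(h2, 3))

    # --- scan (each environment, then joint BLUE) -----------------------
    env_tables = {"BLUE": blues}
    for env, sub in pheno.groupby("env"):
        env_tables[str(env)] = (
            sub.groupby("line")["value"].mean().rename("blue").reset_index()
        )
    qtl_lists = []
    profiles = []
    for env, table in env_tables.items():
        result = scan_trait(
            binmap, gmap, table, env=env,
            n_perm=config.scan.n_perm, alpha=config.scan.alpha,
            drop=config.scan.drop, n_cofactors=config.scan.n_cofactors,
            window_cm=config.scan.window_cm, grid_step=config.scan.grid_step,
            seed=stage_seed(config.seed, f"scan:{env}"),
        )
        qtl_lists.append(result.qtls)
        prof = result.profile.copy()
        prof.insert(0, "env", env)
        profiles.append(prof)
        _log("scan", env=env, threshold=round(result.threshold, 3), qtls=len(result.qtls))
    pd.concat(profiles, ignore_index=True).to_csv(
        out / "lod_profiles.tsv", sep="\t", index=False
    )
    _stamp(out / "lod_profiles.tsv", "scan", phash)

    # --- merge -----------------------------------------------------------
    consensus = merge_across_envs(
        qtl_lists, max_peak_gap_mb=config.merge.max_gap_mb, prefix=config.trait_prefix
    )
    table = report_table(consensus)
    table.to_csv(out / "qtl_report.csv", index=False)
    _stamp(out / "qtl_report.csv", "merge", phash)
    _log("merge", consensus_qtls=len(consensus), report_rows=len(table))

    manifest = {
        "binqtl_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "param_hash": phash,
        "config": json.loads(config.model_dump_json()),
        "stages": log,
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
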