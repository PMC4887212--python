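"""End-to-end orchestration: simulate -> sites -> DMPs -> MRs -> DMRs ->
annotation/enrichment -> clustering, from one configuration, with a run
manifest recording every threshold and the checksum of every output."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import annotation as ann
from . import cluster as clu
from . import dmr as dmrmod
from . import hmm as hmmmod
from . import io as iomod
from . import simulate as sim
from . import sites as sitemod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: a simulation config plus all stage thresholds."""

    outdir: str
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    generations: Sequence[str] = ("G1",)
    lineages: Sequence[str] = ("P0", "P1", "P2")
    treatments: Sequence[str] = ("control", "25", "75")
    replicates: int = 2
    min_cov: int = 3
    min_fraction_samples: float = 0.5
    site_fdr: float = 0.05
    dmp_min_diff: float = 0.30
    dmp_fdr: float = 0.05
    dmr_fdr: float = 0.05
    min_diff_region: float = 0.10
    hmm_distance_break: int = 250
    hmm_min_sites: int = 4
    hmm_posterior_threshold: float = 0.5
    # "shared": fit once on the first sample and reuse (the methylation
    # landscape is genome-wide, not sample-specific); "per-sample": refit per
    # sample; "none": percentile initialization only
    hmm_fit_mode: str = "shared"
    n_boot: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "outdir" not in raw:
            raise ValueError("run config must set 'outdir'")
        sim_cfg = sim.SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim_cfg, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generations"] = list(self.generations)
        d["lineages"] = list(self.lineages)
        d["treatments"] = list(self.treatments)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Every stage logs counts in/out; outputs are written under
    ``config.outdir`` and checksummed into ``manifest.json``. All stages are
    deterministic given ``config.seed``, so re-running a manifest reproduces
    the outputs bit-identically.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest: dict = {"config": config.to_dict(), "stages": {}, "counts": {}}

    def record(stage: str, files: list[Path]) -> None:
        # manifests carry no timestamps so identical runs are byte-identical
        manifest["stages"][stage] = {"outputs": {f.name: _sha256(f) for f in files}}

    # stage: simulate -------------------------------------------------------
    design = sim.default_design(
        generations=config.generations,
        lineages=config.lineages,
        treatments=config.treatments,
        replicates=config.replicates,
    )
    annot = sim.simulate_annotation(config.sim)
    tables = sim.simulate_samples(config.sim, annot, design)
    sheet = outdir / "samples.tsv"
    iomod.write_sample_sheet(design, sheet)
    iomod.write_intervals(annot.tes, outdir / "tes.bed", "BED")
    iomod.write_intervals(annot.genes, outdir / "genes.gff3", "GFF3")
    iomod.write_json(annot.truth.to_json_obj(), outdir / "truth.json")
    table_files = []
    for sid, df in tables.items():
        f = outdir / f"{sid}.cx.tsv"
        iomod.write_cytosine_table(df, f)
        table_files.append(f)
    record("simulate", [sheet, outdir / "tes.bed", outdir / "genes.gff3",
                        outdir / "truth.json", *table_files])
    manifest["counts"]["samples"] = len(tables)

    nuclear = {s: sim.nuclear_table(df) for s, df in tables.items()}

    # stage: sites ----------------------------------------------------------
    pooled_chloro = None
    import pandas as pd

    pooled_chloro = pd.concat([sim.chloroplast_table(df) for df in tables.values()])
    error_rate = sitemod.estimate_error_rate(pooled_chloro)
    calls, universe = sitemod.call_methylated_sites(
        nuclear, error_rate,
        min_cov=config.min_cov,
        min_fraction_samples=config.min_fraction_samples,
        site_fdr=config.site_fdr,
    )
    manifest["counts"]["error_rate"] = error_rate
    manifest["counts"]["universe_sites"] = int(len(universe))
    manifest["counts"]["methylated_sites"] = {
        s: int(df["is_methylated"].sum()) for s, df in calls.items()
    }
    site_file = outdir / "site_calls_summary.json"
    iomod.write_json(manifest["counts"]["methylated_sites"], site_file)
    record("sites", [site_file])

    # stage: dmps (within-treatment pairwise comparisons) -------------------
    dmp_counts = {}
    by_treatment: dict[str, list] = {}
    for m in design:
        by_treatment.setdefault(m.treatment, []).append(m.sample_id)
    dmp_rows = []
    for treatment, members in by_treatment.items():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                res = sitemod.call_dmps(
                    calls[a], calls[b],
                    min_diff=config.dmp_min_diff, fdr=config.dmp_fdr,
                    sample_a=a, sample_b=b,
                )
                dmp_counts[f"{a}|{b}"] = int(res["significant"].sum())
                dmp_rows.append(res[res["significant"]])
    dmps = (
        pd.concat(dmp_rows, ignore_index=True)
        if dmp_rows
        else pd.DataFrame()
    )
    dmp_file = outdir / "dmps.tsv"
    dmps.to_csv(dmp_file, sep="\t", index=False)
    manifest["counts"]["dmps_per_pair"] = dmp_counts
    record("dmps", [dmp_file])

    # stage: mrs ------------------------------------------------------------
    mr_sets = {}
    params_by_sample = {}
    shared_params = None
    for sid, df in nuclear.items():
        init = hmmmod.initial_params(
            df,
            distance_break=config.hmm_distance_break,
            min_sites=config.hmm_min_sites,
            posterior_threshold=config.hmm_posterior_threshold,
        )
        if config.hmm_fit_mode == "per-sample":
            params = hmmmod.fit_hmm(df, init, tol=1.0, max_iter=15)
        elif config.hmm_fit_mode == "shared":
            if shared_params is None:
                shared_params = hmmmod.fit_hmm(df, init, tol=1.0, max_iter=15)
            params = shared_params
        else:
            params = init
        params_by_sample[sid] = params
        mr_sets[sid] = hmmmod.segment_mrs(df, params, sample_id=sid)
    mr_file = outdir / "mrs.bed"
    allmr = pd.concat(mr_sets.values(), ignore_index=True)
    iomod.write_intervals(
        allmr.assign(name=allmr["sample_id"], score=(allmr["mean_freq"] * 1000).round(),
                     strand="."),
        mr_file, "BED",
    )
    iomod.write_json({s: p.to_dict() for s, p in params_by_sample.items()},
                     outdir / "hmm_params.json")
    manifest["counts"]["mrs_per_sample"] = {s: int(len(df)) for s, df in mr_sets.items()}
    record("mrs", [mr_file, outdir / "hmm_params.json"])

    # stage: dmrs (per generation, four-group tests) ------------------------
    dmr_frames = []
    for gen in config.generations:
        groups = dmrmod.assign_groups(design, gen)
        gen_mrs = {s: mr_sets[s] for s in groups}
        candidates = dmrmod.build_segments(gen_mrs)
        result = dmrmod.test_dmrs(
            candidates,
            {s: nuclear[s] for s in groups},
            groups,
            mr_sets=gen_mrs,
            fdr=config.dmr_fdr,
            min_diff_region=config.min_diff_region,
        )
        if len(result):
            result = result.assign(generation=gen)
            dmr_frames.append(result)
        manifest["counts"][f"segments_tested_{gen}"] = int(len(result))
        manifest["counts"][f"dmrs_{gen}"] = (
            int(result["significant"].sum()) if len(result) else 0
        )
    dmrs = pd.concat(dmr_frames, ignore_index=True) if dmr_frames else pd.DataFrame()
    dmr_file = outdir / "dmrs.tsv"
    if len(dmrs):
        dmrs.drop(columns=["sample_freqs"]).to_csv(dmr_file, sep="\t", index=False)
    else:
        dmrs.to_csv(dmr_file, sep="\t", index=False)
    record("dmrs", [dmr_file])

    # stage: annotation & enrichment ----------------------------------------
    hierarchy = ann.build_hierarchy(annot.genes, annot.tes)
    sig = dmrmod.significant_dmrs(dmrs) if len(dmrs) else pd.DataFrame()
    if len(sig):
        composition = ann.annotate_regions(
            sig[["chrom", "start", "end"]].drop_duplicates(), hierarchy
        )
        composition.to_csv(outdir / "dmr_annotation.tsv", sep="\t", index=False)
        hit = ann.overlap_with_window(
            sig[["chrom", "start", "end"]].drop_duplicates(), annot.tes, flank=2000
        )
        te_hits = annot.tes[hit["b_mask"]]
        enrich = ann.te_enrichment(
            ann.count_superfamilies(te_hits), ann.count_superfamilies(annot.tes)
        )
        enrich.to_csv(outdir / "te_enrichment.tsv", sep="\t", index=False)
        record("annotation", [outdir / "dmr_annotation.tsv", outdir / "te_enrichment.tsv"])

    # stage: clustering ------------------------------------------------------
    if len(sig) >= 1 and len(nuclear) >= 3:
        try:
            matrix = dmrmod.dmr_frequency_matrix(sig, nuclear)
            result = clu.cluster_samples(matrix, n_boot=config.n_boot, seed=config.seed)
            (outdir / "dendrogram.nwk").write_text(result.newick + "\n")
            matrix.to_csv(outdir / "dmr_matrix.tsv", sep="\t")
            record("clustering", [outdir / "dendrogram.nwk", outdir / "dmr_matrix.tsv"])
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)

    iomod.write_json(manifest, manifest_path)
    return manifest
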