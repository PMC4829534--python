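"""End-to-end pipeline driver: mask -> normalize -> binarize -> sharing ->
trees -> rarefaction -> regions -> enrichment, with a reproducible run
manifest.

The driver consumes either a simulated dataset (given a model config) or
on-disk fragment/count tables, executes every analysis stage with explicit
per-stage seeds, and writes all artifacts (TSV/BED/Newick/JSON) plus a
manifest recording inputs, outputs, checksums, seeds and warnings.
"""

from __future__ import annotations

import hashlib
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as txio
from . import phylo, presence as pres, regions, saturation, simulate, windows as win

DEFAULT_THRESHOLDS = (1, 10, 100)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; every stochastic stage has its own seed."""

    out_dir: str = "txturn_out"
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_boot: int = 1000
    n_orders: int = 100
    n_depth_draws: int = 10
    n_shuffles: int = 1000
    fdr: float = 0.05
    mask_min_count: int = 1
    genomic_dropout: float = 0.05
    normalize_target: int | None = None
    seeds: dict = field(default_factory=lambda: {
        "simulate": 1, "normalize": 2, "boot": 3, "rarefy_taxa": 4,
        "rarefy_depth": 5, "enrich": 6})
    model: simulate.TurnoverModel | None = None
    # optional on-disk inputs (used instead of simulation when given)
    fragments_path: str | None = None
    genomic_counts_path: str | None = None
    windows_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = txio.read_yaml(path) or {}
        model_cfg = raw.pop("model", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "model"})
        if model_cfg is not None:
            cfg.model = simulate.TurnoverModel(**model_cfg)
        if isinstance(cfg.thresholds, list):
            cfg.thresholds = tuple(cfg.thresholds)
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict, seed=None, **stats) -> None:
        self.stages.append({
            "stage": stage, "seed": seed,
            "outputs": {k: {"path": str(p), "sha256": _checksum(Path(p))}
                        for k, p in outputs.items()},
            **stats,
        })

    def to_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings,
                "n_stages": len(self.stages)}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artifacts under
    ``config.out_dir``; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    for p in (config.fragments_path, config.genomic_counts_path,
              config.windows_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    caught: list = []

    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")

        # stage 1: inputs (simulate or load)
        if config.fragments_path is not None:
            frags = txio.read_fragments(config.fragments_path)
            grid = txio.read_bed(config.windows_path)
            grid = grid.rename_axis(None).reset_index(drop=True)
            grid["index"] = np.arange(len(grid))
            counts = win.count_fragments(frags, grid)
            genomic = txio.read_count_matrix(config.genomic_counts_path)
            windows_df = grid
            dataset = None
        else:
            model = config.model or simulate.TurnoverModel(
                seed=config.seeds["simulate"])
            dataset = simulate.simulate_dataset(model)
            counts = dataset.counts
            windows_df = dataset.windows
            genomic = simulate.simulate_genomic_coverage(
                model, dropout=config.genomic_dropout)
            txio.write_newick(dataset.true_tree, out / "true_tree.nwk")
        txio.write_windows(windows_df, out / "windows.bed")
        txio.write_count_matrix(counts, out / "counts.tsv",
                                out / "samples.tsv")
        manifest.record("input", {"windows": out / "windows.bed",
                                  "counts": out / "counts.tsv"},
                        n_windows=len(windows_df),
                        n_samples=len(counts.sample_ids))

        # stage 2: common-genome mask
        mask = win.common_genome_mask(genomic, genomic.taxa,
                                      min_count=config.mask_min_count)
        txio.write_mask(mask, windows_df, out / "common_genome.bed")
        manifest.record("mask", {"mask": out / "common_genome.bed"},
                        n_masked=mask.n_masked)

        # stage 3: depth normalization
        target = config.normalize_target
        if target is None:
            target = int(counts.counts.sum(axis=0).min())
        counts = win.normalize_by_subsampling(counts, target,
                                              seed=config.seeds["normalize"])
        txio.write_count_matrix(counts, out / "counts_normalized.tsv")
        manifest.record("normalize", {"counts": out / "counts_normalized.tsv"},
                        seed=config.seeds["normalize"], target=target)

        # stage 4: binarize at each threshold + coverage fractions
        pms = {tau: pres.binarize(counts, tau, mask)
               for tau in config.thresholds}
        pm1 = pms[min(config.thresholds)]
        cov = pd.DataFrame({f"tau{tau}": pres.coverage_fraction(pm)
                            for tau, pm in pms.items()})
        txio.write_matrix_tsv(cov, out / "coverage_fractions.tsv", "taxon")
        txio.write_matrix_tsv(pm1.values, out / "presence_tau1.tsv", "window")
        manifest.record("binarize", {"coverage": out / "coverage_fractions.tsv",
                                     "presence": out / "presence_tau1.tsv"})

        # stage 5: sharing classes
        profile = pres.classify_sharing(
            pm1, {tau: pm for tau, pm in pms.items() if tau != pm1.tau})
        txio.write_matrix_tsv(profile.per_window, out / "sharing.tsv", "window")
        txio.write_matrix_tsv(profile.by_threshold, out / "sharing_by_threshold.tsv",
                              "class")
        manifest.record("sharing", {"classes": out / "sharing.tsv"},
                        **{f"n_{k}": int(v)
                           for k, v in profile.class_counts.items()})

        # stage 6: sharing tree with bootstrap supports
        tree, boot_report = phylo.bootstrap_supports(
            pm1, n_boot=config.n_boot, seed=config.seeds["boot"])
        txio.write_newick(tree, out / "sharing_tree.nwk")
        boot_report.to_csv(out / "bootstrap_supports.tsv", sep="\t", index=False)
        manifest.record("tree", {"tree": out / "sharing_tree.nwk",
                                 "supports": out / "bootstrap_supports.tsv"},
                        seed=config.seeds["boot"],
                        n_low_support=int(boot_report["below_cutoff"].sum()))

        # stage 7: rarefaction + saturation fits
        curve_t = saturation.rarefy_taxa(pm1, n_orders=config.n_orders,
                                         seed=config.seeds["rarefy_taxa"])
        curve_d = saturation.rarefy_depth(counts, mask,
                                          n_draws=config.n_depth_draws,
                                          seed=config.seeds["rarefy_depth"])
        fit_t = saturation.fit_saturation(curve_t)
        fit_d = saturation.fit_saturation(curve_d)
        curve_t.to_frame().to_csv(out / "rarefaction_taxa.tsv", sep="\t",
                                  index=False)
        curve_d.to_frame().to_csv(out / "rarefaction_depth.tsv", sep="\t",
                                  index=False)
        txio.write_json({"taxa": fit_t.to_dict(), "depth": fit_d.to_dict()},
                        out / "saturation_fits.json")
        manifest.record("rarefaction", {"fits": out / "saturation_fits.json"},
                        seed=config.seeds["rarefy_taxa"],
                        taxa_winner=fit_t.winner, depth_winner=fit_d.winner)

        # stage 8: run lengths + enrichment
        union = (pm1.values.sum(axis=1) > 0).to_numpy()
        rl = regions.run_lengths(union, windows_df, mask)
        rl.runs.to_csv(out / "run_lengths.tsv", sep="\t", index=False)
        chrom_sizes = (windows_df.groupby("chrom")["end"].max().to_dict())
        masked_windows = windows_df.iloc[mask.indices()]
        n_pres = pm1.values.sum(axis=1)
        target_sets = {
            "single": regions.windows_to_intervals(
                masked_windows, (n_pres == 1).to_numpy()),
            "all": regions.windows_to_intervals(
                masked_windows, (n_pres == len(pm1.taxa)).to_numpy()),
            "any": regions.windows_to_intervals(masked_windows, union),
        }
        target_sets = {k: v for k, v in target_sets.items() if len(v)}
        feature_sets = {}
        if dataset is not None and dataset.is_core.any():
            feature_sets["core_exons"] = regions.windows_to_intervals(
                windows_df, dataset.is_core)
        if feature_sets and target_sets:
            enr = regions.enrichment_family(
                feature_sets, target_sets, chrom_sizes,
                n_shuffles=config.n_shuffles, seed=config.seeds["enrich"],
                fdr=config.fdr)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            enrich_out = {"runlengths": out / "run_lengths.tsv",
                          "enrichment": out / "enrichment.tsv"}
        else:
            enrich_out = {"runlengths": out / "run_lengths.tsv"}
        manifest.record("regions", enrich_out, seed=config.seeds["enrich"],
                        max_desert_bp=rl.max_length("non-transcribed"))

        caught = [str(w.message) for w in wlist]

    manifest.warnings = sorted(set(caught))
    txio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
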