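"""End-to-end orchestration: the adaptation-versus-speciation contrast.

One call runs the full analysis arc on a dataset with a species x location
design: pairwise F_st tables along both axes, per-locus F_st histograms,
percentile-bin clustering/tree summaries, outlier scans with repeated-
outlier reports on both axes, the cross-axis sharing statistic, and
randomization nulls — all written as TSV/Newick/PNG artifacts with a
deterministic manifest.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (SampleGroups, filter_heterozygosity,
                   filter_loci_by_coverage, filter_rare_alleles,
                   select_first_snp_per_stack)
from .fst import percentile_stratify, pairwise_fst_table, wc_fst
from .outliers import (_NullCache, randomized_grouping_scan, repeated_outliers,
                       scan_comparisons)
from .synth import GeneratorConfig, generate_dataset
from .trees import allele_sharing_distance, nj_tree, pca_cluster

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`; load from YAML with
    :meth:`from_yaml`.  Exactly one input source (files or generator) must
    be active."""

    # input: either explicit files ...
    genotype_tsv: str | None = None
    depth_tsv: str | None = None
    metadata_tsv: str | None = None
    vcf: str | None = None
    # ... or the synthetic generator
    synth: dict | None = None

    out_dir: str = "radscan_out"
    seed: int = 0
    # filters
    min_depth: int = 10
    min_inds: int = 5
    min_groups: int = 7
    coverage_group_by: str = "species_location"
    max_het: float = 0.5
    one_snp_per_stack: bool = True
    # scans
    q_thresholds: tuple[float, float] = (0.2, 0.05)
    null_B: int = 200_000
    # percentile bins
    percentile_breaks: tuple[float, ...] = (60, 70, 80, 90)
    # extras
    run_randomization: bool = True
    bootstrap: int = 100
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        problems = []
        file_input = self.vcf or self.genotype_tsv
        if bool(file_input) == bool(self.synth is not None):
            problems.append("exactly one input source (files or synth) must be set")
        if self.genotype_tsv and not self.metadata_tsv:
            problems.append("genotype_tsv input requires metadata_tsv")
        for q in self.q_thresholds:
            if not (0 < q < 1):
                problems.append(f"q threshold {q} outside (0, 1)")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))


def _load_input(cfg: PipelineConfig):
    from . import io

    if cfg.synth is not None:
        synth_args = dict(cfg.synth)
        synth_args.setdefault("seed", cfg.seed)
        gcfg = GeneratorConfig(**synth_args)
        g, cov, groups, truth = generate_dataset(gcfg)
        return g, cov, groups, truth
    if cfg.vcf:
        g, cov, _ = io.read_vcf(cfg.vcf)
        groups = io.read_metadata_tsv(cfg.metadata_tsv)
        return g, cov, groups, None
    g = io.read_genotype_tsv(cfg.genotype_tsv)
    cov = io.read_depth_tsv(cfg.depth_tsv) if cfg.depth_tsv else None
    groups = io.read_metadata_tsv(cfg.metadata_tsv)
    return g, cov, groups, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and return a manifest of produced artifacts."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "steps": []}

    g, cov, groups, truth = _load_input(cfg)
    manifest["input"] = {"n_loci": g.n_loci, "n_samples": g.n_samples}

    # ---- filtering ---------------------------------------------------------
    if cov is not None:
        g2 = filter_loci_by_coverage(
            g, cov, groups, cfg.min_depth, cfg.min_inds, cfg.min_groups,
            group_by=cfg.coverage_group_by,
        )
    else:
        g2 = g
    g3 = filter_rare_alleles(g2, groups)
    g4 = filter_heterozygosity(g3, cfg.max_het)
    g5 = select_first_snp_per_stack(g4) if cfg.one_snp_per_stack else g4
    manifest["filtering"] = {
        "coverage": [g.n_loci, g2.n_loci], "rare_alleles": [g2.n_loci, g3.n_loci],
        "heterozygosity": [g3.n_loci, g4.n_loci], "first_snp": [g4.n_loci, g5.n_loci],
    }
    gf = g5

    # ---- F_st tables along both axes ---------------------------------------
    axis_results = {}
    for axis in ("location", "species"):
        table = pairwise_fst_table(gf, groups, axis=axis)
        table.to_csv(out / f"fst_pairs_{axis}.tsv", sep="\t", index=False)
        res = wc_fst(gf, groups.labels(gf.samples, by=axis))
        res.to_frame().to_csv(out / f"fst_per_locus_{axis}.tsv", sep="\t", index=False)
        axis_results[axis] = res
        manifest["steps"].append({"step": f"fst_{axis}", "seed": cfg.seed,
                                  "multilocus_fst": res.multilocus_fst})
        if cfg.make_plots:
            _histogram(res, out / f"fst_hist_{axis}.png", axis)

    # ---- percentile stratification + clustering + tree ---------------------
    strat = {}
    for axis, res in axis_results.items():
        bins = percentile_stratify(res, cfg.percentile_breaks)
        rows = [{"bin": lab, "locus": lid} for lab in bins.labels for lid in bins.bins[lab]]
        pd.DataFrame(rows).to_csv(out / f"percentile_bins_{axis}.tsv", sep="\t", index=False)
        strat[axis] = bins
        top = bins.bins[bins.labels[-1]]
        pos = {lid: i for i, lid in enumerate(gf.locus_ids)}
        gtop = gf.take_loci(np.array([pos[l] for l in top]))
        cl = pca_cluster(gtop, k_max=6, seed=cfg.seed)
        pd.DataFrame({"sample": cl.sample_names, "cluster": cl.assignment}).to_csv(
            out / f"clusters_top_bin_{axis}.tsv", sep="\t", index=False)
        manifest["steps"].append({"step": f"cluster_top_{axis}", "seed": cfg.seed, "k": cl.k})
        try:
            d = allele_sharing_distance(gtop)
            tree = nj_tree(d, gtop.samples, bootstrap=cfg.bootstrap, g=gtop, seed=cfg.seed)
            (out / f"nj_top_bin_{axis}.nwk").write_text(tree.newick + "\n")
        except ValueError as e:
            logger.warning("NJ tree skipped for %s: %s", axis, e)

    # ---- outlier scans on both axes ----------------------------------------
    cache = _NullCache(B=cfg.null_B, deme_size=1000, seed=cfg.seed)
    scan_outliers = {}
    for axis in ("location", "species"):
        gswap = gf
        grp = groups if axis == "location" else _swap_axes(groups)
        rep_rows = []
        for q in cfg.q_thresholds:
            scans = scan_comparisons(gswap, grp, mode="per_pair", q_threshold=q,
                                     B=cfg.null_B, seed=cfg.seed, null_cache=cache)
            rep = repeated_outliers(scans)
            for s in scans:
                rep_rows.append({
                    "comparison": s.comparison, "q_threshold": q,
                    "n_loci": s.n_considered, "n_outliers": s.n_outliers,
                    "pct_outliers": 100 * s.n_outliers / max(s.n_considered, 1),
                })
            if q == cfg.q_thresholds[0]:
                scan_outliers[axis] = rep
                pd.DataFrame(
                    [{"locus": l, "n_species": c} for l, c in sorted(rep.repeat_counts.items())]
                ).to_csv(out / f"repeated_outliers_{axis}.tsv", sep="\t", index=False)
        pd.DataFrame(rep_rows).to_csv(out / f"scan_table_{axis}.tsv", sep="\t", index=False)
        manifest["steps"].append({
            "step": f"scan_{axis}", "seed": cfg.seed,
            "q_thresholds": list(cfg.q_thresholds),
            "n_repeated": len(scan_outliers[axis].repeated),
            "n_triple": len(scan_outliers[axis].triple_repeated),
            "shared_consideration": scan_outliers[axis].shared_consideration_ratio,
        })

    # ---- cross-axis sharing -------------------------------------------------
    sharing = {}
    top2 = {
        axis: set().union(*(strat[axis].bins[lab] for lab in strat[axis].labels[-2:]))
        for axis in strat
    }
    inter = top2["location"] & top2["species"]
    union = top2["location"] | top2["species"]
    sharing["top_percentile_shared_pct"] = 100 * len(inter) / len(union) if union else 0.0
    o_loc = set().union(*scan_outliers["location"].per_species_outliers.values()) \
        if scan_outliers["location"].per_species_outliers else set()
    o_sp = set().union(*scan_outliers["species"].per_species_outliers.values()) \
        if scan_outliers["species"].per_species_outliers else set()
    ou = o_loc | o_sp
    sharing["outliers_shared_pct"] = 100 * len(o_loc & o_sp) / len(ou) if ou else 0.0
    (out / "cross_axis_sharing.json").write_text(json.dumps(sharing, indent=2))
    manifest["steps"].append({"step": "cross_axis_sharing", "seed": cfg.seed, **sharing})

    # ---- randomization null -------------------------------------------------
    if cfg.run_randomization:
        rfst, rrep = randomized_grouping_scan(
            gf, seed=cfg.seed, q_threshold=cfg.q_thresholds[0], B=cfg.null_B,
            null_cache=cache,
        )
        manifest["steps"].append({
            "step": "randomization", "seed": cfg.seed,
            "global_fst": rfst.multilocus_fst, "n_repeated": len(rrep.repeated),
        })

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete; artifacts in %s", out)
    return manifest


def _swap_axes(groups: SampleGroups) -> SampleGroups:
    """View the design with species and location roles exchanged, so the
    species-axis ('speciation') scan reuses the location-axis machinery."""
    return SampleGroups({s: (loc, sp) for s, (sp, loc) in groups.assignment.items()})


def _histogram(res, path: Path, axis: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = res.fst[res.defined]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(vals, bins=80)
    ax.set_xlabel(f"per-SNP F_st ({axis})")
    ax.set_ylabel("SNPs")
    ax.set_title(f"multilocus F_st = {res.multilocus_fst:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    pd.DataFrame({"fst": vals}).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
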