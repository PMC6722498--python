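"""Reproducible end-to-end runs: simulate -> MR -> scan -> blocks -> models.

A run is fully specified by a :class:`RunConfig` (YAML-serialisable). Every
stage writes its table under the run directory, each output embeds the
config hash and master seed for provenance, and identical configurations
yield byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, blocks, metabolites, predmodel
from .genotypes import write_genotypes_tsv, write_vcf
from .simulate import Cohort, CohortConfig, generate_cohort, select_extreme_subsets


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    n_samples: int = 500
    seed: int = 0
    # metabolic ratio
    mr_cutoff: float = 0.0146
    endoxifen_threshold_ngml: float = 6.0
    # extreme-phenotype GWAS design
    n_per_tail: int = 96
    # association scan
    alpha: float = 0.05
    max_missing: int = 4
    # block selection
    p_block: float = 1e-3
    p_core: float = 1e-4
    gap_max: int = 30_000
    min_size: int = 3
    min_core: int = 2
    # modeling
    entry_p: float = 0.05
    delta_auc: float = 0.005
    k_folds: int = 10
    prob_cutoff: float = 0.5
    auc_mode: str = "cv"
    # cohort generator knobs (LD/effect specs use the generator defaults)
    n_null_snps: int = 200
    missing_rate: float = 0.01
    # chromosome-22 SNPs always carried into verification regardless of the
    # block scan (mirrors hand-picking from the strong long-range LD region)
    chr22_allowlist: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "mr_cutoff",
            "endoxifen_threshold_ngml",
            "alpha",
            "p_block",
            "p_core",
            "gap_max",
            "entry_p",
            "delta_auc",
            "prob_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")
        if 2 * self.n_per_tail > self.n_samples:
            raise PipelineError(
                f"config: 2 x n_per_tail ({2 * self.n_per_tail}) exceeds n_samples ({self.n_samples})"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        raw = {k: v for k, v in raw.items() if k in names}  # drop derived keys
        if "chr22_allowlist" in raw:
            raw["chr22_allowlist"] = tuple(raw["chr22_allowlist"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chr22_allowlist"] = list(self.chr22_allowlist)
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(8, dtype="uint32") >> 1
    names = ["cohort", "cv_approach1", "cv_approach2"]
    return {name: int(state[i]) for i, name in enumerate(names)}


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full pipeline into ``out_dir`` and return that path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_sha256={config.sha256()} seed={config.seed}"
    seeds = _stage_seeds(config.seed)
    log: list[str] = []

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # abort with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- simulate -----------------------------------------------------
    cohort_cfg = CohortConfig(
        n_samples=config.n_samples,
        n_null_snps=config.n_null_snps,
        missing_rate=config.missing_rate,
        mr_cutoff=config.mr_cutoff,
        seed=seeds["cohort"],
    )
    cohort: Cohort = stage("simulate")(generate_cohort, cohort_cfg)
    log.append(f"simulate: {cohort.config.n_samples} samples, {cohort.genotypes.n_snps} SNPs")
    metabolites.write_concentrations(cohort.panels, out / "concentrations.csv")
    write_genotypes_tsv(cohort.genotypes, out / "genotypes.tsv", header_comment=tag)
    write_vcf(cohort.genotypes, out / "genotypes.vcf", header_comment=tag)
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "group": cohort.diplotypes,
            "impaired": cohort.impaired,
        }
    ).to_csv(out / "diplotypes.csv", index=False)
    (out / "truth.json").write_text(
        json.dumps({"provenance": tag, **cohort.truth}, indent=2, default=float)
    )

    # --- metabolic ratio ---------------------------------------------
    mr_frame = stage("mr")(metabolites.mr_table, cohort.panels, config.mr_cutoff)
    mr_frame.to_csv(out / "mr.csv", index=False)
    below = mr_frame["below_threshold"].to_numpy(dtype=bool)
    log.append(f"mr: {int(below.sum())}/{below.size} samples below cutoff {config.mr_cutoff}")

    # --- extreme-phenotype GWAS scan ---------------------------------
    ratios = cohort.activity_ratios()
    low_idx, high_idx = stage("gwas")(
        select_extreme_subsets, ratios, config.n_per_tail, cohort.sample_ids
    )
    subset_idx = np.concatenate([low_idx, high_idx])
    subset = cohort.genotypes.subset_samples(subset_idx)
    subset_filtered, dropped = assoc.filter_probes(subset, config.max_missing)
    extreme_low = np.concatenate(
        [np.ones(low_idx.size, dtype=bool), np.zeros(high_idx.size, dtype=bool)]
    )
    scan = stage("gwas")(assoc.run_association_scan, subset_filtered, extreme_low, config.alpha)
    scan_frame = assoc.scan_to_frame(scan, subset_filtered)
    chi2 = np.array([stats[0] for stats in (assoc.trend_test(r.genotype_counts) for r in scan)])
    lambda_gc = assoc.genomic_lambda(chi2)
    theta = np.nan_to_num(subset_filtered.dosages / 2.0, nan=0.5)
    coords, outliers = assoc.pca_qc(theta)
    qc = {
        "provenance": tag,
        "dropped_probes": dropped,
        "n_probes_tested": len(scan),
        "lambda_gc": lambda_gc,
        "pca_outlier_samples": [subset_filtered.sample_ids[i] for i in outliers],
    }
    (out / "qc.json").write_text(json.dumps(qc, indent=2))
    with open(out / "scan.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        scan_frame.to_csv(fh, sep="\t", index=False)
    log.append(
        f"gwas: {len(scan)} SNPs on {subset_filtered.n_samples} extreme samples "
        f"({len(dropped)} probes dropped, lambda={lambda_gc:.3f})"
    )

    # --- block selection ---------------------------------------------
    track = scan_frame.rename(columns={"p": "p"})[["snp_id", "chrom", "pos", "p"]]
    found = stage("blocks")(
        blocks.find_blocks,
        track,
        config.p_block,
        config.p_core,
        config.gap_max,
        config.min_size,
        config.min_core,
    )
    blocks_frame = blocks.blocks_to_frame(found)
    with open(out / "blocks.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        blocks_frame.to_csv(fh, sep="\t", index=False)
    index_snps = blocks.select_index_snps(found)
    (out / "index_snps.txt").write_text("\n".join(index_snps) + ("\n" if index_snps else ""))
    log.append(f"blocks: {len(found)} blocks, index SNPs: {index_snps}")

    # --- verification scan on the full cohort ------------------------
    tags = cohort.truth["cyp2d6_tags"]
    verified_set = list(
        dict.fromkeys([*index_snps, *config.chr22_allowlist, *cohort.truth["linked"], *tags])
    )
    # significant non-index candidates outside blocks (effect SNPs surface here)
    extra = scan_frame[
        (scan_frame["p"] < config.p_core) & ~scan_frame["snp_id"].isin(verified_set)
    ]["snp_id"].tolist()
    verified_set = list(dict.fromkeys(verified_set + extra))
    keep_idx = [j for j, sid in enumerate(cohort.genotypes.snp_ids) if sid in verified_set]
    verif_matrix = cohort.genotypes.subset_snps(keep_idx)
    verif = stage("verify")(assoc.run_association_scan, verif_matrix, below, config.alpha)
    verif_frame = assoc.scan_to_frame(verif, verif_matrix)
    with open(out / "verification.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        verif_frame.to_csv(fh, sep="\t", index=False)
    log.append(
        f"verify: {len(verif)} SNPs on the full cohort, "
        f"{int(verif_frame['significant'].sum())} significant at "
        f"{config.alpha}/{len(verif)}"
    )

    # --- prediction modeling -----------------------------------------
    snp_candidates = [s for s in verified_set if s not in tags]
    predictor_cols = {s: cohort.genotypes.dosage_of(s) for s in snp_candidates}
    tag_cols = {s: cohort.genotypes.dosage_of(s) for s in tags}
    base = pd.DataFrame({**predictor_cols, **tag_cols})
    outcome = below
    for approach, cols in (
        (1, {**predictor_cols, "cyp2d6_impaired": cohort.impaired.astype(float)}),
        (2, {**predictor_cols, **tag_cols}),
    ):
        frame = pd.DataFrame(cols)
        dataset = predmodel.ModelDataset.complete_cases(frame, outcome)
        result = stage(f"model{approach}")(
            predmodel.run_approach,
            dataset,
            approach,
            config.entry_p,
            config.delta_auc,
            config.k_folds,
            seeds[f"cv_approach{approach}"],
            config.auc_mode,
            config.prob_cutoff,
        )
        sub = out / f"approach{approach}"
        sub.mkdir(exist_ok=True)
        with open(sub / "trace.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            result.trace.to_csv(fh, sep="\t", index=False)
        report = {
            "provenance": tag,
            "approach": approach,
            "n_complete_cases": dataset.n,
            "n_dropped_incomplete": dataset.n_dropped_incomplete,
            "selected": [{"variable": v, "entry_p": p} for v, p in result.selected],
            "final_variables": result.final_variables,
            "cv": result.report.to_dict() if result.report else None,
        }
        (sub / "report.json").write_text(json.dumps(report, indent=2))
        log.append(
            f"model{approach}: selected {[v for v, _ in result.selected]}, "
            f"final {result.final_variables}, "
            f"cv_auc={result.report.auc:.3f}" if result.report else f"model{approach}: empty model"
        )

    # --- provenance ---------------------------------------------------
    resolved = {**config.to_dict(), "config_sha256": config.sha256(), "stage_seeds": seeds}
    (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    (out / "log.txt").write_text("\n".join([tag, *log]) + "\n")
    return out
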