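"""End-to-end orchestration: simulate -> preprocess -> diversity ->
network -> enrichment -> selection -> evaluation.

Every stochastic stage draws its seed deterministically from the master
seed and the stage name, so adding a stage never perturbs the
randomness of earlier ones and a rerun with the same config is
bit-identical.  All intermediate artifacts are written as tab-delimited
text together with a JSON manifest (config, per-stage seeds, package
and library versions, artifact hashes) and a Markdown report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import aggregate_by_rank, bray_curtis, chao1, pcoa, permanova
from .enrichment import family_enrichment
from .evaluation import kfold_cv, random_baseline, summarize
from .io_tables import (CountMatrix, PhenotypeTable, TaxonomyTable,
                        read_count_table, read_phenotypes, read_taxonomy,
                        write_count_table, write_edge_list, write_phenotypes,
                        write_taxonomy)
from .pcit import correlation_matrix, pcit, phenotype_edges
from .preprocess import clr_transform, core_membership, css_normalize, \
    prevalence_filter, rv_coefficient
from .subsets import best_subsets, minimal_subset
from .synthetic import PHENOTYPES, SimulationConfig, generate

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    simulate: bool = True
    counts_path: str | None = None
    taxonomy_path: str | None = None
    phenotypes_path: str | None = None
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    min_samples: int = 20
    css_quantile_mode: str = "fixed:0.5"
    core_threshold: float = 0.5
    phenotype_list: tuple[str, ...] = PHENOTYPES
    selection_threshold: float = 0.95
    baseline_draws: int = 10
    cv_folds: int = 5
    subset_mode: str = "auto"
    p_exhaustive_max: int = 20
    permanova_permutations: int = 999
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        config = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim_raw:
            effects = sim_raw.pop("effects", None)
            config.simulation = SimulationConfig(**sim_raw)
            if effects:
                from .synthetic import EffectSpec
                config.simulation.effects = {
                    p: EffectSpec(**spec) for p, spec in effects.items()}
        config.simulation.seed = stage_seed(config.master_seed, "simulate")
        return config


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of master seed and stage name,
    folded below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every violation (empty list means the config is valid)."""
    errors: list[str] = []
    if config.simulate:
        try:
            config.simulation.validate()
        except ValueError as exc:
            errors.append(str(exc))
        n_samples = config.simulation.n_samples
    else:
        for attr in ("counts_path", "taxonomy_path", "phenotypes_path"):
            if getattr(config, attr) is None:
                errors.append(f"{attr} required when simulate is false")
        n_samples = None
    if config.min_samples < 1:
        errors.append("min_samples must be >= 1")
    if n_samples is not None and config.min_samples > n_samples:
        errors.append(f"min_samples={config.min_samples} exceeds "
                      f"n_samples={n_samples}")
    if not 0 < config.core_threshold <= 1:
        errors.append("core_threshold must lie in (0, 1]")
    if not 0 < config.selection_threshold <= 1:
        errors.append("selection_threshold must lie in (0, 1]")
    if config.baseline_draws < 1:
        errors.append("baseline_draws must be >= 1")
    if config.cv_folds < 2:
        errors.append("cv_folds must be >= 2")
    if config.permanova_permutations < 1:
        errors.append("permanova_permutations must be >= 1")
    return errors


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir`` and return the path.

    Artifacts: the four input tables (simulated or copied through),
    transformed abundances, diversity outputs, the retained network and
    phenotype edge lists, per-phenotype enrichment and subset-selection
    tables, the evaluation summary, a manifest and a report.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid run config: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "parameters": {
            "min_samples": config.min_samples,
            "css_quantile_mode": config.css_quantile_mode,
            "core_threshold": config.core_threshold,
            "selection_threshold": config.selection_threshold,
            "baseline_draws": config.baseline_draws,
            "cv_folds": config.cv_folds,
            "subset_mode": config.subset_mode,
            "permanova_permutations": config.permanova_permutations,
        },
        "stages": {},
    }

    # --- stage: inputs ---
    if config.simulate:
        sim = dataclasses.replace(config.simulation)
        sim.seed = stage_seed(config.master_seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim.seed
        counts, taxonomy, phenotypes, truth = generate(sim)
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        manifest["parameters"]["simulation"] = {
            "n_samples": sim.n_samples, "n_asvs": sim.n_asvs,
            "sparsity_target": sim.sparsity_target,
            "effects": {p: dataclasses.asdict(e) for p, e in sim.effects.items()},
            "n_mediated_asvs": sim.n_mediated_asvs,
        }
    else:
        counts = read_count_table(config.counts_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        phenotypes = read_phenotypes(config.phenotypes_path)
        truth = None
    write_count_table(counts, out / "counts.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    write_phenotypes(phenotypes, out / "phenotypes.tsv")
    manifest["stages"]["inputs"] = {
        "n_asvs": len(counts.feature_ids), "n_samples": len(counts.sample_ids)}

    # --- stage: preprocess ---
    filtered = prevalence_filter(counts, config.min_samples)
    abundances = css_normalize(filtered, config.css_quantile_mode)
    clr = clr_transform(filtered)
    rv = rv_coefficient(abundances.sample_matrix(), clr.sample_matrix())
    frame = pd.DataFrame(abundances.values, index=abundances.feature_ids,
                         columns=abundances.sample_ids)
    frame.index.name = "feature_id"
    _write_tsv(frame, out / "abundances_css_log2.tsv")
    with open(out / "transform.json", "w", encoding="utf-8") as fh:
        json.dump({"transform": abundances.transform,
                   "parameters": abundances.parameters,
                   "rv_css_vs_clr": rv}, fh, indent=1, sort_keys=True)
    core = core_membership(filtered, {s: "all" for s in filtered.sample_ids},
                           config.core_threshold)
    manifest["stages"]["preprocess"] = {
        "n_asvs_after_filter": len(filtered.feature_ids),
        "rv_css_vs_clr": round(rv, 6),
        "n_core": len(core.groups["all"]),
    }

    # --- stage: diversity (sampling-week style grouping check) ---
    div_seed = stage_seed(config.master_seed, "diversity")
    manifest["stage_seeds"]["diversity"] = div_seed
    rng = np.random.default_rng(div_seed)
    week = {s: f"week{1 + (flag % 2)}"
            for s, flag in zip(filtered.sample_ids,
                               rng.permutation(len(filtered.sample_ids)))}
    family_counts = aggregate_by_rank(filtered, taxonomy, "family")
    alpha = pd.DataFrame({
        "sample_id": family_counts.sample_ids,
        "chao1": [chao1(family_counts.counts[:, j])
                  for j in range(len(family_counts.sample_ids))],
    })
    _write_tsv(alpha, out / "alpha_chao1.tsv", index=False)
    distances = bray_curtis(filtered)
    _write_tsv(pd.DataFrame(distances.matrix, index=distances.sample_ids,
                            columns=distances.sample_ids), out / "bray_curtis.tsv")
    ordination = pcoa(distances)
    coords = pd.DataFrame(ordination.coordinates[:, :2], index=ordination.sample_ids,
                          columns=["PC1", "PC2"])
    coords.index.name = "sample_id"
    _write_tsv(coords, out / "pcoa_coordinates.tsv")
    perm = permanova(distances, week, config.permanova_permutations, seed=div_seed)
    with open(out / "permanova.json", "w", encoding="utf-8") as fh:
        json.dump({"pseudo_F": perm.pseudo_f, "p_value": perm.p_value,
                   "n_permutations": perm.n_permutations, "seed": perm.seed,
                   "grouping": "week"}, fh, indent=1, sort_keys=True)
    manifest["stages"]["diversity"] = {
        "permanova_p": perm.p_value,
        "pcoa_pc1_pct": round(100 * float(ordination.explained[0]), 2),
    }

    # --- stage: network ---
    corr = correlation_matrix(abundances, phenotypes)
    network = pcit(corr)
    write_edge_list(network.to_edge_list(config.phenotype_list), out / "edges.tsv")
    edges = phenotype_edges(network, config.phenotype_list)
    pheno_rows = [(p, asv, r, "asv-phenotype")
                  for p in config.phenotype_list
                  for asv, r, _ in edges.edges[p]]
    with open(out / "phenotype_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("phenotype\tasv\tcorrelation\tedge_type\n")
        for p, asv, r, kind in pheno_rows:
            fh.write(f"{p}\t{asv}\t{r:.6f}\t{kind}\n")
    manifest["stages"]["network"] = {
        "n_nodes": len(corr.node_ids),
        "n_edges_retained": len(network.edges),
        "n_phenotype_edges": {p: len(edges.edges[p]) for p in config.phenotype_list},
    }

    # --- stage: enrichment ---
    background = list(abundances.feature_ids)
    enrich_frames = []
    for p in config.phenotype_list:
        selected = edges.asv_ids(p)
        if len(selected) < 2:
            continue
        for res in family_enrichment(selected, background, taxonomy):
            enrich_frames.append((p, res.family, res.x, res.K, res.n, res.N,
                                  res.p_upper, res.score, res.bh_fdr))
    enrich = pd.DataFrame(enrich_frames, columns=[
        "phenotype", "family", "x", "K", "n", "N", "p_upper", "score", "bh_fdr"])
    _write_tsv(enrich, out / "enrichment.tsv", index=False)
    manifest["stages"]["enrichment"] = {"n_rows": len(enrich)}

    # --- stage: selection + evaluation ---
    eval_seed = stage_seed(config.master_seed, "evaluate")
    manifest["stage_seeds"]["evaluate"] = eval_seed
    summary_rows = []
    path_frames = []
    for p in config.phenotype_list:
        selected = edges.asv_ids(p)
        if len(selected) < 1:
            log.warning("phenotype %s has no connected ASVs; skipped", p)
            continue
        y = phenotypes.vector(p, abundances.sample_ids)
        x_full = abundances.sample_matrix(selected)
        path = best_subsets(x_full, y, feature_ids=selected,
                            mode=config.subset_mode,
                            p_exhaustive_max=config.p_exhaustive_max)
        for k, r2, subset in zip(path.sizes, path.r2, path.subsets):
            path_frames.append((p, k, r2, ",".join(path.feature_ids[i] for i in subset),
                                path.search_mode))
        selection = minimal_subset(path, config.selection_threshold)
        baseline = random_baseline(
            background, abundances.sample_matrix, y, m=len(selected),
            n_draws=config.baseline_draws,
            seed=stage_seed(config.master_seed, f"baseline:{p}"))
        cv = kfold_cv(abundances.sample_matrix(selection.subset_ids), y,
                      k=config.cv_folds,
                      seed=stage_seed(config.master_seed, f"cv:{p}"))
        summary_rows.append({
            "dataset": "synthetic" if config.simulate else "input",
            "trait": p,
            "n_full": len(selected),
            "r2_full": path.full_model_r2,
            "r2_random_mean": baseline.mean_r2,
            "n_selected": selection.minimal_k,
            "r2_selected": selection.r2_selected,
            "mean_cv_r2": cv.mean_cv_r2,
        })
    paths = pd.DataFrame(path_frames,
                         columns=["phenotype", "k", "R2", "subset", "mode"])
    _write_tsv(paths, out / "subset_paths.tsv", index=False)
    summary_base = pd.DataFrame(summary_rows)
    if not summary_base.empty:
        summary, aggregates = summarize(summary_base)
    else:
        summary, aggregates = summary_base, {}
    _write_tsv(summary, out / "summary.tsv", index=False)
    manifest["stages"]["evaluation"] = {"aggregates": {
        k: round(v, 6) for k, v in aggregates.items()}}

    # --- manifest + report ---
    artifact_names = sorted(p.name for p in out.iterdir()
                            if p.is_file() and p.name not in ("manifest.json",
                                                              "report.md"))
    _report(out, manifest, summary)
    manifest["artifacts"] = {name: _sha256(out / name) for name in artifact_names}
    manifest["artifacts"]["report.md"] = _sha256(out / "report.md")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _report(out: Path, manifest: dict, summary: pd.DataFrame) -> None:
    lines = ["# Co-association pipeline report", ""]
    lines.append(f"Package version {manifest['package_version']}, "
                 f"master seed {manifest['master_seed']}.")
    lines.append("")
    for stage, info in manifest["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(info, indent=1, sort_keys=True))
        lines.append("```")
        lines.append("")
    if not summary.empty:
        lines.append("## Trait summary")
        lines.append("")
        lines.append("```")
        lines.append(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("```")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
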