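"""End-to-end driver: simulate -> preprocess -> correlate -> bicluster ->
associate -> validate -> enrich, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from methylink import associations as assoc_mod
from methylink import correlation, fabia, preprocess, stats, synthetic
from methylink import io as mio

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Documented counter scheme: per-stage seeds derived from one global
    seed so stages can be rerun in isolation."""
    return (global_seed * 31 + stage_index) % (2 ** 31)


@dataclass
class RunConfig:
    outdir: Path = Path("results/run")
    seed: int = 0
    simulation: synthetic.SimulationConfig | None = None
    study_dir: Path | None = None          # read an existing study instead
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    fabia: fabia.FabiaConfig = field(
        default_factory=lambda: fabia.FabiaConfig(K=10, n_iter=500)
    )
    min_support: int = 3
    p_max: float = 0.05
    n_perm: int = 1000
    write_artifacts: bool = True


@dataclass
class RunResult:
    manifest: dict
    study: synthetic.SyntheticStudy
    biclusters: dict[str, list[fabia.Bicluster]]
    consensus: pd.DataFrame
    validation: dict
    enrichment: pd.DataFrame
    parameter_disease: pd.DataFrame


def run_all(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline; rerunning with the same config and seed
    reproduces identical outputs."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    manifest: dict = {"seed": cfg.seed, "stages": []}

    def record(name: str, t_start: float, **info):
        manifest["stages"].append(
            {"stage": name, "seconds": round(time.time() - t_start, 3), **info}
        )

    # 1. simulate / load
    t = time.time()
    if cfg.study_dir is not None:
        study = synthetic.read_study(cfg.study_dir)
    else:
        sim = cfg.simulation or synthetic.SimulationConfig(seed=stage_seed(cfg.seed, 0))
        study = synthetic.generate_study(sim)
    if cfg.write_artifacts and cfg.study_dir is None:
        synthetic.write_study(study, outdir / "study")
    record("simulate", t, n_subjects=len(study.subjects),
           n_probes=study.config.n_probes, n_parameters=study.config.n_parameters)

    baseline_labels = tuple(f"day{d:+d}" for d in study.config.baseline_days)
    pcfg = dataclasses.replace(cfg.preprocess, baseline_days=baseline_labels)

    # 2. preprocess: QC filters then variability selection
    t = time.time()
    filtered: dict[str, pd.DataFrame] = {}
    var_stats: dict[str, pd.DataFrame] = {}
    qc_reports = {}
    common = None
    for subj in study.subjects:
        fb, rep = preprocess.qc_filter(study.beta[subj], study.qc[subj], pcfg)
        filtered[subj] = fb
        qc_reports[subj] = rep.steps
        common = fb.index if common is None else common.intersection(fb.index)
    for subj in study.subjects:
        filtered[subj] = filtered[subj].loc[common]
        var_stats[subj] = preprocess.variability_stats(filtered[subj], pcfg)
    selected, sel_counts = preprocess.select_probes(var_stats, pcfg)
    for subj in study.subjects:
        filtered[subj] = filtered[subj].loc[selected]
        if cfg.write_artifacts:
            mio.write_table(filtered[subj], outdir / f"filtered_beta_{subj}.tsv")
            mio.write_table(var_stats[subj], outdir / f"variability_{subj}.tsv")
    record("preprocess", t, qc_reports=qc_reports, selection=sel_counts,
           n_selected=len(selected))

    # 3. correlate + standardize per subject
    t = time.time()
    standardized: dict[str, pd.DataFrame] = {}
    for subj in study.subjects:
        rho = correlation.spearman_matrix(filtered[subj], study.params[subj])
        standardized[subj] = correlation.standardize(rho)
        if cfg.write_artifacts:
            mio.write_table(rho, outdir / f"correlation_{subj}.tsv")
    record("correlate", t, shape=list(next(iter(standardized.values())).shape))

    # 4. bicluster per subject
    t = time.time()
    biclusters: dict[str, list[fabia.Bicluster]] = {}
    for s_idx, subj in enumerate(study.subjects):
        fcfg = dataclasses.replace(cfg.fabia, seed=stage_seed(cfg.seed, 30 + s_idx))
        model = fabia.fit(standardized[subj], fcfg)
        biclusters[subj] = fabia.extract_biclusters(model, fcfg, subject=subj)
        if cfg.write_artifacts:
            mio.write_table(
                fabia.biclusters_to_frame(biclusters[subj]),
                outdir / f"biclusters_{subj}.tsv", index=False,
            )
    record("bicluster", t,
           n_biclusters={s: len(b) for s, b in biclusters.items()})

    # 5. associate: per-subject pairs -> consensus
    t = time.time()
    pair_sets = {
        subj: assoc_mod.comembership_pairs(biclusters[subj], study.annotation, level="gene")
        for subj in study.subjects
    }
    consensus = assoc_mod.consensus(pair_sets, min_support=cfg.min_support)
    venn = assoc_mod.venn_counts(pair_sets)
    if cfg.write_artifacts:
        mio.write_table(consensus, outdir / "consensus_associations.tsv", index=False)
        mio.write_json(venn, outdir / "venn_counts.json")
    truth_pairs = set(map(tuple, study.truth.get("truth_pairs", [])))
    found = assoc_mod.association_pairs(consensus) if len(consensus) else set()
    precision = len(found & truth_pairs) / len(found) if found else 0.0
    recall = len(found & truth_pairs) / len(truth_pairs) if truth_pairs else 0.0
    record("associate", t, n_pairs=len(found), n_truth=len(truth_pairs),
           consensus_precision=round(precision, 4), consensus_recall=round(recall, 4))

    # 6. validate against the reference-interaction set
    t = time.time()
    validation: dict = {}
    if found:
        count, ratio = stats.validated_ratio(found, study.reference)
        genes = sorted({g for g, _ in found})
        params = sorted({q for _, q in found})
        perm = stats.permutation_test(
            genes, params, study.reference, n_assoc=len(found),
            observed_count=count, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, 50),
        )
        universe = len(genes) * len(params)
        bg_count = sum(1 for g in genes for q in params if (g, q) in study.reference)
        validation = {
            "validated_count": count,
            "validated_pct": round(100 * ratio, 2),
            "background_pct": round(100 * bg_count / universe, 2) if universe else 0.0,
            "pair_universe": universe,
            "hypergeom_p": stats.hypergeom_tail(count, len(found), bg_count, universe)
            if universe else 1.0,
            "permutation_p": perm.empirical_p,
        }
    if cfg.write_artifacts:
        mio.write_json(validation, outdir / "validation.json")
    record("validate", t, **validation)

    # 7. enrich: consensus genes and per-parameter disease associations
    t = time.time()
    universe_genes = sorted(
        {g for payload in study.anno_sets.values() for g in payload[0]}
    )
    query = sorted(set(consensus["gene"]) & set(universe_genes)) if len(consensus) else []
    enrichment = stats.term_enrichment(query, universe_genes, study.anno_sets,
                                       p_max=cfg.p_max) if query else pd.DataFrame()
    pd_table = (
        stats.parameter_disease(consensus, study.anno_sets, universe_genes, p_max=cfg.p_max)
        if len(consensus) else pd.DataFrame(columns=["parameter", "disease", "k", "p"])
    )
    if cfg.write_artifacts:
        if len(enrichment):
            mio.write_table(enrichment, outdir / "enrichment.tsv", index=False)
        mio.write_table(pd_table, outdir / "parameter_disease.tsv", index=False)
    record("enrich", t, n_enriched_terms=int(enrichment["significant"].sum())
           if len(enrichment) else 0, n_parameter_disease=len(pd_table))

    manifest["total_seconds"] = round(time.time() - t0, 3)
    manifest["software_version"] = __import__("methylink").__version__
    if cfg.write_artifacts:
        for stage in manifest["stages"]:
            stage.setdefault("input_hashes", {})
        mio.write_json(manifest, outdir / "manifest.json")
    return RunResult(
        manifest=manifest, study=study, biclusters=biclusters, consensus=consensus,
        validation=validation, enrichment=enrichment, parameter_disease=pd_table,
    )
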