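"""End-to-end orchestration: simulate/load -> preprocess -> differential
testing -> marker metrics -> classification -> overlap -> clustering.

`run_pipeline` executes the stages in the order a cohort analysis runs
them and writes every stage's table plus one machine-readable
``summary.json``.  A single global seed governs all stochastic stages;
per-stage sub-seeds are derived with a counter-based scheme, so adding a
stage never shifts another stage's random stream.  The same config
therefore produces a byte-identical summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from ._util import child_seed
from .classify import (CVConfig, _positive_label, cross_validate,
                       permutation_control)
from .cluster import cut_and_test, hierarchical_cluster
from .datatypes import ExpressionMatrix, SampleAnnotation
from .differential import build_venn, run_comparison
from .metrics import marker_info
from .overlap import permutation_overlap_test
from .preprocess import correct_background, summarize_replicates, vsn_normalize
from .synthetic import CohortConfig, simulate_cohort

log = logging.getLogger("mirdiag")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Input is either a probe-level TSV plus annotation TSV, an
    already-normalized matrix TSV plus annotation TSV, or (default) a
    simulated cohort per ``cohort``.
    """

    out_dir: str = "mirdiag_out"
    seed: int = 0
    probe_tsv: str | None = None
    matrix_tsv: str | None = None
    annotation_tsv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    background_quantile: float = 0.05
    alpha: float = 0.05
    adjusted: bool = True
    cv: CVConfig = field(default_factory=CVConfig)
    run_classification: bool = True
    run_permutation_control: bool = False
    run_clustering: bool = True
    n_overlap_permutations: int = 100_000
    n_top_markers: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "cv" in raw:
            cv = raw["cv"]
            if "subset_sizes" in cv:
                cv["subset_sizes"] = tuple(cv["subset_sizes"])
            raw["cv"] = CVConfig(**cv)
        return cls(**raw)


def _load_or_simulate(config: PipelineConfig):
    if config.matrix_tsv:
        matrix = mio.read_expression_tsv(config.matrix_tsv)
        annotation = mio.read_annotation_tsv(config.annotation_tsv)
        return matrix, annotation, None
    if config.probe_tsv:
        probes = mio.read_probe_tsv(config.probe_tsv)
        annotation = mio.read_annotation_tsv(config.annotation_tsv)
    else:
        cohort = config.cohort
        cohort.seed = int(child_seed(config.seed,
                                     "pipeline_simulate").generate_state(1)[0]
                          % 2**31)
        log.info("simulating cohort: classes=%s seed=%d",
                 cohort.class_sizes, cohort.seed)
        probes, annotation, _ = simulate_cohort(cohort)
    corrected = correct_background(probes, config.background_quantile)
    summarized = summarize_replicates(corrected)
    matrix, fit = vsn_normalize(summarized)
    log.info("normalized %d samples x %d miRNAs (reference array %s)",
             len(matrix.sample_ids), len(matrix.mirna_ids), fit.reference)
    return matrix, annotation, fit


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary dict (also written
    to ``<out_dir>/summary.json``)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d out=%s", config.seed, out)

    matrix, annotation, _ = _load_or_simulate(config)
    mio.write_expression_tsv(matrix, out / "normalized_matrix.tsv")

    classes = sorted(set(annotation.classes_for(matrix.sample_ids)))
    summary: dict = {"seed": config.seed, "alpha": config.alpha,
                     "classes": classes,
                     "n_samples": len(matrix.sample_ids),
                     "n_mirnas": len(matrix.mirna_ids),
                     "comparisons": {}}

    # --- differential testing + single-marker metrics --------------------
    sig_sets: dict[str, set[str]] = {}
    for a, b in combinations(classes, 2):
        name = f"{a}_vs_{b}"
        result = run_comparison(matrix, annotation, a, b,
                                alpha=config.alpha, adjusted=config.adjusted)
        result.table.to_csv(out / f"markers_{name}.tsv", sep="\t")
        sig_sets[name] = result.significant_set
        log.info("%s: %d significant miRNAs", name, result.n_significant)

        top = result.table.nsmallest(config.n_top_markers, "adjusted_p")
        samples = [s for s in matrix.sample_ids
                   if annotation.classes_for([s]).iloc[0] in (a, b)]
        labels = annotation.classes_for(samples).to_numpy()
        sub = matrix.data.loc[samples]
        pos = _positive_label(np.unique(labels))
        infos = [marker_info(m, sub[m].to_numpy(), labels, pos)
                 for m in top.index]
        pd.DataFrame([vars(i) for i in infos]).to_csv(
            out / f"marker_info_{name}.tsv", sep="\t", index=False)

        summary["comparisons"][name] = {
            "n_significant": result.n_significant,
            "positive_label": str(pos),
        }

        # --- classification ---------------------------------------------
        if config.run_classification:
            cv = CVConfig(**{**vars(config.cv),
                             "seed": int(child_seed(config.seed,
                                                    f"cv_{name}")
                                         .generate_state(1)[0] % 2**31)})
            evaluation = cross_validate(sub, labels, cv, positive_label=pos)
            evaluation.to_json(out / f"cv_{name}.json")
            summary["comparisons"][name]["cv"] = evaluation.aggregate
            summary["comparisons"][name]["cv_mode"] = evaluation.mode
            if config.run_permutation_control:
                control = permutation_control(sub, labels, cv,
                                              positive_label=pos)
                control.to_json(out / f"cv_permuted_{name}.json")
                summary["comparisons"][name]["cv_permuted"] = \
                    control.aggregate
                summary["comparisons"][name]["cv_permuted_mode"] = \
                    control.mode

        # --- clustering check --------------------------------------------
        if config.run_clustering:
            sub_matrix = ExpressionMatrix(sub, stage=matrix.stage)
            dendro = hierarchical_cluster(sub_matrix)
            (out / f"dendrogram_{name}.nwk").write_text(
                dendro.to_newick() + "\n")
            cut_table = cut_and_test(dendro, labels, n_clusters=[2, 3, 4])
            cut_table.to_csv(out / f"cluster_cuts_{name}.tsv", sep="\t",
                             index=False)
            if len(cut_table):
                summary["comparisons"][name]["min_cluster_fisher_p"] = \
                    float(cut_table["fisher_p"].min())

    # --- Venn overlap significance ---------------------------------------
    if len(sig_sets) >= 2:
        names = list(sig_sets)[:3]
        venn = build_venn({n: sig_sets[n] for n in names})
        (out / "venn.json").write_text(
            json.dumps({k: sorted(v) for k, v in venn.regions.items()},
                       indent=1, sort_keys=True))
        summary["venn_region_sizes"] = venn.region_sizes
        nonempty = [n for n in names if sig_sets[n]]
        if len(nonempty) >= 2:
            test = permutation_overlap_test(
                sets={n: sig_sets[n] for n in nonempty[:3]},
                universe=len(matrix.mirna_ids),
                n_permutations=config.n_overlap_permutations,
                seed=int(child_seed(config.seed, "overlap")
                         .generate_state(1)[0] % 2**31))
            summary["overlap_test"] = test.to_dict()

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline done: %s", out / "summary.json")
    return summary
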