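"""Umbrella pipeline: simulate -> (barcode-call) -> score -> states -> growth
-> cohort similarity, with a reproducibility manifest.

Every stage writes plain delimited text into the artifact directory; the
manifest records the package version, seed, and a config hash so two runs
with the same config and seed are byte-comparable.
"""

from __future__ import annotations

import json
import platform
import zlib
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from signalome import cohort as cohort_mod
from signalome import growth as growth_mod
from signalome import scoring, states
from signalome.io import PipelineConfig, write_cell_table, write_score_matrix
from signalome.simulate import (
    generate_cohort_proteomes,
    generate_growth_timecourse,
    generate_screen,
    three_group_design,
)


def _pkg_version() -> str:
    try:
        return version("signalome")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the enabled stages and return the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version(),
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "outputs": [],
    }

    design = three_group_design(
        n_drugs=config.n_drugs,
        seed=config.seed,
        cells_per_well=config.cells_per_well,
    )
    cells, truth = generate_screen(design)
    if config.run_screen:
        write_cell_table(cells.sample(frac=0.01, random_state=config.seed), out / "cells_sample.csv")
        truth.platemap.to_csv(out / "platemap.csv", index=False)
        manifest["outputs"] += ["cells_sample.csv", "platemap.csv"]

    matrix = scoring.score_screen(cells, design.modes, min_cells=config.min_cells)
    write_score_matrix(matrix, out / "scores.csv")
    manifest["outputs"].append("scores.csv")
    null = scoring.dmso_null_scores(cells, design.modes, min_cells=config.min_cells)
    threshold = (
        scoring.derive_threshold(null) if null.size >= 20 else config.score_threshold
    )
    active = sorted(scoring.active_drugs(matrix, threshold))
    summary = {
        "threshold": threshold,
        "n_active": len(active),
        "fraction_active": len(active) / max(len(design.drugs), 1),
    }

    if config.run_states:
        final_t = max(matrix.timepoints)
        slice48 = matrix.slice(final_t).loc[lambda f: f.index.isin(active)]
        clusters = states.cluster_drugs(slice48, k=3)
        system, coords = states.fit_pca(slice48, orient_axis=None)
        clusters.labels.to_frame().to_csv(out / "clusters.csv")
        pd.DataFrame(
            system.loadings,
            index=list(system.pathways),
            columns=[f"PC{i+1}" for i in range(system.loadings.shape[1])],
        ).to_csv(out / "loadings.csv")
        coords.to_csv(out / "drug_metrics.csv")
        manifest["outputs"] += ["clusters.csv", "loadings.csv", "drug_metrics.csv"]
        summary["pc1_explained_fraction"] = float(system.explained_fraction[0])

    if config.run_growth:
        rows = []
        control = growth_mod.fit_condition(
            generate_growth_timecourse(
                truth.control_gamma,
                np.log(2) / truth.control_alpha,
                times=truth.timepoints,
                noise_cv=0.05,
                seed=config.seed,
            )
        )
        for drug, row in truth.drug_table.iterrows():
            tc = generate_growth_timecourse(
                row["gamma_rel"] * truth.control_gamma,
                np.log(2) / (row["alpha_rel"] * truth.control_alpha),
                times=truth.timepoints,
                noise_cv=0.05,
                seed=config.seed + zlib.crc32(str(drug).encode()) % 10_000,
            )
            est = growth_mod.fit_condition(tc)
            g, a, imb = growth_mod.normalize_to_control(est, control)
            rows.append(
                {"drug": drug, "gamma_rel": g, "alpha_rel": a, "imbalance": imb}
            )
        pd.DataFrame(rows).to_csv(out / "growth.csv", index=False)
        manifest["outputs"].append("growth.csv")

    if config.run_cohorts:
        final_t = max(matrix.timepoints)
        ref = states.pathway_correlations(matrix.slice(final_t))
        ref8 = ref.iloc[:8, :8]
        cohorts = generate_cohort_proteomes(
            ref8.to_numpy(),
            n_samples=config.cohort_n_samples,
            n_cohorts=config.n_cohorts,
            seed=config.seed,
            proteins=tuple(ref8.columns),
        )
        sims = []
        for c in cohorts:
            corr = cohort_mod.cohort_correlations(c, min_n=config.min_cohort_n)
            if corr is None:
                continue
            score = cohort_mod.similarity_to_reference(
                corr, ref8, cohort=c.attrs["cohort"]
            )
            sims.append({"cohort": score.cohort, "similarity": score.overall})
        pd.DataFrame(sims).to_csv(out / "cohort_similarity.csv", index=False)
        manifest["outputs"].append("cohort_similarity.csv")

    manifest["summary"] = summary
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
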