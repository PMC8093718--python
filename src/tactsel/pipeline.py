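"""End-to-end orchestration: simulate -> parentage -> morphometrics ->
selection, with a structured JSON report and CSV side tables.

Each stage can run independently from files, or the whole chain can replay
a synthetic study from a single seed.  Every stochastic operation records
its seed in the report so a run is reproducible from the report header.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import morphometrics as mm
from . import parentage as par
from . import selection as sel
from .config import RunConfig, SimulationConfig, default_config
from .datatypes import GenotypeTable, LandmarkSet, write_tps
from .synthetic import simulate_study

logger = logging.getLogger("tactsel")

__all__ = ["run_pipeline", "parentage_stage", "morpho_stage", "selection_stage"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "Infinity" if f > 0 else "-Infinity"
        return f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def parentage_stage(
    genotypes: GenotypeTable, config: RunConfig, run_qc: bool = True
) -> dict:
    """Locus QC, delta-threshold simulation, dam-mismatch filtering,
    assignment, and absolute fitness."""
    report: dict = {"seed": config.seed}
    adults = genotypes.subset(
        np.array([r != "offspring" for r in genotypes.roles])
    )
    freqs = par.allele_frequencies(adults)
    if run_qc:
        qc = par.locus_qc(
            genotypes,
            hwe_params=(
                config.hwe_dememorization,
                config.hwe_batches,
                config.hwe_iter_per_batch,
            ),
            ld_permutations=config.ld_permutations,
            seed=config.seed,
        )
        report["locus_qc"] = qc
    males = genotypes.by_role("sire")
    n_cand = config.n_candidates or len(males)
    sim = par.confidence_simulation(
        freqs,
        n_offspring=config.sim_offspring,
        n_candidates=n_cand,
        prop_sampled=config.prop_sampled,
        prop_typed=config.prop_typed,
        error_rate=config.error_rate,
        levels=(config.strict_level, config.relaxed_level),
        seed=config.seed + 7,
    )
    logger.info("confidence simulation: %s", sim["thresholds"])
    report["confidence_simulation"] = sim
    filtered, dropped = par.filter_dam_mismatches(
        genotypes, config.max_dam_mismatch_loci
    )
    report["dam_mismatch_dropped"] = dropped
    assignments = par.assign_paternity(
        filtered,
        freqs,
        error_rate=config.error_rate,
        strict_delta=sim["thresholds"][config.strict_level],
        relaxed_delta=sim["thresholds"][config.relaxed_level],
        min_typed_loci=config.min_typed_loci,
    )
    fitness = par.fitness_from_assignments(assignments, males.ids)
    n_assigned = sum(a.sire_id is not None for a in assignments)
    report["assignment_summary"] = {
        "n_offspring_input": sum(r == "offspring" for r in genotypes.roles),
        "n_after_dam_filter": sum(r == "offspring" for r in filtered.roles),
        "n_assigned": n_assigned,
        "n_unassigned": len(assignments) - n_assigned,
        "n_sires_with_offspring": int((fitness["n_offspring"] > 0).sum()),
    }
    report["_assignments"] = assignments
    report["_fitness"] = fitness
    return report


def morpho_stage(
    landmarks: LandmarkSet,
    config: RunConfig,
    traits: pd.DataFrame | None = None,
) -> dict:
    """GPA + sliding + tangent projection + covariance PCA; dimorphism
    statistics when a trait table with tactic labels is supplied."""
    report: dict = {}
    if landmarks.missing.any():
        landmarks = mm.estimate_missing(landmarks)
        report["missing_landmarks_estimated"] = True
    aligned = mm.gpa(landmarks)
    aligned = mm.slide_semilandmarks(aligned)
    tangent = mm.tangent_project(aligned)
    pca = mm.shape_pca(tangent, retain_threshold=config.retain_threshold)
    n_ret = int(pca.retained.sum())
    report["pca"] = {
        "proportions": pca.proportions[: max(n_ret + 2, 5)],
        "n_retained": n_ret,
    }
    shape_df = pd.DataFrame({"id": aligned.ids})
    shape_df["centroid_size"] = aligned.centroid_sizes
    for j in range(n_ret):
        shape_df[f"PC{j + 1}"] = pca.scores[:, j]
    report["_shape_traits"] = shape_df
    report["_pca"] = pca
    report["_aligned"] = aligned

    if traits is not None and "tactic" in traits.columns:
        merged = traits.merge(shape_df, on="id", how="inner", validate="1:1")
        tests = {}
        for col in (
            "standard_length", "body_depth", "sword_length", "sword_index",
            "centroid_size", *[f"PC{j + 1}" for j in range(n_ret)],
        ):
            if col == "sword_index" and col not in merged:
                merged["sword_index"] = mm.sword_index(
                    merged["sword_length"].to_numpy(),
                    merged["standard_length"].to_numpy(),
                )
            if col not in merged:
                continue
            vals = merged[col].to_numpy(dtype=float)
            if col in ("standard_length", "body_depth", "sword_length",
                       "sword_index"):
                vals = np.log(vals + 1e-9)  # log-transform linear measures
            t, df_, p = mm.dimorphism_welch(vals, merged["tactic"].to_numpy())
            tests[col] = {"t": t, "df": df_, "p": p}
        report["dimorphism_welch"] = tests
        if "sword_extension" in merged.columns:
            tab = pd.crosstab(merged["tactic"], merged["sword_extension"])
            if tab.shape == (2, 2) and (tab.values.sum(0) > 0).all():
                try:
                    stat, p = mm.yates_chi_square(tab.values)
                    report["sword_extension_chi2"] = {"stat": stat, "p": p}
                except ValueError:
                    pass
        if n_ret >= 2:
            ellipses = {}
            for tactic, grp in merged.groupby("tactic"):
                c, semi, ang = mm.confidence_ellipse(
                    grp[["PC1", "PC2"]].to_numpy()
                )
                ellipses[tactic] = {
                    "center": c, "semi_axes": semi, "angle": ang
                }
            report["confidence_ellipses_pc12"] = ellipses
    return report


def selection_stage(
    traits: pd.DataFrame,
    config: RunConfig,
    trait_cols: list[str],
    label: str,
) -> dict:
    """Differentials per trait, joint linear and quadratic gradients, and
    the conflict verdict for one trait set."""
    table = sel.prepare(traits, trait_cols=trait_cols)
    diffs = {}
    for j, t in enumerate(trait_cols):
        diffs[t] = sel.selection_differential(
            table, t,
            n_perm=config.n_perm, seed=config.seed + 11 * (j + 1),
            alpha=config.alpha, coding=config.art_coding,
            within_tactic_z=config.within_tactic_z,
            plus_one=config.plus_one_p, p_method=config.p_method,
        )
    lin = sel.linear_gradients(
        table, trait_cols, n_perm=config.n_perm, seed=config.seed + 503,
        alpha=config.alpha, coding=config.art_coding,
        within_tactic_z=config.within_tactic_z, plus_one=config.plus_one_p,
        p_method=config.p_method,
    )
    quad = sel.quadratic_gradients(
        table, trait_cols, n_perm=config.n_perm, seed=config.seed + 907,
        alpha=config.alpha, coding=config.art_coding,
        within_tactic_z=config.within_tactic_z, plus_one=config.plus_one_p,
        p_method=config.p_method,
    )
    verdict = sel.iatc_verdict(diffs, alpha=config.alpha)
    return {
        "label": label,
        "n_males": len(table),
        "mean_fitness": float(table["n_offspring"].mean()),
        "differentials": {
            t: {"terms": f.terms, "per_art": f.per_art} for t, f in diffs.items()
        },
        "linear_gradients": {"terms": lin.terms, "per_art": lin.per_art},
        "quadratic_gradients": {"terms": quad.terms, "per_art": quad.per_art},
        "iatc_verdict": verdict,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }


def run_pipeline(
    config: RunConfig,
    sim: SimulationConfig | None = None,
    out_dir: str | None = None,
    run_qc: bool = False,
) -> dict:
    """Full synthetic replay: simulate a study, assign paternity, extract
    shape traits, and run both selection analyses.

    ``run_qc=False`` skips the (slow) per-locus HWE chains; QC is a
    standalone stage via :func:`parentage_stage`.  Returns the report dict;
    writes report.json and CSV side tables when ``out_dir`` is given.
    """
    if sim is None:
        sim = default_config(seed=config.seed)
    traits, pedigree, genotypes, landmarks = simulate_study(sim)
    report: dict = {
        "config": config.to_dict(),
        "stages": ["simulate", "parentage", "morpho", "select"],
    }
    report["simulate"] = {
        "seed": sim.seed,
        "n_males": len(traits),
        "n_offspring": int(traits["n_offspring"].sum()),
        "per_tactic_mean_fitness": {
            t: float(g["n_offspring"].mean())
            for t, g in traits.groupby("tactic")
        },
    }

    p_rep = parentage_stage(genotypes, config, run_qc=run_qc)
    fitness = p_rep.pop("_fitness")
    assignments = p_rep.pop("_assignments")
    report["parentage"] = p_rep

    m_rep = morpho_stage(landmarks, config, traits=traits)
    shape_df = m_rep.pop("_shape_traits")
    m_rep.pop("_pca")
    m_rep.pop("_aligned")
    report["morpho"] = m_rep

    est_traits = traits.drop(columns=["n_offspring"]).merge(
        fitness, on="id", validate="1:1"
    )
    report["select_unidimensional"] = selection_stage(
        est_traits, config,
        ["standard_length", "body_depth", "sword_length"],
        label="unidimensional",
    )
    n_ret = int(m_rep["pca"]["n_retained"])
    geo = est_traits[["id", "tactic", "sword_length", "n_offspring"]].merge(
        shape_df, on="id", validate="1:1"
    )
    geo_cols = ["centroid_size"] + [f"PC{j + 1}" for j in range(n_ret)] + [
        "sword_length"
    ]
    report["select_geomorph"] = selection_stage(
        geo, config, geo_cols, label="geomorph"
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        traits.to_csv(os.path.join(out_dir, "traits.csv"), index=False)
        pedigree.links.to_csv(os.path.join(out_dir, "pedigree.csv"), index=False)
        genotypes.to_csv(os.path.join(out_dir, "genotypes.csv"))
        write_tps(os.path.join(out_dir, "landmarks.tps"), landmarks)
        fitness.to_csv(os.path.join(out_dir, "fitness.csv"), index=False)
        pd.DataFrame([asdict(a) for a in assignments]).to_csv(
            os.path.join(out_dir, "assignments.csv"), index=False
        )
        shape_df.to_csv(os.path.join(out_dir, "shape_traits.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
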