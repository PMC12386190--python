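"""End-to-end study orchestration.

``run_study`` drives the full analysis: landmarks and genotypes in
(from files or the synthetic generator), then measurements ->
morphometrics (GPA + PCA of the upper face) -> population genetics
(allele/haplotype frequencies, LD, haplotype copies) -> per-population
association models -> inverse-variance meta-analysis, writing one TSV
per published-table shape plus wireframe exports and a run log.  All
outputs are a pure function of (inputs, config, seed): numeric tables
are written only after every stage succeeds.

``meta_only`` combines an externally supplied per-population results
table (columns outcome, term, population, B, SE), which is how the
published per-population coefficients are pooled without subject-level
data.
"""
from __future__ import annotations

import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import association, geometry, io, meta, morphometrics, popgen
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)

NASAL_VARS = list(geometry.NASAL_ROOT_VARS)
SNPS = ("rs9288572", "rs7559271")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class StudyConfig(BaseModel):
    """Inputs, model list and inference settings for one study run."""

    simulate: SimulationConfig | None = None
    landmark_csv: str | None = None      # long-format landmark table
    genotype_csv: str | None = None
    models: list[str] = Field(
        default_factory=lambda: ["single_snp", "multi_snp", "haplotype", "pc_scores"]
    )
    followup_variables: list[str] = Field(default_factory=lambda: ["md-n-g", "s-n-g"])
    n_pcs: int = 5
    wireframe_pcs: list[int] = Field(default_factory=lambda: [4])  # 0-based; PC5
    alpha: float = 0.05
    n_tests: int = 16
    seed: int = 0
    out_dir: str | None = None


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return decorator


@_stage("inputs")
def _load_inputs(cfg: StudyConfig):
    if cfg.simulate is not None:
        cohort = simulate_cohort(cfg.simulate, seed=cfg.seed)
        return cohort.measurements(), cohort.genotypes, cohort.landmark_sets()
    if cfg.landmark_csv is None or cfg.genotype_csv is None:
        raise ValueError("need either a simulate config or landmark_csv + genotype_csv")
    genotypes = io.read_genotype_csv(cfg.genotype_csv)
    metadata = genotypes.set_index("subject")[["population", "sex"]]
    sets = io.load_landmark_table(cfg.landmark_csv, metadata=metadata)
    known = {lm.subject_id for lm in sets}
    missing = set(genotypes["subject"]) - known
    if missing:
        raise ValueError(f"subjects without landmarks: {sorted(missing)[:5]} ...")
    records = [geometry.compute_measurement_record(geometry.standardize_orientation(lm))
               for lm in sets]
    table = pd.DataFrame(
        [{"subject": r.subject_id, "population": r.population, "sex": r.sex, **r.values}
         for r in records]
    )
    order = genotypes["subject"].tolist()
    table = table.set_index("subject").loc[order].reset_index()
    return table, genotypes, sets


@_stage("popgen")
def _popgen_tables(genotypes: pd.DataFrame):
    freq_rows, phased = [], {}
    for pop, group in genotypes.groupby("population", sort=False):
        h = popgen.em_phase_two_loci(group["rs9288572"], group["rs7559271"])
        ld = popgen.ld_coefficients(h)
        phased[pop] = h
        freq_rows.append({
            "population": pop,
            "n": len(group),
            "daf_rs9288572": popgen.derived_allele_frequency(group["rs9288572"]),
            "daf_rs7559271": popgen.derived_allele_frequency(group["rs7559271"]),
            **{h_name: h[h_name] for h_name in popgen.HAPLOTYPES},
            "D": ld.D, "D_prime": ld.D_prime, "r_squared": ld.r_squared,
        })
    return pd.DataFrame(freq_rows), phased


@_stage("association")
def _association_tables(measurements: pd.DataFrame, genotypes: pd.DataFrame,
                        phased: dict, cfg: StudyConfig):
    merged = measurements.merge(
        genotypes[["subject", "rs9288572", "rs7559271"]], on="subject"
    )
    single_rows, multi_rows, hap_rows = [], [], []
    for pop, group in merged.groupby("population", sort=False):
        if "single_snp" in cfg.models:
            for snp in SNPS:
                for var in NASAL_VARS:
                    r = association.fit_single_snp_model(group[var], group[snp], group["sex"])
                    single_rows.append({"population": pop, "term": snp, "outcome": var,
                                        "B": r.B, "SE": r.SE, "p": r.p, "n": r.n})
        if "multi_snp" in cfg.models:
            for var in cfg.followup_variables:
                for r in association.fit_multi_snp_model(
                    group[var], group["rs9288572"], group["rs7559271"], group["sex"]
                ):
                    term = {"count1": "rs9288572", "count2": "rs7559271",
                            "interaction": "interaction"}[r.term]
                    multi_rows.append({"population": pop, "term": term, "outcome": var,
                                       "B": r.B, "SE": r.SE, "p": r.p, "n": r.n})
        if "haplotype" in cfg.models:
            copies = popgen.haplotype_copy_table(
                group.set_index("subject"), phased[pop]
            )
            sub = group.set_index("subject").loc[copies.index]
            for var in cfg.followup_variables:
                for r in association.fit_haplotype_model(sub[var], copies, sub["sex"]):
                    hap_rows.append({"population": pop, "term": r.term, "outcome": var,
                                     "B": r.B, "SE": r.SE, "p": r.p, "n": r.n})
    return (pd.DataFrame(single_rows), pd.DataFrame(multi_rows), pd.DataFrame(hap_rows))


@_stage("morphometrics")
def _shape_tables(landmark_sets, measurements, genotypes, cfg: StudyConfig):
    configs = [morphometrics.Configuration.from_landmarks(lm) for lm in landmark_sets]
    gpa = morphometrics.generalized_procrustes_align(configs)
    model = morphometrics.principal_components(gpa, n_pcs=cfg.n_pcs)
    scores = pd.DataFrame(
        model.scores,
        index=pd.Index(model.subject_ids, name="subject"),
        columns=[f"PC{i + 1}" for i in range(model.scores.shape[1])],
    )
    merged = scores.reset_index().merge(genotypes, on="subject")
    rows = []
    for pop, group in merged.groupby("population", sort=False):
        for snp in SNPS:
            for pc in scores.columns:
                r = association.fit_single_snp_model(group[pc], group[snp], group["sex"])
                rows.append({"population": pop, "term": snp, "outcome": pc,
                             "B": r.B, "SE": r.SE, "p": r.p, "n": r.n})
    wireframes = {
        k: morphometrics.wireframe_deviation(model, k, 3.0)
        for k in cfg.wireframe_pcs if k < len(model.components)
    }
    return scores, pd.DataFrame(rows), wireframes, model


@_stage("population_comparison")
def _population_comparison(measurements: pd.DataFrame):
    rows = []
    for sex in ("male", "female"):
        for var in geometry.ALL_VARS:
            res = association.compare_populations(measurements, var, sex=sex)
            row = {"sex": sex, "variable": var, "test": res.omnibus_test,
                   "omnibus_p": res.omnibus_p, "path": res.path_note}
            for label, summ in res.groups.items():
                row[f"{label}_mean"] = summ["mean"]
                row[f"{label}_sd"] = summ["sd"]
            for (a, b), p in res.pairwise.items():
                row[f"{a}_vs_{b}_p"] = p
            rows.append(row)
    return pd.DataFrame(rows)


def meta_only(per_population: pd.DataFrame, method: str = "fixed") -> pd.DataFrame:
    """Combined columns for an externally supplied per-population table."""
    return meta.combine_table(per_population, by=("outcome", "term"), method=method)


def _format(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col in ("B", "SE", "z", "Q", "I2") or col.endswith(("_mean", "_sd")):
            out[col] = out[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
        elif col == "p" or col.endswith("_p") or col == "omnibus_p":
            out[col] = out[col].map(lambda v: f"{v:.1e}" if pd.notna(v) else "")
    return out


def run_study(cfg: StudyConfig) -> dict:
    """Execute the full pipeline; returns the results bundle.

    When ``cfg.out_dir`` is set, writes measurements.tsv,
    frequencies_ld.tsv, single_snp.tsv, multi_snp.tsv,
    haplotype_model.tsv, pc_assoc.tsv, population_comparison.tsv,
    wireframe_pc{k}.csv and run.log, only after all stages succeed.
    """
    measurements, genotypes, landmark_sets = _load_inputs(cfg)
    freq_table, phased = _popgen_tables(genotypes)
    single, multi, hap = _association_tables(measurements, genotypes, phased, cfg)
    log_lines = [
        f"craniogen {_pkg_version('craniogen')}",
        f"seed {cfg.seed}",
        f"subjects {len(genotypes)} in {genotypes['population'].nunique()} population(s)",
        f"models {cfg.models}",
        f"Bonferroni threshold alpha/n_tests = "
        f"{association.bonferroni_threshold(cfg.alpha, cfg.n_tests):.6g} "
        f"({cfg.alpha}/{cfg.n_tests})",
    ]
    results: dict = {
        "measurements": measurements,
        "frequencies_ld": freq_table,
        "phased": phased,
    }
    for name, frame in (("single_snp", single), ("multi_snp", multi),
                        ("haplotype_model", hap)):
        if frame.empty:
            continue
        combined = meta.combine_table(frame, by=("outcome", "term"))
        combined.insert(0, "population", "Combined")
        results[name] = pd.concat([frame, combined], ignore_index=True)

    wireframes = {}
    if "pc_scores" in cfg.models and landmark_sets:
        scores, pc_assoc, wireframes, pc_model = _shape_tables(
            landmark_sets, measurements, genotypes, cfg
        )
        combined = meta.combine_table(pc_assoc, by=("outcome", "term"))
        combined.insert(0, "population", "Combined")
        results["pc_scores"] = scores
        results["pc_assoc"] = pd.concat([pc_assoc, combined], ignore_index=True)
        results["pc_model"] = pc_model
        log_lines.append(
            "PCA cumulative variance (retained PCs): "
            f"{100 * pc_model.variance_fraction.sum():.1f}%"
        )
    results["population_comparison"] = _population_comparison(measurements)
    for _, row in results["population_comparison"].iterrows():
        log_lines.append(f"comparison {row['variable']} [{row['sex']}]: {row['path']}")

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_measurement_tsv(
            measurements.set_index("subject"), out / "measurements.tsv"
        )
        _format(freq_table).to_csv(out / "frequencies_ld.tsv", sep="\t", index=False)
        for name in ("single_snp", "multi_snp", "haplotype_model", "pc_assoc"):
            if name in results:
                _format(results[name]).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        _format(results["population_comparison"]).to_csv(
            out / "population_comparison.tsv", sep="\t", index=False
        )
        for k, wf in wireframes.items():
            morphometrics.write_wireframe_csv(
                wf, out / f"wireframe_pc{k + 1}.csv", out / f"wireframe_pc{k + 1}_edges.csv"
            )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results["log"] = log_lines
    return results
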