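"""End-to-end orchestration: simulate -> preprocess -> univariate ->
STATIS -> PLS-DA -> phenotype, with a hashed output manifest.

Every stage writes tidy CSVs into the run directory; the summary
records per-stage key statistics and a SHA-256 per output file so that
two runs with the same config and seed are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import CohortSpec, default_cohort_spec, generate_cohort, read_cohort
from .design import default_design
from .phenotype import selection_overlap, stability_under_treatment
from .plsda import fit_plsda, q2_loso, treated_labels
from .preprocess import preprocess
from .statis import fit_statis, metabolite_loadings, project_tables
from .univariate import (
    circadian_contrasts,
    count_deregulated,
    precheck_combination,
    run_treatment_anova,
)

log = logging.getLogger("dexmet")

ALL_STAGES = ("simulate", "preprocess", "univariate", "statis", "plsda", "phenotype")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    input_dir: Path | None = None        # read an existing cohort ...
    cohort_spec: CohortSpec | None = None  # ... or simulate one (default spec if both None)
    stages: tuple[str, ...] = ALL_STAGES
    q_threshold: float = 0.05
    stability_threshold: float = 0.6
    n_plsda_components: int = 2

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.input_dir is not None and self.cohort_spec is not None:
            raise ValueError("give either input_dir or cohort_spec, not both")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        spec = None
        if "cohort" in cfg:
            spec_cfg = cfg.pop("cohort")
            spec = CohortSpec(**spec_cfg) if spec_cfg else None
            if spec is not None:
                spec.validate()
        kwargs = dict(
            outdir=Path(cfg.pop("outdir", "results")),
            seed=int(cfg.pop("seed", 0)),
            cohort_spec=spec,
        )
        if "input_dir" in cfg:
            kwargs["input_dir"] = Path(cfg.pop("input_dir"))
        if "stages" in cfg:
            kwargs["stages"] = tuple(cfg.pop("stages"))
        for key in ("q_threshold", "stability_threshold", "n_plsda_components"):
            if key in cfg:
                kwargs[key] = cfg.pop(key)
        if cfg:
            raise ValueError(f"unknown config keys: {sorted(cfg)}")
        return cls(**kwargs)


@dataclass
class RunSummary:
    stages: list[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        payload = {"stages": self.stages, "stats": self.stats, "manifest": self.manifest}
        path.write_text(json.dumps(payload, indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the configured stages in dependency order."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()
    design = default_design()

    def record(name: str, frame: pd.DataFrame, **to_csv_kwargs) -> Path:
        path = outdir / name
        frame.to_csv(path, **to_csv_kwargs)
        summary.manifest[name] = _sha256(path)
        return path

    t_start = time.time()
    # --- cohort -----------------------------------------------------------
    if config.input_dir is not None:
        mpm = read_cohort(config.input_dir)
        log.info("loaded cohort from %s", config.input_dir)
    else:
        spec = config.cohort_spec or default_cohort_spec(seed=config.seed)
        spec.seed = config.seed
        mpm = generate_cohort(spec)
        log.info("simulated cohort: %d samples x %d metabolites", *mpm.values.shape)
        if "simulate" in config.stages:
            for name, path in cohort_mod.write_cohort(mpm, outdir).items():
                summary.manifest[path.name] = _sha256(path)
            record("truth_table.csv", cohort_mod.truth_table(spec))
            summary.stages.append("simulate")

    study_meta = mpm.sample_meta[~mpm.sample_meta["is_pool_reference"]]
    summary.stats["cohort"] = {
        "n_subjects": int(study_meta["subject_id"].nunique()),
        "n_study_samples": int(study_meta.shape[0]),
        "n_pool_samples": int(mpm.sample_meta["is_pool_reference"].sum()),
        "n_metabolites": int(mpm.values.shape[1]),
    }

    needs_processing = set(config.stages) & {"preprocess", "univariate", "statis", "plsda"}
    proc = preprocess(mpm) if needs_processing else None
    if "preprocess" in config.stages:
        record("processed_log10.csv", proc.log_values, index_label="sample_id")
        record("processed_scaled.csv", proc.scaled_values, index_label="sample_id")
        proc.write_provenance(outdir / "provenance.json")
        summary.manifest["provenance.json"] = _sha256(outdir / "provenance.json")
        summary.stages.append("preprocess")

    if "univariate" in config.stages:
        t0 = time.time()
        results = run_treatment_anova(proc, design)
        record("univariate_treatment.csv", results, index=False)
        counts = count_deregulated(results, config.q_threshold)
        circ = circadian_contrasts(proc, design)
        record("univariate_circadian.csv", circ, index=False)
        pre_counts = {}
        for a, b in (("d1_midday", "d2_midday"), ("d1_evening", "d2_evening"),
                     ("d2_morning", "d3_morning")):
            count, expected = precheck_combination(proc, a, b)
            pre_counts[f"{a}_vs_{b}"] = count
        summary.stats["univariate"] = {
            "deregulated": counts,
            "precheck_counts": pre_counts,
            "precheck_expected": expected,
        }
        summary.stages.append("univariate")
        log.info("univariate stage done in %.1f s", time.time() - t0)

    if "statis" in config.stages:
        model = fit_statis(proc)
        record("statis_weights.csv", model.weights_frame())
        record("statis_scores.csv", model.scores_frame(n_axes=2))
        record("statis_trajectories.csv", project_tables(model, n_axes=2), index=False)
        record("statis_loadings.csv", metabolite_loadings(proc, model, n_axes=2))
        ev = pd.DataFrame(
            {
                "axis": [f"axis{a + 1}" for a in range(len(model.eigenvalues))],
                "eigenvalue": model.eigenvalues,
                "explained_variance": model.explained_variance,
            }
        )
        record("statis_explained_variance.csv", ev, index=False)
        summary.stats["statis"] = {
            "weight_min": float(model.weights.min()),
            "weight_max": float(model.weights.max()),
            "explained_variance_2": float(model.explained_variance[:2].sum()),
        }
        summary.stages.append("statis")

    if "plsda" in config.stages:
        X = proc.scaled_values.to_numpy()
        labels = treated_labels(proc.sample_meta)
        subj = proc.sample_meta["subject_id"].to_numpy()
        model = fit_plsda(X, labels, config.n_plsda_components)
        q2, q2_cum, info = q2_loso(X, labels, subj, config.n_plsda_components)
        model.q2_per_component, model.q2_cum = q2, q2_cum
        frame = pd.DataFrame(
            {
                "component": range(1, config.n_plsda_components + 1),
                "r2y": model.r2y,
                "q2": q2,
                "q2_cum": q2_cum,
                "q2_simple": info["q2_simple"],
            }
        )
        record("plsda_q2.csv", frame, index=False)
        scores = pd.DataFrame(
            model.scores,
            index=proc.scaled_values.index,
            columns=[f"component{a + 1}" for a in range(config.n_plsda_components)],
        )
        record("plsda_scores.csv", scores, index_label="sample_id")
        summary.stats["plsda"] = {
            "q2_cum": [float(v) for v in q2_cum],
            "r2y": [float(v) for v in model.r2y],
        }
        summary.stages.append("plsda")

    if "phenotype" in config.stages:
        report = stability_under_treatment(mpm, design, config.stability_threshold)
        record("phenotype_stability.csv", report)
        summary.stats["phenotype"] = selection_overlap(report)
        summary.stages.append("phenotype")

    summary.stats["runtime_s"] = round(time.time() - t_start, 2)
    summary.to_json(outdir / "run_summary.json")
    log.info("pipeline finished in %.1f s", summary.stats["runtime_s"])
    return summary
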