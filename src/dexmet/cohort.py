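"""Synthetic cohort generator for the glucocorticoid time-course design.

The generator emulates the statistical structure the downstream analysis
assumes: log10-additive metabolite abundances with a per-metabolite
baseline, a stable subject-specific offset (the "metabolic phenotype"
when large relative to noise), a monotone within-day circadian trend
applied identically on every day, a metabolite-specific multiplicative
treatment effect at each post-dose offset (+6/+18/+24/+30 h), and
pooled reference samples (per-metabolite mean of all study samples plus
small technical noise) for median normalization.

On the log10 scale the value of subject *i*, metabolite *j* at slot *t* is

    baseline_j + b_ij + circadian_j(daytime(t)) + treatment_j(t) + eps,

with b_ij ~ N(0, subject_sd_j) drawn once per (i, j) and
eps ~ N(0, noise_sd_j) per sample.  Effects are therefore multiplicative
on the linear scale, matching the ratio read-outs of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign, default_design

POST_DOSE_HOURS = (6.0, 18.0, 24.0, 30.0)

# Cohort demographics: mean +/- SD with plausibility truncation.
AGE_MEAN, AGE_SD, AGE_RANGE = 25.5, 2.9, (18.0, 40.0)
BMI_MEAN, BMI_SD, BMI_RANGE = 23.3, 2.7, (17.0, 35.0)


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic cohort.

    Per-metabolite parameters are 1-D arrays of length ``n_metabolites``;
    ``circadian_profile`` holds the signed log10 increments
    (morning->midday, midday->evening) per metabolite, and
    ``treatment_profile`` the log10 effect at each post-dose offset
    (+6, +18, +24, +30 h).  All untreated slots carry zero treatment
    effect by construction.
    """

    n_subjects: int = 20
    n_metabolites: int = 214
    design: StudyDesign = field(default_factory=default_design)
    baseline_log_mean: np.ndarray | None = None
    subject_sd: np.ndarray | None = None
    circadian_profile: np.ndarray | None = None  # (M, 2)
    treatment_profile: np.ndarray | None = None  # (M, 4)
    noise_sd: np.ndarray | None = None
    phenotype_set: frozenset[int] = frozenset()
    n_pool_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.n_metabolites
        if self.baseline_log_mean is None:
            self.baseline_log_mean = np.full(m, 1.5)
        if self.subject_sd is None:
            self.subject_sd = np.full(m, 0.15)
        if self.noise_sd is None:
            self.noise_sd = np.full(m, 0.1)
        if self.circadian_profile is None:
            self.circadian_profile = np.zeros((m, 2))
        if self.treatment_profile is None:
            self.treatment_profile = np.zeros((m, 4))
        for name in ("baseline_log_mean", "subject_sd", "noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(m, float(arr))
            setattr(self, name, arr)
        self.circadian_profile = np.asarray(self.circadian_profile, dtype=float)
        self.treatment_profile = np.asarray(self.treatment_profile, dtype=float)
        self.phenotype_set = frozenset(int(i) for i in self.phenotype_set)

    def validate(self) -> None:
        m = self.n_metabolites
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("baseline_log_mean", "subject_sd", "noise_sd"):
            arr = getattr(self, name)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have shape ({m},), got {arr.shape}")
        for name in ("subject_sd", "noise_sd"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if self.circadian_profile.shape != (m, 2):
            raise ValueError(
                f"circadian_profile must have shape ({m}, 2), "
                f"got {self.circadian_profile.shape}"
            )
        if self.treatment_profile.shape != (m, 4):
            raise ValueError(
                f"treatment_profile must have shape ({m}, 4), "
                f"got {self.treatment_profile.shape}"
            )
        if self.phenotype_set and (
            min(self.phenotype_set) < 0 or max(self.phenotype_set) >= m
        ):
            raise ValueError("phenotype_set indices out of metabolite range")
        if self.n_pool_replicates < 0:
            raise ValueError("n_pool_replicates must be >= 0")


@dataclass
class MetaboliteProfileMatrix:
    """Samples x metabolites abundance matrix with metadata.

    ``values`` is strictly positive on the linear scale; ``sample_meta``
    is indexed like ``values`` and carries subject id, slot, treatment
    status, pool flag and per-subject age/BMI; ``metabolite_meta`` is
    indexed by metabolite name.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def validate(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta indices differ")
        if not self.values.columns.equals(self.metabolite_meta.index):
            raise ValueError("values columns and metabolite_meta index differ")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("abundances must be strictly positive")
        study = self.sample_meta[~self.sample_meta["is_pool_reference"]]
        combos = study.groupby(["subject_id", "slot"], observed=True).size()
        if (combos != 1).any():
            raise ValueError("each (subject, slot) must occur exactly once")

    @property
    def study_samples(self) -> pd.DataFrame:
        """Non-pool rows of the value matrix."""
        mask = ~self.sample_meta["is_pool_reference"].to_numpy()
        return self.values.loc[mask]

    @property
    def pool_samples(self) -> pd.DataFrame:
        mask = self.sample_meta["is_pool_reference"].to_numpy()
        return self.values.loc[mask]


def _metabolite_names(m: int) -> list[str]:
    width = max(3, len(str(m)))
    return [f"metabolite_{i + 1:0{width}d}" for i in range(m)]


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The emulated study conditions.

    214 metabolites over 20 subjects: 78 metabolites rise and 25 fall
    monotonically within the day (about half the panel circadian, more
    up than down, including two steroid-like strong decreasers whose
    evening levels drop to 16% and 34% of morning levels); 150
    metabolites respond to the dose on at least one post-dose slot with
    9 responding on all four; 27 metabolites form the stable-phenotype
    subset with between-subject SD four times the residual noise.
    """
    rng = np.random.default_rng([seed, 101])
    m, spec = 214, None
    baseline = rng.normal(1.5, 0.7, size=m)
    noise_sd = np.full(m, 0.1)
    subject_sd = np.full(m, 0.15)

    order = rng.permutation(m)
    pheno_idx = order[:27]
    subject_sd[pheno_idx] = 0.4  # subject_sd/noise_sd = 4 -> stable ranking

    # Circadian: monotone within-day trends, identical on every day.
    circ = np.zeros((m, 2))
    circ_order = rng.permutation(m)
    up_idx, down_idx = circ_order[:78], circ_order[78 : 78 + 25]
    circ[up_idx] = rng.uniform(0.05, 0.25, size=(78, 2))
    circ[down_idx] = -rng.uniform(0.05, 0.25, size=(25, 2))
    # Two steroid-like metabolites: evening/morning ratios 0.16 and 0.34.
    circ[down_idx[0]] = np.log10(0.16) / 2
    circ[down_idx[1]] = np.log10(0.34) / 2

    # Treatment: 150 metabolites deregulated on >=1 post-dose slot, 9 on all 4.
    treat = np.zeros((m, 4))
    affected = rng.permutation(m)[:150]
    all_four, partial = affected[:9], affected[9:]
    signs = np.where(rng.random(150) < 0.6, 1.0, -1.0)
    mags = rng.uniform(0.1, 0.5, size=(150, 4))
    treat[all_four] = (signs[:9, None] * mags[:9])
    for row, met in enumerate(partial):
        k = rng.integers(1, 4)  # 1-3 affected slots
        slots = rng.choice(4, size=k, replace=False)
        treat[met, slots] = signs[9 + row] * mags[9 + row, slots]

    spec = CohortSpec(
        n_subjects=20,
        n_metabolites=m,
        baseline_log_mean=baseline,
        subject_sd=subject_sd,
        circadian_profile=circ,
        treatment_profile=treat,
        noise_sd=noise_sd,
        phenotype_set=frozenset(int(i) for i in pheno_idx),
        n_pool_replicates=10,
        seed=seed,
    )
    spec.validate()
    return spec


def _circadian_offset(spec: CohortSpec, daytime: str, j: slice | None = None) -> np.ndarray:
    """Cumulative log10 circadian offset relative to morning."""
    sel = slice(None) if j is None else j
    inc = spec.circadian_profile[sel]
    if daytime == "morning":
        return np.zeros(inc.shape[0])
    if daytime == "midday":
        return inc[:, 0]
    return inc[:, 0] + inc[:, 1]


def _treatment_offset(spec: CohortSpec, hours: float | None) -> np.ndarray:
    if hours is None:
        return np.zeros(spec.n_metabolites)
    try:
        col = POST_DOSE_HOURS.index(float(hours))
    except ValueError:
        raise ValueError(f"no treatment profile for offset {hours} h") from None
    return spec.treatment_profile[:, col]


def generate_cohort(spec: CohortSpec) -> MetaboliteProfileMatrix:
    """Draw one cohort; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 202])
    design = spec.design
    n, m = spec.n_subjects, spec.n_metabolites
    subjects = [f"subj{i + 1:02d}" for i in range(n)]
    met_names = _metabolite_names(m)

    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n), *AGE_RANGE)
    bmi = np.clip(rng.normal(BMI_MEAN, BMI_SD, size=n), *BMI_RANGE)
    b = rng.normal(0.0, 1.0, size=(n, m)) * spec.subject_sd[None, :]

    rows, meta_rows = [], []
    for i, subj in enumerate(subjects):
        for slot in design.slots:
            mu = (
                spec.baseline_log_mean
                + b[i]
                + _circadian_offset(spec, slot.daytime)
                + _treatment_offset(spec, slot.hours_post_dose)
            )
            eps = rng.normal(0.0, 1.0, size=m) * spec.noise_sd
            rows.append(10.0 ** (mu + eps))
            meta_rows.append(
                {
                    "sample_id": f"{subj}_{slot.label}",
                    "subject_id": subj,
                    "slot": slot.label,
                    "day": slot.day,
                    "daytime": slot.daytime,
                    "treated": slot.treated,
                    "hours_post_dose": slot.hours_post_dose,
                    "is_pool_reference": False,
                    "age": age[i],
                    "bmi": bmi[i],
                }
            )

    study = np.vstack(rows)
    pool_mean = study.mean(axis=0)
    for p in range(spec.n_pool_replicates):
        eps = rng.normal(0.0, 1.0, size=m) * (spec.noise_sd / 4.0)
        rows.append(pool_mean * 10.0**eps)
        meta_rows.append(
            {
                "sample_id": f"pool{p + 1:02d}",
                "subject_id": "pool",
                "slot": "pool",
                "day": 0,
                "daytime": "pool",
                "treated": False,
                "hours_post_dose": None,
                "is_pool_reference": True,
                "age": np.nan,
                "bmi": np.nan,
            }
        )

    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(
        np.vstack(rows), index=sample_meta.index, columns=met_names
    )
    met_meta = pd.DataFrame(index=pd.Index(met_names, name="metabolite"))
    met_meta["is_phenotype_truth"] = [
        j in spec.phenotype_set for j in range(m)
    ]
    circ_dir = np.sign(spec.circadian_profile.sum(axis=1)).astype(int)
    met_meta["circadian_direction"] = circ_dir
    met_meta["treated_any_slot"] = (spec.treatment_profile != 0).any(axis=1)

    mpm = MetaboliteProfileMatrix(values, sample_meta, met_meta)
    mpm.validate()
    return mpm


def truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Per-metabolite ground truth for recovery tests.

    True post-dose ratios are ``10 ** treatment_profile``; circadian
    direction is the sign of the summed within-day increments.
    """
    spec.validate()
    names = _metabolite_names(spec.n_metabolites)
    table = pd.DataFrame(index=pd.Index(names, name="metabolite"))
    for k, h in enumerate(POST_DOSE_HOURS):
        table[f"true_ratio_{int(h)}h"] = 10.0 ** spec.treatment_profile[:, k]
    table["circadian_direction"] = np.sign(
        spec.circadian_profile.sum(axis=1)
    ).astype(int)
    table["is_phenotype"] = [
        j in spec.phenotype_set for j in range(spec.n_metabolites)
    ]
    return table


# ---------------------------------------------------------------------------
# I/O: tidy long CSV, wide matrix CSV, sample metadata CSV, YAML config.
# ---------------------------------------------------------------------------

def write_cohort(mpm: MetaboliteProfileMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write wide-matrix, sample-metadata and tidy long-format CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "cohort_matrix.csv",
        "samples": outdir / "cohort_samples.csv",
        "long": outdir / "cohort_long.csv",
        "metabolites": outdir / "cohort_metabolites.csv",
    }
    mpm.values.to_csv(paths["matrix"], index_label="sample_id")
    mpm.sample_meta.to_csv(paths["samples"], index_label="sample_id")
    mpm.metabolite_meta.to_csv(paths["metabolites"])
    long = (
        mpm.values.reset_index(names="sample_id")
        .melt(id_vars="sample_id", var_name="metabolite", value_name="value")
        .merge(
            mpm.sample_meta[
                ["subject_id", "day", "daytime", "treated", "hours_post_dose"]
            ].reset_index(names="sample_id"),
            on="sample_id",
        )
    )
    long.to_csv(paths["long"], index=False)
    return paths


def read_cohort(indir: str | Path) -> MetaboliteProfileMatrix:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    values = pd.read_csv(indir / "cohort_matrix.csv", index_col="sample_id")
    sample_meta = pd.read_csv(indir / "cohort_samples.csv", index_col="sample_id")
    met_path = indir / "cohort_metabolites.csv"
    if met_path.exists():
        met_meta = pd.read_csv(met_path, index_col="metabolite")
    else:
        met_meta = pd.DataFrame(index=pd.Index(values.columns, name="metabolite"))
    sample_meta["is_pool_reference"] = sample_meta["is_pool_reference"].astype(bool)
    sample_meta["treated"] = sample_meta["treated"].astype(bool)
    mpm = MetaboliteProfileMatrix(values, sample_meta, met_meta)
    mpm.validate()
    return mpm


def spec_from_config(path: str | Path) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain-text ``key: value`` file.

    Any field may be given; scalar SDs broadcast over metabolites and
    omitted fields fall back to the zero-effect defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    known = {
        "n_subjects",
        "n_metabolites",
        "baseline_log_mean",
        "subject_sd",
        "circadian_profile",
        "treatment_profile",
        "noise_sd",
        "phenotype_set",
        "n_pool_replicates",
        "seed",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    if "phenotype_set" in cfg:
        cfg["phenotype_set"] = frozenset(cfg["phenotype_set"])
    for key in ("circadian_profile", "treatment_profile"):
        if key in cfg:
            cfg[key] = np.asarray(cfg[key], dtype=float)
    spec = CohortSpec(**cfg)
    spec.validate()
    return spec
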