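"""Pooled-reference normalization, log10 transform, and autoscaling.

Entry point of the statistical pipeline: abundances are divided by the
per-metabolite median of the pooled reference samples (removing
instrumental scale), log10-transformed (the analysis scale), and — for
the multivariate stages — centered and scaled to unit variance per
metabolite so no single high-variance metabolite dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .cohort import MetaboliteProfileMatrix


@dataclass
class ScalingParams:
    """Frozen per-metabolite center/scale so new samples can be projected."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, log_values: pd.DataFrame) -> pd.DataFrame:
        return (log_values - self.mean) / self.sd


@dataclass
class ProcessedMatrix:
    """Log10-scale matrix with optional autoscaled view and provenance."""

    log_values: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame
    scaled_values: pd.DataFrame | None = None
    scaling: ScalingParams | None = None
    provenance: list[str] = field(default_factory=list)

    @property
    def linear_values(self) -> pd.DataFrame:
        return 10.0**self.log_values

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"transforms": self.provenance}, indent=2))


def normalize_to_pool(raw: MetaboliteProfileMatrix) -> MetaboliteProfileMatrix:
    """Divide every study sample by the pool-median of its metabolite.

    Pool rows are consumed by the operation and dropped from the output.
    Invariant to any global rescaling of the run (the pools rescale too).
    """
    pool = raw.pool_samples
    if pool.empty:
        raise ValueError("no pool-reference samples present")
    medians = pool.median(axis=0)
    bad = medians.index[(medians <= 0) | medians.isna()].tolist()
    if bad:
        raise ValueError(f"non-positive pool median for metabolites: {bad}")
    study_mask = ~raw.sample_meta["is_pool_reference"].to_numpy()
    values = raw.values.loc[study_mask] / medians
    out = MetaboliteProfileMatrix(
        values=values,
        sample_meta=raw.sample_meta.loc[study_mask].copy(),
        metabolite_meta=raw.metabolite_meta.copy(),
    )
    out.validate()
    return out


def log10_transform(m: MetaboliteProfileMatrix) -> ProcessedMatrix:
    """Elementwise log10; fails loudly on non-positive values."""
    arr = m.values.to_numpy()
    if (arr <= 0).any():
        rows, cols = np.nonzero(arr <= 0)
        coords = [
            (m.values.index[r], m.values.columns[c])
            for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"non-positive values at (sample, metabolite): {coords}")
    return ProcessedMatrix(
        log_values=np.log10(m.values),
        sample_meta=m.sample_meta.copy(),
        metabolite_meta=m.metabolite_meta.copy(),
        provenance=["log10"],
    )


def autoscale(
    p: ProcessedMatrix, sample_subset: pd.Index | list[str] | None = None
) -> ProcessedMatrix:
    """Center and scale each metabolite to unit variance (SD with n-1).

    Parameters are estimated on ``sample_subset`` (default: all samples)
    and stored so held-out samples can be projected onto the same scale.
    """
    subset = p.log_values.index if sample_subset is None else pd.Index(sample_subset)
    train = p.log_values.loc[subset]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()].tolist()
    if bad:
        raise ValueError(f"zero variance over the scaling subset: {bad}")
    scaling = ScalingParams(mean=mean, sd=sd)
    return ProcessedMatrix(
        log_values=p.log_values,
        sample_meta=p.sample_meta,
        metabolite_meta=p.metabolite_meta,
        scaled_values=scaling.apply(p.log_values),
        scaling=scaling,
        provenance=[*p.provenance, "autoscale"],
    )


def preprocess(raw: MetaboliteProfileMatrix) -> ProcessedMatrix:
    """Convenience chain: pool-normalize, log10, autoscale on all samples."""
    normalized = normalize_to_pool(raw)
    processed = log10_transform(normalized)
    processed.provenance.insert(0, "normalize_to_pool")
    return autoscale(processed)
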