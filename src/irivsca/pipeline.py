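"""End-to-end orchestration: trim → IRIV → GF/FD/GFA + SCA → SPXY →
standardize → benchmark, with JSON-serializable results and a run manifest.

The stages are deliberately file-friendly: each produces a serializable
artifact so the expensive IRIV screen can be run once and the downstream
regimes/models swapped freely (see the CLI's staged subcommands).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import preprocess, sca
from .iriv import IrivConfig, IrivResult, run_iriv
from .models import MODEL_NAMES, benchmark, default_model_specs
from .partition import SplitResult, spxy_split
from .spectra_io import SpectrumSet, trim_edges


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run (CLI-facing)."""

    trim_low: float = 400.0
    trim_high: float = 2399.0
    iriv: IrivConfig = field(default_factory=IrivConfig)
    sigma: float = 1.0
    sca_threshold: float = 0.6
    n_cal: Optional[int] = None  # default: round(2/3 · n_samples)
    models: Sequence[str] = MODEL_NAMES
    seed: int = 0

    def __post_init__(self):
        bad = set(self.models) - set(MODEL_NAMES)
        if bad:
            raise PipelineError(f"unknown model name(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"trim_low", "trim_high", "iriv", "sigma", "sca_threshold",
                 "n_cal", "models", "seed"}
        bad = set(d) - known
        if bad:
            raise PipelineError(f"unknown config key(s): {sorted(bad)}")
        if "iriv" in d and isinstance(d["iriv"], dict):
            d["iriv"] = IrivConfig(**d["iriv"])
        elif "seed" in d and "iriv" not in d:
            d["iriv"] = IrivConfig(seed=d["seed"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


@dataclass(frozen=True)
class PipelineResult:
    trimmed: SpectrumSet
    iriv_result: IrivResult
    blocks: dict
    features: sca.FeatureSet
    split: SplitResult
    report: pd.DataFrame


def run_pipeline(ss: SpectrumSet, cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full characteristic-band selection and benchmark chain.

    Both feature regimes — the raw reflectance at the IRIV-selected bands
    ("IRIV") and the SCA-screened GF/FD/GFA features derived from them
    ("IRIV-SCA") — are benchmarked over the same SPXY split, which is
    computed on the raw retained-band reflectance (their common ancestor)
    before any scaling.
    """
    cfg = cfg or RunConfig()
    if ss.target is None:
        raise PipelineError("input SpectrumSet must carry a target")

    trimmed = trim_edges(ss, cfg.trim_low, cfg.trim_high)
    iriv_res = run_iriv(trimmed, cfg.iriv)

    retained = trimmed.select_bands(iriv_res.final_indices)
    if retained.n_bands < 2:
        raise PipelineError(
            f"IRIV retained only {retained.n_bands} band(s); the GF/FD/GFA cascade "
            "needs at least two"
        )
    blocks = preprocess.gfa_cascade(retained, cfg.sigma, full=trimmed)
    features = sca.select_features(blocks, trimmed.target, cfg.sca_threshold)
    if features.is_empty:
        raise PipelineError(
            f"no derived feature exceeded |spearman| > {cfg.sca_threshold}; "
            "lower the threshold or inspect the feature correlations"
        )

    n_cal = cfg.n_cal if cfg.n_cal is not None else int(round(2 / 3 * ss.n_samples))
    split = spxy_split(retained.reflectance, trimmed.target, n_cal)

    regimes = {"IRIV": retained.reflectance, "IRIV-SCA": features.values}
    report = benchmark(regimes, trimmed.target, split,
                       specs=default_model_specs(seed=cfg.seed, names=cfg.models))
    return PipelineResult(
        trimmed=trimmed,
        iriv_result=iriv_res,
        blocks=blocks,
        features=features,
        split=split,
        report=report,
    )


# ------------------------------------------------------------ serialization

def iriv_result_to_dict(res: IrivResult) -> dict:
    return {
        "rounds": [
            {
                "wavelengths": r.wavelengths.tolist(),
                "dmean": r.dmean.tolist(),
                "pvalues": r.pvalues.tolist(),
                "classes": list(r.classes),
                "retained_wavelengths": r.retained_wavelengths.tolist(),
            }
            for r in res.rounds
        ],
        "final_wavelengths": res.final_wavelengths.tolist(),
        "final_indices": res.final_indices.tolist(),
        "final_rmsecv": res.final_rmsecv,
        "eliminated_trace": [[int(i), float(v)] for i, v in res.eliminated_trace],
    }


def split_to_dict(split: SplitResult) -> dict:
    return {"calibration": split.calibration.tolist(),
            "validation": split.validation.tolist()}


def make_manifest(cfg: RunConfig, extra: dict | None = None) -> dict:
    """Run manifest: full config plus a hash for exact-rerun bookkeeping."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
    }
    if extra:
        manifest.update(extra)
    return manifest
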