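"""End-to-end analysis pipeline.

Chains the stages in the order of the underlying study design:
percentile exclusion of cyst-like glands, optional covariate correction,
control-fitted normative model, deviation scoring of everyone, extreme
tail fractions, pairwise rank comparisons (raw melatonin, PGV, and the
deviation scores) and the interaction regression; writes a scores CSV
and a machine-checkable JSON report. Stages are pure record-in /
record-out: no stage mutates its input table.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_phenotypes, write_phenotypes
from .normative import (
    NormativeMelatoninModel,
    as_frame,
    covariate_correction,
)
from .simulate import GroupParams, SimulationConfig, generate_cohort
from .smoothing import SmootherConfig
from .stats import apply_exclusions, fit_linear_model, mann_whitney

logger = logging.getLogger("pinealnorm")

GROUP_ORDER = ("ASD", "relative", "control")


@dataclass
class PipelineConfig:
    """Configuration of :func:`run_pipeline`.

    Exactly one of ``input_path`` / ``simulation`` must be set. The
    correction step runs only when ``correction_covariates`` is
    non-empty.
    """

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    smoother: SmootherConfig = field(default_factory=SmootherConfig)
    threshold: float = 2.0
    correction_covariates: tuple[str, ...] = ()
    correction_mode: str = "linear"
    regression_terms: dict | None = None
    exclusion_percentile: float = 99.0
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        """Build a config from a plain-text key-value (YAML) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            groups = sim.pop("groups", None)
            if groups is not None:
                sim["groups"] = {g: GroupParams(**p) for g, p in groups.items()}
            sim = SimulationConfig(**sim)
        smoother = SmootherConfig(**raw.pop("smoother", {}))
        cc = tuple(raw.pop("correction_covariates", ()))
        cfg = cls(simulation=sim, smoother=smoother, correction_covariates=cc, **raw)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _comparisons(frame: pd.DataFrame, column: str) -> dict:
    out = {}
    for ga, gb in combinations(GROUP_ORDER, 2):
        a = frame.loc[frame["group"] == ga, column].to_numpy(dtype=float)
        b = frame.loc[frame["group"] == gb, column].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        out[f"{ga}_vs_{gb}"] = mann_whitney(a, b, labels=(ga, gb)).to_dict()
    return out


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run the full analysis; returns the report dict.

    With ``write=True`` also writes ``scores.csv``, ``cohort.csv`` (when
    simulated) and ``report.json`` into ``config.output_dir``.
    """
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(
                groups=sim.groups, slope=sim.slope, deficit_mode=sim.deficit_mode,
                n_outliers=sim.n_outliers, outlier_factor=sim.outlier_factor,
                seed=config.seed,
            )
        cohort = generate_cohort(sim)
        source = f"simulated(seed={sim.seed})"
    else:
        cohort = read_phenotypes(config.input_path)
        source = str(config.input_path)
    logger.info("pipeline input: %s (%d records)", source, len(cohort))

    stage = "exclusion"
    try:
        excl = apply_exclusions(cohort, percentile=config.exclusion_percentile)
        kept = excl["kept"]

        analysed = kept
        if config.correction_covariates:
            stage = "covariate_correction"
            analysed = covariate_correction(
                kept, config.correction_covariates, mode=config.correction_mode,
                config=config.smoother,
            )

        stage = "normative_fit"
        results = NormativeMelatoninModel(
            analysed, config=config.smoother, threshold=config.threshold
        ).fit()

        stage = "scoring"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores = results.score_frame()
        fractions = results.extreme_fractions(scores)

        stage = "group_comparisons"
        with_z = analysed.merge(scores[["id", "z"]], on="id")
        comparisons = {
            "melatonin_nM": _comparisons(analysed, "melatonin_nM"),
            "pgv_mm3": _comparisons(analysed, "pgv_mm3"),
            "z": _comparisons(with_z, "z"),
        }

        stage = "regression"
        reg = fit_linear_model(analysed, terms=config.regression_terms)
        anova = {
            term: {"F": float(row["F"]), "p": float(row["PR(>F)"])}
            for term, row in reg.anova.iterrows()
            if np.isfinite(row.get("F", np.nan))
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    groups_report = {}
    for g in GROUP_ORDER:
        if g in fractions.index:
            row = fractions.loc[g]
            groups_report[g] = {
                "n": int(row["n"]),
                "pct_low": float(row["pct_low"]),
                "pct_high": float(row["pct_high"]),
            }
        else:
            groups_report[g] = {"n": 0, "pct_low": None, "pct_high": None}

    report = {
        "pinealnorm_version": __version__,
        "seed": config.seed,
        "input": source,
        "n_input": int(len(cohort)),
        "exclusions": {
            "percentile": config.exclusion_percentile,
            "threshold_mm3": excl["threshold"],
            "n_excluded": int(len(excl["excluded"])),
            "excluded_ids": [str(i) for i in excl["excluded"]["id"]],
        },
        "correction": {
            "covariates": list(config.correction_covariates),
            "mode": config.correction_mode if config.correction_covariates else None,
        },
        "model": {
            "smoother": {
                "span": config.smoother.span,
                "degree": config.smoother.degree,
                "robustness_iters": config.smoother.robustness_iters,
                "scale_floor": config.smoother.scale_floor,
            },
            "threshold": config.threshold,
            "n_controls": results.n_controls,
            "control_range_log_pgv": list(results.control_range),
            "n_clamped": int(scores["clamped"].sum()),
        },
        "groups": groups_report,
        "comparisons": comparisons,
        "regression": {
            "F": reg.fvalue,
            "df_num": reg.df_num,
            "df_den": reg.df_den,
            "p": reg.f_pvalue,
            "r_squared": reg.rsquared,
            "terms": anova,
        },
    }

    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(outdir / "scores.csv", index=False)
        if config.simulation is not None:
            write_phenotypes(cohort, outdir / "cohort.csv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        logger.info("report written to %s", outdir / "report.json")
    return report
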