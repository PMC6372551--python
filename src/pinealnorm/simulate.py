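"""Seedable synthetic case-control cohort generator.

Clinical phenotype tables of the kind this pipeline analyses (autism
probands, their unaffected first-degree relatives, and typically
developing controls, with plasma melatonin, pineal gland volume and total
brain volume) are rarely deposited publicly. This module generates
cohorts with the same statistical structure so that every pipeline stage
can be exercised and calibrated end to end:

* three groups with configurable sizes, sex ratios, age / IQ / SRS
  distributions and biomarker moments (defaults calibrated to a published
  cohort of 78 ASD / 90 relatives / 47 controls);
* strictly positive, right-skewed plasma melatonin, drawn lognormal with
  the log-mean and log-SD solved so the *arithmetic* group mean and SD hit
  their targets exactly in expectation (moment matching);
* a positive dependence of log-melatonin on log-PGV in every group, with
  slope ``b`` planted on the control-centered log-PGV;
* a group-level melatonin deficit entering as a PGV-independent offset of
  the log-melatonin intercept — the generator's default causal structure
  places the deficit in the melatonin pathway itself, not in the gland
  volume (a ``pgv_mediated`` mode is provided for contrast experiments);
* optional planted cyst-like extreme-PGV records, flagged in a provenance
  column, for exercising the percentile exclusion filter.

Everything is deterministic given the seed; :func:`planted_truth` exposes
the exact control curve, group offsets and noise SDs used, which serve as
the ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["GroupParams", "SimulationConfig", "PlantedTruth", "generate_cohort", "planted_truth"]

GROUPS = ("ASD", "relative", "control")

#: Columns of the phenotype table written/consumed by the pipeline.
PHENOTYPE_COLUMNS = [
    "id",
    "group",
    "sex",
    "age",
    "iq",
    "srs",
    "melatonin_nM",
    "pgv_mm3",
    "tbv_cm3",
    "planted_outlier",
]

AGE_FLOOR = 4.0  # years; youngest plausible MRI participant


@dataclass(frozen=True)
class GroupParams:
    """Marginal distribution targets for one participant group.

    ``melatonin_mean`` / ``melatonin_sd`` are *arithmetic* moments in nM;
    ``pgv`` in mm^3, ``tbv`` in cm^3, age in years. Ages are truncated at
    4 years and PGV/TBV at zero; the truncated-normal location is solved
    so the truncated mean still equals the stated target.
    """

    n: int
    male_fraction: float
    age_mean: float
    age_sd: float
    iq_mean: float
    iq_sd: float
    srs_mean: float
    srs_sd: float
    melatonin_mean: float
    melatonin_sd: float
    pgv_mean: float
    pgv_sd: float
    tbv_mean: float
    tbv_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for name in ("age_sd", "iq_sd", "srs_sd", "melatonin_sd", "pgv_sd", "tbv_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("melatonin_mean", "pgv_mean", "tbv_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _default_groups() -> dict[str, GroupParams]:
    # Calibrated to the reference cohort's demographic and biomarker tables.
    return {
        "ASD": GroupParams(
            n=78, male_fraction=60 / 78, age_mean=13.2, age_sd=8.8,
            iq_mean=95.3, iq_sd=26.1, srs_mean=77.56, srs_sd=11.54,
            melatonin_mean=0.08, melatonin_sd=0.04,
            pgv_mean=96.1, pgv_sd=36.7, tbv_mean=1169.1, tbv_sd=123.3,
        ),
        "relative": GroupParams(
            n=90, male_fraction=45 / 90, age_mean=35.7, age_sd=17.5,
            iq_mean=115.0, iq_sd=12.8, srs_mean=46.55, srs_sd=8.98,
            melatonin_mean=0.13, melatonin_sd=0.06,
            pgv_mean=96.2, pgv_sd=35.7, tbv_mean=1135.7, tbv_sd=119.6,
        ),
        "control": GroupParams(
            n=47, male_fraction=25 / 47, age_mean=22.0, age_sd=12.7,
            iq_mean=111.2, iq_sd=16.0, srs_mean=47.46, srs_sd=7.37,
            melatonin_mean=0.14, melatonin_sd=0.07,
            pgv_mean=108.8, pgv_sd=35.5, tbv_mean=1152.7, tbv_sd=88.0,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Parameters
    ----------
    groups : dict
        Per-group :class:`GroupParams`; keys must be exactly
        ``ASD``, ``relative``, ``control``.
    slope : float
        Planted slope ``b`` of log-melatonin on control-centered log-PGV,
        shared by all groups. The default 0.35 gives a control-group
        log-log correlation of about 0.3, a weak-to-moderate dependence
        consistent with reports on healthy cohorts.
    deficit_mode : str
        ``"pathway"`` (default): the ASD melatonin deficit is a
        PGV-independent intercept offset. ``"pgv_mediated"``: melatonin
        depends on PGV only (the group intercepts are equalized to the
        control one), so any group deficit is carried entirely by the
        groups' smaller glands — the contrast hypothesis.
    n_outliers : int
        Planted cyst-like extreme-PGV records, appended beyond the group
        sizes and flagged in the ``planted_outlier`` column. They are
        assigned alternately to the ASD and control groups.
    outlier_factor : float
        Multiplier applied to a fresh PGV draw for each planted outlier.
    seed : int
        Seed for the random generator; identical seeds give identical
        cohorts.
    """

    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    slope: float = 0.35
    deficit_mode: str = "pathway"
    n_outliers: int = 0
    outlier_factor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.groups) != set(GROUPS):
            raise ValueError(f"groups must be exactly {set(GROUPS)}")
        if self.deficit_mode not in ("pathway", "pgv_mediated"):
            raise ValueError("deficit_mode must be 'pathway' or 'pgv_mediated'")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")

    def scaled(self, factor: int) -> "SimulationConfig":
        """Copy of the config with every group size multiplied by `factor`."""
        groups = {
            g: GroupParams(**{**p.__dict__, "n": p.n * factor})
            for g, p in self.groups.items()
        }
        return SimulationConfig(
            groups=groups, slope=self.slope, deficit_mode=self.deficit_mode,
            n_outliers=self.n_outliers, outlier_factor=self.outlier_factor,
            seed=self.seed,
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Exact data-generating parameters behind a :class:`SimulationConfig`.

    The control curve is ``E[log melatonin | log PGV = x] = intercept +
    slope * x``; each non-control group is shifted by ``offsets[group]``
    (log units) and carries Gaussian log-scale noise ``noise_sd[group]``.
    """

    intercept: float
    slope: float
    center: float  # mean control log-PGV used for centering
    offsets: dict[str, float]
    noise_sd: dict[str, float]

    def control_mean(self, log_pgv):
        return self.intercept + self.slope * np.asarray(log_pgv, dtype=float)


def _truncnorm_frozen(mean: float, sd: float, lower: float):
    """Truncated normal with its location solved so that the truncated
    mean equals ``mean`` (plain normal if sd == 0 handled by caller)."""
    def trunc_mean(loc):
        a = (lower - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd) - mean

    lo, hi = mean - 6 * sd, mean + 2 * sd
    loc = optimize.brentq(trunc_mean, min(lo, lower - 6 * sd), hi, xtol=1e-10)
    a = (lower - loc) / sd
    return stats.truncnorm(a, np.inf, loc=loc, scale=sd)


def _melatonin_params(config: SimulationConfig):
    """Solve per-group log-intercept A_g and noise SD from the arithmetic
    moment targets, accounting for the planted PGV term.

    With log mel = A_g + b*(log PGV - c) + eps, eps ~ N(0, s_g^2), and
    P_k = E[(PGV/e^c)^(k*b)] under the group's PGV distribution:
        E[mel]      = exp(A_g + s_g^2/2) * P_1
        E[mel^2]    = exp(2 A_g + 2 s_g^2) * P_2
    which gives s_g^2 = log((1 + sd^2/m^2) * P_1^2 / P_2) and
    A_g = log m - s_g^2/2 - log P_1.
    """
    b = config.slope
    pgv_dists = {
        g: _truncnorm_frozen(p.pgv_mean, p.pgv_sd, 0.0) for g, p in config.groups.items()
    }
    c = pgv_dists["control"].expect(np.log)
    A, noise = {}, {}
    for g, p in config.groups.items():
        dist = pgv_dists[g]
        if b != 0.0:
            p1 = dist.expect(lambda x: np.exp(b * (np.log(x) - c)))
            p2 = dist.expect(lambda x: np.exp(2 * b * (np.log(x) - c)))
        else:
            p1 = p2 = 1.0
        m, s = p.melatonin_mean, p.melatonin_sd
        s2 = np.log((1.0 + s**2 / m**2) * p1**2 / p2)
        if s2 < 0:
            raise ValueError(
                f"infeasible melatonin moment matching for group {g!r}: the "
                f"planted PGV slope already implies more log-variance than the "
                f"target SD/mean ratio allows"
            )
        A[g] = np.log(m) - s2 / 2.0 - np.log(p1)
        noise[g] = float(np.sqrt(s2))
    return c, A, noise, pgv_dists


def planted_truth(config: SimulationConfig | None = None) -> PlantedTruth:
    """Ground-truth control curve, group offsets and noise SDs of a config.

    Serves as the oracle for parameter-recovery tests: a correctly fitted
    normative model must recover ``control_mean`` and the control
    ``noise_sd``, and the scored groups must recover the sign and ordering
    of ``offsets``.
    """
    if config is None:
        config = SimulationConfig()
    c, A, noise, _ = _melatonin_params(config)
    if config.deficit_mode == "pgv_mediated":
        offsets = {g: 0.0 for g in config.groups}
    else:
        offsets = {g: float(A[g] - A["control"]) for g in config.groups}
    return PlantedTruth(
        intercept=float(A["control"] - config.slope * c),
        slope=config.slope,
        center=float(c),
        offsets=offsets,
        noise_sd=noise,
    )


def generate_cohort(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Draw one cohort as a phenotype table (one row per participant).

    Returns a DataFrame with :data:`PHENOTYPE_COLUMNS`; planted outliers
    carry ``planted_outlier == True``. Deterministic given ``config.seed``.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    c, A, noise, pgv_dists = _melatonin_params(config)
    if config.deficit_mode == "pgv_mediated":
        A = {g: A["control"] for g in A}

    frames = []
    counter = 0
    for g in GROUPS:
        p = config.groups[g]
        n = p.n
        if n == 0:
            continue
        sex = np.where(rng.random(n) < p.male_fraction, "male", "female")
        age = _truncnorm_frozen(p.age_mean, p.age_sd, AGE_FLOOR).rvs(n, random_state=rng) \
            if p.age_sd > 0 else np.full(n, max(p.age_mean, AGE_FLOOR))
        iq = rng.normal(p.iq_mean, p.iq_sd, n)
        srs = rng.normal(p.srs_mean, p.srs_sd, n)
        pgv = pgv_dists[g].rvs(n, random_state=rng) if p.pgv_sd > 0 else np.full(n, p.pgv_mean)
        tbv = _truncnorm_frozen(p.tbv_mean, p.tbv_sd, 0.0).rvs(n, random_state=rng) \
            if p.tbv_sd > 0 else np.full(n, p.tbv_mean)
        log_mel = (
            A[g]
            + config.slope * (np.log(pgv) - c)
            + rng.normal(0.0, noise[g], n)
        )
        ids = [f"{g[:3].upper()}{counter + i:05d}" for i in range(n)]
        counter += n
        frames.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "group": g,
                    "sex": sex,
                    "age": age,
                    "iq": iq,
                    "srs": srs,
                    "melatonin_nM": np.exp(log_mel),
                    "pgv_mm3": pgv,
                    "tbv_cm3": tbv,
                    "planted_outlier": False,
                }
            )
        )

    # cyst-like extreme-PGV records, alternately ASD and control
    out_rows = []
    out_groups = ["ASD", "control"]
    for i in range(config.n_outliers):
        g = out_groups[i % 2]
        p = config.groups[g]
        pgv = float(pgv_dists[g].rvs(random_state=rng)) * config.outlier_factor
        log_mel = A[g] + config.slope * (np.log(p.pgv_mean) - c) + rng.normal(0.0, noise[g])
        out_rows.append(
            {
                "id": f"OUT{counter + i:05d}",
                "group": g,
                "sex": "male" if rng.random() < p.male_fraction else "female",
                "age": float(_truncnorm_frozen(p.age_mean, p.age_sd, AGE_FLOOR).rvs(random_state=rng)),
                "iq": float(rng.normal(p.iq_mean, p.iq_sd)),
                "srs": float(rng.normal(p.srs_mean, p.srs_sd)),
                "melatonin_nM": float(np.exp(log_mel)),
                "pgv_mm3": pgv,
                "tbv_cm3": float(_truncnorm_frozen(p.tbv_mean, p.tbv_sd, 0.0).rvs(random_state=rng)),
                "planted_outlier": True,
            }
        )
    if out_rows:
        frames.append(pd.DataFrame(out_rows))
    if not frames:
        return pd.DataFrame(columns=PHENOTYPE_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df[PHENOTYPE_COLUMNS]
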