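"""Control-based normative model of plasma melatonin given pineal volume.

The scientific question the model answers: *given a subject's pineal
gland volume (PGV), is their plasma melatonin lower than one would expect
from gland size alone?* A normative model is a reference distribution of
an outcome conditional on a covariate, fitted on controls only; each
subject is then summarized by a deviation score

    z = (log melatonin - m(log PGV)) / s(log PGV)

where ``m`` and ``s`` are the local mean and local SD of log-melatonin at
the subject's log-PGV, estimated on the control sample by LOESS (see
:mod:`pinealnorm.smoothing`). Unlike a case-control mean comparison, the
score isolates individuals — a subject is "extremely deviant" when
``z < -2`` or ``z > +2`` — which accommodates the phenotypic
heterogeneity of clinical groups.

Both variables are natural-log transformed: hormone concentrations and
volumes are strictly positive and right-skewed, and the dependence is
closer to linear on the log-log scale. Fitting on controls only prevents
the group effect being measured from leaking into the reference.

The module exposes a statsmodels-style pair — :class:`NormativeMelatoninModel`
(built from a phenotype DataFrame, ``fit()`` estimates the control curve)
and :class:`NormativeResults` (scores, extreme fractions, ``summary()``,
plotting, JSON round-trip) — plus the functional layer
(:func:`fit_normative`, :func:`score`, :func:`extreme_fractions`,
:func:`covariate_correction`) that the pipeline composes.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .smoothing import FittedSmoother, SmootherConfig, _Interpolant, loess_fit, local_scale

__all__ = [
    "ParticipantRecord",
    "NormativeScore",
    "NormativeMelatoninModel",
    "NormativeResults",
    "fit_normative",
    "score",
    "extreme_fractions",
    "covariate_correction",
]

MIN_CONTROLS = 10
VALID_GROUPS = ("ASD", "relative", "control")


@dataclass
class ParticipantRecord:
    """One subject's demographics and biomarkers — the row type of every
    pipeline stage.

    Units: age in years, melatonin in nM, PGV in mm^3, TBV in cm^3; ``srs``
    (Social Responsiveness Scale T-score) is optional.
    """

    id: str
    group: str
    sex: str
    age: float
    iq: float
    melatonin: float
    pgv: float
    tbv: float
    srs: float | None = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"record {self.id!r}: group must be one of {VALID_GROUPS}, got {self.group!r}"
            )
        if not self.melatonin > 0:
            raise ValueError(f"record {self.id!r}: melatonin must be > 0, got {self.melatonin}")
        if not self.pgv > 0:
            raise ValueError(f"record {self.id!r}: pgv must be > 0, got {self.pgv}")
        if not self.tbv > 0:
            raise ValueError(f"record {self.id!r}: tbv must be > 0, got {self.tbv}")
        if self.age < 0:
            raise ValueError(f"record {self.id!r}: age must be >= 0, got {self.age}")


@dataclass(frozen=True)
class NormativeScore:
    """One subject's deviation from the normative curve.

    ``clamped`` is set when the subject's log-PGV fell outside the control
    range and the boundary fit was used; ``category`` classifies extreme
    deviance with strict inequalities (``low`` iff ``z < -threshold``,
    ``high`` iff ``z > +threshold``).
    """

    id: str
    z: float
    clamped: bool
    category: str


_COLUMN_MAP = {
    "melatonin": "melatonin_nM",
    "pgv": "pgv_mm3",
    "tbv": "tbv_cm3",
    "age": "age",
    "iq": "iq",
    "srs": "srs",
}


def as_frame(records) -> pd.DataFrame:
    """Normalize a phenotype DataFrame or an iterable of
    :class:`ParticipantRecord` to the standard column layout."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {
            "id": r.id, "group": r.group, "sex": r.sex, "age": r.age, "iq": r.iq,
            "srs": np.nan if r.srs is None else r.srs,
            "melatonin_nM": r.melatonin, "pgv_mm3": r.pgv, "tbv_cm3": r.tbv,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def as_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Inverse of :func:`as_frame`."""
    out = []
    for _, row in frame.iterrows():
        srs = row.get("srs", np.nan)
        out.append(
            ParticipantRecord(
                id=str(row["id"]), group=row["group"], sex=row["sex"],
                age=float(row["age"]), iq=float(row["iq"]),
                melatonin=float(row["melatonin_nM"]), pgv=float(row["pgv_mm3"]),
                tbv=float(row["tbv_cm3"]),
                srs=None if pd.isna(srs) else float(srs),
            )
        )
    return out


def _validate_positive(frame: pd.DataFrame, columns=("melatonin_nM", "pgv_mm3")) -> None:
    for col in columns:
        vals = frame[col].to_numpy(dtype=float)
        bad = ~(vals > 0) | ~np.isfinite(vals)
        if bad.any():
            offender = frame.loc[frame.index[np.nonzero(bad)[0][0]], "id"]
            raise ValueError(
                f"{col} must be positive and finite for all records; "
                f"first offending record: {offender!r}"
            )


class NormativeMelatoninModel:
    """Normative model of log-melatonin given log-PGV, fitted on controls.

    Parameters
    ----------
    data : DataFrame or iterable of ParticipantRecord
        Phenotype table; rows with ``group == 'control'`` form the
        reference sample, all rows are scored by :meth:`fit`'s results.
    config : SmootherConfig, optional
        LOESS settings for the mean and scale curves.
    threshold : float
        Extreme-deviance cut in SD units (default 2).
    outcome, covariate : str
        Column names of the outcome and conditioning covariate; both are
        natural-log transformed before fitting.
    """

    def __init__(
        self,
        data,
        config: SmootherConfig | None = None,
        threshold: float = 2.0,
        outcome: str = "melatonin_nM",
        covariate: str = "pgv_mm3",
    ):
        self.data = as_frame(data).reset_index(drop=True)
        self.config = config if config is not None else SmootherConfig()
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        self.threshold = float(threshold)
        self.outcome = outcome
        self.covariate = covariate

    @classmethod
    def from_records(cls, records: Iterable[ParticipantRecord], **kwargs):
        return cls(as_frame(list(records)), **kwargs)

    def fit(self) -> "NormativeResults":
        controls = self.data[self.data["group"] == "control"]
        n = len(controls)
        if n < MIN_CONTROLS:
            raise ValueError(
                f"need at least {MIN_CONTROLS} control participants to fit a "
                f"normative model, got {n}"
            )
        _validate_positive(controls, (self.outcome, self.covariate))
        x = np.log(controls[self.covariate].to_numpy(dtype=float))
        y = np.log(controls[self.outcome].to_numpy(dtype=float))
        smoother = loess_fit(x, y, self.config)
        resid = y - smoother.mean_at(x)
        smoother.scale_at = local_scale(x, resid, self.config)
        control_range = (float(x.min()), float(x.max()))
        return NormativeResults(
            model=self,
            smoother=smoother,
            control_range=control_range,
            n_controls=n,
        )


class NormativeResults:
    """Fitted normative curve plus scoring, classification and reporting.

    Attributes
    ----------
    smoother : FittedSmoother
        Local mean and SD of log-outcome as functions of log-covariate.
    control_range : (float, float)
        Range of control log-covariate; subjects outside are scored at the
        boundary and flagged ``clamped``.
    n_controls : int
    """

    def __init__(self, model, smoother: FittedSmoother, control_range, n_controls: int):
        lo, hi = control_range
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError("control covariate range is degenerate; cannot score")
        self.model = model
        self.smoother = smoother
        self.control_range = (float(lo), float(hi))
        self.n_controls = int(n_controls)
        self.log_transform = True

    # -- curve evaluation ------------------------------------------------
    def predict(self, pgv, return_sd: bool = False):
        """Normative median melatonin (nM) at the given PGV (mm^3); with
        ``return_sd`` also the local log-scale SD."""
        pgv = np.asarray(pgv, dtype=float)
        if not np.all(pgv > 0):
            raise ValueError("pgv must be positive")
        x = np.clip(np.log(pgv), *self.control_range)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = self.smoother.mean_at(x)
            if return_sd:
                return np.exp(mean), self.smoother.scale_at(x)
        return np.exp(mean)

    def _z_one(self, melatonin: float, pgv: float) -> tuple[float, bool]:
        if not (melatonin > 0 and np.isfinite(melatonin)):
            raise ValueError(f"melatonin must be positive, got {melatonin}")
        if not (pgv > 0 and np.isfinite(pgv)):
            raise ValueError(f"pgv must be positive, got {pgv}")
        lx = float(np.log(pgv))
        clamped = lx < self.control_range[0] or lx > self.control_range[1]
        lx = min(max(lx, self.control_range[0]), self.control_range[1])
        z = (np.log(melatonin) - self.smoother.mean_at(lx)) / self.smoother.scale_at(lx)
        return float(z), clamped

    def categorize(self, z: float) -> str:
        t = self.model.threshold
        if z < -t:
            return "low"
        if z > t:
            return "high"
        return "normal"

    def score(self, subject: ParticipantRecord) -> NormativeScore:
        """Deviation score of a single subject."""
        z, clamped = self._z_one(subject.melatonin, subject.pgv)
        return NormativeScore(id=subject.id, z=z, clamped=clamped, category=self.categorize(z))

    def score_frame(self, data=None) -> pd.DataFrame:
        """Score every row of ``data`` (default: the model's own data).

        Returns a DataFrame with columns id, group, z, clamped, category.
        """
        frame = self.model.data if data is None else as_frame(data)
        _validate_positive(frame, (self.model.outcome, self.model.covariate))
        mel = frame[self.model.outcome].to_numpy(dtype=float)
        pgv = frame[self.model.covariate].to_numpy(dtype=float)
        lx = np.log(pgv)
        clamped = (lx < self.control_range[0]) | (lx > self.control_range[1])
        lxc = np.clip(lx, *self.control_range)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            z = (np.log(mel) - self.smoother.mean_at(lxc)) / self.smoother.scale_at(lxc)
        t = self.model.threshold
        category = np.where(z < -t, "low", np.where(z > t, "high", "normal"))
        return pd.DataFrame(
            {
                "id": frame["id"].to_numpy(),
                "group": frame["group"].to_numpy(),
                "z": z,
                "clamped": clamped,
                "category": category,
            }
        )

    def extreme_fractions(self, scores: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-group percentages of extreme deviation scores; see
        :func:`extreme_fractions`."""
        if scores is None:
            scores = self.score_frame()
        return extreme_fractions(scores, threshold=self.model.threshold)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit and the per-group extreme tails."""
        frac = self.extreme_fractions()
        buf = io.StringIO()
        cfg = self.smoother.config
        buf.write("Normative model of log({}) given log({})\n".format(
            self.model.outcome, self.model.covariate))
        buf.write("=" * 60 + "\n")
        buf.write(f"Controls used:       {self.n_controls}\n")
        buf.write("Control log-range:   [{:.4f}, {:.4f}]\n".format(*self.control_range))
        buf.write(
            f"LOESS:               span={cfg.span}, degree={cfg.degree}, "
            f"robustness_iters={cfg.robustness_iters}\n"
        )
        buf.write(f"Extreme threshold:   |z| > {self.model.threshold}\n\n")
        buf.write(frac.to_string(float_format=lambda v: f"{v:8.2f}"))
        buf.write("\n")
        return buf.getvalue()

    def plot(self, ax=None, scores: pd.DataFrame | None = None):
        """Scatter of log-melatonin vs log-PGV with the normative mean and
        1/2/3-SD bands; groups colour-coded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        grid = np.linspace(*self.control_range, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = self.smoother.mean_at(grid)
            s = self.smoother.scale_at(grid)
        for k, alpha in ((3, 0.12), (2, 0.18), (1, 0.25)):
            ax.fill_between(grid, m - k * s, m + k * s, color="tab:blue", alpha=alpha, lw=0)
        ax.plot(grid, m, color="tab:blue", lw=2, label="normative mean")
        frame = self.model.data
        colors = {"ASD": "tab:red", "relative": "tab:green", "control": "tab:blue"}
        for g, sub in frame.groupby("group"):
            ax.scatter(
                np.log(sub[self.model.covariate]), np.log(sub[self.model.outcome]),
                s=12, color=colors.get(g, "gray"), label=g, alpha=0.8,
            )
        ax.set_xlabel(f"log {self.model.covariate}")
        ax.set_ylabel(f"log {self.model.outcome}")
        ax.legend(fontsize=8)
        return ax

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-serializable representation (the fitted curves are stored
        on the training grid; evaluation is interpolation, so this is a
        faithful round-trip)."""
        grid = self.smoother.training_x
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {
                "config": asdict(self.smoother.config),
                "threshold": self.model.threshold,
                "outcome": self.model.outcome,
                "covariate": self.model.covariate,
                "control_range": list(self.control_range),
                "n_controls": self.n_controls,
                "grid": grid.tolist(),
                "mean": np.asarray(self.smoother.mean_at(grid)).tolist(),
                "scale": np.asarray(self.smoother.scale_at(grid)).tolist(),
            }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "NormativeResults":
        config = SmootherConfig(**payload["config"])
        model = NormativeMelatoninModel(
            pd.DataFrame(columns=["id", "group", payload["outcome"], payload["covariate"]]),
            config=config, threshold=payload["threshold"],
            outcome=payload["outcome"], covariate=payload["covariate"],
        )
        grid = np.asarray(payload["grid"], dtype=float)
        sm = FittedSmoother(
            training_x=grid,
            mean_at=_Interpolant(grid, np.asarray(payload["mean"], dtype=float), "the fitted mean"),
            scale_at=_Interpolant(grid, np.asarray(payload["scale"], dtype=float), "the local scale"),
            config=config,
            fitted_mean=np.asarray(payload["mean"], dtype=float),
        )
        return cls(model, sm, tuple(payload["control_range"]), payload["n_controls"])

    @classmethod
    def load(cls, path) -> "NormativeResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# functional layer


def fit_normative(controls, config: SmootherConfig | None = None,
                  threshold: float = 2.0) -> NormativeResults:
    """Fit the normative model on a control sample.

    ``controls`` may be ParticipantRecords or a phenotype DataFrame; every
    row must be a control with positive melatonin and PGV.
    """
    frame = as_frame(controls)
    if len(frame) and not (frame["group"] == "control").all():
        bad = frame.loc[frame["group"] != "control", "id"].iloc[0]
        raise ValueError(f"fit_normative expects controls only; found record {bad!r}")
    return NormativeMelatoninModel(frame, config=config, threshold=threshold).fit()


def score(results: NormativeResults, subject: ParticipantRecord) -> NormativeScore:
    """Deviation score of one subject under a fitted normative model."""
    return results.score(subject)


def extreme_fractions(scores, threshold: float = 2.0) -> pd.DataFrame:
    """Per-group percentages of extreme deviation scores.

    Parameters
    ----------
    scores : DataFrame with columns ``group`` and ``z``, or iterable of
        ``(group, NormativeScore)`` pairs.

    Returns
    -------
    DataFrame indexed by group with columns ``n``, ``pct_low``
    (% with ``z < -threshold``) and ``pct_high`` (% with ``z > +threshold``).
    Groups with no members are absent (a percentage of nothing is
    undefined, not zero).
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(
            [{"group": g, "z": s.z} for g, s in scores]
        )
    if scores.empty:
        return pd.DataFrame(columns=["n", "pct_low", "pct_high"])
    rows = {}
    for g, sub in scores.groupby("group"):
        z = sub["z"].to_numpy(dtype=float)
        n = len(z)
        rows[g] = {
            "n": n,
            "pct_low": 100.0 * np.count_nonzero(z < -threshold) / n,
            "pct_high": 100.0 * np.count_nonzero(z > threshold) / n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    out["n"] = out["n"].astype(int)
    return out


def covariate_correction(
    records,
    covariates: Sequence[str],
    mode: str = "linear",
    config: SmootherConfig | None = None,
) -> pd.DataFrame:
    """Remove control-estimated covariate effects from melatonin.

    Used to check that group differences in deviation scores are not
    secondary to age or total brain volume: the outcome is replaced by its
    residual from a control-fitted model of the covariates (plus the
    control mean, so the scale is preserved), after which the usual
    PGV-normative analysis is re-run on the corrected table.

    Parameters
    ----------
    records : phenotype DataFrame or iterable of ParticipantRecord
    covariates : non-empty subset of {"age", "tbv"}
    mode : {"linear", "nonlinear"}
        ``linear``: ordinary least squares of log-melatonin on the
        covariates, fitted on controls, applied to everyone.
        ``nonlinear``: sequential LOESS normative correction, one
        covariate at a time in the order given; each pass replaces
        log-melatonin by its deviation from the control smooth.

    Returns
    -------
    DataFrame — a copy with ``melatonin_nM`` replaced by the corrected
    (back-transformed) values.
    """
    frame = as_frame(records).reset_index(drop=True).copy()
    if not covariates:
        raise ValueError("covariates must be a non-empty subset of {'age', 'tbv'}")
    colmap = {"age": "age", "tbv": "tbv_cm3"}
    try:
        cols = [colmap[c] for c in covariates]
    except KeyError as exc:
        raise ValueError(f"unknown correction covariate {exc.args[0]!r}") from None
    if mode not in ("linear", "nonlinear"):
        raise ValueError("mode must be 'linear' or 'nonlinear'")

    _validate_positive(frame, ("melatonin_nM",))
    is_control = (frame["group"] == "control").to_numpy()
    if not is_control.any():
        raise ValueError("covariate correction requires control records")
    y = np.log(frame["melatonin_nM"].to_numpy(dtype=float))

    if mode == "linear":
        X = frame[cols].to_numpy(dtype=float)
        for c, col in zip(covariates, cols):
            if np.ptp(X[is_control, cols.index(col)]) == 0:
                raise ValueError(f"covariate {c!r} is constant across controls; inestimable")
        Xc = np.column_stack([np.ones(len(frame)), X])
        beta, *_ = np.linalg.lstsq(Xc[is_control], y[is_control], rcond=None)
        resid = y - Xc @ beta
        corrected = resid + y[is_control].mean()
    else:
        corrected = y.copy()
        if config is None:
            config = SmootherConfig()
        for c, col in zip(covariates, cols):
            v = frame[col].to_numpy(dtype=float)
            if not np.all(v > 0):
                raise ValueError(f"covariate {c!r} must be positive for the log transform")
            lx = np.log(v)
            if np.ptp(lx[is_control]) == 0:
                raise ValueError(f"covariate {c!r} is constant across controls; inestimable")
            sm = loess_fit(lx[is_control], corrected[is_control], config)
            lo, hi = lx[is_control].min(), lx[is_control].max()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                trend = sm.mean_at(np.clip(lx, lo, hi))
            center = corrected[is_control].mean()
            corrected = corrected - trend + center

    out = frame.copy()
    out["melatonin_nM"] = np.exp(corrected)
    return out
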