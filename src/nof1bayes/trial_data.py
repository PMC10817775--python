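"""Data structures and I/O for N-of-1 trial measurement series.

An N-of-1 trial is a randomized multi-crossover experiment in a single
participant: two or more treatments are alternated in periods, with repeated
outcome measurements in each period.  This module holds the long-format
measurement containers for one trial (:class:`TrialDataset`) and for a
collection of trials to be meta-analyzed (:class:`MultiTrialDataset`),
together with design-level preprocessing: analytic washout trimming and
classification of participants into completion strata.

Times are in study weeks, 0-based at the first baseline measurement.
Period boundaries are declared in the input (``period`` column), never
inferred from a fixed grid, because participants may cross over early.
Missing outcomes are carried as explicit rows with NaN so that imputation
has a design slot for every planned measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("nof1bayes")

#: PROMIS pain-interference T-score ranges by reporter.
DEFAULT_BOUNDS = {"child": (34.0, 78.0), "parent": (38.0, 78.0)}

#: Default column-name map for the long CSV format.
DEFAULT_SCHEMA = {
    "id": "id",
    "time": "time",
    "period": "period",
    "treatment": "treatment",
    "value": "value",
    "reporter": "reporter",
    "sequence": "sequence",
}

COMPLETION_FULL = "full"
COMPLETION_EARLY = "early"
COMPLETION_WITHDRAWAL = "withdrawal"


class TrialDataError(ValueError):
    """Malformed trial data (bad treatment codes, non-monotone times, ...)."""


@dataclass(frozen=True)
class Measurement:
    """One outcome measurement of one individual at one time point."""

    individual_id: str
    time: float
    treatment: int
    value: float  # NaN marks a missing outcome
    period_index: int  # 0 = baseline, 1..P = experimental periods
    reporter: str | None = None


@dataclass
class TrialDataset:
    """All measurements of a single individual, sorted by time.

    Parameters
    ----------
    individual_id : str
        Opaque participant label.
    time, treatment, value, period_index : ndarray
        Parallel arrays, one entry per measurement, sorted by time.
        ``value`` uses NaN for missing outcomes. Treatment codes are
        1..K with 1 the reference treatment.
    K : int
        Number of treatments in the design.
    outcome_bounds : (float, float)
        Declared range of the outcome scale.
    sequence_label : str
        Randomization sequence, e.g. ``"ABAB"`` or ``"BABA"``.
    reporter : str or None
        Who reported the outcome (selects the default bounds).
    """

    individual_id: str
    time: np.ndarray
    treatment: np.ndarray
    value: np.ndarray
    period_index: np.ndarray
    K: int = 2
    outcome_bounds: tuple[float, float] = DEFAULT_BOUNDS["child"]
    sequence_label: str = ""
    reporter: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        self.period_index = np.asarray(self.period_index, dtype=int)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.time)
        for name in ("treatment", "value", "period_index"):
            if len(getattr(self, name)) != n:
                raise TrialDataError(
                    f"{self.individual_id}: column {name!r} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if self.K < 2:
            raise TrialDataError(f"{self.individual_id}: K must be >= 2, got {self.K}")
        if n and np.any(np.diff(self.time) <= 0):
            j = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise TrialDataError(
                f"{self.individual_id}: times not strictly increasing at row {j} "
                f"(t={self.time[j]!r} after t={self.time[j - 1]!r})"
            )
        bad = (self.treatment < 1) | (self.treatment > self.K)
        if np.any(bad):
            j = int(np.argmax(bad))
            raise TrialDataError(
                f"{self.individual_id}: treatment code {self.treatment[j]} at row {j} "
                f"outside 1..{self.K}"
            )
        # treatment constant within a period
        for p in np.unique(self.period_index):
            tr = self.treatment[self.period_index == p]
            if len(np.unique(tr)) > 1:
                raise TrialDataError(
                    f"{self.individual_id}: period {p} mixes treatment codes "
                    f"{sorted(np.unique(tr).tolist())}"
                )
        lo, hi = self.outcome_bounds
        obs = self.value[np.isfinite(self.value)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise TrialDataError(
                f"{self.individual_id}: outcome value outside declared bounds "
                f"[{lo}, {hi}]"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing outcomes."""
        return np.isfinite(self.value)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def measurements(self) -> list[Measurement]:
        return [
            Measurement(
                self.individual_id,
                float(self.time[j]),
                int(self.treatment[j]),
                float(self.value[j]),
                int(self.period_index[j]),
                self.reporter,
            )
            for j in range(self.n)
        ]

    def drop_missing(self) -> "TrialDataset":
        """Copy with missing-outcome rows removed (observed-data analysis)."""
        m = self.observed
        return replace(
            self,
            time=self.time[m],
            treatment=self.treatment[m],
            value=self.value[m],
            period_index=self.period_index[m],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.individual_id,
                "time": self.time,
                "period": self.period_index,
                "treatment": self.treatment,
                "value": self.value,
                "reporter": self.reporter if self.reporter is not None else "",
                "sequence": self.sequence_label,
            }
        )


@dataclass
class MultiTrialDataset:
    """A collection of N-of-1 trials keyed by individual id.

    ``individual_covariates`` holds per-individual values (one row per
    individual, e.g. a sex indicator for subgroup models);
    ``within_covariates`` holds per-measurement covariates keyed like the
    measurement rows.  ``completion_stratum`` maps individual id to one of
    ``full`` / ``early`` / ``withdrawal``.
    """

    trials: dict[str, TrialDataset]
    individual_covariates: pd.DataFrame | None = None
    within_covariates: pd.DataFrame | None = None
    completion_stratum: dict[str, str] = field(default_factory=dict)
    #: how many leading measurements per experimental period have already
    #: been washed out (makes apply_washout idempotent for a fixed n_drop)
    washout_applied: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.trials)

    @property
    def ids(self) -> list[str]:
        return list(self.trials)

    def require_covariates(self, names: list[str]) -> None:
        """Check every referenced individual covariate exists for everyone."""
        cov = self.individual_covariates
        for name in names:
            if cov is None or name not in cov.columns:
                raise TrialDataError(f"individual covariate {name!r} not provided")
            missing = [i for i in self.ids if i not in cov.index]
            if missing:
                raise TrialDataError(
                    f"covariate {name!r} missing for individuals {missing}"
                )
            if cov.loc[self.ids, name].isna().any():
                bad = cov.loc[self.ids, name]
                raise TrialDataError(
                    f"covariate {name!r} is NA for "
                    f"{bad.index[bad.isna()].tolist()}"
                )

    def subset(self, ids: list[str]) -> "MultiTrialDataset":
        cov = self.individual_covariates
        return MultiTrialDataset(
            trials={i: self.trials[i] for i in ids},
            individual_covariates=None if cov is None else cov.loc[[i for i in ids if i in cov.index]],
            within_covariates=self.within_covariates,
            completion_stratum={i: s for i, s in self.completion_stratum.items() if i in ids},
            washout_applied=self.washout_applied,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.trials.values()], ignore_index=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trials(
    path,
    schema: dict[str, str] | None = None,
    K: int | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    default_bounds: tuple[float, float] | None = None,
) -> MultiTrialDataset:
    """Read a long-format CSV of trial measurements.

    One row per individual x time point; columns (names configurable via
    ``schema``): id, time, period, treatment, value, reporter.  Missing
    outcomes are encoded as empty cells or ``NA`` and kept as NaN rows,
    not dropped.

    Parameters
    ----------
    path : path-like
        CSV file, UTF-8, header row.
    schema : dict, optional
        Map from logical names (``id``, ``time``, ...) to column names.
    K : int, optional
        Number of treatments; inferred as the maximum code seen if omitted.
    bounds : dict, optional
        Reporter label -> (lower, upper) outcome bounds; defaults to the
        PROMIS T-score ranges.
    default_bounds : (float, float), optional
        Bounds used when the reporter label is absent or unknown.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    bounds = dict(DEFAULT_BOUNDS) if bounds is None else bounds
    if default_bounds is None:
        default_bounds = DEFAULT_BOUNDS["child"]

    df = pd.read_csv(path, dtype={sch["id"]: str}, keep_default_na=True)
    required = [sch[c] for c in ("id", "time", "period", "treatment", "value")]
    for col in required:
        if col not in df.columns:
            raise TrialDataError(f"{path}: missing required column {col!r}")
    has_reporter = sch["reporter"] in df.columns

    kmax = int(pd.to_numeric(df[sch["treatment"]]).max())
    n_treat = K if K is not None else max(kmax, 2)

    trials: dict[str, TrialDataset] = {}
    for ind, g in df.groupby(sch["id"], sort=True):
        g = g.sort_values(sch["time"], kind="stable")
        reporter = None
        if has_reporter:
            rep = g[sch["reporter"]].dropna()
            reporter = str(rep.iloc[0]) if len(rep) else None
        sequence = ""
        if sch["sequence"] in df.columns:
            seqs = g[sch["sequence"]].dropna()
            sequence = str(seqs.iloc[0]) if len(seqs) else ""
        b = bounds.get(reporter, default_bounds)
        try:
            trials[str(ind)] = TrialDataset(
                individual_id=str(ind),
                time=g[sch["time"]].to_numpy(float),
                treatment=g[sch["treatment"]].to_numpy(int),
                value=g[sch["value"]].to_numpy(float),
                period_index=g[sch["period"]].to_numpy(int),
                K=n_treat,
                outcome_bounds=b,
                reporter=reporter,
                sequence_label=sequence,
            )
        except TrialDataError as exc:
            raise TrialDataError(f"{path}: {exc}") from exc
    return MultiTrialDataset(trials=trials)


def write_trials(data: MultiTrialDataset, path, schema: dict[str, str] | None = None) -> None:
    """Write a dataset back to the long CSV format (inverse of read_trials)."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = data.to_frame().rename(columns=sch)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Design-level preprocessing
# ---------------------------------------------------------------------------

def apply_washout(
    data: MultiTrialDataset, n_drop: int = 1, log: list[str] | None = None
) -> MultiTrialDataset:
    """Analytic washout: drop the first measurements of each experimental period.

    To remove potential carryover of the previous treatment, the first
    ``n_drop`` measurements of every experimental period (period index >= 1)
    are discarded; the baseline period is untouched.  Dropped rows are
    recorded in ``log`` (and the module logger).  Applying the trim twice
    with the same ``n_drop`` removes nothing further, because removal is
    keyed to each period's earliest *planned* measurements, which are gone
    after the first pass.
    """
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    eff = max(0, n_drop - data.washout_applied)
    out: dict[str, TrialDataset] = {}
    for ind, trial in data.trials.items():
        keep = np.ones(trial.n, dtype=bool)
        for p in np.unique(trial.period_index):
            if p < 1:
                continue
            idx = np.flatnonzero(trial.period_index == p)
            drop = idx[:eff]
            keep[drop] = False
            for j in drop:
                msg = (
                    f"washout: dropped {ind} period {p} week {trial.time[j]:g} "
                    f"(value={trial.value[j]!r})"
                )
                logger.info(msg)
                if log is not None:
                    log.append(msg)
            if len(idx) <= eff and eff > 0:
                msg = f"washout: {ind} period {p} empty after trimming {len(idx)} row(s)"
                logger.warning(msg)
                if log is not None:
                    log.append(msg)
        out[ind] = replace(
            trial,
            time=trial.time[keep],
            treatment=trial.treatment[keep],
            value=trial.value[keep],
            period_index=trial.period_index[keep],
        )
    return MultiTrialDataset(
        trials=out,
        individual_covariates=data.individual_covariates,
        within_covariates=data.within_covariates,
        completion_stratum=dict(data.completion_stratum),
        washout_applied=max(n_drop, data.washout_applied),
    )


def classify_completion(trial: TrialDataset, planned_periods: int = 4) -> str:
    """Assign a completion stratum from which periods carry observed outcomes.

    ``full``: every planned experimental period has at least one non-missing
    outcome.  ``early``: exactly the first two periods do (the participant
    stopped after a single crossover).  ``withdrawal``: anything less.  A
    trial with no experimental-period outcomes at all is a withdrawal and is
    flagged baseline-only in the log.
    """
    if planned_periods < 2:
        raise ValueError("planned_periods must be >= 2")
    obs_periods = {
        int(p)
        for p in np.unique(trial.period_index[trial.observed & (trial.period_index >= 1)])
    }
    if not obs_periods:
        logger.warning("%s: baseline-only trial classified as withdrawal", trial.individual_id)
        return COMPLETION_WITHDRAWAL
    if all(p in obs_periods for p in range(1, planned_periods + 1)):
        return COMPLETION_FULL
    if obs_periods == {1, 2}:
        return COMPLETION_EARLY
    return COMPLETION_WITHDRAWAL


def assign_completion_strata(data: MultiTrialDataset, planned_periods: int = 4) -> MultiTrialDataset:
    """Fill ``completion_stratum`` for every individual in place; returns data."""
    for ind, trial in data.trials.items():
        data.completion_stratum[ind] = classify_completion(trial, planned_periods)
    return data
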