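"""Model-based removal of leak/chew artifacts from bout records.

Genuine drinking bouts show a tight linear relation between the number of
licks in a bout and the summed beam-broken time (lick duration): the slope
is roughly the reciprocal of a single lick's contact time.  Slow bottle
leaks break the beam for long stretches with very few licks; chewing on the
spout produces many brief breaks with little accumulated duration.  Both
fall far from the licks-versus-duration line, so an ordinary least squares
fit of ``n_licks`` on ``lick_duration`` followed by a residual cutoff
(default |residual| > 3 licks) removes them in a single pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateFitError
from .lickometer import BoutRecord, SessionRecord

__all__ = [
    "LinearFit",
    "CleaningReport",
    "DEFAULT_RESIDUAL_THRESHOLD",
    "fit_lick_duration_model",
    "clean_bouts",
    "clean_sessions",
]

#: Residual cutoff in lick-count units.
DEFAULT_RESIDUAL_THRESHOLD = 3.0

Grouping = Literal["global", "per_animal"]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of lick count on lick duration for one group of bouts."""

    slope: float  # licks per second of beam-broken time
    intercept: float  # licks
    residuals: np.ndarray  # per-bout, lick units, input order

    def predict(self, durations: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(durations, dtype=float)


@dataclass(frozen=True)
class CleaningReport:
    n_before: int
    n_after: int
    model_slope: float
    model_intercept: float
    threshold: float
    grouping: str = "global"

    @property
    def fraction_retained(self) -> float:
        return self.n_after / self.n_before if self.n_before else 1.0

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "fraction_retained": self.fraction_retained,
            "model_slope": self.model_slope,
            "model_intercept": self.model_intercept,
            "threshold": self.threshold,
            "grouping": self.grouping,
        }


def _fit_one(durations: np.ndarray, licks: np.ndarray) -> tuple[float, float, np.ndarray]:
    if durations.size < 2:
        raise DegenerateFitError(
            f"need >= 2 bouts to fit the lick-duration model, got {durations.size}"
        )
    if np.ptp(durations) == 0.0:
        raise DegenerateFitError("all lick durations identical; slope not identifiable")
    X = np.column_stack([np.ones_like(durations), durations])
    coef, *_ = np.linalg.lstsq(X, licks, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    residuals = licks - (intercept + slope * durations)
    return slope, intercept, residuals


def fit_lick_duration_model(
    bouts: Sequence[BoutRecord],
    grouping: Grouping = "global",
    animal_ids: Sequence[str] | None = None,
) -> dict[str, LinearFit]:
    """OLS of ``n_licks`` on ``lick_duration``, globally or per animal.

    Returns a mapping group-key → :class:`LinearFit` ("__all__" for the
    global fit).  ``animal_ids`` must align with ``bouts`` when grouping per
    animal.  Degenerate groups (< 2 bouts or constant duration) raise
    :class:`DegenerateFitError`.
    """
    durations = np.array([b.lick_duration for b in bouts], dtype=float)
    licks = np.array([b.n_licks for b in bouts], dtype=float)
    if grouping == "global":
        slope, intercept, resid = _fit_one(durations, licks)
        return {"__all__": LinearFit(slope, intercept, resid)}
    if grouping != "per_animal":
        raise ValueError(f"unknown grouping {grouping!r}")
    if animal_ids is None or len(animal_ids) != len(bouts):
        raise ValueError("per_animal grouping needs animal_ids aligned with bouts")
    ids = np.asarray(animal_ids, dtype=object)
    fits: dict[str, LinearFit] = {}
    for key in dict.fromkeys(ids):  # preserves first-seen order
        mask = ids == key
        slope, intercept, resid = _fit_one(durations[mask], licks[mask])
        fits[str(key)] = LinearFit(slope, intercept, resid)
    return fits


def clean_bouts(
    bouts: Sequence[BoutRecord],
    threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    grouping: Grouping = "global",
    animal_ids: Sequence[str] | None = None,
) -> tuple[list[BoutRecord], CleaningReport]:
    """Drop bouts whose |OLS residual| exceeds ``threshold`` lick units.

    Single pass (no refit after removal); kept bouts preserve input order.
    The report's slope/intercept are the global fit's, or the bout-weighted
    mean across animals under per-animal grouping.
    """
    bouts = list(bouts)
    if not bouts:
        return [], CleaningReport(0, 0, float("nan"), float("nan"), threshold, grouping)
    fits = fit_lick_duration_model(bouts, grouping=grouping, animal_ids=animal_ids)
    if grouping == "global":
        resid = fits["__all__"].residuals
    else:
        ids = np.asarray(animal_ids, dtype=object)
        resid = np.empty(len(bouts))
        for key, fit in fits.items():
            resid[ids == key] = fit.residuals
    keep = np.abs(resid) <= threshold
    kept = [b for b, k in zip(bouts, keep) if k]
    n = np.array([len(f.residuals) for f in fits.values()], dtype=float)
    slope = float(np.average([f.slope for f in fits.values()], weights=n))
    intercept = float(np.average([f.intercept for f in fits.values()], weights=n))
    report = CleaningReport(
        n_before=len(bouts),
        n_after=len(kept),
        model_slope=slope,
        model_intercept=intercept,
        threshold=threshold,
        grouping=grouping,
    )
    return kept, report


def clean_sessions(
    sessions: Sequence[SessionRecord],
    threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    grouping: Grouping = "global",
) -> tuple[list[SessionRecord], CleaningReport]:
    """Clean all bouts pooled across sessions, rebuilding each session.

    Degenerate fits are downgraded to a warning here (pipeline mode): the
    affected bout set is kept untouched.
    """
    flat: list[BoutRecord] = []
    owners: list[int] = []
    ids: list[str] = []
    for i, s in enumerate(sessions):
        for b in s.bouts:
            flat.append(b)
            owners.append(i)
            ids.append(s.animal_id)
    try:
        kept, report = clean_bouts(flat, threshold, grouping, ids)
    except DegenerateFitError as exc:
        warnings.warn(f"cleaning skipped: {exc}", stacklevel=2)
        report = CleaningReport(len(flat), len(flat), float("nan"), float("nan"), threshold, grouping)
        return list(sessions), report
    kept_set = {id(b) for b in kept}
    out = []
    for i, s in enumerate(sessions):
        out.append(s.with_bouts([b for b in s.bouts if id(b) in kept_set]))
    return out, report
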