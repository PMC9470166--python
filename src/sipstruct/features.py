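"""Per-session drinking-microstructure features, intake, and cohort filters.

Each session of bout records is summarized into an 18-feature vector
covering totals (licks, lick duration, bouts), per-bout means and maxima,
timing (latency to first drink, inter-drink intervals), rates, and
front-loading (drinking concentrated in the first 30 min of access).
The registry below is the canonical ordered feature set; it is a module
constant so alternative registries remain drop-in for the classifier.

Conventions for degenerate sessions keep the feature matrix rectangular:
with no bouts all totals/maxima are 0, rates are 0, and latency and both
inter-drink-interval features are imputed to the session length in seconds
(a censored "never drank (again)" value); with a single bout only the
inter-drink intervals are imputed.  The inter-drink interval is measured
from one bout's end to the next bout's start, and a bout belongs to the
first 30 min iff it starts before 1800 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .lickometer import ClassLabel, SessionRecord

__all__ = [
    "FEATURE_NAMES",
    "FRONT_LOAD_WINDOW_S",
    "FeatureVector",
    "IntakeRecord",
    "Densities",
    "extract_features",
    "feature_table",
    "compute_intake",
    "inclusion_filter",
    "intake_microstructure_correlation",
]

#: Start of session → 1800 s window used for front-loading features.
FRONT_LOAD_WINDOW_S = 1800.0

#: The canonical ordered 18-feature registry.
FEATURE_NAMES: tuple[str, ...] = (
    "total_licks",
    "total_lick_duration_s",
    "total_bouts",
    "mean_licks_per_bout",
    "mean_lick_duration_per_bout_s",
    "mean_bout_length_s",
    "latency_to_drink_s",
    "mean_inter_drink_interval_s",
    "max_bout_length_s",
    "max_licks_per_bout",
    "max_lick_duration_per_bout_s",
    "max_inter_drink_interval_s",
    "licks_first_30min",
    "lick_duration_first_30min_s",
    "bouts_first_30min",
    "lick_rate_per_min",
    "bout_rate_per_min",
    "front_loading_index",
)


@dataclass(frozen=True)
class FeatureVector:
    animal_id: str
    session_index: int
    label: ClassLabel
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.features.keys()) != FEATURE_NAMES:
            raise ValidationError(
                f"feature registry mismatch: expected {len(FEATURE_NAMES)} ordered "
                f"features, got {list(self.features.keys())}"
            )
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite features after imputation: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array([self.features[k] for k in FEATURE_NAMES], dtype=float)


def extract_features(session: SessionRecord) -> FeatureVector:
    """Compute the 18-feature microstructure vector for one session."""
    bouts = sorted(session.bouts, key=lambda b: b.start)
    T = session.session_length_s
    minutes = T / 60.0
    n = len(bouts)

    licks = np.array([b.n_licks for b in bouts], dtype=float)
    durs = np.array([b.lick_duration for b in bouts], dtype=float)
    spans = np.array([b.span for b in bouts], dtype=float)
    starts = np.array([b.start for b in bouts], dtype=float)
    ends = np.array([b.end for b in bouts], dtype=float)

    early = starts < FRONT_LOAD_WINDOW_S if n else np.zeros(0, dtype=bool)
    idis = starts[1:] - ends[:-1] if n >= 2 else None

    f: dict[str, float] = {}
    f["total_licks"] = float(licks.sum())
    f["total_lick_duration_s"] = float(durs.sum())
    f["total_bouts"] = float(n)
    f["mean_licks_per_bout"] = float(licks.mean()) if n else 0.0
    f["mean_lick_duration_per_bout_s"] = float(durs.mean()) if n else 0.0
    f["mean_bout_length_s"] = float(spans.mean()) if n else 0.0
    f["latency_to_drink_s"] = float(starts[0]) if n else T
    f["mean_inter_drink_interval_s"] = float(idis.mean()) if idis is not None else T
    f["max_bout_length_s"] = float(spans.max()) if n else 0.0
    f["max_licks_per_bout"] = float(licks.max()) if n else 0.0
    f["max_lick_duration_per_bout_s"] = float(durs.max()) if n else 0.0
    f["max_inter_drink_interval_s"] = float(idis.max()) if idis is not None else T
    f["licks_first_30min"] = float(licks[early].sum()) if n else 0.0
    f["lick_duration_first_30min_s"] = float(durs[early].sum()) if n else 0.0
    f["bouts_first_30min"] = float(early.sum()) if n else 0.0
    f["lick_rate_per_min"] = f["total_licks"] / minutes
    f["bout_rate_per_min"] = n / minutes
    f["front_loading_index"] = f["bouts_first_30min"] / max(n, 1)

    return FeatureVector(
        animal_id=session.animal_id,
        session_index=session.session_index,
        label=session.label,
        features=f,
    )


def feature_table(sessions: Iterable[SessionRecord]) -> pd.DataFrame:
    """Stack per-session feature vectors into a labeled DataFrame."""
    rows = []
    for s in sessions:
        fv = extract_features(s)
        rows.append(
            {"animal_id": fv.animal_id, "session_index": fv.session_index}
            | dict(fv.features)
            | {"fluid": fv.label.fluid, "virus": fv.label.virus}
        )
    cols = ["animal_id", "session_index", *FEATURE_NAMES, "fluid", "virus"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Intake
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Densities:
    """Fluid densities (g/ml) used to convert bottle-weight loss to dose."""

    water: float = 1.000
    ethanol: float = 0.789
    alcohol_solution: float = 0.970  # 20% v/v ethanol in water
    ethanol_fraction_v: float = 0.20  # v/v


@dataclass(frozen=True)
class IntakeRecord:
    grams_consumed: float  # grams of fluid (bottle-weight difference)
    dose_g_per_kg: float  # fluid g/kg for water; ethanol g/kg for alcohol


def compute_intake(
    session: SessionRecord, densities: Densities = Densities()
) -> IntakeRecord:
    """Dose from the bottle-weight difference and fluid density.

    Water: grams of fluid per kg body weight.  Alcohol (20% v/v): the weight
    loss is converted to solution volume via the solution density, 20% of
    that volume is ethanol, and ethanol grams follow from ethanol density.
    """
    if not (session.body_weight_g > 0):
        raise ValidationError(
            f"body weight must be positive, got {session.body_weight_g}"
        )
    dw = session.grams_consumed
    if dw < 0:
        raise ValidationError("negative fluid consumption")
    kg = session.body_weight_g / 1000.0
    if session.fluid == "water":
        dose = dw / kg
    else:
        volume_ml = dw / densities.alcohol_solution
        ethanol_g = volume_ml * densities.ethanol_fraction_v * densities.ethanol
        dose = ethanol_g / kg
    return IntakeRecord(grams_consumed=dw, dose_g_per_kg=dose)


# ---------------------------------------------------------------------------
# Cohort inclusion
# ---------------------------------------------------------------------------


def inclusion_filter(
    summed_intakes: pd.DataFrame,
    min_group: int = 4,
    fence_factor: float = 1.5,
) -> tuple[set[str], set[str]]:
    """Exclude under-drinking animals from each fluid group.

    ``summed_intakes`` has columns ``animal_id, fluid, total_intake`` with
    one row per animal (dose summed over the first 15 sessions).  Within
    each fluid group, animals below the Tukey lower fence
    Q1 − ``fence_factor``·IQR (linear-interpolation quantiles) are excluded.
    Groups smaller than ``min_group`` are kept whole with a warning.
    """
    required = {"animal_id", "fluid", "total_intake"}
    if not required <= set(summed_intakes.columns):
        raise ValidationError(f"summed_intakes needs columns {sorted(required)}")
    included: set[str] = set()
    excluded: set[str] = set()
    for fluid, grp in summed_intakes.groupby("fluid"):
        vals = grp["total_intake"].to_numpy(dtype=float)
        if len(vals) < min_group:
            warnings.warn(
                f"{fluid} group has {len(vals)} animals (< {min_group}); "
                "quartile fence skipped, all included",
                stacklevel=2,
            )
            included |= set(grp["animal_id"].astype(str))
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
        fence = q1 - fence_factor * (q3 - q1)
        low = vals < fence
        excluded |= set(grp.loc[low, "animal_id"].astype(str))
        included |= set(grp.loc[~low, "animal_id"].astype(str))
    return included, excluded


def intake_microstructure_correlation(
    features: pd.DataFrame,
    doses: Sequence[float],
    feature_names: Sequence[str] = ("total_licks", "total_bouts", "total_lick_duration_s"),
) -> pd.DataFrame:
    """Pearson r (and p) between selected features and per-session dose.

    Zero variance in either variable leaves r/p as NaN with ``defined`` False.
    """
    doses = np.asarray(doses, dtype=float)
    if len(doses) != len(features):
        raise ValidationError("doses must align with the feature table rows")
    if len(doses) < 3:
        raise ValidationError("need >= 3 paired observations")
    rows = []
    for name in feature_names:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(doses) == 0.0:
            rows.append({"feature": name, "r": np.nan, "p": np.nan, "defined": False})
            continue
        r, p = stats.pearsonr(x, doses)
        rows.append({"feature": name, "r": float(r), "p": float(p), "defined": True})
    return pd.DataFrame(rows).set_index("feature")
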