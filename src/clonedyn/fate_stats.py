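"""Division-type scoring and renewal-rate estimation.

Epidermal progenitors divide in one of three ways: symmetric renewal
(SR, two basal daughters), asymmetric division (AD, one basal and one
suprabasal daughter), and symmetric differentiation (SD, two suprabasal
daughters).  The renewal rate

    r = f_SR + f_AD / 2

is the proportion of daughter cells that remain basal progenitors;
r = 0.5 corresponds to homeostasis, r > 0.5 to net clonal growth and
r < 0.5 to progenitor loss.  Two estimators are provided: a
division-based one operating on scored doublet events (cell fate
identification / EdU-BrdU pulse-chase assay) and a population-based one
operating on cell tables (EdU+ cells scored for the differentiation
marker K10; renewal = fraction of EdU+ cells that are K10-negative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    EmptySelectionError,
    InsufficientReplicatesError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "Morphology",
    "Context",
    "DaughterFate",
    "DivisionEvent",
    "DivisionType",
    "FateFractions",
    "RenewalEstimate",
    "classify_division",
    "classify_event_table",
    "estimate_fate_fractions",
    "renewal_rate_from_fractions",
    "renewal_rate_population",
    "proliferation_rate",
    "compare_groups",
    "significance_band",
    "bootstrap_ci",
    "bin_week",
]


class Layer(str, Enum):
    BASAL = "basal"
    SUPRABASAL = "suprabasal"


class Morphology(str, Enum):
    CUBOIDAL = "cuboidal"
    SQUAMOUS = "squamous"
    UNKNOWN = "unknown"


class Context(str, Enum):
    """Tissue context of the dividing progenitor."""

    SINGLE_CELL = "single_cell"
    CLONE_EDGE = "clone_edge"
    CLONE_INNER = "clone_inner"
    WT_ADJACENT = "wt_adjacent"
    WT_DISTANT = "wt_distant"
    FIELD = "field"


class DivisionType(str, Enum):
    SR = "SR"  # symmetric renewal: two basal daughters
    AD = "AD"  # asymmetric: one basal, one suprabasal daughter
    SD = "SD"  # symmetric differentiation: two suprabasal daughters


@dataclass(frozen=True)
class DaughterFate:
    """Fate readout of one daughter cell: layer (required) and morphology."""

    layer: Layer
    morphology: Morphology = Morphology.UNKNOWN

    def __post_init__(self) -> None:
        if not isinstance(self.layer, Layer):
            object.__setattr__(self, "layer", Layer(str(self.layer).lower()))
        if not isinstance(self.morphology, Morphology):
            object.__setattr__(
                self, "morphology", Morphology(str(self.morphology).lower())
            )


@dataclass(frozen=True)
class DivisionEvent:
    """One scored progenitor division (an EdU-only doublet)."""

    animal_id: str
    daughter_1: DaughterFate
    daughter_2: DaughterFate
    clone_id: str | None = None
    context: Context = Context.FIELD
    week: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.context, Context):
            object.__setattr__(self, "context", Context(str(self.context).lower()))
        if self.week < 0:
            raise InvalidInputError(f"week must be non-negative, got {self.week}")

    @property
    def division_type(self) -> DivisionType:
        return classify_division(self.daughter_1, self.daughter_2)


@dataclass(frozen=True)
class FateFractions:
    """Frequencies of the three division types over ``n_events`` divisions."""

    f_sr: float
    f_ad: float
    f_sd: float
    n_events: int

    def __post_init__(self) -> None:
        for name, f in (("f_sr", self.f_sr), ("f_ad", self.f_ad), ("f_sd", self.f_sd)):
            if not 0.0 <= f <= 1.0:
                raise InvalidInputError(f"{name}={f} outside [0, 1]")
        if abs(self.f_sr + self.f_ad + self.f_sd - 1.0) > 1e-12:
            raise InvalidInputError(
                f"fractions sum to {self.f_sr + self.f_ad + self.f_sd!r}, expected 1"
            )
        if self.n_events < 1:
            raise InvalidInputError("n_events must be a positive integer")

    @classmethod
    def from_counts(cls, n_sr: int, n_ad: int, n_sd: int) -> "FateFractions":
        n = n_sr + n_ad + n_sd
        if n < 1:
            raise EmptySelectionError("no division events to tally")
        # renormalise exactly so the invariant holds to machine precision
        f_sr, f_ad = n_sr / n, n_ad / n
        return cls(f_sr=f_sr, f_ad=f_ad, f_sd=1.0 - f_sr - f_ad, n_events=n)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_sr, self.f_ad, self.f_sd)


@dataclass(frozen=True)
class RenewalEstimate:
    """A renewal-rate estimate with optional confidence interval."""

    rate: float
    method: str  # "division_based" | "population_based"
    n: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise InvalidInputError(f"rate={self.rate} outside [0, 1]")
        if (self.ci_low is None) != (self.ci_high is None):
            raise InvalidInputError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not self.ci_low <= self.rate <= self.ci_high:  # type: ignore[operator]
                raise InvalidInputError("CI must bracket the point estimate")


def classify_division(d1: DaughterFate, d2: DaughterFate) -> DivisionType:
    """Classify a division from its two daughter fates.

    (basal, basal) -> SR; (suprabasal, suprabasal) -> SD; mixed -> AD.
    Symmetric in argument order.
    """
    for d in (d1, d2):
        if d is None or getattr(d, "layer", None) is None:
            raise InvalidInputError("both daughter fates must have a layer set")
    n_basal = (d1.layer is Layer.BASAL) + (d2.layer is Layer.BASAL)
    if n_basal == 2:
        return DivisionType.SR
    if n_basal == 0:
        return DivisionType.SD
    return DivisionType.AD


_LAYER_NORM = {"basal": "basal", "suprabasal": "suprabasal"}


def classify_event_table(events: pd.DataFrame) -> pd.Series:
    """Vectorised division-type call for an event table.

    Requires columns ``daughter1_layer`` and ``daughter2_layer`` with
    values in {basal, suprabasal} (case-insensitive).
    """
    for col in ("daughter1_layer", "daughter2_layer"):
        if col not in events.columns:
            raise InvalidInputError(f"event table missing column {col!r}")
    l1 = events["daughter1_layer"].astype(str).str.lower()
    l2 = events["daughter2_layer"].astype(str).str.lower()
    bad = ~(l1.isin(_LAYER_NORM) & l2.isin(_LAYER_NORM))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InvalidInputError(
            f"row {row}: unrecognised daughter layer "
            f"({l1.iloc[row]!r}, {l2.iloc[row]!r})"
        )
    n_basal = (l1 == "basal").astype(int) + (l2 == "basal").astype(int)
    return n_basal.map({2: DivisionType.SR.value, 1: DivisionType.AD.value,
                        0: DivisionType.SD.value})


def _events_to_types(
    events: Sequence[DivisionEvent] | pd.DataFrame,
    where: Callable | None = None,
) -> np.ndarray:
    """Normalise events to an array of division-type strings, filtered."""
    if isinstance(events, pd.DataFrame):
        df = events
        if where is not None:
            mask = df.apply(where, axis=1).astype(bool)
            df = df.loc[mask]
        n_in, n_out = len(events), len(df)
        if n_out < n_in:
            logger.info("event filter: %d of %d records retained", n_out, n_in)
        if n_out == 0:
            raise EmptySelectionError("no division events after filtering")
        return classify_event_table(df).to_numpy()
    evs = [e for e in events if where is None or where(e)]
    if len(evs) == 0:
        raise EmptySelectionError("no division events after filtering")
    return np.array([e.division_type.value for e in evs])


def estimate_fate_fractions(
    events: Sequence[DivisionEvent] | pd.DataFrame,
    where: Callable | None = None,
) -> FateFractions:
    """Tally division types into fate fractions.

    ``events`` is a sequence of :class:`DivisionEvent` or an event table
    (DataFrame with daughter-layer columns).  ``where`` is an optional
    per-event / per-row predicate (context, week, genotype ...).
    """
    types = _events_to_types(events, where)
    n_sr = int(np.sum(types == DivisionType.SR.value))
    n_ad = int(np.sum(types == DivisionType.AD.value))
    n_sd = int(np.sum(types == DivisionType.SD.value))
    return FateFractions.from_counts(n_sr, n_ad, n_sd)


def renewal_rate_from_fractions(f: FateFractions) -> RenewalEstimate:
    """Division-based renewal rate r = f_SR + f_AD / 2.

    Equivalently (2 n_SR + n_AD) / (2 n_events): each SR contributes two
    basal daughters, each AD one, each SD none.
    """
    rate = f.f_sr + f.f_ad / 2.0
    return RenewalEstimate(rate=rate, method="division_based", n=f.n_events)


def _as_cell_frame(cells) -> pd.DataFrame:
    if isinstance(cells, pd.DataFrame):
        return cells
    return pd.DataFrame([vars(c) if not isinstance(c, dict) else c for c in cells])


def renewal_rate_population(cells) -> RenewalEstimate:
    """Population-based renewal rate: EdU+/K10- cells out of all EdU+ cells.

    ``cells`` is a cell table (DataFrame or records) with boolean-coercible
    ``edu`` and ``k10`` columns.
    """
    df = _as_cell_frame(cells)
    edu = df["edu"].astype(bool)
    n_edu = int(edu.sum())
    if n_edu == 0:
        raise EmptySelectionError("no EdU+ cells in the table")
    n_progenitor = int((edu & ~df["k10"].astype(bool)).sum())
    return RenewalEstimate(
        rate=n_progenitor / n_edu, method="population_based", n=n_edu
    )


def proliferation_rate(cells, clone_id: str | None = None) -> float:
    """Proportion of EdU+ basal (progenitor) cells within a clone."""
    df = _as_cell_frame(cells)
    if clone_id is not None:
        df = df[df["clone_id"] == clone_id]
    basal = df[df["layer"].astype(str).str.lower() == Layer.BASAL.value]
    if len(basal) == 0:
        raise EmptySelectionError(
            f"clone {clone_id!r} has no basal cells" if clone_id else "no basal cells"
        )
    return float(basal["edu"].astype(bool).mean())


def significance_band(p: float) -> str:
    """Map a p-value to the conventional figure-legend band."""
    if p > 0.05:
        return "n.s."
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    if p >= 0.0001:
        return "***"
    return "****"


def compare_groups(
    values_a: Iterable[float], values_b: Iterable[float]
) -> tuple[float, float, str]:
    """Two-tailed two-sample Student's t-test on per-animal values.

    The unit of replication is the animal: pass one summary value per
    animal, not per event.  Returns ``(t, p, band)``.  Degenerate
    zero-variance input with equal means returns (0, 1, "n.s."); zero
    variance with unequal means is rejected rather than reported as
    p = 0.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"each group needs >=2 animal-level values (got {a.size} and {b.size})"
        )
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0, "n.s."
        raise InvalidInputError(
            "zero within-group variance with unequal means: t-test undefined"
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), significance_band(float(p))


def bootstrap_ci(
    events,
    statistic: Callable,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of an event table.

    ``events`` is resampled with replacement at the event level; the
    statistic receives the resampled object (DataFrame or list).
    Reproducible given ``seed`` (or an explicit generator).
    """
    if rng is None:
        if seed is None:
            raise InvalidInputError("bootstrap_ci requires a seed or rng")
        rng = np.random.default_rng(seed)
    if n_boot < 100:
        logger.warning("n_boot=%d is small; interval will be noisy", n_boot)
    is_frame = isinstance(events, pd.DataFrame)
    n = len(events)
    if n < 2:
        raise InvalidInputError("need at least 2 events to bootstrap")
    reps = np.empty(n_boot, dtype=float)
    events_list = None if is_frame else list(events)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = events.iloc[idx] if is_frame else [events_list[j] for j in idx]
        reps[i] = statistic(sample)
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bin_week(week: float, interval: float = 2.0) -> float:
    """Snap a time point to the nearest sampling interval; ties round down.

    Time courses are sampled on a fixed grid (default every 2 weeks);
    recorded ages are snapped to the nearest grid point.
    """
    if week < 0:
        raise InvalidInputError("week must be non-negative")
    k = math.floor(week / interval + 0.5)
    # ties (exact half-interval) round down
    if math.isclose(week / interval + 0.5, k) and k > 0:
        k -= 1
    return k * interval
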