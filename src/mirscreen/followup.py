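"""Long-term competition assays, dose-response and combination summaries.

In the competition assay, cells carrying a construct of interest (GFP−)
are co-cultured with GFP+ reference cells; the GFP−/GFP+ ratio over time
reports relative fitness.  The condition's ratio trajectory is divided by
the empty-vector trajectory and rescaled to 1 at the first shared
timepoint, so the summary is independent of the initial mixing ratio and
of the absolute number of cells analyzed per timepoint.  A per-day
fitness deficit is recovered as the least-squares slope of −ln(relative
cell number) against days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import ValidationError


@dataclass
class CompetitionSeries:
    """GFP+/GFP− counts (or fractions) over days for one condition."""

    condition: str
    days: np.ndarray
    gfp_pos: np.ndarray
    gfp_neg: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.gfp_pos = np.asarray(self.gfp_pos, dtype=float)
        self.gfp_neg = np.asarray(self.gfp_neg, dtype=float)
        if not (self.days.size == self.gfp_pos.size == self.gfp_neg.size):
            raise ValidationError(f"{self.condition}: mismatched series lengths")
        if self.days.size and np.any(self.days < 0):
            raise ValidationError(f"{self.condition}: negative days")
        if self.days.size > 1 and not np.all(np.diff(self.days) > 0):
            raise ValidationError(f"{self.condition}: timepoints must be strictly increasing")
        if np.any(self.gfp_pos < 0) or np.any(self.gfp_neg < 0):
            raise ValidationError(f"{self.condition}: negative counts")

    def ratio(self) -> np.ndarray:
        """GFP−/GFP+ per timepoint; zero GFP+ gives NaN with a warning."""
        out = np.full(self.days.size, np.nan)
        ok = self.gfp_pos > 0
        if not ok.all():
            warnings.warn(
                f"{self.condition}: zero GFP+ count at {int((~ok).sum())} timepoint(s); "
                "ratio undefined there",
                stacklevel=2,
            )
        out[ok] = self.gfp_neg[ok] / self.gfp_pos[ok]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str) -> "CompetitionSeries":
        sub = df[df["condition"] == condition].sort_values("day")
        if sub.empty:
            raise ValidationError(f"no rows for condition {condition!r}")
        return cls(
            condition,
            sub["day"].to_numpy(),
            sub["gfp_pos"].to_numpy(),
            sub["gfp_neg"].to_numpy(),
        )


def competition_relative(
    series: CompetitionSeries,
    ev: CompetitionSeries,
    normalize_first: bool = True,
) -> pd.DataFrame:
    """Relative cell number of a condition versus the empty-vector culture.

    rel(t) = ratio_condition(t) / ratio_EV(t); with ``normalize_first``
    the curve is rescaled so rel = 1 at the first timepoint with a
    defined value (both behaviours are exposed because either convention
    appears in practice).  EV measured on different days is linearly
    interpolated on the log-ratio scale, with a warning; condition days
    outside the EV range are an error.
    """
    r_cond = series.ratio()
    r_ev = ev.ratio()
    if series.days.size == ev.days.size and np.allclose(series.days, ev.days):
        ev_on_days = r_ev
    else:
        warnings.warn(
            f"{series.condition}: EV days differ; interpolating EV log-ratio",
            stacklevel=2,
        )
        ok = np.isfinite(r_ev) & (r_ev > 0)
        if series.days.min() < ev.days[ok].min() or series.days.max() > ev.days[ok].max():
            raise ValidationError("condition timepoints outside the EV range")
        ev_on_days = np.exp(np.interp(series.days, ev.days[ok], np.log(r_ev[ok])))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = r_cond / ev_on_days
    if normalize_first:
        finite = np.isfinite(rel) & (rel > 0)
        if not finite.any():
            raise ValidationError(f"{series.condition}: no defined relative values")
        rel = rel / rel[np.argmax(finite)]
    return pd.DataFrame({"day": series.days, "relative_cell_number": rel})


@dataclass
class FitnessDeficit:
    """Per-day fitness deficit with its regression standard error."""

    rate_per_day: float
    stderr: float
    n_points: int
    r_squared: float


def fitness_deficit(rel: pd.DataFrame | None = None, *, days=None, values=None) -> FitnessDeficit:
    """Least-squares slope of −ln(relative cell number) against days.

    Accepts either the frame produced by :func:`competition_relative` or
    explicit ``days``/``values`` arrays.  Requires at least three defined
    timepoints with positive relative values.
    """
    if rel is not None:
        days = rel["day"].to_numpy()
        values = rel["relative_cell_number"].to_numpy()
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & (values > 0) & np.isfinite(days)
    days, values = days[ok], values[ok]
    if days.size < 3:
        raise ValidationError("fitness_deficit needs >= 3 defined timepoints")
    res = linregress(days, -np.log(values))
    return FitnessDeficit(
        rate_per_day=float(res.slope),
        stderr=float(res.stderr),
        n_points=int(days.size),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class DoseResponseSeries:
    """Viability fractions (relative to mock) across mimic concentrations."""

    rna_species: str
    concentrations: np.ndarray
    viability: np.ndarray
    sd: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        if np.any(self.concentrations <= 0):
            raise ValidationError(f"{self.rna_species}: concentrations must be > 0")
        if self.concentrations.size > 1 and not np.all(np.diff(self.concentrations) > 0):
            raise ValidationError(f"{self.rna_species}: concentrations must be increasing")
        if np.any(self.viability < 0):
            raise ValidationError(f"{self.rna_species}: negative viability fraction")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.rna_species,
                "conc_nM": self.concentrations,
                "viability": self.viability,
                "sd": self.sd,
                "n": self.n_replicates,
            }
        )


def normalize_dose_response(
    raw: pd.DataFrame, mock_value: float, species: str | None = None
) -> DoseResponseSeries:
    """Scale raw per-concentration readouts to fractions of the mock control.

    ``raw`` has columns ``conc_nM`` and ``raw_value`` (one row per
    replicate, optionally a ``species`` column to select from).  The
    replicate standard deviation is carried through on the same relative
    scale.
    """
    if mock_value <= 0:
        raise ValidationError("mock readout must be > 0")
    df = raw
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
        if df.empty:
            raise ValidationError(f"no rows for species {species!r}")
    name = species if species is not None else str(df["species"].iloc[0]) if "species" in df.columns else "series"
    grouped = df.groupby("conc_nM")["raw_value"]
    concs = np.array(sorted(grouped.groups))
    means = grouped.mean().loc[concs].to_numpy() / mock_value
    sds = grouped.std(ddof=1).loc[concs].fillna(0.0).to_numpy() / mock_value
    ns = grouped.count().loc[concs].to_numpy()
    return DoseResponseSeries(name, concs, means, sds, ns)


def minimal_effective_concentration(
    series: DoseResponseSeries,
    reference: DoseResponseSeries,
    margin: float = 0.10,
) -> float | None:
    """Smallest tested concentration with viability below reference − margin.

    The default margin of 0.10 (ten percentage points of relative
    viability) marks an effect clearly outside replicate noise; returns
    None when the series never undercuts the reference by the margin.
    """
    if series.concentrations.size != reference.concentrations.size or not np.allclose(
        series.concentrations, reference.concentrations
    ):
        raise ValidationError("series and reference must share the concentration grid")
    below = series.viability < reference.viability - margin
    if not below.any():
        return None
    return float(series.concentrations[np.argmax(below)])


def combination_effect(
    combo: float,
    single_a: float,
    single_b: float,
    combo_sd: float = 0.0,
    single_a_sd: float = 0.0,
    single_b_sd: float = 0.0,
) -> tuple[float, float]:
    """Additional viability decrease of a two-mimic combination.

    Returns ``min(single_a, single_b) − combo`` — how much further the
    combination pushes viability down compared with the better single
    mimic — with the standard deviation propagated from the combination
    and the better single.
    """
    if single_a <= single_b:
        best, best_sd = single_a, single_a_sd
    else:
        best, best_sd = single_b, single_b_sd
    effect = best - combo
    sd = float(np.hypot(combo_sd, best_sd))
    return float(effect), sd
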