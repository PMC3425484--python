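"""Per-plate B-score normalization, empirical FDR and primary hit selection.

The B-score used here is the robust per-plate standardized score

    B = (X - median) / MAD,

where the median and the MAD (median absolute deviation, *unscaled*: no
1.4826 consistency factor) are computed over all usable wells of the
plate.  Replicate plates are normalized separately and then averaged per
construct; raw values are never pooled across plates.

The empirical false-discovery rate at a cutoff t compares the observed
number of constructs with mean B <= t against the count expected for
standard-normal data.  For the mean of k independent B-scores of normal
data, P(mean B <= t) = Phi(t * c * sqrt(k)) with c = 0.67449, the MAD of
a standard normal.  The constant refers to the large-plate limit; on
60-well plates the estimated median/MAD make the realized null tail
somewhat heavier (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .plate_io import ASSAYS, PlateGrid

#: MAD of the standard normal distribution, Phi^-1(3/4).
NORMAL_MAD = 0.67449


def mad(values: Sequence[float]) -> float:
    """Median absolute deviation, unscaled.

    Median of |x - median(x)|.  Even-length medians use the midpoint
    (average of the two central order statistics) for both the location
    and the deviations.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("mad() of an empty list")
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)))


def bscore_plate(plate: PlateGrid) -> dict[str, float]:
    """B-score every construct-bearing usable well of one plate.

    The plate median and MAD are computed over *all* usable wells
    (samples and on-plate controls alike).  A plate whose MAD is zero has
    no usable scale; every score is returned as NaN with a warning rather
    than an infinity.
    """
    usable = plate.usable_wells()
    if len(usable) < 2:
        raise ValidationError(
            f"plate {plate.plate_id}: need >= 2 usable wells to normalize"
        )
    values = np.array([w.value for w in usable], dtype=float)
    med = float(np.median(values))
    scale = mad(values)
    scored = [w for w in usable if w.construct_id is not None]
    if scale == 0.0:
        warnings.warn(
            f"plate {plate.plate_id}: MAD is 0, B-scores undefined",
            stacklevel=2,
        )
        return {w.construct_id: float("nan") for w in scored}
    return {w.construct_id: (w.value - med) / scale for w in scored}


def intraplate_bias_report(plate: PlateGrid) -> pd.DataFrame:
    """Row/column bias diagnostic: median deviations in plate-MAD units.

    For each row and each column with usable wells, reports the median of
    that lane minus the plate median, divided by the plate MAD.  Purely
    diagnostic — no correction is applied downstream.
    """
    usable = plate.usable_wells()
    rows = {w.row for w in usable}
    cols = {w.col for w in usable}
    if len(rows) < 2 or len(cols) < 2:
        raise ValidationError(
            f"plate {plate.plate_id}: bias report needs >= 2 usable rows and columns"
        )
    values = np.array([w.value for w in usable], dtype=float)
    med = float(np.median(values))
    scale = mad(values)
    out = []
    for kind, key in (("row", lambda w: w.row), ("col", lambda w: w.col)):
        for label in sorted({key(w) for w in usable}, key=str):
            lane = [w.value for w in usable if key(w) == label]
            dev = float(np.median(lane)) - med
            out.append(
                {
                    "kind": kind,
                    "label": str(label),
                    "n_wells": len(lane),
                    "deviation_mad": dev / scale if scale > 0 else float("nan"),
                }
            )
    return pd.DataFrame(out, columns=["kind", "label", "n_wells", "deviation_mad"])


class BScoreTable:
    """Replicate and mean B-scores per construct and assay.

    Undefined scores (from MAD-0 plates or missing replicates) are stored
    as NaN; the per-construct mean is taken over the defined replicates
    and a construct with no defined replicate is flagged undefined.
    """

    def __init__(self) -> None:
        self._records: dict[tuple[str, str], list[float]] = {}

    def add_replicate(self, construct_id: str, assay: str, bscore: float) -> None:
        if assay not in ASSAYS:
            raise ValidationError(f"unknown assay {assay!r}")
        self._records.setdefault((construct_id, assay), []).append(float(bscore))

    def add_plate_scores(self, assay: str, scores: Mapping[str, float]) -> None:
        for cid, b in scores.items():
            self.add_replicate(cid, assay, b)

    def constructs(self, assay: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for cid, a in self._records:
            if assay is None or a == assay:
                seen.setdefault(cid)
        return list(seen)

    def replicates(self, construct_id: str, assay: str) -> list[float]:
        return list(self._records.get((construct_id, assay), []))

    def n_replicates(self, construct_id: str, assay: str) -> int:
        return len(self._records.get((construct_id, assay), []))

    def has(self, construct_id: str, assay: str) -> bool:
        return (construct_id, assay) in self._records

    def is_undefined(self, construct_id: str, assay: str) -> bool:
        reps = self._records.get((construct_id, assay), [])
        return len(reps) == 0 or all(math.isnan(r) for r in reps)

    def mean_bscore(self, construct_id: str, assay: str) -> float:
        reps = [r for r in self._records.get((construct_id, assay), []) if not math.isnan(r)]
        if not reps:
            return float("nan")
        return float(np.mean(reps))

    def means(self, assay: str) -> pd.Series:
        idx = self.constructs(assay)
        return pd.Series(
            [self.mean_bscore(c, assay) for c in idx], index=idx, name=f"{assay}_mean_b"
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per construct, replicate columns per assay."""
        constructs = self.constructs()
        max_reps = {
            a: max((self.n_replicates(c, a) for c in constructs), default=0)
            for a in ASSAYS
        }
        rows = []
        for c in constructs:
            row: dict[str, object] = {"construct_id": c}
            for a in ASSAYS:
                reps = self.replicates(c, a)
                for i in range(max_reps[a]):
                    row[f"{a}_rep{i + 1}"] = reps[i] if i < len(reps) else float("nan")
                if max_reps[a]:
                    row[f"{a}_mean"] = self.mean_bscore(c, a)
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def __len__(self) -> int:
        return len(self._records)


def bscore_tables(plates: Iterable[PlateGrid]) -> BScoreTable:
    """Normalize every plate and collect replicate scores into one table."""
    table = BScoreTable()
    for plate in plates:
        table.add_plate_scores(plate.assay, bscore_plate(plate))
    return table


def null_tail_probability(t: float, k: int = 2, c: float = NORMAL_MAD) -> float:
    """P(mean of k B-scores <= t) for standard-normal well data.

    A single B-score of normal data is approximately Z/c with Z standard
    normal, so the mean of k independent replicates falls below t with
    probability Phi(t * c * sqrt(k)).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    return float(norm.cdf(t * c * math.sqrt(k)))


@dataclass
class FdrCurve:
    """Observed vs expected hit counts over a grid of B-score cutoffs."""

    thresholds: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    fdr: np.ndarray
    n_tested: int
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed": self.observed,
                "expected": self.expected,
                "fdr": self.fdr,
            }
        )

    def expected_at(self, t: float) -> float:
        return self.n_tested * null_tail_probability(t, self.k)

    def fdr_at(self, t: float) -> float:
        obs = int(np.sum(~np.isnan(self._means) & (self._means <= t)))
        if obs == 0:
            return float("nan")
        return min(1.0, self.expected_at(t) / obs)

    _means: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def fdr_curve(
    table: BScoreTable,
    assay: str,
    thresholds: Sequence[float],
    k: int | None = None,
) -> FdrCurve:
    """Empirical FDR curve: expected null hits / observed hits per cutoff.

    ``k`` is the number of replicates entering each construct's mean
    (defaults to the modal replicate count in the table).  The expected
    count is ``N * Phi(t * c * sqrt(k))`` with N the number of constructs
    carrying a defined mean.  The FDR is capped at 1; cutoffs with zero
    observed hits yield NaN (not applicable) rather than 0/0.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0:
        raise ValidationError("empty threshold list")
    if np.any(thr >= 0):
        raise ValidationError("thresholds must be negative B-score cutoffs")
    if thr.size > 1 and not np.all(np.diff(thr) < 0):
        raise ValidationError("thresholds must be strictly decreasing")

    constructs = table.constructs(assay)
    if not constructs:
        raise ValidationError(f"no constructs with assay {assay!r}")
    means = np.array([table.mean_bscore(c, assay) for c in constructs])
    defined = ~np.isnan(means)
    n_tested = int(defined.sum())
    if k is None:
        rep_counts = [table.n_replicates(c, assay) for c in constructs]
        k = int(np.bincount(rep_counts).argmax())
        k = max(k, 1)

    observed = np.array([np.sum(means[defined] <= t) for t in thr], dtype=int)
    expected = np.array([n_tested * null_tail_probability(t, k) for t in thr])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, np.minimum(1.0, expected / observed), np.nan)
    curve = FdrCurve(thr, observed, expected, fdr, n_tested, k)
    curve._means = means[defined]
    return curve


@dataclass
class PrimaryHitCriteria:
    """Cutoffs of the three primary-screen selection branches.

    Branch A selects on the mean viability B-score alone (reaching the
    cutoff counts, i.e. ``<=``).  Branch B requires a milder viability
    score together with a strong cell-count score (both strict ``<`` as
    printed).  Branch C pairs the milder viability cutoff with a low
    virus titer flag supplied externally.
    """

    rule_a_viability_mean: float = -3.0
    rule_b_viability: float = -2.0
    rule_b_count: float = -3.0
    rule_c_viability: float = -2.0

    def __post_init__(self) -> None:
        for name in (
            "rule_a_viability_mean",
            "rule_b_viability",
            "rule_b_count",
            "rule_c_viability",
        ):
            if getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be negative")

    def to_dict(self) -> dict:
        return {
            "rule_a_viability_mean": self.rule_a_viability_mean,
            "rule_b_viability": self.rule_b_viability,
            "rule_b_count": self.rule_b_count,
            "rule_c_viability": self.rule_c_viability,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PrimaryHitCriteria":
        return cls(**dict(d))


@dataclass
class HitCallSet:
    """Selected constructs with the rule branch(es) that selected each."""

    hits: dict[str, tuple[str, ...]]
    criteria: PrimaryHitCriteria
    n_tested: int

    def construct_ids(self) -> list[str]:
        return list(self.hits)

    def via(self, branch: str) -> list[str]:
        return [c for c, rules in self.hits.items() if branch in rules]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "construct_id": c,
                "rule_a": "A" in rules,
                "rule_b": "B" in rules,
                "rule_c": "C" in rules,
                "rules": "+".join(rules),
            }
            for c, rules in self.hits.items()
        ]
        return pd.DataFrame(
            rows, columns=["construct_id", "rule_a", "rule_b", "rule_c", "rules"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.hits)


def select_primary_hits(
    viability: BScoreTable,
    count: BScoreTable,
    low_titer: set[str] | frozenset[str] = frozenset(),
    criteria: PrimaryHitCriteria | None = None,
) -> HitCallSet:
    """Apply the three primary selection branches to mean B-scores.

    A construct is selected iff
      A: mean viability B <= rule_a cutoff, or
      B: mean viability B < rule_b viability cutoff and
         mean cell-count B < rule_b count cutoff, or
      C: mean viability B < rule_c cutoff and the construct is flagged
         low-titer.
    Constructs absent from the viability table are skipped with a
    warning.  Every satisfied branch is recorded.
    """
    if criteria is None:
        criteria = PrimaryHitCriteria()
    hits: dict[str, tuple[str, ...]] = {}
    viab_constructs = viability.constructs("viability")
    count_means = {c: count.mean_bscore(c, "cell_count") for c in count.constructs("cell_count")}
    universe = list(viab_constructs)
    for c in count_means:
        if not viability.has(c, "viability"):
            warnings.warn(
                f"construct {c} missing from viability table; skipped", stacklevel=2
            )
    for cid in universe:
        v = viability.mean_bscore(cid, "viability")
        if math.isnan(v):
            continue
        n = count_means.get(cid, float("nan"))
        rules = []
        if v <= criteria.rule_a_viability_mean:
            rules.append("A")
        if v < criteria.rule_b_viability and not math.isnan(n) and n < criteria.rule_b_count:
            rules.append("B")
        if v < criteria.rule_c_viability and cid in low_titer:
            rules.append("C")
        if rules:
            hits[cid] = tuple(rules)
    return HitCallSet(hits, criteria, n_tested=len(universe))
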