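"""Second-round screen analysis: gating candidates against control populations.

Candidates that scored in the primary screen are re-tested alongside two
reference populations: individually prepared empty-vector samples and a
set of neutral miRNAs with little or no effect in the primary screen.
Two gates are applied to each candidate's mean readout:

* the 95% gate — the candidate mean is lower than at least
  ``ceil(0.95 * n_controls)`` of the individual neutral-control values;
* the all gate — the candidate mean is strictly below the minimum
  control value.

Candidates passing the all gate form the stringent set.  The expected
number of *null* candidates passing the all gate follows from ranks: a
null readout falls below the minimum of n exchangeable controls with
probability 1/(n+1), so expected = n_candidates/(n_controls+1) and the
within-set FDR is expected / |stringent set|, capped at 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError


@dataclass
class ConfirmationDataset:
    """Readouts of candidates and the two control populations."""

    candidates: dict[str, list[float]]
    empty_vectors: list[float]
    control_mirnas: list[float]
    assay: str = "viability"

    def __post_init__(self) -> None:
        if not self.empty_vectors or not self.control_mirnas:
            raise ValidationError("control populations must be non-empty")
        for name, vals in (
            ("empty_vectors", self.empty_vectors),
            ("control_mirnas", self.control_mirnas),
        ):
            if any(v <= 0 for v in vals):
                raise ValidationError(f"{name}: readouts must be positive")
        for cid, vals in self.candidates.items():
            if any(v <= 0 for v in vals):
                raise ValidationError(f"candidate {cid}: readouts must be positive")

    @classmethod
    def from_csv(cls, path, assay: str = "viability") -> "ConfirmationDataset":
        """Read the long CSV ``construct_id,group,replicate,value``."""
        df = pd.read_csv(path)
        need = {"construct_id", "group", "value"}
        if not need <= set(df.columns):
            raise ValidationError(f"confirmation CSV missing columns {sorted(need - set(df.columns))}")
        candidates: dict[str, list[float]] = {}
        ev: list[float] = []
        ctrl: list[float] = []
        for rec in df.itertuples(index=False):
            g = str(rec.group)
            v = float(rec.value)
            if g == "candidate":
                candidates.setdefault(str(rec.construct_id), []).append(v)
            elif g == "empty_vector":
                ev.append(v)
            elif g == "control_mirna":
                ctrl.append(v)
            else:
                raise ValidationError(f"unknown group {g!r} in confirmation CSV")
        return cls(candidates, ev, ctrl, assay=assay)


@dataclass
class ConfirmationResult:
    """Gate outcomes, within-set FDR and group comparisons."""

    per_candidate: pd.DataFrame
    stringent_set: list[str]
    n_candidates: int
    n_controls: int
    within_set_expected: float
    within_set_fdr: float
    group_pvalues: pd.DataFrame
    n_pass_95: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_pass_95 = int(self.per_candidate["passes_95"].sum())

    def write(self, path) -> None:
        self.per_candidate.to_csv(path, sep="\t", index=False, float_format="%.6g")


def gate_95_required(n_controls: int) -> int:
    """Number of controls a candidate must undercut to pass the 95% gate."""
    return math.ceil(0.95 * n_controls)


def within_set_fdr(n_candidates: int, n_controls: int, n_stringent: int) -> float:
    """Rank-based FDR within the stringent (all-gate) set.

    Expected null passes = n_candidates/(n_controls+1); FDR = expected /
    n_stringent, capped at 1.  NaN when the stringent set is empty.
    """
    if n_stringent <= 0:
        return float("nan")
    expected = n_candidates / (n_controls + 1)
    return min(1.0, expected / n_stringent)


def compare_groups(data: ConfirmationDataset) -> pd.DataFrame:
    """Two-sided rank-sum comparison of each pair of populations.

    Candidates enter as their per-candidate means (one value per
    candidate); the control populations enter as raw values.  Fully tied
    comparisons return p = 1 with a warning.
    """
    cand_means = [float(np.mean(v)) for v in data.candidates.values() if v]
    groups = {
        "candidates": cand_means,
        "empty_vectors": list(data.empty_vectors),
        "control_mirnas": list(data.control_mirnas),
    }
    pairs = [
        ("candidates", "empty_vectors"),
        ("candidates", "control_mirnas"),
        ("control_mirnas", "empty_vectors"),
    ]
    rows = []
    for a, b in pairs:
        x, y = groups[a], groups[b]
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(f"group comparison {a} vs {b}: need >= 2 values per group")
        if len(set(x) | set(y)) == 1:
            warnings.warn(f"{a} vs {b}: all values tied; p = 1", stacklevel=2)
            stat, p = float(len(x) * len(y) / 2), 1.0
        else:
            res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])


def gate_candidates(data: ConfirmationDataset) -> ConfirmationResult:
    """Evaluate both gates for every candidate and estimate the within-set FDR.

    Each candidate is summarized by the mean of its replicates before
    gating.  Both gates use strict inequality against individual control
    values, so a candidate tied with the control minimum fails the all
    gate.  Candidates with no readouts are excluded with a warning.
    """
    controls = np.asarray(data.control_mirnas, dtype=float)
    n_controls = controls.size
    need_95 = gate_95_required(n_controls)
    rows = []
    n_candidates = 0
    for cid, vals in data.candidates.items():
        if not vals:
            warnings.warn(f"candidate {cid} has no readouts; excluded", stacklevel=2)
            continue
        n_candidates += 1
        mean = float(np.mean(vals))
        n_below = int(np.sum(mean < controls))
        p95 = n_below >= need_95
        pall = mean < float(controls.min())
        rows.append(
            {
                "construct_id": cid,
                "mean_readout": mean,
                "n_replicates": len(vals),
                "n_controls_above": n_below,
                "passes_95": p95,
                "passes_all": pall,
            }
        )
    per_candidate = pd.DataFrame(
        rows,
        columns=[
            "construct_id",
            "mean_readout",
            "n_replicates",
            "n_controls_above",
            "passes_95",
            "passes_all",
        ],
    )
    stringent = per_candidate.loc[per_candidate["passes_all"], "construct_id"].tolist()
    expected = n_candidates / (n_controls + 1)
    fdr = within_set_fdr(n_candidates, n_controls, len(stringent))
    try:
        pvalues = compare_groups(data)
    except ValidationError as exc:
        warnings.warn(f"group comparison skipped: {exc}", stacklevel=2)
        pvalues = pd.DataFrame(columns=["group_a", "group_b", "statistic", "p_value"])
    return ConfirmationResult(
        per_candidate=per_candidate,
        stringent_set=stringent,
        n_candidates=n_candidates,
        n_controls=n_controls,
        within_set_expected=expected,
        within_set_fdr=fdr,
        group_pvalues=pvalues,
    )
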