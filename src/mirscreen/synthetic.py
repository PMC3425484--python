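"""Synthetic screen, competition, qPCR and expression data with known truth.

The screen generator emulates a 1,072-construct arrayed duplicate screen
on 96-well plates with edge wells excluded (60 usable wells per plate):
plate-to-plate scale and offset effects, multiplicative well noise,
a construct-level latent effect shared (with configurable correlation)
between the viability and cell-count readouts, and a planted subset of
inhibitor constructs that reduce the expected signal by a fractional
effect size delta.  Well signal:

    value = base * (plate_scale * (1 - delta) * effect * noise + plate_offset)

with ``plate_scale`` log-normal around 1, ``plate_offset`` normal around
0 (per plate), ``effect`` the shared construct latent (log-normal, mean
1) and ``noise`` mean-1 multiplicative well noise (log-normal by
default; a Gaussian option exists for calibration against normal-theory
nulls).  All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SizingError, ValidationError
from .expression import ExpressionTable, QpcrRecord
from .followup import CompetitionSeries
from .plate_io import ExclusionMask, PlateGrid, WellRecord, parse_well

BASE_SIGNAL = {"viability": 1.0, "cell_count": 1000.0}


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s = _lognormal_sigma(cv)
    return np.exp(rng.standard_normal(size) * s - s * s / 2.0)


@dataclass(frozen=True)
class EffectModel:
    """Distribution of the fractional viability reduction of inhibitors."""

    kind: str = "uniform"
    low: float = 0.4
    high: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "fixed"):
            raise ValidationError(f"unknown effect model {self.kind!r}")
        if not (0 < self.low <= 1) or not (0 < self.high <= 1) or self.low > self.high:
            raise ValidationError("effect sizes must satisfy 0 < low <= high <= 1")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.low)
        return rng.uniform(self.low, self.high, n)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "low": self.low, "high": self.high}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectModel":
        return cls(**dict(d))


@dataclass
class ScreenSimConfig:
    """Study conditions of a simulated arrayed duplicate screen.

    Defaults mirror the screen being emulated: 1,072 constructs (650
    annotated plus 422 candidate miRNAs), duplicate plates for each of
    two correlated readouts, 60 usable wells per 96-well plate after edge
    exclusion.  Noise magnitudes are calibration knobs (the original
    screen reports none); the defaults are typical of arrayed viability
    screens: ~10% plate-scale spread, ~10% well-level CV and a ~5%
    construct-level biological effect shared between assays.
    """

    n_constructs: int = 1072
    n_inhibitors: int = 50
    effect_model: EffectModel = field(default_factory=EffectModel)
    plate_capacity: int = 60
    n_replicates: int = 2
    plate_scale_sd: float = 0.10
    plate_offset_sd: float = 0.01
    well_noise_cv: float = 0.10
    construct_effect_cv: float = 0.05
    assay_correlation: float = 0.8
    control_fraction: float = 0.05
    low_titer_fraction: float = 0.02
    noise_model: str = "lognormal"
    n_plates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.effect_model, Mapping):
            self.effect_model = EffectModel.from_dict(self.effect_model)
        if self.n_inhibitors > self.n_constructs:
            raise ValidationError("n_inhibitors must be <= n_constructs")
        if self.n_constructs < 1 or self.n_replicates < 1:
            raise ValidationError("n_constructs and n_replicates must be >= 1")
        for name in ("plate_scale_sd", "plate_offset_sd", "well_noise_cv", "construct_effect_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.assay_correlation <= 1:
            raise ValidationError("assay_correlation must be in (0, 1]")
        if not 0 <= self.control_fraction < 1:
            raise ValidationError("control_fraction must be in [0, 1)")
        if not 0 <= self.low_titer_fraction <= 1:
            raise ValidationError("low_titer_fraction must be in [0, 1]")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.plate_capacity < 2:
            raise ValidationError("plate_capacity must be >= 2")

    # -- layout ---------------------------------------------------------
    @property
    def n_controls_per_plate(self) -> int:
        return int(self.control_fraction * self.plate_capacity)

    @property
    def samples_per_plate(self) -> int:
        n = self.plate_capacity - self.n_controls_per_plate
        if n < 1:
            raise SizingError("no sample wells left after controls")
        return n

    @property
    def plates_needed(self) -> int:
        return math.ceil(self.n_constructs / self.samples_per_plate)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["effect_model"] = self.effect_model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenSimConfig":
        return cls(**dict(d))


@dataclass
class TruthTable:
    """Planted ground truth: per construct, inhibitor status, effect size
    and the low-titer flag."""

    records: pd.DataFrame  # construct_id, is_inhibitor, delta, low_titer

    def __post_init__(self) -> None:
        if self.records["construct_id"].duplicated().any():
            raise ValidationError("duplicate construct in truth table")
        non_inh = ~self.records["is_inhibitor"]
        if (self.records.loc[non_inh, "delta"] != 0).any():
            raise ValidationError("non-inhibitors must have delta = 0")

    def inhibitors(self) -> list[str]:
        return self.records.loc[self.records["is_inhibitor"], "construct_id"].tolist()

    def low_titer_set(self) -> set[str]:
        return set(self.records.loc[self.records["low_titer"], "construct_id"])

    def delta_of(self, construct_id: str) -> float:
        row = self.records.loc[self.records["construct_id"] == construct_id, "delta"]
        if row.empty:
            raise ValidationError(f"unknown construct {construct_id}")
        return float(row.iloc[0])

    def construct_ids(self) -> list[str]:
        return self.records["construct_id"].tolist()

    def to_json(self, path) -> None:
        payload = self.records.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(pd.DataFrame(json.load(fh)))

    def __len__(self) -> int:
        return len(self.records)


def generate_screen(
    config: ScreenSimConfig,
) -> tuple[list[PlateGrid], TruthTable]:
    """Simulate the full duplicate two-assay screen.

    Constructs are laid out plate by plate in id order (duplicates land
    on distinct plates because every assay x replicate gets its own
    physical plates).  Control wells (empty vector) occupy the first
    wells of each plate; leftover wells on the last plate are blanks.
    Returns all plates (both assays, all replicates) plus the truth
    table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_constructs

    mask = ExclusionMask.default_edge()
    usable_names = mask.usable_wells()
    if config.plate_capacity > len(usable_names):
        raise SizingError(
            f"plate_capacity {config.plate_capacity} exceeds {len(usable_names)} usable wells"
        )
    usable_names = usable_names[: config.plate_capacity]
    per_plate = config.samples_per_plate
    n_plates = config.plates_needed
    if config.n_plates is not None:
        if config.n_plates < n_plates:
            raise SizingError(
                f"{n} constructs do not fit on {config.n_plates} plates of "
                f"{per_plate} sample wells"
            )
        n_plates = config.n_plates

    ids = [f"mir{i:04d}" for i in range(1, n + 1)]
    deltas = np.zeros(n)
    is_inh = np.zeros(n, dtype=bool)
    if config.n_inhibitors:
        inh_idx = rng.choice(n, size=config.n_inhibitors, replace=False)
        is_inh[inh_idx] = True
        deltas[inh_idx] = config.effect_model.draw(rng, config.n_inhibitors)
    low_titer = rng.random(n) < config.low_titer_fraction

    # construct-level latent effect, correlated between the two assays
    rho = config.assay_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(n)
    s_b = _lognormal_sigma(config.construct_effect_cv)
    effect = {
        "viability": np.exp(z1 * s_b - s_b * s_b / 2),
        "cell_count": np.exp(z2 * s_b - s_b * s_b / 2),
    }

    truth = TruthTable(
        pd.DataFrame(
            {
                "construct_id": ids,
                "is_inhibitor": is_inh,
                "delta": deltas,
                "low_titer": low_titer,
            }
        )
    )

    plates: list[PlateGrid] = []
    n_ctrl = config.n_controls_per_plate
    for assay in ("viability", "cell_count"):
        base = BASE_SIGNAL[assay]
        for rep in range(1, config.n_replicates + 1):
            for p in range(n_plates):
                lo = p * per_plate
                hi = min(lo + per_plate, n)
                idx = np.arange(lo, hi)
                n_samples = idx.size
                n_wells = n_ctrl + n_samples

                scale = (
                    math.exp(rng.normal(0.0, config.plate_scale_sd))
                    if config.plate_scale_sd
                    else 1.0
                )
                offset = (
                    rng.normal(0.0, config.plate_offset_sd)
                    if config.plate_offset_sd
                    else 0.0
                )
                mult = np.ones(n_wells)
                mult[n_ctrl:] = (1.0 - deltas[idx]) * effect[assay][idx]
                if config.noise_model == "lognormal":
                    noise = _mean_one_lognormal(rng, config.well_noise_cv, n_wells)
                else:
                    noise = 1.0 + rng.standard_normal(n_wells) * config.well_noise_cv
                signal = np.maximum(scale * mult * noise + offset, 0.0) * base
                if assay == "cell_count":
                    signal = np.rint(signal)

                plate = PlateGrid(f"{assay}-r{rep}-p{p + 1:02d}", assay, rep)
                for r in "ABCDEFGH":
                    for c in range(1, 13):
                        if mask.excludes(r, c):
                            plate.add_well(WellRecord(r, c, "excluded_edge", None, 0.0))
                for w, name in enumerate(usable_names):
                    r, c = parse_well(name)
                    if w < n_ctrl:
                        plate.add_well(
                            WellRecord(r, c, "empty_vector", None, float(signal[w]))
                        )
                    elif w < n_wells:
                        cid = ids[lo + (w - n_ctrl)]
                        plate.add_well(
                            WellRecord(r, c, "sample", cid, float(signal[w]))
                        )
                    else:
                        plate.add_well(WellRecord(r, c, "blank", None, 0.0))
                plates.append(plate)
    return plates, truth


def generate_competition(
    r_deficit_per_day: float,
    days: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    initial_ratio: float = 1.0,
    cells_analyzed: int = 10_000,
    condition: str = "condition",
) -> tuple[CompetitionSeries, CompetitionSeries]:
    """Simulate a condition + empty-vector competition series pair.

    The condition's expected GFP−/GFP+ ratio decays as
    ``initial_ratio * exp(-r_deficit * t)`` while the empty-vector ratio
    stays at ``initial_ratio``; multiplicative log-normal noise with CV
    ``noise_cv`` is applied to each measured ratio.
    """
    days_arr = np.asarray(days, dtype=float)
    if days_arr.size == 0 or days_arr[0] != 0:
        raise ValidationError("days must start at 0")
    if np.any(days_arr < 0):
        raise ValidationError("negative days")
    if days_arr.size > 1 and not np.all(np.diff(days_arr) > 0):
        raise ValidationError("days must be strictly increasing")
    rng = np.random.default_rng(seed)
    gfp_pos = np.full(days_arr.size, cells_analyzed / 2.0)

    def series(name: str, rate: float) -> CompetitionSeries:
        ratio = initial_ratio * np.exp(-rate * days_arr)
        ratio = ratio * _mean_one_lognormal(rng, noise_cv, days_arr.size)
        return CompetitionSeries(name, days_arr.copy(), gfp_pos.copy(), gfp_pos * ratio)

    return series(condition, r_deficit_per_day), series("EV", 0.0)


def generate_expression_table(
    n_genes: int = 5000,
    n_targets: int = 100,
    repression_factor: float = 0.3,
    dispersion: float = 0.05,
    library_sizes: tuple[int, int] = (2_000_000, 2_000_000),
    seed: int = 0,
) -> ExpressionTable:
    """Simulate control/treated RNA-seq counts with repressed target genes.

    Gene abundances follow a log-normal distribution; counts are negative
    binomial with the given dispersion (var = mu + dispersion * mu^2).
    Target-flagged genes have their treated-sample mean multiplied by
    ``repression_factor``; the flags themselves are the planted truth.
    """
    if not 0 < repression_factor <= 1:
        raise ValidationError("repression_factor must be in (0, 1]")
    if n_targets > n_genes:
        raise ValidationError("n_targets must be <= n_genes")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    abundance = np.exp(rng.standard_normal(n_genes) * 1.2)
    rel = abundance / abundance.sum()
    target = np.zeros(n_genes, dtype=bool)
    if n_targets:
        target[rng.choice(n_genes, size=n_targets, replace=False)] = True

    mu_control = rel * library_sizes[0]
    mu_treated = rel * library_sizes[1] * np.where(target, repression_factor, 1.0)

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(1, n_genes + 1)],
            "reads_control": draw(mu_control),
            "reads_treated": draw(mu_treated),
            "has_target_site": target,
        }
    )
    return ExpressionTable(genes)


def generate_confirmation(
    candidate_deltas: Mapping[str, float],
    n_empty_vectors: int = 11,
    n_control_mirnas: int = 28,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    control_effect_cv: float = 0.03,
    seed: int = 0,
):
    """Simulate a confirmation-screen dataset for gated re-testing.

    Candidate readouts have expectation ``1 - delta``; empty vectors sit
    at 1 and neutral control miRNAs at 1 times a small log-normal
    construct effect (CV ``control_effect_cv``), all with multiplicative
    replicate noise.  Returns a
    :class:`~mirscreen.confirmation.ConfirmationDataset`.
    """
    from .confirmation import ConfirmationDataset

    rng = np.random.default_rng(seed)
    candidates = {
        cid: list(
            (1.0 - delta) * _mean_one_lognormal(rng, noise_cv, n_replicates)
        )
        for cid, delta in candidate_deltas.items()
    }
    ev = list(_mean_one_lognormal(rng, noise_cv, n_empty_vectors))
    ctrl_effect = _mean_one_lognormal(rng, control_effect_cv, n_control_mirnas)
    ctrl = list(ctrl_effect * _mean_one_lognormal(rng, noise_cv, n_control_mirnas))
    return ConfirmationDataset(candidates, ev, ctrl)


def generate_qpcr(
    mirna_levels: Mapping[str, tuple[float, float]],
    ct_reference: float = 20.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[QpcrRecord]:
    """Simulate stem-loop qPCR Ct pairs from known relative levels.

    ``mirna_levels`` maps each miRNA to (endogenous 2^-dCt, fold
    overexpression); the ectopic level is their product.  Ct values are
    derived as ``ct_reference - log2(level)`` with optional Gaussian Ct
    noise per replicate.
    """
    rng = np.random.default_rng(seed)
    records = []
    for mirna, (endo, fold) in mirna_levels.items():
        for condition, level in (("endogenous", endo), ("ectopic", endo * fold)):
            ct_t = ct_reference - math.log2(level)
            cts = ct_t + rng.normal(0.0, ct_noise_sd, n_replicates)
            refs = ct_reference + rng.normal(0.0, ct_noise_sd, n_replicates)
            records.append(QpcrRecord(mirna, condition, list(cts), list(refs)))
    return records
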