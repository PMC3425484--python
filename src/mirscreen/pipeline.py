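"""End-to-end orchestration: simulate -> normalize -> call hits -> confirm
-> follow up -> expression, with a truth-based evaluation report.

One global seed fans out deterministically to per-stage child seeds via
``numpy.random.SeedSequence``, so a stage can be reproduced in isolation
and re-running the same configuration reproduces every output file
bit-identically.  All tables are written with fixed six-significant-digit
float formatting for diffability.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import confirmation as conf
from . import expression as expr
from . import followup as fup
from . import plate_io, screen_stats, synthetic
from .errors import ValidationError

log = logging.getLogger("mirscreen")

DEFAULT_FDR_THRESHOLDS = [-1.0, -1.5, -2.0, -2.5, -3.0, -3.5, -4.0, -4.5, -5.0]


@dataclass
class RunConfig:
    """Single-document configuration of a full pipeline run."""

    out_dir: str = "mirscreen_run"
    seed: int = 0
    screen: synthetic.ScreenSimConfig = field(default_factory=synthetic.ScreenSimConfig)
    criteria: screen_stats.PrimaryHitCriteria = field(
        default_factory=screen_stats.PrimaryHitCriteria
    )
    mask: plate_io.ExclusionMask = field(default_factory=plate_io.ExclusionMask.default_edge)
    fdr_thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_FDR_THRESHOLDS))
    # confirmation stage
    n_empty_vectors: int = 11
    n_control_mirnas: int = 28
    confirm_replicates: int = 3
    confirm_noise_cv: float = 0.05
    # follow-up stage
    competition_days: list[float] = field(default_factory=lambda: [0, 4, 8, 12, 16, 20, 24, 28, 32])
    competition_noise_cv: float = 0.05
    n_competition_conditions: int = 4
    screen_duration_days: float = 6.0
    # expression stage
    n_genes: int = 5000
    n_targets: int = 100
    repression_factor: float = 0.3
    expression_dispersion: float = 0.05
    down_threshold: float = 0.5
    min_control_reads: int = 10
    log_level: str = "INFO"

    def to_json(self, path=None) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["screen"] = self.screen.to_dict()
        d["criteria"] = self.criteria.to_dict()
        d["mask"] = self.mask.to_dict()
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "screen" in d:
            d["screen"] = synthetic.ScreenSimConfig.from_dict(d["screen"])
        if "criteria" in d:
            d["criteria"] = screen_stats.PrimaryHitCriteria.from_dict(d["criteria"])
        if "mask" in d:
            d["mask"] = plate_io.ExclusionMask.from_dict(d["mask"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EvaluationReport:
    """Truth-based evaluation of the hit calls plus per-stage bookkeeping."""

    sensitivity: float
    precision: float
    empirical_fdr: float
    rule_a_sensitivity: float
    rule_a_empirical_fdr: float
    estimated_fdr: float
    calibration_delta: float
    n_constructs: int
    n_hits: int
    n_inhibitors: int
    stage_counts: dict[str, int]
    confirmation_within_set_fdr: float
    fitness_deficits: dict[str, float]
    enrichment_p: float

    def __post_init__(self) -> None:
        for name in (
            "sensitivity",
            "precision",
            "empirical_fdr",
            "rule_a_sensitivity",
            "rule_a_empirical_fdr",
        ):
            v = getattr(self, name)
            if not math.isnan(v) and not 0 <= v <= 1:
                raise ValidationError(f"{name} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "empirical_fdr": self.empirical_fdr,
            "rule_a_sensitivity": self.rule_a_sensitivity,
            "rule_a_empirical_fdr": self.rule_a_empirical_fdr,
            "estimated_fdr": self.estimated_fdr,
            "calibration_delta": self.calibration_delta,
            "n_constructs": self.n_constructs,
            "n_hits": self.n_hits,
            "n_inhibitors": self.n_inhibitors,
            "stage_counts": self.stage_counts,
            "confirmation_within_set_fdr": self.confirmation_within_set_fdr,
            "fitness_deficits": self.fitness_deficits,
            "enrichment_p": self.enrichment_p,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Execute every stage, writing intermediates under ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 5)
    log.info("run seed %d -> stage seeds %s", config.seed, seeds)
    config.to_json(out / "config.json")

    # --- stage 1: simulate + write + read back (validating I/O path) ----
    screen_cfg = synthetic.ScreenSimConfig.from_dict(
        {**config.screen.to_dict(), "seed": seeds[0]}
    )
    plates, truth = synthetic.generate_screen(screen_cfg)
    plate_io.write_plates(plates, out / "plates.csv")
    truth.to_json(out / "truth.json")
    plates = plate_io.read_plates(out / "plates.csv", mask=config.mask)
    log.info("simulated %d plates, %d constructs", len(plates), len(truth))

    # --- stage 2: B-scores, FDR curve, hit selection --------------------
    table = screen_stats.bscore_tables(plates)
    table.write(out / "bscores.tsv")
    curve = screen_stats.fdr_curve(table, "viability", config.fdr_thresholds)
    curve.write(out / "fdr_curve.tsv")
    hits = screen_stats.select_primary_hits(
        table, table, truth.low_titer_set(), config.criteria
    )
    hits.write(out / "hits.tsv")
    log.info("%d primary hits of %d constructs", len(hits), hits.n_tested)

    truth_inh = set(truth.inhibitors())
    hit_ids = set(hits.construct_ids())
    tp = len(hit_ids & truth_inh)
    sensitivity = tp / len(truth_inh) if truth_inh else float("nan")
    precision = tp / len(hit_ids) if hit_ids else float("nan")
    empirical_fdr = 1.0 - precision if hit_ids else float("nan")
    rule_a = set(hits.via("A"))
    tp_a = len(rule_a & truth_inh)
    rule_a_sensitivity = tp_a / len(truth_inh) if truth_inh else float("nan")
    rule_a_empirical_fdr = 1.0 - tp_a / len(rule_a) if rule_a else float("nan")
    t_a = config.criteria.rule_a_viability_mean
    estimated_fdr = curve.fdr_at(t_a)
    calibration_delta = (
        empirical_fdr - estimated_fdr
        if not (math.isnan(empirical_fdr) or math.isnan(estimated_fdr))
        else float("nan")
    )

    # --- stage 3: confirmation against control populations --------------
    candidate_deltas = {cid: truth.delta_of(cid) for cid in hits.construct_ids()}
    confirm = None
    if candidate_deltas:
        data = synthetic.generate_confirmation(
            candidate_deltas,
            n_empty_vectors=config.n_empty_vectors,
            n_control_mirnas=config.n_control_mirnas,
            n_replicates=config.confirm_replicates,
            noise_cv=config.confirm_noise_cv,
            seed=seeds[1],
        )
        confirm = conf.gate_candidates(data)
        confirm.write(out / "confirmation.tsv")
        confirm.group_pvalues.to_csv(
            out / "confirmation_pvalues.tsv", sep="\t", index=False, float_format="%.6g"
        )
        log.info(
            "confirmation: %d/%d pass 95%% gate, %d stringent, FDR %.3f",
            confirm.n_pass_95,
            confirm.n_candidates,
            len(confirm.stringent_set),
            confirm.within_set_fdr,
        )

    # --- stage 4: long-term competition for the strongest hits ----------
    strongest = sorted(candidate_deltas, key=candidate_deltas.get, reverse=True)
    strongest = strongest[: config.n_competition_conditions]
    deficits: dict[str, float] = {}
    rel_frames = []
    for i, cid in enumerate(strongest):
        # a 6-day fractional reduction delta corresponds to a per-day
        # exponential deficit of -ln(1 - delta)/6
        r_true = -math.log(1.0 - min(candidate_deltas[cid], 0.999)) / config.screen_duration_days
        cond, ev = synthetic.generate_competition(
            r_true,
            config.competition_days,
            noise_cv=config.competition_noise_cv,
            seed=seeds[2] + i,
            condition=cid,
        )
        rel = fup.competition_relative(cond, ev)
        rel.insert(0, "condition", cid)
        rel_frames.append(rel)
        deficits[cid] = fup.fitness_deficit(rel).rate_per_day
    if rel_frames:
        pd.concat(rel_frames).to_csv(
            out / "competition.tsv", sep="\t", index=False, float_format="%.6g"
        )

    # --- stage 5: expression + target-site enrichment -------------------
    table_expr = synthetic.generate_expression_table(
        n_genes=config.n_genes,
        n_targets=config.n_targets,
        repression_factor=config.repression_factor,
        dispersion=config.expression_dispersion,
        seed=seeds[3],
    )
    table_expr.write(out / "expression.tsv")
    enr = expr.target_enrichment(
        table_expr,
        down_threshold=config.down_threshold,
        min_control_reads=config.min_control_reads,
    )
    enr.contingency.to_csv(out / "enrichment_contingency.tsv", sep="\t")
    log.info("enrichment p = %.3g, OR = %.2f", enr.p_value, enr.odds_ratio)

    report = EvaluationReport(
        sensitivity=sensitivity,
        precision=precision,
        empirical_fdr=empirical_fdr,
        rule_a_sensitivity=rule_a_sensitivity,
        rule_a_empirical_fdr=rule_a_empirical_fdr,
        estimated_fdr=estimated_fdr,
        calibration_delta=calibration_delta,
        n_constructs=len(truth),
        n_hits=len(hits),
        n_inhibitors=len(truth_inh),
        stage_counts={
            "plates": len(plates),
            "constructs_simulated": len(truth),
            "constructs_scored": len(table.constructs("viability")),
            "hits": len(hits),
            "confirmation_candidates": confirm.n_candidates if confirm else 0,
            "stringent_hits": len(confirm.stringent_set) if confirm else 0,
            "competition_conditions": len(deficits),
            "genes": config.n_genes,
        },
        confirmation_within_set_fdr=confirm.within_set_fdr if confirm else float("nan"),
        fitness_deficits=deficits,
        enrichment_p=enr.p_value,
    )
    if report.stage_counts["constructs_scored"] != report.n_constructs:
        raise ValidationError("construct count not conserved between simulation and scoring")
    report.to_json(out / "evaluation.json")
    return report
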