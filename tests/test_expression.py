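import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mirscreen.errors import ValidationError
from mirscreen.expression import (
    ExpressionTable,
    QpcrRecord,
    SmallRnaCounts,
    fold_overexpression,
    qpcr_summary,
    reads_per_million,
    rel_expr_2dct,
    rnaseq_relative_expression,
    round_sig,
    target_enrichment,
)
from mirscreen.synthetic import generate_expression_table

# printed overexpression summary: (miRNA, endogenous 2^-dCt, ectopic 2^-dCt,
# reported fold); the miR-141 fold is printed at three significant figures,
# the others at two
TABLE1 = [
    ("miR-497", 2.57e-7, 1.75e-5, 68, 2),
    ("miR-16", 5.53e-3, 2.07e-2, 3.7, 2),
    ("miR-96", 1.05e-6, 1.19e-5, 11, 2),
    ("miR-182", 3.01e-6, 3.01e-4, 100, 2),
    ("miR-141", 1.66e-6, 3.94e-4, 237, 3),
    ("miR-200a", 1.12e-7, 6.07e-4, 5.4e3, 2),
    ("miR-184", 8.35e-8, 1.35e-3, 1.6e4, 2),
    ("miR-203", 1.85e-8, 1.09e-3, 5.9e4, 2),
]


class TestQpcr:
    @pytest.mark.parametrize(
        "ct_t, ct_r, expected",
        [(25.0, 25.0, 1.0), (30.0, 20.0, 2.0**-10), (18.0, 20.0, 4.0)],
    )
    def test_two_to_minus_delta_ct(self, ct_t, ct_r, expected):
        assert rel_expr_2dct(ct_t, ct_r) == pytest.approx(expected)

    def test_ct_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            rel_expr_2dct(50.0, 20.0)
        with pytest.raises(ValidationError):
            rel_expr_2dct(float("nan"), 20.0)

    def test_equal_levels_give_unit_fold(self):
        assert fold_overexpression(1e-5, 1e-5) == 1.0

    def test_zero_endogenous_flags_infinite_fold(self):
        assert math.isinf(fold_overexpression(1e-5, 0.0))

    @pytest.mark.parametrize("mirna, endo, ecto, printed, sig", TABLE1)
    def test_printed_folds_reproduced_at_printed_precision(
        self, mirna, endo, ecto, printed, sig
    ):
        fold = fold_overexpression(ecto, endo)
        assert round_sig(fold, sig) == pytest.approx(printed)

    def test_replicates_averaged_on_ct_scale(self):
        rec = QpcrRecord("m", "endogenous", [24.0, 26.0], [20.0, 20.0])
        assert rec.relative_expression() == pytest.approx(2.0**-5)

    def test_summary_combines_conditions(self):
        records = [
            QpcrRecord("m", "endogenous", [30.0], [20.0]),
            QpcrRecord("m", "ectopic", [25.0], [20.0]),
        ]
        row = qpcr_summary(records).iloc[0]
        assert row["fold_overexpression"] == pytest.approx(32.0)
        assert row["fold_reported"] == 32.0


class TestRoundSig:
    @pytest.mark.parametrize(
        "x, digits, expected",
        [
            (237.35, 2, 240.0),
            (237.35, 3, 237.0),
            (68.09, 2, 68.0),
            (0.0974, 2, 0.097),
            (1.65e4, 2, 1.6e4),  # ties to even
            (1.75e4, 2, 1.8e4),
            (0.0, 2, 0.0),
            (-12.34, 2, -12.0),
        ],
    )
    def test_half_even_significant_rounding(self, x, digits, expected):
        assert round_sig(x, digits) == expected


class TestReadsPerMillion:
    def test_definition(self):
        rpm = reads_per_million(SmallRnaCounts({"miR-16": 542}, 500_000))
        assert rpm["miR-16"] == pytest.approx(1084.0)

    def test_zero_reads_is_zero(self):
        assert reads_per_million(SmallRnaCounts({"m": 0}, 100))["m"] == 0.0

    def test_scale_invariance(self):
        a = reads_per_million(SmallRnaCounts({"m": 13, "n": 7}, 1000))
        b = reads_per_million(SmallRnaCounts({"m": 26, "n": 14}, 2000))
        assert a == b

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            reads_per_million(SmallRnaCounts({}, 0))

    def test_counts_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            SmallRnaCounts({"m": 10, "n": 10}, 15)


def make_expression(rows):
    return ExpressionTable(
        pd.DataFrame(
            rows, columns=["gene_id", "reads_control", "reads_treated", "has_target_site"]
        )
    )


class TestRnaseqRelativeExpression:
    def test_equal_relative_reads_give_one(self):
        t = make_expression([("g1", 50, 50, False), ("g2", 50, 50, False)])
        assert np.allclose(rnaseq_relative_expression(t), 1.0)

    def test_halved_share_gives_half(self):
        # g1: control RPM 100/total vs treated 50/total (same library size)
        t = make_expression([("g1", 100, 50, False), ("g2", 900, 950, False)])
        rel = rnaseq_relative_expression(t)
        assert rel["g1"] == pytest.approx(0.5)

    def test_library_size_cancels(self):
        t1 = make_expression([("g1", 100, 300, False), ("g2", 900, 2700, False)])
        rel = rnaseq_relative_expression(t1)
        assert np.allclose(rel, 1.0)

    def test_low_control_reads_flagged_unquantifiable(self):
        t = make_expression([("g1", 2, 50, False), ("g2", 500, 500, False)])
        rel = rnaseq_relative_expression(t, min_control_reads=10)
        assert math.isnan(rel["g1"]) and math.isfinite(rel["g2"])


def hypergeom_tail_oracle(a, b, c, d):
    """P(overlap >= a) by exact tail summation with rational arithmetic."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(math.comb(N, n))
    acc = Fraction(0)
    for i in range(a, min(K, n) + 1):
        if n - i > N - K:
            continue
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i))
    return acc / total


class TestTargetEnrichment:
    def _table_from_contingency(self, a, b, c, d):
        # downregulated gene: treated share 1/4 of control share; others
        # flat.  Library totals are pinned equal so the intended relative
        # expressions (0.25 and 1.0) hold exactly whatever the cell counts.
        rows = []
        gid = 0
        for count, down, target in (
            (a, True, True),
            (b, True, False),
            (c, False, True),
            (d, False, False),
        ):
            for _ in range(count):
                gid += 1
                rows.append(
                    (f"g{gid}", 100, 25 if down else 100, target)
                )
        total = 200 * (a + b + c + d)
        df = pd.DataFrame(
            rows, columns=["gene_id", "reads_control", "reads_treated", "has_target_site"]
        )
        return ExpressionTable(df, total_control=total, total_treated=total)

    def test_balanced_table_is_null(self):
        t = self._table_from_contingency(25, 25, 25, 25)
        res = target_enrichment(t)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.5

    def test_matches_exhaustive_tail_oracle_on_fixed_table(self):
        res = target_enrichment(self._table_from_contingency(30, 70, 70, 830))
        assert res.p_value == pytest.approx(
            float(hypergeom_tail_oracle(30, 70, 70, 830)), rel=1e-10
        )

    def test_matches_oracle_on_random_small_tables(self, rng):
        checked = 0
        while checked < 100:
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = target_enrichment(self._table_from_contingency(a, b, c, d))
            assert res.p_value == pytest.approx(
                float(hypergeom_tail_oracle(a, b, c, d)), rel=1e-9
            )
            checked += 1

    def test_perfect_separation_reaches_minimal_p(self):
        res = target_enrichment(self._table_from_contingency(20, 0, 0, 80))
        assert res.p_value == pytest.approx(
            float(hypergeom_tail_oracle(20, 0, 0, 80)), rel=1e-10
        )
        assert res.p_value == pytest.approx(1.0 / math.comb(100, 20), rel=1e-9)
        assert res.odds_ratio > 1  # Haldane-corrected, finite

    def test_empty_margin_not_applicable(self):
        t = make_expression([("g1", 100, 100, True), ("g2", 100, 100, True)])
        with pytest.raises(ValidationError):
            target_enrichment(t)

    def test_enrichment_p_decreases_with_repression_strength(self):
        # stronger planted repression of target genes must yield smaller
        # enrichment p on average (rank correlation across seeds)
        factors = [1.0, 0.8, 0.6, 0.4]
        mean_logp = []
        for f in factors:
            logs = []
            for seed in range(8):
                t = generate_expression_table(
                    n_genes=800, n_targets=60, repression_factor=f, seed=seed
                )
                logs.append(math.log10(max(target_enrichment(t).p_value, 1e-300)))
            mean_logp.append(np.mean(logs))
        assert all(x > y for x, y in zip(mean_logp, mean_logp[1:]))


def test_smallrna_tsv_reader_round_trip(tmp_path):
    from mirscreen.expression import read_smallrna_tsv

    path = tmp_path / "counts.tsv"
    path.write_text("mirna_id\treads\nmiR-16\t542\nmiR-96\t10\n")
    counts = read_smallrna_tsv(path, total_mapped=500_000)
    rpm = reads_per_million(counts)
    assert rpm["miR-16"] == pytest.approx(1084.0)
    assert read_smallrna_tsv(path).total_mapped == 552
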