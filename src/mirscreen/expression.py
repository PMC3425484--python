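"""Expression quantification: qPCR 2^-dCt, small-RNA RPM, RNA-seq ratios
and target-site enrichment among downregulated genes.

qPCR abundances are expressed relative to the U6 small RNA via
2^-(Ct_target - Ct_U6); fold overexpression is the ratio of the ectopic
(construct-transduced) to the endogenous (empty-vector) relative
abundance, reported at two significant figures.  Small-RNA abundance is
reads per million mapped reads.  RNA-seq relative expression is the ratio
of library-normalized read fractions between the treated and control
samples.  Enrichment of target-site-bearing genes among downregulated
genes uses the one-sided hypergeometric tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError


def rel_expr_2dct(ct_target: float, ct_reference: float) -> float:
    """Relative expression 2^-(Ct_target - Ct_reference)."""
    for name, ct in (("target", ct_target), ("reference", ct_reference)):
        if ct is None or (isinstance(ct, float) and math.isnan(ct)):
            raise ValidationError(f"missing {name} Ct")
        if not 0 < ct < 45:
            raise ValidationError(f"{name} Ct {ct} outside (0, 45)")
    return float(2.0 ** -(ct_target - ct_reference))


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures, ties to even."""
    if digits < 1:
        raise ValidationError("digits must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    exponent = d.adjusted() - digits + 1
    return float(d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_HALF_EVEN))


def fold_overexpression(ectopic_rel: float, endogenous_rel: float) -> float:
    """Fold overexpression: ectopic / endogenous relative abundance.

    Returned at full precision; apply :func:`round_sig` (two significant
    figures) at reporting.  A zero endogenous level yields +inf (an
    infinite-fold flag), not an arbitrary large number.
    """
    if ectopic_rel < 0 or endogenous_rel < 0:
        raise ValidationError("relative expressions must be >= 0")
    if endogenous_rel == 0:
        return float("inf")
    return ectopic_rel / endogenous_rel


@dataclass
class QpcrRecord:
    """Replicate Ct pairs for one miRNA in one condition.

    Replicate Cts are averaged on the Ct scale before the delta is taken,
    the standard practice for relative quantification.
    """

    mirna_id: str
    condition: str
    ct_target: list[float]
    ct_reference: list[float]

    def __post_init__(self) -> None:
        if self.condition not in ("endogenous", "ectopic"):
            raise ValidationError(f"unknown qPCR condition {self.condition!r}")
        if not self.ct_target or not self.ct_reference:
            raise ValidationError(f"{self.mirna_id}/{self.condition}: empty Ct list")
        for ct in [*self.ct_target, *self.ct_reference]:
            if not 0 < ct < 45:
                raise ValidationError(
                    f"{self.mirna_id}/{self.condition}: Ct {ct} outside (0, 45)"
                )

    def relative_expression(self) -> float:
        return rel_expr_2dct(
            float(np.mean(self.ct_target)), float(np.mean(self.ct_reference))
        )


def qpcr_summary(records: list[QpcrRecord]) -> pd.DataFrame:
    """Per-miRNA endogenous/ectopic 2^-dCt and fold overexpression.

    Mirrors the layout of an overexpression summary table: one row per
    miRNA with both conditions and the two-significant-figure fold.
    """
    rel: dict[str, dict[str, float]] = {}
    for r in records:
        rel.setdefault(r.mirna_id, {})[r.condition] = r.relative_expression()
    rows = []
    for mirna, conds in rel.items():
        endo = conds.get("endogenous", float("nan"))
        ecto = conds.get("ectopic", float("nan"))
        fold = (
            fold_overexpression(ecto, endo)
            if not (math.isnan(endo) or math.isnan(ecto))
            else float("nan")
        )
        rows.append(
            {
                "mirna_id": mirna,
                "endogenous_2dct": endo,
                "ectopic_2dct": ecto,
                "fold_overexpression": fold,
                "fold_reported": round_sig(fold) if math.isfinite(fold) else fold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "endogenous_2dct",
            "ectopic_2dct",
            "fold_overexpression",
            "fold_reported",
        ],
    )


def read_qpcr_csv(path) -> list[QpcrRecord]:
    """Read ``mirna_id,condition,replicate,ct_target,ct_u6`` rows."""
    df = pd.read_csv(path)
    need = {"mirna_id", "condition", "ct_target", "ct_u6"}
    if not need <= set(df.columns):
        raise ValidationError(f"qPCR CSV missing columns {sorted(need - set(df.columns))}")
    records = []
    for (mirna, cond), grp in df.groupby(["mirna_id", "condition"], sort=False):
        records.append(
            QpcrRecord(
                str(mirna),
                str(cond),
                grp["ct_target"].astype(float).tolist(),
                grp["ct_u6"].astype(float).tolist(),
            )
        )
    return records


@dataclass
class SmallRnaCounts:
    """Mapped read counts per miRNA plus the total mapped reads."""

    counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("negative read count")
        if sum(self.counts.values()) > self.total_mapped:
            raise ValidationError("per-miRNA reads exceed total mapped reads")


def read_smallrna_tsv(path, total_mapped: int | None = None) -> SmallRnaCounts:
    """Read a ``mirna_id<TAB>reads`` table; the total defaults to the sum."""
    df = pd.read_csv(path, sep="\t")
    need = {"mirna_id", "reads"}
    if not need <= set(df.columns):
        raise ValidationError(f"small-RNA TSV missing columns {sorted(need - set(df.columns))}")
    counts = {str(r.mirna_id): int(r.reads) for r in df.itertuples(index=False)}
    return SmallRnaCounts(counts, total_mapped if total_mapped is not None else sum(counts.values()))


def reads_per_million(counts: SmallRnaCounts) -> dict[str, float]:
    """Reads per million mapped reads per miRNA; absent miRNAs are 0 by
    construction of the count table."""
    if counts.total_mapped <= 0:
        raise ValidationError("total mapped reads must be > 0")
    return {m: c * 1e6 / counts.total_mapped for m, c in counts.counts.items()}


@dataclass
class ExpressionTable:
    """Gene read counts in control and treated samples with target flags."""

    genes: pd.DataFrame  # gene_id, reads_control, reads_treated, has_target_site
    total_control: int = 0
    total_treated: int = 0

    def __post_init__(self) -> None:
        need = {"gene_id", "reads_control", "reads_treated", "has_target_site"}
        if not need <= set(self.genes.columns):
            raise ValidationError(f"expression table missing columns {sorted(need - set(self.genes.columns))}")
        if (self.genes[["reads_control", "reads_treated"]] < 0).any().any():
            raise ValidationError("negative read counts")
        if self.total_control == 0:
            self.total_control = int(self.genes["reads_control"].sum())
        if self.total_treated == 0:
            self.total_treated = int(self.genes["reads_treated"].sum())
        if self.total_control <= 0 or self.total_treated <= 0:
            raise ValidationError("library totals must be > 0")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        df["has_target_site"] = df["has_target_site"].astype(bool)
        return cls(df)

    def write(self, path) -> None:
        out = self.genes.copy()
        out["has_target_site"] = out["has_target_site"].astype(bool)
        out.to_csv(path, sep="\t", index=False)


def rnaseq_relative_expression(
    table: ExpressionTable, min_control_reads: int = 1
) -> pd.Series:
    """Per-gene relative expression: treated read fraction / control read fraction.

    Genes with fewer than ``min_control_reads`` control reads are not
    quantifiable (NaN) rather than divided by ~zero.  Uniformly scaling
    either library leaves the ratios unchanged.
    """
    g = table.genes
    rel_t = g["reads_treated"] / table.total_treated
    rel_c = g["reads_control"] / table.total_control
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rel_t / rel_c
    ratio = ratio.where(g["reads_control"] >= min_control_reads)
    ratio.index = g["gene_id"]
    return ratio.rename("relative_expression")


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    contingency: pd.DataFrame
    n_quantifiable: int
    down_threshold: float


def target_enrichment(
    table: ExpressionTable,
    down_threshold: float = 0.5,
    min_control_reads: int = 10,
) -> EnrichmentResult:
    """Over-representation of target-site genes among downregulated genes.

    Builds the 2x2 table {downregulated vs not} x {has target site vs
    not} over quantifiable genes (>= ``min_control_reads`` control
    reads), with downregulation defined as relative expression below
    ``down_threshold``.  The p-value is the one-sided hypergeometric tail
    for at least the observed overlap; the odds ratio gets the Haldane
    0.5 correction when a cell is empty.
    """
    rel = rnaseq_relative_expression(table, min_control_reads=min_control_reads)
    quantifiable = rel.notna().to_numpy()
    if quantifiable.sum() == 0:
        raise ValidationError("no quantifiable genes")
    down = (rel < down_threshold).to_numpy() & quantifiable
    target = table.genes["has_target_site"].to_numpy(dtype=bool) & quantifiable

    a = int(np.sum(down & target))
    b = int(np.sum(down & ~target & quantifiable))
    c = int(np.sum(~down & target & quantifiable))
    d = int(np.sum(~down & ~target & quantifiable))
    n_total = a + b + c + d
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValidationError("degenerate contingency margin; enrichment not applicable")

    # P(overlap >= a) drawing (a+b) "down" genes from n_total with (a+c) targets
    p = float(hypergeom.sf(a - 1, n_total, a + c, a + b))
    if min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    contingency = pd.DataFrame(
        [[a, b], [c, d]],
        index=["downregulated", "not_downregulated"],
        columns=["target_site", "no_target_site"],
    )
    return EnrichmentResult(
        odds_ratio=float(orat),
        p_value=p,
        contingency=contingency,
        n_quantifiable=n_total,
        down_threshold=down_threshold,
    )
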