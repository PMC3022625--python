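"""Relative expression from tag counts, and the comparative-CT path.

Tag counts are normalized against the internal-control gene in each
sample; the ratio of normalized counts between treated and untreated
samples estimates relative expression.  The 95% CI uses the normal
approximation on log(ratio) with variance sum(1/count) over the four
counts (Katz log method); zero gene counts get a +0.5 continuity
correction and are flagged.

CT convention: dCT = CT(control) - CT(target), so a larger dCT means more
transcript, and fold change = 2**(dCT_treated - dCT_untreated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .deconvolution import TagCountTable

__all__ = [
    "ExpressionEstimate",
    "QpcrRecord",
    "EfficiencyFit",
    "relative_expression",
    "delta_ct",
    "ddct_fold",
    "qpcr_fold_changes",
    "amplification_efficiency",
    "concordance",
    "direction_call",
]


@dataclass(frozen=True)
class ExpressionEstimate:
    gene_id: str
    count_t: int
    control_t: int
    count_u: int
    control_u: int
    ratio: float
    log2_ratio: float
    ci_low: float
    ci_high: float
    call: str  # up | down | unchanged
    corrected: bool = False  # continuity correction applied


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    gene_id: str
    ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ct < 45):
            raise ValueError(
                f"CT {self.ct} for {self.gene_id}/{self.sample_id} outside (0, 45)"
            )


@dataclass(frozen=True)
class EfficiencyFit:
    gene_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    valid: bool


def _call_from_ci(ci_low: float, ci_high: float) -> str:
    if ci_low > 1.0:
        return "up"
    if ci_high < 1.0:
        return "down"
    return "unchanged"


def relative_expression(
    counts: TagCountTable,
    treated: str,
    untreated: str,
    control_gene: str,
    ci_level: float = 0.95,
    genes: list[str] | None = None,
) -> list[ExpressionEstimate]:
    """Control-normalized expression ratios, treated over untreated.

    ratio = (count_t / control_t) / (count_u / control_u).  Raises if the
    control gene has zero counts in either sample.
    """
    for sample in (treated, untreated):
        if counts.get(sample, control_gene) <= 0:
            raise ValueError(
                f"control gene {control_gene!r} has zero tag count in sample {sample!r}"
            )
    if genes is None:
        genes = [g for g in counts.genes if g != control_gene]
    z = stats.norm.ppf(0.5 + ci_level / 2)
    c_t = counts.get(treated, control_gene)
    c_u = counts.get(untreated, control_gene)
    out = []
    for gene in genes:
        n_t = counts.get(treated, gene)
        n_u = counts.get(untreated, gene)
        corrected = n_t == 0 or n_u == 0
        a = n_t + 0.5 if n_t == 0 else float(n_t)
        b = n_u + 0.5 if n_u == 0 else float(n_u)
        ratio = (a / c_t) / (b / c_u)
        log_ratio = math.log(ratio)
        se = math.sqrt(1 / a + 1 / c_t + 1 / b + 1 / c_u)
        ci_low = math.exp(log_ratio - z * se)
        ci_high = math.exp(log_ratio + z * se)
        out.append(
            ExpressionEstimate(
                gene_id=gene,
                count_t=n_t,
                control_t=c_t,
                count_u=n_u,
                control_u=c_u,
                ratio=ratio,
                log2_ratio=math.log2(ratio),
                ci_low=ci_low,
                ci_high=ci_high,
                call=_call_from_ci(ci_low, ci_high),
                corrected=corrected,
            )
        )
    return out


# ---------------------------------------------------------------------------
# comparative CT
# ---------------------------------------------------------------------------


def delta_ct(records: list[QpcrRecord], control_gene: str) -> dict[tuple[str, str], float]:
    """Per (sample, gene) dCT = mean CT(control) - mean CT(target).

    Replicates are averaged before subtraction.  Larger dCT means more
    transcript of the target relative to the control.
    """
    sums: dict[tuple[str, str], list[float]] = {}
    for r in records:
        sums.setdefault((r.sample_id, r.gene_id), []).append(r.ct)
    means = {k: sum(v) / len(v) for k, v in sums.items()}
    samples = {s for s, _ in means}
    out: dict[tuple[str, str], float] = {}
    for sample in samples:
        if (sample, control_gene) not in means:
            raise ValueError(f"sample {sample!r} has no CT for control gene {control_gene!r}")
        ctrl = means[(sample, control_gene)]
        for (s, g), ct in means.items():
            if s == sample and g != control_gene:
                out[(s, g)] = ctrl - ct
    return out


def ddct_fold(dct_treated: float, dct_untreated: float) -> float:
    """Fold change 2**(dCT_treated - dCT_untreated)."""
    if not (math.isfinite(dct_treated) and math.isfinite(dct_untreated)):
        raise ValueError("dCT values must be finite")
    return 2.0 ** (dct_treated - dct_untreated)


def qpcr_fold_changes(
    records: list[QpcrRecord],
    treated: str,
    untreated: str,
    control_gene: str,
) -> dict[str, float]:
    """Per-gene ddCT fold changes between two samples."""
    dct = delta_ct(records, control_gene)
    genes = sorted({g for (s, g) in dct if s == treated})
    out = {}
    for g in genes:
        if (untreated, g) not in dct:
            continue
        out[g] = ddct_fold(dct[(treated, g)], dct[(untreated, g)])
    return out


def amplification_efficiency(
    dilution_cts: list[tuple[float, float]],
    gene_id: str = "",
) -> EfficiencyFit:
    """Standard-curve fit of CT against log10(dilution).

    E = 10**(-1/slope) - 1; a perfect doubling assay has slope
    -1/log10(2) ~ -3.3219 and E = 1.  Requires >= 3 dilution points;
    non-negative slopes and E outside (0, 1.1] are flagged invalid.
    """
    if len(dilution_cts) < 3:
        raise ValueError(f"standard curve needs >= 3 points, got {len(dilution_cts)}")
    x = [p[0] for p in dilution_cts]
    y = [p[1] for p in dilution_cts]
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope >= 0:
        return EfficiencyFit(
            gene_id=gene_id,
            slope=slope,
            intercept=float(fit.intercept),
            efficiency=float("nan"),
            r_squared=float(fit.rvalue) ** 2,
            valid=False,
        )
    eff = 10.0 ** (-1.0 / slope) - 1.0
    return EfficiencyFit(
        gene_id=gene_id,
        slope=slope,
        intercept=float(fit.intercept),
        efficiency=eff,
        r_squared=float(fit.rvalue) ** 2,
        valid=0 < eff <= 1.1,
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def direction_call(fold: float, threshold: float = 1.5) -> str:
    """up/down/unchanged from a fold change at a symmetric threshold."""
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if fold >= threshold:
        return "up"
    if fold <= 1 / threshold:
        return "down"
    return "unchanged"


def concordance(
    estimates: list[ExpressionEstimate],
    qpcr_folds: dict[str, float],
    fold_threshold: float = 1.5,
) -> list[dict]:
    """Per-gene direction agreement between tag counts and qPCR.

    Returns one row per shared gene with both calls and an ``agree``
    flag; raises if the gene sets are disjoint.
    """
    by_gene = {e.gene_id: e for e in estimates}
    shared = sorted(set(by_gene) & set(qpcr_folds))
    if not shared:
        raise ValueError("tag-count and qPCR gene sets are disjoint")
    rows = []
    for g in shared:
        call_tag = by_gene[g].call
        call_qpcr = direction_call(qpcr_folds[g], fold_threshold)
        rows.append(
            {
                "gene_id": g,
                "tag_ratio": by_gene[g].ratio,
                "tag_call": call_tag,
                "qpcr_fold": qpcr_folds[g],
                "qpcr_call": call_qpcr,
                "agree": call_tag == call_qpcr,
            }
        )
    return rows
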