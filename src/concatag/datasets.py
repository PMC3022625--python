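"""Deterministic synthetic fixtures: gene sets, expression profiles, CT data.

The default 20-gene set mirrors the validation experiment's layout: 19
yeast ORF-style targets plus the ACT1 internal control, two-condition
(treated/untreated) profiles whose relative abundances span at least
16-fold, and qPCR CT tables generated from the same ground truth.
"""

from __future__ import annotations

import numpy as np

from .panel_design import (
    DEFAULT_ADAPTORS,
    DEFAULT_CONSTRAINTS,
    DesignConstraints,
    GeneTarget,
    UniversalAdaptors,
    enumerate_candidates,
)
from .quantify import QpcrRecord
from .wetlab_sim import ExpressionProfile

__all__ = [
    "DEFAULT_GENE_IDS",
    "DEFAULT_CONTROL",
    "DEFAULT_LOG2_FOLDS",
    "synthetic_gene_targets",
    "two_condition_profiles",
    "qpcr_records_from_profiles",
    "dilution_series",
]

#: The validation experiment's target set: 19 ORFs plus the ACT1 control.
DEFAULT_GENE_IDS = (
    "YPL122C", "YNR030W", "YDR343C", "YGR088W", "YPR149W",
    "YCL040W", "YBR054W", "YNR001C", "YDR533C", "YDL222C",
    "YML123C", "YEL046C", "YLR180W", "YLR355C", "YLR419W",
    "YLR300W", "YNL300W", "YLR372W", "YAL059W", "ACT1",
)
DEFAULT_CONTROL = "ACT1"

#: Default ground-truth log2 fold changes (treated vs untreated) covering
#: up, down and unchanged genes; the control is always 0.
DEFAULT_LOG2_FOLDS = {
    "YPL122C": 2, "YNR030W": 2, "YDR343C": 1, "YGR088W": 1, "YPR149W": 0,
    "YCL040W": 2, "YBR054W": 1, "YNR001C": 2, "YDR533C": 1, "YDL222C": 0,
    "YML123C": -2, "YEL046C": -1, "YLR180W": -2, "YLR355C": -1, "YLR419W": -2,
    "YLR300W": -1, "YNL300W": -2, "YLR372W": -1, "YAL059W": 0, "ACT1": 0,
}

_TM_TARGET_WINDOW = (64.5, 68.5)  # guarantees a joint <=5 C panel exists


def _gene_is_designable(
    seq: str,
    adaptors: UniversalAdaptors,
    constraints: DesignConstraints,
    tm_window: tuple[float, float],
) -> bool:
    gene = GeneTarget("probe", seq)
    try:
        cands = enumerate_candidates(gene, adaptors, constraints)
    except ValueError:
        return False
    lo, hi = tm_window
    return any(lo <= p.tm_low and p.tm_high <= hi for p in cands)


def synthetic_gene_targets(
    gene_ids: tuple[str, ...] = DEFAULT_GENE_IDS,
    control: str = DEFAULT_CONTROL,
    length: int = 150,
    seed: int = 20110118,
    adaptors: UniversalAdaptors = DEFAULT_ADAPTORS,
    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
) -> list[GeneTarget]:
    """Random gene sequences guaranteed to admit a feasible joint panel.

    Each sequence is redrawn until it hosts at least one candidate primer
    pair with both Tm values inside a fixed 4 C window, so a 20-plex panel
    with pairwise dTm <= 5 C always exists.  Deterministic in ``seed``.
    """
    if control not in gene_ids:
        raise ValueError(f"control {control!r} not among gene ids")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genes = []
    for gid in gene_ids:
        for _ in range(500):
            seq = "".join(rng.choice(bases, size=length))
            if _gene_is_designable(seq, adaptors, constraints, _TM_TARGET_WINDOW):
                genes.append(GeneTarget(gid, seq, is_control=(gid == control)))
                break
        else:  # pragma: no cover - would need a pathological RNG
            raise RuntimeError(f"could not generate a designable sequence for {gid}")
    return genes


def two_condition_profiles(
    gene_ids: tuple[str, ...] = DEFAULT_GENE_IDS,
    control: str = DEFAULT_CONTROL,
    log2_folds: dict[str, float] | None = None,
    seed: int = 7,
    min_dynamic_range: float = 16.0,
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """(treated, untreated) profiles with known per-gene fold changes.

    Untreated abundances are drawn log-uniformly over at least
    ``min_dynamic_range``; treated weights multiply in 2**log2_fold.  The
    control gene's fold is forced to 0 and its weight pinned near the
    middle of the range so control counts stay well-populated.
    """
    if log2_folds is None:
        log2_folds = dict(DEFAULT_LOG2_FOLDS)
    rng = np.random.default_rng(seed)
    span = np.log2(min_dynamic_range)
    weights_u = {}
    for gid in gene_ids:
        if gid == control:
            weights_u[gid] = float(2.0 ** (span / 2))
        else:
            weights_u[gid] = float(2.0 ** rng.uniform(0, span))
    # force the full dynamic range to be present
    non_control = [g for g in gene_ids if g != control]
    weights_u[non_control[0]] = 1.0
    weights_u[non_control[1]] = float(min_dynamic_range)
    weights_t = {
        gid: w * 2.0 ** log2_folds.get(gid, 0.0) for gid, w in weights_u.items()
    }
    return (
        ExpressionProfile("treated", weights_t),
        ExpressionProfile("untreated", weights_u),
    )


def qpcr_records_from_profiles(
    profiles: tuple[ExpressionProfile, ExpressionProfile],
    control: str = DEFAULT_CONTROL,
    ct_sd: float = 0.2,
    replicates: int = 3,
    control_ct: float = 18.0,
    seed: int = 11,
) -> list[QpcrRecord]:
    """Simulated CT table consistent with the profiles' ground truth.

    Noise-free CTs satisfy CT(gene) = CT(control) - log2(w_gene/w_control),
    so dCT = CT(control) - CT(gene) recovers the true log2 abundance ratio;
    Gaussian noise of ``ct_sd`` cycles is added per technical replicate.
    """
    rng = np.random.default_rng(seed)
    records = []
    for profile in profiles:
        w_ctrl = profile.weights[control]
        for gid, w in profile.weights.items():
            base_ct = control_ct if gid == control else control_ct - float(np.log2(w / w_ctrl))
            for rep in range(replicates):
                ct = base_ct + float(rng.normal(0, ct_sd)) if ct_sd > 0 else base_ct
                records.append(
                    QpcrRecord(sample_id=profile.sample_id, gene_id=gid, ct=ct, replicate=rep)
                )
    return records


def dilution_series(
    efficiency: float = 1.0,
    n_points: int = 5,
    top_ct: float = 15.0,
    ct_sd: float = 0.0,
    seed: int = 3,
) -> list[tuple[float, float]]:
    """(log10 dilution, CT) standard-curve points for a given efficiency."""
    if not (0 < efficiency <= 2):
        raise ValueError("efficiency must be in (0, 2]")
    slope = -1.0 / np.log10(1.0 + efficiency)
    rng = np.random.default_rng(seed)
    pts = []
    for i in range(n_points):
        logdil = -float(i)  # 1, 1/10, 1/100, ...
        ct = top_ct + slope * logdil
        if ct_sd > 0:
            ct += float(rng.normal(0, ct_sd))
        pts.append((logdil, ct))
    return pts
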