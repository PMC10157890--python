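"""Endpoint activity-panel analysis.

Specific activities (s⁻¹) from endpoint deacetylation assays are normalized
to a reference peptide (FRKacWR ≡ 1), compared pairwise with two-tailed
pooled-variance t-tests under Bonferroni correction (p ≤ 0.01), combined
into ratios with propagated standard deviations, and validated against
predicted residue preferences with a two-sided Fisher exact test (p ≤ 0.05)
on detectable-vs-not activity.  Peptides below the assay's limit of
reliable detection are treated as "not deacetylated" — censored, not zero —
and are excluded from normalization and correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptides import PeptideSequence
from .selectivity import (
    CorrelationResult,
    activity_interaction_correlation,
    fisher_exact_two_sided,
    pooled_ttest,
)


class NormalizationError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


@dataclass
class ActivityRecord:
    """Replicate specific activities of one enzyme–peptide pair.

    Either ``replicates`` (preferred; mean/sd are derived) or summary
    ``mean``/``sd`` values may be supplied — published tables report only
    the latter.  ``mean`` of ``nan`` encodes "below the limit of reliable
    detection".
    """

    peptide: PeptideSequence
    enzyme: str = ""
    replicates: list[float] = field(default_factory=list)
    mean: float = math.nan
    sd: float = math.nan
    detection_limit: float = 0.0

    def __post_init__(self) -> None:
        if self.replicates:
            arr = np.asarray(self.replicates, dtype=float)
            self.mean = float(arr.mean())
            self.sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    @property
    def detectable(self) -> bool:
        # a value exactly at the limit is still a reported measurement
        return math.isfinite(self.mean) and self.mean >= self.detection_limit


@dataclass
class NormalizedActivity:
    peptide: PeptideSequence
    value: float
    sd: float
    reference_peptide: PeptideSequence


def normalize_activities(
    records: list[ActivityRecord], reference: PeptideSequence
) -> list[NormalizedActivity]:
    """Express activities relative to the reference peptide (value 1).

    Standard deviations propagate as for a ratio:
    sd = value·√((sd/mean)² + (sd_ref/mean_ref)²).  Records below the
    detection limit are skipped.
    """
    ref = next((r for r in records if r.peptide == reference), None)
    if ref is None or not ref.detectable:
        raise NormalizationError(
            f"reference peptide {reference} absent or below detection"
        )
    rel_ref2 = (ref.sd / ref.mean) ** 2
    out = []
    for rec in records:
        if not rec.detectable:
            continue
        value = 1.0 if rec.peptide == reference else rec.mean / ref.mean
        sd = value * math.sqrt((rec.sd / rec.mean) ** 2 + rel_ref2)
        out.append(NormalizedActivity(rec.peptide, value, sd, reference))
    return out


@dataclass
class PairwiseSignificance:
    """Matrix of pairwise two-tailed t-tests with Bonferroni correction.

    ``direction`` holds +1 where the row peptide is significantly more
    active than the column peptide, −1 for the reverse, 0 for no
    significant difference; it is antisymmetric by construction.
    """

    direction: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_pairs: int
    alpha: float


def pairwise_activity_ttests(
    records: list[ActivityRecord], alpha: float = 0.01
) -> PairwiseSignificance:
    """All-pairs pooled-variance t-tests on replicate activities.

    The Bonferroni divisor is the number of unordered pairs; significance
    requires adjusted p ≤ 0.01.
    """
    recs = [r for r in records if len(r.replicates) >= 2]
    names = [str(r.peptide) for r in recs]
    k = len(recs)
    m = k * (k - 1) // 2
    direction = pd.DataFrame(0, index=names, columns=names, dtype=int)
    p_raw = pd.DataFrame(np.nan, index=names, columns=names)
    p_adj = pd.DataFrame(np.nan, index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            t, p = pooled_ttest(
                np.asarray(recs[i].replicates), np.asarray(recs[j].replicates)
            )
            padj = min(1.0, m * p)
            sig = padj <= alpha
            d = int(np.sign(t)) if sig else 0
            direction.iloc[i, j] = d
            direction.iloc[j, i] = -d
            p_raw.iloc[i, j] = p_raw.iloc[j, i] = p
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = padj
    return PairwiseSignificance(direction, p_raw, p_adj, m, alpha)


def activity_ratio_with_error(
    a: ActivityRecord, b: ActivityRecord
) -> tuple[float, float]:
    """Ratio of mean activities with the propagated standard deviation."""
    if not b.detectable:
        raise UndefinedRatioError("denominator activity below detection")
    if not a.detectable:
        raise UndefinedRatioError("numerator activity below detection")
    ratio = a.mean / b.mean
    sd = ratio * math.sqrt((a.sd / a.mean) ** 2 + (b.sd / b.mean) ** 2)
    return ratio, sd


def residue_presence_fisher(
    records: list[ActivityRecord], predicate
) -> tuple[np.ndarray, float]:
    """Fisher test of a sequence feature against detectable activity.

    ``predicate`` is a callable over `PeptideSequence`.  Rows of the 2×2
    table are predicate true/false, columns detectable/not; the p-value is
    the two-sided Fisher exact p.
    """
    flags = [(bool(predicate(r.peptide)), r.detectable) for r in records]
    if all(f for f, _ in flags) or not any(f for f, _ in flags):
        raise ValueError("predicate must split the panel")
    table = np.array(
        [
            [
                sum(1 for f, d in flags if f and d),
                sum(1 for f, d in flags if f and not d),
            ],
            [
                sum(1 for f, d in flags if not f and d),
                sum(1 for f, d in flags if not f and not d),
            ],
        ]
    )
    return table, fisher_exact_two_sided(table).p_value


def aromatic_plus1(peptide: PeptideSequence) -> bool:
    """Tyrosine, tryptophan or phenylalanine directly after the acetyllysine."""
    return peptide.has_residue_at(1, "YWF")


def aromatic_plus1_or_plus2(peptide: PeptideSequence) -> bool:
    """W/Y/F at the +1 or +2 position."""
    return peptide.has_residue_at(1, "YWF") or peptide.has_residue_at(2, "YWF")


def descending_activity_ranks(
    records: list[ActivityRecord],
) -> dict[PeptideSequence, int]:
    """Rank detectable peptides by mean activity, 1 = most active."""
    detectable = sorted(
        (r for r in records if r.detectable), key=lambda r: -r.mean
    )
    return {r.peptide: i + 1 for i, r in enumerate(detectable)}


def endpoint_efficiency_correlation(
    endpoints: dict[PeptideSequence, float],
    efficiencies: dict[PeptideSequence, float],
) -> CorrelationResult:
    """Pearson correlation of endpoint activities vs catalytic efficiency.

    ``efficiencies`` may map to `MichaelisMentenResults`-like objects (their
    ``efficiency`` attribute is used) or plain numbers.
    """
    eff = {
        k: getattr(v, "efficiency", v) for k, v in efficiencies.items()
    }
    return activity_interaction_correlation(endpoints, eff)
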