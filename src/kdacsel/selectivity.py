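"""Cluster-based association of interaction frequencies with activity.

The procedure groups panel peptides into *substrate clusters* — all peptides
carrying one or two particular residues (default alphabet A, E, R, W, Y) at
the +1 or +2 position — and asks, per enzyme residue and interaction type,
whether cluster members interact differently from non-members (pooled
two-sample t-test, Bonferroni-corrected over the whole family, significance
p ≤ 0.01).  Clusters passing that stage are then tested for an activity
difference with a two-sided Mann–Whitney U test (p ≤ 0.05); the ranked test
blunts the influence of the residue at the other position.  Frame-level
co-occurrence of two interactions is assessed with a two-sided Fisher exact
test computed in log space, and interaction–activity relationships with
Pearson correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .peptides import PeptideSequence
from .trajectory import ResidueId

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (zero variance or too few points)."""


@dataclass(frozen=True)
class SubstrateCluster:
    """Peptides sharing one or two residues at one substrate position."""

    position: int
    residues: frozenset[str]
    members: frozenset[PeptideSequence]
    nonmembers: frozenset[PeptideSequence]

    @property
    def testable(self) -> bool:
        return bool(self.members) and bool(self.nonmembers)

    @property
    def label(self) -> str:
        res = "/".join(sorted(self.residues))
        return f"{res}@{self.position:+d}"


@dataclass
class ClusterTestResult:
    cluster: SubstrateCluster
    enzyme_residue: ResidueId
    itype: str
    t_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ActivityAssociation:
    cluster: SubstrateCluster
    U_statistic: float
    p_value: float
    direction: str  # "enhanced" | "inhibited"
    significant: bool


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


@dataclass
class FisherResult:
    table: np.ndarray
    p_value: float
    log10_p: float
    odds_direction: str  # "positive" | "negative" | "none"


# ---------------------------------------------------------------------------
# cluster enumeration
# ---------------------------------------------------------------------------

def enumerate_clusters(
    peptides: list[PeptideSequence],
    alphabet: str = "AERWY",
    positions: tuple[int, ...] = (1, 2),
) -> list[SubstrateCluster]:
    """All clusters of one or two alphabet residues at each position.

    For a 5-letter alphabet this yields 5 + C(5,2) = 15 clusters per
    position.  Clusters with no members or no non-members are still
    returned but flagged untestable.
    """
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    clusters = []
    letters = sorted(set(alphabet))
    subsets = [frozenset(c) for c in letters] + [
        frozenset(c) for c in itertools.combinations(letters, 2)
    ]
    for position in positions:
        for residues in subsets:
            members = frozenset(
                p for p in peptides if p.has_residue_at(position, residues)
            )
            clusters.append(
                SubstrateCluster(
                    position=position,
                    residues=residues,
                    members=members,
                    nonmembers=frozenset(peptides) - members,
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# stage 1: interaction t-tests
# ---------------------------------------------------------------------------

def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance t statistic and two-sided p.

    Degenerate zero-variance inputs: equal means give t = 0, p = 1; unequal
    means give p at the smallest positive double (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need ≥2 observations per group")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means; p → 0")
        return math.copysign(math.inf, diff), float(np.nextafter(0.0, 1.0))
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


def cluster_interaction_ttest(
    cluster: SubstrateCluster,
    freqs: dict[PeptideSequence, float],
    enzyme_residue: ResidueId = ("", 0, ""),
    itype: str = "contact",
    family_size: int = 1,
    alpha: float = 0.01,
) -> ClusterTestResult:
    """Members-vs-nonmembers pooled t-test on one interaction's frequency.

    ``family_size`` is the Bonferroni divisor — the number of tests run in
    the whole analysis invocation.
    """
    members = [freqs[p] for p in cluster.members if p in freqs]
    nonmembers = [freqs[p] for p in cluster.nonmembers if p in freqs]
    t, p = pooled_ttest(np.asarray(members), np.asarray(nonmembers))
    p_adj = min(1.0, family_size * p)
    return ClusterTestResult(
        cluster=cluster,
        enzyme_residue=enzyme_residue,
        itype=itype,
        t_statistic=t,
        p_raw=p,
        p_adjusted=p_adj,
        significant=bool(p_adj <= alpha),
    )


# ---------------------------------------------------------------------------
# stage 2: activity Mann–Whitney
# ---------------------------------------------------------------------------

def cluster_activity_mwu(
    cluster: SubstrateCluster,
    activities: dict[PeptideSequence, float],
    alpha: float = 0.05,
) -> ActivityAssociation:
    """Two-sided Mann–Whitney U of member vs non-member activities.

    Uses the exact null distribution when the smaller group has ≤ 8
    observations and there are no ties, otherwise the tie-corrected normal
    approximation.  Direction is taken from the median difference.
    """
    x = np.asarray(
        [activities[p] for p in cluster.members if p in activities], float
    )
    y = np.asarray(
        [activities[p] for p in cluster.nonmembers if p in activities], float
    )
    if x.size < 1 or y.size < 1:
        raise ValueError("need ≥1 member and ≥1 nonmember with activity")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return ActivityAssociation(
            cluster, x.size * y.size / 2.0, 1.0, "enhanced", False
        )
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = (
        "enhanced" if np.median(x) >= np.median(y) else "inhibited"
    )
    return ActivityAssociation(
        cluster=cluster,
        U_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        significant=bool(res.pvalue <= alpha),
    )


# ---------------------------------------------------------------------------
# Fisher exact test (log space)
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2×2 table, computed in log space.

    Sums hypergeometric probabilities no greater than the observed table's
    (with the customary (1 + 1e-7) relative slack), so p-values far below
    double underflow are still reported via ``log10_p``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2×2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if n_total == 0 or row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        warnings.warn("degenerate margin in Fisher table; p = 1")
        return FisherResult(t, 1.0, 0.0, "none")
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(ks, n_total, col1, row1)
    log_obs = float(logpmf[a - lo])
    mask = logpmf <= log_obs + math.log1p(1e-7)
    log_p = float(min(0.0, logsumexp(logpmf[mask])))
    expected = row1 * col1 / n_total
    direction = "positive" if a > expected else (
        "negative" if a < expected else "none"
    )
    return FisherResult(
        table=t,
        p_value=float(math.exp(log_p)),
        log10_p=log_p / math.log(10.0),
        odds_direction=direction,
    )


def cooccurrence_fisher(mask_a, mask_b) -> tuple[str, float]:
    """Association of two per-frame interaction masks.

    Builds the 2×2 frame-count table {a∧b, a∧¬b, ¬a∧b, ¬a∧¬b} and returns
    the direction of association and the two-sided Fisher p.  A degenerate
    margin (one mask constant) yields p = 1 with a warning.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("masks must be equal-length and non-empty")
    table = [
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ]
    res = fisher_exact_two_sided(table)
    return res.odds_direction, res.p_value


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def activity_interaction_correlation(
    x: dict, y: dict, exclude: set = frozenset()
) -> CorrelationResult:
    """Pearson correlation of summed interaction time against activity.

    ``x`` and ``y`` are keyed by peptide; only their common keys, minus
    ``exclude``, enter the fit.  Needs ≥3 points and non-zero variance.
    """
    keys = sorted(
        (set(x) & set(y)) - set(exclude), key=str
    )
    if len(keys) < 3:
        raise UndefinedCorrelationError("need ≥3 common peptides")
    xv = np.asarray([x[k] for k in keys], float)
    yv = np.asarray([y[k] for k in keys], float)
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    fit = stats.linregress(xv, yv)
    return CorrelationResult(
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(keys),
    )


# ---------------------------------------------------------------------------
# two-stage orchestration
# ---------------------------------------------------------------------------

@dataclass
class SelectivityReport:
    """All stage-1 tests plus stage-2 associations for the passing clusters."""

    cluster_tests: list[ClusterTestResult] = field(default_factory=list)
    activity_associations: dict[str, ActivityAssociation] = field(
        default_factory=dict
    )
    family_size: int = 0

    def significant_pairs(self) -> list[ClusterTestResult]:
        """Stage-1 hits whose cluster also shows an activity association."""
        return [
            r
            for r in self.cluster_tests
            if r.significant
            and self.activity_associations.get(r.cluster.label) is not None
            and self.activity_associations[r.cluster.label].significant
        ]


def run_selectivity_analysis(
    freq_by_key: dict[tuple[ResidueId, int, str], dict[PeptideSequence, float]],
    activities: dict[PeptideSequence, float],
    peptides: list[PeptideSequence] | None = None,
    alphabet: str = "AERWY",
    positions: tuple[int, ...] = (1, 2),
    cluster_alpha: float = 0.01,
    activity_alpha: float = 0.05,
) -> SelectivityReport:
    """Run the full two-stage procedure over a frequency panel.

    ``freq_by_key`` maps each (enzyme residue, substrate position,
    interaction type) to its per-peptide percent-time values.  Each cluster
    at position *P* is tested against every key at that same position; the
    Bonferroni family is every t-test actually run in this invocation.
    """
    if peptides is None:
        peptides = sorted(
            {p for freqs in freq_by_key.values() for p in freqs}, key=str
        )
    clusters = [
        c
        for c in enumerate_clusters(peptides, alphabet, positions)
        if c.testable and len(c.members) >= 2 and len(c.nonmembers) >= 2
    ]
    jobs = []
    for cluster in clusters:
        for key, freqs in freq_by_key.items():
            if key[1] != cluster.position:
                continue
            jobs.append((cluster, key, freqs))
    family = len(jobs)
    report = SelectivityReport(family_size=family)
    for cluster, (enz, _pos, itype), freqs in jobs:
        full = {p: freqs.get(p, 0.0) for p in peptides}
        report.cluster_tests.append(
            cluster_interaction_ttest(
                cluster, full, enz, itype, family_size=family,
                alpha=cluster_alpha,
            )
        )
    for result in report.cluster_tests:
        label = result.cluster.label
        if result.significant and label not in report.activity_associations:
            report.activity_associations[label] = cluster_activity_mwu(
                result.cluster, activities, alpha=activity_alpha
            )
    return report
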