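"""Evaluating a score table against curated gene lists.

The battery mirrors standard practice for gene-ranking validation:
logistic regression of list membership on the score, ROC AUC with a
DeLong confidence interval (low scores predicting membership), a
Mann-Whitney U comparison of member vs background scores, Pearson
correlation between score tables (sensitivity analyses across rho or
subpopulations), and group summaries (mean score, percentile of the mean
under the empirical score distribution, quartile-bin proportions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateStatisticsError, InputError
from .rvis_core import ScoreTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneListAnnotation:
    list_name: str
    members: frozenset
    background: frozenset

    def __post_init__(self) -> None:
        if self.members & self.background:
            raise InputError(
                f"list {self.list_name}: members overlap the background set"
            )


@dataclass
class AssociationResult:
    list_name: str
    n_members_scored: int
    n_background: int
    beta: float
    beta_ci95: tuple[float, float]
    p_logistic: float
    auc: float
    auc_ci95: tuple[float, float]
    u_statistic: float
    p_mwu: float
    separation_flag: bool = False


def resolve_list(
    scores: pd.Series, members, list_name: str = "list", background=None
) -> tuple[GeneListAnnotation, list[str]]:
    """Intersect a raw symbol list with the scored genes.

    Background defaults to all scored genes outside the list; pass an
    explicit iterable (e.g. genes in no disease list) to mirror stricter
    control sets. Returns the resolved annotation and the unresolvable
    symbols (reported, never silently dropped).
    """
    scored = set(scores.index)
    members = set(members)
    unresolved = sorted(members - scored)
    if unresolved:
        logger.warning("list %s: %d symbols not scored: %s",
                       list_name, len(unresolved), unresolved[:10])
    resolved = members & scored
    if background is None:
        bg = scored - resolved
    else:
        bg = (set(background) & scored) - resolved
    return GeneListAnnotation(list_name, frozenset(resolved), frozenset(bg)), unresolved


def _split(scores: pd.Series, gene_list: GeneListAnnotation):
    member_scores = scores.loc[sorted(gene_list.members)].to_numpy(dtype=float)
    bg_scores = scores.loc[sorted(gene_list.background)].to_numpy(dtype=float)
    return member_scores, bg_scores


def logistic_association(scores: pd.Series, gene_list: GeneListAnnotation):
    """Regress membership (0/1) on the score; Wald CI and p for the slope.

    Perfect separation yields a flagged result rather than a crash: beta
    is reported as ±inf (sign from the group-mean direction) with NaN CI
    and p.
    """
    m, b = _split(scores, gene_list)
    if len(m) < 2 or len(b) < 2:
        raise InputError(
            f"list {gene_list.list_name}: need >= 2 members and >= 2 background genes"
        )
    y = np.concatenate([np.ones(len(m)), np.zeros(len(b))])
    x = sm.add_constant(np.concatenate([m, b]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, x).fit(disp=0)
        beta = float(res.params[1])
        ci = tuple(res.conf_int()[1])
        p = float(res.pvalues[1])
        return beta, (float(ci[0]), float(ci[1])), p, False
    except Exception:
        logger.warning("list %s: perfect separation in logistic fit", gene_list.list_name)
        beta = float("-inf") if m.mean() < b.mean() else float("inf")
        return beta, (float("nan"), float("nan")), float("nan"), True


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Midrank-based AUC and DeLong structural components.

    ``pos`` are predictor values for the positive class (already oriented
    so larger predicts positive)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    midranks = stats.rankdata(allv, method="average")
    r_pos = stats.rankdata(pos, method="average")
    r_neg = stats.rankdata(neg, method="average")
    auc = (midranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (midranks[:m] - r_pos) / n            # per-positive components
    v01 = 1.0 - (midranks[m:] - r_neg) / m      # per-negative components
    return float(auc), v10, v01


def roc_auc_delong(
    scores: pd.Series, gene_list: GeneListAnnotation, lower_predicts_member: bool = True
):
    """Empirical ROC AUC (ties at half weight) with a DeLong 95% CI.

    With ``lower_predicts_member`` (the default for an intolerance score)
    low scores count as evidence for membership, so AUC > 0.5 means the
    list is enriched for intolerant genes.
    """
    m, b = _split(scores, gene_list)
    if len(m) == 0 or len(b) == 0:
        raise DegenerateStatisticsError("ROC needs both classes non-empty")
    sign = -1.0 if lower_predicts_member else 1.0
    auc, v10, v01 = _delong_components(sign * m, sign * b)
    var = 0.0
    if len(m) > 1:
        var += np.var(v10, ddof=1) / len(m)
    if len(b) > 1:
        var += np.var(v01, ddof=1) / len(b)
    half = 1.959963984540054 * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def mann_whitney(scores: pd.Series, gene_list: GeneListAnnotation):
    """Two-tailed rank-sum comparison of member vs background scores.

    Exact null distribution below 25 total observations when there are no
    ties; tie-corrected normal approximation with continuity correction
    otherwise.
    """
    m, b = _split(scores, gene_list)
    if len(m) == 0 or len(b) == 0:
        raise DegenerateStatisticsError("Mann-Whitney needs both groups non-empty")
    ties = len(np.unique(np.concatenate([m, b]))) < len(m) + len(b)
    method = "exact" if (len(m) + len(b) < 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(m, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def evaluate_list(
    scores: pd.Series, members, list_name: str = "list", background=None
) -> AssociationResult:
    """Run the full battery for one gene list against one score table."""
    gene_list, _ = resolve_list(scores, members, list_name, background)
    beta, ci, p_log, sep = logistic_association(scores, gene_list)
    auc, auc_ci = roc_auc_delong(scores, gene_list)
    u, p_mwu = mann_whitney(scores, gene_list)
    return AssociationResult(
        list_name=list_name,
        n_members_scored=len(gene_list.members),
        n_background=len(gene_list.background),
        beta=beta,
        beta_ci95=ci,
        p_logistic=p_log,
        auc=auc,
        auc_ci95=auc_ci,
        u_statistic=u,
        p_mwu=p_mwu,
        separation_flag=sep,
    )


@dataclass
class CorrelationResult:
    r: float
    ci95: tuple[float, float]
    n_joined: int
    n_dropped: int


def score_correlation(table_a: ScoreTable, table_b: ScoreTable) -> CorrelationResult:
    """Pearson r between two score tables on their gene intersection,
    with a Fisher-z 95% CI."""
    a = table_a.scores()
    b = table_b.scores()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise InputError(f"need >= 3 shared genes, got {len(common)}")
    x = a.loc[common].to_numpy(dtype=float)
    y = b.loc[common].to_numpy(dtype=float)
    r = float(stats.pearsonr(x, y).statistic)
    n = len(common)
    if abs(r) >= 1.0 or n <= 3:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    n_dropped = len(a.index.union(b.index)) - n
    return CorrelationResult(r=r, ci95=ci, n_joined=n, n_dropped=n_dropped)


@dataclass
class GroupSummary:
    list_name: str
    n_members_scored: int
    mean_score: float
    percentile_of_mean: float
    bin_proportions: tuple[float, ...]
    unresolved: tuple[str, ...]


def group_summary(
    score_table: ScoreTable,
    members,
    list_name: str = "list",
    bin_edges: tuple[float, ...] = (25.0, 50.0, 75.0),
) -> GroupSummary:
    """Mean member score, its percentile, and per-quartile proportions.

    ``percentile_of_mean`` places the mean score value on the empirical
    CDF of all scored genes (×100): "an average score of −0.56 sits at the
    19.5th percentile". Bin proportions count members per percentile bin
    (edges at 25/50/75 by default) and sum to 1.
    """
    scores = score_table.scores()
    percentiles = score_table.percentiles()
    resolved = sorted(set(members) & set(scores.index))
    unresolved = tuple(sorted(set(members) - set(scores.index)))
    if not resolved:
        raise InputError(
            f"list {list_name}: no member has a score; unresolved symbols: {list(unresolved)}"
        )
    member_scores = scores.loc[resolved].to_numpy(dtype=float)
    mean_s = float(member_scores.mean())
    ecdf = float(np.mean(scores.to_numpy(dtype=float) <= mean_s))
    member_pct = percentiles.loc[resolved].to_numpy(dtype=float)
    # right-closed bins: (0,25], (25,50], (50,75], (75,100]
    idx = np.digitize(member_pct, bins=np.asarray(bin_edges), right=True)
    counts = np.bincount(idx, minlength=len(bin_edges) + 1)
    props = tuple(counts / counts.sum())
    return GroupSummary(
        list_name=list_name,
        n_members_scored=len(resolved),
        mean_score=mean_s,
        percentile_of_mean=100.0 * ecdf,
        bin_proportions=props,
        unresolved=unresolved,
    )
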