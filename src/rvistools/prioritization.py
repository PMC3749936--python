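"""De novo mutation prioritization: quartile enrichment and the 2D hot zone.

Two analyses over trio-derived de novo mutation tables joined to a score
table. First, an exact binomial test of whether mutations of a given
effect class land in the most intolerant gene quartile more often than
the quartile's share of sequenced coding real estate predicts (default
success probability 0.38, recomputable from a score table plus gene
regions). Second, a two-dimensional scheme plotting each proband's single
most damaging de novo mutation as (PolyPhen-2 damaging score, gene
percentile) and counting probands in the "hot zone" — damaging score
>= 0.95 in a gene at or below the 25th percentile — with a Fisher exact
comparison of case vs control proportions. Likely gene-disrupting (LGD)
events are recoded to damaging score 1 and silent ones to 0 so that
non-missense mutations can enter the same plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticsError, InputError
from .rvis_core import ScoreTable

EFFECT_TYPES = ("missense", "LGD", "silent")

HOT_ZONE_X = 0.95  # minimum damaging score
HOT_ZONE_Y = 0.25  # maximum gene percentile / 100
DEFAULT_QUARTILE_P0 = 0.38  # coding real-estate share of the intolerant quartile


@dataclass(frozen=True)
class DeNovoMutation:
    """One de novo event in one proband, joined to a gene percentile."""

    proband_id: str
    cohort: str
    gene_symbol: str
    effect: str
    rvis_percentile: float
    pp2_score: float | None = None

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_TYPES:
            raise InputError(f"unknown de novo effect {self.effect!r}")
        if not 0 < self.rvis_percentile <= 100:
            raise InputError(f"percentile {self.rvis_percentile} outside (0, 100]")
        if self.pp2_score is not None and not 0 <= self.pp2_score <= 1:
            raise InputError(f"PolyPhen-2 score {self.pp2_score} outside [0, 1]")


@dataclass
class HotZoneResult:
    n_cases: int
    n_cases_in_zone: int
    n_controls: int
    n_controls_in_zone: int
    odds_ratio: float  # inf flagged when a margin is zero
    p_fisher: float

    @property
    def case_proportion(self) -> float:
        return self.n_cases_in_zone / self.n_cases

    @property
    def control_proportion(self) -> float:
        return self.n_controls_in_zone / self.n_controls


def damaging_score(mutation: DeNovoMutation) -> float:
    """Probabilistic damaging score on [0, 1].

    Missense events keep their PolyPhen-2 score; LGD events (nonsense,
    splice-site, frameshift-class) are recoded to 1 and silent events
    to 0.
    """
    if mutation.effect == "LGD":
        return 1.0
    if mutation.effect == "silent":
        return 0.0
    if mutation.pp2_score is None:
        raise InputError(
            f"missense de novo in {mutation.gene_symbol} ({mutation.proband_id}) "
            "has no PolyPhen-2 score"
        )
    return mutation.pp2_score


def select_representative(mutations, mode: str = "recoded") -> DeNovoMutation | None:
    """The single most damaging de novo of one proband.

    The primary key is the lowest gene percentile (the most intolerant
    gene hit); ties break toward the higher damaging score, then the
    lexicographically smallest gene symbol. ``mode="missense_only"``
    restricts eligibility to missense events; ``"recoded"`` admits every
    effect type via the recoded damaging score. Returns None when the
    proband has no eligible mutation (such probands leave downstream
    denominators).
    """
    if mode not in ("missense_only", "recoded"):
        raise InputError(f"unknown selection mode {mode!r}")
    eligible = [m for m in mutations if mode == "recoded" or m.effect == "missense"]
    if not eligible:
        return None
    return min(
        eligible,
        key=lambda m: (m.rvis_percentile, -damaging_score(m), m.gene_symbol),
    )


def hot_zone_flag(
    rvis_percentile: float,
    damaging: float,
    x_threshold: float = HOT_ZONE_X,
    y_threshold: float = HOT_ZONE_Y,
) -> bool:
    """True iff the mutation falls in the high-interest region: gene
    percentile/100 <= y_threshold and damaging score >= x_threshold,
    both boundaries inclusive."""
    return rvis_percentile / 100.0 <= y_threshold and damaging >= x_threshold


def cohort_zone_counts(
    mutations_by_proband: dict[str, list[DeNovoMutation]],
    mode: str = "recoded",
    x_threshold: float = HOT_ZONE_X,
    y_threshold: float = HOT_ZONE_Y,
) -> tuple[int, int]:
    """(probands with a representative, probands whose representative is
    in the hot zone)."""
    n = in_zone = 0
    for pid in sorted(mutations_by_proband):
        rep = select_representative(mutations_by_proband[pid], mode=mode)
        if rep is None:
            continue
        n += 1
        if hot_zone_flag(rep.rvis_percentile, damaging_score(rep), x_threshold, y_threshold):
            in_zone += 1
    return n, in_zone


def hot_zone_enrichment(
    case_mutations: dict[str, list[DeNovoMutation]],
    control_mutations: dict[str, list[DeNovoMutation]],
    mode: str = "recoded",
    x_threshold: float = HOT_ZONE_X,
    y_threshold: float = HOT_ZONE_Y,
) -> HotZoneResult:
    """Fisher exact comparison of case vs control hot-zone proportions.

    Inputs map proband id -> that proband's de novo mutations; each
    proband contributes one representative mutation. The odds ratio is
    the sample (cross-product) estimate, ``inf`` when a zero margin makes
    it undefined.
    """
    n_case, k_case = cohort_zone_counts(case_mutations, mode, x_threshold, y_threshold)
    n_ctrl, k_ctrl = cohort_zone_counts(control_mutations, mode, x_threshold, y_threshold)
    if n_case == 0 or n_ctrl == 0:
        raise InputError("each cohort needs >= 1 proband with a representative mutation")
    table = [[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]]
    res = stats.fisher_exact(table, alternative="two-sided")
    return HotZoneResult(
        n_cases=n_case,
        n_cases_in_zone=k_case,
        n_controls=n_ctrl,
        n_controls_in_zone=k_ctrl,
        odds_ratio=float(res.statistic),
        p_fisher=float(res.pvalue),
    )


def intolerant_quartile_binomial(
    k_in_intolerant: int, n_total: int, p0: float = DEFAULT_QUARTILE_P0
) -> float:
    """Exact two-tailed binomial p for k of n events in the intolerant
    quartile against success probability ``p0``.

    Two-tailed means summing the probability of every outcome no more
    likely than the observed one. ``p0`` defaults to 0.38, the share of
    sequenced coding bases held by the most intolerant quarter of genes;
    recompute it for other datasets with
    :func:`quartile_real_estate_fraction`.
    """
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= k_in_intolerant <= n_total:
        raise InputError(f"k={k_in_intolerant} outside [0, {n_total}]")
    if not 0 < p0 < 1:
        raise InputError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binomtest(k_in_intolerant, n_total, p0).pvalue)


def quartile_real_estate_fraction(
    score_table: ScoreTable, percentile_cutoff: float = 25.0
) -> float:
    """Fraction of covered coding bases held by genes at or below the
    percentile cutoff — the gene-size-adjusted success probability for
    the quartile binomial test."""
    t = score_table.table
    if "covered_sites" not in t.columns:
        raise InputError("score table lacks covered_sites; rebuild with gene regions")
    sizes = t["covered_sites"].to_numpy(dtype=float)
    total = sizes.sum()
    if total == 0:
        raise DegenerateStatisticsError("zero covered sites in score table")
    mask = t["percentile"].to_numpy(dtype=float) <= percentile_cutoff
    return float(sizes[mask].sum() / total)


def quartile_enrichment_report(
    denovo: pd.DataFrame,
    score_table: ScoreTable,
    p0: float | None = None,
    percentile_cutoff: float = 25.0,
) -> pd.DataFrame:
    """Per-cohort, per-effect-class enrichment of de novo events in the
    intolerant quartile (event counts, not probands).

    ``denovo`` needs columns cohort, gene, effect; genes missing from the
    score table are dropped with their count reported.
    """
    if p0 is None:
        p0 = quartile_real_estate_fraction(score_table, percentile_cutoff)
    pct = score_table.percentiles()
    rows = []
    for (cohort, effect), grp in denovo.groupby(["cohort", "effect"], sort=True):
        in_table = grp["gene"].isin(pct.index)
        scored = grp[in_table]
        n = len(scored)
        if n == 0:
            continue
        k = int((pct.loc[scored["gene"]].to_numpy() <= percentile_cutoff).sum())
        rows.append(
            {
                "cohort": cohort,
                "effect": effect,
                "n_events": n,
                "n_unscored": int((~in_table).sum()),
                "n_in_quartile": k,
                "proportion": k / n,
                "p0": p0,
                "p_binomial": intolerant_quartile_binomial(k, n, p0),
            }
        )
    return pd.DataFrame(rows)


def mutations_from_frame(denovo: pd.DataFrame, score_table: ScoreTable) -> dict[str, dict[str, list[DeNovoMutation]]]:
    """Join a de novo table (proband_id, cohort, gene, effect, pp2_score)
    to gene percentiles, grouped as cohort -> proband -> mutations.

    Events in unscored genes are dropped (no percentile to plot)."""
    pct = score_table.percentiles()
    out: dict[str, dict[str, list[DeNovoMutation]]] = {}
    for row in denovo.itertuples(index=False):
        if row.gene not in pct.index:
            continue
        pp2 = getattr(row, "pp2_score", None)
        if pp2 is not None and np.isnan(pp2):
            pp2 = None
        mut = DeNovoMutation(
            proband_id=str(row.proband_id),
            cohort=str(row.cohort),
            gene_symbol=str(row.gene),
            effect=str(row.effect),
            rvis_percentile=float(pct.loc[row.gene]),
            pp2_score=pp2,
        )
        out.setdefault(mut.cohort, {}).setdefault(mut.proband_id, []).append(mut)
    return out
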