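"""The intolerance score itself: per-gene tallies, regression, studentization.

For each assessable gene, X is the total number of qualifying coding
variants (functional and synonymous alike, at any frequency) and Y is the
number of common (MAF > rho) functional variants. An ordinary
least-squares regression of Y on X across the genome gives each gene a
predicted amount of common functional variation for its mutational burden;
the studentized residual from that fit is the score S. S < 0 means the
gene carries less common functional variation than genes of similar burden
— the signature expected under purifying selection — and S > 0 means more.
Percentiles rank genes ascending in S, so the most intolerant genes sit at
the lowest percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import variant_class as vc
from .errors import DegenerateFitError, DegenerateStatisticsError, InputError, UndefinedScoreError
from .gene_model import CoverageProfile, build_gene_regions

logger = logging.getLogger(__name__)

_LEVERAGE_TOL = 1e-12


@dataclass(frozen=True)
class GeneTally:
    """Per-gene regression inputs: total burden X and common functional Y."""

    gene_symbol: str
    x_total: int
    y_common_functional: int

    def __post_init__(self) -> None:
        if self.x_total < 0 or self.y_common_functional < 0:
            raise InputError(f"{self.gene_symbol}: negative tally")
        if self.y_common_functional > self.x_total:
            raise InputError(
                f"{self.gene_symbol}: Y={self.y_common_functional} exceeds X={self.x_total}"
            )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of Y on X with per-gene leverages and raw residuals.

    ``residual_std`` is sqrt(SSE / (n - 2)); ``leverage`` holds the hat
    matrix diagonal in input gene order.
    """

    intercept: float
    slope: float
    residual_std: float
    leverage: np.ndarray
    residuals: np.ndarray
    genes: tuple[str, ...]
    n_genes: int


@dataclass
class ScoreTable:
    """Per-gene scores plus run provenance.

    ``table`` is indexed by gene symbol with columns
    ``x_total, y_common_functional, rvis, percentile`` (and optionally
    ``covered_sites``); ``meta`` records rho, population, mode and the
    thresholds used; ``unassessable`` lists genes dropped before scoring
    with reasons.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    unassessable: pd.DataFrame | None = None

    def scores(self) -> pd.Series:
        return self.table["rvis"]

    def percentiles(self) -> pd.Series:
        return self.table["percentile"]


def tally_gene(records, rho: float = 0.1, population: str = "ALL", mode: str = "standard") -> GeneTally:
    """Count X and Y for one gene's qualifying records.

    X counts every record classed functional or non-functional (in pp2
    mode, benign-relabeled missense therefore still count toward X); Y
    counts functional records with MAF above rho.
    """
    records = list(records)
    if not records:
        raise InputError("tally_gene needs the gene symbol; pass at least one record")
    genes = {r.gene_symbol for r in records}
    if len(genes) != 1:
        raise InputError(f"records span multiple genes: {sorted(genes)}")
    x = 0
    y = 0
    for r in records:
        cls = vc.classify(r, mode=mode)
        if cls is vc.VariantClass.EXCLUDED:
            continue
        x += 1
        if cls is vc.VariantClass.FUNCTIONAL and vc.is_common(r, rho=rho, population=population):
            y += 1
    return GeneTally(gene_symbol=genes.pop(), x_total=x, y_common_functional=y)


def fit_regression(tallies) -> RegressionFit:
    """Ordinary least squares of Y on X with an intercept.

    Closed-form normal equations; leverages h_i = 1/n + (x_i - x̄)²/Sxx.
    """
    tallies = list(tallies)
    n = len(tallies)
    if n < 3:
        raise DegenerateStatisticsError(f"need >= 3 genes to fit, got {n}")
    x = np.array([t.x_total for t in tallies], dtype=float)
    y = np.array([t.y_common_functional for t in tallies], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateStatisticsError("X is constant across genes; design is degenerate")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    residual_std = float(np.sqrt(sse / (n - 2)))
    leverage = 1.0 / n + (x - x.mean()) ** 2 / sxx
    return RegressionFit(
        intercept=intercept,
        slope=slope,
        residual_std=residual_std,
        leverage=leverage,
        residuals=resid,
        genes=tuple(t.gene_symbol for t in tallies),
        n_genes=n,
    )


def studentize(fit: RegressionFit, method: str = "internal") -> pd.Series:
    """Scale raw residuals by their estimated standard deviation.

    ``internal`` (default): S_i = r_i / (σ̂ · sqrt(1 − h_ii)) with σ̂ the
    whole-fit residual standard deviation. ``external``: σ̂ is recomputed
    excluding gene i (the jackknife form). Either way the leverage term
    gives high-burden genes the wider error band their position in the
    design warrants.
    """
    if method not in ("internal", "external"):
        raise InputError(f"unknown studentization method {method!r}")
    if fit.residual_std == 0:
        raise DegenerateFitError("zero residual variance; studentized residuals undefined")
    h = fit.leverage
    if np.any(h >= 1 - _LEVERAGE_TOL):
        bad = [g for g, hi in zip(fit.genes, h) if hi >= 1 - _LEVERAGE_TOL]
        raise UndefinedScoreError(f"leverage 1 for genes {bad}; score undefined")
    r = fit.residuals
    if method == "internal":
        s = fit.residual_std
        values = r / (s * np.sqrt(1 - h))
    else:
        n = fit.n_genes
        if n < 4:
            raise DegenerateStatisticsError("external studentization needs >= 4 genes")
        sse = fit.residual_std**2 * (n - 2)
        s2_i = (sse - r**2 / (1 - h)) / (n - 3)
        s2_i = np.maximum(s2_i, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = r / (np.sqrt(s2_i) * np.sqrt(1 - h))
        values[r == 0] = 0.0
    return pd.Series(values, index=list(fit.genes), name="rvis")


def percentile_rank(scores: pd.Series) -> pd.Series:
    """Ascending percentile ranks in (0, 100], ties by average rank.

    The lowest score receives the lowest percentile, so the most
    intolerant genes sit at the bottom of the ranking.
    """
    if len(scores) == 0:
        raise InputError("cannot rank an empty score vector")
    ranks = rankdata(scores.to_numpy(), method="average")
    return pd.Series(100.0 * ranks / len(scores), index=scores.index, name="percentile")


def compute_rvis(
    variants,
    exons,
    coverage: CoverageProfile | None,
    *,
    rho: float = 0.1,
    population: str = "ALL",
    mode: str = "standard",
    min_depth: float = 10.0,
    min_fraction: float = 0.70,
    splice_pad: int = 2,
    studentization: str = "internal",
) -> ScoreTable:
    """End-to-end scoring: regions → qualifying variants → tallies → S.

    One row per assessable gene (genes with zero qualifying variants are
    retained with X=Y=0: excluding them would bias the genome-wide fit);
    unassessable genes are reported separately with reasons. Deterministic
    given inputs and configuration.
    """
    regions = build_gene_regions(
        exons, coverage, splice_pad=splice_pad, min_depth=min_depth, min_fraction=min_fraction
    )
    dropped = []
    assessable = {}
    for gene in sorted(regions):
        region = regions[gene]
        if coverage is not None and not region.assessable:
            frac = region.covered_sites / region.total_sites
            dropped.append((gene, f"covered fraction {frac:.3f} < {min_fraction}"))
        else:
            assessable[gene] = region
    logger.info(
        "gene regions: %d total, %d assessable, %d dropped",
        len(regions), len(assessable), len(dropped),
    )

    per_gene: dict[str, list] = {g: [] for g in assessable}
    n_seen = n_unknown_gene = n_disqualified = 0
    for rec in variants:
        n_seen += 1
        region = assessable.get(rec.gene_symbol)
        if region is None:
            n_unknown_gene += 1
            continue
        if not vc.qualify(rec, region):
            n_disqualified += 1
            continue
        per_gene[rec.gene_symbol].append(rec)
    logger.info(
        "variants: %d seen, %d in unassessable/unknown genes, %d disqualified",
        n_seen, n_unknown_gene, n_disqualified,
    )

    tallies = []
    for gene in sorted(assessable):
        recs = per_gene[gene]
        if recs:
            tallies.append(tally_gene(recs, rho=rho, population=population, mode=mode))
        else:
            tallies.append(GeneTally(gene_symbol=gene, x_total=0, y_common_functional=0))

    fit = fit_regression(tallies)
    logger.info(
        "fit: slope=%.6g intercept=%.6g residual_std=%.6g over %d genes",
        fit.slope, fit.intercept, fit.residual_std, fit.n_genes,
    )
    s = studentize(fit, method=studentization)
    pct = percentile_rank(s)
    table = pd.DataFrame(
        {
            "x_total": [t.x_total for t in tallies],
            "y_common_functional": [t.y_common_functional for t in tallies],
            "rvis": s.to_numpy(),
            "percentile": pct.to_numpy(),
            "covered_sites": [
                assessable[t.gene_symbol].covered_sites
                if assessable[t.gene_symbol].covered_sites is not None
                else assessable[t.gene_symbol].total_sites
                for t in tallies
            ],
        },
        index=pd.Index([t.gene_symbol for t in tallies], name="gene"),
    )
    meta = {
        "rho": rho,
        "population": population,
        "mode": mode,
        "min_depth": min_depth,
        "min_fraction": min_fraction,
        "splice_pad": splice_pad,
        "studentization": studentization,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "residual_std": fit.residual_std,
        "n_genes": fit.n_genes,
    }
    unassessable = pd.DataFrame(dropped, columns=["gene", "reason"])
    return ScoreTable(table=table, meta=meta, unassessable=unassessable)
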