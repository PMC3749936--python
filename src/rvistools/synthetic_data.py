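"""Synthetic exome cohorts with known intolerance ground truth.

The generator emulates the statistical structure the score assumes: the
number of common functional variants in a gene grows roughly in
proportion to its total variant burden genome-wide, while a designated
"intolerant" subset of genes has its common functional variation
suppressed (purifying selection keeps functional alleles rare without
changing how many variant sites the gene accumulates overall). Output
tables use the same dialects the file readers consume, so every other
module is testable without any external download. Minor-allele
frequencies come from a two-component mixture (rare: below the common
threshold; common: above) rather than a realistic site-frequency
spectrum — the score only consumes the threshold indicator.

Defaults sketch an ESP-scale exome: 2000 genes with log-normal coding
lengths (median ~1.4 kb), one variant site per ~50 coding bases, 70% of
sites functional, a quarter of sites common at the 0.1% MAF threshold,
10% of genes intolerant with their common functional variation cut to
20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gene_model import TranscriptExon
from .rvis_core import ScoreTable

_BASES = np.array(list("ACGT"))

_FUNCTIONAL_EFFECTS = ["missense", "missense-near-splice", "stop-gained",
                       "splice-5", "splice-3", "stop-lost"]
_FUNCTIONAL_WEIGHTS = [0.87, 0.03, 0.05, 0.02, 0.02, 0.01]
_NON_FUNCTIONAL_EFFECTS = ["coding-synonymous", "coding-synonymous-near-splice"]
_NON_FUNCTIONAL_WEIGHTS = [0.97, 0.03]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the exome and trio generators.

    Lengths are coding base pairs; rates are per base; all fractions are
    probabilities. ``suppression`` multiplies the probability that a
    functional variant in an intolerant gene is common.
    """

    n_genes: int = 2000
    gene_length_log_mean: float = math.log(1400.0)
    gene_length_log_sd: float = 0.6
    variant_rate_per_base: float = 0.02
    functional_fraction: float = 0.70
    common_fraction: float = 0.25
    intolerant_fraction: float = 0.10
    suppression: float = 0.20
    rho: float = 0.1  # percent MAF dividing rare from common
    depth: float = 50.0
    non_pass_fraction: float = 0.02
    pp2_benign_fraction: float = 0.30
    pp2_unknown_fraction: float = 0.02
    # trio simulation
    n_cases: int = 100
    n_controls: int = 100
    background_mutation_mean: float = 1.2
    causal_hit_rate: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError(f"n_genes must be >= 10, got {self.n_genes}")
        for name in (
            "functional_fraction", "common_fraction", "intolerant_fraction",
            "suppression", "non_pass_fraction", "pp2_benign_fraction",
            "pp2_unknown_fraction", "causal_hit_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.variant_rate_per_base <= 0:
            raise ConfigError("variant_rate_per_base must be > 0")
        if not 0 < self.rho < 100:
            raise ConfigError("rho must be in (0, 100)")


@dataclass
class SimulatedExome:
    """Generator output bundle: the standard module inputs plus truth."""

    exons: list  # TranscriptExon
    coverage: pd.DataFrame  # chrom, start, end, mean_depth
    variants: pd.DataFrame  # EVS-style variant table
    truth: pd.DataFrame  # gene, intolerant
    config: SimulationConfig = field(repr=False, default=None)

    def coverage_profile(self):
        from .gene_model import CoverageProfile

        return CoverageProfile(self.coverage.itertuples(index=False, name=None))


def _draw_maf(rng: np.random.Generator, common: np.ndarray, rho: float) -> np.ndarray:
    """Two-component MAF mixture in percent: log-uniform below rho for
    rare sites, log-uniform on (rho, 50] for common ones."""
    n = len(common)
    lo_rare, hi_rare = math.log10(0.008), math.log10(rho)
    lo_com, hi_com = math.log10(rho * 1.0001), math.log10(50.0)
    u = rng.uniform(size=n)
    maf = np.where(
        common,
        10 ** (lo_com + u * (hi_com - lo_com)),
        10 ** (lo_rare + u * (hi_rare - lo_rare)),
    )
    return maf


def simulate_exome(config: SimulationConfig | None = None) -> SimulatedExome:
    """Generate transcripts, coverage, an EVS-style variant table, and
    per-gene truth labels. Deterministic given ``config.seed``.

    Per gene: a log-normal coding length split over 1–3 exons on one
    synthetic chromosome, full coverage at ``config.depth``, a Poisson
    number of variant sites, effects split functional vs synonymous, and
    MAFs drawn so a ``common_fraction`` of sites exceed ``rho`` — except
    that functional sites of intolerant genes are common with probability
    ``common_fraction × suppression``.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    lengths = np.maximum(
        150,
        rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd, cfg.n_genes).astype(int),
    )
    n_intol = int(round(cfg.n_genes * cfg.intolerant_fraction))
    intolerant = np.zeros(cfg.n_genes, dtype=bool)
    intolerant[rng.choice(cfg.n_genes, size=n_intol, replace=False)] = True

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    chrom = "chrS"
    exons: list[TranscriptExon] = []
    gene_intervals: dict[str, list[tuple[int, int]]] = {}
    cursor = 1000
    for i, gene in enumerate(genes):
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, lengths[i]), size=n_ex - 1, replace=False)) \
            if n_ex > 1 else np.empty(0, dtype=int)
        parts = np.diff([0, *cuts, lengths[i]])
        ivs = []
        for j, width in enumerate(parts):
            start, end = cursor, cursor + int(width)
            exons.append(TranscriptExon(gene, f"{gene}.t1", chrom, start, end))
            ivs.append((start, end))
            cursor = end + 200  # intron gap
        gene_intervals[gene] = ivs
        cursor += 1000  # intergenic gap

    pad = 2
    coverage = pd.DataFrame(
        [
            (chrom, max(0, s - pad), e + pad, cfg.depth)
            for gene in genes
            for s, e in gene_intervals[gene]
        ],
        columns=["chrom", "start", "end", "mean_depth"],
    )

    rows = []
    for i, gene in enumerate(genes):
        n_var = rng.poisson(cfg.variant_rate_per_base * lengths[i])
        if n_var == 0:
            continue
        sites = np.concatenate([np.arange(s, e) for s, e in gene_intervals[gene]])
        n_var = min(n_var, len(sites))
        pos = np.sort(rng.choice(sites, size=n_var, replace=False))
        functional = rng.uniform(size=n_var) < cfg.functional_fraction
        effects = np.empty(n_var, dtype=object)
        effects[functional] = rng.choice(
            _FUNCTIONAL_EFFECTS, size=int(functional.sum()), p=_FUNCTIONAL_WEIGHTS
        )
        effects[~functional] = rng.choice(
            _NON_FUNCTIONAL_EFFECTS, size=int((~functional).sum()), p=_NON_FUNCTIONAL_WEIGHTS
        )
        p_common = np.where(
            functional & intolerant[i],
            cfg.common_fraction * cfg.suppression,
            cfg.common_fraction,
        )
        common = rng.uniform(size=n_var) < p_common
        maf_all = _draw_maf(rng, common, cfg.rho)
        # subpopulation MAFs scatter around the combined value
        jitter = lambda: np.clip(maf_all * rng.lognormal(0.0, 0.3, n_var), 0.0, 50.0)
        maf_ea, maf_aa = jitter(), jitter()
        ref_idx = rng.integers(0, 4, size=n_var)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_var)) % 4
        status = np.where(rng.uniform(size=n_var) < cfg.non_pass_fraction, "FAIL", "PASS")
        is_missense = np.isin(effects, ["missense", "missense-near-splice"])
        pp2_label = np.full(n_var, "", dtype=object)
        pp2_score = np.full(n_var, np.nan)
        if is_missense.any():
            k = int(is_missense.sum())
            u = rng.uniform(size=k)
            labels = np.where(
                u < cfg.pp2_benign_fraction,
                "benign",
                np.where(
                    u < cfg.pp2_benign_fraction + cfg.pp2_unknown_fraction,
                    "unknown",
                    rng.choice(["possibly", "probably"], size=k),
                ),
            )
            score = np.where(
                labels == "benign",
                rng.beta(1, 8, size=k),
                rng.beta(8, 1, size=k),
            )
            pp2_label[is_missense] = labels
            pp2_score[is_missense] = np.round(score, 3)
        for j in range(n_var):
            rows.append(
                (
                    gene, chrom, int(pos[j]), _BASES[ref_idx[j]], _BASES[alt_idx[j]],
                    effects[j],
                    f"{maf_ea[j]:.4f}/{maf_aa[j]:.4f}/{maf_all[j]:.4f}",
                    status[j], pp2_label[j],
                    "" if np.isnan(pp2_score[j]) else f"{pp2_score[j]:.3f}",
                )
            )
    variants = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "pos", "ref", "alt", "effect",
            "maf_percent_ea_aa_all", "filter", "pp2_label", "pp2_score",
        ],
    )
    truth = pd.DataFrame({"gene": genes, "intolerant": intolerant})
    return SimulatedExome(
        exons=exons, coverage=coverage, variants=variants, truth=truth, config=cfg
    )


def _draw_background_mutation(rng, genes, weights, pct):
    gene = genes[rng.choice(len(genes), p=weights)]
    u = rng.uniform()
    if u < 0.70:
        effect = "missense"
        pp2 = float(np.round(rng.beta(1, 4) if rng.uniform() < 0.5 else rng.beta(4, 1), 3))
    elif u < 0.80:
        effect, pp2 = "LGD", None
    else:
        effect, pp2 = "silent", None
    return gene, effect, pp2


def simulate_trios(
    score_table: ScoreTable,
    truth: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case and control de novo mutation tables with planted causal hits.

    Control probands draw a Poisson number of background mutations from
    scored genes in proportion to covered length, with bimodal background
    PolyPhen-2 scores. Case probands additionally receive, with
    probability ``causal_hit_rate``, one damaging mutation (missense with
    PolyPhen-2 >= 0.95, or LGD) in a truth-intolerant scored gene.
    Columns: proband_id, cohort, gene, effect, pp2_score. Deterministic
    given the seed (``config.seed`` unless ``seed`` overrides).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t = score_table.table
    genes = list(t.index)
    sizes = t["covered_sites"].to_numpy(dtype=float)
    weights = sizes / sizes.sum()
    pct = score_table.percentiles()
    intol_genes = [
        g for g in truth.loc[truth["intolerant"], "gene"] if g in t.index
    ]
    if not intol_genes:
        raise ConfigError("no truth-intolerant gene is present in the score table")

    def cohort(label: str, n: int, causal: bool) -> pd.DataFrame:
        rows = []
        for p in range(n):
            pid = f"{label}{p:04d}"
            for _ in range(rng.poisson(cfg.background_mutation_mean)):
                gene, effect, pp2 = _draw_background_mutation(rng, genes, weights, pct)
                rows.append((pid, label, gene, effect, pp2))
            if causal and rng.uniform() < cfg.causal_hit_rate:
                gene = intol_genes[rng.choice(len(intol_genes))]
                if rng.uniform() < 0.8:
                    rows.append(
                        (pid, label, gene, "missense",
                         float(np.round(rng.uniform(0.95, 1.0), 3)))
                    )
                else:
                    rows.append((pid, label, gene, "LGD", None))
        return pd.DataFrame(
            rows, columns=["proband_id", "cohort", "gene", "effect", "pp2_score"]
        )

    cases = cohort("case", cfg.n_cases, causal=True)
    controls = cohort("ctrl", cfg.n_controls, causal=False)
    return cases, controls


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
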