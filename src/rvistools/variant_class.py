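"""Qualifying-variant filtering and functional classification.

Only PASS-filtered single-nucleotide substitutions at covered coding sites
qualify. Qualifying variants are partitioned into "functional" (missense,
nonsense/stop, splice acceptor/donor and their near-splice variants) and
"non-functional" (synonymous) classes. In PolyPhen-2-informed mode (the
RVIS-PP2 variant of the score) missense variants with a "benign"
qualitative prediction are relabeled non-functional; truncating and splice
classes are never affected by that mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .errors import InputError
from .gene_model import GeneRegion

logger = logging.getLogger(__name__)

# Effect-annotation vocabulary for coding sites (EVS/ESP dialect).
FUNCTIONAL_EFFECTS = frozenset(
    {
        "missense",
        "stop-gained",
        "missense-near-splice",
        "stop-lost",
        "splice-5",
        "splice-3",
        "stop-gained-near-splice",
        "stop-lost-near-splice",
    }
)
NON_FUNCTIONAL_EFFECTS = frozenset({"coding-synonymous", "coding-synonymous-near-splice"})
CODING_EFFECTS = FUNCTIONAL_EFFECTS | NON_FUNCTIONAL_EFFECTS

#: Effects eligible for PolyPhen-2 relabeling in pp2 mode.
MISSENSE_EFFECTS = frozenset({"missense", "missense-near-splice"})

PP2_LABELS = frozenset({"benign", "possibly", "probably", "unknown"})

_BASES = frozenset("ACGT")


class VariantClass(Enum):
    FUNCTIONAL = "functional"
    NON_FUNCTIONAL = "non-functional"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class VariantRecord:
    """One site-allele with its annotation and allele frequencies.

    MAF fields are percentages in [0, 100]. Multi-allelic sites are
    represented as one record per alternate allele.
    """

    gene_symbol: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    effect: str
    maf_all: float | None
    maf_ea: float | None = None
    maf_aa: float | None = None
    filter_status: str = "PASS"
    pp2_label: str | None = None
    pp2_score: float | None = None

    def __post_init__(self) -> None:
        for name in ("maf_all", "maf_ea", "maf_aa"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise InputError(
                    f"{self.gene_symbol} {self.chrom}:{self.pos}: {name}={v} outside [0, 100]"
                )
        if self.pp2_label is not None and self.pp2_label not in PP2_LABELS:
            raise InputError(f"unknown PolyPhen-2 label {self.pp2_label!r}")
        if self.pp2_score is not None and not 0 <= self.pp2_score <= 1:
            raise InputError(f"PolyPhen-2 score {self.pp2_score} outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele.upper() in _BASES
            and self.alt_allele.upper() in _BASES
        )


def qualify(record: VariantRecord, region: GeneRegion) -> bool:
    """True iff the record counts toward the score at all.

    Requires a PASS filter status, a single-nucleotide substitution
    (indels are excluded as less reliably called), a position inside the
    region's covered-site mask, and a coding effect annotation.
    """
    return (
        record.filter_status == "PASS"
        and record.is_snv
        and record.chrom == region.chrom
        and region.covers(record.pos)
        and record.effect in CODING_EFFECTS
    )


def classify(
    record: VariantRecord,
    mode: str = "standard",
    missing_pp2: str = "error",
) -> VariantClass:
    """Assign the functional / non-functional / excluded class.

    ``mode="pp2"`` relabels benign-predicted missense as non-functional
    while possibly/probably/unknown missense stay functional; truncating
    and splice classes are untouched. Unknown effect strings are excluded
    with a warning. ``missing_pp2`` controls pp2 mode when a missense
    record lacks a label: ``"error"`` (default) raises, ``"exclude"``
    returns EXCLUDED.
    """
    if mode not in ("standard", "pp2"):
        raise InputError(f"unknown classification mode {mode!r}")
    eff = record.effect
    if eff in NON_FUNCTIONAL_EFFECTS:
        return VariantClass.NON_FUNCTIONAL
    if eff not in FUNCTIONAL_EFFECTS:
        logger.warning(
            "unknown effect annotation %r at %s:%d — excluded", eff, record.chrom, record.pos
        )
        return VariantClass.EXCLUDED
    if mode == "pp2" and eff in MISSENSE_EFFECTS:
        if record.pp2_label is None:
            if missing_pp2 == "error":
                raise InputError(
                    f"pp2 mode: missense record at {record.chrom}:{record.pos} "
                    "has no PolyPhen-2 label"
                )
            return VariantClass.EXCLUDED
        if record.pp2_label == "benign":
            return VariantClass.NON_FUNCTIONAL
    return VariantClass.FUNCTIONAL


def is_common(record: VariantRecord, rho: float = 0.1, population: str = "ALL") -> bool:
    """True iff the selected population's MAF strictly exceeds ``rho``
    (both in percent)."""
    if not 0 < rho < 100:
        raise InputError(f"rho must be in (0, 100), got {rho}")
    try:
        maf = {"ALL": record.maf_all, "EA": record.maf_ea, "AA": record.maf_aa}[population]
    except KeyError:
        raise InputError(f"unknown population {population!r}") from None
    if maf is None:
        raise InputError(
            f"{record.gene_symbol} {record.chrom}:{record.pos}: "
            f"no MAF for population {population}"
        )
    return maf > rho
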