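"""File-boundary readers and writers plus run configuration.

Everything on disk is TSV with '#'-prefixed header/metadata lines, except
the standard genomics formats (BED, GFF3, VCF) which follow their own
conventions. Coordinates are 0-based half-open internally; variant
positions are converted from/to the 1-based convention of EVS-style
tables and VCF at this boundary, and BED stays 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import pyranges as pr
import pysam
import yaml

from .errors import ConfigError, InputError
from .gene_model import CoverageProfile, TranscriptExon
from .rvis_core import ScoreTable
from .variant_class import VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs for a scoring run; defaults are the published
    choices (rho 0.1% in the combined cohort, 10-fold depth, 70%
    assessability, 2 bp splice pads, internal studentization, hot zone
    at damaging >= 0.95 and percentile <= 25)."""

    rho: float = 0.1
    population: str = "ALL"
    mode: str = "standard"
    min_depth: float = 10.0
    min_fraction: float = 0.70
    splice_pad: int = 2
    studentization: str = "internal"
    hot_zone_x: float = 0.95
    hot_zone_y: float = 0.25
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.rho < 100:
            raise ConfigError(f"rho must be in (0, 100), got {self.rho}")
        if self.population not in ("ALL", "EA", "AA"):
            raise ConfigError(f"population must be ALL/EA/AA, got {self.population!r}")
        if self.mode not in ("standard", "pp2"):
            raise ConfigError(f"mode must be standard/pp2, got {self.mode!r}")
        if self.min_depth <= 0:
            raise ConfigError("min_depth must be > 0")
        if not 0 < self.min_fraction <= 1:
            raise ConfigError("min_fraction must be in (0, 1]")
        if self.splice_pad < 0:
            raise ConfigError("splice_pad must be >= 0")
        if self.studentization not in ("internal", "external"):
            raise ConfigError(f"unknown studentization {self.studentization!r}")
        if not 0 <= self.hot_zone_x <= 1 or not 0 <= self.hot_zone_y <= 1:
            raise ConfigError("hot zone thresholds must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# transcripts

def write_transcripts_bed(exons, path) -> None:
    """BED6 with name = 'gene|transcript'."""
    with open(path, "w") as fh:
        for e in exons:
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.gene_symbol}|{e.transcript_id}"
                f"\t0\t{e.strand}\n"
            )


def read_transcripts_bed(path) -> list[TranscriptExon]:
    """BED with name = 'gene|transcript' (transcript optional)."""
    df = pr.read_bed(str(path), as_df=True)
    exons = []
    for row in df.itertuples(index=False):
        name = str(row.Name)
        gene, _, transcript = name.partition("|")
        strand = getattr(row, "Strand", "+")
        exons.append(
            TranscriptExon(
                gene_symbol=gene,
                transcript_id=transcript or gene,
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=str(strand) if strand in ("+", "-") else "+",
            )
        )
    if not exons:
        raise InputError(f"no exons read from {path}")
    return exons


def read_transcripts_gff3(
    path, gene_attribute: str = "gene_name", transcript_attribute: str = "transcript_id"
) -> list[TranscriptExon]:
    """Exon features of a GFF3 file; the gene symbol comes from the
    configured attribute key."""
    df = pr.read_gff3(str(path), full=True, as_df=True)
    df = df[df["Feature"] == "exon"]
    if gene_attribute not in df.columns:
        raise ConfigError(f"GFF3 attribute {gene_attribute!r} not present in {path}")
    exons = []
    for row in df.itertuples(index=False):
        gene = getattr(row, gene_attribute)
        transcript = getattr(row, transcript_attribute, None) or gene
        strand = getattr(row, "Strand", "+")
        exons.append(
            TranscriptExon(
                gene_symbol=str(gene),
                transcript_id=str(transcript),
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=str(strand) if strand in ("+", "-") else "+",
            )
        )
    if not exons:
        raise InputError(f"no exon features read from {path}")
    return exons


# ---------------------------------------------------------------------------
# coverage

def write_coverage_bed(coverage: pd.DataFrame, path) -> None:
    coverage.to_csv(path, sep="\t", header=False, index=False)


def read_coverage_bed(path) -> CoverageProfile:
    """BED-like TSV: chrom, start, end, mean depth (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "mean_depth"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise InputError(f"empty coverage file {path}")
    return CoverageProfile(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# variants

#: Column map for the EVS-style dialect the simulator writes. ``maf``
#: names a combined "EA/AA/All" percentage column; alternatively map the
#: separate keys maf_ea / maf_aa / maf_all.
DEFAULT_VARIANT_COLUMNS = {
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "effect": "effect",
    "maf": "maf_percent_ea_aa_all",
    "filter": "filter",
    "pp2_label": "pp2_label",
    "pp2_score": "pp2_score",
}


def write_variant_table(variants: pd.DataFrame, path) -> None:
    """Write the simulator's variant frame in the EVS-style dialect
    (positions converted to 1-based)."""
    out = variants.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_variant_table(
    path, column_map: dict | None = None
) -> tuple[list[VariantRecord], int]:
    """EVS-style TSV to typed records (positions converted to 0-based).

    Per-line parse failures are logged with line numbers and skipped;
    returns (records, n_skipped). A missing required column is a
    configuration error.
    """
    cmap = dict(DEFAULT_VARIANT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, keep_default_na=False)
    required = ["gene", "chrom", "pos", "ref", "alt", "effect", "filter"]
    for key in required:
        if cmap.get(key) not in df.columns:
            raise ConfigError(f"variant table {path} lacks column {cmap.get(key)!r} ({key})")
    has_combined = cmap.get("maf") in df.columns
    records: list[VariantRecord] = []
    n_skipped = 0
    for i, values in enumerate(df.to_dict("records"), start=2):
        try:
            if has_combined:
                parts = str(values[cmap["maf"]]).split("/")
                if len(parts) != 3:
                    raise ValueError(f"bad MAF field {values[cmap['maf']]!r}")
                maf_ea, maf_aa, maf_all = (float(p) for p in parts)
            else:
                maf_ea = _opt_float(values.get(cmap.get("maf_ea", ""), ""))
                maf_aa = _opt_float(values.get(cmap.get("maf_aa", ""), ""))
                maf_all = _opt_float(values.get(cmap.get("maf_all", ""), ""))
            label = values.get(cmap.get("pp2_label", ""), "") or None
            score = _opt_float(values.get(cmap.get("pp2_score", ""), ""))
            records.append(
                VariantRecord(
                    gene_symbol=str(values[cmap["gene"]]),
                    chrom=str(values[cmap["chrom"]]),
                    pos=int(values[cmap["pos"]]) - 1,
                    ref_allele=str(values[cmap["ref"]]),
                    alt_allele=str(values[cmap["alt"]]),
                    effect=str(values[cmap["effect"]]),
                    maf_all=maf_all,
                    maf_ea=maf_ea,
                    maf_aa=maf_aa,
                    filter_status=str(values[cmap["filter"]]),
                    pp2_label=label,
                    pp2_score=score,
                )
            )
        except (ValueError, InputError) as exc:
            n_skipped += 1
            logger.warning("%s line %d skipped: %s", path, i, exc)
    logger.info("%s: %d records read, %d lines skipped", path, len(records), n_skipped)
    return records, n_skipped


def _opt_float(raw) -> float | None:
    raw = str(raw).strip()
    if raw in ("", ".", "NA", "nan"):
        return None
    return float(raw)


#: INFO-key map for VCF input.
DEFAULT_VCF_INFO = {
    "gene": "GENE",
    "effect": "EFFECT",
    "maf_ea": "MAF_EA",
    "maf_aa": "MAF_AA",
    "maf_all": "MAF_ALL",
    "pp2_label": "PP2_LABEL",
    "pp2_score": "PP2_SCORE",
}


def read_variant_vcf(path, info_map: dict | None = None) -> tuple[list[VariantRecord], int]:
    """VCF to typed records, one per alternate allele.

    INFO keys are mapped via ``info_map``; the FILTER column drives PASS
    logic (an empty FILTER counts as PASS per the VCF spec)."""
    imap = dict(DEFAULT_VCF_INFO)
    if info_map:
        imap.update(info_map)
    records: list[VariantRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filt = list(rec.filter.keys())
            status = "PASS" if not filt or filt == ["PASS"] else ";".join(filt)
            info = rec.info

            def get(key, idx=None, default=None):
                v = info.get(imap[key], default)
                if isinstance(v, tuple):
                    v = v[idx if idx is not None else 0]
                return v

            for ai, alt in enumerate(rec.alts or ()):
                try:
                    score = get("pp2_score")
                    records.append(
                        VariantRecord(
                            gene_symbol=str(get("gene")),
                            chrom=str(rec.chrom),
                            pos=int(rec.pos) - 1,
                            ref_allele=str(rec.ref),
                            alt_allele=str(alt),
                            effect=str(get("effect")),
                            maf_all=_opt_float(get("maf_all", idx=ai, default="")),
                            maf_ea=_opt_float(get("maf_ea", idx=ai, default="")),
                            maf_aa=_opt_float(get("maf_aa", idx=ai, default="")),
                            filter_status=status,
                            pp2_label=(str(get("pp2_label")) if get("pp2_label") else None),
                            pp2_score=float(score) if score is not None else None,
                        )
                    )
                except (ValueError, TypeError, InputError) as exc:
                    n_skipped += 1
                    logger.warning("%s %s:%d skipped: %s", path, rec.chrom, rec.pos, exc)
    return records, n_skipped


def records_from_frame(variants: pd.DataFrame) -> list[VariantRecord]:
    """The simulator's in-memory variant frame to typed records, without
    a file round trip (positions already 0-based)."""
    records = []
    for row in variants.itertuples(index=False):
        ea, aa, allm = (float(p) for p in str(row.maf_percent_ea_aa_all).split("/"))
        records.append(
            VariantRecord(
                gene_symbol=str(row.gene),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                effect=str(row.effect),
                maf_all=allm,
                maf_ea=ea,
                maf_aa=aa,
                filter_status=str(row.filter),
                pp2_label=(str(row.pp2_label) or None),
                pp2_score=_opt_float(row.pp2_score),
            )
        )
    return records


# ---------------------------------------------------------------------------
# score tables, gene lists, reports

def write_score_table(st: ScoreTable, path) -> None:
    """TSV with '#key=value' metadata lines; scores to 4 decimals,
    percentiles to 2."""
    with open(path, "w") as fh:
        for k, v in st.meta.items():
            fh.write(f"#{k}={v}\n")
        fh.write("gene\tx_total\ty_common_functional\trvis\tpercentile\tcovered_sites\n")
        for gene, row in st.table.iterrows():
            fh.write(
                f"{gene}\t{int(row.x_total)}\t{int(row.y_common_functional)}\t"
                f"{row.rvis:.4f}\t{row.percentile:.2f}\t{int(row.covered_sites)}\n"
            )


def read_score_table(path) -> ScoreTable:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = _coerce(value)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col="gene")
    if df.empty:
        raise InputError(f"empty score table {path}")
    return ScoreTable(table=df, meta=meta)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_gene_list(path) -> tuple[list[str], int]:
    """One symbol per line, '#' comments; returns (unique symbols in
    first-seen order, duplicate count)."""
    seen: dict[str, None] = {}
    n_dup = 0
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if not sym:
                continue
            if sym in seen:
                n_dup += 1
            else:
                seen[sym] = None
    if n_dup:
        logger.warning("%s: %d duplicate symbols ignored", path, n_dup)
    if not seen:
        raise InputError(f"gene list {path} is empty")
    return list(seen), n_dup


def write_gene_list(symbols, path) -> None:
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def write_denovo_table(denovo: pd.DataFrame, path) -> None:
    denovo.to_csv(path, sep="\t", index=False, na_rep="")


def read_denovo_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"proband_id": str, "cohort": str,
                                            "gene": str, "effect": str})
    required = {"proband_id", "cohort", "gene", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"de novo table {path} lacks columns {sorted(missing)}")
    if "pp2_score" not in df.columns:
        df["pp2_score"] = np.nan
    return df


def write_report(results, path) -> None:
    """Association results (one row per gene list) as a TSV report."""
    rows = []
    for r in results:
        rows.append(
            {
                "list": r.list_name,
                "n_members": r.n_members_scored,
                "n_background": r.n_background,
                "beta": r.beta,
                "beta_ci95_low": r.beta_ci95[0],
                "beta_ci95_high": r.beta_ci95[1],
                "p_logistic": r.p_logistic,
                "auc": r.auc,
                "auc_ci95_low": r.auc_ci95[0],
                "auc_ci95_high": r.auc_ci95[1],
                "u_statistic": r.u_statistic,
                "p_mwu": r.p_mwu,
                "separation_flag": r.separation_flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
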