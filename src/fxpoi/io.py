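"""Readers and writers for cohort CSVs, VCF + annotation sidecars, BED
intervals, gene lists, report tables, and run provenance.

Cohort CSV schema (header row required; empty cell = absent):

    id, repeat_length, age_at_interview, menopause_reported,
    age_at_menopause, cessation_cause, age_at_last_menses, ever_smoked,
    current_hormone_use, bmi, race_ethnicity, <one column per panel rsid>

Booleans are written as 0/1.  Malformed rows are rejected with their line
number and counted; a reader never silently repairs data.

All writers are deterministic: fixed column order, fixed float precision
(three decimals for ages and rates, four for p-values), UTF-8, ``\\t``
separators for report tables.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .cohort import CessationCause, Participant
from .variants import AnnotatedVariant, Consequence, Genotype

logger = logging.getLogger(__name__)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_vcf_with_annotations",
    "read_bed",
    "read_gene_list",
    "write_report_tables",
    "write_provenance",
]

COHORT_COLUMNS = [
    "id",
    "repeat_length",
    "age_at_interview",
    "menopause_reported",
    "age_at_menopause",
    "cessation_cause",
    "age_at_last_menses",
    "ever_smoked",
    "current_hormone_use",
    "bmi",
    "race_ethnicity",
]


def _opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_cohort_csv(path) -> list[Participant]:
    """Read a cohort CSV into typed participants.

    Rows violating the participant invariants (e.g. menopause age after the
    interview age) are rejected with a logged line number; valid rows are
    kept.  Genotype columns are any columns beyond the fixed schema.
    """
    df = pd.read_csv(path, dtype={"id": str, "race_ethnicity": str, "cessation_cause": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    snp_cols = [c for c in df.columns if c not in COHORT_COLUMNS]
    participants: list[Participant] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            d = row._asdict()
            genotypes = {}
            for c in snp_cols:
                g = _opt_float(d[c])
                if g is not None:
                    genotypes[c] = int(g)
            participants.append(
                Participant(
                    id=str(d["id"]),
                    repeat_length=int(d["repeat_length"]),
                    age_at_interview=float(d["age_at_interview"]),
                    menopause_reported=bool(int(d["menopause_reported"])),
                    age_at_menopause=_opt_float(d["age_at_menopause"]),
                    cessation_cause=CessationCause(d["cessation_cause"]),
                    age_at_last_menses=_opt_float(d["age_at_last_menses"]),
                    ever_smoked=bool(int(d["ever_smoked"])),
                    current_hormone_use=bool(int(d["current_hormone_use"])),
                    bmi=_opt_float(d["bmi"]),
                    race_ethnicity=str(d["race_ethnicity"]),
                    genotypes=genotypes,
                )
            )
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            logger.warning("cohort CSV line %d rejected: %s", i, exc)
    logger.info(
        "read %d participants (%d rejected) from %s", len(participants), n_rejected, path
    )
    return participants


def write_cohort_csv(cohort: Sequence[Participant], path) -> None:
    """Write participants to CSV (round-trips through :func:`read_cohort_csv`)."""
    snp_cols = sorted({rsid for p in cohort for rsid in p.genotypes})
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "repeat_length": p.repeat_length,
            "age_at_interview": p.age_at_interview,
            "menopause_reported": int(p.menopause_reported),
            "age_at_menopause": p.age_at_menopause,
            "cessation_cause": p.cessation_cause.value,
            "age_at_last_menses": p.age_at_last_menses,
            "ever_smoked": int(p.ever_smoked),
            "current_hormone_use": int(p.current_hormone_use),
            "bmi": p.bmi,
            "race_ethnicity": p.race_ethnicity,
        }
        for c in snp_cols:
            row[c] = p.genotypes.get(c)
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS + snp_cols).to_csv(path, index=False)


_CONSEQUENCE_ALIASES = {c.value: c for c in Consequence}


def _parse_gt(gt_tuple) -> Genotype:
    alleles = [a for a in gt_tuple if a is not None]
    if not alleles or len(alleles) < len(gt_tuple):
        return Genotype.NO_CALL
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf_with_annotations(vcf_path, tsv_path=None) -> list[AnnotatedVariant]:
    """Read a VCF 4.x and join the annotation sidecar on (chrom,pos,ref,alt).

    Multi-allelic records are decomposed into one bi-allelic record per
    alternate allele (genotype calls are interpreted per alt: any copy of
    that alt counts as carrying it).  Variants without a matching
    annotation row are carried with absent annotation fields and counted in
    a warning.
    """
    ann: dict[tuple, dict] = {}
    if tsv_path is not None:
        adf = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        for r in adf.itertuples(index=False):
            d = r._asdict()
            ann[(str(d["chrom"]), int(d["pos"]), d["ref"], d["alt"])] = d

    variants: list[AnnotatedVariant] = []
    n_unannotated = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            for alt_i, alt in enumerate(rec.alts or (), start=1):
                genotypes = {}
                for s in sample_names:
                    gt = rec.samples[s].get("GT")
                    if gt is None or all(a is None for a in gt):
                        genotypes[s] = Genotype.NO_CALL
                        continue
                    if any(a is None for a in gt):
                        genotypes[s] = Genotype.NO_CALL
                        continue
                    n_this = sum(1 for a in gt if a == alt_i)
                    if n_this == 0:
                        genotypes[s] = Genotype.HOM_REF
                    elif n_this == len(gt):
                        genotypes[s] = Genotype.HOM_ALT
                    else:
                        genotypes[s] = Genotype.HET
                key = (str(rec.chrom), int(rec.pos), rec.ref, alt)
                a = ann.get(key)
                if tsv_path is not None and a is None:
                    n_unannotated += 1
                maf_sources = {}
                consequence = None
                gene = None
                dbsnp = False
                delet = None
                if a is not None:
                    for src, col in (("EVS", "maf_evs"), ("1000G", "maf_1000g"), ("HapMap", "maf_hapmap")):
                        v = _opt_float(a.get(col))
                        if v is not None:
                            maf_sources[src] = v
                    cons_raw = a.get("consequence")
                    if isinstance(cons_raw, str) and cons_raw:
                        consequence = _CONSEQUENCE_ALIASES.get(cons_raw)
                        if consequence is None:
                            raise ValueError(
                                f"unknown consequence {cons_raw!r} at {key}"
                            )
                    gene_raw = a.get("gene")
                    gene = gene_raw if isinstance(gene_raw, str) and gene_raw else None
                    dbsnp = bool(int(a.get("dbsnp_known", 0) or 0))
                    d_raw = a.get("deleteriousness_call")
                    delet = d_raw if isinstance(d_raw, str) and d_raw else None
                variants.append(
                    AnnotatedVariant(
                        chromosome=str(rec.chrom),
                        position=int(rec.pos),
                        ref=rec.ref,
                        alt=alt,
                        site_quality=float(rec.qual) if rec.qual is not None else None,
                        quality_by_depth=float(info["QD"]) if "QD" in info else None,
                        homopolymer_run=int(info["HRun"]) if "HRun" in info else None,
                        strand_bias=float(info["SBL"]) if "SBL" in info else None,
                        genotypes=genotypes,
                        gene=gene,
                        consequence=consequence,
                        dbsnp_known=dbsnp,
                        maf_sources=maf_sources,
                        deleteriousness_call=delet,
                    )
                )
    if n_unannotated:
        logger.warning("%d variant records had no annotation row", n_unannotated)
    return variants


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file as (chrom, start, end) with 0-based half-open
    coordinates.  Malformed lines are a hard failure with the line number."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED line has fewer than 3 fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{i}: end < start")
            intervals.append((chrom, start, end))
    return intervals


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blanks and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out


def _fmt(df: pd.DataFrame, float_cols: Mapping[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in float_cols.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.{nd}f}"
            )
    return out


def write_report_tables(results: Mapping[str, pd.DataFrame], outdir) -> list[Path]:
    """Write each result DataFrame as a deterministic TSV under ``outdir``.

    Keys become file names (``<key>.tsv``).  Ages/means/HRs are printed at
    three decimals, p-values at four; identical inputs produce identical
    bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    float_precision = {
        "mean_age_interview": 3, "sd_age_interview": 3,
        "mean_age_menopause": 3, "sd_age_menopause": 3,
        "hr_incl_pof": 3, "hr_excl_pof": 3,
        "p_incl_pof": 4, "p_excl_pof": 4,
        "coef": 3, "se": 3, "partial_R2": 3, "p": 4, "max_maf": 4,
    }
    written = []
    for name in sorted(results):
        df = results[name]
        path = outdir / f"{name}.tsv"
        out = _fmt(df.reset_index() if df.index.name else df, float_precision)
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    return written


def write_provenance(outdir, *, seed: Optional[int], config: Mapping) -> Path:
    """Drop a machine-readable provenance record beside the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "fxpoi",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": {k: str(v) for k, v in config.items()},
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")
    return path
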