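"""Case/control variant prioritization for the WGS modifier screen.

Cases are premutation carriers with very early FXPOI (menopause before age
30), controls are carriers with menopause after 47; the default design is
five of each.  Starting from annotated variant calls, the pipeline is

1. site-quality filter: quality >= 30, quality/depth >= 5, homopolymer run
   < 6, strand bias < -0.10 (more-negative log-odds = less biased), and a
   called genotype in every case and control sample;
2. region filter: drop sites inside segmental duplications, keep only
   sites inside RefSeq exons (BED 0-based half-open vs VCF 1-based);
3. consequence filter: keep non-synonymous coding changes (missense,
   stop gain/loss, start loss; splice and noncoding excluded);
4. specificity: case-specific = carried by at least one case and no
   control; control-specific symmetric; shared / absent otherwise;
5. MAF stratification: common (max MAF over sources > 1%), rare (known
   with MAF <= 1%), novel (absent from dbSNP with no frequency record);
6. candidate-list intersection and gene-level enrichment: a gene is
   enriched when it holds >= 5 case-specific non-synonymous variants and
   at least twice as many case-specific as control-specific ones, unless
   blocklisted (genes prone to spurious burden: extreme length, relaxed
   selection, cryptic paralogs — supplied by the user, default empty).

All filters are pure (output is a subset of input) and the full pipeline
is exposed as :func:`prioritize`, which also reports stage-by-stage
attrition counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "Consequence",
    "Specificity",
    "MafClass",
    "AnnotatedVariant",
    "SampleDesign",
    "EnrichmentResult",
    "QualityThresholds",
    "site_quality_filter",
    "region_filter",
    "consequence_filter",
    "specificity",
    "maf_stratify",
    "intersect_gene_lists",
    "gene_enrichment",
    "prioritize",
    "PrioritizationReport",
]


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    SPLICE = "splice"
    OTHER_NONCODING = "other_noncoding"


#: Consequences counted as non-synonymous protein changes.
NONSYNONYMOUS = frozenset(
    {Consequence.MISSENSE, Consequence.STOP_GAIN, Consequence.STOP_LOSS, Consequence.START_LOSS}
)


class Specificity(str, Enum):
    CASE_SPECIFIC = "case_specific"
    CONTROL_SPECIFIC = "control_specific"
    SHARED = "shared"
    ABSENT = "absent"


class MafClass(str, Enum):
    COMMON = "common"
    RARE = "rare"
    NOVEL = "novel"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One bi-allelic variant call with annotations consumed as input.

    Quality metrics come from the caller; gene/consequence/MAF/dbSNP fields
    from the annotation sidecar.  ``strand_bias`` is a log-odds where more
    negative means less biased.  ``deleteriousness_call`` is carried as an
    opaque label (deleteriousness is never computed here).
    """

    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    site_quality: Optional[float] = None
    quality_by_depth: Optional[float] = None
    homopolymer_run: Optional[int] = None
    strand_bias: Optional[float] = None
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)
    gene: Optional[str] = None
    consequence: Optional[Consequence] = None
    dbsnp_known: bool = False
    maf_sources: Mapping[str, float] = field(default_factory=dict)
    in_segdup: Optional[bool] = None
    in_refseq_exon: Optional[bool] = None
    deleteriousness_call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for src, maf in self.maf_sources.items():
            if not (0.0 <= maf <= 0.5):
                raise ValueError(
                    f"{self.key}: MAF from {src} out of [0, 0.5]: {maf}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class SampleDesign:
    """The case/control sample sets (disjoint, nonempty)."""

    case_ids: frozenset[str]
    control_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "case_ids", frozenset(self.case_ids))
        object.__setattr__(self, "control_ids", frozenset(self.control_ids))
        if not self.case_ids or not self.control_ids:
            raise ValueError("case and control sets must be nonempty")
        if self.case_ids & self.control_ids:
            raise ValueError(
                f"samples in both arms: {sorted(self.case_ids & self.control_ids)}"
            )

    @property
    def all_ids(self) -> frozenset[str]:
        return self.case_ids | self.control_ids


@dataclass(frozen=True)
class QualityThresholds:
    """Site-level pass thresholds (caller defaults)."""

    min_quality: float = 30.0
    min_quality_by_depth: float = 5.0
    max_homopolymer_run: int = 6  # exclusive: pass requires run < 6
    max_strand_bias: float = -0.10  # exclusive: pass requires SB < -0.10


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-gene case/control-specific variant counts and the verdict."""

    gene: str
    case_specific_count: int
    control_specific_count: int
    enriched: bool
    blocklisted: bool

    def __post_init__(self) -> None:
        if self.case_specific_count < 0 or self.control_specific_count < 0:
            raise ValueError("counts must be non-negative")
        if self.enriched and self.blocklisted:
            raise ValueError("a blocklisted gene cannot be enriched")


def site_quality_filter(
    variants: Iterable[AnnotatedVariant],
    design: SampleDesign,
    thresholds: QualityThresholds = QualityThresholds(),
    *,
    diagnostics: Optional[dict] = None,
) -> list[AnnotatedVariant]:
    """Keep sites passing all quality thresholds and fully called in the design.

    Sites missing any quality metric are dropped and counted under
    ``diagnostics["missing_quality"]`` when a dict is supplied.
    """
    kept: list[AnnotatedVariant] = []
    n_missing = 0
    th = thresholds
    for v in variants:
        metrics = (v.site_quality, v.quality_by_depth, v.homopolymer_run, v.strand_bias)
        if any(m is None for m in metrics):
            n_missing += 1
            continue
        if v.site_quality < th.min_quality:
            continue
        if v.quality_by_depth < th.min_quality_by_depth:
            continue
        if v.homopolymer_run >= th.max_homopolymer_run:
            continue
        if v.strand_bias >= th.max_strand_bias:
            continue
        gts = v.genotypes
        if any(
            gts.get(s, Genotype.NO_CALL) == Genotype.NO_CALL for s in design.all_ids
        ):
            continue
        kept.append(v)
    if diagnostics is not None:
        diagnostics["missing_quality"] = n_missing
    if n_missing:
        logger.warning("%d sites dropped for missing quality metrics", n_missing)
    return kept


def _build_tree(intervals: Sequence[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty/inverted BED interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def region_filter(
    variants: Iterable[AnnotatedVariant],
    segdup_intervals: Sequence[tuple[str, int, int]],
    exon_intervals: Sequence[tuple[str, int, int]],
) -> list[AnnotatedVariant]:
    """Drop segmental-duplication sites; keep only sites in RefSeq exons.

    Interval tuples are BED semantics: 0-based half-open [start, end).  A
    1-based variant position p overlaps such an interval iff
    start <= p - 1 < end.  The returned variants carry their resolved
    ``in_segdup`` / ``in_refseq_exon`` flags.
    """
    segdup = _build_tree(segdup_intervals)
    exons = _build_tree(exon_intervals)
    kept = []
    for v in variants:
        pos0 = v.position - 1
        in_sd = bool(segdup.get(v.chromosome) and segdup[v.chromosome].overlaps(pos0))
        in_ex = bool(exons.get(v.chromosome) and exons[v.chromosome].overlaps(pos0))
        if in_sd or not in_ex:
            continue
        kept.append(replace(v, in_segdup=in_sd, in_refseq_exon=in_ex))
    return kept


def consequence_filter(
    variants: Iterable[AnnotatedVariant],
    keep: frozenset[Consequence] = NONSYNONYMOUS,
) -> list[AnnotatedVariant]:
    """Keep variants whose annotated consequence is non-synonymous coding."""
    return [v for v in variants if v.consequence in keep]


def specificity(variant: AnnotatedVariant, design: SampleDesign) -> Specificity:
    """Classify which arm(s) carry the alternate allele.

    Requires a called genotype in every design sample (run the quality
    filter first).
    """
    gts = variant.genotypes
    for s in design.all_ids:
        if gts.get(s, Genotype.NO_CALL) == Genotype.NO_CALL:
            raise ValueError(
                f"{variant.key}: sample {s} not called; specificity undefined"
            )
    in_cases = any(gts[s].carries_alt for s in design.case_ids)
    in_controls = any(gts[s].carries_alt for s in design.control_ids)
    if in_cases and not in_controls:
        return Specificity.CASE_SPECIFIC
    if in_controls and not in_cases:
        return Specificity.CONTROL_SPECIFIC
    if in_cases and in_controls:
        return Specificity.SHARED
    return Specificity.ABSENT


def case_carrier_count(variant: AnnotatedVariant, design: SampleDesign) -> int:
    """Number of case samples carrying the alternate allele (so both the
    'any case' and 'multiple cases' readings of case-specific are available)."""
    return sum(variant.genotypes[s].carries_alt for s in design.case_ids)


def maf_stratify(variant: AnnotatedVariant) -> MafClass:
    """Classify population frequency: common (> 1%), rare, or novel.

    The MAF is the max over available sources (conservative: a variant
    common anywhere is common).  Known variants at or below 1% are rare;
    a variant absent from dbSNP with no frequency record is novel.
    """
    mafs = [m for m in variant.maf_sources.values() if m is not None]
    if mafs:
        maf = max(mafs)
        return MafClass.COMMON if maf > 0.01 else MafClass.RARE
    return MafClass.RARE if variant.dbsnp_known else MafClass.NOVEL


def intersect_gene_lists(
    variants: Iterable[AnnotatedVariant],
    gene_lists: Mapping[str, Iterable[str]],
) -> dict[str, list[AnnotatedVariant]]:
    """Intersect variants with named candidate-gene lists.

    Symbols are matched case-insensitively (normalized to upper case).  A
    variant whose gene sits on several lists appears under each.
    """
    variants = list(variants)
    out: dict[str, list[AnnotatedVariant]] = {}
    for name, genes in gene_lists.items():
        symbols = {g.strip().upper() for g in genes if g.strip()}
        out[name] = [
            v for v in variants if v.gene is not None and v.gene.upper() in symbols
        ]
    return out


def gene_enrichment(
    variants: Iterable[AnnotatedVariant],
    design: SampleDesign,
    blocklist: Iterable[str] = (),
    *,
    min_case_variants: int = 5,
    case_control_ratio: float = 2.0,
) -> list[EnrichmentResult]:
    """Per-gene counts of case- and control-specific variants and the verdict.

    A gene is enriched iff it has at least ``min_case_variants``
    case-specific variants and at least ``case_control_ratio`` times as many
    case-specific as control-specific variants, and is not blocklisted.
    Input variants should already be consequence-filtered.  Results are
    sorted by descending case count, then gene symbol.
    """
    block = {g.strip().upper() for g in blocklist if g.strip()}
    if not block:
        logger.warning(
            "gene enrichment running with an EMPTY blocklist: genes prone to "
            "spurious variant burden (extreme length, relaxed selection, "
            "cryptic paralogs) will not be excluded"
        )
    case_counts: dict[str, int] = {}
    ctrl_counts: dict[str, int] = {}
    for v in variants:
        if v.gene is None:
            continue
        g = v.gene.upper()
        spec = specificity(v, design)
        if spec == Specificity.CASE_SPECIFIC:
            case_counts[g] = case_counts.get(g, 0) + 1
            ctrl_counts.setdefault(g, 0)
        elif spec == Specificity.CONTROL_SPECIFIC:
            ctrl_counts[g] = ctrl_counts.get(g, 0) + 1
            case_counts.setdefault(g, 0)
    results = []
    for gene in sorted(set(case_counts) | set(ctrl_counts)):
        nc = case_counts.get(gene, 0)
        nk = ctrl_counts.get(gene, 0)
        blocked = gene in block
        enriched = (
            not blocked and nc >= min_case_variants and nc >= case_control_ratio * nk
        )
        results.append(
            EnrichmentResult(
                gene=gene,
                case_specific_count=nc,
                control_specific_count=nk,
                enriched=enriched,
                blocklisted=blocked,
            )
        )
    results.sort(key=lambda r: (-r.case_specific_count, r.gene))
    return results


@dataclass
class PrioritizationReport:
    """Full output of the prioritization pipeline.

    ``candidate_tables`` maps list-name -> DataFrame of case-specific
    variants on that list split by frequency class; ``enrichment`` is the
    genome-wide per-gene table; ``attrition`` records how many variants
    survived each stage.
    """

    candidate_tables: dict[str, pd.DataFrame]
    enrichment: pd.DataFrame
    attrition: dict[str, int]
    retained: list[AnnotatedVariant] = field(repr=False, default_factory=list)

    @property
    def enriched_genes(self) -> list[str]:
        if self.enrichment.empty:
            return []
        return sorted(self.enrichment.loc[self.enrichment["enriched"], "gene"])


_CANDIDATE_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "alt",
    "gene",
    "consequence",
    "maf_class",
    "max_maf",
    "n_case_carriers",
    "deleteriousness_call",
]


def _variant_row(v: AnnotatedVariant, design: SampleDesign) -> dict:
    mafs = [m for m in v.maf_sources.values() if m is not None]
    return {
        "chromosome": v.chromosome,
        "position": v.position,
        "ref": v.ref,
        "alt": v.alt,
        "gene": v.gene,
        "consequence": v.consequence.value if v.consequence else None,
        "maf_class": maf_stratify(v).value,
        "max_maf": max(mafs) if mafs else None,
        "n_case_carriers": case_carrier_count(v, design),
        "deleteriousness_call": v.deleteriousness_call,
    }


def prioritize(
    variants: Iterable[AnnotatedVariant],
    design: SampleDesign,
    gene_lists: Mapping[str, Iterable[str]],
    segdup_intervals: Sequence[tuple[str, int, int]],
    exon_intervals: Sequence[tuple[str, int, int]],
    blocklist: Iterable[str] = (),
    thresholds: QualityThresholds = QualityThresholds(),
) -> PrioritizationReport:
    """Run the full pipeline and assemble candidate and enrichment tables.

    Candidate tables contain, per gene list, the common and the rare/novel
    case-specific non-synonymous variants (one table per list, with a
    ``maf_class`` column).  The enrichment table covers all genes
    genome-wide after quality/region/consequence filtering.
    """
    variants = list(variants)
    attrition = {"input": len(variants)}
    stage = site_quality_filter(variants, design, thresholds)
    attrition["site_quality"] = len(stage)
    stage = region_filter(stage, segdup_intervals, exon_intervals)
    attrition["region"] = len(stage)
    stage = consequence_filter(stage)
    attrition["consequence"] = len(stage)

    case_specific = [v for v in stage if specificity(v, design) == Specificity.CASE_SPECIFIC]
    attrition["case_specific"] = len(case_specific)
    logger.info("attrition: %s", attrition)

    by_list = intersect_gene_lists(case_specific, gene_lists)
    candidate_tables = {}
    for name, vs in by_list.items():
        rows = [_variant_row(v, design) for v in vs]
        df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
        df = df.sort_values(["gene", "chromosome", "position"]).reset_index(drop=True)
        candidate_tables[name] = df

    enr = gene_enrichment(stage, design, blocklist)
    enrichment = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "case_specific": r.case_specific_count,
                "control_specific": r.control_specific_count,
                "enriched": r.enriched,
                "blocklisted": r.blocklisted,
            }
        for r in enr
        ],
        columns=["gene", "case_specific", "control_specific", "enriched", "blocklisted"],
    )
    return PrioritizationReport(
        candidate_tables=candidate_tables,
        enrichment=enrichment,
        attrition=attrition,
        retained=stage,
    )
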