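"""Seeded generators for synthetic cohorts and annotated variant tables.

Every downstream analysis in this package can run without external data:

* :func:`generate_cohort` emulates a premutation-carrier study population
  with the non-linear repeat effect and the SNP burden effect on latent
  age at natural menopause, plus the interview/hysterectomy censoring
  mechanisms.  The regression truths default to the published burden-model
  coefficients (repeat -1.650, repeat^2 0.009, score -3.710 years), and
  panel genotypes are drawn at Hardy-Weinberg with the published effect
  allele frequencies.
* :func:`generate_survival_cohort` draws censored event ages from a
  Weibull baseline hazard scaled by group and covariate log-hazards
  (defaults ln 2.4 / ln 4.1 / ln 2.5 for low/mid/high PM vs noncarriers).
  The two outcome models are deliberately separate: the burden analysis
  models the *age* linearly, the survival analysis models the *hazard*
  proportionally, and no single mechanism reproduces both truths at once.
* :func:`generate_variant_table` writes a ten-sample VCF (five early-FXPOI
  cases, five late-menopause controls), an annotation sidecar TSV,
  segdup/exon BEDs and candidate gene lists, with planted case-specific
  variants and planted enriched genes recorded in a truth dict.

Generation is a pure function of (config, seed): identical inputs yield
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .burden import DEFAULT_PANEL, SnpDefinition, total_snp_risk
from .cohort import (
    CessationCause,
    Participant,
    RepeatGroup,
    SurvivalRecord,
)

__all__ = [
    "CohortGeneratorConfig",
    "SurvivalGeneratorConfig",
    "VariantGeneratorConfig",
    "generate_cohort",
    "generate_survival_cohort",
    "generate_variant_table",
]

#: Lowest physiologic age at menopause; latent ages below are redrawn.
MIN_MENOPAUSE_AGE = 14.0

#: Repeat-length draw ranges per group.  High-PM draws stop at 140: the
#: quadratic latent-age model is calibrated on the observed premutation
#: range (most study repeats fall below ~140) and extrapolates
#: non-physiologically toward 200.
REPEAT_DRAW_RANGES = {
    RepeatGroup.NORMAL: (20, 54),
    RepeatGroup.LOW_PM: (55, 79),
    RepeatGroup.MID_PM: (80, 100),
    RepeatGroup.HIGH_PM: (101, 140),
}


@dataclass(frozen=True)
class RegressionTruth:
    """Ground-truth coefficients of the latent menopause-age model."""

    intercept: float = 126.0
    b_repeat: float = -1.650
    b_repeat_sq: float = 0.009
    b_burden: float = -3.710


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Configuration of the participant-level cohort generator.

    ``group_proportions`` are converted to fixed per-group counts (largest
    remainder).  For premutation women the latent age at natural menopause
    is the quadratic repeat model plus the burden effect plus Gaussian
    noise; noncarrier women get ``normal_intercept`` plus the burden effect
    plus noise (the quadratic is a premutation-range model).  The default
    ``residual_sd`` of 7.6 years is calibrated (see
    ``scripts/calibrate_residual_sd.py``) so the burden predictor's partial
    R^2 at n=72 sits near 0.067 and its coefficient SE near 1.684.

    Censoring: with probability ``p_not_menopausal_scale`` applied through
    the interview-age distribution — a woman whose latent age exceeds her
    interview age has simply not reached menopause yet; with probability
    ``p_hysterectomy`` menses stopped early for a medical reason and she is
    censored at age at last menses.
    """

    n: int = 72
    group_proportions: dict = field(
        default_factory=lambda: {
            RepeatGroup.LOW_PM: 25 / 72,
            RepeatGroup.MID_PM: 40 / 72,
            RepeatGroup.HIGH_PM: 7 / 72,
        }
    )
    truth: RegressionTruth = RegressionTruth()
    normal_intercept: float = 60.1
    residual_sd: float = 7.6
    panel: tuple[SnpDefinition, ...] = DEFAULT_PANEL
    #: interview ages; with ``censoring=False`` interviews are forced to
    #: postdate the latent menopause age so every woman reports menopause.
    censoring: bool = False
    interview_age_mean: float = 44.0
    interview_age_sd: float = 15.0
    interview_age_range: tuple[float, float] = (18.0, 92.0)
    p_hysterectomy: float = 0.0
    smoking_prevalence: float = 0.35
    bmi_mean: float = 26.0
    bmi_sd: float = 5.0
    p_nonwhite: float = 0.15

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, not 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def full_study(cls, n: int = 1404) -> "CohortGeneratorConfig":
        """All four repeat groups with censoring on, at the observed
        cohort composition (694/247/350/113 per group)."""
        return cls(
            n=n,
            group_proportions={
                RepeatGroup.NORMAL: 694 / 1404,
                RepeatGroup.LOW_PM: 247 / 1404,
                RepeatGroup.MID_PM: 350 / 1404,
                RepeatGroup.HIGH_PM: 113 / 1404,
            },
            censoring=True,
            p_hysterectomy=0.10,
        )


def _counts_from_proportions(props: dict, n: int) -> dict:
    """Largest-remainder rounding of proportions to integer counts."""
    groups = list(props)
    raw = np.array([props[g] * n for g in groups])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return dict(zip(groups, counts))


def _draw_genotypes(rng: np.random.Generator, panel: Sequence[SnpDefinition]) -> dict[str, int]:
    return {
        s.rsid: int(rng.binomial(2, s.effect_allele_frequency)) for s in panel
    }


def generate_cohort(
    config: CohortGeneratorConfig = CohortGeneratorConfig(), *, seed: int
) -> tuple[list[Participant], dict]:
    """Draw a synthetic cohort and return it with its ground truth.

    The truth dict carries the latent-model coefficients, the residual SD
    and per-group counts, so parameter-recovery tests can compare against
    exactly what was simulated.
    """
    rng = np.random.default_rng(seed)
    counts = _counts_from_proportions(config.group_proportions, config.n)
    t = config.truth
    participants: list[Participant] = []
    idx = 0
    for group in (
        RepeatGroup.NORMAL,
        RepeatGroup.LOW_PM,
        RepeatGroup.MID_PM,
        RepeatGroup.HIGH_PM,
    ):
        lo, hi = REPEAT_DRAW_RANGES[group]
        for _ in range(counts.get(group, 0)):
            idx += 1
            r = int(rng.integers(lo, hi + 1))
            genotypes = _draw_genotypes(rng, config.panel)
            tsr = total_snp_risk(genotypes, config.panel)
            # latent age at natural menopause; redraw noise below the floor
            for _attempt in range(1000):
                eps = rng.normal(0.0, config.residual_sd)
                if group == RepeatGroup.NORMAL:
                    latent = config.normal_intercept + t.b_burden * tsr + eps
                else:
                    latent = (
                        t.intercept
                        + t.b_repeat * r
                        + t.b_repeat_sq * r * r
                        + t.b_burden * tsr
                        + eps
                    )
                if latent >= MIN_MENOPAUSE_AGE:
                    break
            else:
                raise RuntimeError(
                    "latent menopause age persistently below the physiologic "
                    "floor; infeasible generator configuration"
                )
            smoked = bool(rng.random() < config.smoking_prevalence)
            bmi = float(
                np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 15.0, 55.0)
            )
            race = "Other" if rng.random() < config.p_nonwhite else "White"
            if config.censoring:
                lo_a, hi_a = config.interview_age_range
                interview = float(
                    np.clip(
                        rng.normal(config.interview_age_mean, config.interview_age_sd),
                        lo_a,
                        hi_a,
                    )
                )
                hyst_age: Optional[float] = None
                if rng.random() < config.p_hysterectomy:
                    hyst_age = float(rng.uniform(25.0, 50.0))
                if hyst_age is not None and hyst_age < min(latent, interview):
                    participants.append(
                        Participant(
                            id=f"w{idx:05d}",
                            repeat_length=r,
                            age_at_interview=interview,
                            menopause_reported=False,
                            cessation_cause=CessationCause.HYSTERECTOMY,
                            age_at_last_menses=hyst_age,
                            ever_smoked=smoked,
                            bmi=bmi,
                            race_ethnicity=race,
                            genotypes=genotypes,
                        )
                    )
                    continue
                if latent > interview:  # not yet menopausal at interview
                    participants.append(
                        Participant(
                            id=f"w{idx:05d}",
                            repeat_length=r,
                            age_at_interview=interview,
                            menopause_reported=False,
                            cessation_cause=CessationCause.NONE,
                            ever_smoked=smoked,
                            bmi=bmi,
                            race_ethnicity=race,
                            genotypes=genotypes,
                        )
                    )
                    continue
            else:
                interview = float(latent + rng.uniform(1.0, 10.0))
            participants.append(
                Participant(
                    id=f"w{idx:05d}",
                    repeat_length=r,
                    age_at_interview=interview,
                    menopause_reported=True,
                    age_at_menopause=float(latent),
                    cessation_cause=CessationCause.NATURAL_MENOPAUSE,
                    ever_smoked=smoked,
                    bmi=bmi,
                    race_ethnicity=race,
                    genotypes=genotypes,
                )
            )
    truth = {
        "intercept": t.intercept,
        "b_repeat": t.b_repeat,
        "b_repeat_sq": t.b_repeat_sq,
        "b_burden": t.b_burden,
        "normal_intercept": config.normal_intercept,
        "residual_sd": config.residual_sd,
        "group_counts": {g.value: int(c) for g, c in counts.items()},
        "seed": seed,
    }
    return participants, truth


@dataclass(frozen=True)
class SurvivalGeneratorConfig:
    """Configuration of the censored time-to-menopause generator.

    Event ages follow a Weibull baseline (shape ``weibull_shape``, scale
    ``weibull_scale`` years; sharp late-40s rise) with the hazard
    multiplied by exp(group log-HR + covariate effects).  Censoring: the
    event is observed only if it precedes the (independent) interview age;
    hysterectomy censors at the hysterectomy age when that comes first.
    """

    n: int = 1400
    group_proportions: dict = field(
        default_factory=lambda: {
            RepeatGroup.NORMAL: 694 / 1404,
            RepeatGroup.LOW_PM: 247 / 1404,
            RepeatGroup.MID_PM: 350 / 1404,
            RepeatGroup.HIGH_PM: 113 / 1404,
        }
    )
    group_log_hazard: dict = field(
        default_factory=lambda: {
            RepeatGroup.LOW_PM: float(np.log(2.4)),
            RepeatGroup.MID_PM: float(np.log(4.1)),
            RepeatGroup.HIGH_PM: float(np.log(2.5)),
        }
    )
    # covariate effects on the log-hazard (interview age affects censoring
    # only, so its true regression coefficient is zero)
    smoking_log_hazard: float = 0.25
    bmi_log_hazard_per_unit: float = -0.01
    nonwhite_log_hazard: float = 0.10
    weibull_shape: float = 12.0
    weibull_scale: float = 52.6
    interview_age_mean: float = 44.0
    interview_age_sd: float = 15.0
    interview_age_range: tuple[float, float] = (18.0, 92.0)
    p_hysterectomy: float = 0.10
    smoking_prevalence: float = 0.35
    bmi_mean: float = 26.0
    bmi_sd: float = 5.0
    p_nonwhite: float = 0.15

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")


def generate_survival_cohort(
    config: SurvivalGeneratorConfig = SurvivalGeneratorConfig(), *, seed: int
) -> tuple[list[SurvivalRecord], dict]:
    """Draw censored survival records and return them with the truth.

    The truth dict holds every log-hazard used in generation, keyed by the
    design-column names of the Cox model, plus the baseline parameters.
    """
    rng = np.random.default_rng(seed)
    counts = _counts_from_proportions(config.group_proportions, config.n)
    k, lam = config.weibull_shape, config.weibull_scale
    records: list[SurvivalRecord] = []
    idx = 0
    for group in (
        RepeatGroup.NORMAL,
        RepeatGroup.LOW_PM,
        RepeatGroup.MID_PM,
        RepeatGroup.HIGH_PM,
    ):
        g_lh = config.group_log_hazard.get(group, 0.0)
        for _ in range(counts.get(group, 0)):
            idx += 1
            smoked = float(rng.random() < config.smoking_prevalence)
            bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 15.0, 55.0))
            nonwhite = float(rng.random() < config.p_nonwhite)
            eta = (
                g_lh
                + config.smoking_log_hazard * smoked
                + config.bmi_log_hazard_per_unit * (bmi - config.bmi_mean)
                + config.nonwhite_log_hazard * nonwhite
            )
            # inverse-CDF draw from the scaled Weibull, floored physiologically
            while True:
                u = rng.random()
                event_age = lam * (-np.log(u) / np.exp(eta)) ** (1.0 / k)
                if event_age >= MIN_MENOPAUSE_AGE:
                    break
            lo_a, hi_a = config.interview_age_range
            interview = float(
                np.clip(
                    rng.normal(config.interview_age_mean, config.interview_age_sd),
                    lo_a,
                    hi_a,
                )
            )
            hyst_age = (
                float(rng.uniform(25.0, 50.0))
                if rng.random() < config.p_hysterectomy
                else np.inf
            )
            covs = {
                "age_at_interview": interview,
                "race_nonwhite": nonwhite,
                "ever_smoked": smoked,
                "bmi": bmi,
            }
            t_obs = min(event_age, interview, hyst_age)
            records.append(
                SurvivalRecord(
                    id=f"s{idx:05d}",
                    time=float(t_obs),
                    event=bool(event_age <= min(interview, hyst_age)),
                    covariates=covs,
                    group=group,
                )
            )
    truth = {
        "log_hazard": {
            "group_LowPM": config.group_log_hazard.get(RepeatGroup.LOW_PM, 0.0),
            "group_MidPM": config.group_log_hazard.get(RepeatGroup.MID_PM, 0.0),
            "group_HighPM": config.group_log_hazard.get(RepeatGroup.HIGH_PM, 0.0),
            "ever_smoked": config.smoking_log_hazard,
            "bmi": config.bmi_log_hazard_per_unit,
            "race_nonwhite": config.nonwhite_log_hazard,
            "age_at_interview": 0.0,
        },
        "weibull_shape": k,
        "weibull_scale": lam,
        "group_counts": {g.value: int(c) for g, c in counts.items()},
        "seed": seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# variant-table generator


@dataclass(frozen=True)
class VariantGeneratorConfig:
    """Configuration of the annotated case/control variant-table generator.

    Gene models are laid out on one synthetic chromosome as consecutive
    exon blocks; segmental-duplication decoy intervals overlap dedicated
    decoy positions.  ``planted_enriched_genes`` maps gene symbol ->
    (case-specific count, control-specific count); defaults satisfy the
    enrichment rule (>= 5 case-specific, >= 2x controls) by construction.
    """

    n_genes: int = 40
    n_background_variants: int = 400
    case_ids: tuple[str, ...] = ("poi1", "poi2", "poi3", "poi4", "poi5")
    control_ids: tuple[str, ...] = ("ctr6", "ctr7", "ctr8", "ctr9", "ctr10")
    planted_enriched_genes: dict = field(
        default_factory=lambda: {"GENE001": (6, 2), "GENE002": (5, 2)}
    )
    #: planted case-specific non-synonymous variants in candidate genes:
    #: (gene-list name, frequency class) -> count
    planted_common_goi: int = 3
    planted_rare_goi: int = 2
    planted_novel_goi: int = 1
    fraction_fail_quality: float = 0.10
    fraction_in_segdup: float = 0.05
    fraction_outside_exons: float = 0.05
    fraction_synonymous: float = 0.35
    chromosome: str = "1"
    gene_span: int = 10_000
    exon_len: int = 2_000

    def __post_init__(self) -> None:
        for gene, (nc, nk) in self.planted_enriched_genes.items():
            if not (nc >= 5 and nc >= 2 * nk):
                raise ValueError(
                    f"planted counts for {gene} ({nc}, {nk}) violate the "
                    "enrichment rule"
                )
        if self.n_genes < 10 + len(self.planted_enriched_genes):
            raise ValueError("too few genes for the planted structure")

    @property
    def design_samples(self) -> tuple[str, ...]:
        return self.case_ids + self.control_ids


def _gene_symbols(config: VariantGeneratorConfig) -> list[str]:
    planted = list(config.planted_enriched_genes)
    n_rest = config.n_genes - len(planted)
    return planted + [f"GENE{i:03d}" for i in range(100, 100 + n_rest)]


def _gene_exon(config: VariantGeneratorConfig, gene_index: int) -> tuple[int, int]:
    """0-based half-open exon interval of one gene."""
    start = gene_index * config.gene_span + 1_000
    return start, start + config.exon_len


_BASES = ("A", "C", "G", "T")


def generate_variant_table(
    config: VariantGeneratorConfig = VariantGeneratorConfig(),
    *,
    seed: int,
    outdir: str | Path,
) -> dict:
    """Write VCF, annotation TSV, BEDs, gene lists and a truth record.

    Files written under ``outdir``: ``variants.vcf``, ``annotations.tsv``,
    ``segdup.bed``, ``exons.bed``, ``gene_lists/<name>.txt`` and
    ``truth.json``.  Returns the truth dict.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_symbols(config)
    cases, controls = list(config.case_ids), list(config.control_ids)
    samples = cases + controls
    chrom = config.chromosome

    used_positions: set[int] = set()

    def fresh_position(lo: int, hi: int) -> int:
        for _ in range(10_000):
            p = int(rng.integers(lo, hi))
            if p not in used_positions:
                used_positions.add(p)
                return p
        raise RuntimeError("position space exhausted")

    def alleles() -> tuple[str, str]:
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
        return ref, alt

    def genotype_row(carriers: Sequence[str]) -> dict[str, str]:
        return {s: ("0/1" if s in carriers else "0/0") for s in samples}

    def good_quality() -> dict:
        return {
            "qual": float(rng.uniform(40, 200)),
            "qd": float(rng.uniform(6, 30)),
            "hrun": int(rng.integers(0, 5)),
            "sb": float(rng.uniform(-3.0, -0.2)),
        }

    def bad_quality() -> dict:
        mode = rng.integers(0, 4)
        q = good_quality()
        if mode == 0:
            q["qual"] = float(rng.uniform(5, 29.5))
        elif mode == 1:
            q["qd"] = float(rng.uniform(0.5, 4.5))
        elif mode == 2:
            q["hrun"] = int(rng.integers(6, 12))
        else:
            q["sb"] = float(rng.uniform(-0.09, 0.5))
        return q

    rows: list[dict] = []  # one per variant; VCF + annotation fields
    truth: dict = {
        "planted_enriched_genes": sorted(config.planted_enriched_genes),
        "planted_common_goi": [],
        "planted_rare_goi": [],
        "planted_novel_goi": [],
        "seed": seed,
    }

    def add_variant(
        gene_idx: int,
        carriers: Sequence[str],
        consequence: str,
        maf_class: str,
        *,
        quality: Optional[dict] = None,
        inside_exon: bool = True,
        in_segdup: bool = False,
    ) -> dict:
        lo, hi = _gene_exon(config, gene_idx)
        if not inside_exon:
            pos0 = fresh_position(lo - 900, lo - 10)  # intergenic, before exon
        else:
            pos0 = fresh_position(lo, hi)
        ref, alt = alleles()
        q = quality or good_quality()
        if maf_class == "common":
            maf = float(rng.uniform(0.02, 0.30))
            known = True
        elif maf_class == "rare":
            maf = float(rng.uniform(0.0005, 0.009))
            known = True
        else:  # novel
            maf = None
            known = False
        row = {
            "chrom": chrom,
            "pos": pos0 + 1,  # VCF 1-based
            "ref": ref,
            "alt": alt,
            "gene": genes[gene_idx],
            "consequence": consequence,
            "dbsnp_known": known,
            "maf_evs": maf,
            "maf_1000g": maf if (maf is not None and rng.random() < 0.7) else None,
            "maf_hapmap": None,
            "genotypes": genotype_row(carriers),
            "in_segdup_truth": in_segdup,
            **q,
        }
        rows.append(row)
        return row

    def some_cases(k: int) -> list[str]:
        return list(rng.choice(cases, size=k, replace=False))

    def some_controls(k: int) -> list[str]:
        return list(rng.choice(controls, size=k, replace=False))

    # --- planted candidate-list signal (genes of interest occupy indices
    # after the enriched genes; lists defined below)
    n_enr = len(config.planted_enriched_genes)
    goi_idx = list(range(n_enr, n_enr + 12))  # 12 genes of interest
    mirna_idx = list(range(n_enr + 12, n_enr + 16))
    mtor_idx = list(range(n_enr + 16, n_enr + 24))
    lh_idx = list(range(n_enr + 24, n_enr + 27))

    for i in range(config.planted_common_goi):
        r = add_variant(goi_idx[i], some_cases(int(rng.integers(1, 3))), "missense", "common")
        truth["planted_common_goi"].append([r["chrom"], r["pos"], r["ref"], r["alt"], r["gene"]])
    for i in range(config.planted_rare_goi):
        r = add_variant(goi_idx[4 + i], some_cases(1), "missense", "rare")
        truth["planted_rare_goi"].append([r["chrom"], r["pos"], r["ref"], r["alt"], r["gene"]])
    for i in range(config.planted_novel_goi):
        r = add_variant(goi_idx[7 + i], some_cases(1), "missense", "novel")
        truth["planted_novel_goi"].append([r["chrom"], r["pos"], r["ref"], r["alt"], r["gene"]])

    # --- planted enriched genes
    for g_i, gene in enumerate(config.planted_enriched_genes):
        nc, nk = config.planted_enriched_genes[gene]
        for _ in range(nc):
            add_variant(g_i, some_cases(1), "missense", "rare")
        for _ in range(nk):
            add_variant(g_i, some_controls(1), "missense", "rare")

    # --- background noise: shared/absent/control-specific variants, decoys.
    # Background never lands in the planted enriched genes, so their
    # case/control counts stay exactly as planted.
    n_bg = config.n_background_variants
    gene_pool = list(range(n_enr, len(genes)))
    bg_case_specific_budget: dict[int, int] = {}
    for _ in range(n_bg):
        g_i = int(rng.choice(gene_pool))
        u = rng.random()
        if u < config.fraction_fail_quality:
            add_variant(g_i, some_cases(1), "missense", "common", quality=bad_quality())
            continue
        if u < config.fraction_fail_quality + config.fraction_in_segdup:
            add_variant(g_i, some_cases(1), "missense", "common", in_segdup=True)
            continue
        if u < (
            config.fraction_fail_quality
            + config.fraction_in_segdup
            + config.fraction_outside_exons
        ):
            add_variant(g_i, some_cases(1), "missense", "common", inside_exon=False)
            continue
        cons = "synonymous" if rng.random() < config.fraction_synonymous else "missense"
        kind = rng.random()
        if kind < 0.45:  # shared
            carriers = some_cases(int(rng.integers(1, 3))) + some_controls(
                int(rng.integers(1, 3))
            )
        elif kind < 0.75:  # control-specific
            carriers = some_controls(int(rng.integers(1, 3)))
        elif kind < 0.90:  # absent (hom-ref everywhere)
            carriers = []
        else:  # case-specific background, capped below the enrichment rule
            if cons == "missense":
                used = bg_case_specific_budget.get(g_i, 0)
                # keep candidate-list genes free of unplanted case-specific
                # missense so candidate tables contain exactly the plants
                if g_i < n_enr + 27 or used >= 2:
                    carriers = []
                else:
                    bg_case_specific_budget[g_i] = used + 1
                    carriers = some_cases(1)
            else:
                carriers = some_cases(1)
        add_variant(g_i, carriers, cons, "common" if rng.random() < 0.8 else "rare")

    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]))

    # --- write artifacts
    _write_vcf(outdir / "variants.vcf", rows, samples)
    _write_annotations(outdir / "annotations.tsv", rows)
    # exon BED: every gene's exon; segdup BED: intervals around segdup decoys
    with open(outdir / "exons.bed", "w") as fh:
        for i, gene in enumerate(genes):
            lo, hi = _gene_exon(config, i)
            fh.write(f"{chrom}\t{lo}\t{hi}\t{gene}\n")
    with open(outdir / "segdup.bed", "w") as fh:
        for r in rows:
            if r["in_segdup_truth"]:
                fh.write(f"{chrom}\t{r['pos'] - 1}\t{r['pos']}\tsegdup\n")
    lists_dir = outdir / "gene_lists"
    lists_dir.mkdir(exist_ok=True)
    gene_lists = {
        "genes_of_interest": [genes[i] for i in goi_idx],
        "mirnas": [genes[i] for i in mirna_idx],
        "mtor_pathway": [genes[i] for i in mtor_idx],
        "lh_pathway": [genes[i] for i in lh_idx],
    }
    for name, syms in gene_lists.items():
        (lists_dir / f"{name}.txt").write_text("\n".join(syms) + "\n")
    truth["gene_lists"] = gene_lists
    truth["n_variants"] = len(rows)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def _write_vcf(path: Path, rows: list[dict], samples: list[str]) -> None:
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=HRun,Number=1,Type=Integer,Description="Homopolymer run length">',
        '##INFO=<ID=SBL,Number=1,Type=Float,Description="Strand bias log-odds">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1,length=100000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = list(header)
    for r in rows:
        info = f"QD={r['qd']:.2f};HRun={r['hrun']};SBL={r['sb']:.3f}"
        gts = "\t".join(r["genotypes"][s] for s in samples)
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
            f"{r['qual']:.1f}\tPASS\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_annotations(path: Path, rows: list[dict]) -> None:
    cols = [
        "chrom",
        "pos",
        "ref",
        "alt",
        "gene",
        "consequence",
        "dbsnp_known",
        "maf_evs",
        "maf_1000g",
        "maf_hapmap",
        "deleteriousness_call",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            vals = []
            for c in cols:
                v = r.get(c)
                if v is None:
                    vals.append("")
                elif isinstance(v, bool):
                    vals.append("1" if v else "0")
                elif isinstance(v, float):
                    vals.append(f"{v:.6g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
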