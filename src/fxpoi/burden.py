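"""Total SNP Risk burden score and its regression on age at menopause.

Five common SNPs with the largest known per-allele effects on age at
menopause in the general population form the default panel.  The burden
score for one woman is

    TSR = sum_j  c_j * |w_j|

where ``c_j`` is her count of effect alleles at SNP j (0, 1 or 2) and
``w_j`` the per-allele effect size in years.  The published effect sizes
are negative (years *earlier* per allele); the score uses their magnitudes
so that a larger score means a larger risk burden, which puts the expected
sign of the fitted score coefficient at negative.  A signed-weight mode is
available for sensitivity analysis (``signed_weights=True``), in which case
the expected coefficient sign flips.

The association model is ordinary least squares among women who have
experienced menopause (no censoring here):

    age_at_menopause = b0 + b1 * repeat + b2 * repeat^2 + b3 * TSR + eps

The squared term captures the non-linear premutation effect (mid-range
repeats lower the age most).  Per-predictor "partial R^2" is the squared
partial correlation t^2 / (t^2 + df_resid); the three values need not sum
to the model R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Participant

logger = logging.getLogger(__name__)

__all__ = [
    "SnpDefinition",
    "DEFAULT_PANEL",
    "total_snp_risk",
    "simulate_expected_burden",
    "BurdenRegression",
    "BurdenRegressionResults",
    "fit_burden_regression",
    "read_panel",
    "write_panel",
]


@dataclass(frozen=True)
class SnpDefinition:
    """A menopause-age-associated SNP: effect allele, frequency, effect size.

    ``effect_size`` is the published per-allele shift in years (negative =
    earlier menopause per effect allele).  ``position`` is carried as opaque
    metadata; no liftover or coordinate arithmetic is ever done with it.
    """

    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    effect_allele_frequency: float
    effect_size: float

    def __post_init__(self) -> None:
        if not (0.0 < self.effect_allele_frequency < 1.0):
            raise ValueError(
                f"{self.rsid}: effect allele frequency must be in (0,1)"
            )
        if self.effect_size == 0:
            raise ValueError(f"{self.rsid}: effect size must be nonzero")


#: The default five-SNP panel (effect sizes in years per allele).
DEFAULT_PANEL: tuple[SnpDefinition, ...] = (
    SnpDefinition("rs16991615", "20", 5896227, "G", 0.93, -0.948),
    SnpDefinition("rs11668344", "19", 60525476, "G", 0.36, -0.416),
    SnpDefinition("rs2277339", "12", 55432336, "G", 0.10, -0.380),
    SnpDefinition("rs365132", "5", 176311180, "G", 0.51, -0.287),
    SnpDefinition("rs2517388", "8", 38096889, "T", 0.83, -0.262),
)


def _weights(panel: Sequence[SnpDefinition], signed: bool) -> np.ndarray:
    w = np.array([s.effect_size for s in panel], dtype=float)
    return w if signed else np.abs(w)


def total_snp_risk(
    genotypes: Mapping[str, int],
    panel: Sequence[SnpDefinition] = DEFAULT_PANEL,
    *,
    signed_weights: bool = False,
) -> Optional[float]:
    """Weighted burden of effect alleles over the panel, in years.

    Returns ``None`` when any panel SNP is missing from ``genotypes``
    (complete-case convention; the caller logs and drops the woman).
    """
    counts = []
    for snp in panel:
        c = genotypes.get(snp.rsid)
        if c is None:
            return None
        if c not in (0, 1, 2):
            raise ValueError(f"genotype at {snp.rsid} must be 0/1/2, got {c}")
        counts.append(c)
    w = _weights(panel, signed_weights)
    return float(np.dot(counts, w))


def simulate_expected_burden(
    panel: Sequence[SnpDefinition] = DEFAULT_PANEL, *, signed_weights: bool = False
) -> float:
    """Hardy-Weinberg expectation of the burden score: sum_j 2 p_j |w_j|."""
    p = np.array([s.effect_allele_frequency for s in panel], dtype=float)
    w = _weights(panel, signed_weights)
    return float(np.sum(2.0 * p * w))


@dataclass
class BurdenRegressionResults:
    """OLS fit of age at menopause on repeat, repeat^2 and the burden score.

    ``params``/``bse``/``pvalues`` are indexed by
    ``["const", "repeat_length", "repeat_length_sq", "total_snp_risk"]``;
    ``partial_r2`` (no intercept entry) is the squared partial correlation
    of each predictor given the others.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    partial_r2: pd.Series
    n: int
    df_resid: int
    rsquared: float
    condition_number: float

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "partial_R2": self.partial_r2.reindex(self.params.index),
                "p": self.pvalues,
            }
        )
        return tab

    def __str__(self) -> str:
        head = (
            f"Burden regression (OLS), n = {self.n}, "
            f"R^2 = {self.rsquared:.3f}\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v:.4f}")


class BurdenRegression:
    """Linear model of age at natural menopause on repeat terms and TSR.

    Build from a prepared DataFrame (columns ``age_at_menopause``,
    ``repeat_length``, ``total_snp_risk``) or from participants via
    :meth:`from_participants`, which computes the score and applies
    complete-case filtering on genotypes.

    ``center`` subtracts the mean repeat length before squaring, improving
    conditioning; fitted coefficients are mapped back to the raw
    (uncentered) basis so reported values are directly comparable.
    """

    def __init__(self, data: pd.DataFrame, *, center: bool = False) -> None:
        required = {"age_at_menopause", "repeat_length", "total_snp_risk"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.center = center
        if len(self.data) <= 5:
            raise ValueError(f"need n > 5 complete cases, have {len(self.data)}")

    @classmethod
    def from_participants(
        cls,
        women: Iterable[Participant],
        panel: Sequence[SnpDefinition] = DEFAULT_PANEL,
        *,
        signed_weights: bool = False,
        center: bool = False,
    ) -> "BurdenRegression":
        rows = []
        n_dropped = 0
        for p in women:
            if not p.menopause_reported or p.age_at_menopause is None:
                raise ValueError(
                    f"{p.id}: burden regression requires observed menopause"
                )
            tsr = total_snp_risk(p.genotypes, panel, signed_weights=signed_weights)
            if tsr is None:
                n_dropped += 1
                logger.warning("%s: missing panel genotype, dropped", p.id)
                continue
            rows.append(
                {
                    "age_at_menopause": float(p.age_at_menopause),
                    "repeat_length": float(p.repeat_length),
                    "total_snp_risk": tsr,
                }
            )
        if n_dropped:
            logger.info("complete-case filter dropped %d women", n_dropped)
        return cls(pd.DataFrame(rows), center=center)

    def _design(self) -> tuple[pd.DataFrame, float]:
        r = self.data["repeat_length"].to_numpy(dtype=float)
        mu = r.mean() if self.center else 0.0
        rc = r - mu
        X = pd.DataFrame(
            {
                "repeat_length": rc,
                "repeat_length_sq": rc**2,
                "total_snp_risk": self.data["total_snp_risk"].to_numpy(dtype=float),
            }
        )
        return sm.add_constant(X), mu

    def fit(self, *, cond_max: float = 1e12) -> BurdenRegressionResults:
        X, mu = self._design()
        y = self.data["age_at_menopause"].to_numpy(dtype=float)
        cond = np.linalg.cond(X.to_numpy())
        if cond > cond_max:
            raise ValueError(
                f"design matrix ill-conditioned (condition number {cond:.3g}); "
                "constant or collinear predictor?"
            )
        res = sm.OLS(y, X).fit()
        params = res.params.copy()
        bse = res.bse.copy()
        if self.center and mu != 0.0:
            # map (r-mu), (r-mu)^2 basis back to raw r, r^2:
            # b1' = b1 - 2 mu b2 ; b0' = b0 - mu b1 + mu^2 b2 ; b2 unchanged
            b0, b1, b2 = params["const"], params["repeat_length"], params["repeat_length_sq"]
            params["const"] = b0 - mu * b1 + mu * mu * b2
            params["repeat_length"] = b1 - 2 * mu * b2
            # SEs for the mapped coefficients from the covariance
            cov = res.cov_params()
            a0 = pd.Series({"const": 1.0, "repeat_length": -mu, "repeat_length_sq": mu * mu,
                            "total_snp_risk": 0.0})
            a1 = pd.Series({"const": 0.0, "repeat_length": 1.0, "repeat_length_sq": -2 * mu,
                            "total_snp_risk": 0.0})
            bse = bse.copy()
            bse["const"] = float(np.sqrt(a0 @ cov @ a0))
            bse["repeat_length"] = float(np.sqrt(a1 @ cov @ a1))
        tvals = params / bse
        df = int(res.df_resid)
        pvals = pd.Series(
            2.0 * stats.t.sf(np.abs(tvals.to_numpy()), df), index=params.index
        )
        pred = [c for c in X.columns if c != "const"]
        t2 = tvals[pred] ** 2
        partial_r2 = (t2 / (t2 + df)).rename("partial_R2")
        return BurdenRegressionResults(
            params=params,
            bse=bse,
            pvalues=pvals,
            partial_r2=partial_r2,
            n=int(res.nobs),
            df_resid=df,
            rsquared=float(res.rsquared),
            condition_number=float(cond),
        )


def fit_burden_regression(
    women: Iterable[Participant],
    panel: Sequence[SnpDefinition] = DEFAULT_PANEL,
    *,
    signed_weights: bool = False,
    center: bool = False,
) -> BurdenRegressionResults:
    """Convenience wrapper: score, complete-case filter, and OLS fit."""
    return BurdenRegression.from_participants(
        women, panel, signed_weights=signed_weights, center=center
    ).fit()


PANEL_COLUMNS = [
    "rsid",
    "chrom",
    "position",
    "effect_allele",
    "effect_allele_frequency",
    "effect_size",
]


def read_panel(path) -> tuple[SnpDefinition, ...]:
    """Read a SNP panel TSV (columns: rsid, chrom, position, effect_allele,
    effect_allele_frequency, effect_size)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file lacks columns: {sorted(missing)}")
    return tuple(
        SnpDefinition(
            rsid=row.rsid,
            chromosome=str(row.chrom),
            position=int(row.position),
            effect_allele=row.effect_allele,
            effect_allele_frequency=float(row.effect_allele_frequency),
            effect_size=float(row.effect_size),
        )
        for row in df.itertuples()
    )


def write_panel(panel: Sequence[SnpDefinition], path) -> None:
    df = pd.DataFrame(
        [
            {
                "rsid": s.rsid,
                "chrom": s.chromosome,
                "position": s.position,
                "effect_allele": s.effect_allele,
                "effect_allele_frequency": s.effect_allele_frequency,
                "effect_size": s.effect_size,
            }
            for s in panel
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
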