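"""Cox proportional-hazards estimation of menopause hazard ratios.

The model: the instantaneous hazard of reaching natural menopause at age
``t`` for a woman with covariate vector ``x`` is

    h(t | x) = h0(t) * exp(x' beta)

with an unspecified baseline hazard ``h0``.  ``beta`` is estimated by
maximizing the Cox partial likelihood; tied event ages are handled with the
Efron correction by default (Breslow available).  The design matrix holds
indicator columns for the three premutation repeat groups (noncarriers are
the reference) plus the interview/lifestyle covariates, so ``exp(beta_g)``
is the hazard ratio of PM group ``g`` versus noncarriers.

Age is the time scale, measured from birth; left truncation at study entry
is not modeled.

Numerics: Newton-Raphson with step-halving on partial-likelihood decrease;
convergence when the max absolute score component falls below ``tol``
(default 1e-8); Wald standard errors from the inverse observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    PM_GROUPS,
    Participant,
    RepeatGroup,
    SurvivalRecord,
    build_survival_records,
)

__all__ = ["CoxPH", "CoxPHResults", "ConvergenceError", "fit_cox", "hazard_table"]


class ConvergenceError(RuntimeError):
    """The Newton-Raphson iteration failed to converge; carries diagnostics."""


GROUP_COLUMNS = {
    RepeatGroup.LOW_PM: "group_LowPM",
    RepeatGroup.MID_PM: "group_MidPM",
    RepeatGroup.HIGH_PM: "group_HighPM",
}


def _neg_loglik_parts(beta, times, events, X, order, ties):
    """Partial log-likelihood, score, and observed information at ``beta``.

    ``order`` sorts times ascending.  Risk set at an event time t is
    {i : t_i >= t}.  Efron handles d tied events by stepping the tied mass
    out of the denominator in fractions l/d, l = 0..d-1; Breslow leaves the
    full risk set in every tied factor.
    """
    n, p = X.shape
    t = times[order]
    d = events[order]
    Xs = X[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * Xs
    wXX = wX[:, :, None] * Xs[:, None, :]  # n x p x p

    # reverse cumulative sums: R*[i] = sum over j >= i (sorted order)
    R0 = np.cumsum(w[::-1])[::-1]
    R1 = np.cumsum(wX[::-1], axis=0)[::-1]
    R2 = np.cumsum(wXX.reshape(n, -1)[::-1], axis=0)[::-1].reshape(n, p, p)

    ev_idx = np.flatnonzero(d)
    if ev_idx.size == 0:
        raise ConvergenceError("no events in the data")
    ev_t = t[ev_idx]
    # group events by tied time; ``starts`` marks the first event of a tie set
    new_group = np.empty(ev_idx.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = ev_t[1:] != ev_t[:-1]
    group_id = np.cumsum(new_group) - 1
    n_groups = group_id[-1] + 1
    # first sorted position with t >= tie time (events sorted, censored may
    # share times; risk set anchored at the first index whose time equals it)
    first_at_time = np.searchsorted(t, ev_t, side="left")

    # per-group sums over tied events
    s0 = np.bincount(group_id, weights=w[ev_idx], minlength=n_groups)
    s1 = np.zeros((n_groups, p))
    s2 = np.zeros((n_groups, p, p))
    np.add.at(s1, group_id, wX[ev_idx])
    np.add.at(s2, group_id, wXX[ev_idx])
    d_sizes = np.bincount(group_id, minlength=n_groups)

    # rank l of each event within its tie set
    starts_in_ev = np.flatnonzero(new_group)
    l_rank = np.arange(ev_idx.size) - starts_in_ev[group_id]
    frac = l_rank / d_sizes[group_id] if ties == "efron" else np.zeros(ev_idx.size)

    S0 = R0[first_at_time] - frac * s0[group_id]
    S1 = R1[first_at_time] - frac[:, None] * s1[group_id]
    S2 = R2[first_at_time] - frac[:, None, None] * s2[group_id]

    loglik = float(eta[ev_idx].sum() - np.log(S0).sum())
    Z = S1 / S0[:, None]
    score = Xs[ev_idx].sum(axis=0) - Z.sum(axis=0)
    info = (S2 / S0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", Z, Z)
    return loglik, score, info


@dataclass
class CoxPHResults:
    """Fitted Cox model: log-hazard coefficients and Wald inference.

    ``params`` are log-hazard-ratio coefficients; ``hazard_ratios`` their
    exponentials; ``bse`` Wald standard errors from the inverse observed
    information; ``pvalues`` two-sided Wald p-values.
    """

    params: pd.Series
    bse: pd.Series
    n: int
    n_events: int
    ties_method: str
    converged: bool
    loglik: float
    loglik_null: float
    iterations: int
    covariance: pd.DataFrame = field(repr=False, default=None)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.params.index,
            name="p",
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": np.exp(self.params - z * self.bse),
                "upper": np.exp(self.params + z * self.bse),
            }
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se(coef)": self.bse,
                "HR 95% lower": ci["lower"],
                "HR 95% upper": ci["upper"],
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def __str__(self) -> str:
        head = (
            f"Cox proportional hazards ({self.ties_method} ties)\n"
            f"n = {self.n}, events = {self.n_events}, "
            f"log-partial-likelihood = {self.loglik:.3f}\n"
        )
        return head + self.summary().to_string(float_format=lambda v: f"{v:.4f}")


class CoxPH:
    """Cox proportional-hazards model of age at natural menopause.

    Parameters
    ----------
    durations, events
        Event/censoring ages and event indicators.
    X
        Covariate DataFrame (one column per regression term; repeat-group
        indicators included as columns when built via ``from_records``).
    ties
        ``"efron"`` (default) or ``"breslow"``.
    """

    def __init__(
        self,
        durations: Sequence[float],
        events: Sequence[bool],
        X: pd.DataFrame,
        *,
        ties: str = "efron",
    ) -> None:
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        self.durations = np.asarray(durations, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        self.X = X.astype(float)
        self.ties = ties
        if len(self.durations) != len(self.X) or len(self.events) != len(self.X):
            raise ValueError("durations, events and X must have equal length")
        if self.events.sum() < 2 or np.unique(self.durations[self.events]).size < 2:
            raise ConvergenceError("need at least two distinct event times")
        # full-rank check with a condition diagnostic
        M = np.column_stack([np.ones(len(self.X)), self.X.to_numpy()])
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            raise ConvergenceError(
                f"design matrix rank-deficient (rank {rank} < {M.shape[1]}); "
                f"columns: {list(self.X.columns)}"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[SurvivalRecord],
        covariate_names: Sequence[str] = ("age_at_interview", "race_nonwhite", "ever_smoked", "bmi"),
        *,
        ties: str = "efron",
    ) -> "CoxPH":
        """Build the design from survival records: PM-group indicators
        (noncarriers as reference) plus the named covariates."""
        records = list(records)
        if not records:
            raise ValueError("no survival records")
        if not any(r.group == RepeatGroup.NORMAL for r in records):
            raise ValueError("no noncarrier (Normal) reference group in the data")
        present_pm = [g for g in PM_GROUPS if any(r.group == g for r in records)]
        rows = []
        for r in records:
            row = {GROUP_COLUMNS[g]: float(r.group == g) for g in present_pm}
            for name in covariate_names:
                if name not in r.covariates:
                    raise KeyError(f"record {r.id} lacks covariate {name!r}")
                row[name] = r.covariates[name]
            rows.append(row)
        X = pd.DataFrame(rows, index=[r.id for r in records])
        return cls([r.time for r in records], [r.event for r in records], X, ties=ties)

    def fit(self, *, tol: float = 1e-8, max_iter: int = 100) -> CoxPHResults:
        """Maximize the partial likelihood by Newton-Raphson with step-halving."""
        times = self.durations
        events = self.events
        Xmat = self.X.to_numpy()
        Xc = Xmat - Xmat.mean(axis=0)  # centering improves conditioning only
        order = np.argsort(times, kind="stable")
        p = Xc.shape[1]
        beta = np.zeros(p)
        loglik, score, info = _neg_loglik_parts(beta, times, events, Xc, order, self.ties)
        loglik_null = loglik
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular information matrix at iteration {it}: {exc}"
                ) from exc
            # step-halving: accept the first step that does not decrease loglik
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, score_new, info_new = _neg_loglik_parts(
                    cand, times, events, Xc, order, self.ties
                )
                if ll_new >= loglik - 1e-12:
                    break
                scale /= 2.0
            else:
                raise ConvergenceError(
                    f"step-halving failed at iteration {it} (loglik {loglik:.6f})"
                )
            moved = np.max(np.abs(cand - beta))
            beta, loglik, score, info = cand, ll_new, score_new, info_new
            # score tolerance, or the step has shrunk to float resolution
            # (the score is a sum over events, so its attainable floor
            # grows with n while beta is already fully resolved)
            if np.max(np.abs(score)) < tol or moved < 1e-12:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations; "
                f"max |score| = {np.max(np.abs(score)):.3g}"
            )
        cov = np.linalg.inv(info)
        names = list(self.X.columns)
        return CoxPHResults(
            params=pd.Series(beta, index=names, name="coef"),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names, name="se"),
            n=len(times),
            n_events=int(events.sum()),
            ties_method=self.ties,
            converged=converged,
            loglik=loglik,
            loglik_null=loglik_null,
            iterations=it,
            covariance=pd.DataFrame(cov, index=names, columns=names),
        )

    def loglik_at(self, beta: Sequence[float]) -> float:
        """Partial log-likelihood at an arbitrary coefficient vector."""
        Xmat = self.X.to_numpy()
        Xc = Xmat - Xmat.mean(axis=0)
        order = np.argsort(self.durations, kind="stable")
        ll, _, _ = _neg_loglik_parts(
            np.asarray(beta, dtype=float), self.durations, self.events, Xc, order, self.ties
        )
        return ll


def fit_cox(
    records: Iterable[SurvivalRecord],
    covariate_names: Sequence[str] = ("age_at_interview", "race_nonwhite", "ever_smoked", "bmi"),
    *,
    ties: str = "efron",
) -> CoxPHResults:
    """Convenience wrapper: build a :class:`CoxPH` from records and fit it."""
    return CoxPH.from_records(records, covariate_names, ties=ties).fit()


def hazard_table(
    cohort: list[Participant],
    covariate_names: Sequence[str] = ("age_at_interview", "race_nonwhite", "ever_smoked", "bmi"),
    *,
    ties: str = "efron",
) -> pd.DataFrame:
    """Per-PM-group hazard ratios versus noncarriers, with and without POF women.

    Mirrors the four-column presentation: HR and Wald p including women with
    POF, then HR and p after removing them from the fit entirely.  A cohort
    with no PM carriers yields an empty table.
    """
    out: dict[str, dict[str, float]] = {}
    for exclude, suffix in ((False, "incl_pof"), (True, "excl_pof")):
        records = build_survival_records(cohort, exclude_pof=exclude)
        groups_present = {r.group for r in records} - {RepeatGroup.NORMAL}
        if not groups_present:
            continue
        res = fit_cox(records, covariate_names, ties=ties)
        for g in PM_GROUPS:
            col = GROUP_COLUMNS[g]
            if col not in res.params.index:
                continue
            out.setdefault(g.value, {})[f"hr_{suffix}"] = float(res.hazard_ratios[col])
            out.setdefault(g.value, {})[f"p_{suffix}"] = float(res.pvalues[col])
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "repeat_group"
    wanted = ["hr_incl_pof", "p_incl_pof", "hr_excl_pof", "p_excl_pof"]
    return table.reindex(columns=[c for c in wanted if c in table.columns])
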