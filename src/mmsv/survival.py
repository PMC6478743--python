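"""Survival analysis: Kaplan-Meier, Cox PH, and permutation significance.

Kaplan-Meier curves and (multivariate) Cox proportional-hazards fits are
delegated to lifelines. Two bespoke procedures are implemented here:

* a permutation "bootstrap" p-value for a hazard ratio: the group label is
  shuffled across patients B times (group sizes preserved) and the observed
  |log HR| is compared with the permuted distribution, with the +1/(B+1)
  finite-sample correction;
* a matched downsampling comparison for unequal group sizes: the larger
  group is repeatedly subsampled to the smaller group's size and the
  statistic of interest recomputed, giving an empirical null for the small
  group's observed statistic.

A fast single-covariate Newton solver (Efron tie handling) drives the
permutation loops; it is exact, not an approximation, and agrees with
lifelines to high precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .model import ValidationError, warn


class ConvergenceError(RuntimeError):
    """Monotone partial likelihood (perfect separation) or failed Newton iteration."""


@dataclass
class HazardEstimate:
    covariate: str
    coef: float
    se: float
    p: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.coef - 1.96 * self.se)),
            float(np.exp(self.coef + 1.96 * self.se)),
        )


def km_curve(
    table: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Product-limit survival estimates, one step function per group.

    Returns a DataFrame with columns group, time, survival; the estimate
    starts at 1.0 and is non-increasing within each group.
    """
    frames = []
    groups = (
        [(".", table)] if group_col is None else list(table.groupby(group_col))
    )
    for label, sub in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
) -> list[HazardEstimate]:
    """Cox proportional-hazards fit (partial likelihood, Wald p per covariate)."""
    cols = [time_col, event_col, *covariates]
    sub = table[cols].dropna()
    if len(sub) < len(table):
        warn(f"dropped {len(table) - len(sub)} rows with missing covariates")
    if sub[event_col].sum() == 0:
        raise ValidationError("no events; Cox model undefined")
    cph = CoxPHFitter()
    try:
        cph.fit(
            sub.astype(float),
            duration_col=time_col,
            event_col=event_col,
        )
    except Exception as exc:  # lifelines raises ConvergenceError/Warning variants
        raise ConvergenceError(str(exc)) from exc
    summary = cph.summary
    return [
        HazardEstimate(
            covariate=cov,
            coef=float(summary.loc[cov, "coef"]),
            se=float(summary.loc[cov, "se(coef)"]),
            p=float(summary.loc[cov, "p"]),
        )
        for cov in covariates
    ]


def count_scaled_hr(estimate: HazardEstimate, max_count: float) -> float:
    """Hazard ratio at the maximum of a per-unit count covariate
    (exp(coef * max_count)); expresses the increased hazard of carrying the
    maximum observed number of events."""
    return float(np.exp(estimate.coef * max_count))


def _cox_single(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Newton-Raphson for a single-covariate Cox partial likelihood.

    Efron handling of tied event times (``ties='breslow'`` for the simpler
    correction). Returns (coef, se). Raises ConvergenceError on monotone
    likelihood (separation) or non-convergence.
    """
    order = np.argsort(time, kind="stable")
    t = np.asarray(time, dtype=float)[order]
    d = np.asarray(event, dtype=bool)[order]
    xs = np.asarray(x, dtype=float)[order]
    n_events = int(d.sum())
    if n_events == 0:
        raise ValidationError("no events")

    te = t[d]
    xe = xs[d]
    times_u, group_start, m_u = np.unique(te, return_index=True, return_counts=True)
    # risk-set entry index for each unique event time (at-risk = time >= t)
    risk_idx = np.searchsorted(t, times_u, side="left")
    # within-tie index l = 0..m-1 and group expansion helpers
    l_idx = np.arange(n_events) - np.repeat(group_start, m_u)
    frac = l_idx / np.repeat(m_u, m_u)

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * xs)
        wx = w * xs
        wxx = wx * xs
        # reverse cumulative sums -> risk-set aggregates
        r0 = np.cumsum(w[::-1])[::-1]
        r1 = np.cumsum(wx[::-1])[::-1]
        r2 = np.cumsum(wxx[::-1])[::-1]
        S0 = np.repeat(r0[risk_idx], m_u)
        S1 = np.repeat(r1[risk_idx], m_u)
        S2 = np.repeat(r2[risk_idx], m_u)
        if ties == "efron":
            we = np.exp(beta * xe)
            d0 = np.add.reduceat(we, group_start)
            d1 = np.add.reduceat(we * xe, group_start)
            d2 = np.add.reduceat(we * xe * xe, group_start)
            S0 = S0 - frac * np.repeat(d0, m_u)
            S1 = S1 - frac * np.repeat(d1, m_u)
            S2 = S2 - frac * np.repeat(d2, m_u)
        mean = S1 / S0
        grad = float(xe.sum() - mean.sum())
        info = float(np.sum(S2 / S0 - mean**2))
        if not np.isfinite(info) or info <= 1e-10:
            raise ConvergenceError("monotone partial likelihood (separation?)")
        step = grad / info
        beta += step
        if abs(beta) > 500:
            raise ConvergenceError("coefficient diverged (separation?)")
        if abs(step) < tol:
            return float(beta), float(1.0 / np.sqrt(info))
    raise ConvergenceError(f"Newton did not converge in {max_iter} iterations")


@dataclass
class PermutationResult:
    p: float
    observed_log_hr: float
    permuted_log_hr: np.ndarray = field(repr=False)
    n_redrawn: int = 0


def bootstrap_hr_pvalue(
    table: pd.DataFrame,
    label_col: str,
    time_col: str = "time",
    event_col: str = "event",
    B: int = 1000,
    seed: int | None = None,
    sided: str = "two",
    ties: str = "efron",
) -> PermutationResult:
    """Permutation p-value for the hazard ratio of a binary label.

    The label is permuted across patients ``B`` times (group sizes
    preserved); p = (1 + #{permutations at least as extreme}) / (B + 1).
    Two-sided on |log HR| by default. Degenerate permutations (no events in
    a group, or separation) are redrawn and counted.
    """
    t = table[time_col].to_numpy(dtype=float)
    d = table[event_col].to_numpy()
    x = table[label_col].to_numpy(dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValidationError("label must be binary")
    beta_obs, _ = _cox_single(t, d, x, ties=ties)
    rng = np.random.default_rng(seed)
    perm = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            xp = rng.permutation(x)
            if (d[xp == 1].sum() == 0) or (d[xp == 0].sum() == 0):
                n_redrawn += 1
                continue
            try:
                beta_p, _ = _cox_single(t, d, xp, ties=ties)
            except ConvergenceError:
                n_redrawn += 1
                continue
            perm[b] = beta_p
            break
    if n_redrawn:
        warn(f"{n_redrawn} degenerate permutations redrawn")
    if sided == "two":
        extreme = np.abs(perm) >= abs(beta_obs) - 1e-12
    elif sided == "greater":
        extreme = perm >= beta_obs - 1e-12
    elif sided == "less":
        extreme = perm <= beta_obs + 1e-12
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = (1 + int(extreme.sum())) / (B + 1)
    return PermutationResult(
        p=p, observed_log_hr=float(beta_obs), permuted_log_hr=perm, n_redrawn=n_redrawn
    )


@dataclass
class DownsampleResult:
    p: float | None
    observed: float | None
    samples: np.ndarray = field(repr=False)


def matched_downsample_compare(
    table_large_group: pd.DataFrame,
    n_small: int,
    statistic,
    B: int = 1000,
    seed: int | None = None,
    observed: float | None = None,
    alternative: str = "less",
) -> DownsampleResult:
    """Empirical null for a small group's statistic via matched downsampling.

    ``statistic(df) -> float`` is recomputed on ``B`` subsamples of size
    ``n_small`` drawn without replacement from the larger group. With an
    ``observed`` value, the one-sided empirical p (with the +1 correction)
    is returned: 'less' asks how often a subsample is <= the observed value.
    """
    if not 0 < n_small <= len(table_large_group):
        raise ValidationError("n_small must be in (0, len(large group)]")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(table_large_group))
    samples = np.empty(B)
    for b in range(B):
        take = rng.choice(idx, size=n_small, replace=False)
        samples[b] = statistic(table_large_group.iloc[take])
    p = None
    if observed is not None:
        if alternative == "less":
            extreme = samples <= observed + 1e-12
        elif alternative == "greater":
            extreme = samples >= observed - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        p = (1 + int(extreme.sum())) / (B + 1)
    return DownsampleResult(p=p, observed=observed, samples=samples)
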