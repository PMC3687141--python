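"""Psychometric analysis chain for simulated 4AFC sessions.

Covers per-subject accuracy aggregation, the variance-stabilizing
arcsine transform, sensitivity (d') under the independent-observations
m-AFC signal-detection model, a mixed repeated-measures ANOVA with the
Greenhouse-Geisser sphericity correction and generalized eta-squared
effect sizes, and linear-trend contrast analysis across (log) stimulus
duration.

The ANOVA operates on one value per subject and within-cell (here a
proportion correct, usually arcsine-transformed).  Within-subject
effects are computed through orthonormal contrast scores, which yields
an exact orthogonal decomposition of the total sum of squares for
designs balanced within subject (group sizes may differ; sums of
squares use weighted group means).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps
from scipy.linalg import helmert

__all__ = [
    "CellTable",
    "AnovaResult",
    "AnovaResults",
    "TrendResult",
    "accuracy_table",
    "arcsine_transform",
    "pc_from_dprime",
    "dprime_4afc",
    "mixed_rm_anova",
    "linear_trend_analysis",
]


# ---------------------------------------------------------------------------
# accuracy aggregation


@dataclass(frozen=True)
class CellTable:
    """Per-subject, per-cell proportions correct (long format).

    ``data`` columns: subject, group, one column per within factor,
    p_correct, n_trials.
    """

    data: pd.DataFrame
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"subject", "group", "p_correct", "n_trials",
                    *self.factors}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cell table misses columns {sorted(missing)}")


def accuracy_table(records: pd.DataFrame, factors: Sequence[str],
                   subject: str = "subject", group: str = "group",
                   correct: str = "correct") -> CellTable:
    """Proportion correct per subject and factor cell.

    Every subject must contribute trials to every cell of the factor
    crossing; a missing cell raises an error naming subject and cell.
    """
    factors = tuple(factors)
    grouped = records.groupby([subject, group, *factors], sort=True,
                              observed=True)[correct]
    table = grouped.agg(p_correct="mean", n_trials="size").reset_index()
    table = table.rename(columns={subject: "subject", group: "group"})
    cells = sorted(set(map(tuple, table[list(factors)].itertuples(index=False))))
    for subj, sub in table.groupby("subject"):
        have = set(map(tuple, sub[list(factors)].itertuples(index=False)))
        lost = set(cells) - have
        if lost:
            raise ValueError(
                f"subject {subj!r} has no trials in cell(s) {sorted(lost)}")
    return CellTable(data=table, factors=factors)


def arcsine_transform(p):
    """Variance-stabilizing transform y = arcsin(sqrt(p)), radians."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# d' for m-AFC


def pc_from_dprime(dprime: float, m: int = 4) -> float:
    """Proportion correct under the independent-observations m-AFC model:
    pc = E_z[ Phi(z + d')^(m-1) ] with z standard normal."""
    val, _ = integrate.quad(
        lambda z: sps.norm.pdf(z) * sps.norm.cdf(z + dprime) ** (m - 1),
        -8.5, 8.5 + abs(dprime), limit=200)
    return float(val)


def dprime_4afc(pc: float, m: int = 4, tol: float = 1e-8) -> float:
    """Invert the m-AFC model numerically (bisection to |dpc| < tol).

    Chance (pc = 1/m) maps to 0; below-chance proportions give negative
    d'.  Near-perfect proportions are capped with a warning.
    """
    cap = 1.0 - 1e-6
    if pc >= cap:
        warnings.warn("pc at ceiling; d' computed at pc = 1 - 1e-6",
                      RuntimeWarning, stacklevel=2)
        pc = cap
    if pc <= 0.0:
        raise ValueError("pc must be positive")
    lo, hi = -10.0, 10.0
    f = lambda d: pc_from_dprime(d, m) - pc
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"pc={pc} out of invertible range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


@dataclass(frozen=True)
class AnovaResult:
    """One effect: F, unadjusted dfs, the Greenhouse-Geisser epsilon,
    adjusted p, generalized eta-squared, and the sums of squares."""

    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon_hat: float
    p_unadjusted: float
    p_adjusted: float
    eta2_g: float
    ss: float
    ss_error: float


@dataclass(frozen=True)
class AnovaResults:
    """Result set for one model; iterable, indexable by effect name."""

    effects: tuple[AnovaResult, ...]
    observed: tuple[str, ...]
    ss_total: float

    def __iter__(self):
        return iter(self.effects)

    def __getitem__(self, name: str) -> AnovaResult:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": [e.effect for e in self.effects],
                "F": [e.F for e in self.effects],
                "df_num": [e.df_num for e in self.effects],
                "df_den": [e.df_den for e in self.effects],
                "epsilon_hat": [e.epsilon_hat for e in self.effects],
                "p_unadjusted": [e.p_unadjusted for e in self.effects],
                "p_adjusted": [e.p_adjusted for e in self.effects],
                "eta2_g": [e.eta2_g for e in self.effects],
                "SS": [e.ss for e in self.effects],
                "SS_error": [e.ss_error for e in self.effects],
            }
        )

    def summary(self) -> str:
        frame = self.to_frame()
        with pd.option_context("display.float_format", "{:10.4f}".format):
            body = frame.to_string(index=False)
        head = ("Mixed repeated-measures ANOVA "
                f"(GG-adjusted p; observed: {', '.join(self.observed) or 'none'})")
        return f"{head}\n{'-' * len(head)}\n{body}"


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the constant."""
    return helmert(k, full=False)


def _pivot_wide(table: CellTable, dv: str) -> tuple[np.ndarray, np.ndarray,
                                                    list[np.ndarray]]:
    data = table.data
    factors = list(table.factors)
    levels = [np.array(sorted(data[f].unique())) for f in factors]
    if factors:
        wide = data.pivot_table(index=["subject", "group"], columns=factors,
                                values=dv, observed=True)
        expected = list(itertools.product(*levels))
        cols = [c if isinstance(c, tuple) else (c,) for c in wide.columns]
        if sorted(cols) != sorted(expected) or wide.isna().any().any():
            raise ValueError("design not balanced within subject")
        order = [cols.index(c) for c in expected]
        values = wide.to_numpy()[:, order]
        groups = wide.index.get_level_values("group").to_numpy()
    else:
        sub = data.set_index("subject")
        values = sub[[dv]].to_numpy()
        groups = sub["group"].to_numpy()
    return values, groups, levels


def mixed_rm_anova(table: CellTable, dv: str = "p_correct",
                   observed: Sequence[str] = ("group",)) -> AnovaResults:
    """Mixed-design ANOVA: one between-subjects factor (group) crossed
    with the table's within-subject factors.

    For each within effect the Greenhouse-Geisser epsilon is estimated
    from the pooled covariance of the effect's orthonormal contrast
    scores, eps = tr(S)^2 / (q * tr(S^2)), clamped to [1/q, 1], and the
    adjusted p uses (eps * df_num, eps * df_den).  Generalized
    eta-squared follows the additive-SS recipe with the listed
    ``observed`` (non-manipulated) factors entering every denominator.
    """
    Y, groups, levels = _pivot_wide(table, dv)
    n_subj, p_cells = Y.shape
    labels = pd.unique(groups)
    n_groups = len(labels)
    if n_subj < 2 or (n_groups > 1 and
                      min((groups == g).sum() for g in labels) < 2):
        raise ValueError("need at least 2 subjects per group")
    group_masks = [groups == g for g in labels]
    n_g = np.array([m.sum() for m in group_masks])
    factors = list(table.factors)
    k = [len(lv) for lv in levels]

    # between-subjects part, from subject means
    m_i = Y.mean(axis=1)
    grand = float(np.mean(m_i))
    mbar_g = np.array([m_i[m].mean() for m in group_masks])
    ss_between = p_cells * float(np.sum(n_g * (mbar_g - grand) ** 2))
    ss_subj_err = p_cells * float(
        sum(((m_i[m] - mb) ** 2).sum() for m, mb in zip(group_masks, mbar_g)))
    df_between, df_subj = n_groups - 1, n_subj - n_groups

    # within-subject parts via orthonormal contrast scores
    within_parts = []  # (subset, q, ss_S, ss_SxG, ss_err, eps)
    for r in range(1, len(factors) + 1):
        for subset in itertools.combinations(range(len(factors)), r):
            mats = []
            for j in range(len(factors)):
                mats.append(_orthonormal_contrast(k[j]) if j in subset
                            else np.full((1, k[j]), 1.0 / math.sqrt(k[j])))
            C = mats[0]
            for mmat in mats[1:]:
                C = np.kron(C, mmat)
            q = C.shape[0]
            U = Y @ C.T  # n_subj x q
            ubar_g = np.stack([U[m].mean(axis=0) for m in group_masks])
            ubar_w = (n_g[:, None] * ubar_g).sum(axis=0) / n_subj
            ss_S = n_subj * float(ubar_w @ ubar_w)
            ss_SxG = float(np.sum(n_g * (ubar_g ** 2).sum(axis=1))) - ss_S
            ubar_by_subj = np.zeros_like(U)
            for mask, ub in zip(group_masks, ubar_g):
                ubar_by_subj[mask] = ub
            resid = U - ubar_by_subj
            ss_err = float((resid ** 2).sum())
            if df_subj > 0:
                sigma = sum((U[m] - ub).T @ (U[m] - ub)
                            for m, ub in zip(group_masks, ubar_g)) / df_subj
                tr = float(np.trace(sigma))
                tr2 = float(np.trace(sigma @ sigma))
                eps = 1.0 if q == 1 or tr2 <= 0 else tr * tr / (q * tr2)
                eps = min(1.0, max(1.0 / q, eps))
            else:
                eps = 1.0
            within_parts.append((subset, q, ss_S, ss_SxG, ss_err, eps))

    ss_total = (ss_between + ss_subj_err
                + sum(s + g + e for _, _, s, g, e, _ in within_parts))

    # assemble effects
    all_error_ss = ss_subj_err + sum(p[4] for p in within_parts)
    effect_rows: list[tuple[str, tuple[str, ...], float, float, float,
                            float, float]] = []
    # (name, factor names incl. group?, SS, df_num, df_den, ss_err, eps)
    if n_groups > 1:
        effect_rows.append(("group", ("group",), ss_between, df_between,
                            df_subj, ss_subj_err, 1.0))
    for subset, q, ss_S, ss_SxG, ss_err, eps in within_parts:
        names = tuple(factors[j] for j in subset)
        df_err = q * df_subj
        effect_rows.append((":".join(names), names, ss_S, q, df_err,
                            ss_err, eps))
        if n_groups > 1:
            effect_rows.append(("group:" + ":".join(names),
                                ("group",) + names, ss_SxG,
                                q * (n_groups - 1), df_err, ss_err, eps))

    observed = tuple(observed)
    measured_ss = {name: ss for name, facs, ss, *_ in effect_rows
                   if set(facs) <= set(observed)}

    results = []
    for name, facs, ss, df_num, df_den, ss_err, eps in effect_rows:
        if df_den <= 0:
            raise ValueError("no error degrees of freedom")
        ms = ss / df_num
        mse = ss_err / df_den
        F = ms / mse if mse > 0 else math.inf
        p_un = float(sps.f.sf(F, df_num, df_den))
        p_adj = float(sps.f.sf(F, eps * df_num, eps * df_den))
        denom = ss + all_error_ss + sum(
            v for key, v in measured_ss.items() if key != name)
        eta2 = ss / denom if denom > 0 else 0.0
        results.append(AnovaResult(effect=name, F=F, df_num=df_num,
                                   df_den=df_den, epsilon_hat=eps,
                                   p_unadjusted=p_un, p_adjusted=p_adj,
                                   eta2_g=eta2, ss=ss, ss_error=ss_err))
    return AnovaResults(effects=tuple(results), observed=observed,
                        ss_total=ss_total)


# ---------------------------------------------------------------------------
# linear trend contrasts


@dataclass(frozen=True)
class TrendResult:
    """Per-subject linear-trend contrast scores and their tests: the
    grand-mean test (scores against zero) and the between-group one-way
    ANOVA on the scores."""

    scores: pd.DataFrame
    weights: np.ndarray
    levels: np.ndarray
    grand_mean_F: float
    grand_mean_p: float
    group_F: float
    group_p: float
    df_num: int
    df_den: int


def linear_trend_analysis(table: CellTable, dv: str = "p_correct",
                          level_factor: str = "duration_s",
                          log_levels: bool = True) -> TrendResult:
    """Linear-trend contrast of ``dv`` across an ordered within factor.

    Weights are the (log-)level values, centered and normalized to unit
    sum of squares; each subject's score is the weighted sum of its cell
    values.  The grand mean of the scores is tested against zero and the
    scores are compared across groups with a one-way ANOVA, both using
    the pooled within-group error.
    """
    if level_factor not in table.factors:
        raise ValueError(f"{level_factor!r} is not a factor of the table")
    sub = table.data
    other = [f for f in table.factors if f != level_factor]
    if other:
        sub = (sub.groupby(["subject", "group", level_factor],
                           observed=True)[dv].mean().reset_index())
    wide = sub.pivot_table(index=["subject", "group"], columns=level_factor,
                           values=dv, observed=True)
    levels = np.array(sorted(wide.columns))
    if len(levels) < 2:
        raise ValueError("need at least 2 levels for a trend")
    wide = wide[levels]
    x = np.log(levels.astype(float)) if log_levels else levels.astype(float)
    w = x - x.mean()
    w = w / math.sqrt(float(w @ w))
    scores = wide.to_numpy() @ w
    groups = wide.index.get_level_values("group").to_numpy()
    out = pd.DataFrame({
        "subject": wide.index.get_level_values("subject"),
        "group": groups, "score": scores})
    labels = pd.unique(groups)
    n_g = np.array([(groups == g).sum() for g in labels])
    n = len(scores)
    gbar = np.array([scores[groups == g].mean() for g in labels])
    grand = scores.mean()
    ss_err = float(sum(((scores[groups == g] - gb) ** 2).sum()
                       for g, gb in zip(labels, gbar)))
    df_den = n - len(labels)
    mse = ss_err / df_den if df_den > 0 else math.nan
    F_gm = n * grand ** 2 / mse if mse > 0 else math.inf
    p_gm = float(sps.f.sf(F_gm, 1, df_den))
    if len(labels) > 1:
        ss_b = float(np.sum(n_g * (gbar - grand) ** 2))
        F_g = (ss_b / (len(labels) - 1)) / mse if mse > 0 else math.inf
        p_g = float(sps.f.sf(F_g, len(labels) - 1, df_den))
    else:
        F_g, p_g = math.nan, math.nan
    return TrendResult(scores=out, weights=w, levels=levels,
                       grand_mean_F=float(F_gm), grand_mean_p=p_gm,
                       group_F=float(F_g), group_p=p_g,
                       df_num=1, df_den=df_den)
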