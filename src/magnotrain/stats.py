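"""Mixed-design (split-plot) repeated-measures analysis.

One between-subjects factor (group) crossed with one within-subjects
factor (assessment session). The classical decomposition is

    SS_total            = SS_between_subjects + SS_within_subjects
    SS_between_subjects = SS_group + SS_subjects(group)
    SS_within_subjects  = SS_session + SS_group:session
                          + SS_session:subjects(group)

with F_group = MS_group / MS_subjects(group) and the two within effects
tested against MS_session:subjects(group). Partial eta squared for each
effect is SS_effect / (SS_effect + SS_its_error), which is recoverable
from the F statistic alone as F*df1 / (F*df1 + df2).

Sphericity of the within factor is assessed with Mauchly's W on the
pooled (within-group) covariance of orthonormal session contrasts, and
the Greenhouse-Geisser epsilon (Box's formula on the same contrast
covariance) multiplies the within degrees of freedom when sphericity is
rejected. Follow-up tests (paired t within groups across session pairs,
pooled-variance independent t and Mann-Whitney U between groups) match
the study's reporting style: the pooled-variance t gives df = nA+nB-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

__all__ = [
    "AnovaResult",
    "TestResult",
    "SphericityResult",
    "mixed_anova",
    "mauchly_test",
    "gg_epsilon",
    "pairwise_within",
    "independent_t",
    "mann_whitney_u",
    "partial_eta_sq_from_f",
    "to_wide",
    "format_effect",
]


def partial_eta_sq_from_f(f: float, df1: float, df2: float) -> float:
    """partial eta^2 = F*df1 / (F*df1 + df2)."""
    return f * df1 / (f * df1 + df2)


def to_wide(
    table: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: str = "session",
    between: str = "group",
) -> Tuple[pd.DataFrame, pd.Series]:
    """Pivot a long table to subjects x sessions for one measure.

    Session column order follows first appearance in the table. Returns
    (wide values, per-subject group labels). Raises on missing cells.
    """
    sub = table[table["measure"] == dv] if "measure" in table.columns else table
    value_col = "value" if "value" in sub.columns else dv
    sessions = list(dict.fromkeys(sub[within]))
    wide = sub.pivot_table(
        index=subject, columns=within, values=value_col, aggfunc="first"
    )[sessions]
    if wide.isna().any().any():
        raise ValueError(
            f"incomplete design for {dv!r}: missing cells are not supported"
        )
    groups = sub.groupby(subject)[between].first().reindex(wide.index)
    return wide, groups


class SphericityResult(NamedTuple):
    mauchly_w: float
    chi2: float
    df: int
    p: float
    gg_epsilon: float


def _contrast_covariance(
    wide: np.ndarray, groups: Optional[np.ndarray]
) -> Tuple[np.ndarray, int]:
    """Pooled covariance of orthonormal within-subject contrasts.

    Group means are removed before pooling (error df = N - g).
    """
    n, k = wide.shape
    if groups is None:
        groups = np.zeros(n, dtype=int)
    labels = np.unique(groups)
    g = len(labels)
    if n - g < k - 1:
        raise ValueError("need more subjects than within-levels minus one")
    c = linalg.helmert(k, full=False)  # (k-1, k), orthonormal rows
    z = wide @ c.T
    resid = np.empty_like(z)
    for lab in labels:
        mask = groups == lab
        resid[mask] = z[mask] - z[mask].mean(axis=0)
    s_c = resid.T @ resid / (n - g)
    return s_c, n - g


def mauchly_test(
    wide: pd.DataFrame | np.ndarray, groups: Optional[Sequence] = None
) -> SphericityResult:
    """Mauchly's sphericity test with the chi-square approximation.

    W = det(S_c) / (trace(S_c)/(k-1))**(k-1) on the orthonormal-contrast
    covariance; chi2 = -(N-g) * f * ln W with Mauchly's correction
    factor f. For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    x = np.asarray(wide, dtype=float)
    grp = None if groups is None else np.asarray(pd.factorize(pd.Series(groups))[0])
    k = x.shape[1]
    s_c, d = _contrast_covariance(x, grp)
    eps = gg_epsilon(wide, groups)
    if k == 2:
        return SphericityResult(1.0, 0.0, 0, 1.0, eps)
    det = linalg.det(s_c)
    tr = np.trace(s_c)
    if det <= 0 or tr <= 0:
        raise ValueError("degenerate contrast covariance (singular data)")
    w = det / (tr / (k - 1)) ** (k - 1)
    q = k - 1
    f = 1.0 - (2 * q * q + q + 2) / (6.0 * q * d)
    chi2 = -d * f * math.log(w)
    df = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return SphericityResult(float(w), float(chi2), int(df), p, eps)


def gg_epsilon(
    wide: pd.DataFrame | np.ndarray, groups: Optional[Sequence] = None
) -> float:
    """Greenhouse-Geisser epsilon via Box's formula.

    epsilon = trace(S_c)^2 / ((k-1) * trace(S_c @ S_c)); bounded by
    [1/(k-1), 1], reaching 1 exactly under sphericity.
    """
    x = np.asarray(wide, dtype=float)
    grp = None if groups is None else np.asarray(pd.factorize(pd.Series(groups))[0])
    s_c, _ = _contrast_covariance(x, grp)
    tr = np.trace(s_c)
    tr2 = np.trace(s_c @ s_c)
    if tr2 <= 0:
        raise ValueError("degenerate contrast covariance")
    k1 = s_c.shape[0]
    return float(tr * tr / (k1 * tr2))


@dataclass(frozen=True)
class AnovaResult:
    """Effect table plus the sphericity block for one measure."""

    table: pd.DataFrame
    sphericity: Optional[SphericityResult]
    dv: str

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: str = "session",
    between: str = "group",
    correction: str = "auto",
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """Split-plot ANOVA for a 2-groups x k-sessions complete design.

    ``correction``: "auto" applies Greenhouse-Geisser dfs to the within
    effects when Mauchly's test rejects at ``alpha_sphericity``;
    "always"/"never" force the choice. Both uncorrected and corrected
    p-values are always reported. Constant data yields zero SS and NaN
    F (reported as missing, not an error).
    """
    if correction not in ("auto", "always", "never"):
        raise ValueError(f"unknown correction policy {correction!r}")
    wide, groups = to_wide(data, dv, subject=subject, within=within, between=between)
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    glabels, gidx = np.unique(groups.to_numpy(), return_inverse=True)
    g = len(glabels)
    n_per_group = np.bincount(gidx)
    # g == 1 degenerates to a pure repeated-measures ANOVA (group rows
    # carry zero SS and df); used for the F = t^2 identity at k = 2.
    if g >= 2 and n_per_group.min() < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    sess_means = y.mean(axis=0)
    group_means = np.array([y[gidx == j].mean() for j in range(g)])
    cell_means = np.array(
        [[y[gidx == j, t].mean() for t in range(k)] for j in range(g)]
    )

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(k * (n_per_group * (group_means - grand) ** 2).sum())
    ss_subj = ss_between_subj - ss_group
    ss_session = float(n * ((sess_means - grand) ** 2).sum())
    ss_cells = float(
        (n_per_group[:, None] * (cell_means - grand) ** 2).sum()
    )
    ss_inter = ss_cells - ss_group - ss_session
    ss_within = ss_total - ss_between_subj
    ss_error = ss_within - ss_session - ss_inter

    df_group = g - 1
    df_subj = n - g
    df_session = k - 1
    df_inter = (g - 1) * (k - 1)
    df_error = (n - g) * (k - 1)

    sph: Optional[SphericityResult] = None
    eps = 1.0
    try:
        sph = mauchly_test(y, groups.to_numpy())
        eps = sph.gg_epsilon
    except ValueError:
        pass  # degenerate data: no sphericity block, no correction

    if correction == "always":
        apply_gg = True
    elif correction == "never" or sph is None:
        apply_gg = False
    else:
        apply_gg = sph.p < alpha_sphericity

    def _row(effect, ss, df, ss_err, df_err, within_effect):
        ms = ss / df if df > 0 else float("nan")
        ms_err = ss_err / df_err if df_err > 0 else float("nan")
        if ms_err > 0:
            f = ms / ms_err
            p_unc = float(sps.f.sf(f, df, df_err))
            etap = ss / (ss + ss_err)
        else:
            f, p_unc, etap = float("nan"), float("nan"), float("nan")
        df1c, df2c, p_gg = df, df_err, p_unc
        if within_effect and not math.isnan(f):
            df1c, df2c = df * eps, df_err * eps
            p_gg = float(sps.f.sf(f, df1c, df2c))
        return {
            "effect": effect,
            "SS": ss,
            "df": df,
            "MS": ms,
            "F": f,
            "p_unc": p_unc,
            "df_gg1": df1c if within_effect else float("nan"),
            "df_gg2": df2c if within_effect else float("nan"),
            "p_gg": p_gg if within_effect else float("nan"),
            "p": p_gg if (within_effect and apply_gg) else p_unc,
            "partial_eta_sq": etap,
            "sphericity_corrected": bool(within_effect and apply_gg),
        }

    rows = [
        _row(between, ss_group, df_group, ss_subj, df_subj, False),
        _row(within, ss_session, df_session, ss_error, df_error, True),
        _row(f"{between}:{within}", ss_inter, df_inter, ss_error, df_error, True),
        {
            "effect": f"subjects({between})",
            "SS": ss_subj,
            "df": df_subj,
            "MS": ss_subj / df_subj,
            "F": float("nan"),
            "p_unc": float("nan"),
            "df_gg1": float("nan"),
            "df_gg2": float("nan"),
            "p_gg": float("nan"),
            "p": float("nan"),
            "partial_eta_sq": float("nan"),
            "sphericity_corrected": False,
        },
        {
            "effect": f"{within}:subjects({between})",
            "SS": ss_error,
            "df": df_error,
            "MS": ss_error / df_error if df_error else float("nan"),
            "F": float("nan"),
            "p_unc": float("nan"),
            "df_gg1": float("nan"),
            "df_gg2": float("nan"),
            "p_gg": float("nan"),
            "p": float("nan"),
            "partial_eta_sq": float("nan"),
            "sphericity_corrected": False,
        },
    ]
    table = pd.DataFrame(rows)
    table.attrs["ss_total"] = ss_total
    return AnovaResult(table=table, sphericity=sph, dv=dv)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: Optional[float]
    p: float
    estimate: Optional[float]
    method: str
    label: str = ""
    p_bonferroni: Optional[float] = None


def pairwise_within(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: str = "session",
    between: str = "group",
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> List[TestResult]:
    """Paired t-tests across session pairs within each group.

    The estimate is the signed mean difference ``mean(a) - mean(b)`` for
    pair (a, b). Reports unadjusted p plus a Bonferroni-adjusted p over
    the family of comparisons.
    """
    wide, groups = to_wide(data, dv, subject=subject, within=within, between=between)
    sessions = list(wide.columns)
    if pairs is None:
        pairs = [(sessions[0], s) for s in sessions[1:]]
    results = []
    for glabel in dict.fromkeys(groups):
        sub = wide[groups == glabel]
        if len(sub) < 2:
            raise ValueError(f"group {glabel!r} has fewer than 2 paired observations")
        for a, b in pairs:
            d = sub[a].to_numpy() - sub[b].to_numpy()
            n = len(d)
            if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
                stat = 0.0 if np.isclose(d.mean(), 0.0) else math.inf
                p = 1.0 if stat == 0.0 else 0.0
            else:
                stat, p = sps.ttest_rel(sub[a], sub[b])
            results.append(
                TestResult(
                    statistic=float(stat),
                    df=float(n - 1),
                    p=float(p),
                    estimate=float(np.mean(d)),
                    method="paired_t",
                    label=f"{glabel}: {a} vs {b}",
                )
            )
    m = len(results)
    return [
        TestResult(
            statistic=r.statistic,
            df=r.df,
            p=r.p,
            estimate=r.estimate,
            method=r.method,
            label=r.label,
            p_bonferroni=min(1.0, r.p * m),
        )
        for r in results
    ]


def independent_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t (df = nA + nB - 2), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(a) + len(b) - 2
    diff = float(a.mean() - b.mean())
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        # zero pooled variance: identical constants give t = 0 / p = 1,
        # separated constants are reported as an explicit p = 0 edge
        stat = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(stat),
        df=float(df),
        p=float(p),
        estimate=diff,
        method="independent_t",
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution for small samples (nA*nB <= 400, no ties),
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(u),
        df=None,
        p=float(p),
        estimate=float(np.median(a) - np.median(b)),
        method="mann_whitney_u",
    )


def format_effect(result: AnovaResult, effect: str) -> str:
    """Results-style line: ``F[df1, df2] = x.xx, p = ..., eta2p = ...``."""
    row = result.effect(effect)
    if math.isnan(row["F"]):
        return f"{effect}: F undefined (degenerate data)"
    is_within = not math.isnan(row["df_gg1"])
    if row["sphericity_corrected"]:
        df1, df2 = row["df_gg1"], row["df_gg2"]
    else:
        df1 = row["df"]
        error_term = (
            result.table[result.table["effect"].str.contains("subjects", regex=False)]
        )
        df2 = error_term.iloc[1 if is_within else 0]["df"]
    return (
        f"{effect}: F[{df1:.2f}, {df2:.2f}] = {row['F']:.2f}, "
        f"p = {row['p']:.4g}, eta2p = {row['partial_eta_sq']:.2f}"
    )
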