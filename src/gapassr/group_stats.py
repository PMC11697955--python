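"""Group-level statistics on per-animal measures.

* ERP peak amplitudes: Mann-Whitney U tests with Holm-Sidak step-down
  adjustment over the family of comparisons.
* Gap-ASSR mean 40 Hz ITPC: mixed ("split-plot") repeated-measures ANOVA
  with gap width as the within-subject factor and genotype/treatment (or
  sex) between subjects, Greenhouse-Geisser sphericity correction, and
  Sidak-adjusted post hoc contrasts.

Cortical regions (AC, FC) and ages are analyzed separately, never as
factors: callers filter the cohort table before testing.

The ANOVA is computed in two strata.  Between-subject effects come from a
factorial ANOVA (Type III, sum-to-zero coding) of the per-subject means,
whose residual is the subject-within-groups error.  Within-subject effects
come from the per-subject-centered data: Type III sums of squares for
every term involving the within factor, tested against the subject-by-
condition residual with df (N_subjects - cells) * (K - 1).  For balanced
designs this reproduces the textbook mixed-ANOVA partition exactly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney",
    "holm_sidak_adjust",
    "sidak_adjust",
    "rm_anova",
    "gg_epsilon",
    "sidak_posthoc",
]


def mann_whitney(u, v, alternative: str = "two-sided") -> dict:
    """Two-sample Mann-Whitney U test.

    Uses exact enumeration for combined n <= 12 without ties and the
    tie-corrected normal approximation otherwise.  Returns
    ``{"U", "p", "method"}`` with U the statistic of the first sample.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.size == 0 or v.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([u, v])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (u.size + v.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(u, v, alternative=alternative, method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def holm_sidak_adjust(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order.

    Sorted ascending, the i-th smallest p (0-based) is adjusted to
    ``1 - (1 - p)^(m - i)``; running maxima enforce monotonicity and
    values are capped at 1.
    """
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Single-step Sidak adjustment ``1 - (1 - p)^m``."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return float(1.0 - (1.0 - p) ** m)


def gg_epsilon(profiles: np.ndarray, cell_labels) -> float:
    """Greenhouse-Geisser epsilon from subject-by-condition ``profiles``.

    The covariance of the K within-subject conditions is pooled across
    between-subject cells (each subject's profile has its cell-mean
    profile removed), then
    ``eps = tr(M)^2 / ((K - 1) tr(M^2))`` with ``M = C S C`` and C the
    K-dimensional centering matrix.  Bounded to [1/(K-1), 1]; exactly 1
    for K = 2.
    """
    X = np.asarray(profiles, float)
    n, K = X.shape
    cells = pd.Series([tuple(np.atleast_1d(c)) for c in cell_labels])
    Xc = X.copy()
    for cell in cells.unique():
        sel = (cells == cell).to_numpy()
        Xc[sel] -= X[sel].mean(axis=0, keepdims=True)
    dof = n - cells.nunique()
    if dof < 1:
        raise ValueError("not enough subjects to estimate the within covariance")
    S = Xc.T @ Xc / dof
    C = np.eye(K) - np.ones((K, K)) / K
    M = C @ S @ C
    denom = (K - 1) * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    eps = np.trace(M) ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / (K - 1))))


def _sum_coded(name: str) -> str:
    return f"C({name}, Sum)"


def _f_ratio(ss: float, d1: float, ss_err: float, d2: float) -> tuple[float, float]:
    """F and p with the degenerate zero-variance case mapped to F = 0, p = 1."""
    ms_err = ss_err / d2
    if ms_err <= 0 or ss <= 0:
        if ss <= max(ms_err, 0) * 1e-12 or ss <= 1e-24:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss / d1) / ms_err
    return float(F), float(stats.f.sf(F, d1, d2))


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "animal_id",
    within: str = "gap_width_ms",
    between: tuple[str, ...] = ("genotype", "treatment"),
    gg_threshold: float = 0.75,
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA (between factors x one within factor).

    Requires one observation per subject x within level; subjects with
    incomplete within-factor data are excluded with a log message, and an
    empty or single-subject between-cell is a design error.

    Returns one row per effect with columns ``effect, SS, df1, df2, F, p,
    gg_epsilon, p_gg, p_corrected`` — ``p_gg`` uses Greenhouse-Geisser
    shrunk dfs and ``p_corrected`` selects it when epsilon < ``gg_threshold``
    (between-subject effects carry their uncorrected p).
    """
    between = tuple(between)
    if not 1 <= len(between) <= 2:
        raise ValueError("between must name one or two factors")
    cols = [subject, within, dv, *between]
    df = table[cols].copy()

    wide = df.pivot_table(index=subject, columns=within, values=dv)
    n_levels = df[within].nunique()
    complete = wide.dropna(axis=0)
    excluded = set(wide.index) - set(complete.index)
    if excluded:
        logger.info("excluding %d subjects with incomplete within-factor data", len(excluded))
    if complete.shape[1] != n_levels:
        raise ValueError("no subject covers every within-factor level")
    subj_between = (
        df.drop_duplicates(subject).set_index(subject)[list(between)].loc[complete.index]
    )
    if (df.groupby(subject)[list(between)].nunique() > 1).any().any():
        raise ValueError("between-factor labels must be constant within subject")

    cell_counts = subj_between.groupby(list(between)).size()
    n_cells_full = int(np.prod([subj_between[b].nunique() for b in between]))
    if len(cell_counts) < n_cells_full or (cell_counts < 2).any():
        raise ValueError("every between-subject cell needs at least two subjects")
    n_subj = complete.shape[0]
    n_cells = len(cell_counts)
    K = complete.shape[1]

    # --- between-subject stratum: factorial ANOVA of subject means
    bdat = subj_between.copy()
    bdat["_m"] = complete.mean(axis=1).to_numpy()
    bdat = bdat.rename(columns={b: f"_b{i}" for i, b in enumerate(between)})
    bterms = [_sum_coded(f"_b{i}") for i in range(len(between))]
    bfit = smf.ols(f"_m ~ {'*'.join(bterms)}", data=bdat).fit()
    btab = sm.stats.anova_lm(bfit, typ=3)

    def _pretty(term: str) -> str:
        for i, b in enumerate(between):
            term = term.replace(_sum_coded(f"_b{i}"), b)
        return term.replace(_sum_coded("_w"), within)

    rows = []
    ss_res_b = float(btab.loc["Residual", "sum_sq"])
    df_res_b = float(btab.loc["Residual", "df"])
    for term in btab.index:
        if term in ("Intercept", "Residual"):
            continue
        ss_b = float(btab.loc[term, "sum_sq"])
        F, p = _f_ratio(ss_b, float(btab.loc[term, "df"]), ss_res_b, df_res_b)
        rows.append(
            {
                "effect": _pretty(term),
                "SS": ss_b * K,
                "df1": float(btab.loc[term, "df"]),
                "df2": df_res_b,
                "F": F,
                "p": p,
                "gg_epsilon": np.nan,
                "p_gg": np.nan,
            }
        )

    # --- within-subject stratum: per-subject-centered data
    centered = complete.sub(complete.mean(axis=1), axis=0)
    long = centered.stack().rename("_y").reset_index()
    long.columns = [subject, "_w", "_y"]
    long = long.merge(subj_between.reset_index(), on=subject)
    long = long.rename(columns={b: f"_b{i}" for i, b in enumerate(between)})
    wterms = "*".join([_sum_coded("_w"), *bterms])
    wfit = smf.ols(f"_y ~ {wterms}", data=long).fit()
    wtab = sm.stats.anova_lm(wfit, typ=3)
    ss_err = float(wfit.ssr)
    df_err = (n_subj - n_cells) * (K - 1)
    if df_err < 1:
        raise ValueError("no residual degrees of freedom for the within stratum")
    eps = gg_epsilon(complete.to_numpy(), [tuple(r) for r in subj_between.to_numpy()])
    for term in wtab.index:
        if term in ("Intercept", "Residual") or "_w" not in term:
            continue
        ss = float(wtab.loc[term, "sum_sq"])
        d1 = float(wtab.loc[term, "df"])
        F, p = _f_ratio(ss, d1, ss_err, df_err)
        rows.append(
            {
                "effect": _pretty(term),
                "SS": ss,
                "df1": d1,
                "df2": float(df_err),
                "F": F,
                "p": p,
                "gg_epsilon": eps,
                "p_gg": float(stats.f.sf(F, d1 * eps, df_err * eps))
                if np.isfinite(F) and F > 0 else p,
            }
        )

    out = pd.DataFrame(rows)
    # numerically-zero effects (constant data) report F = 0, p = 1
    y = df[dv].to_numpy(float)
    tol = 1e-12 * float(((y - y.mean()) ** 2).sum()) + 1e-24
    degenerate = ~np.isfinite(out["SS"]) | (out["SS"] < tol)
    out.loc[degenerate, ["SS", "F"]] = 0.0
    out.loc[degenerate, "p"] = 1.0
    out.loc[degenerate & out["p_gg"].notna(), "p_gg"] = 1.0
    out["p_corrected"] = np.where(
        out["gg_epsilon"].notna() & (out["gg_epsilon"] < gg_threshold),
        out["p_gg"],
        out["p"],
    )
    return out


def sidak_posthoc(
    table: pd.DataFrame,
    dv: str = "value",
    factors: tuple[str, ...] = ("genotype", "treatment"),
    contrasts: list[tuple] | None = None,
    subject: str = "animal_id",
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Pairwise cell contrasts with single-step Sidak adjustment.

    Cells are the levels of ``factors`` (subject means over any repeated
    rows are compared).  ``contrasts`` is a list of (cellA, cellB) level
    tuples; all pairwise by default.  ``test`` is ``"mannwhitney"`` or
    ``"ttest"`` (Welch).  Adjusted p is ``1 - (1 - p)^m`` with m the
    number of contrasts.
    """
    factors = tuple(factors)
    means = table.groupby([subject, *factors], observed=True)[dv].mean().reset_index()
    cells = {
        tuple(k) if len(factors) > 1 else (k,): g[dv].to_numpy()
        for k, g in means.groupby(list(factors), observed=True)
    }
    if contrasts is None:
        contrasts = list(itertools.combinations(sorted(cells), 2))
    else:
        contrasts = [
            (tuple(np.atleast_1d(a)), tuple(np.atleast_1d(b))) for a, b in contrasts
        ]
    m = len(contrasts)
    rows = []
    for a, b in contrasts:
        if a not in cells or b not in cells:
            raise ValueError(f"unknown contrast {a} vs {b}")
        if test == "mannwhitney":
            res = mann_whitney(cells[a], cells[b])
            stat, p = res["U"], res["p"]
        elif test == "ttest":
            r = stats.ttest_ind(cells[a], cells[b], equal_var=False)
            stat, p = float(r.statistic), float(r.pvalue)
        else:
            raise ValueError("test must be 'mannwhitney' or 'ttest'")
        rows.append(
            {
                "contrast": f"{'/'.join(map(str, a))} vs {'/'.join(map(str, b))}",
                "statistic": stat,
                "p_raw": p,
                "p_sidak": sidak_adjust(p, m),
            }
        )
    return pd.DataFrame(rows)
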