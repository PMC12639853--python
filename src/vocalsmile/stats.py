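"""Inferential layer: mixed repeated-measures ANOVA, t-tests, Bonferroni
correction, and the default JZS Bayes factor for t-tests.

The ANOVA is the classical univariate mixed-design decomposition. Data are
first aggregated to one mean per subject x within-cell. Each within-subject
stratum is reduced to per-subject scores by projecting the cell means onto
orthonormal (Helmert) contrasts, scaled so the resulting sums of squares
equal the textbook sums of squares exactly:

* between stratum: subject means (scaled by sqrt(#cells)) -> Group effect,
  with subjects-within-groups as the error term;
* each within stratum (a factor or an interaction of within factors):
  contrast scores -> the within effect, its interaction with Group, and the
  contrast x subjects-within-groups error term.

All within factors may have any number of levels (multi-df strata pool
their contrasts, i.e. the sphericity-assuming univariate solution); group
sizes may be unequal (weighted-means solution). Effect sizes are partial
eta squared, SS_effect / (SS_effect + SS_error-of-its-stratum).

The Bayes factor is the default two-sided JZS test: a Cauchy(0, r) prior
(r = 0.707 by default) on the standardized effect, with BF10 computed by
adaptive quadrature of the noncentral-t likelihood over the prior.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "AnovaTable",
    "TTestResult",
    "BayesFactorResult",
    "PearsonResult",
    "rm_anova",
    "mixed_anova_arrays",
    "bonferroni",
    "jzs_bf_ttest",
    "two_sample_t",
    "one_sample_t",
    "paired_t",
    "pearson",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class AnovaTable:
    """Ordered mapping effect name -> AnovaResult."""

    effects: dict[str, AnovaResult]

    def __getitem__(self, name: str) -> AnovaResult:
        return self.effects[name]

    def __iter__(self):
        return iter(self.effects.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": r.effect,
                    "F": r.F,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p": r.p,
                    "partial_eta_sq": r.partial_eta_sq,
                }
                for r in self
            ]
        )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    kind: str
    corrected_p: float | None = None


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    prior_scale: float
    integration_error: float


@dataclass(frozen=True)
class PearsonResult:
    r: float
    df: int
    t: float
    p: float


def _helmert_orthonormal(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, shape (k, k-1), columns orthogonal to 1."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def mixed_anova_arrays(Y: np.ndarray, group_idx: np.ndarray | None,
                       within_names: tuple[str, ...],
                       between_name: str = "Group") -> AnovaTable:
    """Mixed ANOVA on a dense cell-mean array.

    Y has shape (n_subjects, k1[, k2]) with one within axis per factor;
    group_idx assigns each subject an integer group (or None for a fully
    within design).
    """
    Y = np.asarray(Y, dtype=float)
    n_sub = Y.shape[0]
    if not within_names:
        Y = Y.reshape(n_sub, 1)  # between-only: one cell per subject
        k_levels: tuple[int, ...] = ()
    else:
        k_levels = Y.shape[1:]
        if len(k_levels) != len(within_names):
            raise ValueError("one within name per within axis required")
    if group_idx is not None:
        group_idx = np.asarray(group_idx)
        groups = np.unique(group_idx)
        if groups.size < 2:
            raise ValueError("between factor needs >= 2 groups")
    else:
        groups = None

    n_factors = len(k_levels)
    contrasts = [_helmert_orthonormal(k) for k in k_levels]
    means = [np.ones(k) / np.sqrt(k) for k in k_levels]  # scaled mean vectors

    def project(which: tuple[bool, ...]) -> np.ndarray:
        """Scores (n_sub, m): project each subject's cell array onto the
        outer products of contrast columns (where which[f]) and the
        normalized mean vector elsewhere."""
        Z = Y.reshape(n_sub, -1)
        if n_factors == 0:
            return Z
        mats = [contrasts[f] if which[f] else means[f][:, None]
                for f in range(n_factors)]
        basis = mats[0]
        for m in mats[1:]:
            basis = np.einsum("ij,kl->ikjl", basis, m).reshape(
                basis.shape[0] * m.shape[0], basis.shape[1] * m.shape[1]
            )
        return Z @ basis  # scaling: sqrt(k) absorbed in mean vectors

    results: dict[str, AnovaResult] = {}

    # sums of squares below ~machine precision of the data are rounding
    # residue of a constant response, not variance
    tiny = 1e-18 * max(1.0, float(np.mean(Y**2))) * Y.size

    def add(effect, ss_eff, df_eff, ss_err, df_err):
        if df_err <= 0:
            raise ValueError(f"no error degrees of freedom for {effect}")
        if ss_eff < tiny:
            ss_eff = 0.0
        if ss_err < tiny:
            ss_err = 0.0
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        results[effect] = AnovaResult(effect, float(F), df_eff, df_err,
                                      p, float(pes), float(ss_eff), float(ss_err))

    # between stratum
    if groups is not None:
        u = project((False,) * n_factors)[:, 0]
        grand = u.mean()
        g_means = np.array([u[group_idx == g].mean() for g in groups])
        g_ns = np.array([(group_idx == g).sum() for g in groups])
        ss_g = float(np.sum(g_ns * (g_means - grand) ** 2))
        resid = u - g_means[np.searchsorted(groups, group_idx)]
        ss_sg = float(np.sum(resid**2))
        add(between_name, ss_g, groups.size - 1, ss_sg, n_sub - groups.size)

    # within strata
    for subset in itertools.product([False, True], repeat=n_factors):
        if not any(subset):
            continue
        Z = project(subset)
        m = Z.shape[1]
        zbar = Z.mean(axis=0)
        ss_eff = float(n_sub * np.sum(zbar**2))
        name = " * ".join(n for n, s in zip(within_names, subset) if s)
        if groups is not None:
            gm = np.vstack([Z[group_idx == g].mean(axis=0) for g in groups])
            g_ns = np.array([(group_idx == g).sum() for g in groups])
            ss_int = float(np.sum(g_ns[:, None] * (gm - zbar) ** 2))
            resid = Z - gm[np.searchsorted(groups, group_idx)]
            ss_err = float(np.sum(resid**2))
            df_err = m * (n_sub - groups.size)
            add(name, ss_eff, m, ss_err, df_err)
            add(f"{name} * {between_name}", ss_int, m * (groups.size - 1),
                ss_err, df_err)
        else:
            resid = Z - zbar
            ss_err = float(np.sum(resid**2))
            add(name, ss_eff, m, ss_err, m * (n_sub - 1))

    return AnovaTable(results)


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: tuple[str, ...] | list[str] = (),
             between: str | None = None) -> AnovaTable:
    """Mixed repeated-measures ANOVA on a long-format trial table.

    Trials are aggregated to one mean per subject and within-factor cell;
    subjects missing any cell (or, with `between`, an unambiguous group
    label) are dropped with a warning.
    """
    within = tuple(within)
    if not within and between is None:
        raise ValueError("need at least one factor")
    cols = [subject, *within] + ([between] if between else [])
    agg = data.groupby(cols, observed=True)[dv].mean().reset_index()

    levels = [np.unique(agg[w]) for w in within]
    n_cells = int(np.prod([lv.size for lv in levels])) if within else 1

    if between is not None:
        gmap = agg.groupby(subject, observed=True)[between].nunique()
        bad = gmap[gmap > 1].index
        if len(bad):
            raise ValueError(f"subjects with multiple group labels: {list(bad)}")

    if within:
        wide = agg.pivot_table(index=subject, columns=list(within), values=dv)
        full = wide.dropna()
        dropped = set(wide.index) - set(full.index)
        if dropped:
            warnings.warn(f"dropping subjects with missing cells: {sorted(dropped)}")
        if full.shape[1] != n_cells:
            raise ValueError("within-factor cells missing from the design")
        subjects = full.index.to_numpy()
        Y = full.to_numpy().reshape(len(full), *[lv.size for lv in levels])
    else:
        ser = agg.set_index(subject)[dv]
        subjects = ser.index.to_numpy()
        Y = ser.to_numpy()[:, None]

    if between is not None:
        glab = agg.drop_duplicates(subject).set_index(subject)[between]
        glab = glab.loc[subjects]
        cats = np.unique(glab)
        group_idx = np.searchsorted(cats, glab.to_numpy())
        if cats.size < 2:
            raise ValueError("between factor needs >= 2 groups")
    else:
        group_idx = None

    if not within:
        # between-only: treat the single column as a 1-level within axis
        table = mixed_anova_arrays(Y, group_idx, (), between_name=between or "Group")
        return table
    return mixed_anova_arrays(Y, group_idx, within,
                              between_name=between or "Group")


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-corrected p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def one_sample_t(x, popmean: float = 0.0) -> TTestResult:
    """Student one-sample t-test, two-tailed.

    Degenerate zero-variance input at the null mean returns t = 0 with a
    RuntimeWarning (the statistic is formally undefined there).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == popmean:
            warnings.warn("zero variance at the null mean: t set to 0",
                          RuntimeWarning)
            return TTestResult(0.0, n - 1, 1.0, "one-sample")
        raise ValueError("zero variance with mean != popmean: t undefined")
    t = (x.mean() - popmean) / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), "one-sample")


def two_sample_t(a, b) -> TTestResult:
    """Pooled-variance (Student) independent-samples t, df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, "independent")
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), "independent")


def paired_t(a, b) -> TTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(a - b, 0.0)
    return TTestResult(res.t, res.df, res.p, "paired")


def jzs_bf_ttest(t: float, n1: int, n2: int | None = None,
                 prior_scale: float = 0.707) -> BayesFactorResult:
    """Default JZS Bayes factor BF10 for a t statistic.

    Two-sided Cauchy(0, prior_scale) prior on the standardized effect
    size; one-sample/paired when n2 is None, independent-samples
    otherwise. Computed by adaptive quadrature of the noncentral-t
    likelihood over the prior; `integration_error` is the quadrature
    error relative to the marginal likelihood.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("group sizes must be >= 2")
    if n2 is None:
        df, n_eff = n1 - 1, float(n1)
    else:
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    root_n = np.sqrt(n_eff)

    def integrand(delta):
        return sps.nct.pdf(t, df, delta * root_n) * sps.cauchy.pdf(delta, 0.0, prior_scale)

    marginal, abserr = integrate.quad(integrand, -np.inf, np.inf,
                                      epsabs=1e-12, epsrel=1e-10, limit=200)
    null_like = sps.t.pdf(t, df)
    return BayesFactorResult(float(marginal / null_like), prior_scale,
                             float(abserr / marginal))


def pearson(x, y) -> PearsonResult:
    """Pearson correlation with its t statistic: t = r*sqrt(df/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    df = x.size - 2
    denom = max(1.0 - r**2, 1e-300)
    t = r * np.sqrt(df / denom)
    return PearsonResult(float(r), df, float(t), float(p))
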