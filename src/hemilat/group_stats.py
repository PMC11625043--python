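"""Inferential battery for group comparisons and brain-behavior correlations.

Implements the tests a lateralization study leans on: one-sample and
two-sample t, classic and Welch one-way ANOVA (from raw data or from printed
group summaries), Levene's variance-heterogeneity gate, Games-Howell and
BH-FDR post hocs, the Jonckheere-Terpstra ordered-trend test, Pearson
chi-square on contingency tables, and partial correlation via covariate
residualization.

Conventions:

* ANOVA in ``auto`` mode runs mean-centered Levene at alpha = 0.05; when
  variances are heterogeneous it reports Welch's F with Welch-Satterthwaite
  df2 and pairs it with Games-Howell post hocs, otherwise the classic F with
  pooled pairwise t + BH-FDR.
* Partial eta squared is SSB/(SSB+SSW) computed from classic sums of squares
  on the same data, also when the omnibus statistic is Welch's F.
* All p-values are two-sided except Jonckheere-Terpstra, which is one-sided
  and directional by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, DegenerateSignalError, UndefinedStatisticError

HETEROGENEITY_ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """One inferential result: statistic, degrees of freedom, p, effect size."""

    method: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect: float | None = None
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "effect": self.effect,
            "n": list(self.n),
            **({"extra": self.extra} if self.extra else {}),
        }


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and n for one group (SD is the n-1 sample SD)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def of(cls, values: np.ndarray) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=len(v))


def _as_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
    return out


# ---------------------------------------------------------------------------
# t tests


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> StatResult:
    """Two-sided one-sample t against mu0, with Cohen's d = (mean-mu0)/sd."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("one-sample t needs n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateSignalError("one-sample t undefined for zero variance")
    res = stats.ttest_1samp(v, popmean=mu0)
    d = float((v.mean() - mu0) / sd)
    return StatResult("t1", float(res.statistic), (float(len(v) - 1),), float(res.pvalue), effect=d, n=(len(v),))


def t_from_summary(a: GroupSummary, b: GroupSummary, kind: str = "pooled") -> StatResult:
    """Independent two-sample t (pooled or Welch) from group summaries."""
    if a.sd == 0 and b.sd == 0:
        raise DegenerateSignalError("two-sample t undefined when both SDs are 0")
    equal_var = {"pooled": True, "welch": False}[kind]
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var)
    if equal_var:
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        sp2 = (a.sd**2 + b.sd**2) / 2
    d = float((a.mean - b.mean) / math.sqrt(sp2))
    return StatResult("t2", float(t), (df,), float(p), effect=d, n=(a.n, b.n))


def two_sample_t(a: np.ndarray, b: np.ndarray, kind: str = "pooled") -> StatResult:
    return t_from_summary(GroupSummary.of(a), GroupSummary.of(b), kind)


# ---------------------------------------------------------------------------
# ANOVA


def levene(groups: list[np.ndarray]) -> StatResult:
    """Mean-centered Levene test for variance heterogeneity."""
    gs = _as_groups(groups)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        raise DegenerateSignalError("Levene undefined when all values are identical")
    w, p = stats.levene(*gs, center="mean")
    k, n = len(gs), len(pooled)
    return StatResult("levene", float(w), (float(k - 1), float(n - k)), float(p), n=tuple(len(g) for g in gs))


def _classic_ss(summ: list[GroupSummary]) -> tuple[float, float]:
    n_tot = sum(s.n for s in summ)
    grand = sum(s.n * s.mean for s in summ) / n_tot
    ssb = sum(s.n * (s.mean - grand) ** 2 for s in summ)
    ssw = sum((s.n - 1) * s.sd**2 for s in summ)
    return ssb, ssw


def anova_from_summary(summ: list[GroupSummary], kind: str = "classic") -> StatResult:
    """One-way ANOVA (classic or Welch F) reconstructed from group summaries.

    The classic F uses between/within sums of squares; Welch's F weights
    groups by n_i/sd_i^2 and uses the Welch-Satterthwaite df2. Partial eta
    squared is always SSB/(SSB+SSW) from the classic decomposition.
    """
    if len(summ) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    k = len(summ)
    ssb, ssw = _classic_ss(summ)
    if ssb + ssw == 0:
        raise DegenerateSignalError("ANOVA undefined for all-constant data")
    eta_p2 = ssb / (ssb + ssw)
    ns = tuple(s.n for s in summ)
    if kind == "classic":
        df1, df2 = float(k - 1), float(sum(ns) - k)
        if ssw == 0:
            raise DegenerateSignalError("classic F undefined with zero within-group variance")
        f = (ssb / df1) / (ssw / df2)
        method = "classic_f"
    elif kind == "welch":
        if any(s.sd == 0 for s in summ):
            raise DegenerateSignalError("Welch F undefined with a zero-SD group")
        w = np.array([s.n / s.sd**2 for s in summ])
        m = np.array([s.mean for s in summ])
        W = w.sum()
        mbar = float((w * m).sum() / W)
        a = float((w * (m - mbar) ** 2).sum() / (k - 1))
        lam = float((((1 - w / W) ** 2) / np.array([s.n - 1 for s in summ])).sum())
        b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
        f = a / b
        df1 = float(k - 1)
        df2 = (k**2 - 1) / (3.0 * lam)
        method = "welch_f"
    else:
        raise ValueError(f"unknown ANOVA kind {kind!r}")
    p = float(stats.f.sf(f, df1, df2))
    return StatResult(method, float(f), (df1, df2), p, effect=float(eta_p2), n=ns)


def oneway_anova(groups: list[np.ndarray], force: str = "auto") -> StatResult:
    """One-way ANOVA on raw groups; ``auto`` gates Welch vs classic on Levene."""
    gs = _as_groups(groups)
    summ = [GroupSummary.of(g) for g in gs]
    if force == "auto":
        lev = levene(gs)
        kind = "welch" if lev.p < HETEROGENEITY_ALPHA else "classic"
        res = anova_from_summary(summ, kind)
        res.extra["levene_p"] = lev.p
        return res
    if force in ("classic", "welch"):
        return anova_from_summary(summ, force)
    raise ValueError(f"unknown force mode {force!r}")


# ---------------------------------------------------------------------------
# post hocs


def games_howell(groups: list[np.ndarray], labels: list[str] | None = None) -> list[StatResult]:
    """Games-Howell pairwise comparisons (Welch t against the studentized range).

    For each pair: Welch's t with Welch-Satterthwaite df; the p-value comes
    from the studentized-range distribution with q = |t| * sqrt(2) and k =
    total number of groups.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    out = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = gs[i], gs[j]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        if va + vb == 0:
            raise DegenerateSignalError(f"Games-Howell undefined for constant pair ({labels[i]}, {labels[j]})")
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        d = float((a.mean() - b.mean()) / math.sqrt(sp2)) if sp2 > 0 else None
        out.append(
            StatResult(
                "gh", float(t), (df,), min(1.0, p), effect=d, n=(len(a), len(b)),
                extra={"pair": (labels[i], labels[j])},
            )
        )
    return out


def pairwise_t_fdr(groups: list[np.ndarray], labels: list[str] | None = None, kind: str = "pooled") -> list[StatResult]:
    """Pairwise two-sample t tests with BH-FDR adjusted p in ``extra['p_fdr']``."""
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(gs))]
    results = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        r = two_sample_t(gs[i], gs[j], kind)
        r.extra["pair"] = (labels[i], labels[j])
        results.append(r)
    adj = fdr_bh(np.array([r.p for r in results]))
    for r, pa in zip(results, adj):
        r.extra["p_fdr"] = float(pa)
    return results


# ---------------------------------------------------------------------------
# trend test


def jonckheere_terpstra(groups: list[np.ndarray], alternative: str = "increasing") -> StatResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    J sums, over ordered group pairs (i < j), the Mann-Whitney count of
    observations in group j exceeding observations in group i (ties count
    one half). The normal approximation uses the tie-corrected variance; the
    standardized z keeps its natural sign (positive for an increasing trend),
    and the one-sided p follows ``alternative``.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 3:
        raise ValueError("Jonckheere-Terpstra needs at least 3 ordered groups")
    for g in gs:
        if len(g) == 0:
            raise ValueError("Jonckheere-Terpstra: empty group")
    j_stat = 0.0
    for a, b in itertools.combinations(gs, 2):
        # count pairs (x in earlier group, y in later group) with x < y; ties add 1/2
        j_stat += float((b[None, :] > a[:, None]).sum()) + 0.5 * float((b[None, :] == a[:, None]).sum())
    ns = np.array([len(g) for g in gs], dtype=float)
    n = ns.sum()
    mu = (n**2 - (ns**2).sum()) / 4.0
    pooled = np.concatenate(gs)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = (n * (n - 1) * (2 * n + 5) - (ns * (ns - 1) * (2 * ns + 5)).sum() - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
    term2 = ((ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()) / (36.0 * n * (n - 1) * (n - 2))
    term3 = ((ns * (ns - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
    var = term1 + term2 + term3
    if var <= 0:
        z = 0.0  # fully tied data carries no trend information
    else:
        z = (j_stat - mu) / math.sqrt(var)
    p = float(stats.norm.sf(z)) if alternative == "increasing" else float(stats.norm.cdf(z))
    return StatResult(
        "jt", float(z), (math.nan,), p, n=tuple(int(v) for v in ns),
        extra={"J": j_stat, "mu": mu, "var": var, "alternative": alternative},
    )


# ---------------------------------------------------------------------------
# chi-square, partial correlation, FDR


def chi_square_independence(table: np.ndarray) -> StatResult:
    """Pearson chi-square of independence, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(tab, correction=False)
    return StatResult(
        "chi2", float(res.statistic), (float(res.dof),), float(res.pvalue), n=(int(tab.sum()),)
    )


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise CollinearityError("covariate design matrix is rank deficient")
    return y - design @ beta


def partial_correlation(x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None) -> StatResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    With k covariates the t statistic is r * sqrt((n-k-2)/(1-r^2)) with
    df = n - k - 2. With no covariates this reduces exactly to plain Pearson.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match n")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DegenerateSignalError("partial correlation undefined: residual variance is zero")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        t, p = math.inf * math.copysign(1, r), 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    method = "partial_r" if k else "pearson_r"
    return StatResult(method, r, (float(df),), p, effect=r, n=(n,), extra={"t": t, "k": k})


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj
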