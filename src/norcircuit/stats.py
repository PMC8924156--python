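"""The statistical layer: normality screening, group contrasts,
one-sample tests against constants, and brain-behavior correlations
with a one-pass outlier policy.

Normality is screened with the Lilliefors-corrected Kolmogorov-Smirnov
test (mean and SD estimated from the sample); group contrasts use the
two-sided unpaired Student's t-test (equal variances by default, Welch
behind a flag); directional lead-lag means are tested against the
constant 0 (or percentages against 100) with one-sample t-tests.
Pearson brain-behavior correlations are screened for a single gross
outlier with a Grubbs test on the externally studentized residuals of
the y-on-x regression; at most one point is removed and both the pre-
and post-removal fits are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors

ALPHA = 0.05


@dataclass
class StatResult:
    test: str
    variables: tuple
    statistic: float
    p_value: float
    n: tuple
    normality_p: tuple = ()
    outliers_removed: tuple = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "variables": "|".join(map(str, self.variables)),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": "|".join(map(str, self.n)),
            "normality_p": "|".join(f"{p:.4g}" for p in self.normality_p),
            "outliers_removed": "|".join(map(str, self.outliers_removed)),
        }
        d.update(self.extra)
        return d


def ks_normality(sample, pvalmethod: str = "table") -> float:
    """Composite-normality p-value (Lilliefors-corrected KS).

    The plain KS test against a fixed N(mu, sigma) is anti-conservative
    when mu and sigma are estimated from the same sample; the
    Lilliefors table corrects for that. Requires n >= 4.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 4:
        raise ValueError("normality screening needs n >= 4")
    if np.ptp(sample) == 0:
        raise ValueError("constant sample: normality undefined")
    _, p = lilliefors(sample, dist="norm", pvalmethod=pvalmethod)
    return float(p)


def ks_normality_naive(sample) -> float:
    """Naive KS against N(mean, sd) without the Lilliefors correction."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 4:
        raise ValueError("normality screening needs n >= 4")
    sd = sample.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality undefined")
    return float(sstats.kstest(sample, "norm",
                               args=(sample.mean(), sd)).pvalue)


def _screen_normality(*groups) -> tuple:
    ps = []
    for g in groups:
        if len(g) >= 4 and np.ptp(g) > 0:
            p = ks_normality(g)
            if p < ALPHA:
                warnings.warn(
                    f"normality screening failed (Lilliefors p={p:.3g}); "
                    "proceeding with the t-test", stacklevel=3)
            ps.append(p)
        else:
            ps.append(float("nan"))
    return tuple(ps)


def two_sample_ttest(a, b, names=("a", "b"), equal_var: bool = True) -> StatResult:
    """Two-sided unpaired t-test (Student by default; Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    norm_p = _screen_normality(a, b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: both groups constant (same convention as the
        # one-sample case)
        equal = a[0] == b[0]
        return StatResult(
            "two_sample_t" if equal_var else "welch_t", tuple(names),
            0.0 if equal else float("inf") * np.sign(a[0] - b[0]),
            1.0 if equal else 0.0, (len(a), len(b)), norm_p,
            extra={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                   "df": float(len(a) + len(b) - 2), "degenerate": True},
        )
    res = sstats.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(
        "two_sample_t" if equal_var else "welch_t", tuple(names),
        float(res.statistic), float(res.pvalue), (len(a), len(b)), norm_p,
        extra={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
               "df": float(res.df)},
    )


def one_sample_ttest(sample, mu: float, name: str = "x") -> StatResult:
    """Two-sided one-sample t-test against the constant ``mu``.

    Degenerate zero-variance samples: p = 1 when the common value
    equals mu, else p = 0 flagged degenerate with the direction of the
    difference recorded.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 2:
        raise ValueError("one-sample test needs n >= 2")
    if np.ptp(sample) == 0:
        if sample[0] == mu:
            return StatResult("one_sample_t", (name, f"mu={mu:g}"), 0.0, 1.0,
                              (len(sample),), extra={"degenerate": True,
                                                     "mean": float(sample[0])})
        sign = 1.0 if sample[0] > mu else -1.0
        return StatResult("one_sample_t", (name, f"mu={mu:g}"),
                          float("inf") * sign, 0.0, (len(sample),),
                          extra={"degenerate": True, "mean": float(sample[0])})
    res = sstats.ttest_1samp(sample, popmean=mu)
    return StatResult("one_sample_t", (name, f"mu={mu:g}"),
                      float(res.statistic), float(res.pvalue), (len(sample),),
                      extra={"degenerate": False, "mean": float(sample.mean())})


def grubbs_test(values, alpha: float = ALPHA):
    """One-pass two-sided Grubbs test for a single outlier.

    Returns ``(index, G, G_crit)`` where index is the position of the
    most extreme value if G > G_crit, else None. Critical value:
    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{1 - alpha/(2n), n-2}.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = values.std(ddof=1)
    if sd == 0:
        return None, 0.0, float("inf")
    dev = np.abs(values - values.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    t = sstats.t.ppf(1 - alpha / (2 * n), n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
    return (i if g > g_crit else None), float(g), float(g_crit)


def _studentized_residuals(x, y) -> np.ndarray:
    """Externally studentized residuals of the y-on-x simple regression."""
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    return model.get_influence().resid_studentized_external


def pearson_outlier(x, y, ids=None, alpha: float = ALPHA) -> StatResult:
    """Pearson correlation with a one-pass Grubbs outlier screen.

    Fits Pearson r on all points, screens the externally studentized
    residuals of the y-on-x regression with a Grubbs test at ``alpha``,
    removes at most one flagged point, refits, and reports both fits
    plus the removed id. Requires n >= 4 and n >= 3 after removal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("correlation screening needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    ids = list(ids) if ids is not None else list(range(len(x)))
    r_pre, p_pre = sstats.pearsonr(x, y)
    resid = _studentized_residuals(x, y)
    if np.ptp(resid) > 0 and np.all(np.isfinite(resid)):
        idx, _, _ = grubbs_test(resid, alpha=alpha)
    else:
        idx = None
    removed = ()
    r_post, p_post, n_post = r_pre, p_pre, len(x)
    if idx is not None:
        keep = np.ones(len(x), dtype=bool)
        keep[idx] = False
        removed = (ids[idx],)
        r_post, p_post = sstats.pearsonr(x[keep], y[keep])
        n_post = int(keep.sum())
    return StatResult(
        "pearson_outlier", ("x", "y"), float(r_post), float(p_post),
        (n_post,), outliers_removed=removed,
        extra={"r_pre": float(r_pre), "p_pre": float(p_pre),
               "n_pre": len(x)},
    )


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in
    the pipeline, which mirrors uncorrected per-test inference)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
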