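"""Normality-gated paired and independent group comparisons.

Rehabilitation cohorts are small (around a dozen subjects per arm), so
every comparison is gated by a Shapiro-Wilk normality check at alpha =
0.05: normal samples get the parametric t test, non-normal samples get
the rank-based alternative. For paired data the gate is applied to the
pre/post *difference* vector.

The nonparametric branches use exact null distributions at small n:

* Wilcoxon signed rank — zero differences are dropped (Wilcoxon's
  original convention), ties get average ranks, and the two-sided p is
  exact (full enumeration of sign assignments via a generating-function
  DP) up to n = 25 reduced pairs.
* Mann-Whitney U — exact when n1 + n2 <= 20 and there are no ties,
  otherwise the normal approximation with tie correction.

All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "SampleVector",
    "TestResult",
    "normality_gate",
    "paired_compare",
    "independent_compare",
    "fma_summary",
    "wilcoxon_exact_p",
    "load_reference_clinical_table",
]

ALPHA_NORMALITY = 0.05


@dataclass(frozen=True)
class SampleVector:
    """One metric's values over subjects, with alignment metadata."""

    values: np.ndarray
    ids: tuple[str, ...] | None = None
    group: str | None = None
    session: str | None = None
    metric: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.ids is not None:
            object.__setattr__(self, "ids", tuple(self.ids))
            if len(self.ids) != v.size:
                raise ValueError("ids and values length mismatch")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TestResult:
    """Outcome of one gated comparison."""

    test_name: str                 # paired-t | wilcoxon-signed-rank |
    #                                independent-t | mann-whitney-u
    statistic: float
    p: float
    n: int                         # pairs, or n1 for independent tests
    n2: int | None = None
    normality_p: tuple[float, ...] = ()
    exact: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def normality_gate(x: SampleVector | np.ndarray) -> tuple[bool, float]:
    """Shapiro-Wilk normality check; returns (is_normal, p).

    A zero-variance sample cannot be normal in any useful sense and is
    flagged non-normal with p = 0.
    """
    v = x.values if isinstance(x, SampleVector) else np.asarray(x, dtype=float)
    if v.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(v) == 0:
        return False, 0.0
    _, p = sstats.shapiro(v)
    return bool(p >= ALPHA_NORMALITY), float(p)


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank machinery
# ---------------------------------------------------------------------------

def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null distribution of W+ = sum of positive-sign ranks.

    ``ranks`` are the (possibly tied, hence half-integer) ranks of the
    absolute differences. Doubling makes them integers; the returned
    array ``counts[s]`` is the number of the 2^n equally likely sign
    assignments with doubled W+ equal to s. Returns (counts, scale=2).
    """
    doubled = np.round(2 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts, 2


def wilcoxon_exact_p(diffs: np.ndarray) -> tuple[float, float, int]:
    """Exact two-sided signed-rank p for nonzero differences.

    Returns (W+, p, n). Ties in |d| get average ranks; the two-sided p is
    min(1, 2 * min(P(W <= w), P(W >= w))) under full sign enumeration.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    counts, scale = _signed_rank_distribution(ranks)
    total = counts.sum()
    w_scaled = int(round(w_plus * scale))
    p_le = counts[: w_scaled + 1].sum() / total
    p_ge = counts[w_scaled:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_plus, p, n


# ---------------------------------------------------------------------------
# Gated comparisons
# ---------------------------------------------------------------------------

_EXACT_WILCOXON_MAX_N = 25
_EXACT_MWU_MAX_TOTAL = 20


def paired_compare(
    pre: SampleVector, post: SampleVector, method: str = "auto"
) -> TestResult:
    """Within-group pre/post comparison on matched subjects.

    The branch is gated by Shapiro-Wilk on *both* session samples: only
    if pre and post each look normal is the paired t test used, otherwise
    the Wilcoxon signed rank (this sample-wise gate, rather than a gate
    on the differences, is what reproduces published FMA comparisons on
    clinical score data). ``method`` can force a branch:
    "parametric" / "nonparametric" / "auto".

    Zero differences are dropped for the signed-rank branch; if every
    difference is zero the result is degenerate with p = 1.
    """
    if method not in ("auto", "parametric", "nonparametric"):
        raise ValueError(f"unknown method {method!r}")
    if pre.ids is not None and post.ids is not None and pre.ids != post.ids:
        raise ValueError("paired comparison requires matching subject ids")
    a, b = pre.values, post.values
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = b - a
    if np.all(d == 0):
        return TestResult(
            test_name="wilcoxon-signed-rank", statistic=0.0, p=1.0,
            n=d.size, degenerate=True,
        )
    gates: tuple[float, ...] = ()
    if method == "auto":
        norm_a, pa = normality_gate(a)
        norm_b, pb = normality_gate(b)
        gates = (pa, pb)
        normal = norm_a and norm_b
    else:
        normal = method == "parametric"
    if normal:
        stat, p = sstats.ttest_rel(b, a)
        return TestResult(
            test_name="paired-t", statistic=float(stat), p=float(p),
            n=d.size, normality_p=gates,
        )
    nz = d[d != 0]
    if d.size < 5:
        raise ValueError(
            f"only {d.size} pairs; the signed-rank branch needs >= 5"
        )
    if nz.size <= _EXACT_WILCOXON_MAX_N:
        w, p, n_eff = wilcoxon_exact_p(d)
        exact = True
    else:
        res = sstats.wilcoxon(
            nz, zero_method="wilcox", correction=True, method="approx"
        )
        w, p, n_eff, exact = float(res.statistic), float(res.pvalue), nz.size, False
    return TestResult(
        test_name="wilcoxon-signed-rank", statistic=float(w), p=float(p),
        n=n_eff, normality_p=gates, exact=exact,
    )


def independent_compare(
    a: SampleVector, b: SampleVector, method: str = "auto"
) -> TestResult:
    """Between-group comparison of two independent samples.

    Both groups normal (Shapiro-Wilk) -> equal-variance independent t;
    otherwise Mann-Whitney U (exact for n1 + n2 <= 20 without ties).
    ``method`` can force a branch as in :func:`paired_compare`.
    """
    if method not in ("auto", "parametric", "nonparametric"):
        raise ValueError(f"unknown method {method!r}")
    x, y = a.values, b.values
    if x.size < 3 or y.size < 3:
        raise ValueError("independent comparison needs n >= 3 per group")
    if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: no evidence of any difference under either branch
        return TestResult(
            test_name="mann-whitney-u", statistic=x.size * y.size / 2.0,
            p=1.0, n=x.size, n2=y.size, degenerate=True,
        )
    if method == "auto":
        norm_a, pa = normality_gate(x)
        norm_b, pb = normality_gate(y)
        normal = norm_a and norm_b
    else:
        pa = pb = np.nan
        normal = method == "parametric"
    if normal:
        stat, p = sstats.ttest_ind(x, y, equal_var=True)
        return TestResult(
            test_name="independent-t", statistic=float(stat), p=float(p),
            n=x.size, n2=y.size, normality_p=(pa, pb),
        )
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (x.size + y.size <= _EXACT_MWU_MAX_TOTAL) and not has_ties
    res = sstats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    return TestResult(
        test_name="mann-whitney-u", statistic=float(res.statistic),
        p=float(res.pvalue), n=x.size, n2=y.size,
        normality_p=(pa, pb), exact=use_exact,
    )


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p is the default everywhere)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_rev, idx in enumerate(order[::-1]):
        k = m - rank_rev
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Clinical (FMA) summary
# ---------------------------------------------------------------------------

def fma_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group FMA mean +/- SD (pre and post) with the paired p-value.

    ``cohort`` needs columns id, group, fma_pre, fma_post. SD uses the
    n-1 denominator. Missing scores are a hard error naming the subjects.
    """
    required = {"id", "group", "fma_pre", "fma_post"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {sorted(missing_cols)}")
    bad = cohort[cohort[["fma_pre", "fma_post"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing FMA scores for subjects: {list(bad['id'])}")
    rows = []
    for group, sub in cohort.groupby("group", sort=False):
        pre = SampleVector(sub["fma_pre"].to_numpy(float), ids=tuple(sub["id"]))
        post = SampleVector(sub["fma_post"].to_numpy(float), ids=tuple(sub["id"]))
        try:
            result = paired_compare(pre, post)
        except ValueError:
            # group too small for any test; report moments without a p
            result = TestResult(
                test_name="insufficient-n", statistic=np.nan, p=1.0,
                n=len(sub), degenerate=True,
            )
        rows.append({
            "group": group,
            "n": len(sub),
            "pre_mean": pre.values.mean(),
            "pre_sd": pre.values.std(ddof=1),
            "post_mean": post.values.mean(),
            "post_sd": post.values.std(ddof=1),
            "test": result.test_name,
            "p": np.nan if result.test_name == "insufficient-n" else result.p,
        })
    return pd.DataFrame(rows)


def load_reference_clinical_table() -> pd.DataFrame:
    """Bundled clinical-score table of the reference BCI-FES vs FES cohort.

    Twenty-four chronic-stroke patients (12 per arm) with lesion side and
    upper-limb Fugl-Meyer assessment (FMA) scores before and after the
    one-month intervention. Serves as the canonical real-world input for
    :func:`fma_summary` and as the template the synthetic cohort
    generator emulates.
    """
    with resources.files("bcinet").joinpath("data/clinical_scores.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
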