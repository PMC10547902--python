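"""Cross-modal statistical battery.

Condition comparisons (Mann-Whitney U, Kruskal-Wallis with Dunn's
post-hoc, bootstrap Tukey-Kramer after one-way ANOVA), Holm-Bonferroni
multiplicity control, the Spearman correlation matrix across acoustic,
EEG, NIRS and COMFORT features, and Kendall's coefficient of
concordance W between feature pairs per condition, with strong
(W >= 0.5) and very strong (W > 0.7) agreement flags.

Standard tests delegate to scipy/statsmodels; Dunn's z statistics,
the bootstrap Tukey-Kramer null and tie-corrected Kendall W are
implemented here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .config import StatsConfig


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    group_sizes: tuple = ()
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# balancing


def balanced_subsample(groups: dict, seed: int) -> dict:
    """Down-sample every group without replacement to the smallest size."""
    rng = np.random.default_rng(seed)
    n_min = min(len(v) for v in groups.values())
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals)
        if len(vals) == n_min:
            out[name] = vals.copy()
        else:
            idx = rng.choice(len(vals), size=n_min, replace=False)
            out[name] = vals[np.sort(idx)]
    return out


# ---------------------------------------------------------------------------
# hypothesis tests


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      group_sizes=(len(a), len(b)))


def kruskal_dunn(groups: dict) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis H followed by Dunn's pairwise z tests.

    Dunn's statistic compares mean ranks of the pooled ranking with the
    tie-corrected variance; pairwise p values are Holm-adjusted within
    the family of all pairs.
    """
    names = list(groups)
    vals = [np.asarray(groups[k], float) for k in names]
    if any(len(v) < 2 for v in vals):
        raise ValueError("each group needs at least 2 observations")
    h, p = stats.kruskal(*vals)
    omnibus = TestResult("kruskal-wallis", float(h), float(p),
                         group_sizes=tuple(len(v) for v in vals))

    pooled = np.concatenate(vals)
    ranks = rankdata(pooled)
    n_tot = len(pooled)
    # tie correction sum(t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    mean_ranks, sizes = [], []
    i0 = 0
    for v in vals:
        mean_ranks.append(ranks[i0 : i0 + len(v)].mean())
        sizes.append(len(v))
        i0 += len(v)

    pairs, raw = [], []
    for i, j in combinations(range(len(names)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        pairs.append((i, j, z))
        raw.append(2.0 * stats.norm.sf(abs(z)))
    adj = holm_bonferroni(raw) if raw else []
    posthoc = [
        TestResult("dunn", float(z), float(pr), float(pa),
                   group_sizes=(sizes[i], sizes[j]),
                   extra={"pair": (names[i], names[j])})
        for (i, j, z), pr, pa in zip(pairs, raw, adj)
    ]
    return omnibus, posthoc


def anova_tukey_bootstrap(
    groups: dict, reps: int = 10_000, seed: int = 0,
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA with bootstrap Tukey-Kramer pairwise comparisons.

    The null distribution of the maximum studentised-range statistic is
    estimated by resampling mean-centred observations within groups
    with replacement (``reps`` draws); each observed pairwise q is
    referred to that null, which controls the family-wise error the
    way the classical Tukey-Kramer procedure does without assuming
    normality.
    """
    names = list(groups)
    vals = [np.asarray(groups[k], float) for k in names]
    if any(len(v) < 2 for v in vals):
        raise ValueError("each group needs at least 2 observations")
    f, p = stats.f_oneway(*vals)
    omnibus = TestResult("anova", float(f), float(p),
                         group_sizes=tuple(len(v) for v in vals))

    rng = np.random.default_rng(seed)
    sizes = np.array([len(v) for v in vals])
    n_tot = int(sizes.sum())
    k = len(vals)

    def q_stats(sample_means, mse):
        qs = {}
        for i, j in combinations(range(k), 2):
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            qs[(i, j)] = abs(sample_means[i] - sample_means[j]) / se if se > 0 else 0.0
        return qs

    means = [v.mean() for v in vals]
    mse = sum(((v - v.mean()) ** 2).sum() for v in vals) / (n_tot - k)
    q_obs = q_stats(means, mse)

    centred = [v - v.mean() for v in vals]
    q_null = np.empty(reps)
    for r in range(reps):
        bm, ss = [], 0.0
        for v in centred:
            draw = v[rng.integers(0, len(v), len(v))]
            bm.append(draw.mean())
            ss += ((draw - draw.mean()) ** 2).sum()
        mse_b = ss / (n_tot - k)
        q_null[r] = max(q_stats(bm, mse_b).values())

    posthoc = []
    for (i, j), q in q_obs.items():
        p_pair = float((np.sum(q_null >= q) + 1) / (reps + 1))
        posthoc.append(TestResult(
            "tukey-kramer-bootstrap", float(q), p_pair, p_pair,
            group_sizes=(int(sizes[i]), int(sizes[j])),
            extra={"pair": (names[i], names[j])},
        ))
    return omnibus, posthoc


def holm_bonferroni(p_values) -> list[float]:
    """Step-down Holm adjustment (monotone, order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    _, adj, _, _ = multipletests(p, method="holm")
    return [float(v) for v in adj]


# ---------------------------------------------------------------------------
# correlation and concordance


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho and p matrices."""
    cols = list(table.columns)
    if len(cols) != len(set(cols)):
        raise ValueError("column names must be unique")
    n = len(cols)
    rho = np.eye(n)
    pval = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        x = table[cols[i]].to_numpy(dtype=float)
        y = table[cols[j]].to_numpy(dtype=float)
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3:
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(x[m], y[m])
        rho[i, j] = rho[j, i] = r
        pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def kendall_w(rankings: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``rankings`` is an (m rankers x n items) array of scores; each
    ranker's scores are converted to ranks (mean ranks for ties).
    W = 12 S / (m^2 (n^3 - n) - m T) with S the sum of squared
    deviations of item rank sums and T the tie correction
    sum(t^3 - t) accumulated over rankers.
    """
    arr = np.asarray(rankings, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rankings must be 2-D (m rankers x n items)")
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 rankers and 2 items")
    ranks = np.vstack([rankdata(row) for row in arr])
    r_sums = ranks.sum(axis=0)
    s = float(((r_sums - r_sums.mean()) ** 2).sum())
    t = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        t += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * t
    if denom <= 0:
        return np.nan
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


def concordance_report(
    tables_by_condition: dict[str, pd.DataFrame],
    audio_features: list[str],
    partner_features: list[str],
    cfg: StatsConfig | None = None,
) -> pd.DataFrame:
    """Pairwise Kendall W between audio and other-modality features.

    Each (audio feature, partner feature) pair is treated as two
    rankers over the condition's segments, computed separately per
    condition; W >= 0.5 is flagged as strong agreement and W > 0.7 as
    very strong.
    """
    cfg = cfg or StatsConfig()
    rows = []
    for condition, table in tables_by_condition.items():
        for af in audio_features:
            for pf in partner_features:
                x = table[af].to_numpy(dtype=float)
                y = table[pf].to_numpy(dtype=float)
                m = np.isfinite(x) & np.isfinite(y)
                w = kendall_w(np.vstack([x[m], y[m]])) if m.sum() >= 3 else np.nan
                rows.append({
                    "audio_feature": af, "partner_feature": pf,
                    "condition": condition, "n": int(m.sum()), "W": w,
                    "strong": bool(np.isfinite(w) and w >= cfg.strong_agreement_w),
                    "framed": bool(np.isfinite(w) and w > cfg.framed_agreement_w),
                })
    return pd.DataFrame(rows)
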