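"""Statistical battery for group comparisons of electrophysiological measures.

Mirrors the analysis conventions of comparative ex vivo retina studies:
normality is screened with both Shapiro-Wilk and a Lilliefors-corrected
Kolmogorov-Smirnov test; non-parametric two-group comparisons use the
Mann-Whitney U test (exact null distribution for small tie-free samples);
repeated measures across protocol stages use the Friedman test with Dunn-style
pairwise post-hoc comparisons (Wilcoxon signed-rank, Holm-adjusted); and the
per-cell intrinsic-property comparison between species uses the pooled-variance
two-sided Student t test.  Group values are reported as mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TestResult",
    "DegenerateDataError",
    "InsufficientDataError",
    "normality_gate",
    "mann_whitney",
    "friedman_posthoc",
    "unpaired_t",
    "summary_table",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested test."""


class DegenerateDataError(ValueError):
    """The sample is degenerate (e.g. zero variance) for the requested test."""


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, SD and SEM of one group of observations."""

    label: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)

    @classmethod
    def from_sample(cls, x: Sequence[float], label: str = "") -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 1:
            raise InsufficientDataError("empty sample")
        return cls(label=label, n=int(x.size), mean=float(np.mean(x)),
                   sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    adjusted: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def normality_gate(x: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Screen a sample for normality with Shapiro-Wilk and Lilliefors-KS.

    Returns ``(shapiro_p, ks_p, reject)`` where ``reject`` is True only when
    both tests fall below ``alpha`` — the gate used before switching to
    rank-based comparisons.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("normality tests need n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: normality undefined")
    shapiro_p = float(sps.shapiro(x).pvalue)
    _, ks_p = lilliefors(x, dist="norm")
    return shapiro_p, float(ks_p), bool(shapiro_p < alpha and ks_p < alpha)


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 two_sided: bool = True) -> TestResult:
    """Mann-Whitney U test.

    Uses the exact null distribution of U when the smaller sample has at most
    8 observations and there are no ties across the pooled sample; otherwise
    the normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided" if two_sided else "greater",
        method="exact" if exact else "asymptotic",
    )
    return TestResult(
        test_name="mann-whitney-exact" if exact else "mann-whitney-normal",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_per_group=(int(x.size), int(y.size)),
    )


def friedman_posthoc(blocks: np.ndarray, condition_names: Sequence[str] | None = None,
                     alpha: float = 0.05) -> TestResult:
    """Friedman test over a subjects x conditions block, with post-hoc pairs.

    Pairwise follow-up uses Wilcoxon signed-rank tests on each condition pair
    with Holm adjustment across the pairs.  Requires a complete block (no
    missing cells), at least 2 subjects and at least 3 conditions.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D subjects x conditions array")
    n_sub, n_cond = blocks.shape
    if n_cond < 3:
        raise InsufficientDataError("Friedman test needs >= 3 conditions")
    if n_sub < 2:
        raise InsufficientDataError("Friedman test needs >= 2 subjects")
    if np.isnan(blocks).any():
        bad = np.where(np.isnan(blocks).any(axis=1))[0].tolist()
        raise ValueError(f"missing cells for subjects {bad}")
    names = list(condition_names) if condition_names is not None else [
        f"c{j}" for j in range(n_cond)
    ]
    if np.all(blocks == blocks[:, :1]):
        # scipy raises on all-identical rankings; the statistic is exactly 0
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*blocks.T)
    pairs = [(i, j) for i in range(n_cond) for j in range(i + 1, n_cond)]
    raw_p = []
    stats_w = []
    for i, j in pairs:
        d = blocks[:, i] - blocks[:, j]
        if np.all(d == 0):
            stats_w.append(0.0)
            raw_p.append(1.0)
        else:
            w = sps.wilcoxon(blocks[:, i], blocks[:, j],
                             zero_method="wilcox", method="auto")
            stats_w.append(float(w.statistic))
            raw_p.append(float(w.pvalue))
    adj = multipletests(raw_p, alpha=alpha, method="holm")[1]
    comparisons = [
        {"pair": (names[i], names[j]), "statistic": s, "p_raw": pr,
         "p_adjusted": float(pa), "significant": bool(pa < alpha)}
        for (i, j), s, pr, pa in zip(pairs, stats_w, raw_p, adj)
    ]
    return TestResult(
        test_name="friedman", statistic=float(stat), p_value=float(p),
        n_per_group=(n_sub,) * n_cond, adjusted=True,
        extra={"comparisons": comparisons},
    )


def unpaired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided unpaired Student t test with pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("t test needs n >= 2 per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateDataError("zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(test_name="unpaired-t", statistic=float(t),
                      p_value=float(p), n_per_group=(int(x.size), int(y.size)))


def summary_table(profiles: pd.DataFrame, group_col: str = "species",
                  parameters: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean ± SEM per parameter per group, with per-parameter unpaired t tests.

    ``profiles`` holds one row per cell with a grouping column (e.g. species)
    and one column per intrinsic parameter.  Returns a tidy frame with one row
    per (parameter, group) carrying n/mean/sd/sem, plus the two-group pooled-t
    p-value when exactly two groups are present.
    """
    groups = list(dict.fromkeys(profiles[group_col]))
    if parameters is None:
        parameters = [c for c in profiles.columns
                      if c != group_col and np.issubdtype(profiles[c].dtype, np.number)]
    rows = []
    for param in parameters:
        samples = {g: profiles.loc[profiles[group_col] == g, param].dropna().to_numpy()
                   for g in groups}
        if len(groups) == 2:
            a, b = (samples[g] for g in groups)
            try:
                p_val = unpaired_t(a, b).p_value
            except DegenerateDataError:
                p_val = np.nan
        else:
            p_val = np.nan
        for g in groups:
            s = GroupSummary.from_sample(samples[g], label=str(g))
            rows.append({"parameter": param, group_col: g, "n": s.n,
                         "mean": s.mean, "sd": s.sd, "sem": s.sem,
                         "t_p_value": p_val})
    return pd.DataFrame(rows)
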