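"""Kin-discrimination and dominance statistics from chimeric fruiting bodies.

When two haploid strains are mixed and starved together, the cells
aggregate into chimeric fruiting bodies.  How unevenly the strains sort
across bodies measures kin discrimination; how far a strain's mean
fruiting-body share departs from its share in the initial cell mix
measures dominance.  Strain shares are quantified by allele-specific
pyrosequencing, calibrated by a per-marker linear standard curve of peak
height against known mixture proportion.

Statistics (for fruiting-body proportions p_1..p_N of a focal strain,
p-bar their mean, p_o the measured initial-mix proportion):

* relatedness within body i:          r_i  = (p_i - p_bar) / (1 - p_bar)
  for the other strain:               r_i' = (p_bar - p_i) / p_bar
* global fruiting-body relatedness:   r_fb = (1/N) * sum_i [ p_i r_i + (1 - p_i) r_i' ]
  ranging 0 (random mixing) to 1 (complete segregation).
* dominance:                          d = mean(p_i) - p_o       (antisymmetric in the focal strain)
* Levene-style dispersion:            LS = mean_i |x_i - x_bar|
* arcsine variance: sample variance of arcsin(sqrt(x_i)).

The r_fb normalization by the number of fruiting bodies is chosen so the
stated 0/1 endpoints hold exactly; d, LS and the arcsine variance follow
the verbal definitions of the assay literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ChimeraExperiment",
    "SocialStats",
    "GroupComparison",
    "fit_standard_curve",
    "estimate_proportions",
    "fruiting_body_relatedness",
    "dominance",
    "levene_statistic",
    "arcsine_variance",
    "experiment_stats",
    "compare_groups",
]


@dataclass
class StandardCurve:
    """Least-squares line of pyrosequencing peak-height ratio vs known
    allele proportion, with its fit r^2 and replicate count."""

    slope: float
    intercept: float
    r2: float
    n_points: int


@dataclass
class ChimeraExperiment:
    """Per-fruiting-body strain proportions for one or more strain pairs.

    Backed by a DataFrame with columns ``pair``, ``strain_a``, ``strain_b``,
    ``marker``, ``replicate``, ``fruiting_body``, ``p_i``, ``p_o``.  ``p_i``
    is the focal strain's (strain_a) proportion in one fruiting body;
    ``p_o`` its measured proportion in the initial cell mix of that
    replicate.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"pair", "marker", "replicate", "fruiting_body", "p_i", "p_o"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"chimera table missing columns {sorted(missing)}")
        for col in ("p_i", "p_o"):
            vals = self.frame[col]
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")

    @property
    def pairs(self) -> list[str]:
        return sorted(self.frame["pair"].unique())


@dataclass
class SocialStats:
    """Per-pair social statistics with marker/replicate breakdown."""

    pair: str
    r_fb: float
    r_fb_se: float
    d: float
    abs_d: float
    abs_d_se: float
    levene: float
    arcsine_var: float
    per_marker: pd.DataFrame  # one row per (marker, replicate)


@dataclass
class GroupComparison:
    sympatric_mean: float
    allopatric_mean: float
    p_value_r_fb: float
    p_value_abs_d: float
    regression_r2_r_fb: float
    regression_r2_abs_d: float
    low_divergence: pd.DataFrame
    high_divergence: pd.DataFrame
    median_divergence: float


def fit_standard_curve(
    known_proportions: np.ndarray, peak_heights: np.ndarray
) -> StandardCurve:
    """Ordinary least squares of peak height on known allele proportion.

    Replicate measurements enter as separate points.  Requires at least 3
    distinct proportions.
    """
    x = np.asarray(known_proportions, dtype=float)
    y = np.asarray(peak_heights, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct known proportions")
    res = stats.linregress(x, y)
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2), len(x))


def estimate_proportions(
    curve: StandardCurve, measured_heights: np.ndarray
) -> tuple[np.ndarray, int]:
    """Invert the standard curve; clip to [0, 1] and count clipped values."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope; cannot invert")
    raw = (np.asarray(measured_heights, dtype=float) - curve.intercept) / curve.slope
    clipped = int(((raw < 0) | (raw > 1)).sum())
    return np.clip(raw, 0.0, 1.0), clipped


def fruiting_body_relatedness(p_list: np.ndarray) -> float:
    """Global fruiting-body relatedness r_fb in [0, 1].

    Averages, over fruiting bodies, each strain's frequency-weighted
    deviation from its sample mean scaled by the maximum possible
    deviation.  All-equal proportions give 0; proportions all at {0, 1}
    give exactly 1.  Undefined (ValueError) when one strain is absent from
    every fruiting body (p-bar of 0 or 1).
    """
    p = np.asarray(p_list, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 fruiting bodies")
    pbar = float(p.mean())
    if pbar in (0.0, 1.0):
        raise ValueError("one strain absent from all fruiting bodies; r_fb undefined")
    r_a = (p - pbar) / (1.0 - pbar)
    r_b = (pbar - p) / pbar
    return float(np.mean(p * r_a + (1.0 - p) * r_b))


def dominance(p_list: np.ndarray, p_o: float) -> tuple[float, float]:
    """d = mean fruiting-body proportion minus the initial-mix proportion.

    Returns (d, |d|); antisymmetric under swapping the focal strain.
    """
    p = np.asarray(p_list, dtype=float)
    if len(p) == 0:
        raise ValueError("empty fruiting-body list")
    if not 0 < p_o < 1:
        raise ValueError("p_o must be strictly inside (0, 1)")
    d = float(p.mean() - p_o)
    return d, abs(d)


def levene_statistic(p_list: np.ndarray) -> float:
    """Mean absolute deviation from the mean (Levene transform)."""
    p = np.asarray(p_list, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 values")
    return float(np.mean(np.abs(p - p.mean())))


def arcsine_variance(p_list: np.ndarray) -> float:
    """Sample variance (n-1 denominator) of arcsin(sqrt(x))."""
    p = np.asarray(p_list, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must be in [0, 1]")
    return float(np.var(np.arcsin(np.sqrt(p)), ddof=1))


def experiment_stats(experiment: ChimeraExperiment) -> list[SocialStats]:
    """Per-pair social statistics.

    Statistics are computed per (marker, replicate) series of fruiting-body
    proportions, then averaged: the two markers are technical replicates
    and the mean-of-marker-level-statistics convention is used for the
    headline values (marker-level rows are retained).  Standard errors are
    over the marker x replicate series.
    """
    out = []
    for pair, sub in experiment.frame.groupby("pair"):
        rows = []
        for (marker, rep), series in sub.groupby(["marker", "replicate"]):
            p = series.sort_values("fruiting_body")["p_i"].to_numpy()
            p_o = float(series["p_o"].iloc[0])
            d, abs_d = dominance(p, p_o)
            rows.append(
                {
                    "marker": marker,
                    "replicate": rep,
                    "r_fb": fruiting_body_relatedness(p),
                    "d": d,
                    "abs_d": abs_d,
                    "levene": levene_statistic(p),
                    "arcsine_var": arcsine_variance(p),
                }
            )
        per = pd.DataFrame(rows)
        se = lambda v: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        out.append(
            SocialStats(
                pair=pair,
                r_fb=float(per["r_fb"].mean()),
                r_fb_se=se(per["r_fb"]),
                d=float(per["d"].mean()),
                abs_d=float(per["abs_d"].mean()),
                abs_d_se=se(per["abs_d"]),
                levene=float(per["levene"].mean()),
                arcsine_var=float(per["arcsine_var"].mean()),
                per_marker=per,
            )
        )
    return out


def _perm_test_diff_means(a, b, n_perm, rng) -> float:
    """One-sided permutation p for mean(a) > mean(b), add-one rule."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa = pooled[perm[: len(a)]]
        pb = pooled[perm[len(a):]]
        if pa.mean() - pb.mean() >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def compare_groups(
    stats_by_pair: list[SocialStats],
    sympatric: dict[str, bool],
    divergence: dict[str, float],
    n_perm: int = 10_000,
    seed: int | None = None,
    test: str = "permutation",
) -> GroupComparison:
    """Sympatric-vs-allopatric comparison and divergence regressions.

    ``sympatric`` labels each pair (shared collection site or not);
    ``divergence`` gives pairwise SNP difference counts.  The group test is
    a one-sided permutation test on the difference of group means of r_fb
    (and of |d|); a Welch t-test is available via ``test='welch'``.
    Regressions of r_fb and |d| on divergence report OLS R^2; pairs are
    also partitioned at the sample median divergence.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "pair": [s.pair for s in stats_by_pair],
            "r_fb": [s.r_fb for s in stats_by_pair],
            "abs_d": [s.abs_d for s in stats_by_pair],
            "sympatric": [sympatric[s.pair] for s in stats_by_pair],
            "divergence": [divergence[s.pair] for s in stats_by_pair],
        }
    )
    sym = df[df["sympatric"]]
    allo = df[~df["sympatric"]]
    if len(sym) == 0 or len(allo) == 0:
        raise ValueError("both sympatric and allopatric pairs are required")

    if test == "permutation":
        p_r = _perm_test_diff_means(sym["r_fb"], allo["r_fb"], n_perm, rng)
        p_d = _perm_test_diff_means(sym["abs_d"], allo["abs_d"], n_perm, rng)
    elif test == "welch":
        p_r = float(
            stats.ttest_ind(sym["r_fb"], allo["r_fb"], equal_var=False, alternative="greater").pvalue
        )
        p_d = float(
            stats.ttest_ind(sym["abs_d"], allo["abs_d"], equal_var=False, alternative="greater").pvalue
        )
    else:
        raise ValueError(f"unknown test {test!r}")

    reg_r = stats.linregress(df["divergence"], df["r_fb"])
    reg_d = stats.linregress(df["divergence"], df["abs_d"])
    med = float(df["divergence"].median())
    return GroupComparison(
        sympatric_mean=float(sym["r_fb"].mean()),
        allopatric_mean=float(allo["r_fb"].mean()),
        p_value_r_fb=p_r,
        p_value_abs_d=p_d,
        regression_r2_r_fb=float(reg_r.rvalue**2),
        regression_r2_abs_d=float(reg_d.rvalue**2),
        low_divergence=df[df["divergence"] < med].reset_index(drop=True),
        high_divergence=df[df["divergence"] >= med].reset_index(drop=True),
        median_divergence=med,
    )
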