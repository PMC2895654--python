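"""Linkage disequilibrium: pairwise r-squared, distance-decay profile,
baseline from inter-chromosome pairs, and the distance-permutation test.

Haplotypes are observed directly (haploid organism), so two-locus counts
are complete-case tallies over strains called at both sites.  Distances are
differences of assembly coordinates; pairs on different chromosomes are
flagged unlinked and define the background LD level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import MISSING, SnpMatrix

__all__ = [
    "LdProfile",
    "LdDecayTest",
    "maf_filter",
    "r2_from_counts",
    "pairwise_r2",
    "paper_bin_edges",
    "ld_profile",
    "ld_decay_permutation_test",
]

#: Short-range distance-class edges (bp): <0.1 kb, 0.1-0.5 kb, 0.5-10 kb,
#: 10-25 kb, 25-50 kb, 50-100 kb, then every 100 kb to 1 Mb; 1 Mb windows
#: beyond are appended per dataset by :func:`paper_bin_edges`.
_BASE_EDGES = [0, 100, 500, 10_000, 25_000, 50_000, 100_000] + [
    100_000 * k for k in range(2, 11)
]


@dataclass
class LdProfile:
    edges: np.ndarray  # bin edges, bp; left-closed right-open intervals
    mean_r2: np.ndarray  # per-bin mean (NaN for empty bins)
    counts: np.ndarray
    elevated: np.ndarray  # bool; only defined when a baseline exists
    baseline_mean: float | None
    baseline_p80: float | None
    n_unlinked: int


@dataclass
class LdDecayTest:
    statistic: float
    p_value: float
    n_perm: int
    n_pairs: int
    method: str


def maf_filter(matrix: SnpMatrix, threshold: float = 0.10) -> SnpMatrix:
    """Retain sites whose minor-allele frequency among non-missing calls
    is at least ``threshold`` (default 10%, the rare-allele cutoff used for
    all LD and recombination analyses)."""
    k = matrix.minor_counts()
    m = matrix.callable_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(m > 0, k / np.maximum(m, 1), 0.0)
    return matrix.take_sites(np.flatnonzero(freq >= threshold))


def r2_from_counts(n00: int, n01: int, n10: int, n11: int) -> float | None:
    """r^2 from complete-case two-locus haplotype counts.

    ``None`` when either margin is monomorphic among complete cases.
    """
    n = n00 + n01 + n10 + n11
    if n == 0:
        return None
    p1 = (n10 + n11) / n  # allele 1 at first site
    q1 = (n01 + n11) / n  # allele 1 at second site
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        return None
    D = n11 / n - p1 * q1
    return float(D * D / (p1 * (1 - p1) * q1 * (1 - q1)))


def pairwise_r2(matrix: SnpMatrix) -> pd.DataFrame:
    """Two-locus r^2 for every SNP pair.

    Returns a pair table with columns ``i, j`` (site indices), ``linked``
    (same chromosome), ``distance`` (bp; NaN for unlinked pairs), ``r2`` and
    ``n`` (complete-case strains).  Pairs whose complete-case margin is
    monomorphic are dropped; the dropped count is in
    ``df.attrs["n_monomorphic_dropped"]``.
    """
    if matrix.s < 2:
        raise ValueError("need at least 2 retained sites for pairwise LD")
    g = matrix.genotypes
    one = (g == 1).astype(np.int64)
    zero = (g == 0).astype(np.int64)
    n11 = one @ one.T
    n10 = one @ zero.T
    n01 = zero @ one.T
    n00 = zero @ zero.T
    iu, ju = np.triu_indices(matrix.s, k=1)

    tot = (n00 + n01 + n10 + n11)[iu, ju].astype(float)
    p1 = np.where(tot > 0, (n10 + n11)[iu, ju] / np.maximum(tot, 1), 0.0)
    q1 = np.where(tot > 0, (n01 + n11)[iu, ju] / np.maximum(tot, 1), 0.0)
    poly = (tot > 0) & (p1 > 0) & (p1 < 1) & (q1 > 0) & (q1 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = n11[iu, ju] / np.maximum(tot, 1) - p1 * q1
        r2 = D * D / (p1 * (1 - p1) * q1 * (1 - q1))
    same = matrix.chromosomes[iu] == matrix.chromosomes[ju]
    dist = np.abs(matrix.positions[iu] - matrix.positions[ju]).astype(float)
    dist[~same] = np.nan

    df = pd.DataFrame(
        {
            "i": iu[poly],
            "j": ju[poly],
            "linked": same[poly],
            "distance": dist[poly],
            "r2": r2[poly],
            "n": tot[poly].astype(int),
        }
    )
    df.attrs["n_monomorphic_dropped"] = int((~poly).sum())
    return df


def paper_bin_edges(max_distance: float) -> np.ndarray:
    """Distance-class edges extended with 1 Mb windows to cover the data."""
    edges = list(_BASE_EDGES)
    while edges[-1] <= max_distance:
        edges.append(edges[-1] + 1_000_000)
    return np.asarray(edges, dtype=float)


def ld_profile(pairs: pd.DataFrame, edges: np.ndarray | None = None) -> LdProfile:
    """Bin linked pairs by distance; estimate the unlinked baseline.

    A bin is flagged *elevated* only when it holds more than 10 pairs and
    its mean r^2 exceeds the 80th percentile of the unlinked (different
    chromosome) pairs.  Intervals are left-closed, right-open in bp.  With
    no unlinked pairs the baseline is undefined and elevation flags are
    withheld (all False, baseline fields None).
    """
    linked = pairs[pairs["linked"]]
    unlinked = pairs[~pairs["linked"]]
    if edges is None:
        maxd = float(linked["distance"].max()) if len(linked) else 0.0
        edges = paper_bin_edges(maxd)
    edges = np.asarray(edges, dtype=float)
    which = np.digitize(linked["distance"].to_numpy(), edges, right=False) - 1
    nbins = len(edges) - 1
    mean_r2 = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    r2 = linked["r2"].to_numpy()
    for b in range(nbins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            mean_r2[b] = r2[sel].mean()

    if len(unlinked):
        base_mean = float(unlinked["r2"].mean())
        base_p80 = float(np.percentile(unlinked["r2"], 80))
        # strict exceedance with a float-noise guard: a bin whose mean equals
        # the 80th percentile (e.g. constant r^2 everywhere) is not elevated
        elevated = (counts > 10) & (mean_r2 > base_p80 + 1e-12)
    else:
        base_mean = base_p80 = None
        elevated = np.zeros(nbins, dtype=bool)
    return LdProfile(edges, mean_r2, counts, elevated, base_mean, base_p80, len(unlinked))


def ld_decay_permutation_test(
    pairs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "spearman",
) -> LdDecayTest:
    """Permutation test for decay of r^2 with distance over linked pairs.

    The statistic is the rank (Spearman; Pearson by flag) correlation of
    r^2 with distance.  The null is built by permuting distances across
    pairs; the one-sided p-value for decay (negative correlation) uses the
    add-one rule p = (1 + #{perm stat <= observed}) / (n_perm + 1).
    """
    linked = pairs[pairs["linked"]]
    if len(linked) < 10:
        raise ValueError("need at least 10 linked pairs for the decay test")
    r2 = linked["r2"].to_numpy()
    dist = linked["distance"].to_numpy()
    if np.allclose(r2, r2[0]):
        return LdDecayTest(0.0, 1.0, n_perm, len(linked), method)

    if method == "spearman":
        x = stats.rankdata(dist)
        y = stats.rankdata(r2)
    elif method == "pearson":
        x, y = dist.astype(float), r2.astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    m = len(x)
    observed = float(x @ y / m)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        if float(x[perm] @ y / m) <= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return LdDecayTest(observed, p, n_perm, m, method)
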