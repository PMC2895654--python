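"""Classical nucleotide-diversity statistics for haploid SNP panels.

Implements Watterson's theta, pairwise nucleotide diversity (pi), Tajima's D,
pairwise-difference matrices, Hudson's Fst, and the two back-of-envelope
genome summaries (mean inter-SNP spacing and expected genome-wide pairwise
SNP differences).

Missing-data policy: pi, pairwise differences and Fst use pairwise deletion
(each strain pair is compared over its jointly non-missing calls, then
rescaled to the surveyed length); theta_W counts sites that are biallelic
among non-missing calls against the full surveyed length; Tajima's D uses
the per-site unbiased heterozygosity sum for its numerator and constants
computed from the panel size n (not per-site n) -- an approximation that is
negligible at the sporadic missingness levels this package targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seqio import MISSING, SnpMatrix

__all__ = [
    "DiversitySummary",
    "PairwiseDiffMatrix",
    "GenomeSummaries",
    "harmonic_number",
    "tajima_constants",
    "watterson_theta",
    "nucleotide_diversity",
    "site_heterozygosity_sum",
    "tajimas_d",
    "pairwise_differences",
    "hudson_fst",
    "genome_summaries",
    "summarize",
]


@dataclass
class PairwiseDiffMatrix:
    """Strain x strain counts of differing sites over jointly callable sites."""

    strains: tuple[str, ...]
    diffs: np.ndarray  # int, symmetric, zero diagonal
    compared: np.ndarray  # jointly non-missing site counts per pair

    def mean_sd(self, group: list[str] | None = None) -> tuple[float, float]:
        """Mean and SD of pairwise difference counts within a strain group."""
        idx = (
            np.arange(len(self.strains))
            if group is None
            else np.array([self.strains.index(s) for s in group])
        )
        iu = np.triu_indices(len(idx), k=1)
        vals = self.diffs[np.ix_(idx, idx)][iu]
        return float(np.mean(vals)), float(np.std(vals, ddof=1))


@dataclass
class DiversitySummary:
    S: int
    L: int
    n: int
    theta_w: float
    pi: float
    tajima_d: float | None
    per_fragment: "object | None" = None  # DataFrame when computed


@dataclass
class GenomeSummaries:
    snp_spacing_bp: float | None
    expected_genome_diffs: float


def harmonic_number(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalization constants a1, a2, b1, b2, c1, c2, e1, e2."""
    if n < 2:
        raise ValueError("Tajima constants require n >= 2")
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def watterson_theta(S: int, n: int, L: float) -> float:
    """Per-site Watterson estimate S / (a_{n-1} * L)."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    if L <= 0:
        raise ValueError("surveyed length must be positive")
    return S / (harmonic_number(n - 1) * L)


def _pair_diffs(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise difference and jointly-callable counts.

    Returns (diffs, compared), both (n x n) symmetric with zero diagonals.
    """
    called = genotypes != MISSING  # S x n
    g = genotypes.astype(np.int16)
    n = genotypes.shape[1]
    diffs = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for a in range(n):
        both = called[:, a][:, None] & called  # S x n
        ne = (g[:, a][:, None] != g) & both
        diffs[a] = ne.sum(axis=0)
        comp[a] = both.sum(axis=0)
    np.fill_diagonal(diffs, 0)
    np.fill_diagonal(comp, 0)
    return diffs, comp


def pairwise_differences(matrix: SnpMatrix) -> PairwiseDiffMatrix:
    """Pairwise SNP difference counts with pairwise deletion of missing calls."""
    diffs, comp = _pair_diffs(matrix.genotypes)
    return PairwiseDiffMatrix(matrix.strains, diffs, comp)


def _scaled_pair_rates(matrix: SnpMatrix) -> np.ndarray:
    """Per-pair difference counts rescaled for missingness at assayed sites.

    Pairs with zero jointly-callable sites are NaN (excluded with a warning
    by callers).  When nothing is missing this is simply the raw count.
    """
    diffs, comp = _pair_diffs(matrix.genotypes)
    S = matrix.s
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(comp > 0, diffs * (S / np.maximum(comp, 1)), np.nan)
    np.fill_diagonal(scaled, 0.0)
    return scaled


def nucleotide_diversity(matrix: SnpMatrix, L: float) -> float:
    """Mean per-site pairwise diversity pi, pairwise deletion for missing data.

    Each pair's difference count over jointly callable assayed sites is
    rescaled to the surveyed length ``L``; pi is the mean over all strain
    pairs.  Identical strains give 0; the result is invariant under strain
    relabeling.
    """
    if matrix.n < 2:
        raise ValueError("nucleotide_diversity requires n >= 2")
    if matrix.s == 0:
        return 0.0
    scaled = _scaled_pair_rates(matrix)
    iu = np.triu_indices(matrix.n, k=1)
    vals = scaled[iu]
    if np.isnan(vals).any():
        warnings.warn(
            f"{int(np.isnan(vals).sum())} strain pair(s) share no callable sites; excluded"
        )
        vals = vals[~np.isnan(vals)]
    return float(np.mean(vals) / L)


def site_heterozygosity_sum(matrix: SnpMatrix) -> float:
    """Sum over sites of unbiased heterozygosity 2k(m-k)/(m(m-1)).

    With no missing data this equals the mean pairwise difference count;
    it is the numerator quantity used for Tajima's D.
    """
    k = matrix.minor_counts().astype(float)
    m = matrix.callable_counts().astype(float)
    ok = m >= 2
    return float(np.sum(2.0 * k[ok] * (m[ok] - k[ok]) / (m[ok] * (m[ok] - 1.0))))


def tajimas_d(matrix: SnpMatrix, L: float | None = None) -> float | None:
    """Tajima's D; ``None`` when S = 0 (undefined for invariant data).

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the 1989 constants
    computed from the panel n.  ``L`` is accepted for interface symmetry but
    cancels out of the statistic.
    """
    S = matrix.s
    if S == 0:
        return None
    consts = tajima_constants(matrix.n)
    pi_total = site_heterozygosity_sum(matrix)
    var = consts["e1"] * S + consts["e2"] * S * (S - 1)
    return float((pi_total - S / consts["a1"]) / np.sqrt(var))


def hudson_fst(
    matrix: SnpMatrix, group1: list[str], group2: list[str]
) -> float | None:
    """Hudson's Fst = 1 - Hw/Hb between two strain groups.

    Hw averages the two groups' mean within-group pairwise diversity; Hb is
    the mean between-group diversity.  Returns ``None`` when Hb = 0
    (undefined).  Pairwise deletion for missing calls.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 strains")
    scaled = _scaled_pair_rates(matrix)
    idx1 = np.array([matrix.strains.index(s) for s in group1])
    idx2 = np.array([matrix.strains.index(s) for s in group2])

    def group_mean(ix, iy, within):
        block = scaled[np.ix_(ix, iy)]
        if within:
            iu = np.triu_indices(len(ix), k=1)
            vals = block[iu]
        else:
            vals = block.ravel()
        return float(np.nanmean(vals))

    hw = 0.5 * (group_mean(idx1, idx1, True) + group_mean(idx2, idx2, True))
    hb = group_mean(idx1, idx2, False)
    if hb == 0:
        return None
    return 1.0 - hw / hb


def genome_summaries(
    S: int, L: float, genome_size: float, pi: float
) -> GenomeSummaries:
    """Mean inter-SNP spacing (L/S) and expected genome-wide pairwise diffs.

    The expected difference count between two random strains over the whole
    genome is pi * genome_size; spacing is undefined (None) when S = 0.
    """
    spacing = L / S if S > 0 else None
    return GenomeSummaries(spacing, pi * genome_size)


def summarize(
    matrix: SnpMatrix,
    L: int,
    fragment_lengths: "dict[str, int] | None" = None,
    fragment_of_site: "np.ndarray | None" = None,
) -> DiversitySummary:
    """Pooled diversity summary; optional per-fragment breakdown.

    Pooled values use totals (S and L summed over fragments); the optional
    per-fragment table recomputes theta_W, pi and D per fragment for
    histogram-style views.
    """
    import pandas as pd

    theta = watterson_theta(matrix.s, matrix.n, L) if matrix.s else 0.0
    pi = nucleotide_diversity(matrix, L) if matrix.s else 0.0
    d = tajimas_d(matrix, L)
    per_frag = None
    if fragment_lengths is not None and fragment_of_site is not None:
        rows = []
        for fid, flen in fragment_lengths.items():
            idx = np.flatnonzero(fragment_of_site == fid)
            sub = matrix.take_sites(idx)
            rows.append(
                {
                    "fragment_id": fid,
                    "S": sub.s,
                    "L": flen,
                    "theta_w": watterson_theta(sub.s, matrix.n, flen) if sub.s else 0.0,
                    "pi": nucleotide_diversity(sub, flen) if sub.s else 0.0,
                    "tajima_d": tajimas_d(sub, flen),
                }
            )
        per_frag = pd.DataFrame(rows)
    return DiversitySummary(matrix.s, L, matrix.n, theta, pi, d, per_frag)
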