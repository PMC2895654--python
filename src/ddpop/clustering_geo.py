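"""Strain clustering and geographic structure.

Kimura two-parameter distances on the concatenated fragments, unrooted
neighbor joining with column-bootstrap support, great-circle geographic
distances between collection sites, and a Mantel test for isolation by
distance.

Neighbor joining itself delegates to scikit-bio's Saitou-Nei
implementation (negative branch lengths are clamped to zero with the
deficit moved to the sibling edge); everything around it -- K2P, the
bootstrap, bipartition supports, haversine, Mantel -- is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import TreeNode, nj

from .seqio import Concatenation, StrainTable

__all__ = [
    "DistanceResult",
    "StrainTree",
    "EARTH_RADIUS_KM",
    "k2p_distance",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "haversine_km",
    "geographic_distances",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DistanceResult:
    matrix: SkbioDistanceMatrix
    metric: str  # "K2P" | "SNP-count" | "geographic-km"
    undefined_pairs: list[tuple[str, str]]


@dataclass
class StrainTree:
    tree: TreeNode  # unrooted topology with branch lengths
    supports: dict[frozenset, float] | None = None  # bipartition -> % of replicates


def _alignment_arrays(concat: Concatenation) -> tuple[list[str], np.ndarray]:
    strains = list(concat.strains)
    arr = np.array(
        [np.frombuffer(concat.sequences[s].encode(), dtype="S1") for s in strains]
    ).astype("U1")
    return strains, arr


def _k2p_from_columns(arr: np.ndarray, weights: np.ndarray | None = None):
    """K2P distances given a (strain x column) array; optional per-column
    multiplicities (bootstrap reweighting).  Returns (dist, undefined)."""
    n = arr.shape[0]
    if weights is None:
        weights = np.ones(arr.shape[1])
    valid = ~np.isin(arr, ("N", "-"))
    purine = np.isin(arr, ("A", "G"))
    dist = np.zeros((n, n))
    undefined = []
    for a in range(n):
        for b in range(a + 1, n):
            both = valid[a] & valid[b]
            w = weights * both
            total = w.sum()
            if total == 0:
                dist[a, b] = dist[b, a] = np.nan
                undefined.append((a, b))
                continue
            diff = (arr[a] != arr[b]) & both
            transition = diff & (purine[a] == purine[b])
            P = float((w * transition).sum() / total)
            Q = float((w * (diff & ~transition)).sum() / total)
            x1, x2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if x1 <= 0 or x2 <= 0:
                dist[a, b] = dist[b, a] = np.nan
                undefined.append((a, b))
            else:
                d = -0.5 * np.log(x1) - 0.25 * np.log(x2)
                dist[a, b] = dist[b, a] = d
    return dist, undefined


def k2p_distance(concat: Concatenation) -> DistanceResult:
    """Kimura two-parameter distance over jointly non-missing columns.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P/Q the transition/
    transversion proportions.  Saturated pairs (non-positive log argument)
    are reported undefined rather than silently dropped.
    """
    strains, arr = _alignment_arrays(concat)
    dist, undef = _k2p_from_columns(arr)
    named_undef = [(strains[a], strains[b]) for a, b in undef]
    if named_undef:
        # skbio requires finite entries; callers must handle undefined pairs
        dist = np.nan_to_num(dist, nan=0.0)
    return DistanceResult(SkbioDistanceMatrix(dist, ids=strains), "K2P", named_undef)


def neighbor_joining(dist: DistanceResult | SkbioDistanceMatrix) -> StrainTree:
    """Saitou-Nei neighbor joining; errors if any pair was undefined."""
    if isinstance(dist, DistanceResult):
        if dist.undefined_pairs:
            raise ValueError(
                f"distances undefined for pairs {dist.undefined_pairs}; cannot build tree"
            )
        dm = dist.matrix
    else:
        dm = dist
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 strains")
    return StrainTree(nj(dm))


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    frozenset of leaf names on the smaller side (ties: lexicographic)."""
    leaves = frozenset(l.name for l in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (
            len(side) == len(other) and sorted(side) < sorted(other)
        ):
            parts.add(side)
        else:
            parts.add(other)
    return parts


def bootstrap_support(
    concat: Concatenation, replicates: int = 1000, seed: int | None = None
) -> StrainTree:
    """Column bootstrap of the concatenation (fragment boundaries ignored).

    Support for each internal bipartition of the full-data NJ tree is the
    percentage of replicate NJ trees containing it.  Identical alignment
    columns are collapsed to patterns, so each replicate reduces to a
    multinomial reweighting -- bit-identical to naive column resampling for
    a fixed seed but far cheaper on long concatenations.
    """
    strains, arr = _alignment_arrays(concat)
    patterns, inverse = np.unique(arr, axis=1, return_inverse=True)
    base_counts = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
    L = arr.shape[1]

    dist, undef = _k2p_from_columns(patterns, base_counts)
    if undef:
        raise ValueError("undefined K2P distances; cannot bootstrap")
    reference = nj(SkbioDistanceMatrix(dist, ids=strains))
    ref_parts = bipartitions(reference)
    hits = {part: 0 for part in ref_parts}

    rng = np.random.default_rng(seed)
    probs = base_counts / L
    for _ in range(replicates):
        weights = rng.multinomial(L, probs).astype(float)
        bdist, bundef = _k2p_from_columns(patterns, weights)
        if bundef:
            continue
        btree = nj(SkbioDistanceMatrix(bdist, ids=strains))
        bparts = bipartitions(btree)
        for part in ref_parts & bparts:
            hits[part] += 1
    supports = {p: 100.0 * h / replicates for p, h in hits.items()}
    for node in reference.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        leaves = frozenset(l.name for l in reference.tips())
        key = side if side in supports else (leaves - side)
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return StrainTree(reference, supports)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distances(
    table: StrainTable, within_site_km: float = 1.0
) -> DistanceResult:
    """Great-circle strain-to-strain distances.

    Pairs sharing a collection-site name get the fixed within-site
    distance (default 1 km), generalizing the convention of assigning a
    nominal 1 km to strains from the single densely sampled station.
    Strains with missing coordinates are rejected by name.
    """
    df = table.frame
    missing = df[df["latitude"].isna() | df["longitude"].isna()]["strain_id"].tolist()
    if missing:
        raise ValueError(f"missing coordinates for strains {missing}")
    ids = list(df["strain_id"])
    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()
    site = df["site_name"].to_numpy()
    n = len(ids)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if site[a] == site[b]:
                d = within_site_km
            else:
                d = haversine_km(lat[a], lon[a], lat[b], lon[b])
            dist[a, b] = dist[b, a] = d
    return DistanceResult(SkbioDistanceMatrix(dist, ids=ids), "geographic-km", [])


def mantel_test(
    genetic: DistanceResult | SkbioDistanceMatrix,
    geographic: DistanceResult | SkbioDistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over upper-triangle entries; the null is
    built by jointly permuting rows/columns (strain labels) of one matrix;
    the one-sided p-value for positive association uses the add-one rule.
    Matrices must share the same strain set (matched by id).
    """
    dm1 = genetic.matrix if isinstance(genetic, DistanceResult) else genetic
    dm2 = geographic.matrix if isinstance(geographic, DistanceResult) else geographic
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("strain sets differ between matrices")
    order = list(dm1.ids)
    m1 = dm1.data
    m2 = dm2.filter(order).data
    iu = np.triu_indices(len(order), k=1)
    x = m1[iu]
    if np.allclose(x, x[0]) or np.allclose(m2[iu], m2[iu][0]):
        raise ValueError("constant distance matrix; Mantel r undefined")

    def corr(perm: np.ndarray) -> float:
        y = m2[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(x, y)[0, 1])

    identity = np.arange(len(order))
    observed = corr(identity)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if corr(rng.permutation(identity)) >= observed:
            count += 1
    return observed, (1 + count) / (n_perm + 1)
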