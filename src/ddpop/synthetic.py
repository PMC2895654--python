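"""Synthetic data with the statistical structure of a fragment re-sequencing
study of wild haploid strains.

The centerpiece is a Hudson coalescent with recombination (ancestral
recombination graph, infinite-sites mutation), implemented directly so its
behavior is fully controlled by explicit parameters and seeds.  On top of it,
:func:`simulate_study_design` emulates the sampling layout the analyses
assume: 25 strains, 137 gene fragments of 400-600 bp (94 on a densely
sampled chromosome at a mean adjacent spacing of 55.6 kb within a
2.3-233.7 kb range, the remaining 43 spread over the other five
chromosomes), a per-site diversity target of about 0.0008, and sporadic
missing data.

Time is scaled so a pair of lineages coalesces at rate 1 (units of 2N
generations for haploid effective size N).  Mutation is placed at rate
``theta_site / 2`` per bp per lineage per unit time, giving E[pi] =
``theta_site`` per bp; recombination acts at ``rho_total / span / 2`` per bp
per lineage, so ``rho_total`` is the scaled recombination rate of the whole
simulated span, 2Nr(1-F) in the compound-parameter sense.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqio import CHROMOSOMES, MISSING, FragmentAlignment, SnpMatrix, StrainTable
from .social import ChimeraExperiment

__all__ = [
    "SimParams",
    "ChimeraSimParams",
    "StudyData",
    "simulate_coalescent",
    "matrix_from_haplotypes",
    "simulate_study_design",
    "inject_missing",
    "simulate_chimera",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimParams:
    """Study-design generator parameters.

    Defaults are the study conditions themselves: 25 strains, per-site
    scaled mutation rate 0.0008 (the diversity level the panel shows),
    a dense chromosome-4 layout of 94 fragments at 55.6 kb mean spacing,
    43 fragments elsewhere, scaled recombination 40 for the dense region
    (the order of the composite-likelihood estimate), and 2% sporadically
    missing calls.
    """

    n: int = 25
    theta_site: float = 0.0008
    rho_dense: float = 40.0
    missing_rate: float = 0.02
    seed: int = 0
    n_fragments_dense: int = 94
    n_fragments_other: int = 43
    fragment_length_range: tuple[int, int] = (400, 600)
    spacing_range_bp: tuple[float, float] = (2_300.0, 108_900.0)
    spacing_mean_bp: float = 55_600.0
    spacing_max_bp: float = 233_700.0
    dense_chromosome: str = "chr4"
    n_dense_site_strains: int = 13
    transversion_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 strains")
        if self.theta_site < 0 or self.rho_dense < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class ChimeraSimParams:
    """Chimera-assay generator: clonal/mixed fruiting-body mixture model.

    With probability ``segregation`` a fruiting body is clonal (all cells
    one strain, chosen with probability ``p_o``); otherwise it reflects the
    initial mix exactly.  Truncated-Gaussian measurement noise ``sigma`` is
    then applied per marker and clipped to [0, 1].  Under the implemented
    relatedness statistic the expectation equals ``segregation`` itself,
    giving an interpretable recovery target.
    """

    p_o: float = 0.5
    n_fruiting_bodies: int = 16
    replicates: int = 3
    segregation: float = 0.0
    sigma: float = 0.0
    seed: int = 0
    pair: tuple[str, str] = ("strainA", "strainB")
    markers: tuple[str, ...] = ("m1", "m2")

    def __post_init__(self) -> None:
        if not (0 <= self.p_o <= 1 and 0 <= self.segregation <= 1):
            raise ValueError("p_o and segregation must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class StudyData:
    """Output bundle of :func:`simulate_study_design`."""

    fragments: list[FragmentAlignment]
    coords: pd.DataFrame  # fragment_id, chromosome, start, length
    strains: StrainTable
    truth: dict


class _Lineage:
    """An ancestral lineage: disjoint intervals of (start, end, sample bitmask)."""

    __slots__ = ("intervals", "left", "right", "links", "pieces", "cum", "wlen")

    def __init__(self, intervals, windows):
        self.intervals = intervals
        self.left = intervals[0][0]
        self.right = intervals[-1][1]
        self.links = self.right - self.left
        # window-restricted pieces for mutation placement
        pieces = []
        for a, b, m in intervals:
            for wa, wb in windows:
                lo, hi = max(a, wa), min(b, wb)
                if hi > lo:
                    pieces.append((lo, hi, m))
        self.pieces = pieces
        lens = np.array([hi - lo for lo, hi, _ in pieces], dtype=float)
        self.cum = np.cumsum(lens)
        self.wlen = float(self.cum[-1]) if len(lens) else 0.0

    def sample_position(self, rng) -> tuple[float, int]:
        u = rng.random() * self.wlen
        k = int(np.searchsorted(self.cum, u, side="right"))
        k = min(k, len(self.pieces) - 1)
        lo, hi, m = self.pieces[k]
        prev = self.cum[k - 1] if k else 0.0
        return lo + (u - prev), m


def _merge_intervals(ints1, ints2, full_mask):
    """Overlay two interval lists, OR-ing masks; drop MRCA-complete segments."""
    pts = sorted({x for a, b, _ in ints1 + ints2 for x in (a, b)})
    out = []
    for a, b in zip(pts, pts[1:]):
        mid = 0.5 * (a + b)
        m = 0
        for lst in (ints1, ints2):
            for x, y, msk in lst:
                if x <= mid < y:
                    m |= msk
                    break
        if m and m != full_mask:
            if out and out[-1][1] == a and out[-1][2] == m:
                out[-1] = (out[-1][0], b, m)
            else:
                out.append((a, b, m))
    return out


def simulate_coalescent(
    n: int,
    span: float,
    theta_site: float,
    rho_total: float,
    seed: int | np.random.Generator | None = None,
    windows: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Haploid haplotypes under the neutral coalescent with recombination.

    Parameters
    ----------
    n, span : sample size and simulated length in bp.
    theta_site : scaled mutation rate per bp (E[pi] per bp).
    rho_total : scaled recombination rate of the whole span.
    windows : optional half-open [start, end) bp intervals; mutations are
        placed only inside them (ancestry is still simulated over the full
        span, so linkage between windows is preserved).  Default: the whole
        span.

    Returns
    -------
    positions : sorted, unique integer bp positions (0-based).
    genotypes : (sites x n) int8 array, 0 ancestral / 1 derived.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    windows = [(0.0, float(span))] if windows is None else [
        (float(a), float(b)) for a, b in windows
    ]
    full = (1 << n) - 1
    rho_bp = rho_total / span
    lineages = [_Lineage([(0.0, float(span), 1 << i)], windows) for i in range(n)]
    mutations: list[tuple[float, int]] = []

    while lineages:
        k = len(lineages)
        coal_rate = k * (k - 1) / 2.0
        rec_rates = np.array([0.5 * rho_bp * lin.links for lin in lineages])
        total_rec = float(rec_rates.sum())
        total = coal_rate + total_rec
        dt = rng.exponential(1.0 / total)

        # mutation opportunity accrues along every live lineage during dt
        if theta_site > 0:
            for lin in lineages:
                if lin.wlen > 0:
                    n_mut = rng.poisson(0.5 * theta_site * lin.wlen * dt)
                    for _ in range(n_mut):
                        pos, mask = lin.sample_position(rng)
                        mutations.append((pos, mask))

        if rng.random() < coal_rate / total:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            merged = _merge_intervals(a.intervals, b.intervals, full)
            lineages = [lin for t, lin in enumerate(lineages) if t not in (int(i), int(j))]
            if merged:
                lineages.append(_Lineage(merged, windows))
        else:
            # recombination: pick lineage weighted by link length
            probs = rec_rates / total_rec
            i = int(rng.choice(k, p=probs))
            lin = lineages[i]
            bp = lin.left + rng.random() * lin.links
            left, right = [], []
            for a, b, m in lin.intervals:
                if b <= bp:
                    left.append((a, b, m))
                elif a >= bp:
                    right.append((a, b, m))
                else:
                    left.append((a, bp, m))
                    right.append((bp, b, m))
            if left and right:
                lineages[i] = _Lineage(left, windows)
                lineages.append(_Lineage(right, windows))

    mutations.sort(key=lambda t: t[0])
    positions, rows, seen = [], [], set()
    for pos, mask in mutations:
        ip = int(pos)
        if ip in seen:  # infinite sites on a discrete grid: drop rare collisions
            continue
        seen.add(ip)
        positions.append(ip)
        rows.append([(mask >> b) & 1 for b in range(n)])
    if positions:
        return np.asarray(positions, dtype=np.int64), np.asarray(rows, dtype=np.int8)
    return np.zeros(0, dtype=np.int64), np.zeros((0, n), dtype=np.int8)


def matrix_from_haplotypes(
    positions: np.ndarray,
    genotypes: np.ndarray,
    chromosome: str = "chr4",
    strains: tuple[str, ...] | None = None,
    offset: int = 1,
) -> SnpMatrix:
    """Wrap raw 0/1 haplotypes as a major/minor-coded :class:`SnpMatrix`.

    Derived alleles in the majority are flipped so code 1 is always the
    minor allele (alphabetical A/G placeholder nucleotides).  ``offset``
    converts 0-based simulation coordinates to 1-based assembly ones.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8).copy()
    n = genotypes.shape[1]
    strains = strains or tuple(f"s{i + 1:02d}" for i in range(n))
    major = np.full(len(positions), "A", dtype="U1")
    minor = np.full(len(positions), "G", dtype="U1")
    for i in range(len(positions)):
        row = genotypes[i]
        called = row != MISSING
        if row[called].sum() * 2 > called.sum():
            row[called] = 1 - row[called]
            major[i], minor[i] = "G", "A"
    chroms = np.full(len(positions), chromosome, dtype=object)
    return SnpMatrix(
        chroms, np.asarray(positions) + offset, major, minor, genotypes, strains
    )


def _dense_layout(params: SimParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Fragment starts/lengths (bp, 0-based) on the densely sampled chromosome.

    Adjacent spacings are drawn uniformly in ``spacing_range_bp`` and then
    rescaled so their mean is exactly ``spacing_mean_bp`` (respecting the
    stated minimum and maximum by adjusting the largest gap)."""
    nf = params.n_fragments_dense
    lengths = rng.integers(
        params.fragment_length_range[0], params.fragment_length_range[1] + 1, size=nf
    )
    lo, hi = params.spacing_range_bp
    gaps = rng.uniform(lo, hi, size=nf - 1)
    gaps *= params.spacing_mean_bp / gaps.mean()
    gaps = np.clip(gaps, lo, params.spacing_max_bp)
    # restore the exact target mean by moving the residual onto the largest gap
    residual = params.spacing_mean_bp * (nf - 1) - gaps.sum()
    gaps[int(np.argmax(gaps))] += residual
    starts = np.zeros(nf, dtype=np.int64)
    pos = 10_000
    for i in range(nf):
        starts[i] = pos
        pos += int(lengths[i]) + (int(round(gaps[i])) if i < nf - 1 else 0)
    return starts, lengths.astype(np.int64)


def _haplotypes_to_fragment(
    fid: str,
    chromosome: str,
    start0: int,
    length: int,
    site_pos: np.ndarray,
    site_geno: np.ndarray,
    strains: tuple[str, ...],
    rng,
    transversion_fraction: float,
) -> FragmentAlignment:
    """Convert 0/1 haplotypes in a window to a nucleotide alignment.

    The invariant background is AT-rich (about 78% A+T, echoing the
    organism's genome); derived alleles are transitions on the background
    base (transversions optionally injected), keeping substitution-model
    distances well behaved."""
    background = rng.choice(
        np.array(["A", "C", "G", "T"]), size=length, p=[0.39, 0.11, 0.11, 0.39]
    )
    offsets = site_pos - start0
    derived_base = {}
    for off in offsets:
        anc = background[off]
        table = (
            _TRANSVERSION
            if rng.random() < transversion_fraction
            else _TRANSITION
        )
        derived_base[off] = table[anc]
    seqs = {}
    for si, strain in enumerate(strains):
        row = background.copy()
        for j, off in enumerate(offsets):
            if site_geno[j, si] == 1:
                row[off] = derived_base[off]
        seqs[strain] = "".join(row)
    return FragmentAlignment(fid, chromosome, start0 + 1, seqs)


def simulate_study_design(params: SimParams = SimParams()) -> StudyData:
    """Generate a full synthetic study: fragments, coordinates, strains.

    The dense chromosome is simulated as one recombining region with
    mutations restricted to the fragment windows (so inter-fragment linkage
    is real); the remaining fragments are simulated as independent loci --
    their spacings (hundreds of kb) put them far beyond the LD scale, so
    independence is the faithful limit.  Half the strains are assigned to a
    single collection site, the rest spread over distinct sites.
    """
    rng = np.random.default_rng(params.seed)
    strains = tuple(f"s{i + 1:02d}" for i in range(params.n))

    starts, lengths = _dense_layout(params, rng)
    dense_span = int(starts[-1] + lengths[-1] + 10_000)
    windows = [(float(a), float(a + l)) for a, l in zip(starts, lengths)]
    pos, geno = simulate_coalescent(
        params.n, dense_span, params.theta_site, params.rho_dense, rng, windows
    )

    fragments: list[FragmentAlignment] = []
    coords_rows = []
    for i, (a, l) in enumerate(zip(starts, lengths)):
        fid = f"frag{i + 1:03d}"
        in_win = (pos >= a) & (pos < a + l)
        fragments.append(
            _haplotypes_to_fragment(
                fid,
                params.dense_chromosome,
                int(a),
                int(l),
                pos[in_win],
                geno[in_win],
                strains,
                rng,
                params.transversion_fraction,
            )
        )
        coords_rows.append((fid, params.dense_chromosome, int(a) + 1, int(l)))

    # remaining fragments: independent loci spread over the other chromosomes
    others = [c for c in CHROMOSOMES if c != params.dense_chromosome]
    counts = np.full(len(others), params.n_fragments_other // len(others))
    counts[: params.n_fragments_other % len(others)] += 1
    rho_per_bp = params.rho_dense / dense_span
    fi = params.n_fragments_dense
    for chrom, cnt in zip(others, counts):
        cursor = 50_000
        for _ in range(cnt):
            fi += 1
            fid = f"frag{fi:03d}"
            l = int(
                rng.integers(
                    params.fragment_length_range[0], params.fragment_length_range[1] + 1
                )
            )
            fpos, fgeno = simulate_coalescent(
                params.n, float(l), params.theta_site, rho_per_bp * l, rng
            )
            fragments.append(
                _haplotypes_to_fragment(
                    fid, chrom, cursor, l, fpos + cursor, fgeno, strains, rng,
                    params.transversion_fraction,
                )
            )
            coords_rows.append((fid, chrom, cursor + 1, l))
            cursor += l + int(rng.uniform(2e5, 1.2e6))

    if params.missing_rate > 0:
        fragments = inject_missing(fragments, params.missing_rate, rng)

    coords = pd.DataFrame(
        coords_rows, columns=["fragment_id", "chromosome", "start", "length"]
    )
    strain_table = _synthetic_strain_table(params, strains, rng)
    truth = {
        "theta_site": params.theta_site,
        "rho_dense": params.rho_dense,
        "dense_span": dense_span,
        "dense_chromosome": params.dense_chromosome,
        "L_total": int(sum(f.length for f in fragments)),
    }
    return StudyData(fragments, coords, strain_table, truth)


def _synthetic_strain_table(params: SimParams, strains, rng) -> StrainTable:
    n_dense = min(params.n_dense_site_strains, params.n)
    rows = []
    for i, s in enumerate(strains):
        if i < n_dense:
            site, lat, lon = "dense_site", 37.375, -80.522
        else:
            site = f"site_{i - n_dense + 1:02d}"
            lat = float(rng.uniform(30.0, 45.0))
            lon = float(rng.uniform(-97.0, -70.0))
        mt = rng.choice(
            np.array(["matA1", "matA2", "matA3", "unknown"]),
            p=[4 / 24, 8 / 24, 6 / 24, 6 / 24],
        )
        rows.append((s, site, lat, lon, str(mt)))
    return StrainTable(
        pd.DataFrame(
            rows,
            columns=["strain_id", "site_name", "latitude", "longitude", "mating_type"],
        )
    )


def inject_missing(data, rate: float, seed=None):
    """Mask each call independently missing with probability ``rate``.

    Accepts a :class:`SnpMatrix` (calls set to the missing code) or a list
    of :class:`FragmentAlignment` (characters set to ``N``); returns the
    same kind of object.  ``rate`` 0 is the identity.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(data, SnpMatrix):
        geno = data.genotypes.copy()
        mask = rng.random(geno.shape) < rate
        geno[mask] = MISSING
        keep = []
        for i in range(geno.shape[0]):
            vals = {g for g in geno[i] if g != MISSING}
            if len(vals) == 2:
                keep.append(i)
        return SnpMatrix(
            data.chromosomes[keep],
            data.positions[keep],
            data.major[keep],
            data.minor[keep],
            geno[keep],
            data.strains,
        )
    out = []
    for frag in data:
        seqs = {}
        for s, seq in frag.sequences.items():
            chars = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            mask = rng.random(len(chars)) < rate
            chars[mask] = "N"
            seqs[s] = "".join(chars)
        out.append(FragmentAlignment(frag.fragment_id, frag.chromosome, frag.start, seqs))
    return out


def write_study_design(data: StudyData, outdir) -> None:
    """Write a simulated study to disk in the formats the readers consume:
    per-fragment FASTA + coords.tsv + strains.tsv (+ truth.json)."""
    import json
    from pathlib import Path

    from .seqio import write_fragment_alignments, write_strain_table

    outdir = Path(outdir)
    write_fragment_alignments(data.fragments, data.coords, outdir)
    write_strain_table(data.strains, outdir / "strains.tsv")
    (outdir / "truth.json").write_text(json.dumps(data.truth, indent=2) + "\n")


def simulate_chimera(params: ChimeraSimParams = ChimeraSimParams()) -> ChimeraExperiment:
    """Generate one chimeric-mixing experiment under the mixture model.

    Each replicate plate yields ``n_fruiting_bodies`` bodies; a body is
    clonal with probability ``segregation`` (all one strain, picked with
    probability ``p_o``) and otherwise mirrors the initial mix.  Both
    markers measure the same biological proportion with independent
    truncated-Gaussian noise.  The measured initial proportion gets the
    same noise treatment, echoing the before-plating quantification.
    """
    rng = np.random.default_rng(params.seed)

    def noisy(x: float) -> float:
        if params.sigma == 0:
            return float(x)
        return float(np.clip(x + rng.normal(0.0, params.sigma), 0.0, 1.0))

    rows = []
    pair = "-".join(params.pair)
    for rep in range(1, params.replicates + 1):
        p_o_measured = noisy(params.p_o)
        for fb in range(1, params.n_fruiting_bodies + 1):
            if rng.random() < params.segregation:
                p_bio = 1.0 if rng.random() < params.p_o else 0.0
            else:
                p_bio = params.p_o
            for marker in params.markers:
                rows.append(
                    {
                        "pair": pair,
                        "strain_a": params.pair[0],
                        "strain_b": params.pair[1],
                        "marker": marker,
                        "replicate": rep,
                        "fruiting_body": fb,
                        "p_i": noisy(p_bio),
                        "p_o": p_o_measured,
                    }
                )
    return ChimeraExperiment(pd.DataFrame(rows))
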