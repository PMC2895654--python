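"""Readers, writers, and SNP calling for fragment re-sequencing panels.

The study design this package targets is a panel of haploid strains
re-sequenced at many short gene fragments (sequence-tagged sites, STS)
scattered over a six-chromosome genome.  Each fragment is a small multiple
alignment; segregating sites are called per alignment column and assembled
into a genome-wide biallelic SNP matrix with assembly coordinates.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout (genome-browser style).
* ``N`` and the gap character ``-`` are both treated as missing data; a site
  is biallelic with respect to its non-missing calls only.
* Sites with more than two observed alleles are excluded (and counted).
* Fragments are stored on the orientation given in the input FASTA; no
  reverse-complement handling is applied.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CHROMOSOMES",
    "MATING_TYPES",
    "MISSING",
    "FragmentAlignment",
    "SnpMatrix",
    "StrainTable",
    "Concatenation",
    "FragmentReadResult",
    "SnpCallResult",
    "MatingTypeTally",
    "read_fragment_alignments",
    "call_snps",
    "concatenate_alignments",
    "split_concatenation",
    "tally_mating_types",
    "write_snps",
    "read_snps",
    "read_strain_table",
    "write_strain_table",
    "load_mating_type_panel",
]

#: Declared chromosome labels for the 34 Mb, six-chromosome genome.
CHROMOSOMES: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6")

#: Recognized mating-type labels (three cross-compatibility classes plus
#: strains that failed to form macrocysts with either tester).
MATING_TYPES: tuple[str, ...] = ("matA1", "matA2", "matA3", "unknown")

#: Genotype code for a missing call in :class:`SnpMatrix`.
MISSING: int = -1

_MISSING_CHARS = frozenset("N-")
_VALID_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class FragmentAlignment:
    """One gene fragment's multiple alignment plus its assembly placement.

    Parameters
    ----------
    fragment_id : str
        Unique fragment identifier.
    chromosome : str
        One of :data:`CHROMOSOMES`.
    start : int
        1-based assembly coordinate of the first alignment column.
    sequences : dict
        Mapping strain id -> aligned nucleotide string (``A/C/G/T/N/-``),
        all of equal length.
    """

    fragment_id: str
    chromosome: str
    start: int
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"fragment {self.fragment_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if not lengths or lengths == {0}:
            raise ValueError(f"fragment {self.fragment_id}: empty alignment")
        bad = {
            strain
            for strain, seq in self.sequences.items()
            if not set(seq.upper()) <= _VALID_CHARS
        }
        if bad:
            raise ValueError(
                f"fragment {self.fragment_id}: invalid characters in {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def to_array(self, strains: Sequence[str] | None = None) -> np.ndarray:
        """Alignment as a (strain x column) array of single characters."""
        order = list(strains) if strains is not None else list(self.sequences)
        rows = []
        for s in order:
            seq = self.sequences.get(s, "N" * self.length)
            rows.append(np.frombuffer(seq.upper().encode(), dtype="S1"))
        return np.vstack(rows).astype("U1")


@dataclass
class SnpMatrix:
    """Biallelic haploid genotypes at genomic positions.

    ``genotypes`` is a (site x strain) ``int8`` array with 0 = major allele,
    1 = minor allele and :data:`MISSING` (-1) = missing call.  Major/minor
    are assigned by sample frequency (alphabetical tie-break).  Sites are
    sorted by (chromosome, position), coordinates strictly increasing within
    a chromosome.
    """

    chromosomes: np.ndarray
    positions: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    genotypes: np.ndarray
    strains: tuple[str, ...]

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.major = np.asarray(self.major, dtype="U1")
        self.minor = np.asarray(self.minor, dtype="U1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.strains = tuple(self.strains)
        s = len(self.positions)
        if self.genotypes.shape != (s, len(self.strains)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{s} sites x {len(self.strains)} strains"
            )
        for chrom in np.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n(self) -> int:
        """Number of strains."""
        return len(self.strains)

    @property
    def s(self) -> int:
        """Number of segregating sites."""
        return len(self.positions)

    def minor_counts(self) -> np.ndarray:
        return (self.genotypes == 1).sum(axis=1)

    def callable_counts(self) -> np.ndarray:
        return (self.genotypes != MISSING).sum(axis=1)

    def take_sites(self, index: np.ndarray) -> "SnpMatrix":
        index = np.asarray(index)
        return SnpMatrix(
            self.chromosomes[index],
            self.positions[index],
            self.major[index],
            self.minor[index],
            self.genotypes[index],
            self.strains,
        )

    def take_strains(self, strains: Sequence[str]) -> "SnpMatrix":
        idx = [self.strains.index(s) for s in strains]
        sub = SnpMatrix(
            self.chromosomes.copy(),
            self.positions.copy(),
            self.major.copy(),
            self.minor.copy(),
            self.genotypes[:, idx],
            tuple(strains),
        )
        # Restrict to sites still segregating in the subset.
        keep = [
            i
            for i in range(sub.s)
            if len({g for g in sub.genotypes[i] if g != MISSING}) == 2
        ]
        return sub.take_sites(np.asarray(keep, dtype=int))

    def on_chromosome(self, chromosome: str) -> "SnpMatrix":
        return self.take_sites(np.flatnonzero(self.chromosomes == chromosome))


@dataclass
class StrainTable:
    """Strain metadata: collection site, coordinates, mating type.

    Backed by a DataFrame with columns ``strain_id``, ``site_name``,
    ``latitude``, ``longitude``, ``mating_type``.  Coordinates may be NaN
    (geographic operations will refuse such strains explicitly).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["strain_id", "site_name", "latitude", "longitude", "mating_type"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"strain table missing columns {missing}")
        self.frame = self.frame[required].reset_index(drop=True)
        ids = self.frame["strain_id"]
        if ids.duplicated().any():
            raise ValueError(
                f"duplicate strain ids: {sorted(ids[ids.duplicated()])}"
            )
        bad = set(self.frame["mating_type"]) - set(MATING_TYPES)
        if bad:
            raise ValueError(f"unrecognized mating-type labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["strain_id"])

    def sites(self) -> pd.Series:
        return self.frame.set_index("strain_id")["site_name"]


@dataclass
class Concatenation:
    """Concatenated fragment alignments with an invertible boundary map."""

    sequences: dict[str, str]
    boundaries: list[tuple[str, int, int]]  # (fragment_id, start_col, end_col) 0-based half-open
    fragment_meta: dict[str, tuple[str, int]]  # fragment_id -> (chromosome, start)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def locate(self, column: int) -> tuple[str, int]:
        """Map a 0-based concatenation column to (fragment_id, 0-based offset)."""
        for fid, a, b in self.boundaries:
            if a <= column < b:
                return fid, column - a
        raise IndexError(f"column {column} outside concatenation of length {self.length}")


@dataclass
class FragmentReadResult:
    fragments: list[FragmentAlignment]
    rejected: dict[str, str] = field(default_factory=dict)


@dataclass
class SnpCallResult:
    matrix: SnpMatrix
    n_multiallelic: int
    n_columns_scanned: int


@dataclass
class MatingTypeTally:
    counts: dict[str, int]
    total: int
    assigned: int


def read_fragment_alignments(
    paths: Iterable[str | Path], coords: str | Path
) -> FragmentReadResult:
    """Load per-fragment FASTA alignments and attach assembly coordinates.

    The coordinate table is a TSV with columns ``fragment_id``,
    ``chromosome``, ``start``, ``length``.  A fragment whose sequences are
    not all of equal length is rejected (recorded with a reason) while the
    remaining fragments load normally.  Strains are harmonized across
    fragments: a strain absent from some fragment receives an all-``N``
    sequence there.  Fragments are returned sorted by (chromosome, start).
    """
    coord_df = pd.read_csv(coords, sep="\t", dtype={"fragment_id": str, "chromosome": str})
    required = {"fragment_id", "chromosome", "start", "length"}
    if not required <= set(coord_df.columns):
        raise ValueError(f"coordinate table must have columns {sorted(required)}")
    bad_chrom = set(coord_df["chromosome"]) - set(CHROMOSOMES)
    if bad_chrom:
        raise ValueError(f"unknown chromosome labels in coordinate table: {sorted(bad_chrom)}")
    coord_map = {
        r.fragment_id: (r.chromosome, int(r.start)) for r in coord_df.itertuples()
    }

    raw: list[tuple[str, dict[str, str]]] = []
    rejected: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        fid = path.stem
        if fid not in coord_map:
            raise ValueError(f"fragment {fid} absent from coordinate table")
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            rejected[fid] = "no sequences parsed"
            continue
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            rejected[fid] = f"unequal sequence lengths {sorted(lengths)}"
            continue
        raw.append((fid, seqs))

    all_strains = sorted({s for _, seqs in raw for s in seqs})
    fragments = []
    for fid, seqs in raw:
        chrom, start = coord_map[fid]
        length = len(next(iter(seqs.values())))
        harmonized = {s: seqs.get(s, "N" * length) for s in all_strains}
        fragments.append(FragmentAlignment(fid, chrom, start, harmonized))
    fragments.sort(key=lambda f: (CHROMOSOMES.index(f.chromosome), f.start))
    return FragmentReadResult(fragments, rejected)


def call_snps(fragments: Sequence[FragmentAlignment]) -> SnpCallResult:
    """Call biallelic SNPs from fragment alignments.

    A column is a SNP when exactly two distinct nucleotides occur among its
    non-missing calls (gaps and ``N`` are missing).  Columns with three or
    more alleles are excluded and counted.  Singletons are retained; any
    minor-allele-frequency filtering happens downstream.  The result is
    invariant under strain and fragment reordering.
    """
    if not fragments:
        raise ValueError("no fragments supplied")
    strains = sorted({s for f in fragments for s in f.sequences})
    if len(strains) < 2:
        raise ValueError("need at least 2 strains to call SNPs")

    bases = np.array(["A", "C", "G", "T"])
    records = []  # (chrom_rank, pos, chrom, major, minor, genotype row)
    n_multi = 0
    n_cols = 0
    for frag in fragments:
        arr = frag.to_array(strains)  # strains x columns
        n_cols += arr.shape[1]
        # per-column allele counts over the 4 nucleotides (gaps/N drop out)
        counts = np.stack([(arr == b).sum(axis=0) for b in bases])  # 4 x L
        n_alleles = (counts > 0).sum(axis=0)
        n_multi += int((n_alleles > 2).sum())
        for col in np.flatnonzero(n_alleles == 2):
            present = np.flatnonzero(counts[:, col] > 0)
            a, b = bases[present[0]], bases[present[1]]
            # major by count; alphabetical tie-break for determinism
            if counts[present[1], col] > counts[present[0], col]:
                major, minor = b, a
            else:
                major, minor = a, b
            row = np.full(len(strains), MISSING, dtype=np.int8)
            obs = arr[:, col]
            row[obs == major] = 0
            row[obs == minor] = 1
            pos = frag.start + col  # 1-based: column 0 is at `start`
            records.append(
                (CHROMOSOMES.index(frag.chromosome), int(pos), frag.chromosome, major, minor, row)
            )

    records.sort(key=lambda r: (r[0], r[1]))
    if records:
        chroms = np.array([r[2] for r in records], dtype=object)
        pos = np.array([r[1] for r in records], dtype=np.int64)
        major = np.array([r[3] for r in records], dtype="U1")
        minor = np.array([r[4] for r in records], dtype="U1")
        geno = np.vstack([r[5] for r in records])
    else:
        chroms = np.array([], dtype=object)
        pos = np.array([], dtype=np.int64)
        major = np.array([], dtype="U1")
        minor = np.array([], dtype="U1")
        geno = np.zeros((0, len(strains)), dtype=np.int8)
    matrix = SnpMatrix(chroms, pos, major, minor, geno, tuple(strains))
    return SnpCallResult(matrix, n_multi, n_cols)


def concatenate_alignments(fragments: Sequence[FragmentAlignment]) -> Concatenation:
    """Concatenate fragment alignments into a single super-alignment.

    The boundary map records each fragment's 0-based half-open column range
    and is invertible via :meth:`Concatenation.locate` /
    :func:`split_concatenation`.
    """
    if not fragments:
        raise ValueError("nothing to concatenate")
    strains = sorted({s for f in fragments for s in f.sequences})
    parts: dict[str, list[str]] = {s: [] for s in strains}
    boundaries = []
    meta = {}
    offset = 0
    for frag in fragments:
        for s in strains:
            parts[s].append(frag.sequences.get(s, "N" * frag.length))
        boundaries.append((frag.fragment_id, offset, offset + frag.length))
        meta[frag.fragment_id] = (frag.chromosome, frag.start)
        offset += frag.length
    return Concatenation({s: "".join(parts[s]) for s in strains}, boundaries, meta)


def split_concatenation(concat: Concatenation) -> list[FragmentAlignment]:
    """Invert :func:`concatenate_alignments` using the boundary map."""
    out = []
    for fid, a, b in concat.boundaries:
        chrom, start = concat.fragment_meta[fid]
        out.append(
            FragmentAlignment(
                fid, chrom, start, {s: seq[a:b] for s, seq in concat.sequences.items()}
            )
        )
    return out


def tally_mating_types(table: StrainTable) -> MatingTypeTally:
    """Count strains per mating-type label.

    ``assigned`` is the number of strains with a definite label, i.e. the
    table size minus the ``unknown`` count.  Label validity is enforced by
    :class:`StrainTable` itself.
    """
    counts = {label: 0 for label in MATING_TYPES}
    for label in table.frame["mating_type"]:
        counts[label] += 1
    total = len(table)
    return MatingTypeTally(counts, total, total - counts["unknown"])


def write_snps(matrix: SnpMatrix, path: str | Path) -> None:
    """Export a SNP matrix as an uncompressed VCF v4.2 file (haploid GT)."""
    for chrom in np.unique(matrix.chromosomes):
        pos = matrix.positions[matrix.chromosomes == chrom]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted positions on {chrom}; refusing to write VCF")
    lines = ["##fileformat=VCFv4.2", "##source=ddpop"]
    for chrom in CHROMOSOMES:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(matrix.strains)
    lines.append("\t".join(header))
    for i in range(matrix.s):
        gts = [
            "." if g == MISSING else str(int(g)) for g in matrix.genotypes[i]
        ]
        lines.append(
            "\t".join(
                [
                    str(matrix.chromosomes[i]),
                    str(int(matrix.positions[i])),
                    ".",
                    str(matrix.major[i]),
                    str(matrix.minor[i]),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snps(path: str | Path) -> SnpMatrix:
    """Read a haploid VCF (as written by :func:`write_snps`) via pysam."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        strains = tuple(vcf.header.samples)
        chroms, pos, major, minor, rows = [], [], [], [], []
        for rec in vcf:
            chroms.append(rec.chrom)
            pos.append(rec.pos)
            major.append(rec.ref)
            minor.append(rec.alts[0] if rec.alts else ".")
            row = np.full(len(strains), MISSING, dtype=np.int8)
            for k, s in enumerate(strains):
                gt = rec.samples[s]["GT"]
                if gt and gt[0] is not None:
                    row[k] = gt[0]
            rows.append(row)
    geno = np.vstack(rows) if rows else np.zeros((0, len(strains)), dtype=np.int8)
    return SnpMatrix(
        np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(major, dtype="U1"),
        np.array(minor, dtype="U1"),
        geno,
        strains,
    )


def write_fragment_alignments(
    fragments: Sequence[FragmentAlignment],
    coords: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Write per-fragment FASTA files plus the coordinate table TSV.

    Inverse of :func:`read_fragment_alignments` (file stems are fragment
    ids); used by the synthetic-study writer and round-trip tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for frag in fragments:
        lines = []
        for strain, seq in frag.sequences.items():
            lines.append(f">{strain}")
            lines.append(seq)
        (outdir / f"{frag.fragment_id}.fasta").write_text("\n".join(lines) + "\n")
    coords.to_csv(outdir / "coords.tsv", sep="\t", index=False)


def read_strain_table(path: str | Path) -> StrainTable:
    """Read strain metadata TSV (strain_id, site, lat, lon, mating_type)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "site_name": str})
    return StrainTable(df)


def write_strain_table(table: StrainTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_mating_type_panel() -> StrainTable:
    """The 24-strain mating-type panel shipped with the package.

    Coordinates are not part of the assay record and are left NaN; the
    table supports :func:`tally_mating_types` and site-based grouping.
    """
    ref = importlib.resources.files("ddpop") / "data" / "mating_types.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    df["latitude"] = np.nan
    df["longitude"] = np.nan
    return StrainTable(df)
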