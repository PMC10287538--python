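"""Polarized haplotype matrices and I/O (ms format, VCF, genetic maps).

The substrate of every statistic in this package is a binary haplotype
matrix: rows are phased chromosomes, columns are biallelic sites coded
0 = ancestral allele, 1 = derived allele, with strictly increasing
physical positions on a locus of known length.  Coordinates are 0-based
half-open internally; VCF's 1-based convention is converted at the
boundary only.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np


class MsParseError(ValueError):
    """Raised when an ms-style stream is structurally malformed."""


@dataclass
class HaplotypeMatrix:
    """Phased, polarized haplotypes at segregating sites.

    Parameters
    ----------
    alleles
        ``(n_haplotypes, n_sites)`` array of 0 (ancestral) / 1 (derived).
    positions
        Physical bp coordinates, strictly increasing, in ``[0, locus_length)``.
    locus_length
        Length of the locus in bp.
    sample_labels
        Optional per-haplotype identifiers.
    """

    alleles: np.ndarray
    positions: np.ndarray
    locus_length: int
    sample_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.int8))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError(
                f"{self.alleles.shape[1]} allele columns but "
                f"{self.positions.shape[0]} positions"
            )
        bad = (self.alleles != 0) & (self.alleles != 1)
        if bad.any():
            raise ValueError("alleles must contain only 0 (ancestral) and 1 (derived)")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 0 or self.positions[-1] >= self.locus_length:
                raise ValueError("positions must lie in [0, locus_length)")
        if self.locus_length <= 0:
            raise ValueError("locus_length must be positive")
        if self.sample_labels is not None and len(self.sample_labels) != self.n_haplotypes:
            raise ValueError("sample_labels length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Per-site derived allele counts."""
        return self.alleles.sum(axis=0).astype(np.int64)

    def derived_freqs(self) -> np.ndarray:
        """Per-site derived allele frequencies."""
        return self.derived_counts() / self.n_haplotypes

    def window(self, start: int, end: int) -> "HaplotypeMatrix":
        """Sub-matrix of sites with ``start <= pos < end`` (positions kept absolute)."""
        keep = (self.positions >= start) & (self.positions < end)
        return HaplotypeMatrix(
            self.alleles[:, keep],
            self.positions[keep],
            self.locus_length,
            self.sample_labels,
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.locus_length == other.locus_length
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class GeneticMap:
    """Piecewise-linear physical (bp) -> genetic (cM) map.

    Built from a 2-column table of (position_bp, cM) or (position_bp, cM/Mb);
    with the rate dialect the cumulative map is integrated trapezoidally.
    A uniform map is the default throughout the package.
    """

    pos_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.pos_bp.shape != self.cm.shape or self.pos_bp.ndim != 1:
            raise ValueError("map columns must be 1-D and equal length")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")

    @classmethod
    def uniform(cls, locus_length: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(
            np.array([0.0, float(locus_length)]),
            np.array([0.0, cm_per_mb * locus_length / 1e6]),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, dialect: str = "cM") -> "GeneticMap":
        """Load a 2-column TSV: position_bp and cM (``dialect='cM'``) or
        cM/Mb (``dialect='cM/Mb'``)."""
        arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
        pos, val = arr[:, 0], arr[:, 1]
        if dialect == "cM":
            return cls(pos, val)
        if dialect == "cM/Mb":
            # integrate rate to a cumulative map (trapezoid)
            seg = np.diff(pos) * (val[:-1] + val[1:]) / 2.0 / 1e6
            return cls(pos, np.concatenate([[0.0], np.cumsum(seg)]))
        raise ValueError(f"unknown map dialect {dialect!r}")

    def at(self, pos_bp: np.ndarray | float) -> np.ndarray | float:
        """Genetic position (cM) at physical position(s), linear interpolation."""
        return np.interp(pos_bp, self.pos_bp, self.cm)


# ---------------------------------------------------------------------------
# ms-style format
# ---------------------------------------------------------------------------

def read_ms(source: str | Path | io.TextIOBase, locus_length: int) -> list[HaplotypeMatrix]:
    """Parse ms/msms/discoal-style output into one matrix per replicate.

    Positions on [0, 1] are rescaled by ``locus_length`` and rounded to the
    nearest bp; duplicates arising from rounding are jittered by +1 bp to
    keep positions strictly increasing.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    out: list[HaplotypeMatrix] = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        # segsites line
        while i < n and not lines[i].strip():
            i += 1
        if i >= n or not lines[i].startswith("segsites:"):
            raise MsParseError(f"line {i + 1}: expected 'segsites:' after '//'")
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError as e:
            raise MsParseError(f"line {i + 1}: bad segsites value") from e
        i += 1
        if segsites == 0:
            # no positions line; haplotype count unknown from block — emit 2 empty rows
            out.append(
                HaplotypeMatrix(
                    np.zeros((2, 0), dtype=np.int8), np.array([], dtype=np.int64), locus_length
                )
            )
            continue
        while i < n and not lines[i].strip():
            i += 1
        if i >= n or not lines[i].startswith("positions:"):
            raise MsParseError(f"line {i + 1}: expected 'positions:'")
        rel = np.array(lines[i].split()[1:], dtype=np.float64)
        if rel.size != segsites:
            raise MsParseError(
                f"line {i + 1}: {rel.size} positions but segsites: {segsites}"
            )
        i += 1
        rows = []
        while i < n and lines[i].strip() and re.fullmatch(r"[01]+", lines[i].strip()):
            row = lines[i].strip()
            if len(row) != segsites:
                raise MsParseError(
                    f"line {i + 1}: haplotype width {len(row)} != segsites {segsites}"
                )
            rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
            i += 1
        if len(rows) < 2:
            raise MsParseError(f"line {i + 1}: replicate has fewer than 2 haplotype rows")
        pos = np.rint(rel * locus_length).astype(np.int64)
        pos = _dedupe_positions(pos, locus_length)
        out.append(HaplotypeMatrix(np.vstack(rows).astype(np.int8), pos, locus_length))
    return out


def _dedupe_positions(pos: np.ndarray, locus_length: int) -> np.ndarray:
    """Jitter duplicate bp positions by +1 to restore strict ordering."""
    pos = pos.copy()
    for j in range(1, pos.size):
        if pos[j] <= pos[j - 1]:
            pos[j] = pos[j - 1] + 1
    if pos.size and pos[-1] >= locus_length:
        # pushed past the end: clamp from the right preserving strict order
        pos[-1] = locus_length - 1
        for j in range(pos.size - 2, -1, -1):
            if pos[j] >= pos[j + 1]:
                pos[j] = pos[j + 1] - 1
    return pos


def write_ms(matrices: Iterable[HaplotypeMatrix], stream: io.TextIOBase, header: str = "sweepnet") -> None:
    """Write replicates as an ms-style stream (positions scaled to [0, 1])."""
    stream.write(header + "\n\n")
    for m in matrices:
        stream.write("//\n")
        stream.write(f"segsites: {m.n_sites}\n")
        if m.n_sites:
            rel = m.positions / m.locus_length
            stream.write("positions: " + " ".join(f"{p:.8f}" for p in rel) + "\n")
            for row in m.alleles:
                stream.write("".join("1" if a else "0" for a in row) + "\n")
        stream.write("\n")


def write_ms_file(matrices: Iterable[HaplotypeMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        write_ms(matrices, fh)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

@dataclass
class VcfReadReport:
    """Bookkeeping from VCF polarization."""

    n_sites: int = 0
    n_dropped_unmatched_aa: int = 0
    n_dropped_missing: int = 0
    n_dropped_multiallelic: int = 0
    n_dropped_no_aa: int = 0
    flipped: int = 0


def read_vcf_region(
    vcf_path: str | Path,
    region: tuple[str, int, int],
    ancestral: str | Path | dict[int, str] | None = None,
    aa_tag: str = "AA",
) -> tuple[HaplotypeMatrix, VcfReadReport]:
    """Read phased biallelic SNPs in a region and polarize to derived/ancestral.

    Parameters
    ----------
    vcf_path
        VCF file (plain or bgzipped).  The file is streamed and filtered, so
        no tabix index is required.
    region
        ``(chrom, start, end)`` with 0-based half-open coordinates.
    ancestral
        Ancestral-allele source: ``None`` to use the ``AA`` INFO tag, a FASTA
        path for a per-base ancestral sequence, or a ``{0-based pos: base}``
        mapping (mainly for tests).

    Returns the polarized matrix (1 = derived) and a drop-count report.
    Sites with any missing allele, multiallelic sites, and sites whose
    ancestral allele matches neither REF nor ALT are dropped and counted.
    Unphased genotypes raise, since every statistic assumes phased haplotypes.
    """
    from cyvcf2 import VCF

    chrom, start, end = region
    anc_lookup = None
    if ancestral is not None and not isinstance(ancestral, dict):
        from pyfaidx import Fasta

        anc_lookup = Fasta(str(ancestral))

    vcf = VCF(str(vcf_path))
    labels: list[str] = []
    for s in vcf.samples:
        labels += [f"{s}_1", f"{s}_2"]
    cols: list[np.ndarray] = []
    positions: list[int] = []
    rep = VcfReadReport()
    for var in vcf:
        if var.CHROM != chrom:
            continue
        pos0 = var.POS - 1  # VCF is 1-based
        if pos0 < start or pos0 >= end:
            continue
        rep.n_sites += 1
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            rep.n_dropped_multiallelic += 1
            continue
        gt = np.array(var.genotypes)  # (n_samples, 3): a, b, phased
        if np.any(gt[:, 2] == 0):
            raise ValueError(f"unphased genotype at {chrom}:{var.POS}; phased data required")
        alleles = gt[:, :2].reshape(-1)
        if np.any(alleles < 0):
            rep.n_dropped_missing += 1
            continue
        if isinstance(ancestral, dict):
            aa = ancestral.get(pos0)
        elif anc_lookup is not None:
            aa = str(anc_lookup[chrom][pos0]).upper()
        else:
            aa = var.INFO.get(aa_tag)
            aa = aa.split("|")[0].upper() if aa else None
        if aa is None or aa in (".", "-", "N"):
            rep.n_dropped_no_aa += 1
            continue
        aa = aa.upper()
        if aa == var.REF.upper():
            col = alleles.astype(np.int8)
        elif aa == var.ALT[0].upper():
            col = (1 - alleles).astype(np.int8)
            rep.flipped += 1
        else:
            rep.n_dropped_unmatched_aa += 1
            continue
        if col.min() == col.max():
            continue  # monomorphic after polarization
        cols.append(col)
        positions.append(pos0)
    if not cols:
        mat = HaplotypeMatrix(
            np.zeros((max(len(labels), 2), 0), dtype=np.int8),
            np.array([], dtype=np.int64),
            end - start if end - start > 0 else 1,
        )
        return mat, rep
    alleles_arr = np.stack(cols, axis=1)
    pos_arr = np.asarray(positions, dtype=np.int64) - start
    mat = HaplotypeMatrix(alleles_arr, pos_arr, end - start, labels or None)
    return mat, rep


# ---------------------------------------------------------------------------
# Mispolarization
# ---------------------------------------------------------------------------

def inject_mispolarization(matrix: HaplotypeMatrix, rate: float, seed: int) -> HaplotypeMatrix:
    """Flip ancestral/derived labels of random sites (whole columns) at ``rate``.

    Emulates polarization error from a misleading outgroup: each site is
    independently mispolarized with probability ``rate``; deterministic
    under ``seed``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    flip = rng.random(matrix.n_sites) < rate
    alleles = matrix.alleles.copy()
    alleles[:, flip] = 1 - alleles[:, flip]
    return HaplotypeMatrix(alleles, matrix.positions, matrix.locus_length, matrix.sample_labels)
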