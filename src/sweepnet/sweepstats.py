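"""New derived/ancestral-background statistics and DAF-binned standardization.

During a sweep the haplotype carrying the adaptive allele hitchhikes to high
frequency, dragging linked variants with it and depleting variation on the
derived background relative to the ancestral background at a focal site.
The statistics here quantify that asymmetry:

* ``hapdaf`` (two flavours, *-o* for older incomplete sweeps and *-s* for
  sweeps from standing variation) compares the frequencies of shared
  flanking variants on the derived vs. ancestral backgrounds,
* ``sratio`` compares the number of segregating sites on the two
  backgrounds,
* ``lowfreq`` / ``highfreq`` measure the excess of rare / high-frequency
  derived alleles on the derived background.

Focal sites are only considered when their derived allele frequency lies in
[0.25, 0.95]; below that there is little power, above it the ancestral
background is too small.  Every per-SNP statistic in the package is made
comparable across focal frequencies by standardizing against the empirical
mean/SD of the same statistic in 2%-wide derived-allele-frequency bins
(50 bins on (0, 1]) estimated from neutral simulations:

    standardized = (value - E_p[value]) / SD_p[value]

with ``p`` the focal variant's frequency bin.

Not-computable values (focal DAF out of range, empty background, S_d = 0)
are returned as NaN, which is distinct from a true 0 and is excluded from
window aggregation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hapdata import HaplotypeMatrix

DAF_RANGE = (0.25, 0.95)
N_BINS = 50

HAPDAF_O_THRESHOLDS = (0.25, 0.25)  # (fa_max, sum_min) for older incomplete sweeps
HAPDAF_S_THRESHOLDS = (0.10, 0.10)  # for sweeps from standing variation


@dataclass(frozen=True)
class FocalSiteContext:
    """A focal variant and its derived/ancestral haplotype backgrounds."""

    focal_index: int
    derived_carriers: np.ndarray  # haplotype row indices carrying the derived allele
    ancestral_carriers: np.ndarray
    focal_daf: float

    @property
    def computable(self) -> bool:
        return DAF_RANGE[0] <= self.focal_daf <= DAF_RANGE[1]


def context_at(matrix: HaplotypeMatrix, focal_index: int) -> FocalSiteContext:
    col = matrix.alleles[:, focal_index]
    der = np.flatnonzero(col == 1)
    anc = np.flatnonzero(col == 0)
    return FocalSiteContext(focal_index, der, anc, der.size / matrix.n_haplotypes)


def focal_contexts(matrix: HaplotypeMatrix) -> list[FocalSiteContext]:
    """Contexts for every site whose DAF lies in the computable range."""
    freqs = matrix.derived_freqs()
    lo, hi = DAF_RANGE
    return [
        context_at(matrix, j)
        for j in range(matrix.n_sites)
        if lo <= freqs[j] <= hi
    ]


def _flank_indices(matrix: HaplotypeMatrix, focal_index: int, half_span_bp: int) -> np.ndarray:
    pos = matrix.positions
    centre = pos[focal_index]
    idx = np.flatnonzero(np.abs(pos - centre) <= half_span_bp)
    return idx[idx != focal_index]


def hapdaf(
    matrix: HaplotypeMatrix,
    context: FocalSiteContext,
    half_span_bp: int = 25_000,
    fa_max: float = 0.25,
    sum_min: float = 0.25,
) -> float:
    """hapDAF = mean over qualifying flanking variants of (f_d^2 - f_a^2).

    A flanking variant qualifies when (all strict): it is present on at
    least one derived and one ancestral background; its frequency on the
    derived background exceeds that on the ancestral background
    (f_d > f_a); f_a < ``fa_max``; and f_d + f_a > ``sum_min``.
    Returns 0.0 when no variant qualifies, NaN when the focal site is
    outside the computable DAF range.
    """
    if not context.computable:
        return float("nan")
    der, anc = context.derived_carriers, context.ancestral_carriers
    nd, na = der.size, anc.size
    total = 0.0
    k = 0
    for i in _flank_indices(matrix, context.focal_index, half_span_bp):
        cd = int(matrix.alleles[der, i].sum())
        ca = int(matrix.alleles[anc, i].sum())
        if cd == 0 or ca == 0:
            continue
        fd, fa = cd / nd, ca / na
        if fd > fa and fa < fa_max and fd + fa > sum_min:
            total += fd * fd - fa * fa
            k += 1
    return total / k if k else 0.0


def hapdaf_o(matrix: HaplotypeMatrix, context: FocalSiteContext, half_span_bp: int = 25_000) -> float:
    return hapdaf(matrix, context, half_span_bp, *HAPDAF_O_THRESHOLDS)


def hapdaf_s(matrix: HaplotypeMatrix, context: FocalSiteContext, half_span_bp: int = 25_000) -> float:
    return hapdaf(matrix, context, half_span_bp, *HAPDAF_S_THRESHOLDS)


def sratio(matrix: HaplotypeMatrix, context: FocalSiteContext, half_span_bp: int = 25_000) -> float:
    """Ratio S_a / S_d of segregating-site counts on the two backgrounds.

    NaN (not computable) when no site segregates on the derived background.
    """
    if not context.computable:
        return float("nan")
    der, anc = context.derived_carriers, context.ancestral_carriers
    s_d = 0
    s_a = 0
    for i in _flank_indices(matrix, context.focal_index, half_span_bp):
        cd = int(matrix.alleles[der, i].sum())
        ca = int(matrix.alleles[anc, i].sum())
        if 0 < cd < der.size:
            s_d += 1
        if 0 < ca < anc.size:
            s_a += 1
    if s_d == 0:
        return float("nan")
    return s_a / s_d


def _freq_terms(
    matrix: HaplotypeMatrix, context: FocalSiteContext, half_span_bp: int
) -> np.ndarray:
    """f_dd for each flanking variant present on the derived background."""
    der = context.derived_carriers
    out = []
    for i in _flank_indices(matrix, context.focal_index, half_span_bp):
        cd = int(matrix.alleles[der, i].sum())
        if cd > 0:
            out.append(cd / der.size)
    return np.asarray(out)


def lowfreq(matrix: HaplotypeMatrix, context: FocalSiteContext, half_span_bp: int = 25_000) -> float:
    """Mean of (1 - f_dd)^2 over flanking derived alleles with 0 < f_dd < 0.25.

    Captures the excess of rare alleles on the derived background expected
    after a (locally) complete sweep, like Tajima's D but standardized
    empirically rather than by theory.
    """
    if not context.computable:
        return float("nan")
    f = _freq_terms(matrix, context, half_span_bp)
    f = f[f < 0.25]
    if f.size == 0:
        return 0.0
    return float(np.mean((1.0 - f) ** 2))


def highfreq(matrix: HaplotypeMatrix, context: FocalSiteContext, half_span_bp: int = 25_000) -> float:
    """Mean of f_dd^2 over flanking derived alleles with f_dd > 0.25.

    The high-frequency analogue of :func:`lowfreq`, in the spirit of Fay
    and Wu's H.
    """
    if not context.computable:
        return float("nan")
    f = _freq_terms(matrix, context, half_span_bp)
    f = f[f > 0.25]
    if f.size == 0:
        return 0.0
    return float(np.mean(f ** 2))


# ---------------------------------------------------------------------------
# DAF-binned standardization
# ---------------------------------------------------------------------------

def daf_bin(daf: float | np.ndarray) -> np.ndarray:
    """0-based index of the 2% bin containing ``daf``; bins are (lo, hi]."""
    daf = np.asarray(daf, dtype=np.float64)
    if np.any(daf <= 0) or np.any(daf > 1):
        raise ValueError("derived allele frequency must lie in (0, 1]")
    return np.minimum(np.ceil(daf * N_BINS).astype(np.int64) - 1, N_BINS - 1)


class BinnedNorms:
    """Per-statistic mean/SD in 50 derived-allele-frequency bins of 2%.

    Fit on per-SNP statistic values from neutral simulations; bins holding
    fewer than ``min_per_bin`` values are pooled with their nearest
    neighbours (symmetric expansion) before the moments are taken, since
    the SD of tiny samples is unstable.  Statistics without a focal DAF
    (per-locus values such as HAF and H12) are stored as a single bin.
    """

    VERSION = 1

    def __init__(self, provenance: str = "") -> None:
        self.provenance = provenance
        self._mean: dict[str, np.ndarray] = {}
        self._sd: dict[str, np.ndarray] = {}

    @property
    def statistics(self) -> list[str]:
        return sorted(self._mean)

    def fit(
        self,
        name: str,
        values: np.ndarray,
        dafs: np.ndarray | None = None,
        min_per_bin: int = 20,
    ) -> "BinnedNorms":
        """Fit one statistic's bins.  ``dafs=None`` fits a single global bin."""
        values = np.asarray(values, dtype=np.float64)
        ok = np.isfinite(values)
        values = values[ok]
        if dafs is None:
            if values.size < 2:
                raise ValueError(f"{name}: too few values for global norms")
            sd = float(values.std(ddof=1))
            if sd <= 0:
                raise ValueError(f"{name}: zero variance in global bin")
            self._mean[name] = np.array([values.mean()])
            self._sd[name] = np.array([sd])
            return self
        dafs = np.asarray(dafs, dtype=np.float64)[ok]
        bins = daf_bin(dafs)
        mean = np.empty(N_BINS)
        sd = np.empty(N_BINS)
        counts = np.bincount(bins, minlength=N_BINS)
        for b in range(N_BINS):
            lo = hi = b
            pooled = values[bins == b]
            # expand until the bin is both populated and non-degenerate;
            # a statistic that is constant across *all* bins is an error
            while (
                pooled.size < min_per_bin or pooled.size < 2 or pooled.std(ddof=1) <= 0
            ) and (lo > 0 or hi < N_BINS - 1):
                lo = max(lo - 1, 0)
                hi = min(hi + 1, N_BINS - 1)
                pooled = values[(bins >= lo) & (bins <= hi)]
            if pooled.size < 2:
                raise ValueError(f"{name}: bin {b} has too few values even after pooling")
            m, s = pooled.mean(), pooled.std(ddof=1)
            if s <= 0:
                raise ValueError(f"{name}: zero variance in pooled bin {b}")
            mean[b], sd[b] = m, s
        self._mean[name] = mean
        self._sd[name] = sd
        return self

    def standardize(
        self, name: str, value: float | np.ndarray, focal_daf: float | np.ndarray | None = None
    ) -> float | np.ndarray:
        """(value - E_p) / SD_p for the bin containing ``focal_daf``."""
        if name not in self._mean:
            raise KeyError(f"no norms fitted for statistic {name!r}")
        mean, sd = self._mean[name], self._sd[name]
        if mean.size == 1:
            return (np.asarray(value, dtype=np.float64) - mean[0]) / sd[0]
        if focal_daf is None:
            raise ValueError(f"{name} requires a focal DAF for standardization")
        b = daf_bin(focal_daf)
        return (np.asarray(value, dtype=np.float64) - mean[b]) / sd[b]

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.statistics:
            mean, sd = self._mean[name], self._sd[name]
            if mean.size == 1:
                rows.append((name, 0.0, 1.0, mean[0], sd[0]))
            else:
                for b in range(N_BINS):
                    rows.append((name, b / N_BINS, (b + 1) / N_BINS, mean[b], sd[b]))
        return pd.DataFrame(rows, columns=["statistic", "bin_low", "bin_high", "mean", "sd"])

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#binned_norms_v{self.VERSION}\tprovenance={self.provenance}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load(cls, path: str | Path) -> "BinnedNorms":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#binned_norms_v"):
                raise ValueError("not a binned-norms file")
            prov = header.strip().split("provenance=", 1)[-1]
            df = pd.read_csv(fh, sep="\t")
        norms = cls(provenance=prov)
        for name, grp in df.groupby("statistic"):
            if len(grp) == 1:
                norms._mean[name] = grp["mean"].to_numpy()
                norms._sd[name] = grp["sd"].to_numpy()
            else:
                grp = grp.sort_values("bin_low")
                norms._mean[name] = grp["mean"].to_numpy()
                norms._sd[name] = grp["sd"].to_numpy()
        return norms

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, BinnedNorms):
            return NotImplemented
        return (
            self.statistics == other.statistics
            and all(np.allclose(self._mean[k], other._mean[k]) for k in self._mean)
            and all(np.allclose(self._sd[k], other._sd[k]) for k in self._sd)
        )


def build_norms(
    values_by_stat: dict[str, tuple[np.ndarray, np.ndarray | None]],
    provenance: str = "",
    min_per_bin: int = 20,
) -> BinnedNorms:
    """Fit :class:`BinnedNorms` from ``{name: (values, dafs-or-None)}``."""
    norms = BinnedNorms(provenance=provenance)
    for name, (values, dafs) in values_by_stat.items():
        norms.fit(name, values, dafs, min_per_bin=min_per_bin)
    return norms
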