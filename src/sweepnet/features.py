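"""Feature tensors: 11 statistics x (21 centres x 5 nested windows).

A locus is summarised for the classifier by evaluating all eleven
statistics at 21 centre points spaced regularly across the middle of the
locus, each with five nested windows around it (50/100/200/500/1000 kb at
the default 1.2-Mb scale).  Per-SNP statistics are standardized against
neutral-simulation norms in 2% derived-allele-frequency bins and averaged
over the computable focal SNPs in each window; HAF and H12 are single
per-locus values broadcast across all 105 columns so the tensor stays
rectangular for convolution.  Cells with no computable value are imputed
with 0 — the neutral-standardized mean, i.e. the least informative value —
and counted in the tensor's flag total.

The default row order interleaves statistics that summarise different
aspects of variation (haplotype structure, SFS, derived-background
diversity), which helps convolution kernels mix information types early.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._engine import LocusEngine
from .classicstats import h12_80, haf_top, safe_or_isafe
from .hapdata import GeneticMap, HaplotypeMatrix
from .sweepstats import BinnedNorms, build_norms

#: statistics evaluated per focal SNP and aggregated per window
PER_SNP_ROW_STATS = (
    "ihs",
    "hapdaf_o",
    "dind",
    "nsl",
    "hapdaf_s",
    "sratio",
    "lowfreq",
    "highfreq",
)

#: default interleaved row order (haplotype / SFS / derived-background diversity)
DEFAULT_ROW_ORDER = (
    "ihs",
    "hapdaf_o",
    "dind",
    "nsl",
    "hapdaf_s",
    "sratio",
    "isafe",
    "lowfreq",
    "haf",
    "highfreq",
    "h12",
)

LOCUS_STATS = ("haf", "h12")


@dataclass(frozen=True)
class FeatureConfig:
    """Geometry of the feature tensor."""

    locus_length: int = 1_200_000
    window_sizes: tuple[int, ...] = (50_000, 100_000, 200_000, 500_000, 1_000_000)
    center_step: int = 10_000
    n_centers: int = 21

    @classmethod
    def scaled(cls, factor: int, **overrides) -> "FeatureConfig":
        """Geometry shrunk by an integer factor (same 21 x 5 tensor shape)."""
        base = cls()
        return cls(
            locus_length=base.locus_length // factor,
            window_sizes=tuple(w // factor for w in base.window_sizes),
            center_step=base.center_step // factor,
            n_centers=base.n_centers,
            **overrides,
        )

    @property
    def n_windows(self) -> int:
        return self.n_centers * len(self.window_sizes)


def center_points(locus_length: int, config: FeatureConfig | None = None) -> np.ndarray:
    """The centre positions, symmetric about the locus midpoint.

    Placement requires the largest nested window to fit inside the locus
    for every centre; at the default geometry (1.2-Mb locus, 1-Mb largest
    window) this puts 21 centres at 500 kb ... 700 kb in 10-kb steps.
    """
    cfg = config or FeatureConfig(locus_length=locus_length)
    half_span = (cfg.n_centers - 1) // 2
    mid = locus_length // 2
    centres = mid + cfg.center_step * np.arange(-half_span, cfg.n_centers - half_span)
    biggest = max(cfg.window_sizes)
    if centres[0] - biggest // 2 < 0 or centres[-1] + biggest // 2 > locus_length:
        raise ValueError(
            f"locus of {locus_length} bp too short for {cfg.n_centers} centres "
            f"with a {biggest} bp window"
        )
    return centres


@dataclass
class FeatureTensor:
    """11 x (n_centers * n_sizes) standardized feature values for one locus."""

    values: np.ndarray
    row_order: tuple[str, ...]
    n_flagged: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.row_order):
            raise ValueError("row count does not match row_order")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor must be finite after imputation")

    def reordered(self, row_order: tuple[str, ...]) -> "FeatureTensor":
        idx = [self.row_order.index(name) for name in row_order]
        return FeatureTensor(self.values[idx], tuple(row_order), self.n_flagged, dict(self.metadata))


def norm_key(stat: str, size: int) -> str:
    return f"{stat}@{size}"


def compute_window_stats(
    matrix: HaplotypeMatrix,
    center: int,
    size: int,
    norms: BinnedNorms,
    gmap: GeneticMap | None = None,
    engine: LocusEngine | None = None,
) -> dict[str, float]:
    """One window's standardized statistic values (NaN where not computable).

    Per-SNP statistics use focal-centred spans equal to the nested window
    size and are averaged over computable focal SNPs falling inside
    [center - size/2, center + size/2); the SAFE/iSAFE window summary is
    the maximum per-SNP score.  HAF/H12 are per-locus and not produced
    here.
    """
    eng = engine or LocusEngine(matrix, gmap)
    tab = eng.table(size // 2)
    lo, hi = center - size // 2, center + size // 2
    sel = (tab["pos"] >= lo) & (tab["pos"] < hi)
    out: dict[str, float] = {}
    for stat in PER_SNP_ROW_STATS:
        vals = tab.loc[sel, stat].to_numpy()
        dafs = tab.loc[sel, "daf"].to_numpy()
        finite = np.isfinite(vals)
        if finite.any():
            std = norms.standardize(norm_key(stat, size), vals[finite], dafs[finite])
            out[stat] = float(np.mean(std))
        else:
            out[stat] = float("nan")
    wmat = matrix.window(lo, hi)
    if wmat.n_sites >= 2:
        scores, _branch = safe_or_isafe(wmat)
        out["isafe"] = float(norms.standardize(norm_key("isafe", size), scores.max()))
    else:
        out["isafe"] = float("nan")
    return out


def assemble(
    matrix: HaplotypeMatrix,
    norms: BinnedNorms,
    config: FeatureConfig | None = None,
    gmap: GeneticMap | None = None,
    row_order: tuple[str, ...] = DEFAULT_ROW_ORDER,
    locus_id: str = "",
) -> FeatureTensor:
    """Assemble the full feature tensor for one locus.

    Columns are centre-major (all window sizes of centre 0, then centre 1,
    ...), so convolution kernels span adjacent centres and statistic rows.
    """
    cfg = config or FeatureConfig(locus_length=matrix.locus_length)
    if sorted(row_order) != sorted(DEFAULT_ROW_ORDER):
        unknown = set(row_order) ^ set(DEFAULT_ROW_ORDER)
        raise ValueError(f"row_order must be a permutation of the 11 statistics ({unknown})")
    centres = center_points(matrix.locus_length, cfg)
    sizes = cfg.window_sizes
    engine = LocusEngine(matrix, gmap)
    by_span = engine.tables([size // 2 for size in sizes])
    tables = {size: by_span[size // 2] for size in sizes}

    n_cols = len(centres) * len(sizes)
    cells: dict[str, np.ndarray] = {name: np.full(n_cols, np.nan) for name in row_order}
    for ci, centre in enumerate(centres):
        for si, size in enumerate(sizes):
            col = ci * len(sizes) + si
            tab = tables[size]
            lo, hi = centre - size // 2, centre + size // 2
            sel = ((tab["pos"] >= lo) & (tab["pos"] < hi)).to_numpy()
            dafs = tab["daf"].to_numpy()[sel]
            for stat in PER_SNP_ROW_STATS:
                vals = tab[stat].to_numpy()[sel]
                finite = np.isfinite(vals)
                if finite.any():
                    std = norms.standardize(norm_key(stat, size), vals[finite], dafs[finite])
                    cells[stat][col] = float(np.mean(std))
            wmat = matrix.window(lo, hi)
            if wmat.n_sites >= 2:
                scores, _ = safe_or_isafe(wmat)
                cells["isafe"][col] = float(
                    norms.standardize(norm_key("isafe", size), scores.max())
                )
    cells["haf"][:] = float(norms.standardize("haf", haf_top(matrix)))
    h12 = h12_80(matrix)
    cells["h12"][:] = (
        float(norms.standardize("h12", h12)) if np.isfinite(h12) else np.nan
    )

    values = np.vstack([cells[name] for name in row_order])
    n_flagged = int(np.sum(~np.isfinite(values)))
    values = np.nan_to_num(values, nan=0.0)
    return FeatureTensor(
        values,
        tuple(row_order),
        n_flagged,
        {"locus_id": locus_id, "norms_provenance": norms.provenance},
    )


# ---------------------------------------------------------------------------
# Norms fitting from neutral simulations
# ---------------------------------------------------------------------------

def build_norms_from_neutral(
    matrices: list[HaplotypeMatrix],
    config: FeatureConfig | None = None,
    gmap: GeneticMap | None = None,
    provenance: str = "",
    min_per_bin: int = 20,
) -> BinnedNorms:
    """Fit :class:`BinnedNorms` for every (statistic, window size) from a
    batch of neutral replicates.

    Per-SNP statistics are pooled across replicates with their focal DAFs
    (2% bins); SAFE/iSAFE window maxima, HAF and H12 get single global
    bins because they have no focal variant.
    """
    if not matrices:
        raise ValueError("need at least one neutral replicate")
    cfg = config or FeatureConfig(locus_length=matrices[0].locus_length)
    sizes = cfg.window_sizes
    acc_vals: dict[str, list[np.ndarray]] = {}
    acc_dafs: dict[str, list[np.ndarray]] = {}
    safe_vals: dict[int, list[float]] = {s: [] for s in sizes}
    haf_vals: list[float] = []
    h12_vals: list[float] = []
    for matrix in matrices:
        engine = LocusEngine(matrix, gmap)
        centres = center_points(matrix.locus_length, cfg)
        by_span = engine.tables([size // 2 for size in sizes])
        for size in sizes:
            tab = by_span[size // 2]
            for stat in PER_SNP_ROW_STATS:
                key = norm_key(stat, size)
                vals = tab[stat].to_numpy()
                finite = np.isfinite(vals)
                acc_vals.setdefault(key, []).append(vals[finite])
                acc_dafs.setdefault(key, []).append(tab["daf"].to_numpy()[finite])
            for centre in centres:
                wmat = matrix.window(centre - size // 2, centre + size // 2)
                if wmat.n_sites >= 2:
                    scores, _ = safe_or_isafe(wmat)
                    safe_vals[size].append(float(scores.max()))
        haf_vals.append(haf_top(matrix))
        h12 = h12_80(matrix)
        if np.isfinite(h12):
            h12_vals.append(h12)

    spec: dict[str, tuple[np.ndarray, np.ndarray | None]] = {}
    for key in acc_vals:
        spec[key] = (np.concatenate(acc_vals[key]), np.concatenate(acc_dafs[key]))
    for size in sizes:
        spec[norm_key("isafe", size)] = (np.asarray(safe_vals[size]), None)
    spec["haf"] = (np.asarray(haf_vals), None)
    spec["h12"] = (np.asarray(h12_vals), None)
    return build_norms(
        spec,
        provenance=provenance or f"neutral:n={len(matrices)}",
        min_per_bin=min_per_bin,
    )


# ---------------------------------------------------------------------------
# Batch persistence
# ---------------------------------------------------------------------------

def stack_tensors(tensors: list[FeatureTensor]) -> np.ndarray:
    """(N, 11, n_windows) array; all tensors must share a row order."""
    if not tensors:
        raise ValueError("empty tensor list")
    row_order = tensors[0].row_order
    if any(t.row_order != row_order for t in tensors):
        raise ValueError("tensors have inconsistent row orders")
    return np.stack([t.values for t in tensors])


def save_batch(
    path: str | Path,
    tensors: list[FeatureTensor],
    labels: np.ndarray | None = None,
) -> None:
    """Persist a tensor batch as .npz with a JSON sidecar (row order,
    norms provenance, labels)."""
    path = Path(path)
    arr = stack_tensors(tensors)
    np.savez_compressed(path, values=arr)
    sidecar = {
        "row_order": list(tensors[0].row_order),
        "norms_provenance": tensors[0].metadata.get("norms_provenance", ""),
        "locus_ids": [t.metadata.get("locus_id", "") for t in tensors],
        "labels": None if labels is None else np.asarray(labels).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_batch(path: str | Path) -> tuple[list[FeatureTensor], np.ndarray | None]:
    path = Path(path)
    arr = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))["values"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    row_order = tuple(sidecar["row_order"])
    tensors = [
        FeatureTensor(
            arr[i],
            row_order,
            metadata={
                "locus_id": sidecar["locus_ids"][i],
                "norms_provenance": sidecar["norms_provenance"],
            },
        )
        for i in range(arr.shape[0])
    ]
    labels = sidecar.get("labels")
    return tensors, (None if labels is None else np.asarray(labels))
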