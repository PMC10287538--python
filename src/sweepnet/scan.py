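"""Genome-scan mode: tile, featurize, classify, merge streaks, estimate FDR.

Chromosomes are tiled into overlapping windows (1.2 Mb stepped by 10 kb at
the default scale), each window is featurized and classified, maximal
streaks of sweep-classified windows are merged into candidate regions with
a peak at the most confident member window, and an FDR is estimated by
comparing the model's validation false-positive rate with the positive
rate observed in sets of windows far enough apart to be effectively
independent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import TrainedModel, predict
from .features import FeatureConfig, assemble
from .hapdata import GeneticMap, HaplotypeMatrix, read_vcf_region
from .sweepstats import BinnedNorms

DEFAULT_WINDOW = 1_200_000
DEFAULT_STEP = 10_000
MAX_FLAGGED_FRACTION = 0.20  # windows with more imputed cells are unclassifiable


@dataclass
class ScanResult:
    """Per-window classification records for one chromosome."""

    chrom: str
    windows: pd.DataFrame  # start, end, center, probability, classified, snp_count, flagged
    threshold: float
    window_length: int
    step: int

    def positives(self) -> pd.DataFrame:
        return self.windows[self.windows["classified"] == 1]

    def to_tsv(self, path: str | Path) -> None:
        df = self.windows.copy()
        df.insert(0, "chrom", self.chrom)
        df.to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.positives().iterrows():
                fh.write(
                    f"{self.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                    f"sweep\t{row.probability:.4f}\n"
                )


@dataclass(frozen=True)
class SweepRegion:
    """A merged streak of sweep-classified windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    max_probability: float
    peak_position: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


def tile_windows(
    chrom_length: int,
    window_length: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[tuple[int, int]]:
    """Overlapping (start, end) windows: starts 0, step, 2*step, ... with
    end <= chrom_length.  Empty (with a warning) for chromosomes shorter
    than one window."""
    if chrom_length < window_length:
        warnings.warn(
            f"chromosome length {chrom_length} shorter than window {window_length}; no windows"
        )
        return []
    n = (chrom_length - window_length) // step + 1
    return [(i * step, i * step + window_length) for i in range(n)]


def scan_matrix(
    matrix: HaplotypeMatrix,
    model: TrainedModel,
    norms: BinnedNorms,
    config: FeatureConfig | None = None,
    gmap: GeneticMap | None = None,
    threshold: float = 0.5,
    chrom: str = "chr",
    step: int | None = None,
) -> ScanResult:
    """Classify every window of a chromosome-scale haplotype matrix.

    The window length is the feature geometry's locus length; windows with
    too little data (fewer than 2 SNPs in the smallest nested window set,
    or more than 20% imputed cells) are flagged unclassifiable and carry
    probability NaN.
    """
    cfg = config or FeatureConfig()
    step = step or cfg.center_step
    win_len = cfg.locus_length
    rows = []
    for start, end in tile_windows(matrix.locus_length, win_len, step):
        sub = matrix.window(start, end)
        sub = HaplotypeMatrix(sub.alleles, sub.positions - start, win_len)
        record = {
            "start": start,
            "end": end,
            "center": start + win_len // 2,
            "snp_count": sub.n_sites,
            "probability": np.nan,
            "classified": 0,
            "flagged": 1,
            "n_imputed": -1,
        }
        if sub.n_sites >= 2:
            tensor = assemble(sub, norms, cfg, gmap, locus_id=f"{chrom}:{start}-{end}")
            record["n_imputed"] = tensor.n_flagged
            if tensor.n_flagged <= MAX_FLAGGED_FRACTION * tensor.values.size:
                prob = predict(model, tensor)
                record.update(
                    probability=prob, classified=int(prob > threshold), flagged=0
                )
        rows.append(record)
    df = pd.DataFrame(
        rows,
        columns=[
            "start",
            "end",
            "center",
            "probability",
            "classified",
            "snp_count",
            "flagged",
            "n_imputed",
        ],
    )
    return ScanResult(chrom, df, threshold, win_len, step)


def classify_genome(
    vcf_path: str | Path,
    chrom: str,
    chrom_length: int,
    model: TrainedModel,
    norms: BinnedNorms,
    config: FeatureConfig | None = None,
    ancestral: str | Path | dict | None = None,
    gmap: GeneticMap | None = None,
    threshold: float = 0.5,
) -> ScanResult:
    """Scan one chromosome of a phased, polarized VCF."""
    matrix, report = read_vcf_region(vcf_path, (chrom, 0, chrom_length), ancestral)
    if matrix.n_sites == 0:
        raise ValueError(
            f"no polarizable biallelic SNPs on {chrom} "
            f"(no-AA: {report.n_dropped_no_aa}, unmatched AA: {report.n_dropped_unmatched_aa})"
        )
    return scan_matrix(
        matrix, model, norms, config, gmap, threshold, chrom=chrom
    )


def merge_streaks(result: ScanResult, threshold: float | None = None) -> list[SweepRegion]:
    """Merge maximal runs of consecutive sweep-classified windows.

    The region span is the union of its member windows; the peak is the
    centre of the member window with the highest probability (leftmost on
    ties).  Flagged or negative windows break streaks.
    """
    df = result.windows
    if threshold is not None:
        classified = (df["probability"] > threshold) & (df["flagged"] == 0)
    else:
        classified = (df["classified"] == 1) & (df["flagged"] == 0)
    regions: list[SweepRegion] = []
    run: list[int] = []
    idx = list(df.index)
    for k, i in enumerate(idx):
        if classified[i]:
            run.append(i)
        if run and (not classified[i] or k == len(idx) - 1):
            sub = df.loc[run]
            best = sub["probability"].idxmax()  # idxmax takes the first maximum
            regions.append(
                SweepRegion(
                    chrom=result.chrom,
                    start=int(sub["start"].min()),
                    end=int(sub["end"].max()),
                    n_windows=len(run),
                    max_probability=float(sub.loc[best, "probability"]),
                    peak_position=int(sub.loc[best, "center"]),
                )
            )
            run = []
    return regions


def regions_to_bed(regions: list[SweepRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tsweep_region\t{r.max_probability:.4f}\t"
                f"+\t{r.peak_position}\t{r.n_windows}\n"
            )


def estimate_fdr(
    result: ScanResult,
    model_fpr: float,
    n_sets: int = 100,
    spacing: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Mean FDR over random sets of approximately independent windows.

    Each set takes windows ``spacing`` apart (so their spans barely
    overlap and they behave like independent draws); the expected number
    of false positives in a set is ``model_fpr * set size`` (from the
    model's validation FPR under the matched demography), and the set's
    FDR is that expectation divided by the number of positively classified
    windows in the set.  Sets with zero positives have an undefined FDR
    and are excluded with a warning.  Deterministic under ``seed``.
    """
    df = result.windows[result.windows["flagged"] == 0]
    if df.empty:
        raise ValueError("no classifiable windows")
    stride = max(1, int(np.ceil(spacing / result.step)))
    rng = np.random.default_rng(seed)
    fdrs = []
    n_skipped = 0
    for _ in range(n_sets):
        offset = int(rng.integers(0, stride))
        sel = df.iloc[offset::stride]
        if sel.empty:
            n_skipped += 1
            continue
        n_pos = int(sel["classified"].sum())
        if model_fpr == 0:
            fdrs.append(0.0)
            continue
        if n_pos == 0:
            n_skipped += 1
            continue
        fdrs.append(model_fpr * len(sel) / n_pos)
    if n_skipped:
        warnings.warn(f"{n_skipped} window sets had no positives and were excluded")
    if not fdrs:
        raise ValueError("FDR undefined: no set contained a positive window")
    return float(np.mean(fdrs))


def write_run_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (seeds, thresholds, versions) for reproducibility."""
    from . import __version__

    payload = {"sweepnet_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
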