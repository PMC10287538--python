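"""Training/testing data generation: neutral and sweep coalescent simulations.

Neutral loci come from the standard coalescent; sweep loci from msprime's
structured-coalescent sweep model (genic selection with a conditioned
allele-frequency trajectory), composed as

    StandardCoalescent(duration = tau)  ->  SweepGenicSelection  ->  StandardCoalescent

so the sample is taken ``tau`` generations after selection ended at the
ending allele frequency (EAF).  The selected site sits at the centre of the
locus.  Sweep parameters are drawn from configurable distributions whose
defaults span the regimes the detector is meant to cover: ages up to
0.125*4Ne generations, selection coefficients down to s = 0.001
(gamma = 2Ns = 20 at Ne = 10,000), starting allele frequencies (SAF) up to
10% (soft sweeps from standing variation), and ending frequencies from 20%
(very incomplete) to fixation.

Everything is deterministic under an integer seed.  Externally simulated
data (discoal, SLiM, ...) are ingested via ms-format with a label manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .hapdata import HaplotypeMatrix, _dedupe_positions, read_ms, write_ms_file

DEMOGRAPHIC_SCENARIOS = ("equilibrium", "decline", "expansion", "bottleneck")


@dataclass(frozen=True)
class SweepParams:
    """One sweep's parameters.

    tau: generations since selection ended; s: selection coefficient
    (per-generation advantage of the beneficial allele); saf/eaf: starting
    and ending allele frequency of the beneficial allele; ne: effective
    population size.
    """

    tau: float
    s: float
    saf: float
    eaf: float
    ne: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.saf < self.eaf <= 1.0:
            raise ValueError(f"need 0 <= saf < eaf <= 1, got saf={self.saf}, eaf={self.eaf}")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.tau > 0.25 * 4 * self.ne:
            raise ValueError("tau exceeds the outer detection bound of 0.25*4*Ne generations")
        if self.s < 10.0 / (2.0 * self.ne):
            raise ValueError(
                "s must exceed 10/(2*Ne); weaker selection is indistinguishable from drift"
            )


@dataclass(frozen=True)
class ParamDistributions:
    """Sweep-parameter distributions: ('uniform'|'loguniform'|'point', lo[, hi])."""

    tau: tuple = ("uniform", 0.0, None)  # None -> 0.125 * 4 * ne
    s: tuple = ("loguniform", 0.001, 0.1)
    saf: tuple = ("uniform", 0.0, 0.10)
    eaf: tuple = ("uniform", 0.2, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Shared settings for one simulated dataset."""

    ne: float = 10_000.0
    locus_length: int = 1_200_000
    n_haplotypes: int = 100
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1.25e-8
    scenario: str = "equilibrium"
    # (time_in_generations, size) changes going back in time; overrides scenario presets
    size_changes: tuple[tuple[float, float], ...] | None = None
    label: str = "neutral"
    distributions: ParamDistributions = field(default_factory=ParamDistributions)

    def __post_init__(self) -> None:
        if self.locus_length <= 0:
            raise ValueError("locus_length must be positive")
        if self.mutation_rate <= 0 or self.recombination_rate < 0:
            raise ValueError("rates must be positive")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be an even count >= 2 (diploid sampling)")
        if self.scenario not in DEMOGRAPHIC_SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def demography(self) -> msprime.Demography:
        """Piecewise-constant single-population demography.

        Preset scenarios change size 0.05*4Ne generations ago: decline
        (present Ne, 5x larger ancestrally), expansion (present Ne, 10x
        smaller ancestrally), bottleneck (10x reduction for 0.05*4Ne
        generations before recovery to Ne).
        """
        demo = msprime.Demography()
        demo.add_population(name="pop", initial_size=self.ne)
        t_event = 0.05 * 4 * self.ne
        changes: tuple[tuple[float, float], ...]
        if self.size_changes is not None:
            changes = self.size_changes
        elif self.scenario == "decline":
            changes = ((t_event, 5 * self.ne),)
        elif self.scenario == "expansion":
            changes = ((t_event, self.ne / 10),)
        elif self.scenario == "bottleneck":
            changes = ((t_event, self.ne / 10), (2 * t_event, self.ne))
        else:
            changes = ()
        for t, size in sorted(changes):
            demo.add_population_parameters_change(time=t, initial_size=size, population="pop")
        return demo


def draw_sweep_params(config: SimulationConfig, seed: int, max_attempts: int = 1000) -> SweepParams:
    """Draw one :class:`SweepParams` from the configured distributions.

    Deterministic under ``seed``.  Draws violating saf < eaf are
    resampled; after ``max_attempts`` failures the ranges are considered
    inconsistent and an error is raised.
    """
    rng = np.random.default_rng(seed)

    def draw(spec: tuple, default_hi: float | None = None) -> float:
        kind, lo = spec[0], spec[1]
        hi = spec[2] if len(spec) > 2 else None
        if hi is None:
            hi = default_hi
        if kind == "point":
            return float(lo)
        if kind == "uniform":
            return float(rng.uniform(lo, hi))
        if kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        raise ValueError(f"unknown distribution kind {kind!r}")

    d = config.distributions
    tau_hi = 0.125 * 4 * config.ne
    for _ in range(max_attempts):
        tau = draw(d.tau, tau_hi)
        s = draw(d.s)
        saf = draw(d.saf)
        eaf = draw(d.eaf)
        if saf < eaf:
            return SweepParams(tau=tau, s=s, saf=saf, eaf=eaf, ne=config.ne)
    raise ValueError("could not draw saf < eaf; parameter ranges are inconsistent")


def _ts_to_matrix(ts, locus_length: int) -> HaplotypeMatrix:
    """Tree sequence (infinite-sites, binary mutations) -> haplotype matrix."""
    G = ts.genotype_matrix()  # (sites, samples)
    pos = np.array([s.position for s in ts.sites()])
    # keep strictly biallelic 0/1 columns (binary model guarantees this)
    keep = (G.max(axis=1) <= 1) & (G.min(axis=1) >= 0) & (G.max(axis=1) > 0)
    G = G[keep]
    pos = np.floor(pos[keep]).astype(np.int64)
    pos = _dedupe_positions(pos, locus_length)
    return HaplotypeMatrix(G.T.astype(np.int8), pos, locus_length)


def simulate_neutral(config: SimulationConfig, seed: int) -> HaplotypeMatrix:
    """One neutral replicate under the configured demography."""
    a_seed, m_seed = _split_seed(seed)
    ts = msprime.sim_ancestry(
        samples=config.n_haplotypes // 2,
        ploidy=2,
        demography=config.demography(),
        sequence_length=config.locus_length,
        recombination_rate=config.recombination_rate,
        random_seed=a_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=m_seed,
    )
    return _ts_to_matrix(ts, config.locus_length)


def simulate_sweep(
    config: SimulationConfig, params: SweepParams, seed: int
) -> HaplotypeMatrix:
    """One sweep replicate: selected site at the locus centre, sampled
    ``params.tau`` generations after the allele reached ``params.eaf``."""
    a_seed, m_seed = _split_seed(seed)
    n2 = 2.0 * params.ne
    sweep = msprime.SweepGenicSelection(
        position=config.locus_length / 2,
        start_frequency=max(params.saf, 1.0 / n2),
        end_frequency=min(params.eaf, 1.0 - 1.0 / n2),
        s=params.s,
        dt=1.0 / (40.0 * params.ne),
    )
    models: list = []
    if params.tau > 0:
        models.append(msprime.StandardCoalescent(duration=params.tau))
    models.append(sweep)
    models.append(msprime.StandardCoalescent())
    ts = msprime.sim_ancestry(
        samples=config.n_haplotypes // 2,
        ploidy=2,
        demography=config.demography(),
        sequence_length=config.locus_length,
        recombination_rate=config.recombination_rate,
        model=models,
        random_seed=a_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=m_seed,
    )
    return _ts_to_matrix(ts, config.locus_length)


def _split_seed(seed: int) -> tuple[int, int]:
    """Two independent msprime seeds (1..2^31-2) derived from one seed."""
    h = hashlib.sha256(str(int(seed)).encode()).digest()
    a = int.from_bytes(h[:4], "little") % (2**31 - 2) + 1
    b = int.from_bytes(h[4:8], "little") % (2**31 - 2) + 1
    return a, b


def simulate_batch(
    config: SimulationConfig, n_replicates: int, seed: int
) -> tuple[list[HaplotypeMatrix], list[SweepParams | None]]:
    """A batch of replicates of the configured class with per-replicate
    parameter draws (sweep class) and derived seeds."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(1, 2**31 - 1, size=2 * n_replicates)
    matrices = []
    params_list: list[SweepParams | None] = []
    for i in range(n_replicates):
        if config.label == "sweep":
            params = draw_sweep_params(config, int(sub_seeds[2 * i]))
            matrices.append(simulate_sweep(config, params, int(sub_seeds[2 * i + 1])))
            params_list.append(params)
        else:
            matrices.append(simulate_neutral(config, int(sub_seeds[2 * i + 1])))
            params_list.append(None)
    return matrices, params_list


# ---------------------------------------------------------------------------
# Labeled datasets / external-simulator ingestion
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Shuffled, labeled replicate collection with provenance."""

    matrices: list[HaplotypeMatrix]
    labels: np.ndarray  # 1 = sweep, 0 = neutral
    ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.matrices) == self.labels.size == len(self.ids)):
            raise ValueError("matrices/labels/ids length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate replicate IDs")

    @property
    def class_balance(self) -> float:
        return float(self.labels.mean()) if self.labels.size else float("nan")

    def __len__(self) -> int:
        return len(self.matrices)


def import_dataset(
    files_with_labels: list[tuple[str | Path, str]],
    locus_length: int,
    seed: int = 0,
) -> LabeledDataset:
    """Ingest ms-format files with class labels ('neutral' or 'sweep').

    Each file may contain several replicates; replicate IDs are
    ``<stem>#<index>``.  The combined collection is shuffled
    deterministically under ``seed``.
    """
    matrices: list[HaplotypeMatrix] = []
    labels: list[int] = []
    ids: list[str] = []
    for path, label in files_with_labels:
        if label not in ("neutral", "sweep"):
            raise ValueError(f"label must be 'neutral' or 'sweep', got {label!r}")
        reps = read_ms(path, locus_length)
        for i, m in enumerate(reps):
            matrices.append(m)
            labels.append(1 if label == "sweep" else 0)
            ids.append(f"{Path(path).stem}#{i}")
    order = np.random.default_rng(seed).permutation(len(matrices))
    return LabeledDataset(
        [matrices[i] for i in order],
        np.asarray(labels)[order],
        [ids[i] for i in order],
    )


def export_dataset(dataset: LabeledDataset, directory: str | Path) -> Path:
    """Write a dataset as one ms file per class plus a manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for label_name, flag in (("neutral", 0), ("sweep", 1)):
        sel = [i for i in range(len(dataset)) if dataset.labels[i] == flag]
        if sel:
            write_ms_file([dataset.matrices[i] for i in sel], directory / f"{label_name}.ms")
            rows += [(dataset.ids[i], label_name) for i in sel]
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows, columns=["replicate_id", "label"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest
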