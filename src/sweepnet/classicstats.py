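"""Previously published sweep statistics, with this package's modifications.

Six statistics complement the derived/ancestral-background statistics in
:mod:`sweepnet.sweepstats`:

* ``ihs`` — integrated haplotype score (Voight et al.): log-ratio of the
  EHH integrals on the ancestral vs. derived background.
* ``nsl`` — number of segregating sites by length (Ferrer-Admetlla et
  al.): map-free analogue of iHS using pairwise shared-segment lengths
  measured in segregating sites.
* ``dind`` — derived intra-allelic nucleotide diversity (Barreiro et
  al.): ratio of pairwise diversity pi on the ancestral vs. derived
  background.
* ``safe_or_isafe`` — SAFE/iSAFE scores (Akbari et al.), with the SAFE
  fallback whenever a window holds fewer than 300 SNPs.
* ``haf_top`` — haplotype allele frequency score (Ronen et al.), summarised
  as the mean of the top 10% of per-haplotype HAF values, which carries a
  better signal for incomplete sweeps than the full distribution.
* ``h12_80`` — H12 (Garud et al.) computed on haplotype clusters formed at
  an 80% pairwise-identity threshold rather than exact identity, so that
  recombined or mutated copies of a sweeping haplotype still count
  towards the leading classes.

Ratios and logs are oriented ancestral-over-derived so that sweeps on the
derived background give positive values, matching the iHS/DIND convention.
Values that cannot be computed (empty background, zero denominator) are
returned as NaN and excluded from window aggregation downstream.
"""

from __future__ import annotations

import math

import numpy as np

from .hapdata import GeneticMap, HaplotypeMatrix
from .sweepstats import FocalSiteContext

EHH_CUTOFF = 0.05
ISAFE_MIN_SNPS = 300  # below this, plain SAFE is used
H12_IDENTITY = 0.80


# ---------------------------------------------------------------------------
# EHH machinery (shared by iHS; reference single-focal implementation)
# ---------------------------------------------------------------------------

def _ehh_curve(haps: np.ndarray, focal: int, direction: int) -> np.ndarray:
    """EHH at successive sites from ``focal`` outward (inclusive of focal).

    ``haps`` holds only the background haplotypes; EHH(0) = 1 because the
    background is defined by a shared focal allele.
    """
    m, s = haps.shape
    if direction > 0:
        idx = range(focal, s)
    else:
        idx = range(focal, -1, -1)
    npairs = m * (m - 1) // 2
    # group haplotypes by growing prefix identity
    codes = np.zeros(m, dtype=np.int64)
    out = []
    for j in idx:
        _, codes = np.unique(
            np.stack([codes, haps[:, j].astype(np.int64)]), axis=1, return_inverse=True
        )
        counts = np.bincount(codes)
        same = (counts * (counts - 1) // 2).sum()
        out.append(same / npairs)
    return np.asarray(out)


def _ihh_side(
    haps: np.ndarray,
    focal: int,
    direction: int,
    positions: np.ndarray,
    gmap: GeneticMap | None,
    lo: int,
    hi: int,
) -> tuple[float, bool]:
    """Trapezoid EHH integral on one side, truncated at EHH < cutoff.

    Returns (integral, decayed) where ``decayed`` is False when the window
    edge was reached with EHH still at or above the cutoff.
    """
    if direction > 0:
        sites = np.arange(focal, hi + 1)
    else:
        sites = np.arange(focal, lo - 1, -1)
    if sites.size <= 1:
        # focal at the window edge: no extent on this side, nothing to decay
        return 0.0, True
    ehh = _ehh_curve(haps, focal, direction)[: sites.size]
    x = positions[sites].astype(np.float64)
    if gmap is not None:
        x = np.asarray(gmap.at(x), dtype=np.float64)
    x = np.abs(x - x[0])
    total = 0.0
    decayed = False
    for k in range(1, sites.size):
        total += (ehh[k - 1] + ehh[k]) / 2.0 * (x[k] - x[k - 1])
        if ehh[k] < EHH_CUTOFF:
            decayed = True
            break
    return total, decayed


def ihs(
    matrix: HaplotypeMatrix,
    context: FocalSiteContext,
    gmap: GeneticMap | None = None,
    half_span_bp: int | None = None,
) -> float:
    """Unstandardized iHS = ln(iHH_derived / iHH_ancestral).

    EHH is integrated by trapezoid outward from the focal site on each
    background until it drops below 0.05 or the window edge is reached;
    with a genetic map, distance is measured in cM, otherwise in bp (the
    ratio makes the unit irrelevant).  Oriented so that extended
    homozygosity on the derived background — the sweep signature — gives
    positive values, consistent with the DIND/Sratio orientation here.
    NaN when either background has fewer than 2 haplotypes, either
    integral is 0, or EHH fails to decay below the cutoff on both sides
    for both backgrounds.
    """
    if not context.computable:
        return float("nan")
    der, anc = context.derived_carriers, context.ancestral_carriers
    if der.size < 2 or anc.size < 2:
        return float("nan")
    pos = matrix.positions
    focal = context.focal_index
    if half_span_bp is None:
        lo_i, hi_i = 0, matrix.n_sites - 1
    else:
        centre = pos[focal]
        in_win = np.flatnonzero(np.abs(pos - centre) <= half_span_bp)
        lo_i, hi_i = int(in_win[0]), int(in_win[-1])
    ihh = {}
    undecayed_sides = 0
    for key, rows in (("a", anc), ("d", der)):
        haps = matrix.alleles[rows]
        right, dec_r = _ihh_side(haps, focal, +1, pos, gmap, lo_i, hi_i)
        left, dec_l = _ihh_side(haps, focal, -1, pos, gmap, lo_i, hi_i)
        ihh[key] = right + left
        undecayed_sides += (not dec_r) + (not dec_l)
    if undecayed_sides == 4:  # EHH never fell below cutoff anywhere
        return float("nan")
    if ihh["d"] <= 0 or ihh["a"] <= 0:
        return float("nan")
    return math.log(ihh["d"] / ihh["a"])


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

def _mean_pairwise_sl(
    haps: np.ndarray, focal: int, lo: int, hi: int
) -> float:
    """Mean over haplotype pairs of the length (in number of segregating
    sites) of the maximal identical segment spanning the focal site,
    bounded by the window [lo, hi] in site indices."""
    m, s = haps.shape
    total = 0
    npairs = 0
    for a in range(m):
        for b in range(a + 1, m):
            diff = np.flatnonzero(haps[a] != haps[b])
            right = diff[diff > focal]
            left = diff[diff < focal]
            r = int(right[0]) if right.size and right[0] <= hi else hi + 1
            l = int(left[-1]) if left.size and left[-1] >= lo else lo - 1
            total += r - l - 1
            npairs += 1
    return total / npairs


def nsl(
    matrix: HaplotypeMatrix,
    context: FocalSiteContext,
    half_span_bp: int | None = None,
) -> float:
    """Unstandardized nSL = ln(SL_derived / SL_ancestral).

    SL is the mean pairwise length, counted in segregating sites, of the
    maximal identical haplotype segment spanning the focal variant on the
    respective background.  Map-free; oriented sweep-positive like iHS.
    NaN when either background has fewer than 2 haplotypes.
    """
    if not context.computable:
        return float("nan")
    der, anc = context.derived_carriers, context.ancestral_carriers
    if der.size < 2 or anc.size < 2:
        return float("nan")
    pos = matrix.positions
    focal = context.focal_index
    if half_span_bp is None:
        lo, hi = 0, matrix.n_sites - 1
    else:
        in_win = np.flatnonzero(np.abs(pos - pos[focal]) <= half_span_bp)
        lo, hi = int(in_win[0]), int(in_win[-1])
    sl_d = _mean_pairwise_sl(matrix.alleles[der], focal, lo, hi)
    sl_a = _mean_pairwise_sl(matrix.alleles[anc], focal, lo, hi)
    if sl_d <= 0 or sl_a <= 0:
        return float("nan")
    return math.log(sl_d / sl_a)


# ---------------------------------------------------------------------------
# DIND
# ---------------------------------------------------------------------------

def _pi(haps: np.ndarray) -> float:
    """Mean pairwise difference (nucleotide diversity, unscaled by length)."""
    m = haps.shape[0]
    if m < 2:
        return float("nan")
    c = haps.sum(axis=0).astype(np.float64)
    return float((2.0 * c * (m - c)).sum() / (m * (m - 1)))


def dind(
    matrix: HaplotypeMatrix,
    context: FocalSiteContext,
    half_span_bp: int = 25_000,
) -> float:
    """Derived intra-allelic nucleotide diversity: pi_ancestral / pi_derived
    over the window.  NaN when pi_derived = 0 or a background is too small."""
    if not context.computable:
        return float("nan")
    der, anc = context.derived_carriers, context.ancestral_carriers
    if der.size < 2 or anc.size < 2:
        return float("nan")
    pos = matrix.positions
    keep = np.abs(pos - pos[context.focal_index]) <= half_span_bp
    pi_d = _pi(matrix.alleles[np.ix_(der, np.flatnonzero(keep))])
    pi_a = _pi(matrix.alleles[np.ix_(anc, np.flatnonzero(keep))])
    if not np.isfinite(pi_d) or not np.isfinite(pi_a) or pi_d <= 0:
        return float("nan")
    return pi_a / pi_d


# ---------------------------------------------------------------------------
# HAF / SAFE / iSAFE
# ---------------------------------------------------------------------------

def haf_scores(matrix: HaplotypeMatrix) -> np.ndarray:
    """Per-haplotype HAF score: sum over carried derived alleles of their
    sample counts."""
    counts = matrix.derived_counts().astype(np.float64)
    return matrix.alleles @ counts


def haf_top(matrix: HaplotypeMatrix, top_fraction: float = 0.1) -> float:
    """Mean of the top ``ceil(top_fraction * n)`` per-haplotype HAF scores."""
    if matrix.n_sites == 0:
        return 0.0
    scores = np.sort(haf_scores(matrix))[::-1]
    k = math.ceil(top_fraction * matrix.n_haplotypes)
    return float(scores[:k].mean())


def safe_scores(matrix: HaplotypeMatrix) -> np.ndarray:
    """Per-SNP SAFE score from the kappa/phi contrast on HAF scores.

    phi(i) is the fraction of total HAF mass carried by haplotypes with the
    derived allele at i; kappa(i) the fraction of distinct haplotypes among
    them; SAFE(i) = (phi - kappa) / sqrt(f (1 - f)) with f the derived
    allele frequency.  Favored (hitchhiking-driving) variants concentrate
    HAF mass on few distinct haplotypes, giving large positive scores.
    """
    if matrix.n_sites < 2:
        raise ValueError("SAFE needs at least 2 SNPs")
    A = matrix.alleles.astype(np.float64)
    haf = haf_scores(matrix)
    total_haf = haf.sum()
    phi = (A.T @ haf) / total_haf if total_haf > 0 else np.zeros(matrix.n_sites)
    packed = np.packbits(matrix.alleles.astype(np.uint8), axis=1)  # cheap row hashing
    _, hap_id = np.unique(packed, axis=0, return_inverse=True)
    n_unique = hap_id.max() + 1
    # distinct-haplotype count among carriers, per site, via group membership
    membership = np.zeros((n_unique, matrix.n_haplotypes))
    membership[hap_id, np.arange(matrix.n_haplotypes)] = 1.0
    kappa = ((membership @ A) > 0).sum(axis=0) / n_unique
    f = matrix.derived_freqs()
    denom = np.sqrt(np.clip(f * (1.0 - f), 1e-12, None))
    return (phi - kappa) / denom


def isafe_scores(
    matrix: HaplotypeMatrix, window_snps: int = 300, step_snps: int = 150
) -> np.ndarray:
    """iSAFE: SAFE computed in overlapping SNP windows and aggregated with
    per-window weights equal to the window's peak SAFE score, so windows
    containing a strong candidate dominate each SNP's final score."""
    s = matrix.n_sites
    if s < 2:
        raise ValueError("iSAFE needs at least 2 SNPs")
    starts = list(range(0, max(s - window_snps, 0) + 1, step_snps))
    if not starts:
        starts = [0]
    if starts[-1] + window_snps < s:
        starts.append(s - window_snps)
    acc = np.zeros(s)
    wsum = np.zeros(s)
    for st in starts:
        en = min(st + window_snps, s)
        sub = HaplotypeMatrix(
            matrix.alleles[:, st:en], matrix.positions[st:en], matrix.locus_length
        )
        sc = safe_scores(sub)
        psi = max(sc.max(), 1e-9)
        acc[st:en] += psi * sc
        wsum[st:en] += psi
    return acc / np.where(wsum > 0, wsum, 1.0)


def safe_or_isafe(matrix: HaplotypeMatrix) -> tuple[np.ndarray, str]:
    """Per-SNP localization scores with the small-window fallback: SAFE
    when the window holds fewer than 300 SNPs, iSAFE otherwise.

    Returns ``(scores, branch)`` with branch ``'safe'`` or ``'isafe'``.
    """
    if matrix.n_sites < 2:
        raise ValueError("need at least 2 SNPs")
    if matrix.n_sites < ISAFE_MIN_SNPS:
        return safe_scores(matrix), "safe"
    return isafe_scores(matrix), "isafe"


# ---------------------------------------------------------------------------
# H12 with 80% identity clustering
# ---------------------------------------------------------------------------

def h12_80(matrix: HaplotypeMatrix, identity_threshold: float = H12_IDENTITY) -> float:
    """H12 on haplotype clusters formed at a pairwise-identity threshold.

    Haplotypes are grouped greedily: distinct haplotype sequences are
    ordered by multiplicity, ties broken lexicographically on the
    sequence (so the clustering is deterministic and invariant to the
    haplotype row order); each unassigned sequence in turn seeds a
    cluster and absorbs every remaining sequence whose identity with the
    seed (fraction of matching alleles over the window SNPs) is at least
    the threshold.  H12 is then ``(p1 + p2)^2 + sum_{i>2} p_i^2`` over
    cluster frequencies.  NaN when the window has no SNPs.
    """
    if matrix.n_sites == 0:
        return float("nan")
    uniq, counts = np.unique(matrix.alleles, axis=0, return_counts=True)
    # np.unique returns rows lexicographically sorted; a stable sort on
    # -counts therefore breaks ties lexicographically
    order = np.argsort(-counts, kind="stable")
    assigned = np.zeros(uniq.shape[0], dtype=bool)
    cluster_freq: list[float] = []
    n = matrix.n_haplotypes
    for seed in order:
        if assigned[seed]:
            continue
        members = [seed]
        assigned[seed] = True
        for other in order:
            if assigned[other]:
                continue
            identity = np.mean(uniq[seed] == uniq[other])
            if identity >= identity_threshold:
                members.append(other)
                assigned[other] = True
        cluster_freq.append(counts[members].sum() / n)
    p = np.sort(np.asarray(cluster_freq))[::-1]
    p1 = p[0]
    p2 = p[1] if p.size > 1 else 0.0
    rest = p[2:] if p.size > 2 else np.array([])
    return float((p1 + p2) ** 2 + (rest ** 2).sum())
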