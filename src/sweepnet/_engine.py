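"""Vectorized per-locus computation of all per-SNP statistics.

The per-focal functions in :mod:`sweepstats` and :mod:`classicstats` are
the readable reference implementations; featurizing a locus needs the same
quantities for every focal site at five window spans, which this module
computes in bulk:

* frequency-contrast statistics (hapDAF-o/s, Sratio, lowfreq, highfreq,
  DIND) from a single site-by-site co-occurrence count matrix
  ``C = A^T A`` shared across window spans, and
* haplotype-length statistics (iHS, nSL) from per-pair next/previous
  mismatch indices, from which the EHH curve at any extent and the maximal
  shared segment in any window are direct lookups; the per-pair sort is
  shared across window spans.

Agreement with the reference implementations is enforced by tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classicstats import EHH_CUTOFF
from .hapdata import GeneticMap, HaplotypeMatrix
from .sweepstats import DAF_RANGE

PER_SNP_STATS = (
    "hapdaf_o",
    "hapdaf_s",
    "sratio",
    "lowfreq",
    "highfreq",
    "dind",
    "ihs",
    "nsl",
)

_HAPDAF_THRESH = {"hapdaf_o": (0.25, 0.25), "hapdaf_s": (0.10, 0.10)}


class LocusEngine:
    """Shared precomputation for one haplotype matrix.

    Builds the co-occurrence counts for focal sites in the computable DAF
    range and the per-pair mismatch indices once; statistic extraction for
    a given window half-span is then cheap, so the five nested window
    sizes reuse the same cache.
    """

    def __init__(self, matrix: HaplotypeMatrix, gmap: GeneticMap | None = None) -> None:
        self.matrix = matrix
        self.gmap = gmap
        A = matrix.alleles
        n, S = A.shape
        self.n, self.S = n, S
        self.pos = matrix.positions
        self.tot = A.sum(axis=0).astype(np.int64)
        daf = self.tot / n
        lo, hi = DAF_RANGE
        self.focal = np.flatnonzero((daf >= lo) & (daf <= hi))
        self.daf = daf[self.focal]
        # co-occurrence counts: C[i, j] = # haplotypes derived at both i and focal j
        Af = A.astype(np.int32)
        C = (Af.T @ Af[:, self.focal]).astype(np.float64)  # (S, F)
        self.n_d = self.tot[self.focal]
        self.n_a = n - self.n_d
        self.cd = C
        self.ca = self.tot[:, None] - C
        self.fd = C / self.n_d
        self.fa = self.ca / self.n_a
        self._pairs_built = False
        self._tables: dict[int | None, pd.DataFrame] = {}

    # -- pair machinery -----------------------------------------------------

    def _build_pairs(self) -> None:
        if self._pairs_built:
            return
        A = self.matrix.alleles.astype(bool)
        n, S = self.n, self.S
        ia, ib = np.triu_indices(n, k=1)
        self.pair_a, self.pair_b = ia, ib
        diff = A[ia] != A[ib]  # (P, S)
        idx = np.arange(S, dtype=np.int32)
        with_next = np.where(diff, idx, np.int32(S))
        suff_min = np.minimum.accumulate(with_next[:, ::-1], axis=1)[:, ::-1]
        nxt = np.full((ia.size, S), S, dtype=np.int32)
        if S > 1:
            nxt[:, :-1] = suff_min[:, 1:]
        with_prev = np.where(diff, idx, np.int32(-1))
        pref_max = np.maximum.accumulate(with_prev, axis=1)
        prv = np.full((ia.size, S), -1, dtype=np.int32)
        if S > 1:
            prv[:, 1:] = pref_max[:, :-1]
        self.nxt, self.prv = nxt, prv
        self._pair_der = A[ia], A[ib]
        self._pairs_built = True

    def _window_bounds(self, half_span_bp: int | None) -> tuple[np.ndarray, np.ndarray]:
        """First/last site index within the focal-centred window, per focal."""
        if half_span_bp is None:
            lo = np.zeros(self.focal.size, dtype=np.int64)
            hi = np.full(self.focal.size, self.S - 1, dtype=np.int64)
            return lo, hi
        centres = self.pos[self.focal]
        lo = np.searchsorted(self.pos, centres - half_span_bp, side="left")
        hi = np.searchsorted(self.pos, centres + half_span_bp, side="right") - 1
        return lo, hi

    # -- frequency-contrast statistics --------------------------------------

    def freq_stats(self, half_span_bp: int | None) -> dict[str, np.ndarray]:
        """hapdaf_o/s, sratio, lowfreq, highfreq, dind for every focal site."""
        S, F = self.S, self.focal.size
        out = {k: np.full(F, np.nan) for k in PER_SNP_STATS if k not in ("ihs", "nsl")}
        if F == 0:
            return out
        cd, ca, fd, fa = self.cd, self.ca, self.fd, self.fa
        if half_span_bp is None:
            W = np.ones((S, F), dtype=bool)
        else:
            W = (
                np.abs(self.pos[:, None] - self.pos[self.focal][None, :])
                <= half_span_bp
            )
        W[self.focal, np.arange(F)] = False  # the focal site is not its own flank

        shared = W & (cd > 0) & (ca > 0)
        for name, (fa_max, sum_min) in _HAPDAF_THRESH.items():
            q = shared & (fd > fa) & (fa < fa_max) & (fd + fa > sum_min)
            k = q.sum(axis=0)
            val = np.where(q, fd * fd - fa * fa, 0.0).sum(axis=0)
            out[name] = np.where(k > 0, val / np.maximum(k, 1), 0.0)

        seg_d = (W & (cd > 0) & (cd < self.n_d)).sum(axis=0)
        seg_a = (W & (ca > 0) & (ca < self.n_a)).sum(axis=0)
        out["sratio"] = np.where(seg_d > 0, seg_a / np.maximum(seg_d, 1), np.nan)

        present = W & (cd > 0)
        low = present & (fd < 0.25)
        k = low.sum(axis=0)
        val = np.where(low, (1.0 - fd) ** 2, 0.0).sum(axis=0)
        out["lowfreq"] = np.where(k > 0, val / np.maximum(k, 1), 0.0)
        high = present & (fd > 0.25)
        k = high.sum(axis=0)
        val = np.where(high, fd ** 2, 0.0).sum(axis=0)
        out["highfreq"] = np.where(k > 0, val / np.maximum(k, 1), 0.0)

        # DIND: pi per background over the window (focal contributes 0)
        Wd = W.copy()
        Wd[self.focal, np.arange(F)] = True
        nd, na = self.n_d.astype(np.float64), self.n_a.astype(np.float64)
        pi_d = np.where(Wd, 2.0 * cd * (nd - cd), 0.0).sum(axis=0) / np.maximum(
            nd * (nd - 1), 1
        )
        pi_a = np.where(Wd, 2.0 * ca * (na - ca), 0.0).sum(axis=0) / np.maximum(
            na * (na - 1), 1
        )
        ok = (self.n_d >= 2) & (self.n_a >= 2) & (pi_d > 0)
        out["dind"] = np.where(ok, pi_a / np.where(pi_d > 0, pi_d, 1.0), np.nan)
        return out

    # -- haplotype-length statistics -----------------------------------------

    @staticmethod
    def _truncated_integral(ehh: np.ndarray, x: np.ndarray) -> tuple[float, bool]:
        """Trapezoid of the EHH curve, stopping after the first point below
        the cutoff.  Returns (integral, decayed)."""
        below = ehh < EHH_CUTOFF
        if below.any():
            k = int(np.argmax(below))
            dx = np.diff(x[: k + 1])
            return float(0.5 * np.dot(ehh[:k] + ehh[1 : k + 1], dx)), True
        dx = np.diff(x)
        return float(0.5 * np.dot(ehh[:-1] + ehh[1:], dx)), False

    def hap_length_stats_multi(
        self, half_spans: list[int | None]
    ) -> dict[int | None, dict[str, np.ndarray]]:
        """iHS and nSL for every focal site at each window half-span.

        One pass over focal sites; the per-pair mismatch lookups and sorts
        are shared across spans.
        """
        self._build_pairs()
        F = self.focal.size
        out = {
            h: {"ihs": np.full(F, np.nan), "nsl": np.full(F, np.nan)} for h in half_spans
        }
        bounds = {h: self._window_bounds(h) for h in half_spans}
        pos = self.pos.astype(np.float64)
        if self.gmap is not None:
            pos = np.asarray(self.gmap.at(pos), dtype=np.float64)
        for j in range(F):
            if self.n_d[j] < 2 or self.n_a[j] < 2:
                continue
            f = int(self.focal[j])
            av = self.matrix.alleles[self.pair_a, f].astype(bool)
            bv = self.matrix.alleles[self.pair_b, f].astype(bool)
            masks = {"d": av & bv, "a": ~av & ~bv}
            u_all, v_all = self.nxt[:, f], self.prv[:, f]
            per_bg = {}
            for key, mask in masks.items():
                u = u_all[mask]
                v = v_all[mask]
                per_bg[key] = (u, v, np.sort(u), np.sort(v), u.size)
            for h in half_spans:
                lo, hi = int(bounds[h][0][j]), int(bounds[h][1][j])
                ihh = {}
                sl = {}
                undecayed = 0
                for key, (u, v, us, vs, npairs) in per_bg.items():
                    total = 0.0
                    # right side: EHH(r) = mean(u > r) over sites r in (f, hi]
                    if hi > f:
                        r_idx = np.arange(f, hi + 1)
                        ehh = 1.0 - np.searchsorted(us, r_idx, side="right") / npairs
                        val, dec = self._truncated_integral(ehh, np.abs(pos[r_idx] - pos[f]))
                        total += val
                        undecayed += not dec
                    # left side: EHH(l) = mean(v < l) over sites l in [lo, f)
                    if lo < f:
                        l_idx = np.arange(f, lo - 1, -1)
                        ehh = np.searchsorted(vs, l_idx, side="left") / npairs
                        val, dec = self._truncated_integral(ehh, np.abs(pos[l_idx] - pos[f]))
                        total += val
                        undecayed += not dec
                    ihh[key] = total
                    seg = np.minimum(u, hi + 1) - np.maximum(v, lo - 1) - 1
                    sl[key] = seg.mean()
                if undecayed < 4 and ihh["d"] > 0 and ihh["a"] > 0:
                    out[h]["ihs"][j] = np.log(ihh["d"] / ihh["a"])
                if sl["d"] > 0 and sl["a"] > 0:
                    out[h]["nsl"][j] = np.log(sl["d"] / sl["a"])
        return out

    def hap_length_stats(self, half_span_bp: int | None) -> dict[str, np.ndarray]:
        return self.hap_length_stats_multi([half_span_bp])[half_span_bp]

    # -- assembled tables ----------------------------------------------------

    def tables(self, half_spans: list[int | None]) -> dict[int | None, pd.DataFrame]:
        """Per-SNP statistic tables for several window half-spans at once."""
        missing = [h for h in half_spans if h not in self._tables]
        if missing:
            hls = self.hap_length_stats_multi(missing)
            for h in missing:
                data: dict[str, np.ndarray] = {
                    "pos": self.pos[self.focal],
                    "daf": self.daf,
                }
                data.update(self.freq_stats(h))
                data.update(hls[h])
                self._tables[h] = pd.DataFrame(data, index=self.focal)
        return {h: self._tables[h] for h in half_spans}

    def table(self, half_span_bp: int | None) -> pd.DataFrame:
        """All per-SNP statistics at one window half-span.

        Index: site index of the focal variant; columns: position, DAF and
        the eight per-SNP statistics (NaN = not computable).
        """
        return self.tables([half_span_bp])[half_span_bp]
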