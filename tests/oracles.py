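"""Independent brute-force implementations used as oracles in tests.

Everything here is written in deliberately naive set/loop style, directly
from the statistic definitions, and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def hapdaf_brute(A, pos, focal, half_span, fa_max, sum_min):
    n, s = A.shape
    daf = A[:, focal].sum() / n
    if not 0.25 <= daf <= 0.95:
        return float("nan")
    derived = [h for h in range(n) if A[h, focal] == 1]
    ancestral = [h for h in range(n) if A[h, focal] == 0]
    terms = []
    for i in range(s):
        if i == focal or abs(pos[i] - pos[focal]) > half_span:
            continue
        cd = sum(A[h, i] for h in derived)
        ca = sum(A[h, i] for h in ancestral)
        if cd < 1 or ca < 1:  # criterion 1: present on both backgrounds
            continue
        fd = cd / len(derived)
        fa = ca / len(ancestral)
        if fd > fa and fa < fa_max and fd + fa > sum_min:  # criteria 2-4
            terms.append(fd ** 2 - fa ** 2)
    return sum(terms) / len(terms) if terms else 0.0


def sratio_brute(A, pos, focal, half_span):
    n, s = A.shape
    daf = A[:, focal].sum() / n
    if not 0.25 <= daf <= 0.95:
        return float("nan")
    derived = [h for h in range(n) if A[h, focal] == 1]
    ancestral = [h for h in range(n) if A[h, focal] == 0]
    sa = sd = 0
    for i in range(s):
        if i == focal or abs(pos[i] - pos[focal]) > half_span:
            continue
        dvals = {A[h, i] for h in derived}
        avals = {A[h, i] for h in ancestral}
        if len(dvals) > 1:
            sd += 1
        if len(avals) > 1:
            sa += 1
    return sa / sd if sd else float("nan")


def lowfreq_brute(A, pos, focal, half_span):
    return _freq_brute(A, pos, focal, half_span, "low")


def highfreq_brute(A, pos, focal, half_span):
    return _freq_brute(A, pos, focal, half_span, "high")


def _freq_brute(A, pos, focal, half_span, which):
    n, s = A.shape
    daf = A[:, focal].sum() / n
    if not 0.25 <= daf <= 0.95:
        return float("nan")
    derived = [h for h in range(n) if A[h, focal] == 1]
    terms = []
    for i in range(s):
        if i == focal or abs(pos[i] - pos[focal]) > half_span:
            continue
        fdd = sum(A[h, i] for h in derived) / len(derived)
        if fdd == 0:
            continue
        if which == "low" and fdd < 0.25:
            terms.append((1 - fdd) ** 2)
        if which == "high" and fdd > 0.25:
            terms.append(fdd ** 2)
    return sum(terms) / len(terms) if terms else 0.0


def dind_brute(A, pos, focal, half_span):
    n, s = A.shape
    daf = A[:, focal].sum() / n
    if not 0.25 <= daf <= 0.95:
        return float("nan")
    derived = [h for h in range(n) if A[h, focal] == 1]
    ancestral = [h for h in range(n) if A[h, focal] == 0]
    if len(derived) < 2 or len(ancestral) < 2:
        return float("nan")
    window = [i for i in range(s) if abs(pos[i] - pos[focal]) <= half_span]

    def pi(group):
        total = 0
        count = 0
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                total += sum(A[group[x], i] != A[group[y], i] for i in window)
                count += 1
        return total / count

    pi_d = pi(derived)
    pi_a = pi(ancestral)
    if pi_d <= 0:
        return float("nan")
    return pi_a / pi_d


def _ehh_at(A, group, focal, extent_lo, extent_hi):
    """Fraction of pairs in ``group`` identical over site span [lo, hi]."""
    pairs = same = 0
    for x in range(len(group)):
        for y in range(x + 1, len(group)):
            pairs += 1
            if all(
                A[group[x], i] == A[group[y], i] for i in range(extent_lo, extent_hi + 1)
            ):
                same += 1
    return same / pairs


def ihs_brute(A, pos, focal, half_span, cutoff=0.05):
    n, s = A.shape
    daf = A[:, focal].sum() / n
    if not 0.25 <= daf <= 0.95:
        return float("nan")
    derived = [h for h in range(n) if A[h, focal] == 1]
    ancestral = [h for h in range(n) if A[h, focal] == 0]
    if len(derived) < 2 or len(ancestral) < 2:
        return float("nan")
    if half_span is None:
        lo, hi = 0, s - 1
    else:
        inwin = [i for i in range(s) if abs(pos[i] - pos[focal]) <= half_span]
        lo, hi = min(inwin), max(inwin)

    def side(group, direction):
        sites = list(range(focal, hi + 1)) if direction > 0 else list(range(focal, lo - 1, -1))
        if len(sites) <= 1:
            return 0.0, True
        ehh = []
        for r in sites:
            a, b = (focal, r) if direction > 0 else (r, focal)
            ehh.append(_ehh_at(A, group, focal, a, b))
        total = 0.0
        decayed = False
        for k in range(1, len(sites)):
            dx = abs(pos[sites[k]] - pos[sites[k - 1]])
            total += (ehh[k - 1] + ehh[k]) / 2 * dx
            if ehh[k] < cutoff:
                decayed = True
                break
        return total, decayed

    undecayed = 0
    ihh = {}
    for key, group in (("a", ancestral), ("d", derived)):
        r, dec_r = side(group, +1)
        l, dec_l = side(group, -1)
        ihh[key] = r + l
        undecayed += (not dec_r) + (not dec_l)
    if undecayed == 4 or ihh["d"] <= 0 or ihh["a"] <= 0:
        return float("nan")
    return math.log(ihh["d"] / ihh["a"])


def nsl_brute(A, pos, focal, half_span):
    n, s = A.shape
    daf = A[:, focal].sum() / n
    if not 0.25 <= daf <= 0.95:
        return float("nan")
    derived = [h for h in range(n) if A[h, focal] == 1]
    ancestral = [h for h in range(n) if A[h, focal] == 0]
    if len(derived) < 2 or len(ancestral) < 2:
        return float("nan")
    if half_span is None:
        lo, hi = 0, s - 1
    else:
        inwin = [i for i in range(s) if abs(pos[i] - pos[focal]) <= half_span]
        lo, hi = min(inwin), max(inwin)

    def mean_sl(group):
        lengths = []
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                r = focal
                while r + 1 <= hi and A[group[x], r + 1] == A[group[y], r + 1]:
                    r += 1
                l = focal
                while l - 1 >= lo and A[group[x], l - 1] == A[group[y], l - 1]:
                    l -= 1
                lengths.append(r - l + 1)
        return sum(lengths) / len(lengths)

    sl_d = mean_sl(derived)
    sl_a = mean_sl(ancestral)
    if sl_d <= 0 or sl_a <= 0:
        return float("nan")
    return math.log(sl_d / sl_a)


def haf_top_brute(A, top_fraction=0.1):
    A = [[int(v) for v in row] for row in A]  # plain ints, no narrow dtypes
    n, s = len(A), len(A[0]) if A else 0
    if s == 0:
        return 0.0
    counts = [sum(A[h][i] for h in range(n)) for i in range(s)]
    scores = sorted(
        (sum(counts[i] for i in range(s) if A[h][i] == 1) for h in range(n)),
        reverse=True,
    )
    k = math.ceil(top_fraction * n)
    return sum(scores[:k]) / k


def safe_brute(A):
    A = [[int(v) for v in row] for row in A]
    n, s = len(A), len(A[0])
    counts = [sum(A[h][i] for h in range(n)) for i in range(s)]
    haf = [sum(counts[i] for i in range(s) if A[h][i] == 1) for h in range(n)]
    total_haf = sum(haf)
    uniq = {tuple(A[h]) for h in range(n)}
    out = []
    for i in range(s):
        carriers = [h for h in range(n) if A[h][i] == 1]
        phi = sum(haf[h] for h in carriers) / total_haf if total_haf else 0.0
        kappa = len({tuple(A[h]) for h in carriers}) / len(uniq)
        f = counts[i] / n
        out.append((phi - kappa) / math.sqrt(max(f * (1 - f), 1e-12)))
    return np.array(out)


def h12_brute(A, threshold=0.8):
    """Greedy 80%-identity clustering then (p1+p2)^2 + sum p_i^2."""
    n, s = A.shape
    if s == 0:
        return float("nan")
    seqs = [tuple(int(v) for v in A[h]) for h in range(n)]
    uniq = sorted(set(seqs))
    counts = {q: seqs.count(q) for q in uniq}
    order = sorted(uniq, key=lambda q: (-counts[q], q))  # lexicographic ties
    assigned = set()
    freqs = []
    for seed in order:
        if seed in assigned:
            continue
        members = [seed]
        assigned.add(seed)
        for other in order:
            if other in assigned:
                continue
            identity = sum(a == b for a, b in zip(seed, other)) / s
            if identity >= threshold:
                members.append(other)
                assigned.add(other)
        freqs.append(sum(counts[m] for m in members) / n)
    freqs.sort(reverse=True)
    p1 = freqs[0]
    p2 = freqs[1] if len(freqs) > 1 else 0.0
    return (p1 + p2) ** 2 + sum(p ** 2 for p in freqs[2:])


def random_matrix(rng, max_hap=12, max_sites=20, locus=10_000):
    """A random small haplotype matrix guaranteed to have >= 1 focal site
    in the computable DAF range."""
    from sweepnet import HaplotypeMatrix

    while True:
        n = int(rng.integers(4, max_hap + 1))
        s = int(rng.integers(4, max_sites + 1))
        A = (rng.random((n, s)) < rng.uniform(0.1, 0.7)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, locus), size=s, replace=False))
        daf = A.sum(axis=0) / n
        if np.any((daf >= 0.25) & (daf <= 0.95)):
            return HaplotypeMatrix(A, pos, locus)
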