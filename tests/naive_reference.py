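"""Deliberately slow, loop-based reference implementations of every
population-genetic statistic, used as independent oracles in tests.

These follow the published formulas directly with O(n^2 L) scans and no
shared code with the package's vectorized implementations.
"""

from __future__ import annotations

import math


def clean_columns(seqs: list[str]) -> list[int]:
    """Complete deletion: indices of columns with only A/C/G/T everywhere."""
    L = len(seqs[0])
    out = []
    for j in range(L):
        if all(s[j] in "ACGT" for s in seqs):
            out.append(j)
    return out


def seg_sites(seqs: list[str]) -> list[int]:
    cols = clean_columns(seqs)
    out = []
    for j in cols:
        if len({s[j] for s in seqs}) >= 2:
            out.append(j)
    return out


def eta_counts(seqs: list[str]) -> tuple[int, int]:
    """(eta_s singleton mutations, eta total mutations)."""
    eta = eta_s = 0
    for j in seg_sites(seqs):
        col = [s[j] for s in seqs]
        states = sorted(set(col))
        eta += len(states) - 1
        for st in states:
            if col.count(st) == 1:
                eta_s += 1
    return eta_s, eta


def pair_diffs(seqs: list[str]) -> list[int]:
    cols = clean_columns(seqs)
    n = len(seqs)
    out = []
    for i in range(n):
        for k in range(i + 1, n):
            out.append(sum(1 for j in cols if seqs[i][j] != seqs[k][j]))
    return out


def mean_k(seqs: list[str]) -> float:
    d = pair_diffs(seqs)
    return sum(d) / len(d)


def var_k(seqs: list[str]) -> float:
    d = pair_diffs(seqs)
    m = sum(d) / len(d)
    return sum((x - m) ** 2 for x in d) / len(d)


def pi(seqs: list[str]) -> float:
    L = len(clean_columns(seqs))
    return mean_k(seqs) / L if L else 0.0


def a_n(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson(seqs: list[str]) -> float:
    return len(seg_sites(seqs)) / a_n(len(seqs))


def tajima_d(seqs: list[str]) -> float:
    n = len(seqs)
    S = len(seg_sites(seqs))
    if S == 0:
        return math.nan
    a1 = a_n(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1)
    return (mean_k(seqs) - S / a1) / math.sqrt(var)


def fu_li(seqs: list[str]) -> tuple[float, float]:
    n = len(seqs)
    eta_s, eta = eta_counts(seqs)
    if eta == 0:
        return math.nan, math.nan
    an = a_n(n)
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
        1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n
    )
    vD = (
        (n / (n - 1)) ** 2 * bn + an**2 * dn
        - 2 * (n * an * (an + 1)) / (n - 1) ** 2
    ) / (an**2 + bn)
    uD = (n / (n - 1)) * (an - n / (n - 1)) - vD
    dstar = ((n / (n - 1)) * eta - an * eta_s) / math.sqrt(uD * eta + vD * eta**2)
    vF = (
        dn + 2 * (n * n + n + 3) / (9 * n * (n - 1))
        - (2 / (n - 1)) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    uF = (
        n / (n - 1)
        + (n + 1) / (3 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
    ) / an - vF
    fstar = (mean_k(seqs) - ((n - 1.0) / n) * eta_s) / math.sqrt(uF * eta + vF * eta**2)
    return dstar, fstar


def rarest(seqs: list[str]) -> tuple[float, float]:
    minima = []
    for j in seg_sites(seqs):
        col = [s[j] for s in seqs]
        minima.append(min(col.count(st) for st in set(col)))
    if not minima:
        return math.nan, math.nan
    m = sum(minima) / len(minima)
    return m, sum((x - m) ** 2 for x in minima) / len(minima)


def r2(seqs: list[str]) -> float:
    n = len(seqs)
    sites = seg_sites(seqs)
    S = len(sites)
    if S == 0:
        return math.nan
    U = [0.0] * n
    for j in sites:
        col = [s[j] for s in seqs]
        for st in set(col):
            if col.count(st) == 1:
                U[col.index(st)] += 1
    K = mean_k(seqs)
    return math.sqrt(sum((u - K / 2) ** 2 for u in U) / n) / S


def hudson_fst(seqs1: list[str], seqs2: list[str]) -> float:
    pooled = seqs1 + seqs2
    cols = clean_columns(pooled)

    def diff(a: str, b: str) -> int:
        return sum(1 for j in cols if a[j] != b[j])

    hw = []
    for seqs in (seqs1, seqs2):
        ds = [
            diff(seqs[i], seqs[k])
            for i in range(len(seqs))
            for k in range(i + 1, len(seqs))
        ]
        hw.append(sum(ds) / len(ds))
    hb = [diff(a, b) for a in seqs1 for b in seqs2]
    Hb = sum(hb) / len(hb)
    if Hb == 0:
        return math.nan
    return 1.0 - 0.5 * (hw[0] + hw[1]) / Hb


def divergence(seqs1: list[str], seqs2: list[str]) -> tuple[float, float, float]:
    """(Kxy, Dxy, Da) on jointly clean columns."""
    pooled = seqs1 + seqs2
    cols = clean_columns(pooled)
    L = len(cols)
    hb = [
        sum(1 for j in cols if a[j] != b[j]) for a in seqs1 for b in seqs2
    ]
    Kxy = sum(hb) / len(hb)
    Dxy = Kxy / L if L else 0.0

    def pi_on(seqs: list[str]) -> float:
        ds = [
            sum(1 for j in cols if seqs[i][j] != seqs[k][j])
            for i in range(len(seqs))
            for k in range(i + 1, len(seqs))
        ]
        return (sum(ds) / len(ds)) / L if L else 0.0

    Da = Dxy - 0.5 * (pi_on(seqs1) + pi_on(seqs2))
    return Kxy, Dxy, Da


def mismatch(seqs: list[str]) -> dict[int, int]:
    out: dict[int, int] = {}
    for d in pair_diffs(seqs):
        out[d] = out.get(d, 0) + 1
    return out
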