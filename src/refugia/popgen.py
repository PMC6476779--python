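"""Single- and two-population summary statistics for sequence alignments.

All statistics honor a common site-filtering rule.  The default is
"complete" deletion: any alignment column containing an N or a gap in any
sequence of the analysis set is dropped, and ``L_effective`` is the number
of retained columns.  Pairwise deletion (per-pair/per-site use of
non-missing entries) is available for the pair-difference family.

Statistics whose preconditions fail on a given dataset (e.g. Tajima's D
with no segregating sites) return NaN; the ABC summary-vector layer
converts NaN to a 0 sentinel plus an explicit definedness mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .seq_io import Alignment, PopulationAssignment, collapse_haplotypes

N_BASES = 4  # A,C,G,T


# ---------------------------------------------------------------------------
# site filtering and column summaries


def missing_mask(matrix: np.ndarray) -> np.ndarray:
    """True where a residue is N or '-'."""
    return matrix >= N_BASES


def retained_columns(matrix: np.ndarray, site_filter: str = "complete") -> np.ndarray:
    """Boolean mask of columns kept by the site filter."""
    if site_filter == "complete":
        return ~missing_mask(matrix).any(axis=0)
    if site_filter == "pairwise":
        # a column is usable if at least two sequences have data there
        return (~missing_mask(matrix)).sum(axis=0) >= 2
    raise ValueError(f"unknown site_filter {site_filter!r}")


def base_counts(matrix: np.ndarray) -> np.ndarray:
    """Per-column counts of A,C,G,T (shape L x 4); missing entries ignored."""
    L = matrix.shape[1]
    counts = np.zeros((L, N_BASES), dtype=np.int64)
    for b in range(N_BASES):
        counts[:, b] = (matrix == b).sum(axis=0)
    return counts


@dataclass(frozen=True)
class SegregatingSites:
    count: int
    positions: tuple[int, ...]  # 1-based alignment coordinates
    n_mutations: int  # eta: sum over sites of (observed states - 1)


def segregating_sites(
    a: Alignment, site_filter: str = "complete"
) -> SegregatingSites:
    """Count columns with >= 2 distinct non-missing nucleotides."""
    if a.n < 2:
        raise InsufficientDataError("segregating sites require n >= 2")
    keep = retained_columns(a.matrix, site_filter)
    counts = base_counts(a.matrix)
    n_states = (counts > 0).sum(axis=1)
    seg = keep & (n_states >= 2)
    eta = int((n_states[seg] - 1).sum())
    return SegregatingSites(
        int(seg.sum()), tuple(int(i) + 1 for i in np.nonzero(seg)[0]), eta
    )


# ---------------------------------------------------------------------------
# pairwise differences


def pairwise_difference_matrix(
    a: Alignment, site_filter: str = "complete"
) -> np.ndarray:
    """n x n matrix of per-pair nucleotide differences over retained columns.

    Under pairwise deletion each pair uses the columns where both sequences
    have data (no rescaling to a common length).
    """
    m = a.matrix
    keep = retained_columns(m, site_filter)
    if site_filter == "complete":
        sub = m[:, keep]
        # restrict to polymorphic columns; monomorphic ones contribute 0
        counts = base_counts(sub)
        poly = (counts > 0).sum(axis=1) >= 2
        sub = sub[:, poly]
        matches = np.zeros((a.n, a.n), dtype=np.int64)
        for b in range(N_BASES):
            x = (sub == b).astype(np.int64)
            matches += x @ x.T
        diffs = sub.shape[1] - matches
        np.fill_diagonal(diffs, 0)
        return diffs
    # pairwise deletion: count sites where both present and unequal
    present = (~missing_mask(m)).astype(np.int64)
    both = present @ present.T
    matches = np.zeros((a.n, a.n), dtype=np.int64)
    for b in range(N_BASES):
        x = (m == b).astype(np.int64)
        matches += x @ x.T
    diffs = both - matches
    np.fill_diagonal(diffs, 0)
    return diffs


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def pairwise_difference_moments(
    a: Alignment, site_filter: str = "complete"
) -> tuple[float, float, np.ndarray]:
    """Mean K and population variance of per-pair difference counts."""
    if a.n < 2:
        raise InsufficientDataError("pairwise differences require n >= 2")
    pairs = _upper(pairwise_difference_matrix(a, site_filter))
    return float(pairs.mean()), float(pairs.var()), pairs


def effective_length(a: Alignment, site_filter: str = "complete") -> int:
    return int(retained_columns(a.matrix, site_filter).sum())


def nucleotide_diversity(a: Alignment, site_filter: str = "complete") -> float:
    """pi: mean per-site pairwise difference, K / L_effective."""
    K, _, _ = pairwise_difference_moments(a, site_filter)
    L = effective_length(a, site_filter)
    return K / L if L else 0.0


# ---------------------------------------------------------------------------
# theta estimators and neutrality statistics


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n} 1/i^power."""
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


def watterson_theta(
    a: Alignment, site_filter: str = "complete"
) -> tuple[float, float]:
    """(theta_W per site, theta_W per locus) from S and the harmonic number."""
    if a.n < 2:
        raise InsufficientDataError("Watterson's theta requires n >= 2")
    S = segregating_sites(a, site_filter).count
    a1 = harmonic(a.n - 1)
    theta_locus = S / a1
    L = effective_length(a, site_filter)
    return (theta_locus / L if L else 0.0), theta_locus


def tajimas_D(a: Alignment, site_filter: str = "complete") -> float:
    """Tajima's (1989) D from K, S and n; NaN when S = 0."""
    n = a.n
    if n < 4:
        raise InsufficientDataError("Tajima's D requires n >= 4")
    S = segregating_sites(a, site_filter).count
    if S == 0:
        return math.nan
    K, _, _ = pairwise_difference_moments(a, site_filter)
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (K - S / a1) / math.sqrt(var)


def _singleton_and_total_mutations(
    a: Alignment, site_filter: str = "complete"
) -> tuple[int, int]:
    """(eta_s, eta): singleton mutations and total mutations.

    A mutation is counted per extra observed state at a site; a singleton
    mutation is a state observed in exactly one sequence (folded —
    no outgroup is used)."""
    keep = retained_columns(a.matrix, site_filter)
    counts = base_counts(a.matrix)[keep]
    n_states = (counts > 0).sum(axis=1)
    seg = n_states >= 2
    counts = counts[seg]
    eta = int((n_states[seg] - 1).sum())
    eta_s = int(((counts == 1).sum(axis=1)).sum())
    return eta_s, eta


def fu_li_Dstar_Fstar(
    a: Alignment, site_filter: str = "complete"
) -> tuple[float, float]:
    """Fu & Li's (1993) intraspecific D* and F* (no outgroup).

    Uses the corrected F* variance constants (Simonsen, Churchill &
    Aquadro 1995), matching common reference implementations.
    """
    n = a.n
    if n < 4:
        raise InsufficientDataError("Fu & Li's D*/F* require n >= 4")
    eta_s, eta = _singleton_and_total_mutations(a, site_filter)
    if eta == 0:
        return math.nan, math.nan
    an = harmonic(n - 1)
    bn = harmonic(n - 1, power=2)
    an1 = an + 1.0 / n  # a_{n+1}
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    # D* constants
    vD = (
        (n / (n - 1)) ** 2 * bn
        + an**2 * dn
        - 2 * (n * an * (an + 1)) / (n - 1) ** 2
    ) / (an**2 + bn)
    uD = (n / (n - 1)) * (an - n / (n - 1)) - vD
    Dstar = ((n / (n - 1)) * eta - an * eta_s) / math.sqrt(uD * eta + vD * eta**2)
    # F* constants (corrected)
    K, _, _ = pairwise_difference_moments(a, site_filter)
    vF = (
        dn
        + 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        - (2 / (n - 1)) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    uF = (
        (
            n / (n - 1)
            + (n + 1) / (3 * (n - 1))
            - 4.0 / (n * (n - 1))
            + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2 * n / (n + 1))
        )
        / an
        - vF
    )
    Fstar = (K - ((n - 1.0) / n) * eta_s) / math.sqrt(uF * eta + vF * eta**2)
    return Dstar, Fstar


def rarest_allele_moments(
    a: Alignment, site_filter: str = "complete"
) -> tuple[float, float]:
    """Mean and population variance of the minor-allele count at segregating
    sites; (NaN, NaN) when S = 0."""
    keep = retained_columns(a.matrix, site_filter)
    counts = base_counts(a.matrix)[keep].astype(float)
    counts[counts == 0] = np.inf
    minima = counts.min(axis=1)
    seg = (np.isfinite(counts).sum(axis=1)) >= 2
    minima = minima[seg]
    if minima.size == 0:
        return math.nan, math.nan
    return float(minima.mean()), float(minima.var())


# ---------------------------------------------------------------------------
# two-population statistics


def _between_difference_moments(
    a1: Alignment, a2: Alignment, site_filter: str = "complete"
) -> tuple[float, int, Alignment]:
    """Mean between-population pair differences on jointly retained columns."""
    pooled = Alignment(
        tuple(f"p1::{s}" for s in a1.sample_ids)
        + tuple(f"p2::{s}" for s in a2.sample_ids),
        np.vstack([a1.matrix, a2.matrix]),
        a1.locus_name,
        a1.inheritance,
    )
    diffs = pairwise_difference_matrix(pooled, site_filter)
    between = diffs[: a1.n, a1.n :]
    L = effective_length(pooled, site_filter)
    return float(between.mean()), L, pooled


def hudson_fst(
    a1: Alignment, a2: Alignment, site_filter: str = "complete"
) -> float:
    """Hudson, Slatkin & Maddison's F_ST = 1 - Hw/Hb.

    Hw is the unweighted mean of the two within-population mean pairwise
    differences; Hb the mean between-population pairwise difference, all on
    jointly retained columns.  NaN when Hb = 0.
    """
    if a1.n < 2 or a2.n < 2:
        raise InsufficientDataError("Hudson's F_ST requires n >= 2 per population")
    Hb, _, pooled = _between_difference_moments(a1, a2, site_filter)
    diffs = pairwise_difference_matrix(pooled, site_filter)
    Hw1 = float(_upper(diffs[: a1.n, : a1.n]).mean())
    Hw2 = float(_upper(diffs[a1.n :, a1.n :]).mean())
    Hw = 0.5 * (Hw1 + Hw2)
    if Hb == 0:
        return math.nan
    return 1.0 - Hw / Hb


@dataclass(frozen=True)
class DivergenceStats:
    Kxy: float  # mean between-population pair differences (per locus)
    Dxy: float  # Kxy / L_effective
    Da: float  # net per-site divergence
    fst: float
    S_private_1: int
    S_private_2: int
    S_joint: int
    L_effective: int


def _private_sites(
    a1: Alignment, a2: Alignment, keep: np.ndarray
) -> tuple[int, int]:
    """Sites segregating in one population and monomorphic in the other."""
    c1 = base_counts(a1.matrix)[keep]
    c2 = base_counts(a2.matrix)[keep]
    seg1 = (c1 > 0).sum(axis=1) >= 2
    seg2 = (c2 > 0).sum(axis=1) >= 2
    return int((seg1 & ~seg2).sum()), int((seg2 & ~seg1).sum())


def divergence_stats(
    a1: Alignment, a2: Alignment, site_filter: str = "complete"
) -> DivergenceStats:
    """Between-population divergence measures on jointly retained columns."""
    if a1.n < 2 or a2.n < 2:
        raise InsufficientDataError("divergence stats require n >= 2 per population")
    Kxy, L, pooled = _between_difference_moments(a1, a2, site_filter)
    Dxy = Kxy / L if L else 0.0
    keep = retained_columns(pooled.matrix, site_filter)
    # within-population diversity on the joint retained columns
    sub1 = Alignment(a1.sample_ids, pooled.matrix[: a1.n][:, keep], a1.locus_name, a1.inheritance) if L else a1
    sub2 = Alignment(a2.sample_ids, pooled.matrix[a1.n :][:, keep], a2.locus_name, a2.inheritance) if L else a2
    pi1 = nucleotide_diversity(sub1) if L else 0.0
    pi2 = nucleotide_diversity(sub2) if L else 0.0
    Da = Dxy - 0.5 * (pi1 + pi2)
    fst = hudson_fst(a1, a2, site_filter)
    S1, S2 = _private_sites(a1, a2, keep)
    S_joint = segregating_sites(pooled, site_filter).count
    return DivergenceStats(Kxy, Dxy, Da, fst, S1, S2, S_joint, L)


# ---------------------------------------------------------------------------
# per-population diversity summary


@dataclass(frozen=True)
class DiversityStats:
    n: int
    S: int
    n_hap: int
    pi: float
    K: float
    var_K: float
    theta_w_site: float
    theta_w_locus: float
    tajima_D: float
    fu_li_Dstar: float
    fu_li_Fstar: float
    rarest_mean: float
    rarest_var: float
    L_effective: int


def diversity_stats(a: Alignment, site_filter: str = "complete") -> DiversityStats:
    """All Table-1-style within-population statistics for one alignment."""
    S = segregating_sites(a, site_filter).count
    K, var_K, _ = pairwise_difference_moments(a, site_filter)
    th_site, th_locus = watterson_theta(a, site_filter)
    L = effective_length(a, site_filter)
    if a.n >= 4:
        D = tajimas_D(a, site_filter)
        Dstar, Fstar = fu_li_Dstar_Fstar(a, site_filter)
    else:
        D = Dstar = Fstar = math.nan
    r_mean, r_var = rarest_allele_moments(a, site_filter)
    return DiversityStats(
        n=a.n,
        S=S,
        n_hap=collapse_haplotypes(a).n_haplotypes,
        pi=K / L if L else 0.0,
        K=K,
        var_K=var_K,
        theta_w_site=th_site,
        theta_w_locus=th_locus,
        tajima_D=D,
        fu_li_Dstar=Dstar,
        fu_li_Fstar=Fstar,
        rarest_mean=r_mean,
        rarest_var=r_var,
        L_effective=L,
    )


def diversity_table(
    loci: dict[str, Alignment], pa: PopulationAssignment, site_filter: str = "complete"
) -> pd.DataFrame:
    """Per-population, per-locus diversity statistics as a tidy table."""
    from .seq_io import partition_by_population

    rows = []
    for locus_name, aln in loci.items():
        parts = partition_by_population(aln, pa)
        for label in sorted(parts) + ["All"]:
            sub = aln if label == "All" else parts[label]
            if sub.n < 2:
                continue
            d = diversity_stats(sub, site_filter)
            rows.append(
                {"locus": locus_name, "population": label}
                | {f.name: getattr(d, f.name) for f in fields(d)}
            )
    return pd.DataFrame(rows)


def divergence_table(
    loci: dict[str, Alignment], pa: PopulationAssignment, site_filter: str = "complete"
) -> pd.DataFrame:
    """Pairwise between-population divergence statistics as a tidy table."""
    from .seq_io import partition_by_population

    rows = []
    for locus_name, aln in loci.items():
        parts = partition_by_population(aln, pa)
        labels = sorted(parts)
        for i, li in enumerate(labels):
            for lj in labels[i + 1 :]:
                if parts[li].n < 2 or parts[lj].n < 2:
                    continue
                d = divergence_stats(parts[li], parts[lj], site_filter)
                rows.append(
                    {"locus": locus_name, "pop1": li, "pop2": lj}
                    | {f.name: getattr(d, f.name) for f in fields(d)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ABC summary-statistic vector


@dataclass(frozen=True)
class SummaryStatisticVector:
    """Fixed-order statistic vector with a definedness mask.

    Ordering contract: loci in the given order; within each locus, for each
    population in lexicographic label order:
    [S, S_private, K_mean, K_var, rarest_mean, rarest_var, tajima_D];
    then for each population pair (lexicographic order):
    [S_pooled, Kxy, fst].  Undefined entries hold 0.0 with mask False.
    """

    values: np.ndarray
    mask: np.ndarray  # True where defined
    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def _population_indices(
    a: Alignment, pa: PopulationAssignment
) -> dict[str, np.ndarray]:
    idx: dict[str, list[int]] = {}
    for i, s in enumerate(a.sample_ids):
        if s not in pa.mapping:
            raise KeyError(f"sample {s!r} has no population assignment")
        idx.setdefault(pa.mapping[s], []).append(i)
    return {k: np.array(v) for k, v in sorted(idx.items())}


def _tajimas_D_from_parts(n: int, S: int, K: float) -> float:
    if n < 4 or S == 0:
        return math.nan
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (K - S / a1) / math.sqrt(var) if var > 0 else math.nan


def _fast_locus_vector(
    locus_name: str, aln: Alignment, pops: dict[str, np.ndarray]
) -> tuple[list[float], list[str]]:
    """Single-pass summary statistics for one locus (complete deletion).

    Works on the matrix reduced to retained polymorphic columns; every
    statistic in the vector is invariant to dropping monomorphic columns.
    """
    keep = retained_columns(aln.matrix, "complete")
    counts_all = base_counts(aln.matrix)
    poly = keep & ((counts_all > 0).sum(axis=1) >= 2)
    m = aln.matrix[:, poly]
    labels = list(pops)
    n_all, S_all = m.shape
    onehot = [(m == b) for b in range(N_BASES)]
    X = np.concatenate([o.astype(np.float32) for o in onehot], axis=1)
    matches = X @ X.T  # matching polymorphic columns per pair (exact in f32)
    diffs = np.rint(S_all - matches).astype(np.int64)
    pc = {
        lab: np.stack([o[idx].sum(axis=0) for o in onehot], axis=1)
        for lab, idx in pops.items()
    }  # per-pop column base counts (S x 4)
    seg = {lab: (c > 0).sum(axis=1) >= 2 for lab, c in pc.items()}
    total_counts = sum(pc.values())
    values: list[float] = []
    names: list[str] = []
    for lab in labels:
        idx = pops[lab]
        n = len(idx)
        S = int(seg[lab].sum())
        rest = total_counts - pc[lab]
        seg_rest = (rest > 0).sum(axis=1) >= 2
        S_priv = int((seg[lab] & ~seg_rest).sum())
        sub = diffs[np.ix_(idx, idx)]
        pairs = sub[np.triu_indices(n, k=1)]
        K = float(pairs.mean())
        vK = float(pairs.var())
        cl = pc[lab][seg[lab]].astype(float)
        if len(cl):
            cl[cl == 0] = np.inf
            minima = cl.min(axis=1)
            rm, rv = float(minima.mean()), float(minima.var())
        else:
            rm = rv = math.nan
        D = _tajimas_D_from_parts(n, S, K)
        values += [S, S_priv, K, vK, rm, rv, D]
        names += [
            f"{locus_name}.{lab}.{s}"
            for s in ("S", "S_private", "K_mean", "K_var",
                      "rarest_mean", "rarest_var", "tajima_D")
        ]
    for i, li in enumerate(labels):
        for lj in labels[i + 1 :]:
            ci, cj = pc[li], pc[lj]
            S2 = int((((ci + cj) > 0).sum(axis=1) >= 2).sum())
            between = diffs[np.ix_(pops[li], pops[lj])]
            Kxy = float(between.mean())
            Hw1 = float(diffs[np.ix_(pops[li], pops[li])][
                np.triu_indices(len(pops[li]), k=1)].mean())
            Hw2 = float(diffs[np.ix_(pops[lj], pops[lj])][
                np.triu_indices(len(pops[lj]), k=1)].mean())
            fst = 1.0 - 0.5 * (Hw1 + Hw2) / Kxy if Kxy > 0 else math.nan
            values += [S2, Kxy, fst]
            names += [f"{locus_name}.{li}|{lj}.{s}" for s in ("S2", "Kxy", "fst")]
    return values, names


def summary_vector(
    loci: dict[str, Alignment],
    pa: PopulationAssignment,
    site_filter: str = "complete",
) -> SummaryStatisticVector:
    """Compute the full ABC summary-statistic vector for a multi-locus dataset."""
    values: list[float] = []
    names: list[str] = []
    for locus_name, aln in loci.items():
        pops = _population_indices(aln, pa)
        for lab, idx in pops.items():
            if len(idx) < 2:
                raise InsufficientDataError(
                    f"population {lab!r} has fewer than 2 sequences at {locus_name}"
                )
        if site_filter == "complete":
            v, nm = _fast_locus_vector(locus_name, aln, pops)
            values += v
            names += nm
            continue
        labels = list(pops)
        for lab in labels:
            if len(pops[lab]) < 2:
                raise InsufficientDataError(
                    f"population {lab!r} has fewer than 2 sequences at {locus_name}"
                )
        subs = {lab: aln.take(pops[lab]) for lab in labels}
        for lab in labels:
            sub = subs[lab]
            S = segregating_sites(sub, site_filter).count
            K, vK, _ = pairwise_difference_moments(sub, site_filter)
            rm, rv = rarest_allele_moments(sub, site_filter)
            try:
                D = tajimas_D(sub, site_filter)
            except InsufficientDataError:
                D = math.nan
            # private sites: segregating here, monomorphic in the pooled rest
            others = [subs[o] for o in labels if o != lab]
            rest = Alignment(
                tuple(
                    f"{o.locus_name}:{i}"
                    for o in others
                    for i in o.sample_ids
                ),
                np.vstack([o.matrix for o in others]),
                aln.locus_name,
                aln.inheritance,
            )
            pooled = Alignment(
                tuple(f"a:{s}" for s in sub.sample_ids)
                + tuple(f"b:{s}" for s in rest.sample_ids),
                np.vstack([sub.matrix, rest.matrix]),
                aln.locus_name,
                aln.inheritance,
            )
            keep = retained_columns(pooled.matrix, site_filter)
            S_priv, _ = _private_sites(sub, rest, keep)
            values += [S, S_priv, K, vK, rm, rv, D]
            names += [
                f"{locus_name}.{lab}.{s}"
                for s in ("S", "S_private", "K_mean", "K_var", "rarest_mean", "rarest_var", "tajima_D")
            ]
        for i, li in enumerate(labels):
            for lj in labels[i + 1 :]:
                d = divergence_stats(subs[li], subs[lj], site_filter)
                values += [d.S_joint, d.Kxy, d.fst]
                names += [
                    f"{locus_name}.{li}|{lj}.{s}" for s in ("S2", "Kxy", "fst")
                ]
    arr = np.array(values, dtype=float)
    mask = np.isfinite(arr)
    arr[~mask] = 0.0
    return SummaryStatisticVector(arr, mask, tuple(names))


__all__ = [
    "SegregatingSites",
    "DiversityStats",
    "DivergenceStats",
    "SummaryStatisticVector",
    "segregating_sites",
    "pairwise_difference_matrix",
    "pairwise_difference_moments",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_D",
    "fu_li_Dstar_Fstar",
    "rarest_allele_moments",
    "hudson_fst",
    "divergence_stats",
    "diversity_stats",
    "diversity_table",
    "divergence_table",
    "summary_vector",
    "effective_length",
    "harmonic",
]
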