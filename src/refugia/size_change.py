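"""Population-size-change and neutrality testing.

Covers the R2 statistic of Ramos-Onsins & Rozas (2002), mismatch
distributions, Fay & Wu's H, coalescent-simulated null p-values for any
alignment statistic, and the compound DH test (Tajima's D and Fay & Wu's H
jointly, after Zeng, Shi & Wu 2006).

Null distributions come from constant-size neutral coalescent simulations
without recombination, conditioned on theta estimated from the observed
data (Watterson's theta by default; conditioning on the observed number of
segregating sites is available as an alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coalescent import LocusConfig, mutate_sequences, standard_coalescent
from .errors import ConfigError, InsufficientDataError
from .popgen import (
    base_counts,
    pairwise_difference_matrix,
    pairwise_difference_moments,
    retained_columns,
    segregating_sites,
    tajimas_D,
    watterson_theta,
)
from .seq_io import MITOCHONDRIAL, Alignment, encode

# gene copies used for null simulations; arbitrary because only the product
# G * mu enters the sampling distribution and mu is solved from theta
_NULL_GENE_COPIES = 1.0e4


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    observed_value: float
    p_value: float
    n_simulations: int
    tail: str  # lower | upper | two-sided
    extras: dict = field(default_factory=dict)

    def rejects(self, alpha: float = 0.05) -> bool:
        return alpha > 0 and self.p_value <= alpha


@dataclass(frozen=True)
class MismatchDistribution:
    counts: np.ndarray  # indexed by pairwise-difference value 0..max

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def n_modes(self, smooth: int = 1, min_height: float = 0.05) -> int:
        """Count local maxima after a moving-average window of 2*smooth+1.

        Maxima shorter than ``min_height`` of the tallest peak are ignored
        (they are sampling blips in the histogram tails).  Descriptive
        only: modality of mismatch distributions is conventionally judged
        by eye, and this is the corresponding mechanical summary."""
        y = self.counts.astype(float)
        if smooth > 0:
            kernel = np.ones(2 * smooth + 1) / (2 * smooth + 1)
            y = np.convolve(y, kernel, mode="same")
        peak = y.max() if len(y) else 0.0
        modes = 0
        for i in range(len(y)):
            left = y[i - 1] if i > 0 else -np.inf
            right = y[i + 1] if i < len(y) - 1 else -np.inf
            if y[i] > left and y[i] >= right and y[i] >= min_height * peak:
                modes += 1
        return max(modes, 1 if len(y) else 0)


def r2_statistic(a: Alignment, site_filter: str = "complete") -> float:
    """Ramos-Onsins & Rozas' R2.

    R2 = sqrt(mean_i (U_i - K/2)^2) / S, where U_i counts the singleton
    mutations carried by sequence i (folded: minor-allele count exactly 1).
    Small values indicate population growth.  NaN when S = 0.
    """
    if a.n < 3:
        raise InsufficientDataError("R2 requires n >= 3")
    seg = segregating_sites(a, site_filter)
    if seg.count == 0:
        return math.nan
    keep = retained_columns(a.matrix, site_filter)
    counts = base_counts(a.matrix)
    U = np.zeros(a.n)
    for pos in seg.positions:
        col = pos - 1
        if not keep[col]:
            continue
        c = counts[col]
        for b in range(4):
            if c[b] == 1:
                carrier = int(np.nonzero(a.matrix[:, col] == b)[0][0])
                U[carrier] += 1
    K, _, _ = pairwise_difference_moments(a, site_filter)
    return float(np.sqrt(np.mean((U - K / 2.0) ** 2)) / seg.count)


def mismatch_distribution(
    a: Alignment, site_filter: str = "complete"
) -> MismatchDistribution:
    """Histogram of pairwise difference counts over all unordered pairs."""
    if a.n < 2:
        raise InsufficientDataError("mismatch distribution requires n >= 2")
    diffs = pairwise_difference_matrix(a, site_filter)
    iu = np.triu_indices(a.n, k=1)
    pairs = diffs[iu]
    counts = np.bincount(pairs, minlength=int(pairs.max()) + 1 if pairs.size else 1)
    return MismatchDistribution(counts)


def fay_wu_H(a: Alignment, outgroup_sequence, site_filter: str = "complete") -> float:
    """Fay & Wu's (2000) H = theta_pi - theta_H, polarized by an outgroup.

    Only biallelic segregating sites where the outgroup carries one of the
    two observed states (and no missing data) are used; the other state is
    the derived allele.  NaN when no site is polarizable.
    """
    if isinstance(outgroup_sequence, str):
        out = encode(outgroup_sequence)
    else:
        out = np.asarray(outgroup_sequence, dtype=np.uint8)
    if len(out) != a.length:
        raise InsufficientDataError("outgroup length does not match alignment")
    keep = retained_columns(a.matrix, site_filter)
    counts = base_counts(a.matrix)
    n = a.n
    total = 0.0
    used = 0
    for col in np.nonzero(keep)[0]:
        c = counts[col]
        observed = np.nonzero(c > 0)[0]
        if len(observed) != 2:
            continue
        og = int(out[col])
        if og not in observed or og >= 4:
            continue
        derived = int(observed[0] if observed[1] == og else observed[1])
        d = int(c[derived])
        total += 2.0 * d * (n - 2.0 * d)
        used += 1
    if used == 0:
        return math.nan
    return total / (n * (n - 1.0))


# ---------------------------------------------------------------------------
# null simulation


def _null_locus(a: Alignment) -> LocusConfig:
    return LocusConfig("null", a.length, MITOCHONDRIAL, "mu", model="JC69")


def simulate_null_replicates(
    a: Alignment,
    n_sims: int,
    theta_mode: str = "watterson",
    seed: int | np.random.Generator | None = None,
    site_filter: str = "complete",
):
    """Yield (alignment, ancestral sequence) pairs simulated under the
    constant-size neutral coalescent matched to the observed data.

    ``theta_mode="watterson"`` fixes the per-locus mutation rate so that
    the expected theta equals the observed Watterson estimate;
    ``"fixed_S"`` instead conditions on the observed number of segregating
    sites, placing exactly S mutations proportionally to branch lengths.
    """
    if theta_mode not in ("watterson", "fixed_S"):
        raise ConfigError(f"unknown theta_mode {theta_mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a.n
    locus = _null_locus(a)
    _, theta_locus = watterson_theta(a, site_filter)
    S_obs = segregating_sites(a, site_filter).count
    # theta_locus = 2 * G * mu_locus
    mu_site = theta_locus / (2.0 * _NULL_GENE_COPIES * max(a.length, 1))
    for _ in range(n_sims):
        tree = standard_coalescent(n, _NULL_GENE_COPIES, rng)
        if theta_mode == "watterson":
            yield mutate_sequences(tree, locus, mu_site, rng, return_ancestral=True)
        else:
            yield _fixed_s_alignment(tree, a.length, S_obs, rng)


def _fixed_s_alignment(tree, length: int, S: int, rng: np.random.Generator):
    """Infinite-sites alignment with exactly S mutations at distinct sites."""
    n = tree.n_samples
    matrix = np.zeros((n, length), dtype=np.uint8)
    root = np.zeros(length, dtype=np.uint8)
    if S > 0:
        blen = tree.branch_lengths()
        nodes = rng.choice(tree.n_nodes, size=S, p=blen / blen.sum())
        sites = rng.choice(length, size=min(S, length), replace=False)
        leaf = tree.leaf_sets()
        for k, site in enumerate(sites):
            matrix[leaf[nodes[k]], site] = 1
    ids = tuple(f"s{i + 1}" for i in range(n))
    return Alignment(ids, matrix, "null", MITOCHONDRIAL), root


def simulate_null_pvalue(
    statistic,
    a: Alignment,
    n_sims: int = 10_000,
    theta_mode: str = "watterson",
    tail: str = "lower",
    seed: int | None = None,
    statistic_name: str | None = None,
) -> TestResult:
    """Empirical p-value of an alignment statistic under the neutral null.

    The statistic callable maps an Alignment to a float (NaN = undefined;
    undefined replicates are excluded).  The p-value carries a +1/+1
    continuity correction: (b + 1) / (m + 1).
    """
    if tail not in ("lower", "upper", "two-sided"):
        raise ConfigError(f"unknown tail {tail!r}")
    obs = statistic(a)
    if not np.isfinite(obs):
        return TestResult(
            statistic_name or getattr(statistic, "__name__", "statistic"),
            obs, math.nan, 0, tail,
        )
    sims = []
    for sim_a, _anc in simulate_null_replicates(a, n_sims, theta_mode, seed):
        v = statistic(sim_a)
        if np.isfinite(v):
            sims.append(v)
    sims = np.array(sims)
    m = len(sims)
    lower = (np.sum(sims <= obs) + 1) / (m + 1)
    upper = (np.sum(sims >= obs) + 1) / (m + 1)
    if tail == "lower":
        p = lower
    elif tail == "upper":
        p = upper
    else:
        p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(
        statistic_name or getattr(statistic, "__name__", "statistic"),
        float(obs), float(p), m, tail,
        extras={"null_mean": float(sims.mean()) if m else math.nan},
    )


# ---------------------------------------------------------------------------
# compound DH test


def _joint_null_DH(
    a: Alignment, n_sims: int, seed, theta_mode: str = "watterson"
) -> tuple[np.ndarray, np.ndarray]:
    Ds, Hs = [], []
    for sim_a, anc in simulate_null_replicates(a, n_sims, theta_mode, seed):
        try:
            d = tajimas_D(sim_a)
        except InsufficientDataError:
            d = math.nan
        h = fay_wu_H(sim_a, anc)
        if np.isfinite(d) and np.isfinite(h):
            Ds.append(d)
            Hs.append(h)
    return np.array(Ds), np.array(Hs)


def compound_DH_test(
    a: Alignment,
    outgroup_sequence,
    n_sims: int = 10_000,
    seed: int | None = None,
    theta_mode: str = "watterson",
) -> TestResult:
    """Compound DH test: reject neutrality only when Tajima's D *and*
    Fay & Wu's H are both in their lower tails jointly at the nominal level.

    Following the construction of Zeng et al. (2006), the marginal quantile
    gamma is calibrated on the simulated joint null so that
    P(D <= q_D(gamma) and H <= q_H(gamma)) equals the nominal level; the
    reported p-value is the smallest level at which the observed pair
    rejects.
    """
    try:
        D_obs = tajimas_D(a)
    except InsufficientDataError:
        D_obs = math.nan
    H_obs = fay_wu_H(a, outgroup_sequence)
    if not (np.isfinite(D_obs) and np.isfinite(H_obs)):
        return TestResult("DH", math.nan, math.nan, 0, "lower")
    Ds, Hs = _joint_null_DH(a, n_sims, seed, theta_mode)
    m = len(Ds)
    if m == 0:
        return TestResult("DH", D_obs, math.nan, 0, "lower")
    # smallest marginal fraction at which both observed values are inside
    # their lower tails, then the joint mass of that rejection region
    fD = (np.sum(Ds <= D_obs) + 1) / (m + 1)
    fH = (np.sum(Hs <= H_obs) + 1) / (m + 1)
    gamma = max(fD, fH)
    qD = np.quantile(Ds, min(gamma, 1.0))
    qH = np.quantile(Hs, min(gamma, 1.0))
    p = (np.sum((Ds <= qD) & (Hs <= qH)) + 1) / (m + 1)
    return TestResult(
        "DH", float(D_obs), float(p), m, "lower",
        extras={"tajima_D": float(D_obs), "fay_wu_H": float(H_obs),
                "gamma": float(gamma)},
    )


__all__ = [
    "TestResult",
    "MismatchDistribution",
    "r2_statistic",
    "mismatch_distribution",
    "fay_wu_H",
    "simulate_null_replicates",
    "simulate_null_pvalue",
    "compound_DH_test",
]
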