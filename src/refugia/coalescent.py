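"""Coalescent simulation of three-population divergence-with-bottleneck
histories.

This is the generative engine behind the ABC machinery, the neutrality-test
null distributions, and the synthetic fixtures.  Histories are rooted
three-population trees ("Northern", "Central", "Southern") with exactly two
divergence events.  Every founding event carries a founder bottleneck: the
derived population originates at a small bottleneck size for a short
duration and then switches to its stationary effective size.

Thirteen competing scenarios are built in:

* R1..R6  — single-refugium histories: one population is the source of both
  others (e.g. R3 = "N-S;N-C": Northern founded Southern at the older time,
  then Northern founded Central).
* DS1..DS6 — distributional-shift (stepping-stone) histories: the derived
  population of the first event is the source of the second
  (e.g. DS1 = "S-N;N-C").
* V — vicariance: an ancestral population split into Northern and Southern
  at the older time, then Northern founded Central.

Time is measured in generations with a 1-year generation time, so values
divide by 1,000 to give kya.  Copy-number scaling: a population of Ne
diploid individuals carries 2Ne gene copies at a nuclear autosomal locus
and Ne/2 at a mitochondrial locus (theta_W = 4Ne*mu and Ne*mu respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .seq_io import MITOCHONDRIAL, NUCLEAR, Alignment, PopulationAssignment

POPULATIONS = ("Northern", "Central", "Southern")
_LETTER = {"N": "Northern", "C": "Central", "S": "Southern"}


# ---------------------------------------------------------------------------
# scenario specification


@dataclass(frozen=True)
class DivergenceEvent:
    """One divergence event, read forward in time.

    ``kind`` is "founding" (source persists, derived originates from it) or
    "vicariant_split" (an ancestral population splits into two daughters and
    ceases to exist).  ``time_param`` names the prior parameter holding the
    event time.
    """

    time_param: str
    kind: str
    source: str
    derived: tuple[str, ...]


@dataclass(frozen=True)
class ScenarioSpec:
    """A rooted three-population history: two ordered divergence events
    (oldest first)."""

    scenario_id: str
    events: tuple[DivergenceEvent, DivergenceEvent]
    populations: tuple[str, ...] = POPULATIONS

    def __post_init__(self) -> None:
        if len(self.events) != 2:
            raise ConfigError("a scenario has exactly 2 divergence events")

    @property
    def bottlenecked(self) -> tuple[str, ...]:
        """Populations that originate via a founder event (all derived)."""
        out: list[str] = []
        for ev in self.events:
            out.extend(ev.derived)
        return tuple(out)

    @property
    def root_population(self) -> str:
        """The population (or 'ancestral') in which all lineages end up."""
        older = self.events[0]
        return "ancestral" if older.kind == "vicariant_split" else older.source


def _parse_code(scenario_id: str, code: str) -> ScenarioSpec:
    """Parse a compact code like "S-N;N-C" or "N/S;N-C" (oldest event first)."""
    older_s, recent_s = code.split(";")
    events: list[DivergenceEvent] = []
    for i, part in enumerate([older_s, recent_s]):
        tp = "T_old" if i == 0 else "T_recent"
        if "/" in part:
            a, b = part.split("/")
            events.append(
                DivergenceEvent(tp, "vicariant_split", "ancestral",
                                (_LETTER[a], _LETTER[b]))
            )
        else:
            src, der = part.split("-")
            events.append(
                DivergenceEvent(tp, "founding", _LETTER[src], (_LETTER[der],))
            )
    return ScenarioSpec(scenario_id, (events[0], events[1]))


SCENARIO_CODES = {
    "R1": "S-N;S-C",
    "R2": "S-C;S-N",
    "R3": "N-S;N-C",
    "R4": "N-C;N-S",
    "R5": "C-S;C-N",
    "R6": "C-N;C-S",
    "DS1": "S-N;N-C",
    "DS2": "S-C;C-N",
    "DS3": "N-S;S-C",
    "DS4": "N-C;C-S",
    "DS5": "C-S;S-N",
    "DS6": "C-N;N-S",
    "V": "N/S;N-C",
}

SCENARIOS: dict[str, ScenarioSpec] = {
    sid: _parse_code(sid, code) for sid, code in SCENARIO_CODES.items()
}

REFUGIAL_IDS = tuple(f"R{i}" for i in range(1, 7))
SHIFT_IDS = tuple(f"DS{i}" for i in range(1, 7))
ALL_SCENARIO_IDS = REFUGIAL_IDS + SHIFT_IDS + ("V",)


def scenario(scenario_id: str) -> ScenarioSpec:
    try:
        return SCENARIOS[scenario_id]
    except KeyError:
        raise ConfigError(f"unknown scenario id {scenario_id!r}") from None


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class Prior:
    """A one-dimensional prior: uniform, loguniform, or a point mass.

    ``rel`` names another parameter whose drawn value scales the upper
    bound (used for bottleneck sizes bounded by a fraction of the stationary
    Ne)."""

    kind: str  # uniform | loguniform | point
    low: float
    high: float = math.nan
    rel: str | None = None
    frac: float = 1.0

    def draw(self, rng: np.random.Generator, realized: dict[str, float]) -> float:
        lo, hi = self.low, self.high
        if self.rel is not None:
            hi = max(lo * 2, self.frac * realized[self.rel])
        if self.kind == "point":
            return lo
        if self.kind == "loguniform" and lo <= 0:
            raise ConfigError("loguniform prior requires positive bounds")
        if self.kind == "uniform":
            return float(rng.uniform(lo, hi))
        if self.kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        raise ConfigError(f"unknown prior kind {self.kind!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Named priors for every demographic and mutational parameter."""

    priors: dict[str, Prior]

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def replace(self, **overrides: Prior) -> "PriorSpec":
        merged = dict(self.priors)
        merged.update(overrides)
        return PriorSpec(merged)


def default_priors() -> PriorSpec:
    """Broad defaults.

    Divergence-time priors follow the glacial chronology: the recent event
    spans the Mid-Holocene (~6 kya) to the Last Glacial Maximum (~22 kya),
    the older event the LGM to the Last Interglacial (~130 kya), at one
    generation per year.  Mutation-rate priors are per site per generation,
    with the mitochondrial range an order of magnitude above the nuclear.
    """
    priors: dict[str, Prior] = {
        "T_recent": Prior("uniform", 6_000, 22_000),
        "T_old": Prior("uniform", 22_000, 130_000),
        "mu_mt": Prior("uniform", 5.0e-9, 5.0e-7),
        "mu_nuc": Prior("uniform", 5.0e-10, 2.5e-8),
    }
    for pop in POPULATIONS + ("ancestral",):
        priors[f"Ne_{pop}"] = Prior("loguniform", 1e2, 1e6)
        priors[f"bot_duration_{pop}"] = Prior("uniform", 1, 100)
        priors[f"bot_Ne_{pop}"] = Prior("loguniform", 10, rel=f"Ne_{pop}", frac=0.1)
    return PriorSpec(priors)


@dataclass(frozen=True)
class ParameterDraw:
    """A realized parameter set for one scenario."""

    scenario_id: str
    values: dict[str, float]
    seed: int | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def required_parameters(spec: ScenarioSpec) -> list[str]:
    names = ["T_old", "T_recent", "mu_mt", "mu_nuc"]
    pops = set(spec.populations)
    if spec.root_population == "ancestral":
        pops.add("ancestral")
    for pop in sorted(pops):
        names.append(f"Ne_{pop}")
    for pop in spec.bottlenecked:
        names.append(f"bot_duration_{pop}")
        names.append(f"bot_Ne_{pop}")
    return names


def sample_prior(
    ps: PriorSpec,
    spec: ScenarioSpec,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 1000,
) -> ParameterDraw:
    """Draw one parameter set; rejection enforces T_old > T_recent."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = required_parameters(spec)
    for _ in range(max_retries):
        values: dict[str, float] = {}
        for name in names:
            values[name] = ps[name].draw(rng, values)
        if values["T_old"] > values["T_recent"]:
            # alias event times by the derived population they create
            for ev, key in zip(spec.events, ("T_old", "T_recent")):
                values[f"T_{'_'.join(p[0] for p in ev.derived)}"] = values[key]
            return ParameterDraw(spec.scenario_id, values,
                                 seed if isinstance(seed, int) else None)
    raise ConfigError(
        "could not draw T_old > T_recent from the given priors "
        f"after {max_retries} tries"
    )


# ---------------------------------------------------------------------------
# loci


@dataclass(frozen=True)
class LocusConfig:
    """A locus to simulate: length, inheritance, mutation model."""

    name: str
    length: int
    inheritance: str
    mu_param: str  # which ParameterDraw entry holds the per-site rate
    model: str = "HKY"  # HKY | K2P | JC69
    kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def gene_copies(self, ne_diploid: float) -> float:
        """Gene copies carried by Ne diploid individuals at this locus."""
        if self.inheritance == MITOCHONDRIAL:
            return ne_diploid / 2.0
        if self.inheritance == NUCLEAR:
            return 2.0 * ne_diploid
        raise DataError(f"unknown inheritance {self.inheritance!r}")

    @property
    def sequences_per_individual(self) -> int:
        return 2 if self.inheritance == NUCLEAR else 1


def default_loci() -> tuple[LocusConfig, LocusConfig]:
    """The study design: a ~1.5 kb mitochondrial locus (COI+COII scale) and
    a ~0.5 kb phased nuclear locus."""
    return (
        LocusConfig("mtDNA", 1500, MITOCHONDRIAL, "mu_mt"),
        LocusConfig("nDNA", 500, NUCLEAR, "mu_nuc"),
    )


# ---------------------------------------------------------------------------
# genealogy simulation


@dataclass
class CoalescentTree:
    """A rooted binary genealogy; node times in generations.

    Nodes 0..n-1 are samples (time 0); internal nodes are appended in
    coalescence order.  ``parent[root] == -1``.
    """

    parent: np.ndarray
    time: np.ndarray
    n_samples: int
    sample_population: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to the parent (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has = self.parent >= 0
        out[has] = self.time[self.parent[has]] - self.time[has]
        return out

    def leaf_sets(self) -> np.ndarray:
        """(n_nodes, n_samples) bool matrix of descendant samples."""
        n = self.n_nodes
        mat = np.zeros((n, self.n_samples), dtype=bool)
        mat[np.arange(self.n_samples), np.arange(self.n_samples)] = True
        # children appear before parents in node order
        for child in np.argsort(self.time, kind="stable"):
            p = self.parent[child]
            if p >= 0:
                mat[p] |= mat[child]
        return mat

    def pair_tmrca(self, i: int, j: int) -> float:
        """Time to the most recent common ancestor of samples i and j."""
        anc_i = set()
        k = i
        while k != -1:
            anc_i.add(k)
            k = int(self.parent[k])
        k = j
        while k not in anc_i:
            k = int(self.parent[k])
        return float(self.time[k])


def _population_epochs(
    spec: ScenarioSpec, draw: ParameterDraw, locus: LocusConfig
) -> tuple[dict[str, list[tuple[float, float]]], list[tuple[float, list[str], str]]]:
    """Backward-time size functions and merge events.

    Returns (epochs, merges): epochs[pop] is a list of (start_time,
    gene_copies) pieces, start times ascending; merges is a list of
    (time, source_pops_to_empty, destination_pop), time ascending.
    """
    epochs: dict[str, list[tuple[float, float]]] = {}
    pops = set(spec.populations)
    if spec.root_population == "ancestral":
        pops.add("ancestral")
    for pop in pops:
        ne = draw[f"Ne_{pop}"]
        if ne <= 0:
            raise ConfigError(f"Ne_{pop} must be positive")
        epochs[pop] = [(0.0, locus.gene_copies(ne))]
    merges: list[tuple[float, list[str], str]] = []
    for ev, key in zip(spec.events, ("T_old", "T_recent")):
        t = draw[key]
        for derived in ev.derived:
            dur = draw[f"bot_duration_{derived}"]
            bne = draw[f"bot_Ne_{derived}"]
            if bne <= 0:
                raise ConfigError(f"bot_Ne_{derived} must be positive")
            start = max(0.0, t - dur)
            epochs[derived].append((start, locus.gene_copies(bne)))
        merges.append((t, list(ev.derived), ev.source))
    merges.sort(key=lambda m: m[0])
    for pop in epochs:
        epochs[pop].sort(key=lambda e: e[0])
    return epochs, merges


def _size_at(pieces: list[tuple[float, float]], t: float) -> float:
    g = pieces[0][1]
    for start, size in pieces:
        if start <= t:
            g = size
        else:
            break
    return g


def simulate_genealogy(
    spec: ScenarioSpec,
    draw: ParameterDraw,
    locus: LocusConfig,
    sample_sizes: dict[str, int],
    seed: int | np.random.Generator | None = None,
) -> CoalescentTree:
    """Simulate one genealogy under the scenario's demography.

    ``sample_sizes`` gives gene copies (sequences) per extant population.
    Backward in time, lineages within a population coalesce at rate
    C(k,2)/G for G gene copies; at a divergence event all lineages of the
    derived population(s) move into the source.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    epochs, merges = _population_epochs(spec, draw, locus)
    n_total = sum(sample_sizes.values())
    if n_total < 1:
        raise DataError("at least one sampled sequence is required")
    parent = np.full(2 * n_total - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n_total - 1)
    sample_population: list[str] = []
    lineages: dict[str, list[int]] = {}
    nid = 0
    for pop in spec.populations:
        k = sample_sizes.get(pop, 0)
        lineages[pop] = list(range(nid, nid + k))
        sample_population.extend([pop] * k)
        nid += k
    if spec.root_population == "ancestral":
        lineages["ancestral"] = []
    next_node = n_total

    # interval breakpoints: epoch starts and merge times
    breaks = sorted(
        {s for pieces in epochs.values() for s, _ in pieces}
        | {t for t, _, _ in merges}
        | {0.0}
    )
    breaks.append(math.inf)
    merge_at = {t: (srcs, dst) for t, srcs, dst in merges}

    t = 0.0
    for b0, b1 in zip(breaks, breaks[1:]):
        t = max(t, b0)
        if b0 in merge_at:
            srcs, dst = merge_at[b0]
            for s in srcs:
                lineages.setdefault(dst, []).extend(lineages.pop(s, []))
        active = [p for p, lin in lineages.items() if len(lin) >= 2]
        while active:
            rates = np.array(
                [
                    len(lineages[p]) * (len(lineages[p]) - 1) / 2.0
                    / _size_at(epochs[p], t)
                    for p in active
                ]
            )
            total = rates.sum()
            dt = rng.exponential(1.0 / total)
            if t + dt >= b1:
                break
            t += dt
            p = active[rng.choice(len(active), p=rates / total)] if len(active) > 1 else active[0]
            lin = lineages[p]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[i], lin[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            time[node] = t
            for x in sorted([i, j], reverse=True):
                lin.pop(x)
            lin.append(node)
            active = [q for q, l2 in lineages.items() if len(l2) >= 2]
        if next_node == 2 * n_total - 1:
            break
    return CoalescentTree(parent, time, n_total, tuple(sample_population))


def standard_coalescent(
    n: int, gene_copies: float, seed: int | np.random.Generator | None = None
) -> CoalescentTree:
    """Constant-size single-population coalescent for n gene copies.

    Pair coalescence rate is C(k,2)/G per generation; E[pairwise TMRCA] = G.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if gene_copies <= 0:
        raise ConfigError("gene_copies must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    lineages = list(range(n))
    t = 0.0
    nid = n
    k = n
    while k > 1:
        t += rng.exponential(gene_copies / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent[a] = parent[b] = nid
        time[nid] = t
        for x in sorted([i, j], reverse=True):
            lineages.pop(x)
        lineages.append(nid)
        nid += 1
        k -= 1
    return CoalescentTree(parent, time, n, tuple(["pop"] * n))


# ---------------------------------------------------------------------------
# sequence mutation


_TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def _substitution_tables(
    model: str, kappa: float, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base replacement alternatives and cumulative probabilities.

    Row b lists the three bases a mutation can turn b into, weighted by
    kappa for transitions (K2P/HKY) and by target frequency (HKY)."""
    others = np.zeros((4, 3), dtype=np.uint8)
    cum = np.zeros((4, 3))
    for b in range(4):
        alts = [x for x in range(4) if x != b]
        others[b] = alts
        if model == "JC69":
            w = np.ones(3)
        else:
            w = np.array(
                [
                    (kappa if _TRANSITION_PARTNER[b] == x else 1.0)
                    * (freqs[x] if model == "HKY" else 1.0)
                    for x in alts
                ]
            )
        cum[b] = np.cumsum(w / w.sum())
    return others, cum


def mutate_sequences(
    tree: CoalescentTree,
    locus: LocusConfig,
    mu: float,
    seed: int | np.random.Generator | None = None,
    sample_ids: tuple[str, ...] | None = None,
    return_ancestral: bool = False,
) -> Alignment:
    """Drop finite-site substitutions on a genealogy and return sequences.

    Substitution count is Poisson(total branch length x mu x L); events are
    placed uniformly over branch length and sites, then resolved oldest
    first under the locus substitution model from a random root sequence.
    With ``return_ancestral`` the (alignment, root sequence) pair is
    returned, which lets callers polarize derived states exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, L = tree.n_samples, locus.length
    freqs = np.asarray(locus.base_frequencies)
    root_seq = rng.choice(4, size=L, p=freqs / freqs.sum()).astype(np.uint8)
    matrix = np.repeat(root_seq[None, :], n, axis=0)
    blen = tree.branch_lengths()
    total = blen.sum()
    n_mut = rng.poisson(total * mu * L) if mu > 0 and total > 0 else 0
    if n_mut > 0:
        nodes = rng.choice(tree.n_nodes, size=n_mut, p=blen / total)
        sites = rng.integers(L, size=n_mut)
        ages = tree.time[nodes] + rng.uniform(size=n_mut) * blen[nodes]
        us = rng.uniform(size=n_mut)
        others, cum = _substitution_tables(locus.model, locus.kappa, freqs)
        leaf = tree.leaf_sets()
        first_leaf = np.array(
            [int(np.argmax(leaf[v])) if leaf[v].any() else -1
             for v in range(tree.n_nodes)]
        )
        order = np.argsort(-ages)  # oldest first
        for k in order:
            v = nodes[k]
            if first_leaf[v] < 0:
                continue
            site = sites[k]
            current = matrix[first_leaf[v], site]
            new = others[current, np.searchsorted(cum[current], us[k])]
            matrix[leaf[v], site] = new
    if sample_ids is None:
        counters: dict[str, int] = {}
        ids = []
        for pop in tree.sample_population:
            counters[pop] = counters.get(pop, 0) + 1
            ids.append(f"{pop}_{counters[pop]}")
        sample_ids = tuple(ids)
    aln = Alignment(sample_ids, matrix, locus.name, locus.inheritance)
    if return_ancestral:
        return aln, root_seq
    return aln


# ---------------------------------------------------------------------------
# full dataset simulation


DEFAULT_SAMPLE_SIZES = {"Southern": 16, "Northern": 24, "Central": 82}


def simulate_dataset(
    spec: ScenarioSpec,
    draw: ParameterDraw,
    loci: tuple[LocusConfig, ...],
    sample_sizes: dict[str, int],
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, Alignment], PopulationAssignment]:
    """Simulate a multi-locus dataset under one demographic draw.

    ``sample_sizes`` counts diploid individuals per population; a nuclear
    locus contributes two phased sequences per individual (ids suffixed
    /1, /2), a mitochondrial locus one.  Genealogies are independent across
    loci (free recombination between, none within).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alignments: dict[str, Alignment] = {}
    mapping: dict[str, str] = {}
    for pop, k in sample_sizes.items():
        for i in range(1, k + 1):
            ind = f"{pop}_{i}"
            mapping[ind] = pop
            mapping[f"{ind}/1"] = pop
            mapping[f"{ind}/2"] = pop
    for locus in loci:
        copies = locus.sequences_per_individual
        sizes = {p: k * copies for p, k in sample_sizes.items()}
        tree = simulate_genealogy(spec, draw, locus, sizes, rng)
        ids: list[str] = []
        counters: dict[str, int] = {}
        for pop in tree.sample_population:
            c = counters.get(pop, 0)
            counters[pop] = c + 1
            ind = c // copies + 1
            ids.append(
                f"{pop}_{ind}" if copies == 1 else f"{pop}_{ind}/{c % copies + 1}"
            )
        mu = draw[locus.mu_param]
        alignments[locus.name] = mutate_sequences(
            tree, locus, mu, rng, sample_ids=tuple(ids)
        )
    return alignments, PopulationAssignment(mapping)


__all__ = [
    "POPULATIONS",
    "DivergenceEvent",
    "ScenarioSpec",
    "SCENARIO_CODES",
    "SCENARIOS",
    "REFUGIAL_IDS",
    "SHIFT_IDS",
    "ALL_SCENARIO_IDS",
    "scenario",
    "Prior",
    "PriorSpec",
    "default_priors",
    "ParameterDraw",
    "required_parameters",
    "sample_prior",
    "LocusConfig",
    "default_loci",
    "CoalescentTree",
    "standard_coalescent",
    "simulate_genealogy",
    "mutate_sequences",
    "simulate_dataset",
    "DEFAULT_SAMPLE_SIZES",
]
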