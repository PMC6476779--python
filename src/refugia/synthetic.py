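"""Synthetic fixtures with known truth for every pipeline stage.

Sequence fixtures are drawn from the coalescent engine under the
best-supported stepping-stone history (Southern founded Northern ~64.8 kya,
Northern founded Central ~8.6 kya, founder bottlenecks at both events) with
effective sizes chosen to reproduce the study system's qualitative
signature: within-population diversity ordered pi_S > pi_N > pi_C and a
negative Tajima's D in the recently founded, expanding Central population.

Raster fixtures are spatially autocorrelated probability surfaces whose
high-suitability ridge can drift northward between periods, so that the
shift-map algebra exercises all four categories; occurrence fixtures place
presences preferentially in high-probability cells and pseudo-absences
uniformly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .coalescent import (
    DEFAULT_SAMPLE_SIZES,
    LocusConfig,
    ParameterDraw,
    Prior,
    PriorSpec,
    ScenarioSpec,
    default_loci,
    default_priors,
    sample_prior,
    scenario,
    simulate_dataset,
)
from .errors import DataError
from .popgen import nucleotide_diversity, segregating_sites, tajimas_D
from .sdm import GridSpec, OccurrenceSet, ProbabilityRaster
from .seq_io import (
    Alignment,
    PopulationAssignment,
    partition_by_population,
    write_alignment,
    write_assignment,
)

# Truth defaults: divergence times are the study's point estimates (in
# generations at 1 generation/year); mutation rates are the ABC point
# estimates (12% per lineage per My for mtDNA, 0.6% for nDNA); effective
# sizes are set so that theta = Ne*mu reproduces the observed per-site
# diversities (pi_S ~ 0.016, pi_N ~ 0.010, pi_C ~ 0.003).
DEFAULT_TRUTH = {
    "T_old": 64_800.0,
    "T_recent": 8_630.0,
    "mu_mt": 1.2e-7,
    "mu_nuc": 6.0e-9,
    "Ne_Southern": 130_000.0,
    "Ne_Northern": 85_000.0,
    "Ne_Central": 25_000.0,
    "Ne_ancestral": 100_000.0,
    "bot_duration": 50.0,
    "bot_Ne": 100.0,
}


def default_truth_draw(scenario_id: str = "DS1") -> ParameterDraw:
    """The fixture's true parameter set for any of the 13 scenarios."""
    spec = scenario(scenario_id)
    values = {
        k: v for k, v in DEFAULT_TRUTH.items() if not k.startswith("bot_")
    }
    for pop in spec.bottlenecked:
        values[f"bot_duration_{pop}"] = DEFAULT_TRUTH["bot_duration"]
        values[f"bot_Ne_{pop}"] = DEFAULT_TRUTH["bot_Ne"]
    for ev, key in zip(spec.events, ("T_old", "T_recent")):
        values[f"T_{'_'.join(p[0] for p in ev.derived)}"] = values[key]
    return ParameterDraw(scenario_id, values)


def separated_priors() -> PriorSpec:
    """Narrow priors that make the 13 scenarios mutually distinguishable.

    Divergence-time bands are tight and non-overlapping, founder
    bottlenecks are strong, and mutation rates are fixed at their point
    estimates, so that scenario-recovery experiments probe the model-choice
    machinery rather than prior diffuseness.
    """
    priors = dict(default_priors().priors)
    priors.update(
        {
            "T_old": Prior("uniform", 55_000, 75_000),
            "T_recent": Prior("uniform", 7_000, 11_000),
            "mu_mt": Prior("point", 1.2e-7),
            "mu_nuc": Prior("point", 6.0e-9),
        }
    )
    # Ne is set so the mitochondrial locus (Ne/2 gene copies) coalesces on
    # the scale of the divergence times while the nuclear locus (2Ne) is
    # much deeper: the shallow locus then records the direction of the
    # recent founding and the deep locus preserves the older founder
    # signature instead of re-equilibrating.
    for pop in ("Northern", "Central", "Southern", "ancestral"):
        priors[f"Ne_{pop}"] = Prior("loguniform", 1.2e5, 2.0e5)
        priors[f"bot_duration_{pop}"] = Prior("uniform", 80, 100)
        priors[f"bot_Ne_{pop}"] = Prior("loguniform", 10, 50)
    return PriorSpec(priors)


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to reproduce a fixture byte-for-byte."""

    scenario_id: str
    params: dict[str, float]
    seed: int
    attempt: int
    sample_sizes: dict[str, int]
    loci: tuple[dict, ...]
    signature_ok: bool
    files: tuple[str, ...] = ()

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _signature_holds(
    loci_data: dict[str, Alignment], pa: PopulationAssignment
) -> bool:
    """pi_S > pi_N > pi_C and Tajima's D < 0 in Central, on the mtDNA locus."""
    mt = next(
        (a for a in loci_data.values() if a.inheritance == "mitochondrial_haploid"),
        None,
    )
    if mt is None:
        return True
    parts = partition_by_population(mt, pa)
    try:
        pi = {lab: nucleotide_diversity(parts[lab]) for lab in parts}
        if segregating_sites(parts["Central"]).count == 0:
            return False
        d_central = tajimas_D(parts["Central"])
    except (KeyError, DataError):
        return False
    return (
        pi.get("Southern", 0) > pi.get("Northern", 0) > pi.get("Central", 0)
        and np.isfinite(d_central)
        and d_central < 0
    )


def make_sequence_fixture(
    scenario_id: str = "DS1",
    params: ParameterDraw | None = None,
    priors: PriorSpec | None = None,
    sample_sizes: dict[str, int] | None = None,
    loci: tuple[LocusConfig, ...] | None = None,
    seed: int = 0,
    outdir=None,
    check_signature: bool = True,
    max_retries: int = 5,
) -> tuple[dict[str, Alignment], PopulationAssignment, TruthRecord]:
    """Generate a multi-locus dataset with known demographic truth.

    If ``params`` is omitted the defaults above are used (or a prior draw
    when ``priors`` is given).  The realized data are checked for the
    study signature (diversity ordering and Central expansion); generation
    retries with a derived seed up to ``max_retries`` times and reports
    the outcome in the TruthRecord rather than looping forever.
    """
    spec = scenario(scenario_id)
    sample_sizes = dict(sample_sizes or DEFAULT_SAMPLE_SIZES)
    loci = loci or default_loci()
    signature_ok = False
    loci_data: dict[str, Alignment] = {}
    pa = PopulationAssignment({})
    attempt = 0
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        if params is not None:
            draw = params
        elif priors is not None:
            draw = sample_prior(priors, spec, rng)
        else:
            draw = default_truth_draw(scenario_id)
        loci_data, pa = simulate_dataset(spec, draw, loci, sample_sizes, rng)
        if not check_signature or _signature_holds(loci_data, pa):
            signature_ok = True
            break
    files: list[str] = []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, aln in loci_data.items():
            p = outdir / f"{name}.fasta"
            write_alignment(aln, p)
            files.append(str(p))
        p = outdir / "populations.csv"
        write_assignment(pa, p)
        files.append(str(p))
    record = TruthRecord(
        scenario_id,
        dict(draw.values),
        seed,
        attempt,
        sample_sizes,
        tuple(
            {"name": l.name, "length": l.length, "inheritance": l.inheritance}
            for l in loci
        ),
        signature_ok,
        tuple(files),
    )
    if outdir is not None:
        record.to_json(Path(outdir) / "truth.json")
    return loci_data, pa, record


# ---------------------------------------------------------------------------
# raster fixtures


def make_raster_fixture(
    shape: tuple[int, int] = (60, 80),
    n_periods: int = 4,
    length_scale: float = 6.0,
    trend: str = "northward_shift",
    seed: int = 0,
    grid: GridSpec | None = None,
) -> list[ProbabilityRaster]:
    """Smooth correlated probability surfaces for successive time periods.

    Returned oldest first (period labels LIG, LGM, MH, present for the
    default four).  ``northward_shift`` migrates the high-probability
    ridge toward low row indices (north) between periods so that shift
    maps show colonization at the leading and extinction at the trailing
    edge; ``expansion`` widens the ridge; ``static`` keeps it fixed with
    only small independent noise.
    """
    if shape[0] < 10 or shape[1] < 10:
        raise DataError("raster fixture needs shape >= 10x10")
    if trend not in ("northward_shift", "expansion", "static"):
        raise DataError(f"unknown trend {trend!r}")
    rng = np.random.default_rng(seed)
    grid = grid or GridSpec(0.0, 0.0, 1.0)
    labels = ["LIG", "LGM", "MH", "present"]
    if n_periods != 4:
        labels = [f"period{i + 1}" for i in range(n_periods)]
    base = gaussian_filter(rng.standard_normal(shape), length_scale)
    base /= max(base.std(), 1e-12)
    rows = np.arange(shape[0], dtype=float)[:, None]
    out: list[ProbabilityRaster] = []
    for i in range(n_periods):
        frac = i / max(n_periods - 1, 1)
        if trend == "northward_shift":
            center = shape[0] * (0.8 - 0.6 * frac)
            width = shape[0] / 6.0
        elif trend == "expansion":
            center = shape[0] * 0.5
            width = shape[0] * (0.08 + 0.30 * frac)
        else:
            center = shape[0] * 0.5
            width = shape[0] / 3.0
        ridge = np.exp(-0.5 * ((rows - center) / width) ** 2)
        noise = gaussian_filter(rng.standard_normal(shape), length_scale)
        noise /= max(noise.std(), 1e-12)
        amp = 0.01 if trend == "static" else 0.6
        # steep squashing keeps suitability near 0/1 so suitable area is a
        # minority of cells and presences concentrate strongly
        logit = 4.0 * (4.0 * ridge - 3.5 + 0.8 * base + amp * noise)
        prob = 1.0 / (1.0 + np.exp(-logit))
        out.append(ProbabilityRaster(prob, grid, labels[i]))
    return out


def make_occurrence_fixture(
    raster: ProbabilityRaster,
    n_presence: int = 91,
    n_pseudo_absence: int = 100,
    n_replicates: int = 20,
    seed: int = 0,
) -> OccurrenceSet:
    """Sample presences proportionally to cell probability and replicated
    pseudo-absences uniformly over valid cells; points sit at cell centers."""
    valid = np.isfinite(raster.values)
    if not valid.any():
        raise DataError("raster is entirely no-data")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(valid)
    probs = raster.values[rows, cols]
    weights = probs / probs.sum()
    nrows = raster.shape[0]
    g = raster.grid

    def _xy(r: int, c: int) -> tuple[float, float]:
        x = g.xll + (c + 0.5) * g.cellsize
        y = g.yll + (nrows - 1 - r + 0.5) * g.cellsize
        return x, y

    pres_idx = rng.choice(len(rows), size=n_presence, p=weights)
    presences = np.array([_xy(rows[i], cols[i]) for i in pres_idx])
    reps = []
    for _ in range(n_replicates):
        idx = rng.choice(len(rows), size=n_pseudo_absence)
        reps.append(np.array([_xy(rows[i], cols[i]) for i in idx]))
    return OccurrenceSet(presences, tuple(reps))


__all__ = [
    "DEFAULT_TRUTH",
    "default_truth_draw",
    "separated_priors",
    "TruthRecord",
    "make_sequence_fixture",
    "make_raster_fixture",
    "make_occurrence_fixture",
]
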