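"""Forward simulation of gametes, crosses, and pseudo-backcross programs.

Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson(L/100) for a map length of L cM, breakpoints are uniform, and there
is no interference, no obligate chiasma, and no sex difference. Truth
ancestry labels (exotic vs domestic) are spliced at the same breakpoints as
the alleles, so every simulated individual carries scoreable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .genome_model import (
    AncestrySegment,
    GeneticMap,
    Pedigree,
    PedigreeRecord,
    PhasedIndividual,
    RGeneLocus,
    ValidationError,
    truth_origin_fraction,
)
from .synthetic_data import EXOTIC, FounderSet


class ProgramExtinctionError(RuntimeError):
    """A breeding-program generation ended with zero surviving carriers."""


@dataclass(frozen=True)
class ProgramConfig:
    """Settings for a multi-generation marker-assisted pseudo-backcross run.

    ``flowering_probs`` are per-vernalization-cycle success probabilities
    (at most four cycles; seedlings not flowering by the fourth are
    discarded). ``background_selection`` ranks surviving carriers by truth
    exotic fraction and keeps the lowest ``n_background_keep``.
    """

    n_generations: int = 5
    offspring_per_cross: int = 60
    foreground_selection: bool = True
    flowering_probs: tuple[float, ...] = ()
    background_selection: str = "off"  # off | min_donor_fraction
    n_background_keep: int = 2
    n_parents_per_generation: int = 1

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValidationError("n_generations must be >= 1")
        if any(not 0.0 <= p <= 1.0 for p in self.flowering_probs):
            raise ValidationError("flowering probabilities must lie in [0, 1]")
        if self.background_selection not in ("off", "min_donor_fraction"):
            raise ValidationError("unknown background_selection mode")


def _splice_truth(
    segsA: list[AncestrySegment],
    segsB: list[AncestrySegment],
    breaks: np.ndarray,
    start: int,
    chrom: str,
    lo: float,
    hi: float,
) -> list[AncestrySegment]:
    """Splice two tiled segment lists at the given breakpoints."""
    src = (segsA, segsB)
    bounds = np.concatenate(([lo], breaks, [hi]))
    out: list[AncestrySegment] = []
    for k in range(len(bounds) - 1):
        a, b = float(bounds[k]), float(bounds[k + 1])
        if b <= a:
            continue
        for seg in src[(start + k) % 2]:
            s, e = max(seg.start_cM, a), min(seg.end_cM, b)
            if e > s:
                if (
                    out
                    and out[-1].origin == seg.origin
                    and out[-1].source == seg.source
                    and out[-1].end_cM >= s - 1e-9
                ):
                    out[-1] = AncestrySegment(
                        chrom, out[-1].start_cM, e, seg.origin, seg.source
                    )
                else:
                    out.append(AncestrySegment(chrom, s, e, seg.origin, seg.source))
    return out


def simulate_gamete(
    parent: PhasedIndividual, gmap: GeneticMap, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], Optional[dict[str, list[AncestrySegment]]]]:
    """One recombinant gamete: alleles plus (if available) ancestry labels."""
    hap: dict[str, np.ndarray] = {}
    truth: Optional[dict[str, list[AncestrySegment]]] = (
        {} if parent.truth is not None else None
    )
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        lo, hi = float(pos[0]), float(pos[-1])
        L = hi - lo
        n_co = rng.poisson(L / 100.0)
        breaks = np.sort(rng.uniform(lo, hi, n_co))
        start = int(rng.integers(2))
        homolog_at = (start + np.searchsorted(breaks, pos, side="right")) % 2
        hap[chrom] = parent.hap[chrom][homolog_at, np.arange(pos.size)]
        if truth is not None:
            truth[chrom] = _splice_truth(
                parent.truth[chrom][0], parent.truth[chrom][1],
                breaks, start, chrom, lo, hi,
            )
    return hap, truth


def make_cross(
    mother: PhasedIndividual,
    father: PhasedIndividual,
    n_offspring: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str = "IND",
    generation: str = "",
) -> list[PhasedIndividual]:
    """Offspring = one maternal + one paternal gamete each."""
    out = []
    for j in range(n_offspring):
        mh, mt = simulate_gamete(mother, gmap, rng)
        fh, ft = simulate_gamete(father, gmap, rng)
        truth = None
        if mt is not None and ft is not None:
            truth = {c: [mt[c], ft[c]] for c in gmap.chromosomes}
        out.append(
            PhasedIndividual(
                id=f"{id_prefix}_{j + 1:04d}",
                hap={c: np.vstack([mh[c], fh[c]]) for c in gmap.chromosomes},
                truth=truth,
                generation=generation,
                mother=mother.id,
                father=father.id,
            )
        )
    return out


def apply_flowering_attrition(
    pop: Sequence[PhasedIndividual],
    flowering_probs: Sequence[float],
    rng: np.random.Generator,
) -> tuple[list[PhasedIndividual], list[PhasedIndividual]]:
    """Split a cohort into (flowered, discarded) over vernalization cycles.

    An individual flowers at cycle k with probability p_k conditional on
    not having flowered before; the cumulative fraction by cycle 4 is
    1 - prod(1 - p_k). More than four cycles is an error (the protocol
    discards seedlings that have not flowered by then).
    """
    if len(flowering_probs) > 4:
        raise ValidationError("at most four vernalization cycles are modeled")
    flowered, discarded = [], []
    for ind in pop:
        cycle = None
        for k, p in enumerate(flowering_probs, start=1):
            if rng.random() < p:
                cycle = k
                break
        if cycle is None:
            discarded.append(ind)
        else:
            ind.meta["flowered_cycle"] = cycle
            flowered.append(ind)
    return flowered, discarded


@dataclass
class PbcResult:
    """Output of a pseudo-backcross program run."""

    generations: dict[str, list[PhasedIndividual]]  # label -> retained carriers
    all_offspring: dict[str, list[PhasedIndividual]]
    pedigree: Pedigree
    summary: "object" = None  # pandas DataFrame, set by run_pbc_series

    def generation_labels(self) -> list[str]:
        return list(self.generations)


def generation_label(g: int) -> str:
    """Meiosis count from the donor -> cohort label (1 -> F1, 2 -> pBC1...)."""
    return "F1" if g == 1 else f"pBC{g - 1}"


def run_pbc_series(
    founders: FounderSet,
    config: ProgramConfig,
    rng: np.random.Generator,
) -> PbcResult:
    """Run a marker-assisted pseudo-backcross program.

    Each generation crosses the current carrier parents to fresh unrelated
    domestic recurrent parents, retains offspring that carry the foreground
    R-gene (when foreground selection is on), applies flowering attrition,
    and optionally background-selects the carriers with the least truth
    exotic genome. Generations are parameterized by meiosis count from the
    donor, never by label.
    """
    from . import mas_calls  # local import to avoid a cycle

    gmap = founders.gmap
    parents: list[PhasedIndividual] = [founders.donor]
    ped_records = [
        PedigreeRecord(founders.donor.id, founders.donor.mother,
                       founders.donor.father, "donor")
    ]
    known = {founders.donor.id}
    generations: dict[str, list[PhasedIndividual]] = {}
    all_offspring: dict[str, list[PhasedIndividual]] = {}
    rows = []
    for g in range(1, config.n_generations + 1):
        label = generation_label(g)
        offspring: list[PhasedIndividual] = []
        use_parents = parents[: config.n_parents_per_generation]
        for pi, parent in enumerate(use_parents):
            rp = founders.fresh_domestic(1, rng)[0]
            offspring.extend(
                make_cross(
                    parent, rp, config.offspring_per_cross, gmap, rng,
                    id_prefix=f"{label}_{pi + 1}", generation=label,
                )
            )
            ped_records.append(PedigreeRecord(rp.id, None, None, "founder"))
            known.add(rp.id)
        for o in offspring:
            ped_records.append(PedigreeRecord(o.id, o.mother, o.father, label))
        all_offspring[label] = offspring

        if config.foreground_selection and founders.panel:
            screen = mas_calls.screen_population(
                offspring, founders.panel, [founders.rgene.name],
                marker_loci=founders.panel_loci,
            )
            retained = screen.selected
        else:
            retained = list(offspring)

        if config.flowering_probs:
            flowered, _ = apply_flowering_attrition(
                retained, config.flowering_probs, rng
            )
        else:
            flowered = retained

        if config.background_selection == "min_donor_fraction" and flowered:
            flowered = sorted(
                flowered, key=lambda i: truth_origin_fraction(i, gmap, EXOTIC)
            )[: config.n_background_keep]

        if not flowered:
            raise ProgramExtinctionError(
                f"no surviving carriers in generation {label}"
            )
        generations[label] = flowered
        fracs = [truth_origin_fraction(i, gmap, EXOTIC) for i in flowered]
        rows.append(
            {
                "generation": label,
                "n_meioses": g,
                "n_offspring": len(offspring),
                "n_retained": len(flowered),
                "mean_truth_exotic_pct": 100.0 * float(np.mean(fracs)),
            }
        )
        parents = flowered
    import pandas as pd

    return PbcResult(
        generations=generations,
        all_offspring=all_offspring,
        pedigree=Pedigree(ped_records),
        summary=pd.DataFrame(rows),
    )
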