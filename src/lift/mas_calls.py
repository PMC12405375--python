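"""Foreground marker-assisted selection.

An R-gene is called present in a seedling when its panel markers show the
coupling allele — the allele in cis with the resistance allele in the donor.
Markers with missing genotypes are uninformative; with zero informative
markers a call is *undetermined*, never *absent*. Two combination rules are
offered: "all" (every informative marker must support, the default) and
"majority".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binomtest

from .genome_model import MarkerPanelEntry, PhasedIndividual, ValidationError

PRESENT, ABSENT, UNDETERMINED = "present", "absent", "undetermined"

#: genotype code -> observed unordered allele pair, array (A/B) encoding
_CODE_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}


@dataclass(frozen=True)
class MarkerEvidence:
    marker: str
    observed: Optional[tuple]
    informative: bool
    supports: bool


@dataclass
class MasCall:
    individual: str
    rgene: str
    status: str  # present | absent | undetermined
    evidence: list[MarkerEvidence] = field(default_factory=list)
    discordant: bool = False

    @property
    def present(self) -> Optional[bool]:
        return None if self.status == UNDETERMINED else self.status == PRESENT


def _norm(a) -> str:
    return str(a).strip()


def call_rgene_presence(
    genotypes: Mapping[str, Optional[Sequence]],
    entries: Sequence[MarkerPanelEntry],
    rule: str = "all",
    individual: str = "",
) -> MasCall:
    """Call one R-gene from the observed alleles at its panel markers.

    ``genotypes`` maps marker name -> observed alleles (an unordered pair
    for SSR/SNP, a presence flag for SCAR) or None when not genotyped. A
    marker supports presence iff its coupling allele is among the observed
    alleles.
    """
    if rule not in ("all", "majority"):
        raise ValidationError(f"unknown combination rule {rule!r}")
    if not entries:
        raise ValidationError("no panel entries supplied")
    rgene = entries[0].rgene
    evidence = []
    for e in entries:
        obs = genotypes.get(e.marker_name)
        if obs is None:
            evidence.append(MarkerEvidence(e.marker_name, None, False, False))
            continue
        obs_t = tuple(obs) if isinstance(obs, (tuple, list, set, frozenset)) else (obs,)
        supports = _norm(e.coupling_allele) in {_norm(a) for a in obs_t}
        evidence.append(MarkerEvidence(e.marker_name, obs_t, True, supports))
    informative = [ev for ev in evidence if ev.informative]
    if not informative:
        return MasCall(individual, rgene, UNDETERMINED, evidence)
    n_support = sum(ev.supports for ev in informative)
    discordant = 0 < n_support < len(informative)
    if rule == "all":
        status = PRESENT if n_support == len(informative) else ABSENT
    else:
        status = PRESENT if n_support * 2 > len(informative) else ABSENT
    return MasCall(individual, rgene, status, evidence, discordant)


def snp_marker_genotypes(
    ind: PhasedIndividual, marker_loci: Mapping[str, tuple[str, int]]
) -> dict[str, Optional[tuple]]:
    """Observed unordered allele pairs at SNP panel markers (A/B letters)."""
    out: dict[str, Optional[tuple]] = {}
    for marker, (chrom, i) in marker_loci.items():
        code = int(ind.genotypes(chrom)[i])
        out[marker] = _CODE_ALLELES.get(code)  # missing -> None
    return out


@dataclass
class ScreenResult:
    selected: list[PhasedIndividual]
    rejected: list[PhasedIndividual]
    undetermined: list[PhasedIndividual]
    calls: dict[str, dict[str, MasCall]]  # individual -> rgene -> call
    per_gene_counts: dict[str, dict[str, int]]

    @property
    def n_tested(self) -> int:
        return len(self.selected) + len(self.rejected) + len(self.undetermined)


def screen_population(
    pop: Sequence[PhasedIndividual],
    panel: Sequence[MarkerPanelEntry],
    required_rgenes: Sequence[str],
    marker_loci: Optional[Mapping[str, tuple[str, int]]] = None,
    genotype_getter=None,
    rule: str = "all",
) -> ScreenResult:
    """Partition a population into (selected, rejected, undetermined).

    Selected = all required R-genes called present; undetermined = at least
    one required gene undetermined and none absent; rejected otherwise.
    Genotypes come from ``genotype_getter(ind)`` or, for SNP panels on
    simulated individuals, from ``marker_loci``.
    """
    missing = [g for g in required_rgenes if not any(e.rgene == g for e in panel)]
    if missing:
        raise ValidationError(f"panel does not cover required gene(s): {missing}")
    if genotype_getter is None:
        if marker_loci is None and required_rgenes:
            raise ValidationError("need marker_loci or a genotype_getter")
        genotype_getter = lambda ind: snp_marker_genotypes(ind, marker_loci)

    by_gene: dict[str, list[MarkerPanelEntry]] = {}
    for e in panel:
        by_gene.setdefault(e.rgene, []).append(e)

    selected, rejected, undet = [], [], []
    calls: dict[str, dict[str, MasCall]] = {}
    counts = {g: {PRESENT: 0, ABSENT: 0, UNDETERMINED: 0} for g in required_rgenes}
    for ind in pop:
        if not required_rgenes:
            selected.append(ind)
            continue
        geno = genotype_getter(ind)
        ind_calls = {}
        for g in required_rgenes:
            call = call_rgene_presence(geno, by_gene[g], rule=rule, individual=ind.id)
            ind_calls[g] = call
            counts[g][call.status] += 1
        calls[ind.id] = ind_calls
        statuses = [c.status for c in ind_calls.values()]
        if all(s == PRESENT for s in statuses):
            selected.append(ind)
        elif any(s == ABSENT for s in statuses):
            rejected.append(ind)
        else:
            undet.append(ind)
    return ScreenResult(selected, rejected, undet, calls, counts)


@dataclass(frozen=True)
class SegregationRatio:
    n_carriers: int
    n_tested: int
    fraction: float
    ci_low: float
    ci_high: float
    deviates_from_half: bool


def segregation_ratio(
    result_or_carriers, n_tested: Optional[int] = None, alpha: float = 0.05
) -> SegregationRatio:
    """Carrier fraction with an exact (Clopper-Pearson) binomial CI.

    Accepts a :class:`ScreenResult` (undetermined individuals excluded from
    the denominator) or raw (n_carriers, n_tested) counts. Flags when the
    CI excludes the Mendelian expectation of one half.
    """
    if isinstance(result_or_carriers, ScreenResult):
        k = len(result_or_carriers.selected)
        n = k + len(result_or_carriers.rejected)
    else:
        k, n = int(result_or_carriers), int(n_tested)
    if n < 1:
        raise ValidationError("segregation ratio needs at least one tested seedling")
    ci = binomtest(k, n).proportion_ci(confidence_level=1 - alpha, method="exact")
    lo, hi = float(ci.low), float(ci.high)
    return SegregationRatio(k, n, k / n, lo, hi, not (lo <= 0.5 <= hi))
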