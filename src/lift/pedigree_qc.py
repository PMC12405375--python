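"""Mendelian-error pedigree inference and null-allele call adjustment.

Parent-offspring duos are screened by the opposing-homozygote rate: a true
duo shows (almost) no sites where one member is AA and the other BB, while
unrelated pairs show many. Null alleles — marker alleles that fail to read,
so heterozygotes appear homozygous — inflate this rate in exactly the
material that carries them; recurring conflicts across a parent's offspring
are therefore adjusted (conservatively to missing, or recoded as
heterozygous-with-null) before haplotype tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_model import MISSING, GeneticMap, Pedigree, PhasedIndividual
from .haplotype_tracing import find_shared_segments, merge_intervals

PARENT_OFFSPRING = "parent_offspring_candidate"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class DuoErrorSummary:
    pair: tuple[str, str]
    n_compared: int
    n_opposing_homozygous: int
    error_rate: float
    verdict: str
    identical: bool = False


def mendelian_error_rate(
    a: PhasedIndividual,
    b: PhasedIndividual,
    gmap: GeneticMap,
    threshold: float = 0.005,
) -> DuoErrorSummary:
    """Opposing-homozygote rate over jointly non-missing sites.

    Symmetric in its arguments. ``verdict`` is parent_offspring_candidate
    when the rate is at or below ``threshold``. Identical genotype vectors
    are flagged separately (duplicate samples, not duos).
    """
    n_comp = 0
    n_opp = 0
    n_diff = 0
    for chrom in gmap.chromosomes:
        ga, gb = a.genotypes(chrom), b.genotypes(chrom)
        both = (ga != MISSING) & (gb != MISSING)
        n_comp += int(both.sum())
        n_opp += int((both & (np.abs(ga - gb) == 2)).sum())
        n_diff += int((both & (ga != gb)).sum())
    if n_comp == 0:
        raise ValueError(f"{a.id}/{b.id}: no jointly genotyped sites")
    rate = n_opp / n_comp
    return DuoErrorSummary(
        pair=(a.id, b.id),
        n_compared=n_comp,
        n_opposing_homozygous=n_opp,
        error_rate=rate,
        verdict=PARENT_OFFSPRING if rate <= threshold else EXCLUDED,
        identical=n_diff == 0,
    )


@dataclass
class PedigreeInference:
    candidates: list[DuoErrorSummary]
    conflicts: list[DuoErrorSummary]  # recorded parent-offspring pairs excluded
    all_pairs: list[DuoErrorSummary]


def infer_parent_offspring(
    pop: Sequence[PhasedIndividual],
    gmap: GeneticMap,
    pedigree: Optional[Pedigree] = None,
    threshold: float = 0.005,
) -> PedigreeInference:
    """All-pairs duo screen; recorded-pedigree conflicts reported.

    A conflict is a recorded parent-offspring pair whose observed
    opposing-homozygote rate excludes the relationship.
    """
    summaries = []
    for i in range(len(pop)):
        for j in range(i + 1, len(pop)):
            summaries.append(
                mendelian_error_rate(pop[i], pop[j], gmap, threshold)
            )
    candidates = [s for s in summaries if s.verdict == PARENT_OFFSPRING]
    conflicts = []
    if pedigree is not None:
        recorded = {frozenset(p) for p in pedigree.true_duos()}
        for s in summaries:
            if frozenset(s.pair) in recorded and s.verdict == EXCLUDED:
                conflicts.append(s)
    return PedigreeInference(candidates, conflicts, summaries)


@dataclass(frozen=True)
class CallAdjustment:
    individual: str
    chrom: str
    index: int
    old_code: int
    new_code: int
    reason: str


def adjust_null_allele_calls(
    parent: PhasedIndividual,
    offspring: Sequence[PhasedIndividual],
    gmap: GeneticMap,
    mode: str = "missing",
    recode_min_offspring: int = 2,
) -> tuple[list[PhasedIndividual], list[CallAdjustment]]:
    """Resolve opposing-homozygote conflicts between a parent and offspring.

    Conservative default (``mode="missing"``): every conflicting site is
    set to missing in both duo members. With ``mode="recode"``, a site
    where at least ``recode_min_offspring`` independent offspring show the
    same opposing-homozygote conflict is instead interpreted as a null
    allele in the parent: the parent's call is recoded heterozygous (the
    visible allele plus the unread one) and kept in the offspring, while
    singleton conflicts still fall back to missing. Returns adjusted
    copies (parent first) and a log of every change; the adjustment never
    increases the error rate of a true duo.
    """
    if mode not in ("missing", "recode"):
        raise ValueError(f"unknown adjustment mode {mode!r}")
    parent_adj = parent.copy()
    offs_adj = [o.copy() for o in offspring]
    log: list[CallAdjustment] = []
    for chrom in gmap.chromosomes:
        gp = parent.genotypes(chrom)
        conflicts: dict[int, list[int]] = {}
        for k, o in enumerate(offspring):
            go = o.genotypes(chrom)
            opp = np.flatnonzero(
                (gp != MISSING) & (go != MISSING) & (np.abs(gp - go) == 2)
            )
            for i in opp:
                conflicts.setdefault(int(i), []).append(k)
        for i, ks in conflicts.items():
            if mode == "recode" and len(ks) >= recode_min_offspring:
                # parent is homozygous-with-null: recode heterozygous
                old = int(gp[i])
                parent_adj.hap[chrom][0, i] = 0
                parent_adj.hap[chrom][1, i] = 1
                log.append(
                    CallAdjustment(parent.id, chrom, i, old, 1, "parent-null-recode")
                )
            else:
                old = int(gp[i])
                parent_adj.hap[chrom][:, i] = MISSING
                log.append(
                    CallAdjustment(parent.id, chrom, i, old, MISSING, "set-missing")
                )
                for k in ks:
                    old_o = int(offspring[k].genotypes(chrom)[i])
                    offs_adj[k].hap[chrom][:, i] = MISSING
                    log.append(
                        CallAdjustment(
                            offspring[k].id, chrom, i, old_o, MISSING, "set-missing"
                        )
                    )
    return [parent_adj, *offs_adj], log


@dataclass
class SharingSummary:
    pair: tuple[str, str]
    per_pairing_percent: dict[tuple[int, int], float]
    per_homolog_percent: tuple[float, float]  # a's homologs, union over b's
    diploid_percent: float
    max_pairing_percent: float


def genomewide_sharing_fraction(
    a: PhasedIndividual,
    b: PhasedIndividual,
    gmap: GeneticMap,
    min_segment_snps: int = 16,
) -> SharingSummary:
    """Percent of map cM in shared segments, per homolog pairing.

    For each homolog of *a*, coverage is the union of qualifying shared
    segments against either homolog of *b*; ``diploid_percent`` averages
    the two, so a parent-offspring duo sits near 50 and a
    grandparent-grandchild duo near 25.
    """
    total = gmap.total_length_cM
    pairing_cM = {(ha, hb): 0.0 for ha in (0, 1) for hb in (0, 1)}
    hom_cM = [0.0, 0.0]
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        for ha in (0, 1):
            union_ivs = []
            for hb in (0, 1):
                ivs = [
                    (s.start_index, s.end_index)
                    for s in find_shared_segments(
                        a.hap[chrom][ha], b.hap[chrom][hb], gmap, chrom,
                        source_homolog=ha, target_homolog=hb,
                    )
                    if s.n_shared_snps >= min_segment_snps
                ]
                pairing_cM[(ha, hb)] += sum(
                    float(pos[e] - pos[s]) for s, e in merge_intervals(ivs)
                )
                union_ivs.extend(ivs)
            hom_cM[ha] += sum(
                float(pos[e] - pos[s]) for s, e in merge_intervals(union_ivs)
            )
    per_pairing = {k: 100.0 * v / total for k, v in pairing_cM.items()}
    per_hom = (100.0 * hom_cM[0] / total, 100.0 * hom_cM[1] / total)
    return SharingSummary(
        pair=(a.id, b.id),
        per_pairing_percent=per_pairing,
        per_homolog_percent=per_hom,
        diploid_percent=0.5 * (per_hom[0] + per_hom[1]),
        max_pairing_percent=max(per_pairing.values()),
    )
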