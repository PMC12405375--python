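"""Shared-haplotype tracing of unadapted donor genome.

The analysis core. Unadapted exotic haplotypes are first *defined* in the
resistance donor by subtracting every haplotype it shares with identified
domestic ancestors; the remainder is then traced into descendants as runs
of matching SNPs subject to the study's segment rules:

* a shared haplotype starts and stops at shared SNPs, either at chromosome
  ends or at shared SNPs adjacent to SNPs that are not shared;
* a candidate run must contain more than 15 (i.e. at least 16) informative
  shared SNPs;
* it must not also be present in the non-admixed (domestic) parent — unless
  the region extended outward matches the donor strictly farther than it
  matches that parent on at least one side (the extended-region exception);
* missing sites neither break a run nor count toward its SNP total.

All segment accounting is in centimorgans, measured from the first to the
last shared SNP of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome_model import (
    MISSING,
    GeneticMap,
    PhasedIndividual,
    RGeneLocus,
    ValidationError,
)

DONOR_EXCLUSIVE = "donor-exclusive"
EXCEPTION_RETAINED = "exception-retained"


@dataclass(frozen=True)
class SharedSegment:
    """A maximal run of matching informative SNPs between two haplotypes."""

    chrom: str
    start_index: int
    end_index: int
    start_cM: float
    end_cM: float
    n_shared_snps: int
    n_missing_spanned: int
    source_homolog: int = 0
    target_homolog: int = 0
    disposition: str = ""
    rgene_linked: bool = False

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


def find_shared_segments(
    hapA: np.ndarray,
    hapB: np.ndarray,
    gmap: GeneticMap,
    chrom: str,
    source_homolog: int = 0,
    target_homolog: int = 0,
    lo: int = 0,
    hi: Optional[int] = None,
) -> list[SharedSegment]:
    """Maximal matching runs between two haplotypes on one chromosome.

    A mismatching informative SNP breaks a run; SNPs missing on either side
    are spanned silently and do not count toward ``n_shared_snps``. Runs
    are trimmed to informative shared SNPs at both ends. ``lo``/``hi``
    restrict the scan to a locus-index window (inclusive).
    """
    pos = gmap.positions[chrom]
    if hi is None:
        hi = len(pos) - 1
    sl = slice(lo, hi + 1)
    a, b = np.asarray(hapA[sl]), np.asarray(hapB[sl])
    informative = (a != MISSING) & (b != MISSING)
    ii = np.flatnonzero(informative) + lo
    if ii.size == 0:
        return []
    match = hapA[ii] == hapB[ii]
    segments: list[SharedSegment] = []
    run_start: Optional[int] = None
    n_in_run = 0
    prev_idx = -1
    for j, idx in enumerate(ii):
        if match[j]:
            if run_start is None:
                run_start = int(idx)
                n_in_run = 0
            n_in_run += 1
            prev_idx = int(idx)
        else:
            if run_start is not None:
                segments.append(
                    _make_segment(
                        chrom, run_start, prev_idx, n_in_run, pos,
                        source_homolog, target_homolog,
                    )
                )
                run_start = None
    if run_start is not None:
        segments.append(
            _make_segment(
                chrom, run_start, prev_idx, n_in_run, pos,
                source_homolog, target_homolog,
            )
        )
    return segments


def _make_segment(chrom, s, e, n_shared, pos, sh, th) -> SharedSegment:
    span = e - s + 1
    return SharedSegment(
        chrom=chrom,
        start_index=s,
        end_index=e,
        start_cM=float(pos[s]),
        end_cM=float(pos[e]),
        n_shared_snps=n_shared,
        n_missing_spanned=span - n_shared,
        source_homolog=sh,
        target_homolog=th,
    )


def _extension_length(
    ref: np.ndarray, test: np.ndarray, edge: int, step: int, limit: int
) -> int:
    """Informative matches walking outward from a segment edge.

    Starts at ``edge + step`` and walks until the first informative
    mismatch or the chromosome end; missing sites are spanned. Returns the
    count of informative matching SNPs passed.
    """
    n = 0
    i = edge + step
    while 0 <= i <= limit:
        ra, ta = int(ref[i]), int(test[i])
        if ra != MISSING and ta != MISSING:
            if ra != ta:
                break
            n += 1
        i += step
    return n


def _carries_segment(
    parent_hap: np.ndarray, target_hap: np.ndarray, s: int, e: int
) -> bool:
    """Does this parent homolog carry the descendant's haplotype over [s, e]?

    Carried = no informative mismatch and at least one informative match.
    """
    a = parent_hap[s : e + 1]
    b = target_hap[s : e + 1]
    informative = (a != MISSING) & (b != MISSING)
    if not informative.any():
        return False
    return bool(np.all(a[informative] == b[informative]))


def filter_candidate_segments(
    segments: Sequence[SharedSegment],
    descendant: PhasedIndividual,
    donor: PhasedIndividual,
    nonadmixed_parent: Optional[PhasedIndividual],
    min_snps: int = 16,
    min_extension: int = 1,
) -> list[SharedSegment]:
    """Apply the length and non-admixed-parent rules to candidate runs.

    Segments with fewer than ``min_snps`` informative shared SNPs are
    dropped. A survivor also present in the non-admixed parent is dropped
    unless, extending outward SNP by SNP from the run on either side, the
    descendant's match to the donor runs strictly farther (by at least
    ``min_extension`` informative SNPs) than its match to the parent on at
    least one side. Retained segments record their disposition.
    """
    out: list[SharedSegment] = []
    for seg in segments:
        if seg.n_shared_snps < min_snps:
            continue
        if nonadmixed_parent is None:
            out.append(replace(seg, disposition=DONOR_EXCLUSIVE))
            continue
        chrom = seg.chrom
        target = descendant.hap[chrom][seg.target_homolog]
        donor_hap = donor.hap[chrom][seg.source_homolog]
        parent_haps = nonadmixed_parent.hap[chrom]
        carriers = [
            h for h in (0, 1)
            if _carries_segment(parent_haps[h], target, seg.start_index, seg.end_index)
        ]
        if not carriers:
            out.append(replace(seg, disposition=DONOR_EXCLUSIVE))
            continue
        limit = len(target) - 1
        retained = False
        for step, edge in ((-1, seg.start_index), (+1, seg.end_index)):
            ext_donor = _extension_length(donor_hap, target, edge, step, limit)
            ext_parent = max(
                _extension_length(parent_haps[h], target, edge, step, limit)
                for h in carriers
            )
            if ext_donor - ext_parent >= min_extension:
                retained = True
                break
        if retained:
            out.append(replace(seg, disposition=EXCEPTION_RETAINED))
    return out


# ---------------------------------------------------------------------------
# Defining unadapted donor haplotypes by subtraction
# ---------------------------------------------------------------------------


@dataclass
class UnadaptedPartition:
    """Donor homologs partitioned into domestic and unadapted index intervals."""

    donor_id: str
    # chrom -> per homolog -> list of (start_index, end_index), inclusive
    unadapted: dict[str, list[list[tuple[int, int]]]]
    domestic: dict[str, list[list[tuple[int, int]]]]
    gmap: GeneticMap

    def unadapted_cM(self) -> float:
        total = 0.0
        for chrom, homologs in self.unadapted.items():
            pos = self.gmap.positions[chrom]
            for intervals in homologs:
                total += sum(float(pos[e] - pos[s]) for s, e in intervals)
        return total

    def diploid_percent(self) -> float:
        return 100.0 * self.unadapted_cM() / (2.0 * self.gmap.total_length_cM)


def define_unadapted_haplotypes(
    donor: PhasedIndividual,
    identified_domestic_ancestors: Sequence[PhasedIndividual],
    gmap: GeneticMap,
    min_snps: int = 16,
) -> UnadaptedPartition:
    """Label donor genome domestic where it matches an identified ancestor.

    Any donor-homolog interval shared (as a >= ``min_snps``-SNP segment)
    with any ancestor haplotype is domestic; the complement is unadapted.
    With no ancestors supplied the whole genome is unadapted.
    """
    for chrom in gmap.chromosomes:
        h = donor.hap[chrom]
        miss = float(np.mean(h == MISSING))
        if miss > 0.5:
            raise ValidationError(
                f"{donor.id}/{chrom}: {miss:.0%} missing — refusing to define "
                "unadapted haplotypes on such data"
            )
    unadapted: dict[str, list[list[tuple[int, int]]]] = {}
    domestic: dict[str, list[list[tuple[int, int]]]] = {}
    for chrom in gmap.chromosomes:
        n = gmap.n_loci(chrom)
        un_homs, dom_homs = [], []
        for h in (0, 1):
            dom_intervals: list[tuple[int, int]] = []
            for anc in identified_domestic_ancestors:
                for ah in (0, 1):
                    for seg in find_shared_segments(
                        donor.hap[chrom][h], anc.hap[chrom][ah], gmap, chrom,
                        source_homolog=h, target_homolog=ah,
                    ):
                        if seg.n_shared_snps >= min_snps:
                            dom_intervals.append((seg.start_index, seg.end_index))
            dom_merged = merge_intervals(dom_intervals)
            dom_homs.append(dom_merged)
            un_homs.append(_complement_intervals(dom_merged, n))
        unadapted[chrom] = un_homs
        domestic[chrom] = dom_homs
    return UnadaptedPartition(donor.id, unadapted, domestic, gmap)


def partition_from_truth(
    donor: PhasedIndividual, gmap: GeneticMap
) -> UnadaptedPartition:
    """Donor partition taken from simulator truth labels (no subtraction).

    Useful to score the tracer in isolation: subtraction-by-sharing has an
    intrinsic boundary uncertainty of a few chance-matching SNPs at each
    domestic/exotic junction, which truth labels do not.
    """
    if donor.truth is None:
        raise ValueError(f"{donor.id} carries no truth labels")
    unadapted: dict[str, list[list[tuple[int, int]]]] = {}
    domestic: dict[str, list[list[tuple[int, int]]]] = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        un_homs, dom_homs = [], []
        for h in (0, 1):
            un, dom = [], []
            for seg in donor.truth[chrom][h]:
                s = int(np.searchsorted(pos, seg.start_cM - 1e-9, side="left"))
                e = int(np.searchsorted(pos, seg.end_cM + 1e-9, side="right")) - 1
                if e >= s:
                    (un if seg.origin == "exotic" else dom).append((s, e))
            un_homs.append(merge_intervals(un))
            dom_homs.append(merge_intervals(dom))
        unadapted[chrom] = un_homs
        domestic[chrom] = dom_homs
    return UnadaptedPartition(donor.id, unadapted, domestic, gmap)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent inclusive index intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _complement_intervals(
    intervals: Sequence[tuple[int, int]], n: int
) -> list[tuple[int, int]]:
    """Complement of merged inclusive intervals within [0, n-1]."""
    out = []
    prev_end = -1
    for s, e in intervals:
        if s > prev_end + 1:
            out.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    if prev_end < n - 1:
        out.append((prev_end + 1, n - 1))
    return out


# ---------------------------------------------------------------------------
# Tracing into descendants
# ---------------------------------------------------------------------------


@dataclass
class UnadaptedReport:
    """Retained unadapted segments for one descendant, with cM accounting."""

    individual: str
    segments: list[SharedSegment]
    total_unadapted_cM: float
    percent_of_diploid_genome: float
    per_chromosome_cM: dict[str, float]
    exception_fired: bool = False
    mas_conflict: bool = False


def trace_unadapted(
    descendant: PhasedIndividual,
    donor: PhasedIndividual,
    partition: UnadaptedPartition,
    nonadmixed_parent: Optional[PhasedIndividual],
    gmap: GeneticMap,
    rgene_loci: Sequence[RGeneLocus] = (),
    min_snps: int = 16,
    min_extension: int = 1,
) -> UnadaptedReport:
    """Trace the donor's unadapted haplotypes into one descendant.

    For every unadapted donor interval, finds shared segments against each
    descendant homolog, applies the length and non-admixed-parent filters,
    merges overlapping retained intervals per descendant homolog, and
    reports cM totals, the diploid-genome percentage, and R-gene linkage
    (any retained segment whose cM span overlaps an R-gene window).
    """
    retained_by_hom: dict[tuple[str, int], list[SharedSegment]] = {}
    for chrom in gmap.chromosomes:
        for s_hom in (0, 1):
            for (a, b) in partition.unadapted[chrom][s_hom]:
                for t_hom in (0, 1):
                    segs = find_shared_segments(
                        donor.hap[chrom][s_hom],
                        descendant.hap[chrom][t_hom],
                        gmap, chrom,
                        source_homolog=s_hom, target_homolog=t_hom,
                        lo=a, hi=b,
                    )
                    kept = filter_candidate_segments(
                        segs, descendant, donor, nonadmixed_parent,
                        min_snps=min_snps, min_extension=min_extension,
                    )
                    if kept:
                        retained_by_hom.setdefault((chrom, t_hom), []).extend(kept)

    merged_segments: list[SharedSegment] = []
    exception_fired = False
    for (chrom, t_hom), segs in sorted(retained_by_hom.items()):
        pos = gmap.positions[chrom]
        ivs = merge_intervals(
            [(s.start_index, s.end_index) for s in segs]
        )
        for s_idx, e_idx in ivs:
            inside = [
                s for s in segs
                if s.start_index >= s_idx and s.end_index <= e_idx
            ]
            disposition = (
                EXCEPTION_RETAINED
                if any(s.disposition == EXCEPTION_RETAINED for s in inside)
                else DONOR_EXCLUSIVE
            )
            if disposition == EXCEPTION_RETAINED:
                exception_fired = True
            start_cM, end_cM = float(pos[s_idx]), float(pos[e_idx])
            linked = any(
                rg.chrom == chrom
                and start_cM <= rg.window_cM[1]
                and end_cM >= rg.window_cM[0]
                for rg in rgene_loci
            )
            merged_segments.append(
                SharedSegment(
                    chrom=chrom,
                    start_index=s_idx,
                    end_index=e_idx,
                    start_cM=start_cM,
                    end_cM=end_cM,
                    n_shared_snps=max(s.n_shared_snps for s in inside)
                    if inside else e_idx - s_idx + 1,
                    n_missing_spanned=0,
                    source_homolog=inside[0].source_homolog if inside else 0,
                    target_homolog=t_hom,
                    disposition=disposition,
                    rgene_linked=linked,
                )
            )
    per_chrom: dict[str, float] = {}
    total = 0.0
    for seg in merged_segments:
        per_chrom[seg.chrom] = per_chrom.get(seg.chrom, 0.0) + seg.length_cM
        total += seg.length_cM
    return UnadaptedReport(
        individual=descendant.id,
        segments=merged_segments,
        total_unadapted_cM=total,
        percent_of_diploid_genome=100.0 * total / (2.0 * gmap.total_length_cM),
        per_chromosome_cM=per_chrom,
        exception_fired=exception_fired,
    )


RGENE_ONLY = "rgene_only"
RGENE_PLUS_EXTRA = "rgene_plus_extra"
NO_RGENE_SEGMENT = "no_rgene_segment"


def rgene_only_classifier(report: UnadaptedReport) -> str:
    """Classify a report by whether only R-gene-linked segments remain."""
    if not report.segments or not any(s.rgene_linked for s in report.segments):
        return NO_RGENE_SEGMENT
    if all(s.rgene_linked for s in report.segments):
        return RGENE_ONLY
    return RGENE_PLUS_EXTRA


# ---------------------------------------------------------------------------
# Truth-label scoring (simulator-only)
# ---------------------------------------------------------------------------


def _truth_exotic_index_intervals(
    descendant: PhasedIndividual, gmap: GeneticMap, chrom: str, homolog: int
) -> list[tuple[int, int]]:
    """Truth exotic pieces as locus-index intervals, split at source changes.

    A piece inherited intact from one donor haplotype is the unit a
    haplotype tracer can recover; adjacent exotic pieces from different
    source haplotypes are therefore not merged.
    """
    pos = gmap.positions[chrom]
    out = []
    for seg in descendant.truth[chrom][homolog]:
        if seg.origin != "exotic":
            continue
        s = int(np.searchsorted(pos, seg.start_cM - 1e-9, side="left"))
        e = int(np.searchsorted(pos, seg.end_cM + 1e-9, side="right")) - 1
        if e >= s:
            out.append((s, e))
    return out


@dataclass
class TruthComparison:
    recall_segments: float
    recall_cM: float
    precision_cM: float
    n_truth_segments: int
    max_boundary_error_intervals: int


def compare_to_truth(
    report: UnadaptedReport,
    descendant: PhasedIndividual,
    gmap: GeneticMap,
    min_snps: int = 16,
    boundary_slack_snps: int = 1,
) -> TruthComparison:
    """Score traced segments against the simulator's truth exotic labels.

    Only truth segments holding at least ``min_snps`` SNPs are scoreable.
    A truth segment counts as recalled when a single traced interval on
    the same homolog covers it to within ``boundary_slack_snps`` SNPs at
    each end; cM-level recall and precision weight by overlap length.
    """
    if descendant.truth is None:
        raise ValueError("descendant carries no truth labels")
    traced: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for seg in report.segments:
        traced.setdefault((seg.chrom, seg.target_homolog), []).append(
            (seg.start_index, seg.end_index)
        )
    n_truth = 0
    n_recalled = 0
    truth_cM = 0.0
    recall_overlap_cM = 0.0
    precision_overlap_cM = 0.0
    traced_cM = 0.0
    max_berr = 0
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        for hom in (0, 1):
            t_ivs = traced.get((chrom, hom), [])
            traced_cM += sum(float(pos[e] - pos[s]) for s, e in t_ivs)
            for (s, e) in _truth_exotic_index_intervals(descendant, gmap, chrom, hom):
                qualifies = e - s + 1 >= min_snps
                best = None
                for (ts, te) in t_ivs:
                    ov_s, ov_e = max(s, ts), min(e, te)
                    if ov_e >= ov_s:
                        ov = float(pos[ov_e] - pos[ov_s])
                        precision_overlap_cM += ov
                        if qualifies:
                            recall_overlap_cM += ov
                        berr = max(ts - s, 0) + max(e - te, 0)
                        best = berr if best is None else min(best, berr)
                if qualifies:
                    n_truth += 1
                    truth_cM += float(pos[e] - pos[s])
                    if best is not None and best <= 2 * boundary_slack_snps:
                        n_recalled += 1
                        max_berr = max(max_berr, best)
    return TruthComparison(
        recall_segments=n_recalled / n_truth if n_truth else float("nan"),
        recall_cM=recall_overlap_cM / truth_cM if truth_cM else float("nan"),
        precision_cM=precision_overlap_cM / traced_cM if traced_cM else float("nan"),
        n_truth_segments=n_truth,
        max_boundary_error_intervals=max_berr,
    )
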