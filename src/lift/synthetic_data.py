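"""Apple-like synthetic fixtures: maps, founders with labeled exotic genome, noise.

The generator emulates the study system: a 17-linkage-group genetic map, a
resistance-donor founder whose genome is a stated fraction of unadapted
exotic *Malus* origin (MR5-like 75%, 'Evereste'-like 50%), a pool of
domesticated founders, heterozygous R-gene loci, and SNP null-allele
dropout. Truth ancestry labels ("exotic" vs "domestic") ride along on every
simulated individual so downstream tracing can be scored against them.

Exotic and domestic allele-frequency profiles are drawn independently per
SNP (Uniform(0,1) each), so exotic haplotypes share no extended runs with
domestic material — the property the tracing rules rely on — without
imposing any particular frequency model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_model import (
    A,
    B,
    MISSING,
    AncestrySegment,
    GeneticMap,
    MarkerPanelEntry,
    PhasedIndividual,
    RGeneLocus,
    ValidationError,
    lg_name,
)

EXOTIC = "exotic"
DOMESTIC = "domestic"


@dataclass(frozen=True)
class FounderSpec:
    """Recipe for a resistance-donor founder.

    ``unadapted_fraction`` is the target fraction of the diploid map length
    labeled exotic. If an R-gene is given, its window is guaranteed to lie
    inside an exotic segment on the carrier homolog (``rgene_phase``).
    """

    id: str
    unadapted_fraction: float
    rgene: Optional[RGeneLocus] = None
    rgene_phase: int = 0
    construction: str = "admixed_parent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.unadapted_fraction <= 1.0:
            raise ValidationError("unadapted_fraction must lie in [0, 1]")
        if self.rgene_phase not in (0, 1):
            raise ValidationError("rgene_phase must be 0 or 1")


@dataclass(frozen=True)
class NoiseSpec:
    """Genotyping noise: null-allele dropout and random missingness."""

    null_allele_rate: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.null_allele_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("noise rates must lie in [0, 1]")


def write_truth_segments(pop: Sequence[PhasedIndividual], path) -> None:
    """Truth-segment TSV: id, homolog, chrom, start_cM, end_cM, origin."""
    import pandas as pd

    rows = []
    for ind in pop:
        if ind.truth is None:
            continue
        for chrom, homologs in ind.truth.items():
            for h, segs in enumerate(homologs):
                for s in segs:
                    rows.append(
                        (ind.id, h, chrom, round(s.start_cM, 2),
                         round(s.end_cM, 2), s.origin)
                    )
    pd.DataFrame(
        rows, columns=["id", "homolog", "chrom", "start_cM", "end_cM", "origin"]
    ).to_csv(path, sep="\t", index=False)


def make_apple_map(
    n_chrom: int = 17,
    chrom_length_cM: float = 80.0,
    snps_per_chrom: int = 100,
    seed: int = 0,
) -> GeneticMap:
    """Uniform-random SNP map: first SNP at 0, last at ``chrom_length_cM``.

    Deterministic for a fixed seed. The default desk-scale map (1,700 SNPs
    over 17 x 80 cM) is a scaled-down stand-in for the curated ~10k-SNP
    array map; scale ``snps_per_chrom`` up to approach it.
    """
    if snps_per_chrom < 2:
        raise ValidationError("snps_per_chrom must be >= 2")
    rng = np.random.default_rng(seed)
    chroms = tuple(lg_name(i + 1) for i in range(n_chrom))
    markers = {}
    positions = {}
    for chrom in chroms:
        interior = np.sort(rng.uniform(0.0, chrom_length_cM, snps_per_chrom - 2))
        pos = np.concatenate(([0.0], interior, [chrom_length_cM]))
        # enforce strict monotonicity at float resolution
        while np.any(np.diff(pos) <= 0):
            interior = np.sort(
                rng.uniform(0.0, chrom_length_cM, snps_per_chrom - 2)
            )
            pos = np.concatenate(([0.0], interior, [chrom_length_cM]))
        positions[chrom] = pos
        markers[chrom] = np.array(
            [f"{chrom}_S{i:04d}" for i in range(snps_per_chrom)], dtype=object
        )
    return GeneticMap(chroms, markers, positions)


@dataclass
class FounderSet:
    """A simulated founder population plus everything needed to extend it.

    Holds the map, the donor (with truth labels), its pseudo-parents (the
    identified-ancestor stand-ins used for haplotype subtraction), a pool of
    domestic founders, per-SNP allele-frequency profiles, and the synthetic
    SNP marker panel for the donor's R-gene.
    """

    gmap: GeneticMap
    donor: PhasedIndividual
    domestic: list[PhasedIndividual]
    exotic_parent: PhasedIndividual
    domestic_parent: PhasedIndividual
    p_dom: dict[str, np.ndarray]
    p_exo: dict[str, np.ndarray]
    rgene: Optional[RGeneLocus]
    panel: list[MarkerPanelEntry] = field(default_factory=list)
    panel_loci: dict[str, tuple[str, int]] = field(default_factory=dict)
    seed: int = 0
    _fresh_counter: int = 0

    def fresh_domestic(
        self, n: int, rng: np.random.Generator, prefix: str = "RP"
    ) -> list[PhasedIndividual]:
        """Fresh unrelated domestic founders (recurrent parents)."""
        out = []
        for _ in range(n):
            self._fresh_counter += 1
            out.append(
                _draw_domestic(
                    self.gmap, self.p_dom, f"{prefix}{self._fresh_counter:04d}", rng
                )
            )
        return out


def _draw_hap(gmap: GeneticMap, freqs: dict[str, np.ndarray], rng) -> dict:
    return {
        c: (rng.random(gmap.n_loci(c)) < freqs[c]).astype(np.int8)
        for c in gmap.chromosomes
    }


def _full_truth(gmap: GeneticMap, origin: str, iid: str = "") -> dict:
    return {
        c: [
            [AncestrySegment(c, float(gmap.positions[c][0]),
                             float(gmap.positions[c][-1]), origin,
                             f"{iid}:h{h}")]
            for h in range(2)
        ]
        for c in gmap.chromosomes
    }


def _draw_domestic(gmap, p_dom, iid, rng) -> PhasedIndividual:
    h0 = _draw_hap(gmap, p_dom, rng)
    h1 = _draw_hap(gmap, p_dom, rng)
    hap = {c: np.vstack([h0[c], h1[c]]) for c in gmap.chromosomes}
    return PhasedIndividual(
        id=iid, hap=hap, truth=_full_truth(gmap, DOMESTIC, iid),
        generation="founder",
    )


def _mosaic_homolog(
    gmap: GeneticMap,
    frac: float,
    exotic_alleles: dict[str, np.ndarray],
    domestic_alleles: dict[str, np.ndarray],
    rng: np.random.Generator,
    must_cover: Optional[RGeneLocus] = None,
) -> tuple[dict[str, np.ndarray], dict[str, list[AncestrySegment]]]:
    """One homolog that is *frac* exotic by cM, the rest domestic.

    Per chromosome, a single breakpoint is snapped to the midpoint between
    adjacent SNPs; a running carry keeps the genome-wide total within one
    inter-SNP interval of the target. ``must_cover`` forces the exotic block
    onto the side containing the R-gene window.
    """
    hap: dict[str, np.ndarray] = {}
    truth: dict[str, list[AncestrySegment]] = {}
    carry = 0.0
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        L = gmap.chrom_length_cM(chrom)
        target = frac * L + carry
        target = min(max(target, 0.0), L)
        forced = must_cover is not None and must_cover.chrom == chrom
        if forced:
            lo, hi = must_cover.window_cM
            exotic_first = lo - pos[0] <= pos[-1] - hi
        else:
            exotic_first = bool(rng.integers(2))
        if forced:
            # widen the target so the exotic block spans the R-gene window
            if exotic_first:
                target = max(target, must_cover.window_cM[1] - pos[0] + 1e-9)
            else:
                target = max(target, pos[-1] - must_cover.window_cM[0] + 1e-9)
        # breakpoint at a midpoint between SNP k and k+1
        if exotic_first:
            cut = pos[0] + target
            k = int(np.searchsorted(pos, cut) - 1)
            k = min(max(k, 0), len(pos) - 2)
            mid = 0.5 * (pos[k] + pos[k + 1])
            n_exotic_left = k + 1
            exotic_idx = np.arange(len(pos)) < n_exotic_left
            exotic_len = mid - pos[0]
        else:
            cut = pos[-1] - target
            k = int(np.searchsorted(pos, cut))
            k = min(max(k, 1), len(pos) - 1)
            mid = 0.5 * (pos[k - 1] + pos[k])
            exotic_idx = np.arange(len(pos)) >= k
            exotic_len = pos[-1] - mid
        if target <= 0:
            exotic_idx = np.zeros(len(pos), bool)
            exotic_len = 0.0
        elif target >= L:
            exotic_idx = np.ones(len(pos), bool)
            exotic_len = L
        carry = (frac * L + carry) - exotic_len
        alleles = np.where(exotic_idx, exotic_alleles[chrom], domestic_alleles[chrom])
        hap[chrom] = alleles.astype(np.int8)
        segs: list[AncestrySegment] = []
        if exotic_len <= 0:
            segs = [AncestrySegment(chrom, pos[0], pos[-1], DOMESTIC)]
        elif exotic_len >= L:
            segs = [AncestrySegment(chrom, pos[0], pos[-1], EXOTIC)]
        elif exotic_first:
            segs = [
                AncestrySegment(chrom, float(pos[0]), float(mid), EXOTIC),
                AncestrySegment(chrom, float(mid), float(pos[-1]), DOMESTIC),
            ]
        else:
            segs = [
                AncestrySegment(chrom, float(pos[0]), float(mid), DOMESTIC),
                AncestrySegment(chrom, float(mid), float(pos[-1]), EXOTIC),
            ]
        truth[chrom] = segs
    return hap, truth


def make_founders(
    gmap: GeneticMap,
    donor_spec: FounderSpec,
    n_domestic: int = 4,
    seed: int = 0,
    n_panel_markers: int = 2,
) -> FounderSet:
    """Build the donor, its pseudo-parents, and a domestic founder pool.

    The donor is constructed as the offspring of a fully exotic
    pseudo-parent and a pseudo-parent carrying the donor's domestic
    ancestry (mirroring 'Evereste' = PRI-like domestic x unknown exotic,
    and MR5 with a domestic grandparent). Homolog 0 carries
    ``min(2f, 1)`` exotic genome and homolog 1 the remainder, so the
    diploid exotic fraction hits ``f`` to within one inter-SNP interval.
    """
    rng = np.random.default_rng(seed)
    f = donor_spec.unadapted_fraction
    # feasibility: one inter-SNP interval must resolve the requested fraction
    min_interval = min(
        float(np.diff(gmap.positions[c]).min()) for c in gmap.chromosomes
    )
    if 0 < f < 1 and min_interval >= gmap.total_length_cM:
        raise ValidationError("map too coarse for the requested fraction")

    p_dom = {c: rng.random(gmap.n_loci(c)) for c in gmap.chromosomes}
    p_exo = {c: rng.random(gmap.n_loci(c)) for c in gmap.chromosomes}

    e0, e1 = _draw_hap(gmap, p_exo, rng), _draw_hap(gmap, p_exo, rng)
    exotic_parent = PhasedIndividual(
        id="EXO_P",
        hap={c: np.vstack([e0[c], e1[c]]) for c in gmap.chromosomes},
        truth=_full_truth(gmap, EXOTIC, "EXO_P"),
        generation="founder",
    )
    domestic_parent = _draw_domestic(gmap, p_dom, "DOM_P", rng)

    f0 = min(2.0 * f, 1.0)
    f1 = 2.0 * f - f0
    rg = donor_spec.rgene
    cover0 = rg if (rg is not None and donor_spec.rgene_phase == 0) else None
    cover1 = rg if (rg is not None and donor_spec.rgene_phase == 1) else None
    h0, t0 = _mosaic_homolog(
        gmap, f0, {c: exotic_parent.hap[c][0] for c in gmap.chromosomes},
        {c: domestic_parent.hap[c][0] for c in gmap.chromosomes}, rng, cover0
    )
    h1, t1 = _mosaic_homolog(
        gmap, f1, {c: exotic_parent.hap[c][1] for c in gmap.chromosomes},
        {c: domestic_parent.hap[c][1] for c in gmap.chromosomes}, rng, cover1
    )
    # donor truth pieces are tagged with the donor's own haplotype as source:
    # tracing compares descendants against donor haplotypes, so a contiguous
    # single-source piece is the unit a tracer can hope to recover
    truth = {
        c: [
            [s._replace(source=f"{donor_spec.id}:h{h}") for s in segs]
            for h, segs in enumerate((t0[c], t1[c]))
        ]
        for c in gmap.chromosomes
    }
    donor = PhasedIndividual(
        id=donor_spec.id,
        hap={c: np.vstack([h0[c], h1[c]]) for c in gmap.chromosomes},
        truth=truth,
        generation="donor",
        mother=domestic_parent.id,
        father=exotic_parent.id,
    )

    panel: list[MarkerPanelEntry] = []
    panel_loci: dict[str, tuple[str, int]] = {}
    if rg is not None:
        # R-gene window must sit inside an exotic truth segment on the carrier
        carrier_truth = donor.truth[rg.chrom][donor_spec.rgene_phase]
        lo, hi = rg.window_cM
        ok = any(
            s.origin == EXOTIC and s.start_cM <= lo and s.end_cM >= hi
            for s in carrier_truth
        )
        if not ok:
            raise ValidationError(
                f"{rg.name}: window not containable in an exotic segment at "
                f"fraction {f}"
            )
        # diagnostic SNP panel: coupling allele B on the carrier homolog,
        # absent from the domestic pool (donor-unique, as for real SSRs)
        pos = gmap.positions[rg.chrom]
        in_window = np.flatnonzero((pos >= lo) & (pos <= hi))
        if in_window.size < n_panel_markers:
            raise ValidationError(f"{rg.name}: window holds too few SNPs")
        order = in_window[np.argsort(np.abs(pos[in_window] - rg.position_cM))]
        chosen = np.sort(order[:n_panel_markers])
        for i in chosen:
            donor.hap[rg.chrom][donor_spec.rgene_phase, i] = B
            donor.hap[rg.chrom][1 - donor_spec.rgene_phase, i] = A
            p_dom[rg.chrom][i] = 0.0
            # keep the already-drawn pool consistent with the profile
            for d in (domestic_parent,):
                d.hap[rg.chrom][:, i] = A
            marker = str(gmap.markers[rg.chrom][i])
            panel.append(
                MarkerPanelEntry(
                    rgene=rg.name,
                    linkage_group=int(rg.chrom[2:]),
                    marker_name=marker,
                    marker_type="SNP",
                    coupling_allele="B",
                    reference_alleles=("A", "A"),
                )
            )
            panel_loci[marker] = (rg.chrom, int(i))

    domestic = [
        _draw_domestic(gmap, p_dom, f"DOM{j + 1:03d}", rng) for j in range(n_domestic)
    ]
    return FounderSet(
        gmap=gmap,
        donor=donor,
        domestic=domestic,
        exotic_parent=exotic_parent,
        domestic_parent=domestic_parent,
        p_dom=p_dom,
        p_exo=p_exo,
        rgene=rg,
        panel=panel,
        panel_loci=panel_loci,
        seed=seed,
    )


# default donor presets used throughout the package and CLI ---------------

def mr5_like_spec() -> FounderSpec:
    """75%-exotic donor with its fire blight R-gene on LG03."""
    return FounderSpec(
        id="MR5",
        unadapted_fraction=0.75,
        rgene=RGeneLocus("FB_MR5", "LG03", 40.0, (35.0, 45.0)),
        rgene_phase=0,
    )


def evereste_like_spec() -> FounderSpec:
    """50%-exotic donor with its fire blight R-gene on LG12."""
    return FounderSpec(
        id="EVE",
        unadapted_fraction=0.50,
        rgene=RGeneLocus("Fb_E", "LG12", 40.0, (35.0, 45.0)),
        rgene_phase=0,
    )


def inject_null_alleles(
    pop: Sequence[PhasedIndividual], noise: NoiseSpec
) -> tuple[list[PhasedIndividual], int]:
    """Corrupt observed calls with null-allele dropout (and missingness).

    At each selected heterozygous site, one allele is chosen (uniformly) to
    be the null: the observed genotype then shows the *visible* allele as
    homozygous on both homologs. Truth haplotypes and ancestry labels are
    untouched on the originals; corrupted copies are returned, with the
    injected (chrom, index, homolog) sites recorded in
    ``meta["null_sites"]``.
    """
    rng = np.random.default_rng(noise.seed)
    out = []
    n_injected = 0
    for ind in pop:
        cp = ind.copy()
        cp.meta["null_sites"] = []
        for chrom, h in cp.hap.items():
            het = (h[0] != h[1]) & (h[0] != MISSING) & (h[1] != MISSING)
            hit = het & (rng.random(h.shape[1]) < noise.null_allele_rate)
            idx = np.flatnonzero(hit)
            for i in idx:
                null_homolog = int(rng.integers(2))
                visible = int(h[1 - null_homolog, i])
                h[:, i] = visible
                cp.meta["null_sites"].append((chrom, int(i), null_homolog))
            n_injected += idx.size
            if noise.missing_rate > 0:
                miss = rng.random(h.shape[1]) < noise.missing_rate
                h[:, miss] = MISSING
        out.append(cp)
    return out, n_injected
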