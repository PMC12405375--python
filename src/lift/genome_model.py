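"""Core data model: genetic maps, phased individuals, pedigrees, marker panels.

All coordinates are genetic (centimorgan); there are no base-pair positions
anywhere in this package. Biallelic SNP alleles are encoded array-style as
A/B (integers 0/1), with -1 for missing; SSR alleles are integer fragment
sizes. Chromosomes are linkage groups named ``LG01`` .. ``LG17``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

#: allele codes
A, B, MISSING = 0, 1, -1


class ValidationError(ValueError):
    """An input violated a structural invariant (bad map, cycle, ...)."""


class AncestrySegment(NamedTuple):
    """A cM interval on one homolog labeled by founder origin.

    ``source`` names the founder haplotype the interval descends from
    (e.g. ``"MR5:h0"``); it is preserved through simulated meioses so
    traced segments can be scored against single-source truth pieces.
    """

    chrom: str
    start_cM: float
    end_cM: float
    origin: str  # "exotic" or "domestic"
    source: str = ""

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


def lg_name(i: int) -> str:
    """1-based linkage-group index -> canonical name (1 -> 'LG01')."""
    return f"LG{i:02d}"


@dataclass(frozen=True)
class GeneticMap:
    """Ordered SNP loci per linkage group with cM positions.

    Positions are strictly increasing within a chromosome and each
    chromosome carries at least two loci. ``total_length_cM`` is the sum of
    (last - first) positions over chromosomes.
    """

    chromosomes: tuple[str, ...]
    markers: Mapping[str, np.ndarray]  # chrom -> array of marker ids (object)
    positions: Mapping[str, np.ndarray]  # chrom -> float cM, strictly increasing

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions[chrom], dtype=float)
            if pos.size < 2:
                raise ValidationError(f"{chrom}: a chromosome needs >=2 mapped loci")
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(
                    f"{chrom}: cM positions must be strictly increasing"
                )
            if len(self.markers[chrom]) != pos.size:
                raise ValidationError(f"{chrom}: marker/position length mismatch")

    def n_loci(self, chrom: str) -> int:
        return len(self.positions[chrom])

    @property
    def n_loci_total(self) -> int:
        return sum(self.n_loci(c) for c in self.chromosomes)

    def chrom_length_cM(self, chrom: str) -> float:
        pos = self.positions[chrom]
        return float(pos[-1] - pos[0])

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chrom_length_cM(c) for c in self.chromosomes))

    def marker_index(self) -> dict[str, tuple[str, int]]:
        """marker id -> (chrom, locus index)."""
        out: dict[str, tuple[str, int]] = {}
        for chrom in self.chromosomes:
            for i, m in enumerate(self.markers[chrom]):
                out[str(m)] = (chrom, i)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            rows.append(
                pd.DataFrame(
                    {
                        "marker": self.markers[chrom],
                        "chrom": chrom,
                        "cM": self.positions[chrom],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, GeneticMap):
            return NotImplemented
        if self.chromosomes != other.chromosomes:
            return False
        for c in self.chromosomes:
            if list(self.markers[c]) != list(other.markers[c]):
                return False
            if not np.allclose(self.positions[c], other.positions[c]):
                return False
        return True


@dataclass
class PhasedIndividual:
    """Two allele sequences per chromosome, plus optional truth ancestry.

    ``hap[chrom]`` is a (2, n_loci) int8 array over {0 (A), 1 (B), -1
    (missing)}. ``truth[chrom]`` — simulator-only ground truth — is a pair of
    lists of :class:`AncestrySegment` that tile the chromosome per homolog.
    """

    id: str
    hap: dict[str, np.ndarray]
    truth: Optional[dict[str, list[list[AncestrySegment]]]] = None
    generation: str = ""
    mother: Optional[str] = None
    father: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def genotypes(self, chrom: str) -> np.ndarray:
        """Unphased genotype view: 0 (AA), 1 (AB), 2 (BB), -1 (missing).

        A site is missing if either observed allele is missing.
        """
        h = self.hap[chrom]
        g = (h[0] + h[1]).astype(np.int8)
        g[(h[0] == MISSING) | (h[1] == MISSING)] = MISSING
        return g

    def validate_against(self, gmap: GeneticMap) -> None:
        for chrom in gmap.chromosomes:
            h = self.hap.get(chrom)
            if h is None or h.shape != (2, gmap.n_loci(chrom)):
                raise ValidationError(
                    f"{self.id}/{chrom}: haplotypes must be 2 x {gmap.n_loci(chrom)}"
                )

    def copy(self) -> "PhasedIndividual":
        return PhasedIndividual(
            id=self.id,
            hap={c: h.copy() for c, h in self.hap.items()},
            truth=None
            if self.truth is None
            else {c: [list(s) for s in pair] for c, pair in self.truth.items()},
            generation=self.generation,
            mother=self.mother,
            father=self.father,
            meta=dict(self.meta),
        )


def truth_origin_fraction(
    ind: PhasedIndividual, gmap: GeneticMap, origin: str = "exotic"
) -> float:
    """Fraction of the diploid map length whose truth label equals *origin*."""
    if ind.truth is None:
        raise ValueError(f"{ind.id} carries no truth ancestry labels")
    total = 0.0
    for chrom in gmap.chromosomes:
        for homolog in ind.truth[chrom]:
            total += sum(s.length_cM for s in homolog if s.origin == origin)
    return total / (2.0 * gmap.total_length_cM)


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    mother: Optional[str]
    father: Optional[str]
    generation: str = ""


@dataclass
class Pedigree:
    """Topologically ordered pedigree; unknown parents allowed (None)."""

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate pedigree ids: {sorted(dupes)}")
        self.records = _toposort(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        rec = self._by_id()[iid]
        return rec.mother, rec.father

    def _by_id(self) -> dict[str, PedigreeRecord]:
        return {r.id: r for r in self.records}

    def true_duos(self) -> list[tuple[str, str]]:
        """All recorded parent-offspring pairs (parent first)."""
        known = {r.id for r in self.records}
        out = []
        for r in self.records:
            for p in (r.mother, r.father):
                if p is not None and p in known:
                    out.append((p, r.id))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "mother": [r.mother for r in self.records],
                "father": [r.father for r in self.records],
                "generation": [r.generation for r in self.records],
            }
        )


def _toposort(records: Sequence[PedigreeRecord]) -> list[PedigreeRecord]:
    """Kahn topological sort; raises naming a cycle if one exists."""
    by_id = {r.id: r for r in records}
    indeg = {r.id: 0 for r in records}
    children: dict[str, list[str]] = {r.id: [] for r in records}
    for r in records:
        for p in (r.mother, r.father):
            if p is not None and p in by_id:
                indeg[r.id] += 1
                children[p].append(r.id)
    queue = [i for i, d in indeg.items() if d == 0]
    out: list[PedigreeRecord] = []
    while queue:
        i = queue.pop(0)
        out.append(by_id[i])
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != len(records):
        cycle = sorted(i for i, d in indeg.items() if d > 0)
        raise ValidationError(f"pedigree contains a cycle involving: {cycle}")
    return out


@dataclass(frozen=True)
class MarkerPanelEntry:
    """One marker of the foreground-selection panel (Table-1 style).

    ``coupling_allele`` is the allele in cis with the resistance allele in
    the donor: an SSR fragment size (int), a SNP base or A/B code, or, for
    SCAR markers, band presence (1).
    """

    rgene: str
    linkage_group: int
    marker_name: str
    marker_type: str  # SSR | SCAR | SNP
    coupling_allele: object
    reference_alleles: Optional[tuple] = None  # e.g. the 'Gala Galaxy' sizes

    def __post_init__(self) -> None:
        if self.coupling_allele in (None, ""):
            raise ValidationError(f"{self.marker_name}: empty coupling allele")
        if not 1 <= int(self.linkage_group) <= 17:
            raise ValidationError(f"{self.marker_name}: linkage group outside 1..17")


@dataclass(frozen=True)
class RGeneLocus:
    """A major resistance gene placed on the map with a containing window."""

    name: str
    chrom: str
    position_cM: float
    window_cM: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window_cM
        if not lo <= self.position_cM <= hi:
            raise ValidationError(f"{self.name}: position outside its window")


# ---------------------------------------------------------------------------
# Readers / writers. The genetic map is the single coordinate authority:
# loading never reorders loci relative to it.
# ---------------------------------------------------------------------------

_ALLELE_CHAR = {A: "A", B: "B", MISSING: "N"}
_CHAR_ALLELE = {"A": A, "B": B, "N": MISSING}


def load_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    for col in ("marker", "chrom", "cM"):
        if col not in df.columns:
            raise ValidationError(f"map file missing column {col!r}")
    bad = df[df["cM"].isna() | df["marker"].isna()]
    if len(bad):
        raise ValidationError(f"malformed map row(s) at line(s) {list(bad.index + 2)}")
    chroms = tuple(dict.fromkeys(df["chrom"]))
    markers = {}
    positions = {}
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        markers[chrom] = sub["marker"].to_numpy(dtype=object)
        positions[chrom] = sub["cM"].to_numpy(dtype=float)
    return GeneticMap(chroms, markers, positions)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "mother", "father"):
        if col not in df.columns:
            raise ValidationError(f"pedigree file missing column {col!r}")
    recs = []
    for _, row in df.iterrows():
        recs.append(
            PedigreeRecord(
                id=row["id"],
                mother=None if row["mother"] in ("", "NA") else row["mother"],
                father=None if row["father"] in ("", "NA") else row["father"],
                generation=row.get("generation", ""),
            )
        )
    return Pedigree(recs)


def write_pedigree(ped: Pedigree, path) -> None:
    df = ped.to_frame().fillna("NA")
    df.to_csv(path, index=False)


def write_phased_vcf(
    individuals: Sequence[PhasedIndividual], gmap: GeneticMap, path
) -> None:
    """Write phased genotypes as a minimal text VCF (REF=A, ALT=B).

    VCF POS must be a positive integer, so positions are cM x 10^4 + 1;
    the map file remains the coordinate authority.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in gmap.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        ids = [ind.id for ind in individuals]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for chrom in gmap.chromosomes:
            pos = gmap.positions[chrom]
            mk = gmap.markers[chrom]
            haps = [ind.hap[chrom] for ind in individuals]
            for i in range(len(pos)):
                gts = []
                for h in haps:
                    a0, a1 = int(h[0, i]), int(h[1, i])
                    if a0 == MISSING or a1 == MISSING:
                        gts.append(".|.")
                    else:
                        gts.append(f"{a0}|{a1}")
                ipos = int(round(pos[i] * 10_000)) + 1
                fh.write(
                    f"{chrom}\t{ipos}\t{mk[i]}\tA\tB\t.\t.\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


def load_phased_vcf(path, gmap: GeneticMap) -> list[PhasedIndividual]:
    """Load phased individuals from a VCF (via cyvcf2), in map order.

    Unphased or half-missing calls become missing on both homologs (a
    warning is emitted). Markers absent from the map are an error.
    """
    from cyvcf2 import VCF

    midx = gmap.marker_index()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    haps = {
        s: {
            c: np.full((2, gmap.n_loci(c)), MISSING, dtype=np.int8)
            for c in gmap.chromosomes
        }
        for s in samples
    }
    n_unphased = 0
    offenders: list[str] = []
    for variant in vcf:
        marker = variant.ID
        if marker not in midx:
            offenders.append(str(marker))
            continue
        chrom, i = midx[marker]
        for s, (a0, a1, phased) in zip(samples, variant.genotypes):
            if a0 < 0 or a1 < 0:
                continue  # half- or fully-missing stays missing
            if not phased and a0 != a1:
                n_unphased += 1  # ambiguous phase: missing on both homologs
                continue
            haps[s][chrom][0, i] = a0
            haps[s][chrom][1, i] = a1
    vcf.close()
    if offenders:
        raise ValidationError(f"markers absent from the map: {offenders[:10]}")
    if n_unphased:
        warnings.warn(
            f"{n_unphased} unphased genotype(s) set to missing", stacklevel=2
        )
    return [PhasedIndividual(id=s, hap=haps[s]) for s in samples]


def write_haplotype_table(
    individuals: Sequence[PhasedIndividual], gmap: GeneticMap, path
) -> None:
    """Wide TSV: marker + two columns per individual (<id>_h1, <id>_h2)."""
    data: dict[str, list] = {"marker": [], "chrom": []}
    for ind in individuals:
        data[f"{ind.id}_h1"] = []
        data[f"{ind.id}_h2"] = []
    for chrom in gmap.chromosomes:
        data["marker"].extend(gmap.markers[chrom])
        data["chrom"].extend([chrom] * gmap.n_loci(chrom))
        for ind in individuals:
            h = ind.hap[chrom]
            data[f"{ind.id}_h1"].extend(_ALLELE_CHAR[int(a)] for a in h[0])
            data[f"{ind.id}_h2"].extend(_ALLELE_CHAR[int(a)] for a in h[1])
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def load_haplotype_table(path, gmap: GeneticMap) -> list[PhasedIndividual]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    midx = gmap.marker_index()
    missing_markers = [m for m in df["marker"] if m not in midx]
    if missing_markers:
        raise ValidationError(
            f"markers absent from the map: {missing_markers[:10]}"
        )
    ids = sorted(
        {c[:-3] for c in df.columns if c.endswith("_h1") or c.endswith("_h2")}
    )
    out = []
    for iid in ids:
        hap = {
            c: np.full((2, gmap.n_loci(c)), MISSING, dtype=np.int8)
            for c in gmap.chromosomes
        }
        for marker, a1, a2 in zip(df["marker"], df[f"{iid}_h1"], df[f"{iid}_h2"]):
            chrom, i = midx[marker]
            hap[chrom][0, i] = _CHAR_ALLELE[a1]
            hap[chrom][1, i] = _CHAR_ALLELE[a2]
        out.append(PhasedIndividual(id=iid, hap=hap))
    return out


def load_marker_panel(path) -> list[MarkerPanelEntry]:
    """Panel TSV with columns rgene, LG, marker, type, coupling_allele
    [, gala_ref]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        ref = row.get("gala_ref")
        ref_tuple = None
        if isinstance(ref, str) and ref not in ("", "NA"):
            ref_tuple = tuple(ref.split("/"))
        entries.append(
            MarkerPanelEntry(
                rgene=row["rgene"],
                linkage_group=int(row["LG"]),
                marker_name=row["marker"],
                marker_type=row["type"],
                coupling_allele=row["coupling_allele"],
                reference_alleles=ref_tuple,
            )
        )
    return entries
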