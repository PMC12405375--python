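"""Shared-segment calling, the segment filter rules, and tracing recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lift import genome_model as gm
from lift import haplotype_tracing as ht
from lift import meiosis_sim as ms
from lift import synthetic_data as sd


def _line_map(n, length=None):
    return sd.make_apple_map(1, float(length or n - 1), n, seed=13)


def _ind(name, *haps):
    arr = np.vstack([np.asarray(h, dtype=np.int8) for h in haps])
    return gm.PhasedIndividual(name, {"LG01": arr})


def naive_shared_segments(a, b):
    """Quadratic reference scanner for maximal matching runs.

    Enumerates candidate (i, j) pairs and checks validity (no informative
    mismatch inside, informative matches at both ends) and maximality (the
    nearest informative SNP outside each end, if any, is a mismatch).
    """
    n = len(a)
    informative = [(a[i] != -1 and b[i] != -1) for i in range(n)]
    match = [informative[i] and a[i] == b[i] for i in range(n)]
    mismatch = [informative[i] and a[i] != b[i] for i in range(n)]
    out = []
    for i in range(n):
        if not match[i]:
            continue
        for j in range(i, n):
            if not match[j]:
                continue
            if any(mismatch[k] for k in range(i, j + 1)):
                continue
            prev = next((k for k in range(i - 1, -1, -1) if informative[k]), None)
            nxt = next((k for k in range(j + 1, n) if informative[k]), None)
            if prev is not None and match[prev]:
                continue
            if nxt is not None and match[nxt]:
                continue
            out.append((i, j, sum(match[i : j + 1])))
    return out


class TestFindSharedSegments:
    def test_identical_haplotypes_single_full_segment(self):
        m = _line_map(20)
        h = np.tile([0, 1], 10).astype(np.int8)
        (seg,) = ht.find_shared_segments(h, h.copy(), m, "LG01")
        assert (seg.start_index, seg.end_index) == (0, 19)
        assert seg.n_shared_snps == 20
        assert seg.start_cM == m.positions["LG01"][0]
        assert seg.end_cM == m.positions["LG01"][-1]

    def test_single_mismatch_splits_run(self):
        m = _line_map(20)
        a = np.zeros(20, dtype=np.int8)
        b = a.copy()
        b[9] = 1
        segs = ht.find_shared_segments(a, b, m, "LG01")
        assert [(s.start_index, s.end_index) for s in segs] == [(0, 8), (10, 19)]

    def test_missing_spans_but_does_not_count(self):
        m = _line_map(10)
        a = np.zeros(10, dtype=np.int8)
        b = a.copy()
        b[4] = -1
        (seg,) = ht.find_shared_segments(a, b, m, "LG01")
        assert seg.n_shared_snps == 9
        assert seg.n_missing_spanned == 1
        assert (seg.start_index, seg.end_index) == (0, 9)

    def test_run_trimmed_to_informative_shared_ends(self):
        m = _line_map(10)
        a = np.zeros(10, dtype=np.int8)
        b = a.copy()
        b[0] = -1
        b[9] = 1
        (seg,) = ht.find_shared_segments(a, b, m, "LG01")
        assert (seg.start_index, seg.end_index) == (1, 8)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        m = _line_map(n)
        a = rng.integers(0, 2, n).astype(np.int8)
        if rng.random() < 0.5:
            b = a.copy()  # related pair with sparse differences
            flip = rng.random(n) < 0.1
            b[flip] = 1 - b[flip]
        else:
            b = rng.integers(0, 2, n).astype(np.int8)
        a[rng.random(n) < 0.15] = -1
        b[rng.random(n) < 0.15] = -1
        fast = [
            (s.start_index, s.end_index, s.n_shared_snps)
            for s in ht.find_shared_segments(a, b, m, "LG01")
        ]
        assert fast == naive_shared_segments(a, b)


class TestFilterCandidateSegments:
    def _setup(self, n_match):
        m = _line_map(40)
        donor_h = np.zeros(40, dtype=np.int8)
        desc_h = np.ones(40, dtype=np.int8)
        desc_h[:n_match] = 0
        parent_h = np.ones(40, dtype=np.int8)  # never matches descendant 0s
        donor = _ind("DON", donor_h, 1 - donor_h)
        desc = _ind("DESC", desc_h, 1 - desc_h)
        parent = _ind("PAR", parent_h, parent_h)
        segs = ht.find_shared_segments(
            donor.hap["LG01"][0], desc.hap["LG01"][0], m, "LG01"
        )
        return m, donor, desc, parent, segs

    def test_sixteen_snp_boundary(self):
        _, donor, desc, parent, segs = self._setup(16)
        kept = ht.filter_candidate_segments(segs, desc, donor, parent)
        assert len(kept) == 1
        assert kept[0].disposition == ht.DONOR_EXCLUSIVE
        _, donor, desc, parent, segs = self._setup(15)
        assert ht.filter_candidate_segments(segs, desc, donor, parent) == []

    def test_segment_also_in_parent_dropped(self):
        m = _line_map(40)
        base = np.tile([0, 1], 20).astype(np.int8)
        donor = _ind("DON", base, 1 - base)
        desc = _ind("DESC", base, 1 - base)
        parent = _ind("PAR", base, 1 - base)  # carries the identical haplotype
        segs = ht.find_shared_segments(
            donor.hap["LG01"][0], desc.hap["LG01"][0], m, "LG01"
        )
        assert ht.filter_candidate_segments(segs, desc, donor, parent) == []

    def test_extended_region_exception_retained(self):
        # donor matches the descendant 5 SNPs beyond where the parent's
        # match breaks on the left; segment itself carried by both
        m = _line_map(40)
        desc_h = np.tile([0, 1], 20).astype(np.int8)
        donor_h = desc_h.copy()
        parent_h = desc_h.copy()
        parent_h[9] = 1 - parent_h[9]  # parent mismatch just left of window
        donor = _ind("DON", donor_h, np.ones(40, dtype=np.int8))
        desc = _ind("DESC", desc_h, np.ones(40, dtype=np.int8))
        parent = _ind("PAR", parent_h, 1 - desc_h)
        segs = ht.find_shared_segments(
            donor.hap["LG01"][0], desc.hap["LG01"][0], m, "LG01", lo=10, hi=30
        )
        kept = ht.filter_candidate_segments(segs, desc, donor, parent)
        assert len(kept) == 1
        assert kept[0].disposition == ht.EXCEPTION_RETAINED

    def test_no_differential_extension_dropped(self):
        m = _line_map(40)
        desc_h = np.tile([0, 1], 20).astype(np.int8)
        donor = _ind("DON", desc_h.copy(), np.ones(40, dtype=np.int8))
        parent = _ind("PAR", desc_h.copy(), 1 - desc_h)
        desc = _ind("DESC", desc_h, np.ones(40, dtype=np.int8))
        segs = ht.find_shared_segments(
            donor.hap["LG01"][0], desc.hap["LG01"][0], m, "LG01", lo=10, hi=30
        )
        assert ht.filter_candidate_segments(segs, desc, donor, parent) == []


class TestDefineUnadapted:
    def test_homolog_copied_from_ancestor_is_domestic(self, rng):
        m = _line_map(60)
        anc_h = rng.integers(0, 2, 60).astype(np.int8)
        exotic_h = rng.integers(0, 2, 60).astype(np.int8)
        anc = _ind("ANC", anc_h, rng.integers(0, 2, 60).astype(np.int8))
        donor = _ind("DON", anc_h.copy(), exotic_h)
        part = ht.define_unadapted_haplotypes(donor, [anc], m)
        assert part.unadapted["LG01"][0] == []
        assert part.domestic["LG01"][0] == [(0, 59)]

    def test_no_ancestors_whole_genome_unadapted(self, default_map,
                                                 mr5_founders):
        part = ht.define_unadapted_haplotypes(mr5_founders.donor, [], default_map)
        assert part.diploid_percent() == pytest.approx(100.0)

    def test_evereste_like_donor_near_half(self, default_map,
                                           evereste_founders):
        part = ht.define_unadapted_haplotypes(
            evereste_founders.donor, [evereste_founders.domestic_parent],
            default_map,
        )
        assert abs(part.diploid_percent() - 50.0) <= 2.0

    def test_high_missingness_refused(self, default_map, mr5_founders):
        bad = mr5_founders.donor.copy()
        first = default_map.chromosomes[0]
        bad.hap[first][:, :] = gm.MISSING
        with pytest.raises(gm.ValidationError, match="missing"):
            ht.define_unadapted_haplotypes(bad, [], default_map)


class TestTraceUnadapted:
    def test_donor_traced_against_itself(self, default_map, mr5_founders):
        part = ht.define_unadapted_haplotypes(
            mr5_founders.donor, [mr5_founders.domestic_parent], default_map
        )
        rep = ht.trace_unadapted(
            mr5_founders.donor, mr5_founders.donor, part, None, default_map
        )
        assert rep.percent_of_diploid_genome == pytest.approx(
            part.diploid_percent(), rel=0.02
        )

    def test_noise_free_recovery(self, default_map, mr5_founders):
        rng = np.random.default_rng(40)
        rp = mr5_founders.fresh_domestic(1, rng)[0]
        off = ms.make_cross(mr5_founders.donor, rp, 20, default_map, rng)
        part = ht.partition_from_truth(mr5_founders.donor, default_map)
        n_truth = n_rec = 0
        precisions = []
        for o in off:
            rep = ht.trace_unadapted(o, mr5_founders.donor, part, rp,
                                     default_map)
            tc = ht.compare_to_truth(rep, o, default_map)
            n_truth += tc.n_truth_segments
            n_rec += round(tc.recall_segments * tc.n_truth_segments)
            precisions.append(tc.precision_cM)
            assert tc.max_boundary_error_intervals <= 2
        assert n_rec / n_truth >= 0.95
        assert np.mean(precisions) >= 0.95

    def test_end_to_end_recovery_with_subtraction(self, default_map,
                                                  mr5_founders):
        rng = np.random.default_rng(41)
        rp = mr5_founders.fresh_domestic(1, rng)[0]
        off = ms.make_cross(mr5_founders.donor, rp, 20, default_map, rng)
        part = ht.define_unadapted_haplotypes(
            mr5_founders.donor, [mr5_founders.domestic_parent], default_map
        )
        recalls = []
        for o in off:
            rep = ht.trace_unadapted(o, mr5_founders.donor, part, rp,
                                     default_map)
            tc = ht.compare_to_truth(rep, o, default_map)
            if tc.n_truth_segments:
                recalls.append(tc.recall_cM)
        assert np.mean(recalls) >= 0.9

    def test_null_allele_noise_costs_at_most_five_points(self, default_map,
                                                         mr5_founders):
        rng = np.random.default_rng(42)
        rp = mr5_founders.fresh_domestic(1, rng)[0]
        off = ms.make_cross(mr5_founders.donor, rp, 15, default_map, rng)
        part = ht.partition_from_truth(mr5_founders.donor, default_map)

        def mean_recall(pop):
            vals = []
            for o in pop:
                rep = ht.trace_unadapted(o, mr5_founders.donor, part, rp,
                                         default_map)
                tc = ht.compare_to_truth(rep, o, default_map)
                if tc.n_truth_segments:
                    vals.append(tc.recall_cM)
            return float(np.mean(vals))

        clean = mean_recall(off)
        noisy_pop, _ = sd.inject_null_alleles(
            off, sd.NoiseSpec(null_allele_rate=0.02, seed=77)
        )
        noisy = mean_recall(noisy_pop)
        assert clean - noisy <= 0.05

    def test_min_snps_monotonicity(self, default_map, mr5_founders):
        rng = np.random.default_rng(43)
        rp = mr5_founders.fresh_domestic(1, rng)[0]
        (o,) = ms.make_cross(mr5_founders.donor, rp, 1, default_map, rng)
        part = ht.define_unadapted_haplotypes(
            mr5_founders.donor, [mr5_founders.domestic_parent], default_map
        )
        totals = [
            ht.trace_unadapted(
                o, mr5_founders.donor, part, rp, default_map, min_snps=k
            ).total_unadapted_cM
            for k in (4, 8, 16, 24, 40)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_huge_min_snps_gives_empty_report(self, default_map, mr5_founders):
        part = ht.define_unadapted_haplotypes(
            mr5_founders.donor, [mr5_founders.domestic_parent], default_map
        )
        rep = ht.trace_unadapted(
            mr5_founders.donor, mr5_founders.donor, part, None, default_map,
            min_snps=10**6,
        )
        assert rep.segments == []
        assert rep.percent_of_diploid_genome == 0.0

    def test_selected_carrier_has_rgene_linked_segment(self, default_map,
                                                       mr5_founders):
        rng = np.random.default_rng(44)
        res = ms.run_pbc_series(
            mr5_founders,
            ms.ProgramConfig(n_generations=3, offspring_per_cross=40),
            rng,
        )
        part = ht.define_unadapted_haplotypes(
            mr5_founders.donor, [mr5_founders.domestic_parent], default_map
        )
        for carrier in res.generations["pBC2"][:5]:
            rep = ht.trace_unadapted(
                carrier, mr5_founders.donor, part, None, default_map,
                rgene_loci=[mr5_founders.rgene],
            )
            linked = [s for s in rep.segments if s.rgene_linked]
            assert linked
            lo, hi = mr5_founders.rgene.window_cM
            assert any(s.start_cM <= lo and s.end_cM >= hi for s in linked)


class TestIntervalAlgebra:
    @given(
        ivs=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)), max_size=8
        ),
        n=st.integers(51, 80),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_merge_and_complement_partition_the_index_range(self, ivs, n):
        ivs = [(min(a, b), max(a, b)) for a, b in ivs]
        merged = ht.merge_intervals(ivs)
        comp = ht._complement_intervals(merged, n)
        both = merged + comp
        covered = sum(e - s + 1 for s, e in both)
        assert covered == n  # disjoint cover of [0, n-1]
        assert set().union(*(range(s, e + 1) for s, e in both)) == set(range(n))


class TestRgeneOnlyClassifier:
    def _report(self, flags):
        segs = [
            ht.SharedSegment("LG03", 0, 20, 0.0, 15.0, 21, 0,
                             rgene_linked=f)
            for f in flags
        ]
        return ht.UnadaptedReport("X", segs, 15.0 * len(flags), 1.0, {})

    def test_single_linked_segment(self):
        assert ht.rgene_only_classifier(self._report([True])) == ht.RGENE_ONLY

    def test_linked_plus_extra(self):
        assert (
            ht.rgene_only_classifier(self._report([True, False]))
            == ht.RGENE_PLUS_EXTRA
        )

    def test_empty_report_flags_conflict(self):
        assert (
            ht.rgene_only_classifier(self._report([]))
            == ht.NO_RGENE_SEGMENT
        )
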