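"""SV merging, projection, tallies, enrichment and concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from introscan import simgen, svmap
from introscan.archdetect import SegmentCall


def rec(start, end=None, type="DEL", length=None, carriers=("s1_hap1",), source="a",
        chrom="chr1"):
    if type == "INS":
        end = start + 1
        length = length or 100
    else:
        end = end if end is not None else start + (length or 100)
        length = end - start
    return svmap.SVRecord(
        chrom=chrom, start=start, end=end, type=type, length=length,
        carriers=frozenset(carriers), source=source,
    )


class TestSVRecordValidation:
    def test_short_sv_rejected(self):
        with pytest.raises(ValueError, match="50"):
            rec(0, 20)

    def test_del_length_must_match_interval(self):
        with pytest.raises(ValueError):
            svmap.SVRecord("chr1", 0, 100, "DEL", 60)

    def test_ins_spans_breakpoint(self):
        with pytest.raises(ValueError):
            svmap.SVRecord("chr1", 0, 200, "INS", 200)


def brute_force_clusters(records, reciprocal=0.5, ins_window=500):
    """Independent O(n^2) single-linkage oracle."""
    n = len(records)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom != b.chrom or a.type != b.type:
                continue
            if a.type == "INS":
                lo, hi = sorted((a.length, b.length))
                linked = abs(a.start - b.start) <= ins_window and lo >= reciprocal * hi
            else:
                ov = min(a.end, b.end) - max(a.start, b.start)
                linked = ov >= reciprocal * a.length and ov >= reciprocal * b.length
            if linked:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(frozenset((records[k].start, records[k].end, records[k].type,
                                records[k].source) for k in comp))
    return set(comps)


class TestMergeSVs:
    def test_reciprocal_overlap_links(self):
        merged = svmap.merge_svs([rec(100, 200), rec(120, 220, source="b")])
        assert len(merged) == 1
        assert len(merged[0].members) == 2

    def test_insufficient_overlap_keeps_separate(self):
        merged = svmap.merge_svs([rec(100, 200), rec(190, 400, source="b")])
        assert len(merged) == 2

    def test_types_never_mix(self):
        merged = svmap.merge_svs([rec(100, 200, type="DEL"), rec(100, 200, type="INV")])
        assert len(merged) == 2

    def test_ins_breakpoint_and_size_rule(self):
        a = rec(1000, type="INS", length=200)
        b = rec(1300, type="INS", length=150, source="b")
        c = rec(1400, type="INS", length=50, source="c")  # size ratio 0.25 vs a
        merged = svmap.merge_svs([a, b, c])
        sizes = sorted(len(m.members) for m in merged)
        assert sizes == [1, 2]

    def test_representative_is_longest_then_leftmost(self):
        merged = svmap.merge_svs([rec(100, 220), rec(110, 220, source="b")])
        assert merged[0].representative.start == 100

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_on_random_records(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(200):
            svtype = str(rng.choice(["DEL", "INV", "INS"], p=[0.5, 0.2, 0.3]))
            start = int(rng.integers(0, 50_000))
            length = int(rng.integers(50, 2000))
            records.append(rec(start, type=svtype, length=length, source=f"s{i}"))
        merged = svmap.merge_svs(records)
        got = {
            frozenset((m.start, m.end, m.type, m.source) for m in cl.members)
            for cl in merged
        }
        assert got == brute_force_clusters(records)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        records = [
            rec(int(rng.integers(0, 5000)), length=int(rng.integers(50, 500)),
                source=f"s{i}")
            for i in range(60)
        ]
        def key(ms):
            return sorted(
                tuple(sorted((m.start, m.end, m.source) for m in cl.members))
                for cl in ms
            )
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert key(svmap.merge_svs(records)) == key(svmap.merge_svs(shuffled))


class TestProjection:
    @staticmethod
    def seg(start, end, hap, origin="NDL"):
        return SegmentCall("chr1", start, end, hap, 0.9, origin=origin)

    def test_contained_sv_inherits_origin(self):
        merged = svmap.merge_svs([rec(10, 60, carriers=("s1_hap1",))])
        imap = svmap.project_svs(merged, [self.seg(0, 100, "s1_hap1")])
        assert len(imap.entries) == 1
        assert imap.entries[0][2] == "NDL"

    def test_haplotype_mismatch_excluded(self):
        merged = svmap.merge_svs([rec(10, 60, carriers=("s1_hap1",))])
        imap = svmap.project_svs(merged, [self.seg(0, 100, "s1_hap2")])
        assert imap.entries == []

    def test_rejected_segments_never_match(self):
        merged = svmap.merge_svs([rec(10, 60)])
        imap = svmap.project_svs(
            merged, [self.seg(0, 100, "s1_hap1", origin="REJECTED")]
        )
        assert imap.entries == []

    def test_partial_overlap_needs_overlap_mode(self):
        merged = svmap.merge_svs([rec(80, 180, carriers=("s1_hap1",))])
        segs = [self.seg(0, 100, "s1_hap1")]
        assert svmap.project_svs(merged, segs).entries == []
        assert len(svmap.project_svs(merged, segs, mode="overlap").entries) == 1

    def test_shrinking_segments_monotone(self):
        rng = np.random.default_rng(8)
        records = [
            rec(int(rng.integers(0, 9000)), length=int(rng.integers(50, 400)),
                carriers=("s1_hap1",), source=f"s{i}")
            for i in range(50)
        ]
        merged = svmap.merge_svs(records)
        big = [self.seg(0, 10_000, "s1_hap1")]
        small = [self.seg(2000, 6000, "s1_hap1")]
        n_big = len(svmap.project_svs(merged, big).entries)
        n_small = len(svmap.project_svs(merged, small).entries)
        assert n_small <= n_big

    def test_truth_round_trip_recall(self, papuan_cohort):
        """SVs implanted strictly inside truth tracts are all recovered as
        introgressed when projecting onto the truth segments themselves."""
        coh = simgen.implant_svs(papuan_cohort, n_svs=25, seed=9,
                                 inside_tracts_only=True)
        records = []
        for i, row in coh.truth_svs.iterrows():
            records.append(
                svmap.SVRecord(
                    chrom=row["chrom"], start=row["start"], end=row["end"],
                    type=row["type"], length=row["length"],
                    carriers=frozenset(row["carriers"].split(",")), source=f"t{i}",
                )
            )
        segments = [
            SegmentCall(coh.chrom, r["start"], r["end"], r["haplotype"], 1.0,
                        origin=r["donor"])
            for _, r in coh.truth_tracts.iterrows()
        ]
        merged = svmap.merge_svs(records)
        imap = svmap.project_svs(merged, segments)
        recovered = {
            (sv.representative.start, sv.representative.end) for sv, _, _ in imap.entries
        }
        assert len(recovered) == len(coh.truth_svs)


class TestTallies:
    def test_ins_bases_sum(self):
        svs = [
            rec(10, type="INS", length=100, carriers=("s1_hap1",)),
            rec(500, type="INS", length=300, carriers=("s1_hap1",), source="b"),
        ]
        merged = svmap.merge_svs(svs)
        seg = SegmentCall("chr1", 0, 1000, "s1_hap1", 0.9, origin="DNS")
        tal = svmap.tally_bases(svmap.project_svs(merged, [seg]))
        assert tal.loc[tal["type"] == "INS", "bases"].sum() == 400

    def test_empty_map_all_zero(self):
        tal = svmap.tally_bases(svmap.IntrogressionMap())
        assert len(tal) == 0

    def test_consistency_with_entry_list(self, papuan_cohort):
        coh = simgen.implant_svs(papuan_cohort, n_svs=40, seed=10,
                                 inside_tracts_only=True)
        records = [
            svmap.SVRecord(
                chrom=r["chrom"], start=r["start"], end=r["end"], type=r["type"],
                length=r["length"], carriers=frozenset(r["carriers"].split(",")),
                source=f"t{i}",
            )
            for i, r in coh.truth_svs.iterrows()
        ]
        segments = [
            SegmentCall(coh.chrom, r["start"], r["end"], r["haplotype"], 1.0,
                        origin=r["donor"])
            for _, r in coh.truth_tracts.iterrows()
        ]
        imap = svmap.project_svs(svmap.merge_svs(records), segments)
        tal = svmap.tally_bases(imap)
        # independent recomputation from the triple list
        expect = {}
        seen = set()
        for sv, seg, origin in imap.entries:
            sample = seg.haplotype.rsplit("_hap", 1)[0]
            if (id(sv), sample) in seen or sv.type == "INV":
                continue
            seen.add((id(sv), sample))
            k = (sample, origin, sv.type)
            expect[k] = expect.get(k, 0) + sv.representative.length
        got = {
            (r["sample"], r["origin"], r["type"]): r["bases"]
            for _, r in tal.iterrows()
        }
        assert got == expect


def hypergeom_tail_oracle(a, b, c, d):
    """One-sided Fisher p as an explicit hypergeometric tail sum."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )
    return p


class TestGenicEnrichment:
    def test_odds_ratio_cross_product(self):
        # table [[20,80],[10,90]] realised via constructed SV/gene layout
        rows = []
        genes = [(i * 1000, i * 1000 + 100) for i in range(30)]
        k = 0
        for intro, near, count in [(True, True, 20), (True, False, 80),
                                   (False, True, 10), (False, False, 90)]:
            for _ in range(count):
                if near:
                    start = (k % 30) * 1000 + 20
                else:
                    start = 40_000 + k * 10
                rows.append({"start": start, "end": start + 5, "introgressed": intro})
                k += 1
        res = svmap.genic_enrichment(
            pd.DataFrame(rows), genes, chrom_length=60_000, flank=10, n_perm=10,
            seed=1,
        )
        assert res.table.tolist() == [[20, 80], [10, 90]]
        assert res.odds_ratio == pytest.approx(2.25)
        assert res.fisher_p == pytest.approx(
            hypergeom_tail_oracle(20, 80, 10, 90), rel=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fisher_matches_hypergeometric_oracle(self, seed):
        """scipy's one-sided Fisher p equals the explicit tail sum on random
        tables with margins <= 30."""
        rng = np.random.default_rng(seed)
        from scipy.stats import fisher_exact

        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), abs=1e-12)

    def test_permutation_floor(self):
        """Observed statistic above every permutation gives p = 1/(n_perm+1)."""
        rng = np.random.default_rng(5)
        genes = [(0, 1000)]
        rows = [{"start": i, "end": i + 60, "introgressed": True} for i in range(0, 900, 90)]
        rows += [{"start": 900_000 + i * 100, "end": 900_000 + i * 100 + 60,
                  "introgressed": False} for i in range(20)]
        res = svmap.genic_enrichment(
            pd.DataFrame(rows), genes, chrom_length=1_000_000, flank=10,
            n_perm=1000, seed=2,
        )
        assert res.perm_p >= 1 / 1001
        assert res.perm_p < 0.05

    def test_zero_margin_flagged(self):
        rows = [{"start": 10, "end": 20, "introgressed": True}]
        res = svmap.genic_enrichment(
            pd.DataFrame(rows), [(0, 100)], chrom_length=1000, n_perm=10, seed=3
        )
        assert res.or_corrected


class TestGenotypeConcordance:
    @staticmethod
    def table(gts, cls="SNV"):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(len(gts)),
                "ref": "A",
                "alt": "T",
                "class": cls,
                "length": 1,
                "s1": gts,
            }
        )

    def test_identical_sets_fully_concordant(self):
        t = self.table(["0|1"] * 50)
        out = svmap.genotype_concordance(t, t)
        assert (out["concordance"] == 1.0).all()

    def test_one_mismatch_in_hundred(self):
        truth = self.table(["0|1"] * 100)
        test = truth.copy()
        test.loc[0, "s1"] = "1|1"
        out = svmap.genotype_concordance(truth, test)
        assert out["concordance"].iloc[0] == pytest.approx(0.99)

    def test_phase_flip_still_concordant(self):
        truth = self.table(["0|1"] * 10)
        test = self.table(["1|0"] * 10)
        out = svmap.genotype_concordance(truth, test)
        assert (out["concordance"] == 1.0).all()

    def test_missing_genotypes_leave_denominator(self):
        truth = self.table(["0|1"] * 10)
        test = truth.copy()
        test.loc[:4, "s1"] = "./."
        out = svmap.genotype_concordance(truth, test)
        assert out["n_compared"].iloc[0] == 5

    def test_disjoint_keys_error(self):
        a = self.table(["0|1"] * 5)
        b = self.table(["0|1"] * 5)
        b["pos"] += 1000
        with pytest.raises(ValueError, match="shared"):
            svmap.genotype_concordance(a, b)

    def test_corruption_rate_reflected(self):
        """Genotypes corrupted at rate 0.009 give ~0.991 concordance."""
        rng = np.random.default_rng(11)
        n = 20_000
        truth = self.table(["0|1"] * n)
        test = truth.copy()
        flip = rng.random(n) < 0.009
        test.loc[flip, "s1"] = "1|1"
        out = svmap.genotype_concordance(truth, test)
        assert out["concordance"].iloc[0] == pytest.approx(0.991, abs=0.003)


class TestVCFInput:
    def test_sv_vcf_round_trip(self, tmp_path, papuan_cohort):
        coh = simgen.implant_svs(papuan_cohort, n_svs=15, seed=12)
        simgen.write_cohort(coh, tmp_path)
        records = svmap.read_sv_vcf(tmp_path / "svs.vcf", source="truth")
        assert len(records) == len(coh.truth_svs)
        by_start = {r.start: r for r in records}
        for _, row in coh.truth_svs.iterrows():
            r = by_start[row["start"]]
            assert r.type == row["type"]
            assert r.length == row["length"]
            assert r.carriers == frozenset(row["carriers"].split(","))
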