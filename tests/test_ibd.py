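"""IBD merging/binning/sharing, Weir-Cockerham F_ST, private allelic richness."""

import itertools

import numpy as np
import pytest

from paleoniche import synth
from paleoniche.ibd import (DEFAULT_MIN_BLOCKS, GenotypeMatrix, IBDSegment,
                            bin_by_length, fst_two_pops, merge_segments,
                            pairwise_fst, private_allelic_richness,
                            sharing_by_class, sharing_network)


def seg(a, b, start, end, chrom="chr1"):
    return IBDSegment(ind_a=a, ind_b=b, chrom=chrom, start_cm=start, end_cm=end)


class TestMergeSegments:
    def test_blocks_within_gap_fused(self):
        out = merge_segments([seg("x", "y", 0, 2), seg("x", "y", 2.5, 4)])
        assert len(out) == 1
        assert (out[0].start_cm, out[0].end_cm) == (0, 4)

    def test_blocks_beyond_gap_kept_separate(self):
        out = merge_segments([seg("x", "y", 0, 2), seg("x", "y", 2.7, 4)])
        assert len(out) == 2

    def test_transitive_chain_becomes_one_block(self):
        out = merge_segments([seg("x", "y", 0, 1), seg("x", "y", 1.4, 2.4),
                              seg("x", "y", 2.8, 3.8)])
        assert len(out) == 1
        assert (out[0].start_cm, out[0].end_cm) == (0, 3.8)

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(0)
        segs = []
        for _ in range(40):
            s = rng.uniform(0, 50)
            segs.append(seg("x", "y", s, s + rng.uniform(0.2, 3)))
        merged = merge_segments(segs, gap_cm=0.6)
        # oracle: pad each interval by gap/2, union, then unpad
        ivs = sorted((s.start_cm, s.end_cm) for s in segs)
        union = []
        for a, b in ivs:
            if union and a - union[-1][1] <= 0.6:
                union[-1][1] = max(union[-1][1], b)
            else:
                union.append([a, b])
        assert [(m.start_cm, m.end_cm) for m in merged] \
            == [tuple(u) for u in union]

    def test_idempotent_and_length_never_decreases(self):
        rng = np.random.default_rng(1)
        segs = [seg("x", "y", s, s + rng.uniform(0.5, 2))
                for s in rng.uniform(0, 30, 20)]
        once = merge_segments(segs)
        twice = merge_segments(once)
        assert [(m.start_cm, m.end_cm) for m in once] \
            == [(m.start_cm, m.end_cm) for m in twice]
        assert sum(m.length_cm for m in once) \
            >= sum(s.length_cm for s in merge_segments(segs, gap_cm=0.0)) - 1e-9

    def test_different_pairs_and_chroms_not_fused(self):
        out = merge_segments([seg("x", "y", 0, 2), seg("x", "z", 2.2, 4),
                              seg("x", "y", 2.2, 4, chrom="chr2")])
        assert len(out) == 3

    def test_consistency_hook_can_veto(self):
        vetoed = merge_segments([seg("x", "y", 0, 2), seg("x", "y", 2.5, 4)],
                                consistency_hook=lambda a, b: False)
        assert len(vetoed) == 2


class TestBinByLength:
    @pytest.mark.parametrize("length,expected", [
        (4.9, "1-5"), (5.0, "5-10"), (9.99, "5-10"), (10.0, ">10"), (1.0, "1-5")])
    def test_boundaries_half_open(self, length, expected):
        binned = bin_by_length([seg("x", "y", 0, length)])
        assert len(binned[expected]) == 1

    def test_sub_centimorgan_discarded(self):
        binned = bin_by_length([seg("x", "y", 0, 0.8)])
        assert all(len(v) == 0 for v in binned.values())


class TestSharingNetwork:
    def test_all_dyads_connected_gives_probability_one(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        segs = [seg(a, b, k * 12, k * 12 + 11)
                for a in ("a1", "a2") for b in ("b1", "b2") for k in range(2)]
        res = sharing_network(segs, labels, min_blocks=2)
        assert len(res) == 1
        assert res[0].probability == 1.0
        assert res[0].possible_dyads == 4

    def test_no_qualifying_dyads_gives_zero(self):
        labels = {"a1": "A", "b1": "B"}
        res = sharing_network([seg("a1", "b1", 0, 11)], labels, min_blocks=2)
        assert res[0].probability == 0.0

    def test_hand_built_set_matches_brute_force_dyad_enumeration(self):
        rng = np.random.default_rng(2)
        inds = [f"A_i{k}" for k in range(3)] + [f"B_i{k}" for k in range(3)]
        labels = {i: i[0] for i in inds}
        segs = []
        for a, b in itertools.combinations(inds, 2):
            for _ in range(int(rng.integers(0, 6))):
                s = rng.uniform(0, 100)
                segs.append(seg(a, b, s, s + rng.uniform(1, 4)))
        binned = bin_by_length(merge_segments(segs))
        for cls, mb in DEFAULT_MIN_BLOCKS.items():
            res = sharing_network(binned[cls], labels, min_blocks=mb)
            counts = {}
            for s in binned[cls]:
                key = tuple(sorted((s.ind_a, s.ind_b)))
                counts[key] = counts.get(key, 0) + 1
            expect = sum(
                1 for a in inds[:3] for b in inds[3:]
                if counts.get(tuple(sorted((a, b))), 0) >= mb) / 9
            assert res[0].probability == pytest.approx(expect)

    def test_probability_symmetric_and_monotone_in_min_blocks(self):
        rng = np.random.default_rng(3)
        labels = {f"A{k}": "A" for k in range(4)} | {f"B{k}": "B" for k in range(4)}
        segs = []
        for a in range(4):
            for b in range(4):
                for _ in range(int(rng.integers(0, 5))):
                    s = rng.uniform(0, 100)
                    segs.append(seg(f"A{a}", f"B{b}", s, s + 2.0))
        p = [sharing_network(segs, labels, min_blocks=m)[0].probability
             for m in (1, 2, 3, 4)]
        assert all(x >= y for x, y in zip(p, p[1:]))

    def test_configured_rate_recovered_through_full_pipeline(self):
        rates = {"1-5": 0.4, "5-10": 0.3, ">10": 0.2}
        segs, labels = synth.gen_ibd_segments({"A": 20, "B": 20}, rates, seed=4)
        shared = sharing_by_class(segs, labels)
        n_dyads = 400
        for cls, rate in rates.items():
            p = shared[cls][0].probability
            sd = np.sqrt(rate * (1 - rate) / n_dyads)
            assert abs(p - rate) < 1.96 * sd + 0.02


class TestFst:
    def test_fixed_alternate_alleles_give_one(self):
        ga = np.zeros((10, 50), dtype=int)
        gb = np.full((10, 50), 2, dtype=int)
        assert fst_two_pops(ga, gb) == pytest.approx(1.0)

    def test_identical_frequencies_give_near_zero(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 1000)
        ga = rng.binomial(2, p, size=(200, 1000))
        gb = rng.binomial(2, p, size=(200, 1000))
        assert abs(fst_two_pops(ga, gb)) < 0.01

    def test_island_model_recovery(self):
        geno, labels = synth.gen_genotypes(100, 5000, fst=0.10, seed=6)
        G = GenotypeMatrix(genotypes=geno, populations=labels)
        f = pairwise_fst(G).loc["pop0", "pop1"]
        assert 0.09 <= f <= 0.11

    def test_matches_per_site_textbook_oracle(self):
        """Ratio-of-sums aggregation agrees with an independently coded
        per-site Weir-Cockerham formula on a small dataset."""
        rng = np.random.default_rng(7)
        ga = rng.binomial(2, 0.3, size=(12, 40))
        gb = rng.binomial(2, 0.7, size=(15, 40))
        num = den = 0.0
        for s in range(40):
            xa, xb = ga[:, s], gb[:, s]
            na, nb = 12.0, 15.0
            pa, pb = xa.sum() / (2 * na), xb.sum() / (2 * nb)
            ha, hb = np.mean(xa == 1), np.mean(xb == 1)
            nbar = (na + nb) / 2
            nc = (na + nb - (na ** 2 + nb ** 2) / (na + nb))  # r-1 = 1
            pbar = (na * pa + nb * pb) / (na + nb)
            if pbar in (0.0, 1.0):
                continue
            s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / nbar
            hbar = (na * ha + nb * hb) / (2 * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4)
                               / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                       - hbar * (2 * nbar - 1) / (4 * nbar))
            c = hbar / 2
            num += a
            den += a + b + c
        assert fst_two_pops(ga, gb) == pytest.approx(num / den, abs=1e-12)

    def test_label_permutation_centers_at_zero(self):
        rng = np.random.default_rng(8)
        geno, labels = synth.gen_genotypes(30, 400, fst=0.05, seed=9)
        vals = []
        for _ in range(200):
            perm = rng.permutation(len(labels))
            vals.append(fst_two_pops(geno[perm[:30]], geno[perm[30:]]))
        assert abs(np.mean(vals)) < 0.005

    def test_too_small_population_rejected(self):
        G = GenotypeMatrix(genotypes=np.zeros((3, 5), dtype=int),
                           populations=["A", "A", "B"])
        with pytest.raises(ValueError):
            pairwise_fst(G)


class TestPrivateAllelicRichness:
    def test_fully_private_fixed_allele_contributes_one(self):
        # alt fixed in A and B, absent in C; 1 variable site
        geno = np.array([[2], [2], [2], [2], [0], [0]])
        G = GenotypeMatrix(genotypes=geno, populations=["A", "A", "B", "B", "C", "C"])
        out = private_allelic_richness(G, g=4)
        assert out.loc["A|B", "private_richness"] == pytest.approx(1.0)

    def test_allele_present_elsewhere_contributes_zero(self):
        geno = np.array([[2, 0], [2, 0], [2, 0], [2, 0], [1, 1], [0, 1]])
        G = GenotypeMatrix(genotypes=geno, populations=["A", "A", "B", "B", "C", "C"])
        out = private_allelic_richness(G, g=4)
        # site 0 alt: present in C (one copy) -> excluded from A|B
        # site 1: A,B fixed ref, C carries alt; ref not private to A|B either
        assert out.loc["A|B", "private_richness"] < 1.0

    def test_matches_exhaustive_subsample_enumeration(self):
        """On populations of <= 6 gene copies, the hypergeometric formula must
        equal the average over all subsamples of size g."""
        from itertools import combinations as comb

        rng = np.random.default_rng(10)
        geno = rng.integers(0, 3, size=(9, 6))
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        G = GenotypeMatrix(genotypes=geno, populations=pops)
        g = 4
        out = private_allelic_richness(G, g=g)

        def copies(pop, site):
            rows = [i for i, p in enumerate(pops) if p == pop]
            arr = []
            for r in rows:
                arr += [1] * geno[r, site] + [0] * (2 - geno[r, site])
            return arr

        tot_alt = geno.sum(axis=0)
        variable = (tot_alt > 0) & (tot_alt < 2 * len(pops))
        for pa, pb in [("A", "B"), ("A", "C"), ("B", "C")]:
            other = ({"A", "B", "C"} - {pa, pb}).pop()
            expect = 0.0
            for site in np.where(variable)[0]:
                for allele in (0, 1):
                    oc = copies(other, site)
                    if sum(1 for x in oc if x == allele) > 0:
                        continue

                    def mean_present(pop):
                        cp = copies(pop, site)
                        subs = list(comb(range(len(cp)), g))
                        return np.mean([any(cp[i] == allele for i in s)
                                        for s in subs])

                    expect += mean_present(pa) * mean_present(pb)
            expect /= variable.sum()
            assert out.loc[f"{pa}|{pb}", "private_richness"] \
                == pytest.approx(expect, abs=1e-12)

    def test_oversized_subsample_rejected(self):
        geno = np.zeros((4, 3), dtype=int)
        geno[0, 0] = 1
        G = GenotypeMatrix(genotypes=geno, populations=["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            private_allelic_richness(G, g=10)
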