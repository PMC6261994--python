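import numpy as np
import pandas as pd
import pytest

from crosspop import loci


def snp_frame(positions, chrom="1", ids=None):
    ids = ids or [f"s{i}" for i in range(len(positions))]
    return pd.DataFrame({"CHR": chrom, "POS": positions, "SNP": ids})


class TestClusterLoci:
    def test_gap_rule(self):
        frame = snp_frame([1_000_000, 1_400_000, 2_000_000])
        found = loci.cluster_loci(frame)
        assert [sorted(l.members) for l in found] == [["s0", "s1"], ["s2"]]

    def test_boundary_gap_inclusive(self):
        frame = snp_frame([1_000_000, 1_500_000, 2_000_000])
        found = loci.cluster_loci(frame)
        assert len(found) == 1 and len(found[0]) == 3

    def test_chromosomes_separate(self):
        frame = pd.concat(
            [snp_frame([1_000_000], "1", ["a"]), snp_frame([1_000_000], "2", ["b"])]
        )
        assert len(loci.cluster_loci(frame)) == 2

    def test_matches_brute_force_transitive_closure(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(2, 200))
            positions = np.sort(rng.integers(1, 20_000_000, n))
            chroms = rng.choice(["1", "2"], n)
            frame = pd.DataFrame(
                {"CHR": chroms, "POS": positions, "SNP": [f"s{i}" for i in range(n)]}
            )
            # oracle: union-find over the <=500kb same-chromosome relation
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    if chroms[i] == chroms[j] and abs(
                        int(positions[i]) - int(positions[j])
                    ) <= 500_000:
                        parent[find(i)] = find(j)
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(f"s{i}")
            got = {frozenset(l.members) for l in loci.cluster_loci(frame)}
            assert got == {frozenset(v) for v in oracle.values()}


class TestSentinel:
    def test_min_p_wins(self):
        locus = loci.Locus("1", 100, 200, ["a", "b"])
        pvals = pd.DataFrame(
            {"SNP": ["a", "b"], "TRAIT": "SBP", "P": [1e-9, 1e-8], "POS": [100, 200]}
        )
        loci.select_sentinel(locus, pvals)
        assert locus.sentinel == "a"

    def test_tie_broken_by_position(self):
        locus = loci.Locus("1", 100, 200, ["a", "b"])
        pvals = pd.DataFrame(
            {"SNP": ["b", "a"], "TRAIT": "SBP", "P": [1e-9, 1e-9], "POS": [200, 100]}
        )
        loci.select_sentinel(locus, pvals)
        assert locus.sentinel == "a"

    def test_cross_trait_argmin_over_pairs(self):
        locus = loci.Locus("1", 100, 300, ["a", "b", "c"])
        pvals = pd.DataFrame(
            {
                "SNP": ["a", "b", "c", "a", "b", "c"],
                "TRAIT": ["SBP"] * 3 + ["DBP"] * 3,
                "P": [1e-5, 1e-7, 1e-6, 1e-9, 1e-4, 1e-3],
                "POS": [100, 200, 300] * 2,
            }
        )
        loci.select_sentinel(locus, pvals)
        # brute-force argmin over all trait x SNP pairs
        best = pvals.sort_values(["P", "POS"]).iloc[0]
        assert locus.sentinel == best["SNP"]
        assert locus.sentinel_trait == best["TRAIT"]
        assert locus.trait_sentinels == {"SBP": "b", "DBP": "a"}


class TestNovelty:
    known = pd.DataFrame({"CHR": "1", "POS": [5_000_000], "SNP": ["known1"]})

    @staticmethod
    def ld_fixed(value):
        return lambda a, b: value

    def _sentinels(self, pos):
        return pd.DataFrame({"CHR": "1", "POS": [pos], "SNP": ["lead"]})

    def test_distant_low_ld_is_novel(self):
        out = loci.nominate_novel(
            self._sentinels(5_600_000), self.known, self.ld_fixed(0.05)
        )
        assert out["NOVEL"].iloc[0]

    def test_within_500kb_not_novel(self):
        out = loci.nominate_novel(
            self._sentinels(5_300_000), self.known, self.ld_fixed(0.0)
        )
        assert not out["NOVEL"].iloc[0]

    def test_distant_but_high_ld_not_novel(self):
        out = loci.nominate_novel(
            self._sentinels(5_600_000), self.known, self.ld_fixed(0.5)
        )
        assert not out["NOVEL"].iloc[0]

    def test_unknown_ld_flagged_for_review(self):
        out = loci.nominate_novel(
            self._sentinels(5_600_000), self.known, self.ld_fixed(None)
        )
        assert out["NOVEL"].iloc[0] and out["NEEDS_REVIEW"].iloc[0]

    def test_monotone_in_known_set(self):
        rng = np.random.default_rng(1)
        sentinels = pd.DataFrame(
            {
                "CHR": "1",
                "POS": rng.integers(1, 50_000_000, 20),
                "SNP": [f"s{i}" for i in range(20)],
            }
        )
        known_small = pd.DataFrame(
            {"CHR": "1", "POS": rng.integers(1, 50_000_000, 5),
             "SNP": [f"k{i}" for i in range(5)]}
        )
        extra = pd.DataFrame(
            {"CHR": "1", "POS": rng.integers(1, 50_000_000, 5),
             "SNP": [f"k{i+5}" for i in range(5)]}
        )
        known_big = pd.concat([known_small, extra], ignore_index=True)
        small = loci.nominate_novel(sentinels, known_small, self.ld_fixed(0.0))
        big = loci.nominate_novel(sentinels, known_big, self.ld_fixed(0.0))
        assert (big["NOVEL"] <= small["NOVEL"]).all()


class TestGroups:
    @pytest.mark.parametrize(
        "maf_pair,expected",
        [
            ((0.30, 0.20), "group1"),
            ((0.005, 0.30), "group2a"),
            ((0.005, 0.02), "group2b"),
            ((0.005, 0.005), "excluded"),
            ((0.30, 0.005), "group2a"),
            ((0.01, 0.01), "group1"),
            ((np.nan, 0.3), "excluded"),
        ],
    )
    def test_threshold_rules(self, maf_pair, expected):
        assert loci.classify_groups(*maf_pair).value == expected

    def test_partition_counts(self):
        rng = np.random.default_rng(2)
        mafs = rng.uniform(0, 0.5, size=(500, 2))
        labels = [loci.classify_groups(a, b) for a, b in mafs]
        m1, m2 = mafs[:, 0], mafs[:, 1]
        lo, hi = np.minimum(m1, m2), np.maximum(m1, m2)
        expected = {
            "group1": int((lo >= 0.01).sum()),
            "group2a": int(((lo < 0.01) & (hi >= 0.05)).sum()),
            "group2b": int(((lo < 0.01) & (hi >= 0.01) & (hi < 0.05)).sum()),
            "excluded": int((hi < 0.01).sum()),
        }
        from collections import Counter

        assert Counter(l.value for l in labels) == Counter(
            {k: v for k, v in expected.items() if v}
        )


class TestAncestrySpecific:
    def _other(self, n_snps, min_p):
        rng = np.random.default_rng(3)
        ps = rng.uniform(0.2, 1.0, n_snps)
        ps[0] = min_p
        return pd.DataFrame(
            {"CHR": "1", "POS": np.linspace(4_600_000, 5_400_000, n_snps).astype(int),
             "P": ps}
        )

    def test_specific_when_no_window_signal(self):
        flag, detail = loci.flag_ancestry_specific(
            5_000_000, "1", 1e-9, 0.02, self._other(100, 0.01)
        )
        assert flag == loci.AncestryFlag.SPECIFIC
        assert detail["threshold"] == pytest.approx(0.05 / 100)

    def test_not_specific_when_window_signal(self):
        flag, _ = loci.flag_ancestry_specific(
            5_000_000, "1", 1e-9, 0.02, self._other(100, 1e-5)
        )
        assert flag == loci.AncestryFlag.NOT_SPECIFIC

    def test_common_in_other_population_ineligible(self):
        flag, _ = loci.flag_ancestry_specific(
            5_000_000, "1", 1e-9, 0.30, self._other(100, 0.01)
        )
        assert flag == loci.AncestryFlag.INELIGIBLE

    def test_empty_window_specific_with_warning(self):
        empty = pd.DataFrame({"CHR": [], "POS": [], "P": []})
        flag, detail = loci.flag_ancestry_specific(5_000_000, "1", 1e-9, 0.02, empty)
        assert flag == loci.AncestryFlag.SPECIFIC
        assert "warning" in detail

    def test_requires_significant_sentinel(self):
        with pytest.raises(ValueError):
            loci.flag_ancestry_specific(5_000_000, "1", 1e-4, 0.02, self._other(10, 0.5))
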