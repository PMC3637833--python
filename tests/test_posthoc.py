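"""Venn partition, pairwise positive set, global chaining and cutoff 2."""

import itertools

import pytest

from posthocalign import (
    AlignedPair,
    GlobalChain,
    PairwiseAlignment,
    PosthocConfig,
    ScorerConfig,
    build_chains,
    global_posthoc,
    make_scorer,
    naive_align,
    pairwise_posthoc,
    venn_partition,
)
from posthocalign.peaklist import Peak, PeakList
from posthocalign.posthoc import CUTOFF1_GRID, _consensus
from conftest import make_merged_replicates


def alignment(id_a, id_b, pairs, **kw):
    return PairwiseAlignment(id_a, id_b, [AlignedPair(*p) for p in pairs], **kw)


def random_alignments(rng, n_peaks=30):
    """Two random one-to-one alignments over the same index space."""

    def one(provenance):
        k = int(rng.integers(5, n_peaks))
        left = rng.permutation(n_peaks)[:k]
        right = rng.permutation(n_peaks)[:k]
        return PairwiseAlignment(
            "E1",
            "E2",
            [
                AlignedPair(int(i), int(j), score=float(rng.random()), provenance=provenance)
                for i, j in zip(left, right)
            ],
        )

    return one("naive"), one("method")


class TestVennPartition:
    def test_worked_example_counts(self, demo):
        naive = naive_align(demo.a, demo.b)
        venn = venn_partition(naive, demo.method)
        assert len(naive) == 56
        assert len(demo.method) == 57
        assert (len(venn.ca), len(venn.da1), len(venn.da2)) == (49, 7, 8)
        assert venn.union_size == 64

    def test_identical_alignments_have_empty_disjoint_areas(self):
        aln = alignment("E1", "E2", [(0, 0, 0.9), (1, 2, 0.8)])
        venn = venn_partition(aln, aln)
        assert len(venn.ca) == 2 and not venn.da1 and not venn.da2

    def test_mismatched_replicate_ids_rejected(self):
        a = alignment("E1", "E2", [(0, 0, 0.9)])
        b = alignment("E1", "E3", [(0, 0, 0.9)])
        with pytest.raises(ValueError, match="different replicate pairs"):
            venn_partition(a, b)

    def test_matches_brute_force_partition(self, rng):
        for _ in range(20):
            naive, method = random_alignments(rng)
            venn = venn_partition(naive, method)
            nset, mset = naive.index_pairs(), method.index_pairs()
            assert {(p.index_a, p.index_b) for p in venn.ca} == nset & mset
            assert {(p.index_a, p.index_b) for p in venn.da1} == nset - mset
            assert {(p.index_a, p.index_b) for p in venn.da2} == mset - nset
            assert venn.union_size == len(nset | mset)

    def test_sets_reassemble_the_inputs(self, rng):
        naive, method = random_alignments(rng)
        venn = venn_partition(naive, method)
        ca = {(p.index_a, p.index_b) for p in venn.ca}
        da1 = {(p.index_a, p.index_b) for p in venn.da1}
        da2 = {(p.index_a, p.index_b) for p in venn.da2}
        assert ca | da1 == naive.index_pairs()
        assert ca | da2 == method.index_pairs()
        assert not (ca & da1) and not (ca & da2) and not (da1 & da2)


class TestPairwisePosthoc:
    def test_worked_example_positive_set_of_54(self, demo):
        naive = naive_align(demo.a, demo.b)
        scorer = make_scorer(ScorerConfig())
        positive = pairwise_posthoc(
            naive, demo.method, demo.a, demo.b, scorer, PosthocConfig(cutoff1=demo.cutoff1)
        )
        assert len(positive) == 54

    def test_cutoff_one_keeps_only_common_pairs(self, demo):
        naive = naive_align(demo.a, demo.b)
        scorer = make_scorer(ScorerConfig())
        positive = pairwise_posthoc(
            naive, demo.method, demo.a, demo.b, scorer, PosthocConfig(cutoff1=1.0)
        )
        venn = venn_partition(naive, demo.method)
        assert positive.index_pairs() == {(p.index_a, p.index_b) for p in venn.ca}

    def test_cutoff_zero_gives_union(self, rng):
        # holds whenever all matching scores are strictly positive
        naive, method = random_alignments(rng)
        positive = pairwise_posthoc(
            naive, method, None, None, None, PosthocConfig(cutoff1=0.0)
        )
        assert positive.index_pairs() == naive.index_pairs() | method.index_pairs()

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff1"):
            PosthocConfig(cutoff1=1.5)

    def test_matches_filter_then_union_brute_force(self, rng):
        """Random instances with pre-scored pairs against a double-loop oracle."""
        scorer = None  # all pairs carry scores already

        def brute(naive, method, cutoff):
            nset = {(p.index_a, p.index_b) for p in naive.pairs}
            mset = {(p.index_a, p.index_b) for p in method.pairs}
            scores = {(p.index_a, p.index_b): p.score for p in naive.pairs}
            scores.update({(p.index_a, p.index_b): p.score for p in method.pairs})
            keep = nset & mset
            for key in (nset - mset) | (mset - nset):
                if scores[key] > cutoff:
                    keep.add(key)
            return keep

        for _ in range(50):
            naive, method = random_alignments(rng)
            cutoff = float(rng.random())
            positive = pairwise_posthoc(
                naive, method, None, None, scorer, PosthocConfig(cutoff1=cutoff)
            )
            assert positive.index_pairs() == brute(naive, method, cutoff)

    def test_positive_between_ca_and_union_and_monotone(self, rng):
        naive, method = random_alignments(rng)
        venn = venn_partition(naive, method)
        ca = {(p.index_a, p.index_b) for p in venn.ca}
        union = naive.index_pairs() | method.index_pairs()
        sizes = []
        for cutoff in CUTOFF1_GRID:
            positive = pairwise_posthoc(
                naive, method, None, None, None, PosthocConfig(cutoff1=cutoff)
            )
            pairs = positive.index_pairs()
            assert ca <= pairs <= union
            sizes.append(len(pairs))
        assert sizes == sorted(sizes, reverse=True)


def chain_list(rid, names):
    peaks = [
        Peak(name=n, cas=f"{i}-0-0", rt1=100.0 + i, rt2=1.0, area=1.0, similarity=900)
        for i, n in enumerate(names)
    ]
    return PeakList(rid, peaks, merged=True)


class TestBuildChains:
    def test_two_replicates_chains_are_the_positive_pairs(self):
        lists = [chain_list("E1", ["a", "b"]), chain_list("E2", ["a", "b"])]
        positive = alignment("E1", "E2", [(0, 0, 0.9), (1, 1, 0.9)])
        chains = build_chains([positive], lists)
        assert {c.peak_indices for c in chains} == {(0, 0), (1, 1)}

    def test_noiseless_series_yields_one_chain_per_compound(self):
        merged, _, library = make_merged_replicates(
            jitter_sd1=0.0,
            jitter_sd2=0.0,
            area_logsd=0.0,
            spectral_noise_sd=0.0,
            similarity_sd=0.0,
            dropout_p=0.0,
            misid_p=0.0,
            split_p=0.0,
            n_compounds=15,
            n_replicates=4,
            seed=2,
        )
        from posthocalign import pairwise_pipeline

        positives = [
            pairwise_pipeline(merged[i], merged[i + 1], cfg=PosthocConfig(cutoff1=0.9))
            for i in range(3)
        ]
        chains = build_chains(positives, merged)
        assert len(chains) == len(library)
        assert all(c.consensus_count == 4 for c in chains)

    def test_matches_exhaustive_path_enumeration(self, rng):
        n_reps, n_peaks = 4, 8
        lists = [
            chain_list(f"E{r + 1}", [f"c{i}" for i in range(n_peaks)])
            for r in range(n_reps)
        ]
        for _ in range(10):
            positives = []
            for r in range(n_reps - 1):
                k = int(rng.integers(2, n_peaks))
                left = rng.permutation(n_peaks)[:k]
                right = rng.permutation(n_peaks)[:k]
                positives.append(
                    alignment(
                        f"E{r + 1}",
                        f"E{r + 2}",
                        [(int(i), int(j), 0.9) for i, j in zip(left, right)],
                    )
                )
            chains = {c.peak_indices for c in build_chains(positives, lists)}
            link_sets = [aln.index_pairs() for aln in positives]
            expected = {
                path
                for path in itertools.product(range(n_peaks), repeat=n_reps)
                if all(
                    (path[r], path[r + 1]) in link_sets[r] for r in range(n_reps - 1)
                )
            }
            assert chains == expected

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_chains([], [chain_list("E1", ["a"])])


class TestGlobalPosthoc:
    def make_chain(self, names):
        name, count = _consensus(names)
        return GlobalChain(
            peak_indices=tuple(range(len(names))),
            names=tuple(names),
            consensus_name=name,
            consensus_count=count,
        )

    def test_three_of_four_names_kept_and_corrected(self):
        chain = self.make_chain(["X", "X", "X", "Y"])
        kept = global_posthoc(
            [chain], PosthocConfig(cutoff2=3, correct_names=True), n_replicates=4
        )
        assert len(kept) == 1
        assert kept[0].names == ("X", "X", "X", "X")
        assert kept[0].consensus_count == 4
        assert kept[0].kept

    def test_unanimous_chain_kept_at_cutoff_n(self):
        chain = self.make_chain(["X"] * 4)
        kept = global_posthoc([chain], PosthocConfig(cutoff2=4), n_replicates=4)
        assert len(kept) == 1

    def test_cutoff2_not_exceeding_half_rejected(self):
        chain = self.make_chain(["X", "X", "Y", "Y"])
        with pytest.raises(ValueError, match="cutoff2"):
            global_posthoc([chain], PosthocConfig(cutoff2=2), n_replicates=4)

    def test_kept_set_matches_modal_count_filter(self, rng):
        n = 5
        names_pool = ["A", "B", "C"]
        chains = [
            self.make_chain([names_pool[int(k)] for k in rng.integers(0, 3, size=n)])
            for _ in range(100)
        ]
        for cutoff2 in (3, 4, 5):
            kept = global_posthoc(chains, PosthocConfig(cutoff2=cutoff2), n_replicates=n)
            expected = [
                c for c in chains if max(c.names.count(x) for x in set(c.names)) >= cutoff2
            ]
            assert len(kept) == len(expected)

    def test_kept_count_monotone_in_cutoff2(self, rng):
        n = 6
        chains = [
            self.make_chain([f"N{int(k)}" for k in rng.integers(0, 4, size=n)])
            for _ in range(60)
        ]
        counts = [
            len(global_posthoc(chains, PosthocConfig(cutoff2=c2), n_replicates=n))
            for c2 in (4, 5, 6)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_name_correction_never_changes_kept_count(self, rng):
        n = 5
        chains = [
            self.make_chain([f"N{int(k)}" for k in rng.integers(0, 3, size=n)])
            for _ in range(50)
        ]
        for cutoff2 in (3, 4, 5):
            plain = global_posthoc(chains, PosthocConfig(cutoff2=cutoff2), n_replicates=n)
            corrected = global_posthoc(
                chains,
                PosthocConfig(cutoff2=cutoff2, correct_names=True),
                n_replicates=n,
            )
            assert len(plain) == len(corrected)
            assert [c.peak_indices for c in plain] == [c.peak_indices for c in corrected]
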