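"""BBH construction and pairwise ANI/AF scores."""

import numpy as np
import pytest

from misig import (
    EvolveParams,
    Gene,
    GeneSet,
    MisiConfig,
    MisigError,
    best_hits,
    bidirectional_best_hits,
    compute_pairwise_score,
    evolve_genome,
    make_reference_genome,
)

from _oracles import oracle_pairwise


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _substitute(rng, seq, k):
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = [c for c in "ACGT" if c != out[p]][rng.integers(0, 3)]
    return "".join(out)


class TestBestHits:
    def test_max_identity_hit_retained(self, rng, lenient_cfg):
        q = _random_seq(rng, 200)
        query = GeneSet("Q", (Gene("q1", q),))
        target = GeneSet(
            "T",
            (Gene("t_close", _substitute(rng, q, 16)), Gene("t_far", _substitute(rng, q, 40))),
        )
        hits = best_hits(query, target, lenient_cfg)
        assert hits["q1"].target_gene_id == "t_close"

    def test_tie_broken_lexicographically(self, rng, lenient_cfg):
        q = _random_seq(rng, 150)
        query = GeneSet("Q", (Gene("q1", q),))
        target = GeneSet("T", (Gene("gB", q), Gene("gA", q)))
        hits = best_hits(query, target, lenient_cfg)
        assert hits["q1"].target_gene_id == "gA"

    def test_unqualified_query_absent(self, rng, lenient_cfg):
        query = GeneSet("Q", (Gene("q1", _random_seq(rng, 200)),))
        target = GeneSet("T", (Gene("t1", _random_seq(rng, 200)),))
        assert best_hits(query, target, lenient_cfg) == {}


class TestBidirectionalBestHits:
    def test_identical_genomes_full_bbh(self, small_ref, lenient_cfg):
        pairs = bidirectional_best_hits(small_ref, small_ref, lenient_cfg)
        assert len(pairs) == len(small_ref.genes)
        assert all(p.identity == 1.0 for p in pairs)

    def test_reciprocity_required(self, rng, lenient_cfg):
        # b1 is closest to a2; a1's best hit b1 must not form a BBH with a1.
        base = _random_seq(rng, 200)
        a1 = _substitute(rng, base, 30)
        a2 = base
        b1 = _substitute(rng, base, 6)
        a = GeneSet("A", (Gene("a1", a1), Gene("a2", a2)))
        b = GeneSet("B", (Gene("b1", b1),))
        pairs = bidirectional_best_hits(a, b, lenient_cfg)
        assert [(p.gene_id_a, p.gene_id_b) for p in pairs] == [("a2", "b1")]

    def test_disjoint_genomes_no_bbh(self, rng, lenient_cfg):
        a = GeneSet("A", tuple(Gene(f"a{i}", _random_seq(rng, 150)) for i in range(3)))
        b = GeneSet("B", tuple(Gene(f"b{i}", _random_seq(rng, 150)) for i in range(3)))
        assert bidirectional_best_hits(a, b, lenient_cfg) == []


class TestComputePairwiseScore:
    def test_self_comparison(self, small_ref, lenient_cfg):
        s = compute_pairwise_score(small_ref, small_ref, lenient_cfg)
        assert s.ani_mean == 100.0
        assert s.af_mean == 1.0
        assert s.defined

    def test_worked_partial_overlap_example(self, rng, lenient_cfg):
        """Two shared genes at exactly 90% identity plus one unshared gene."""
        a1, a2 = _random_seq(rng, 300), _random_seq(rng, 600)
        b = GeneSet(
            "B",
            (
                Gene("b1", _substitute(rng, a1, 30)),
                Gene("b2", _substitute(rng, a2, 60)),
                Gene("b3", _random_seq(rng, 300)),
            ),
        )
        a = GeneSet("A", (Gene("a1", a1), Gene("a2", a2)))
        s = compute_pairwise_score(a, b, lenient_cfg)
        assert s.n_bbh == 2
        assert s.ani_12 == pytest.approx(90.0, abs=1e-9)
        assert s.ani_21 == pytest.approx(90.0, abs=1e-9)
        assert s.af_12 == pytest.approx(900 / 900)
        assert s.af_21 == pytest.approx(900 / 1200)
        assert s.af_mean == pytest.approx(0.875)

    def test_no_shared_genes_undefined(self, rng, lenient_cfg):
        a = GeneSet("A", tuple(Gene(f"a{i}", _random_seq(rng, 150)) for i in range(3)))
        b = GeneSet("B", tuple(Gene(f"b{i}", _random_seq(rng, 150)) for i in range(3)))
        s = compute_pairwise_score(a, b, lenient_cfg)
        assert s.af_12 == 0.0 and s.af_21 == 0.0
        assert not s.defined
        assert s.ani_mean is None

    def test_min_bbh_gates_ani_not_af(self, small_pair):
        ref, evolved = small_pair
        strict = compute_pairwise_score(ref, evolved, MisiConfig(min_bbh=50))
        assert not strict.defined and strict.ani_mean is None
        assert strict.af_mean > 0.9

    def test_empty_gene_set_errors(self, small_ref, lenient_cfg):
        from misig import FeatureClass

        rna_only = GeneSet("R", (Gene("r", "ACGT" * 30, FeatureClass.rRNA),))
        with pytest.raises(MisigError, match="no protein-coding genes"):
            compute_pairwise_score(small_ref, rna_only, lenient_cfg)

    def test_symmetry(self, small_pair, lenient_cfg):
        ref, evolved = small_pair
        s_ab = compute_pairwise_score(ref, evolved, lenient_cfg)
        s_ba = compute_pairwise_score(evolved, ref, lenient_cfg)
        assert s_ba.ani_12 == s_ab.ani_21
        assert s_ba.af_12 == s_ab.af_21
        assert s_ba.af_21 == s_ab.af_12
        assert s_ba.ani_mean == s_ab.ani_mean
        assert s_ba.af_mean == s_ab.af_mean
        assert s_ba == s_ab.swapped()

    def test_unweighted_vs_weighted_averaging(self, rng):
        # one long near-perfect gene + one short diverged gene: the weighting
        # mode must change ANI in the expected direction
        long_seq, short_seq = _random_seq(rng, 600), _random_seq(rng, 150)
        a = GeneSet("A", (Gene("a1", long_seq), Gene("a2", short_seq)))
        b = GeneSet(
            "B",
            (Gene("b1", _substitute(rng, long_seq, 6)), Gene("b2", _substitute(rng, short_seq, 30))),
        )
        weighted = compute_pairwise_score(a, b, MisiConfig(min_bbh=1))
        unweighted = compute_pairwise_score(
            a, b, MisiConfig(min_bbh=1, ani_weighting="unweighted")
        )
        assert weighted.ani_mean > unweighted.ani_mean

    def test_prescreen_equals_exhaustive(self, small_pair):
        ref, evolved = small_pair
        off = compute_pairwise_score(ref, evolved, MisiConfig(min_bbh=1))
        on = compute_pairwise_score(ref, evolved, MisiConfig(min_bbh=1, prescreen_k=12))
        assert on == off

    def test_matches_brute_force_oracle(self):
        """Full-stack equivalence with the pure-Python all-pairs DP oracle."""
        rng = np.random.default_rng(99)
        ref = make_reference_genome(4, (50, 110), 0.5, seed=15, genome_id="A")
        evolved = evolve_genome(
            ref,
            EvolveParams(per_site_substitution_prob=0.12, gene_retention_fraction=0.75,
                         n_novel_genes=1, seed=5),
            genome_id="B",
        )
        cfg = MisiConfig(min_bbh=1)
        s = compute_pairwise_score(ref, evolved, cfg)
        ani, af_12, af_21, n = oracle_pairwise(
            {g.gene_id: g.sequence for g in ref.genes},
            {g.gene_id: g.sequence for g in evolved.genes},
        )
        assert s.n_bbh == n
        assert s.af_12 == af_12
        assert s.af_21 == af_21
        if ani is None:
            assert s.ani_mean is None
        else:
            assert s.ani_mean == pytest.approx(ani, abs=1e-9)
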