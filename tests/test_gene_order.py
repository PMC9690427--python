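"""Signed circular gene orders: normalization, breakpoints, blocks, search."""

import pytest

import mitocharter as mc
from mitocharter.gene_order import (
    RearrangementOp, SignedGeneOrder, apply_op, breakpoint_count,
    explain_rearrangement, extract_order, normalize, same_order,
    shared_blocks,
)

EXPECTED_PCG13 = [
    ("cox1", 1), ("cox2", 1), ("atp8", 1), ("atp6", 1),
    ("nad5", -1), ("nad4", -1), ("nad4l", -1), ("cob", -1),
    ("nad6", -1), ("nad1", -1), ("cox3", 1), ("nad3", 1), ("nad2", 1),
]


@pytest.fixture(scope="module")
def template37(erumphii):
    return extract_order(erumphii, "all")


@pytest.fixture(scope="module")
def pcg13(erumphii):
    return extract_order(erumphii, "pcg")


class TestExtractOrder:
    def test_pcg13(self, pcg13):
        assert list(pcg13.genes) == EXPECTED_PCG13

    def test_single_gene(self):
        from mitocharter.model import GeneFeature, MitoAnnotation
        ann = MitoAnnotation(genome_length=2000, features=[
            GeneFeature("cox1", 1, 1500, "H")])
        assert len(extract_order(ann, "pcg")) == 1

    def test_simulated_matches_template(self, sim_genome, template37):
        assert same_order(extract_order(sim_genome.annotation, "all"),
                          template37)

    def test_empty_subset_rejected(self, erumphii):
        with pytest.raises(ValueError):
            extract_order(erumphii, [])


class TestNormalize:
    def test_idempotent(self, pcg13):
        once = normalize(pcg13)
        assert normalize(once).genes == once.genes

    def test_all_representatives_agree(self, pcg13):
        """All 2n linear representatives of the circular order reduce to
        one canonical form."""
        canon = normalize(pcg13).genes
        reps = [pcg13.rotate(k) for k in range(len(pcg13))]
        reps += [pcg13.reflect().rotate(k) for k in range(len(pcg13))]
        assert all(normalize(rep).genes == canon for rep in reps)

    def test_missing_anchor_names_alternatives(self, pcg13):
        with pytest.raises(ValueError, match="trnA"):
            normalize(pcg13.restrict({"cox1", "cox2"}), anchor="trnA")


class TestSameOrder:
    def test_rotation(self, pcg13):
        assert same_order(pcg13, pcg13.rotate(5))

    def test_reflection_with_sign_flip(self, pcg13):
        assert same_order(pcg13, pcg13.reflect())

    def test_single_sign_flip_differs(self, pcg13):
        genes = list(pcg13.genes)
        genes[3] = (genes[3][0], -genes[3][1])
        assert not same_order(pcg13, SignedGeneOrder(tuple(genes)))

    def test_disjoint_sets_rejected(self, pcg13):
        a = pcg13.restrict({"cox1", "cox2"})
        b = pcg13.restrict({"nad1", "nad2"})
        with pytest.raises(ValueError):
            same_order(a, b)


def _brute_breakpoints(o1, o2):
    """Independent adjacency-set oracle."""
    def adj(o):
        n = len(o.genes)
        return {(o.genes[i], o.genes[(i + 1) % n]) for i in range(n)}
    other = adj(o2)
    count = 0
    for (a, sa), (b, sb) in adj(o1):
        if ((a, sa), (b, sb)) in other or ((b, -sb), (a, -sa)) in other:
            continue
        count += 1
    return count


class TestBreakpoints:
    def test_identical_orders(self, pcg13):
        assert breakpoint_count(pcg13, pcg13.rotate(3)) == 0

    def test_reflected_self(self, pcg13):
        assert breakpoint_count(pcg13, pcg13.reflect()) == 0

    def test_small_reversal_against_oracle(self):
        o1 = SignedGeneOrder((("cox1", 1), ("cox2", 1), ("cox3", 1),
                              ("cob", 1), ("nad1", 1)))
        o2 = apply_op(o1, RearrangementOp("reversal", (1, 2)))
        assert breakpoint_count(o1, o2) == _brute_breakpoints(o1, o2)
        assert breakpoint_count(o1, o2) == 2

    def test_symmetry_and_zero_iff_same(self, template37, rng):
        for _ in range(20):
            perm = rng.permutation(len(template37))
            signs = rng.choice([1, -1], size=len(template37))
            o2 = SignedGeneOrder(tuple(
                (template37.genes[int(i)][0], int(s))
                for i, s in zip(perm, signs)))
            b12 = breakpoint_count(template37, o2)
            assert b12 == breakpoint_count(o2, template37)
            assert b12 == _brute_breakpoints(template37, o2)
            assert (b12 == 0) == same_order(template37, o2)


class TestSharedBlocks:
    def test_identical_is_one_block(self, pcg13):
        blocks = shared_blocks(pcg13, pcg13.rotate(4))
        assert len(blocks) == 1
        assert not blocks[0].reversed_in_other

    def test_planted_reversal_block_tagged(self, pcg13):
        op = RearrangementOp("reversal", (4, 7))
        moved = apply_op(pcg13, op)
        blocks = shared_blocks(pcg13, moved)
        assert 2 <= len(blocks) <= 3
        planted = {g for g, _ in pcg13.genes[4:8]}
        rev = [b for b in blocks if {g for g, _ in b.genes} == planted]
        assert len(rev) == 1 and rev[0].reversed_in_other

    def test_blocks_partition_common_genes(self, template37, rng):
        op = RearrangementOp("block-swap", (2, 6), (10, 14))
        moved = apply_op(template37, op)
        blocks = shared_blocks(template37, moved)
        seen = [g for b in blocks for g, _ in b.genes]
        assert sorted(seen) == sorted(g for g, _ in template37.genes)
        assert len(blocks) - 1 <= breakpoint_count(template37, moved)

    def test_published_rearrangement_blocks_recovered(self, template37):
        """The two gene blocks reported for the limpet-like rearrangement
        (one long block reversed and exchanged with its neighbor) come
        back as units."""
        block_a = ("cob", "nad6", "trnP", "nad1", "trnL2", "trnL1", "rrnL",
                   "trnV", "rrnS", "trnM", "trnY", "trnC", "trnW", "trnQ",
                   "trnG", "trnE")
        block_b = ("atp6", "trnF", "nad5", "trnH", "nad4", "nad4l",
                   "trnT", "trnS1")
        tokens = [g for g, _ in template37.genes]
        ia, ib = tokens.index(block_a[0]), tokens.index(block_b[0])
        rev = RearrangementOp("reversal", (ia, ia + len(block_a) - 1))
        swap = RearrangementOp("block-swap", (ib, ib + len(block_b) - 1),
                               (ia, ia + len(block_a) - 1))
        moved = apply_op(apply_op(template37, rev), swap)
        blocks = shared_blocks(template37, moved)
        sets = [tuple(g for g, _ in b.genes) for b in blocks]
        assert block_a in sets or tuple(reversed(block_a)) in sets
        assert block_b in sets or tuple(reversed(block_b)) in sets


class TestRearrangementOps:
    def test_one_gene_reversal_flips_sign_in_place(self, pcg13):
        moved = apply_op(pcg13, RearrangementOp("reversal", (2, 2)))
        assert moved.genes[2] == (pcg13.genes[2][0], -pcg13.genes[2][1])
        assert moved.genes[:2] == pcg13.genes[:2]
        assert moved.genes[3:] == pcg13.genes[3:]

    def test_overlapping_swap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RearrangementOp("block-swap", (0, 3), (2, 5))

    def test_swap_preserves_middle(self, pcg13):
        moved = apply_op(pcg13, RearrangementOp("block-swap", (0, 1), (5, 6)))
        assert moved.genes[2:5] == pcg13.genes[2:5]
        assert moved.genes[0:2] == pcg13.genes[5:7]
        assert moved.genes[5:7] == pcg13.genes[0:2]


class TestExplain:
    def test_identical_orders_empty_script(self, pcg13):
        assert explain_rearrangement(pcg13, pcg13.rotate(2), max_ops=1) == []

    def test_planted_reversal_recovered(self, erumphii, rng):
        o = extract_order(erumphii, "pcg+rrna")
        for _ in range(25):
            op = mc.random_reversal(o, rng)
            moved, truth = mc.apply_rearrangement(o, op)
            script = explain_rearrangement(o, moved, max_ops=1)
            assert script is not None and len(script) == 1
            state = apply_op(o, script[0])
            assert same_order(state, moved)

    def test_two_sign_flips_not_explainable_in_one_op(self, pcg13):
        flips = apply_op(apply_op(pcg13, RearrangementOp("reversal", (2, 2))),
                         RearrangementOp("reversal", (8, 8)))
        assert explain_rearrangement(pcg13, flips, max_ops=1) is None
        script = explain_rearrangement(pcg13, flips, max_ops=2)
        assert script is not None and len(script) == 2

    def test_script_bound_respected(self, pcg13):
        with pytest.raises(ValueError):
            explain_rearrangement(pcg13, pcg13, max_ops=5)
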