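"""Ranking and contrastive losses: hand values, invariances, gradients."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketrank._autodiff import Var
from pocketrank.objectives import (
    AssayBatchItem,
    ConfigError,
    ContractError,
    RankedAssayBatch,
    build_negative_mask,
    combined_loss,
    contrastive_loss,
    ranking_loss,
    regression_baseline_loss,
    step_selection_prob,
)


def make_item(
    assay_id="a",
    group="g",
    pocket=(0.0, 1.0),
    ligands=((1.0, 0.0),),
    potencies=(9.0,),
    active=None,
    n_total=None,
):
    m = len(ligands)
    return AssayBatchItem(
        assay_id=assay_id,
        target_group_id=group,
        pocket_emb=Var(np.array([pocket], dtype=float)) if pocket is not None else None,
        ligand_embs=Var(np.array(ligands, dtype=float)),
        potency=np.array(potencies, dtype=float),
        active=np.array(active if active is not None else [False] * m),
        ligand_ids=tuple(f"{assay_id}:l{i}" for i in range(m)),
        n_ligands_total=n_total,
    )


class TestStepSelection:
    def test_softmax_value(self):
        assert step_selection_prob([2, 1, 0], 0, 1.0) == pytest.approx(
            np.e**2 / (np.e**2 + np.e + 1.0)
        )

    @pytest.mark.parametrize("m", [2, 3, 7])
    def test_equal_scores_give_uniform(self, m):
        for chosen in range(m):
            assert step_selection_prob([1.3] * m, chosen, 0.5) == pytest.approx(1 / m)

    def test_single_candidate_is_certain(self):
        assert step_selection_prob([0.2], 0, 0.07) == 1.0

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ContractError):
            step_selection_prob([], 0, 1.0)


class TestRankingLoss:
    def test_single_ligand_assay_is_zero(self):
        b = RankedAssayBatch([make_item()], tau_rank=1.0)
        assert ranking_loss(b).value == pytest.approx(0.0)

    def test_two_ligand_equal_scores_is_half(self):
        item = make_item(
            ligands=((1.0, 0.0), (1.0, 0.0)), potencies=(9.0, 6.0)
        )
        b = RankedAssayBatch([item], tau_rank=1.0)
        assert ranking_loss(b).value == pytest.approx(0.5)

    def test_invariant_under_monotone_potency_transform(self, rng):
        pot = rng.normal(5.0, 2.0, size=6)
        ligs = rng.normal(size=(6, 4))
        base = make_item(pocket=(1.0, 0.0, 0.0, 0.0), ligands=ligs, potencies=pot)
        transformed = make_item(
            pocket=(1.0, 0.0, 0.0, 0.0), ligands=ligs, potencies=np.exp(pot)
        )
        l1 = ranking_loss(RankedAssayBatch([base], tau_rank=0.3)).value
        l2 = ranking_loss(RankedAssayBatch([transformed], tau_rank=0.3)).value
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_batch_order_equivariance(self, rng):
        items = [
            make_item(
                assay_id=f"a{i}", group=f"g{i}",
                pocket=rng.normal(size=3),
                ligands=rng.normal(size=(4, 3)),
                potencies=rng.normal(5, 1, size=4),
            )
            for i in range(3)
        ]
        l1 = ranking_loss(RankedAssayBatch(items)).value
        l2 = ranking_loss(RankedAssayBatch(items[::-1])).value
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_true_order_scores_beat_adjacent_swap(self):
        """Local optimality on 3-ligand instances over a score grid."""
        pot = np.array([9.0, 7.0, 5.0])
        grid = np.linspace(-1, 1, 5)
        pocket = np.array([[1.0, 0.0]])
        for s in itertools.product(grid, repeat=3):
            s = np.array(s)
            if not (s[0] > s[1] > s[2]):
                continue

            def loss_of(scores):
                # embed scores directly: ligand k = (score_k, sqrt(1-s^2))
                ligs = np.stack([scores, np.sqrt(1 - scores**2)], axis=1)
                item = make_item(pocket=pocket[0], ligands=ligs, potencies=pot)
                return ranking_loss(RankedAssayBatch([item], tau_rank=0.5)).value

            base = loss_of(s)
            for i in (0, 1):
                swapped = s.copy()
                swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
                assert base <= loss_of(swapped) + 1e-12

    def test_bad_temperature_rejected(self):
        with pytest.raises(ConfigError):
            RankedAssayBatch([make_item()], tau_rank=0.0)


class TestNegativeMask:
    def test_same_group_cross_pairs_masked(self):
        b = RankedAssayBatch(
            [make_item("a", "X"), make_item("b", "X", ligands=((0.5, 0.5),))]
        )
        m = build_negative_mask(b)
        assert not m.usable.any()

    def test_different_groups_usable(self):
        b = RankedAssayBatch([make_item("a", "X"), make_item("b", "Y")])
        m = build_negative_mask(b)
        assert m.usable[0, 1] and m.usable[1, 0]
        assert not m.usable[0, 0] and not m.usable[1, 1]

    def test_three_assays_block_structure(self):
        b = RankedAssayBatch(
            [make_item("a", "X"), make_item("b", "X"), make_item("c", "Y")]
        )
        m = build_negative_mask(b)
        expected = np.array(
            [
                [False, False, True],
                [False, False, True],
                [True, True, False],
            ]
        )
        assert np.array_equal(m.usable, expected)


class TestContrastiveLoss:
    def test_isolated_assay_is_zero(self):
        item = make_item(active=[True])
        b = RankedAssayBatch([item], tau_contrast=1.0)
        loss = contrastive_loss(b, build_negative_mask(b))
        assert loss.value == pytest.approx(0.0)

    def test_single_foreign_negative_gives_ln2(self):
        it1 = make_item("a", "gA", pocket=(1.0, 0.0), ligands=((0.0, 1.0),),
                        potencies=(9.0,), active=[True], n_total=1)
        it2 = make_item("b", "gB", pocket=None, ligands=((0.0, 1.0),),
                        potencies=(8.0,), n_total=1)
        b = RankedAssayBatch([it1, it2], tau_contrast=1.0)
        loss = contrastive_loss(b, build_negative_mask(b))
        assert loss.value == pytest.approx(np.log(2.0), abs=1e-12)

    def test_masked_foreign_negative_gives_zero(self):
        it1 = make_item("a", "gA", pocket=(1.0, 0.0), ligands=((0.0, 1.0),),
                        potencies=(9.0,), active=[True], n_total=1)
        it2 = make_item("b", "gA", pocket=None, ligands=((0.0, 1.0),),
                        potencies=(8.0,), n_total=1)
        b = RankedAssayBatch([it1, it2], tau_contrast=1.0)
        loss = contrastive_loss(b, build_negative_mask(b))
        assert loss.value == pytest.approx(0.0, abs=1e-12)

    def test_loss_decreases_when_positive_similarity_increases(self):
        def loss_at(eps):
            it1 = make_item("a", "gA", pocket=(1.0, 0.0),
                            ligands=((eps, np.sqrt(1 - eps**2)),),
                            potencies=(9.0,), active=[True], n_total=1)
            it2 = make_item("b", "gB", pocket=None, ligands=((0.0, 1.0),),
                            potencies=(8.0,), n_total=1)
            b = RankedAssayBatch([it1, it2], tau_contrast=1.0)
            return contrastive_loss(b, build_negative_mask(b)).value

        assert loss_at(0.2) < loss_at(0.0)


class TestCombinedLoss:
    def test_sum_of_components(self, rng):
        items = [
            make_item("a", "X", pocket=rng.normal(size=3),
                      ligands=rng.normal(size=(3, 3)),
                      potencies=[9.0, 7.0, 5.0], active=[True, False, False]),
            make_item("b", "Y", pocket=rng.normal(size=3),
                      ligands=rng.normal(size=(2, 3)),
                      potencies=[8.0, 6.0], active=[True, True]),
        ]
        b = RankedAssayBatch(items)
        m = build_negative_mask(b)
        total = combined_loss(b, m).value
        assert total == pytest.approx(
            contrastive_loss(b, m).value + ranking_loss(b).value, abs=1e-12
        )

    def test_gradient_is_sum_of_component_gradients(self):
        rng = np.random.default_rng(4)
        L = rng.normal(size=(3, 2))
        P = rng.normal(size=(1, 2))

        def build(Lv, Pv):
            item = AssayBatchItem(
                "a", "X", Pv, Lv,
                potency=np.array([9.0, 7.0, 5.0]),
                active=np.array([True, False, False]),
                ligand_ids=("l0", "l1", "l2"),
            )
            other = make_item("b", "Y", pocket=(0.3, -0.2), ligands=((0.7, 0.1),),
                              potencies=(8.0,), active=[True])
            b = RankedAssayBatch([item, other])
            return b, build_negative_mask(b)

        def grad_of(loss_fn):
            Lv, Pv = Var(L.copy()), Var(P.copy())
            b, m = build(Lv, Pv)
            loss_fn(b, m).backward()
            return Lv.grad.copy()

        g_total = grad_of(combined_loss)
        g_sum = grad_of(lambda b, m: contrastive_loss(b, m)) + grad_of(
            lambda b, m: ranking_loss(b)
        )
        assert np.allclose(g_total, g_sum, atol=1e-10)

        # numerical check of the combined gradient
        eps = 1e-6
        num = np.zeros_like(L)
        for i in range(L.shape[0]):
            for j in range(L.shape[1]):
                Lp, Lm = L.copy(), L.copy()
                Lp[i, j] += eps
                Lm[i, j] -= eps
                bp, mp = build(Var(Lp), Var(P.copy()))
                bm, mm = build(Var(Lm), Var(P.copy()))
                num[i, j] = (
                    combined_loss(bp, mp).value - combined_loss(bm, mm).value
                ) / (2 * eps)
        assert np.allclose(g_total, num, atol=1e-5)


class TestPlackettLuceConsistency:
    @settings(max_examples=15, derandomize=True)
    @given(m=st.integers(2, 6), seed=st.integers(0, 100))
    def test_stepwise_product_sums_to_one_over_permutations(self, m, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=m)
        tau = 0.7
        total = 0.0
        for perm in itertools.permutations(range(m)):
            p = 1.0
            remaining = list(range(m))
            for k in range(m):
                p *= step_selection_prob(
                    scores[remaining], remaining.index(perm[k]), tau
                )
                remaining.remove(perm[k])
            total += p
        assert total == pytest.approx(1.0, abs=1e-10)


class TestRegressionBaseline:
    def test_perfect_predictions_zero(self):
        assert regression_baseline_loss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).value == 0.0

    def test_constant_offset_squared(self):
        loss = regression_baseline_loss(
            np.array([1.0, 2.0]) + 0.3, [1.0, 2.0]
        )
        assert loss.value == pytest.approx(0.09)

    def test_rank_only_assay_rejected(self):
        with pytest.raises(ContractError):
            regression_baseline_loss([1.0], [50.0], rank_only=True)
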