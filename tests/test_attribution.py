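"""Integrated gradients: exactness, completeness, grouping, aggregation."""

import numpy as np
import pytest

from rxnlens.attribution import (
    AttributionQuery,
    StructureError,
    aggregate,
    group_tokens,
    integrated_gradients,
    probability_difference,
    uniform_attribution,
)
from rxnlens.autodiff import Tensor
from rxnlens.model import ReferenceModelConfig, train_reference_model
from rxnlens.reaction_io import tokenize_smiles


class LinearSurrogate:
    """A 'model' whose probability difference is linear in the embedding:
    dF(x) = sum(W * x).  Its integrated gradients have the closed form
    IG_i = sum_d W[i, d] (x[i, d] - x'[i, d]) for any step count."""

    def __init__(self, n, d, seed=0):
        rng = np.random.default_rng(seed)
        self.weights = rng.normal(size=(n, d))
        self.emb = rng.normal(size=(n, d))
        self.base = rng.normal(size=d)

    def embed(self, source):
        return self.emb.copy()

    def baseline_embedding(self, n, token="."):
        return np.tile(self.base, (n, 1))

    def seq_prob_tensor(self, emb: Tensor, target):
        # the major product carries the linear term; the minor contributes 0,
        # so the probability difference is exactly sum(W * emb)
        value = (emb * self.weights).sum()
        return value * 0.0 if "".join(target) == "CCN" else value


def _query(n_tokens, steps):
    src = tokenize_smiles("C" * n_tokens)
    return AttributionQuery(
        source=src, product_major="CCO", product_minor="CCN", steps=steps
    )


class TestIntegratedGradients:
    @pytest.mark.parametrize("steps", [1, 7, 50])
    def test_exact_on_linear_objective(self, steps):
        """Midpoint IG equals the closed form exactly for linear dF."""
        n, d = 5, 8
        model = LinearSurrogate(n, d)
        result = integrated_gradients(model, _query(n, steps))
        expected = ((model.emb - model.baseline_embedding(n)) * model.weights).sum(
            axis=1
        )
        np.testing.assert_allclose(result.token_attributions, expected, atol=1e-9)
        assert result.completeness_gap <= 1e-9

    def test_baseline_input_gets_zero_attribution(self):
        n, d = 4, 6
        model = LinearSurrogate(n, d)
        model.emb = model.baseline_embedding(n).copy()  # x == x'
        result = integrated_gradients(model, _query(n, 3))
        np.testing.assert_array_equal(result.token_attributions, np.zeros(n))

    def test_completeness_on_trained_model(self, trained_model, balanced_data):
        """Riemann-sum IG satisfies the completeness axiom within 1% of the
        probability-difference span at 500 steps, with a gap that does not
        grow as the discretization refines."""
        train, _ = balanced_data
        rxn = next(r for r in train if r.benzyl_id == "fluorobenzene")
        src = tokenize_smiles(
            ".".join(rxn.record.reactants)
        )
        para = rxn.record.products[0]
        from rxnlens.fc_data import generate_fc_reaction

        meta = generate_fc_reaction(
            rxn.record.reactants[0], rxn.record.reactants[1], "meta"
        ).record.products[0]
        gaps = {}
        for steps in (20, 100, 500):
            q = AttributionQuery(
                source=src, product_major=para, product_minor=meta, steps=steps
            )
            res = integrated_gradients(trained_model, q)
            gaps[steps] = res.completeness_gap
        span = abs(res.span)
        assert span > 0
        assert gaps[500] <= 1e-2 * span
        assert gaps[500] <= gaps[100] * (1 + 1e-9)
        assert gaps[100] <= gaps[20] * (1 + 1e-9)

    def test_sign_flips_when_products_swap(self, trained_model, balanced_data):
        """Positive attributions favour the major product: swapping the
        two candidates negates every attribution."""
        train, _ = balanced_data
        rxn = train[0]
        src = tokenize_smiles(".".join(rxn.record.reactants))
        from rxnlens.fc_data import generate_fc_reaction

        other = generate_fc_reaction(
            rxn.record.reactants[0],
            rxn.record.reactants[1],
            "meta" if rxn.orientation == "para" else "para",
        ).record.products[0]
        fwd = integrated_gradients(
            trained_model,
            AttributionQuery(src, rxn.record.products[0], other, steps=20),
        )
        rev = integrated_gradients(
            trained_model,
            AttributionQuery(src, other, rxn.record.products[0], steps=20),
        )
        np.testing.assert_allclose(
            fwd.token_attributions, -rev.token_attributions, rtol=1e-8, atol=1e-12
        )

    def test_identical_products_rejected(self):
        src = tokenize_smiles("CCO")
        with pytest.raises(ValueError):
            AttributionQuery(src, "CCO", "OCC", steps=5)


@pytest.fixture(scope="module")
def small_model():
    pairs = [
        (["C", "C", "O"], ["C", "C", "O"]),
        (["C", "O"], ["C", "O"]),
        (["O", "C", "C"], ["C", "C", "O"]),
    ]
    cfg = ReferenceModelConfig(
        d_model=16, n_layers=1, n_heads=2, d_ff=32, epochs=40, batch_size=4
    )
    return train_reference_model(pairs, cfg)


class TestProbabilityDifference:
    def test_bounded(self, small_model):
        delta = probability_difference(small_model, ["C", "C", "O"], "CCO", "CO")
        assert -1.0 <= delta <= 1.0

    def test_difference_of_sequence_probabilities(self, small_model):
        from rxnlens.model import sequence_probability

        src = ["C", "C", "O"]
        delta = probability_difference(small_model, src, "CCO", "CO")
        expected = sequence_probability(
            small_model, src, list("CCO")
        ) - sequence_probability(small_model, src, list("CO"))
        assert delta == pytest.approx(expected)

    def test_identical_products_rejected(self, small_model):
        with pytest.raises(ValueError):
            probability_difference(small_model, ["C"], "CCO", "OCC")


class TestGrouping:
    def tokens_of(self, grouping, tok):
        return [
            (label, [tok.tokens[i] for i in members])
            for label, members in grouping.groups
        ]

    def test_ring_branch_singletons(self):
        tok = tokenize_smiles("c1ccccc1C(=O)Cl")
        got = self.tokens_of(group_tokens(tok), tok)
        assert ("ring", ["c", "1", "c", "c", "c", "c", "c", "1"]) in got
        assert ("branch", ["(", "=", "O", ")"]) in got
        assert ("atom/other", ["C"]) in got
        assert ("atom/other", ["Cl"]) in got

    def test_reagent_is_single_unit_with_its_dot(self):
        tok = tokenize_smiles("CC=C.OO")
        got = self.tokens_of(group_tokens(tok, reagent_molecule_indices=(1,)), tok)
        assert ("reagent-molecule", [".", "O", "O"]) in got
        singles = [g for g in got if g[0] == "atom/other"]
        assert [t for _, ts in singles for t in ts] == ["C", "C", "=", "C"]

    def test_chain_is_all_singletons(self):
        tok = tokenize_smiles("CCCC")
        groups = group_tokens(tok).groups
        assert all(label == "atom/other" for label, _ in groups)
        assert len(groups) == 4

    def test_branch_off_ring_atom_is_not_a_branch_unit(self):
        tok = tokenize_smiles("c1ccc(F)cc1")
        got = self.tokens_of(group_tokens(tok), tok)
        labels = [label for label, _ in got]
        assert "branch" not in labels
        ring = next(ts for label, ts in got if label == "ring")
        assert ring.count("c") == 6

    def test_nested_branches_absorbed_into_outermost(self):
        tok = tokenize_smiles("CC(C(C)C)O")
        got = self.tokens_of(group_tokens(tok), tok)
        branch = next(ts for label, ts in got if label == "branch")
        assert branch == ["(", "C", "(", "C", ")", "C", ")"]

    def test_fused_rings_merge_into_one_system(self):
        tok = tokenize_smiles("c1ccc2ccccc2c1")
        got = group_tokens(tok)
        ring_groups = [g for g in got.groups if g[0] == "ring"]
        assert len(ring_groups) == 1
        assert len(ring_groups[0][1]) == len(tok)

    def test_partition_property(self):
        tok = tokenize_smiles("CC(C)c1ccccc1.CCC(=O)Cl")
        grouping = group_tokens(tok, reagent_molecule_indices=(1,))
        covered = sorted(i for _, m in grouping.groups for i in m)
        assert covered == list(range(len(tok)))

    def test_unmatched_parenthesis(self):
        tok = tokenize_smiles("CC(C")  # tokenizes fine, malformed structure
        with pytest.raises(StructureError):
            group_tokens(tok)


class TestAggregation:
    def test_single_group_sums(self):
        tok = tokenize_smiles("CCO")
        grouping = group_tokens(tok)
        from rxnlens.attribution import SubstructureGrouping

        one = SubstructureGrouping(groups=(("atom/other", (0, 1, 2)),), n_tokens=3)
        np.testing.assert_allclose(aggregate([0.1, 0.2, -0.05], one), [0.25])

    def test_singleton_grouping_is_identity(self):
        tok = tokenize_smiles("CCCC")
        grouping = group_tokens(tok)
        attr = [0.3, -0.1, 0.0, 0.5]
        np.testing.assert_allclose(aggregate(attr, grouping), attr)

    def test_conservation_on_random_attributions(self):
        tok = tokenize_smiles("CC(C)c1ccccc1.CCC(=O)Cl")
        grouping = group_tokens(tok, reagent_molecule_indices=(1,))
        rng = np.random.default_rng(3)
        for _ in range(20):
            attr = rng.normal(size=len(tok))
            assert aggregate(attr, grouping).sum() == pytest.approx(
                attr.sum(), abs=1e-9
            )

    def test_wrong_length_rejected(self):
        tok = tokenize_smiles("CCO")
        with pytest.raises(IndexError):
            aggregate([0.1], group_tokens(tok))


class TestUniformAttribution:
    def test_even_spread(self):
        tok = tokenize_smiles("CCCCCCCCCCCC")  # 12 tokens
        grouping = group_tokens(tok)
        per_token, per_group = uniform_attribution(0.12, 0.0, grouping)
        assert per_token == pytest.approx(0.01)
        np.testing.assert_allclose(per_group, np.full(12, 0.01))

    def test_group_share_scales_with_size(self):
        from rxnlens.attribution import SubstructureGrouping

        grouping = SubstructureGrouping(
            groups=(("ring", (0, 1, 2, 3, 4)), ("atom/other", (5,))), n_tokens=6
        )
        per_token, per_group = uniform_attribution(0.06, 0.0, grouping)
        assert per_group[0] == pytest.approx(5 * per_token)

    def test_zero_span(self):
        tok = tokenize_smiles("CCO")
        per_token, per_group = uniform_attribution(0.2, 0.2, group_tokens(tok))
        assert per_token == 0.0
        np.testing.assert_array_equal(per_group, np.zeros(3))
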