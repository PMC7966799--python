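"""The synthetic Friedel-Crafts benchmark generator."""

import json
from dataclasses import replace
from fractions import Fraction

import pytest
from rdkit import Chem

from rxnlens.fc_data import (
    META_BENZYLS,
    PARA_BENZYLS,
    PRESETS,
    TEST_META_BENZYLS,
    TEST_PARA_BENZYLS,
    BiasDatasetSpec,
    GenerationError,
    build_datasets,
    classify_orientation,
    counts,
    enumerate_r_groups,
    generate_fc_reaction,
    make_acyl_chlorides,
    write_datasets,
)
from rxnlens.reaction_io import canonicalize


class TestEnumerateRGroups:
    def test_single_saturated_chain(self):
        assert enumerate_r_groups((2, 2), 0) == ["CC"]

    def test_double_bond_positions_dedup(self):
        # lengths 2-3 with 0-1 C=C: {CC, CCC, C=C, C=CC}; CC=C and C=CC
        # canonicalize together
        got = enumerate_r_groups((2, 3), 1)
        assert sorted(got) == sorted(["CC", "CCC", "C=C", "C=CC"])

    def test_long_saturated_chains(self):
        assert enumerate_r_groups((9, 10), 0) == ["C" * 9, "C" * 10]

    def test_training_pool_size(self):
        # 7 saturated + 16 symmetry-distinct mono-enes for lengths 2-8
        assert len(enumerate_r_groups((2, 8), 1)) == 23


class TestAcylChlorides:
    def test_ethane_gives_propanoyl_chloride(self):
        got = make_acyl_chlorides(["CC"], placement="random")
        assert got == [canonicalize("CCC(Cl)=O")]

    def test_ethylene_skipped_no_sp3(self):
        with pytest.raises(GenerationError):
            make_acyl_chlorides(["C=C"])  # nothing left after the skip

    def test_mixed_pool_skips_only_sp3_free(self):
        got = make_acyl_chlorides(["C=C", "CC"], placement="exhaustive")
        assert got == [canonicalize("CCC(Cl)=O")]

    def test_seeded_determinism(self):
        rg = enumerate_r_groups((2, 8), 1)
        one = make_acyl_chlorides(rg, seed=9, placement="random")
        two = make_acyl_chlorides(rg, seed=9, placement="random")
        assert one == two

    def test_exhaustive_dedups_symmetric_placements(self):
        # butane: positions 1/2 are equivalent to 4/3
        assert len(make_acyl_chlorides(["CCCC"], placement="exhaustive")) == 2

    def test_exhaustive_training_pool_size(self):
        rg = enumerate_r_groups((2, 8), 1)
        assert len(make_acyl_chlorides(rg, placement="exhaustive")) == 75

    def test_every_acyl_has_one_acyl_chloride_group(self):
        query = Chem.MolFromSmarts("[CX3](=O)Cl")
        for smi in make_acyl_chlorides(enumerate_r_groups((2, 4), 1),
                                       placement="exhaustive"):
            mol = Chem.MolFromSmiles(smi)
            assert len(mol.GetSubstructMatches(query)) == 1


class TestGenerateReaction:
    def test_para_fluorobenzene(self):
        rxn = generate_fc_reaction("Fc1ccccc1", "CCC(Cl)=O", "para")
        assert rxn.record.products == [canonicalize("CCC(=O)c1ccc(F)cc1")]
        assert rxn.orientation == "para"

    def test_meta_nitrobenzene(self):
        rxn = generate_fc_reaction("O=[N+]([O-])c1ccccc1", "CCC(Cl)=O", "meta")
        assert rxn.record.products == [
            canonicalize("CCC(=O)c1cccc([N+](=O)[O-])c1")
        ]

    def test_acyl_without_chloride_rejected(self):
        with pytest.raises(GenerationError):
            generate_fc_reaction("Fc1ccccc1", "CCC(=O)O", "para")

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError):
            generate_fc_reaction("Fc1ccccc1", "CCC(Cl)=O", "ortho")

    @pytest.mark.parametrize("benzyl_name, smiles",
                             sorted({**PARA_BENZYLS, **META_BENZYLS}.items()))
    @pytest.mark.parametrize("orientation", ["para", "meta"])
    def test_template_roundtrips_on_all_benzyls(self, benzyl_name, smiles,
                                                orientation):
        """The SMARTS templates and the independent substructure-query
        classifier agree for every benzyl in both orientations."""
        rxn = generate_fc_reaction(smiles, "CCCC(Cl)=O", orientation)
        assert classify_orientation(rxn.record.products[0], smiles) == orientation


class TestClassifyOrientation:
    def test_para(self):
        assert classify_orientation("CCC(=O)c1ccc(F)cc1", "Fc1ccccc1") == "para"

    def test_meta(self):
        assert classify_orientation("CCC(=O)c1cccc(F)c1", "Fc1ccccc1") == "meta"

    def test_ortho(self):
        assert classify_orientation("CCC(=O)c1ccccc1F", "Fc1ccccc1") == "ortho"

    def test_invalid_string(self):
        assert classify_orientation("not-a-smiles", "Fc1ccccc1") == "invalid"

    def test_empty_string(self):
        assert classify_orientation("", "Fc1ccccc1") == "invalid"

    def test_unrelated_molecule_is_other(self):
        assert classify_orientation("CCCCCC", "Fc1ccccc1") == "other"

    def test_ring_without_acyl_is_other(self):
        assert classify_orientation("Fc1ccccc1", "Fc1ccccc1") == "other"


@pytest.fixture(scope="module")
def all_corpora():
    return {name: build_datasets(spec) for name, spec in PRESETS.items()}


class TestBuildDatasets:
    def test_balanced_exact_equality(self, all_corpora):
        train, _ = all_corpora["balanced"]
        c = counts(train)
        assert c["para"] == c["meta"] > 0

    def test_biased_exact_nine_to_one(self, all_corpora):
        train, _ = all_corpora["biased"]
        c = counts(train)
        assert c["para"] == 9 * c["meta"]

    def test_severe_exact_hundred_to_one(self, all_corpora):
        train, _ = all_corpora["severe"]
        c = counts(train)
        assert c["para"] == 100 * c["meta"]

    def test_test_set_balanced_and_named_benzyls(self, all_corpora):
        _, test = all_corpora["balanced"]
        c = counts(test)
        assert c["para"] == c["meta"]
        benzyls = {r.benzyl_id for r in test}
        assert benzyls == set(TEST_PARA_BENZYLS) | set(TEST_META_BENZYLS)

    def test_train_test_acyl_chlorides_disjoint(self, all_corpora):
        for train, test in all_corpora.values():
            train_acyls = {r.record.reactants[1] for r in train}
            test_acyls = {r.record.reactants[1] for r in test}
            assert not (train_acyls & test_acyls)

    def test_orientation_self_consistency(self, all_corpora):
        benzyls = {**PARA_BENZYLS, **META_BENZYLS}
        train, test = all_corpora["balanced"]
        for r in train[::17] + test:
            assert (
                classify_orientation(r.record.products[0], benzyls[r.benzyl_id])
                == r.orientation
            )

    def test_every_reaction_parses(self, all_corpora):
        train, test = all_corpora["severe"]
        for r in train[::25] + test:
            for smi in r.record.reactants + r.record.products:
                assert Chem.MolFromSmiles(smi) is not None

    def test_unattainable_ratio_reports(self):
        spec = replace(
            PRESETS["severe"], r_group_lengths=(2, 2),
            acyl_split_ratio=Fraction(100, 1),
        )
        with pytest.raises(GenerationError):
            build_datasets(spec)

    def test_seeded_reproducibility_byte_identical(self, tmp_path):
        spec = replace(PRESETS["biased"], seed=7)
        m1 = write_datasets(spec, tmp_path / "a")
        m2 = write_datasets(spec, tmp_path / "b")
        assert m1["train_counts"] == m2["train_counts"]
        for name in ("train.txt", "test.txt", "train.src", "train.tgt"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_manifest_counts_match_files(self, tmp_path):
        manifest = write_datasets(PRESETS["balanced"], tmp_path / "d")
        lines = (tmp_path / "d" / "train.txt").read_text().splitlines()
        assert len(lines) == sum(manifest["train_counts"].values())
        labels = json.loads((tmp_path / "d" / "train.labels.json").read_text())
        assert len(labels) == len(lines)


def test_spec_validation():
    with pytest.raises(ValueError):
        BiasDatasetSpec(name="x", para_benzyls=())
    with pytest.raises(ValueError):
        BiasDatasetSpec(name="x", r_group_lengths=(1, 4))
    with pytest.raises(ValueError):
        BiasDatasetSpec(name="x", placement="everywhere")
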