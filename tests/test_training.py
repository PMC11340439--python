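"""Loss, conformer expansion, CV folds, splits and the training loop."""

import numpy as np
import pytest

from geqshift import autodiff as ad
from geqshift import (ModelConfig, ShiftDataset, TrainConfig,
                      expand_with_conformers, mae_loss, make_cv_folds,
                      make_exclusion_split, parse_smiles, train)
from geqshift.synthetic import (SyntheticOracleConfig, make_synthetic_dataset,
                                make_toy_molecules)

from conftest import TINY_CONFIG


class TestMaeLoss:
    def test_perfect_prediction_is_zero(self):
        assert mae_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                        np.array([True, True])) == 0.0

    def test_hand_computed_values(self):
        pred = np.array([1.0, 2.0])
        target = np.array([2.0, 4.0])
        assert mae_loss(pred, target, np.array([True, True])) == 1.5
        assert mae_loss(pred, target, np.array([True, False])) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no supervised"):
            mae_loss(np.zeros(2), np.zeros(2), np.array([False, False]))

    def test_tensor_variant_matches_and_differentiates(self):
        pred = ad.parameter(np.array([1.0, 2.0, 5.0]))
        target = np.array([2.0, 4.0, 100.0])
        mask = np.array([True, True, False])
        loss = mae_loss(pred, target, mask)
        assert float(loss.data) == 1.5
        loss.backward()
        np.testing.assert_allclose(pred.grad, [-0.5, -0.5, 0.0])


@pytest.fixture(scope="module")
def small_dataset():
    return make_synthetic_dataset(12, 2, SyntheticOracleConfig(seed=5))


class TestExpansion:
    def test_one_sample_per_molecule_conformer_pair(self, small_dataset):
        ds, ens = small_dataset
        samples = expand_with_conformers(ds, ens)
        assert len(samples) == sum(len(e) for e in ens.values())

    def test_targets_identical_across_conformers(self, small_dataset):
        ds, ens = small_dataset
        samples = expand_with_conformers(ds, ens)
        by_mol = {}
        for s in samples:
            by_mol.setdefault(s.molecule_id, []).append(s)
        for group in by_mol.values():
            for s in group[1:]:
                np.testing.assert_array_equal(s.target_c13,
                                              group[0].target_c13)
                np.testing.assert_array_equal(s.mask_h1, group[0].mask_h1)

    def test_missing_ensemble_errors(self, small_dataset):
        ds, ens = small_dataset
        partial = dict(ens)
        partial.pop(ds.molecule_ids[0])
        with pytest.raises(ValueError, match="no conformer ensemble"):
            expand_with_conformers(ds, partial)


def _dataset_with_classes(counts: dict[str, int]) -> ShiftDataset:
    base = {"mono": "OCC(O)CO", "di": "OC[C@H](O)[C@@H](O)[C@H](O)CO",
            "tri": "CO[C@H]1O[C@H](COC(C)=O)[C@H](O)[C@H](O)[C@H]1O"}
    mols = []
    k = 0
    for klass, n in counts.items():
        for _ in range(n):
            mols.append(parse_smiles(base[klass], molecule_id=f"m{k:04d}",
                                     saccharide_class=klass))
            k += 1
    return ShiftDataset(mols, [], provenance="classes fixture")


class TestCvFolds:
    def test_balanced_small_case_counting_oracle(self):
        ds = _dataset_with_classes({"mono": 10, "di": 10, "tri": 10})
        plan = make_cv_folds(ds, k=10, seed=0)
        for fold in range(10):
            classes = [plan.strata[m] for m in plan.fold_ids(fold)]
            assert sorted(classes) == ["di", "mono", "tri"]

    def test_folds_partition_dataset(self):
        ds = _dataset_with_classes({"mono": 13, "di": 17, "tri": 12})
        plan = make_cv_folds(ds, k=5, seed=3)
        all_ids = [m for f in range(5) for m in plan.fold_ids(f)]
        assert sorted(all_ids) == sorted(ds.molecule_ids)

    def test_deterministic_under_seed(self):
        ds = _dataset_with_classes({"mono": 12, "di": 12, "tri": 12})
        p1 = make_cv_folds(ds, k=4, seed=9)
        p2 = make_cv_folds(ds, k=4, seed=9)
        assert p1.assignments == p2.assignments
        p3 = make_cv_folds(ds, k=4, seed=10)
        assert p3.assignments != p1.assignments

    def test_k_one_rejected(self):
        ds = _dataset_with_classes({"mono": 5})
        with pytest.raises(ValueError, match="k must be >= 2"):
            make_cv_folds(ds, k=1)

    def test_class_smaller_than_k_rejected(self):
        ds = _dataset_with_classes({"mono": 10, "di": 3})
        with pytest.raises(ValueError, match="smaller than k"):
            make_cv_folds(ds, k=5)


class TestExclusionSplit:
    def test_counting_oracle_13_7(self):
        ds = _dataset_with_classes({"mono": 20})
        flagged = set(ds.molecule_ids[:7])
        train_ds, test_ds = make_exclusion_split(
            ds, lambda m: m.molecule_id in flagged)
        assert len(train_ds.molecules) == 13
        assert len(test_ds.molecules) == 7

    def test_substring_predicate_matches_hand_labels(self):
        mols = [parse_smiles(s, molecule_id=f"m{i}") for i, s in enumerate([
            "CC(=O)OCC(O)CO", "OCC(O)CO", "CC(=O)OC[C@H](C)O", "OCCO"])]
        ds = ShiftDataset(mols, [])
        train_ds, test_ds = make_exclusion_split(
            ds, lambda m: "CC(=O)O" in m.smiles)
        assert {m.molecule_id for m in test_ds.molecules} == {"m0", "m2"}

    def test_trivial_predicates_rejected(self):
        ds = _dataset_with_classes({"mono": 4})
        with pytest.raises(ValueError):
            make_exclusion_split(ds, lambda m: False)
        with pytest.raises(ValueError):
            make_exclusion_split(ds, lambda m: True)


@pytest.fixture(scope="module")
def samples():
    ds, ens = make_synthetic_dataset(10, 2, SyntheticOracleConfig(seed=2))
    return expand_with_conformers(ds, ens)


class TestTrainLoop:

    def test_loss_decreases_over_training(self, samples):
        res = train(ModelConfig(**TINY_CONFIG),
                    TrainConfig(lr=3e-3, batch_size=8, epochs=6, seed=0),
                    samples)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_ensemble_mode_lr_schedule(self, samples):
        res = train(ModelConfig(**TINY_CONFIG),
                    TrainConfig(lr=3e-4, batch_size=8, mode="ensemble",
                                epochs=3, seed=0),
                    samples)
        assert len(res.loss_trace) == 3
        np.testing.assert_allclose(res.lr_trace, [3e-4, 3e-5, 3e-6],
                                   rtol=1e-12)
        assert res.val_trace == []  # no validation split in ensemble mode

    def test_same_seed_identical_traces(self, samples):
        cfg = TrainConfig(lr=1e-3, batch_size=8, epochs=3, seed=7)
        r1 = train(ModelConfig(**TINY_CONFIG), cfg, samples)
        r2 = train(ModelConfig(**TINY_CONFIG), cfg, samples)
        assert r1.loss_trace == r2.loss_trace
        for a, b in zip(r1.net.state_arrays(), r2.net.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_validation_split_is_molecule_level(self, samples):
        # with 2 conformers per molecule, every molecule's conformers must
        # land on one side of the split only
        from geqshift.training import GeqShiftNet  # noqa: F401
        res = train(ModelConfig(**TINY_CONFIG),
                    TrainConfig(lr=1e-3, batch_size=8, epochs=2,
                                val_fraction=0.2, seed=1),
                    samples)
        assert len(res.val_trace) == 2

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="no training samples"):
            train(ModelConfig(**TINY_CONFIG), TrainConfig(), [])

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=-1).validate()
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=0.9).validate()
        with pytest.raises(ValueError):
            TrainConfig(mode="bogus").validate()


class TestToyMolecules:
    def test_deterministic(self):
        a = make_toy_molecules(3, seed=4)
        b = make_toy_molecules(3, seed=4)
        assert [m.smiles for m in a] == [m.smiles for m in b]

    def test_all_parse_and_have_stereocenters_somewhere(self):
        mols = make_toy_molecules(30, seed=0)
        for m in mols:
            assert m.n_atoms >= 5
        assert any("@" in m.smiles for m in mols)

    def test_class_proportions_approximate_catalogue(self):
        mols = make_toy_molecules(300, seed=1)
        counts = {}
        for m in mols:
            counts[m.saccharide_class] = counts.get(m.saccharide_class, 0) + 1
        for klass, p in (("mono", 107 / 375), ("di", 153 / 375),
                         ("tri", 115 / 375)):
            assert abs(counts[klass] / 300 - p) < 0.05
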