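"""Self-contained verification experiments.

These are the package's standard self-checks: symmetry audits of the
network, the conformer-pipeline contract, the ensemble-averaging
inequality, and a scaled-down oracle-recovery study on synthetic data.
They are used by the test suite and by ``scripts/acceptance.py``; each
function is deterministic given its seed and returns plain numbers.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import ShiftDataset, parse_smiles
from .conformers import (Conformer, check_ensemble, generate_ensemble,
                         rmsd_heavy)
from .estimator import GeqShiftRegressor
from .featurize import build_graph
from .inference import ensemble_mae_inequality, predict_ensemble
from .model import GeqShiftNet, ModelConfig
from .synthetic import (SyntheticOracleConfig, make_synthetic_dataset,
                        make_toy_molecules)
from .training import expand_with_conformers, make_cv_folds

# the scaled-down model used throughout the recovery study: two attention
# layers, reduced irreps
SMALL_MODEL = dict(n_layers=2, node_emb_dim=32, edge_emb_dim=8,
                   hidden="16x0e+8x1o+4x2e", readout_scalars=32,
                   readout_hidden=64, weight_hidden=32)
SMALL_TRAIN = dict(mode="single_conformer", epochs=40, batch_size=32,
                   lr=3e-3, plateau_patience=8)

MONOSACCHARIDE_SMILES = "CO[C@H]1O[C@H](CO)[C@H](O)[C@H](O)[C@H]1O"


def random_transforms(n: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random E(3) elements: (orthogonal matrix, translation); every other
    one is improper (a reflection composed with the rotation)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        if k % 2 == 1:
            R = R @ np.diag([-1.0, 1.0, 1.0])
        t = rng.normal(scale=5.0, size=3)
        out.append((R, t))
    return out


def _forward_normalized(net_or_est, sample):
    if isinstance(net_or_est, GeqShiftNet):
        c, h = net_or_est.forward(sample)
        return c.data, h.data
    c, h = net_or_est.net_.forward(sample)
    return c.data, h.data


def invariance_suite(models, n_molecules: int = 20, n_transforms: int = 10,
                     seed: int = 0) -> float:
    """Max absolute change of predictions (normalized units) under random
    rotations, translations and reflections, over fixture molecules."""
    mols = make_toy_molecules(n_molecules, seed=seed)
    rng = np.random.default_rng(seed + 1)
    worst = 0.0
    for mol in mols:
        coords = rng.normal(scale=2.0, size=(mol.n_atoms, 3))
        base = build_graph(mol, Conformer(mol.molecule_id, coords, 0.0))
        refs = [_forward_normalized(m, base) for m in models]
        for R, t in random_transforms(n_transforms, seed=seed + hash(mol.molecule_id) % 1000):
            moved = build_graph(mol, Conformer(mol.molecule_id,
                                               coords @ R.T + t, 0.0))
            for m, (c0, h0) in zip(models, refs):
                c1, h1 = _forward_normalized(m, moved)
                worst = max(worst, float(np.abs(c1 - c0).max()),
                            float(np.abs(h1 - h0).max()))
    return worst


def layer_equivariance(net: GeqShiftNet, n_molecules: int = 5,
                       n_rotations: int = 3, seed: int = 0) -> float:
    """Max relative deviation between hidden features of rotated inputs and
    the Wigner-rotated hidden features, over every layer."""
    mols = make_toy_molecules(n_molecules, seed=seed)
    rng = np.random.default_rng(seed + 2)
    D_cache = {}
    worst = 0.0
    hidden = net.config.hidden_irreps()
    for mol in mols:
        coords = rng.normal(scale=2.0, size=(mol.n_atoms, 3))
        base = build_graph(mol, Conformer(mol.molecule_id, coords, 0.0))
        feats0 = net.hidden_features(base)
        for _ in range(n_rotations):
            R = Rotation.random(
                random_state=int(rng.integers(2 ** 31))).as_matrix()
            key = R.tobytes()
            if key not in D_cache:
                D_cache[key] = hidden.rep(R)
            D = D_cache[key]
            rot = build_graph(mol, Conformer(mol.molecule_id,
                                             coords @ R.T, 0.0))
            feats1 = net.hidden_features(rot)
            for f0, f1 in zip(feats0, feats1):
                expected = f0.data @ D.T
                scale = max(float(np.abs(expected).max()), 1e-12)
                worst = max(worst,
                            float(np.abs(f1.data - expected).max()) / scale)
    return worst


def conformer_pipeline_check(smiles: str = MONOSACCHARIDE_SMILES,
                             n_generate: int = 200, n_keep: int = 100,
                             rmsd_min: float = 0.01,
                             seed: int = 0) -> dict[str, float]:
    """Run the default generate -> filter -> rank pipeline and verify its
    invariants post hoc."""
    mol = parse_smiles(smiles, molecule_id="monosaccharide",
                       saccharide_class="mono")
    ens = generate_ensemble(mol, n_generate=n_generate, n_keep=n_keep,
                            rmsd_min=rmsd_min, seed=seed)
    check_ensemble(ens)  # raises if the pairwise-RMSD invariant fails
    confs = ens.conformers
    min_rmsd = min(rmsd_heavy(confs[i], confs[j], align=True)
                   for i in range(len(confs))
                   for j in range(i + 1, len(confs)))
    energies = ens.energies()
    return dict(retained=len(ens),
                min_pairwise_rmsd=float(min_rmsd),
                energies_sorted=float(np.all(np.diff(energies) >= 0)))


def recovery_experiment(seed: int = 0, n_mol: int = 50, n_conf: int = 5,
                        n_test: int = 10,
                        train_overrides: dict | None = None) -> dict:
    """Scaled-down oracle-recovery study.

    Trains the reduced model on synthetic molecules with conformer-expanded
    samples, then evaluates ensemble-mean predictions on held-out molecules.
    Returns per-nucleus held-out MAE normalized by the population std of the
    oracle targets, plus the ensemble-averaging inequality terms.
    """
    cfg = SyntheticOracleConfig(seed=seed + 11)
    ds, ens = make_synthetic_dataset(n_mol, n_conf, cfg)
    rng = np.random.default_rng(seed + 5)
    test_ids = set(rng.choice(ds.molecule_ids, size=n_test, replace=False))
    train_ds = ShiftDataset(
        [m for m in ds.molecules if m.molecule_id not in test_ids],
        [s for s in ds.shifts if s.molecule_id not in test_ids])
    samples = expand_with_conformers(train_ds, ens)
    tr = dict(SMALL_TRAIN)
    tr.update(train_overrides or {})
    est = GeqShiftRegressor(**SMALL_MODEL, **tr, seed=seed)
    est.fit(samples)

    stds = {nuc: float(np.array([s.shift_ppm for s in ds.shifts
                                 if s.nucleus == nuc]).std())
            for nuc in ("C13", "H1")}
    errs = {"C13": [], "H1": []}
    test_ds = ShiftDataset(
        [m for m in ds.molecules if m.molecule_id in test_ids],
        [s for s in ds.shifts if s.molecule_id in test_ids])
    all_preds = []
    for mid in sorted(test_ids):
        preds = predict_ensemble(est, ds.molecule(mid), ens[mid])
        all_preds.extend(preds)
        by_key = {(p.atom_index, p.nucleus): p for p in preds}
        for s in ds.shifts_for(mid):
            errs[s.nucleus].append(
                abs(by_key[(s.atom_index, s.nucleus)].mean_ppm - s.shift_ppm))
    lhs, rhs = ensemble_mae_inequality(all_preds, test_ds)
    return dict(
        estimator=est, dataset=ds, ensembles=ens, test_ids=test_ids,
        mae_c13_ppm=float(np.mean(errs["C13"])),
        mae_h1_ppm=float(np.mean(errs["H1"])),
        std_c13_ppm=stds["C13"], std_h1_ppm=stds["H1"],
        norm_mae_c13=float(np.mean(errs["C13"])) / stds["C13"],
        norm_mae_h1=float(np.mean(errs["H1"])) / stds["H1"],
        ensemble_mean_mae=lhs, mean_per_conformer_mae=rhs)


ABLATION_ORACLE = dict(pair_weight=4.0, angle_weight=15.0, noise_sd=0.05)

# the ablation comparison needs enough directional capacity to show the
# equivariant advantage: three layers, wider l>0 multiplicities
ABLATION_MODEL = dict(n_layers=3, node_emb_dim=64, edge_emb_dim=16,
                      hidden="32x0e+16x1o+8x2e", readout_scalars=64,
                      readout_hidden=128, weight_hidden=48)
ABLATION_TRAIN = dict(mode="single_conformer", epochs=40, batch_size=32,
                      lr=2e-3, plateau_patience=10)


def _angular_tri_dataset(cfg: SyntheticOracleConfig, n_mol: int):
    """Trisaccharide-class molecules with single-conformer angular targets.

    The larger, more flexible structures carry the richest three-body
    geometry, which is what separates the equivariant model from its
    distance-only ablation."""
    from .chem_io import ShiftRecord
    from .synthetic import CATALOGUE, oracle_shift

    pool = CATALOGUE["tri"]
    mols = [parse_smiles(pool[i % len(pool)], molecule_id=f"tri-{i:03d}",
                         saccharide_class="tri") for i in range(n_mol)]
    ensembles, shifts = {}, []
    for k, mol in enumerate(mols):
        ens = generate_ensemble(mol, n_generate=2, n_keep=1,
                                seed=cfg.seed * 100003 + k)
        ensembles[mol.molecule_id] = ens
        for idx, el, hc in mol.atoms:
            for nuc, ok in (("C13", el == "C"), ("H1", hc >= 1)):
                if ok:
                    vals = [oracle_shift(mol, c, idx, cfg, nuc)
                            for c in ens.conformers]
                    shifts.append(ShiftRecord(mol.molecule_id, idx, nuc,
                                              float(np.mean(vals))))
    return ShiftDataset(mols, shifts), ensembles


def ablation_experiment(seeds=(0, 1, 2), n_mol: int = 48,
                        n_test: int = 10, epochs: int = 40,
                        data_seed: int = 21) -> dict:
    """Equivariant model vs its invariant ablation on the angular oracle.

    The ablation follows the original mechanism: the same architecture with
    the maximum order of the hidden irreps set to zero (scalars only, edge
    harmonics truncated to l=0), so geometry enters only through pairwise
    distances.  The oracle variant emphasizes the three-body term
    (``ABLATION_ORACLE``) on trisaccharide-class molecules with one
    conformer each, making the task purely geometric.  Returns per-seed
    held-out C13 MAEs and the win count.
    """
    cfg = SyntheticOracleConfig(seed=data_seed, **ABLATION_ORACLE)
    ds, ens = _angular_tri_dataset(cfg, n_mol)
    rng = np.random.default_rng(9)
    test_ids = set(rng.choice(ds.molecule_ids, size=n_test, replace=False))
    train_ds = ShiftDataset(
        [m for m in ds.molecules if m.molecule_id not in test_ids],
        [s for s in ds.shifts if s.molecule_id not in test_ids])
    samples = expand_with_conformers(train_ds, ens)

    def fit_and_eval(hidden, l_max_sh, seed):
        model = dict(ABLATION_MODEL)
        model.update(hidden=hidden, l_max_sh=l_max_sh)
        tr = dict(ABLATION_TRAIN)
        tr.update(epochs=epochs)
        est = GeqShiftRegressor(**model, **tr, seed=seed)
        est.fit(samples)
        errs = []
        for mid in sorted(test_ids):
            preds = predict_ensemble(est, ds.molecule(mid), ens[mid])
            by_key = {(p.atom_index, p.nucleus): p for p in preds}
            for s in ds.shifts_for(mid):
                if s.nucleus == "C13":
                    errs.append(abs(by_key[(s.atom_index, "C13")].mean_ppm
                                    - s.shift_ppm))
        return float(np.mean(errs))

    scalar_hidden = ABLATION_MODEL["hidden"].split("+")[0]  # drop l>0 blocks
    results = []
    for seed in seeds:
        full = fit_and_eval(ABLATION_MODEL["hidden"], 2, seed)
        inv = fit_and_eval(scalar_hidden, 0, seed)
        results.append(dict(seed=seed, full_mae=full, inv_mae=inv,
                            win=full < inv))
    return dict(per_seed=results,
                wins=int(sum(r["win"] for r in results)),
                n_seeds=len(results))


def dataset_shape_check(tmp_dir, n_mono: int = 107, n_di: int = 153,
                        n_tri: int = 115) -> dict:
    """Loader check on a synthetic file with a realistic dataset shape.

    Writes a CSV with the reference class composition of a curated
    mono-to-trisaccharide collection (375 molecules for the defaults) through the package's own writer, reloads it and reports the
    counts the loader sees.
    """
    from pathlib import Path

    from .chem_io import load_shift_dataset, write_shift_dataset
    from .synthetic import CATALOGUE

    mols = []
    k = 0
    for klass, n in (("mono", n_mono), ("di", n_di), ("tri", n_tri)):
        pool = CATALOGUE[klass]
        for i in range(n):
            mols.append(parse_smiles(pool[i % len(pool)],
                                     molecule_id=f"mol-{k:04d}",
                                     saccharide_class=klass))
            k += 1
    ds = ShiftDataset(mols, [], provenance="synthetic dataset-shape check")
    path = Path(tmp_dir) / "dataset_shape.csv"
    write_shift_dataset(ds, path)
    back = load_shift_dataset(path)
    counts = back.class_counts()
    return dict(molecules=len(back.molecules),
                mono=counts.get("mono", 0), di=counts.get("di", 0),
                tri=counts.get("tri", 0))


def cv_mechanics_check(seed: int = 0) -> dict:
    """Stratified 10-fold plan on a 375-molecule dataset (107/153/115)."""
    from .synthetic import CATALOGUE
    mols = []
    k = 0
    for klass, n in (("mono", 107), ("di", 153), ("tri", 115)):
        pool = CATALOGUE[klass]
        for i in range(n):
            mols.append(parse_smiles(pool[i % len(pool)],
                                     molecule_id=f"mol-{k:04d}",
                                     saccharide_class=klass))
            k += 1
    ds = ShiftDataset(mols, [])
    plan = make_cv_folds(ds, k=10, seed=seed)
    sizes = [len(plan.fold_ids(f)) for f in range(10)]
    all_ids = [m for f in range(10) for m in plan.fold_ids(f)]
    balanced = True
    global_counts = {"mono": 107, "di": 153, "tri": 115}
    for f in range(10):
        counts = {}
        for m in plan.fold_ids(f):
            counts[plan.strata[m]] = counts.get(plan.strata[m], 0) + 1
        for klass, tot in global_counts.items():
            lo, hi = np.floor(tot / 10), np.ceil(tot / 10)
            if not lo <= counts.get(klass, 0) <= hi:
                balanced = False
    return dict(fold_size_min=min(sizes), fold_size_max=max(sizes),
                disjoint_exhaustive=float(sorted(all_ids)
                                          == sorted(ds.molecule_ids)),
                class_balanced=float(balanced))
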