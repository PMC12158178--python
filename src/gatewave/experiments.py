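"""Reusable experiment drivers built on the estimator.

These functions run the reconstruction studies end to end on synthetic
data: planted-dependency recovery, the curriculum-ordering comparison on
hemispherically symmetric data, and the missing-channel (DV count) sweep.
They exist so that tests, the command line and reproduction scripts share
one implementation. All sizes are parameters; the defaults are the reduced
desk-scale study conditions described in the methods note.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ReconReport, sign_test
from .io import SegmentSet, split_dataset
from .model import WGLAE
from .montage import ElectrodeMontage, build_montage
from .synthetic import SyntheticSpec, planted_dependency_set, simulate

__all__ = [
    "single_channel_sweep_rmse",
    "curriculum_sweep_rmse",
    "planted_recovery",
    "ordering_comparison",
    "dv_sweep",
]


def _fit(segments: SegmentSet, montage, mechanism, n_dv, epochs, lr, seed,
         batch_size=1024, gate_seed=None, lesson_update="aggregate") -> WGLAE:
    model = WGLAE(
        montage=montage,
        mechanism=mechanism,
        n_dv=n_dv,
        learning_rate=lr,
        epochs=epochs,
        batch_size=batch_size,
        lesson_update=lesson_update,
        gate_seed=gate_seed,
        data_seed=seed,
        random_state=seed,
    )
    return model.fit(segments)


def single_channel_sweep_rmse(model: WGLAE, test: SegmentSet) -> ReconReport:
    """Evaluate a fitted model on the full single-channel deletion sweep.

    Every channel is blocked once (alone); each blocked channel's RMSE is
    measured on its own deletion, and the overall figure is the mean across
    channels. This is a mechanism-independent evaluation task, so two models
    trained under different curricula are compared on identical footing.
    """
    x = model.normalize_input(test)
    per: dict[str, float] = {}
    for i, lab in enumerate(model.labels_):
        recon = model.reconstruct(test, missing=[lab])
        per[lab] = float(np.sqrt(((recon[:, i, :] - x[:, i, :]) ** 2).mean()))
    overall = float(np.mean(list(per.values())))
    return ReconReport(per_channel_rmse=per, overall_rmse=overall,
                       n_dv=1, dv_labels=tuple(model.labels_),
                       mechanism=model.mechanism or "")


def curriculum_sweep_rmse(model: WGLAE, test: SegmentSet) -> ReconReport:
    """Evaluate a fitted model over its own curriculum's lesson masks.

    Each lesson's DV block is removed in turn; blocked-channel RMSE is
    averaged over all lessons (the mechanism-matched protocol: each model
    is tested on exactly the missing-channel patterns its curriculum used).
    """
    x = model.normalize_input(test)
    per: dict[str, float] = {}
    for mask in model.masks_:
        recon = model.reconstruct(test, mask=mask)
        for lab in mask.dv_labels:
            i = model.labels_.index(lab)
            per[lab] = float(np.sqrt(((recon[:, i, :] - x[:, i, :]) ** 2).mean()))
    overall = float(np.mean(list(per.values())))
    return ReconReport(per_channel_rmse=per, overall_rmse=overall,
                       n_dv=model.n_dv, dv_labels=tuple(per),
                       mechanism=model.mechanism or "")


def planted_recovery(
    seed: int = 0,
    target_label: str = "Cz",
    noise_sd: float = 0.02,
    n_segments: int = 2000,
    epochs: int = 500,
    learning_rate: float = 3e-3,
    fs: float = 16.0,
    duration: float = 0.5,
    montage_name: str = "10-20-19ch",
) -> dict:
    """Train on a planted linear dependency and measure blocked-target RMSE.

    The target channel is a known convex combination of three neighbours
    plus noise of sd ``noise_sd``; the noise is unpredictable, so
    ``noise_sd`` is the recovery floor. Returns the held-out blocked-target
    RMSE together with that floor.
    """
    mont = build_montage(montage_name)
    segs = planted_dependency_set(
        mont, target_label, noise_sd=noise_sd, n_segments=n_segments,
        seed=seed, fs=fs, duration=duration,
    )
    train_part, _val, test_part = split_dataset(segs, seed=seed)
    model = _fit(train_part, mont, "partition", 1, epochs, learning_rate, seed)
    x = model.normalize_input(test_part)
    ti = model.labels_.index(target_label)
    recon = model.reconstruct(test_part, missing=[target_label])
    target_rmse = float(np.sqrt(((recon[:, ti, :] - x[:, ti, :]) ** 2).mean()))
    return {
        "target": target_label,
        "rmse": target_rmse,
        "noise_floor": noise_sd,
        "n_train": train_part.n_segments,
        "n_test": test_part.n_segments,
        "epochs": epochs,
    }


def _symmetric_spec(montage: ElectrodeMontage, n_segments: int, seed: int,
                    fs: float, duration: float) -> SyntheticSpec:
    return SyntheticSpec(
        montage=montage,
        n_segments=n_segments,
        fs=fs,
        duration=duration,
        symmetry=1.0,
        mixing_decay=0.5,
        noise_sd=0.05,
        seed=seed,
    )


def ordering_comparison(
    n_runs: int = 10,
    seed: int = 0,
    n_segments: int = 300,
    n_dv: int = 2,
    epochs: int = 150,
    learning_rate: float = 1e-3,
    fs: float = 16.0,
    duration: float = 0.5,
    montage_name: str = "10-20-19ch",
    mechanism_a: str = "hemisphere_rotation",
    mechanism_b: str = "random",
) -> dict:
    """Paired comparison of two gating curricula on symmetric synthetic data.

    Per run: one symmetric dataset (symmetry=1), two models trained with
    identical data/weight seeds differing only in the gating mechanism, both
    evaluated on the common single-channel deletion sweep (a shared task, so
    the comparison is not confounded by mask difficulty). Training uses the
    sequential ``interleave`` update mode, under which the lesson order of
    the gate sequence — the variable this experiment studies — actually
    enters the optimisation dynamics. Returns per-run paired RMSEs, their
    means, and a one-sided sign test for mechanism A achieving lower error.
    """
    mont = build_montage(montage_name)
    rmse_a, rmse_b = [], []
    base = np.random.SeedSequence(seed).generate_state(n_runs) % (2 ** 31)
    for r in range(n_runs):
        run_seed = int(base[r])
        segs = simulate(_symmetric_spec(mont, n_segments, run_seed, fs, duration))
        train_part, _val, test_part = split_dataset(segs, seed=run_seed)
        ra = single_channel_sweep_rmse(
            _fit(train_part, mont, mechanism_a, n_dv, epochs, learning_rate,
                 run_seed, gate_seed=run_seed, lesson_update="interleave"),
            test_part,
        )
        rb = single_channel_sweep_rmse(
            _fit(train_part, mont, mechanism_b, n_dv, epochs, learning_rate,
                 run_seed, gate_seed=run_seed, lesson_update="interleave"),
            test_part,
        )
        rmse_a.append(ra.overall_rmse)
        rmse_b.append(rb.overall_rmse)
    rmse_a, rmse_b = np.array(rmse_a), np.array(rmse_b)
    return {
        "mechanism_a": mechanism_a,
        "mechanism_b": mechanism_b,
        "rmse_a": rmse_a.tolist(),
        "rmse_b": rmse_b.tolist(),
        "mean_a": float(rmse_a.mean()),
        "mean_b": float(rmse_b.mean()),
        "wins_a": int((rmse_a < rmse_b).sum()),
        "sign_test_p": sign_test(rmse_a - rmse_b, alternative="less"),
        "n_runs": n_runs,
    }


def dv_sweep(
    n_dvs: tuple[int, ...] = (1, 3, 5),
    n_seeds: int = 5,
    seed: int = 0,
    n_segments: int = 300,
    epochs: int = 150,
    learning_rate: float = 1e-3,
    fs: float = 16.0,
    duration: float = 0.5,
    montage_name: str = "10-20-19ch",
    mechanism: str = "partition",
) -> dict:
    """Mean blocked-channel RMSE as a function of the number of missing
    channels, averaged over seeded runs (mechanism-matched evaluation)."""
    mont = build_montage(montage_name)
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    means: dict[int, float] = {}
    per_run: dict[int, list[float]] = {d: [] for d in n_dvs}
    for s in range(n_seeds):
        run_seed = int(base[s])
        segs = simulate(SyntheticSpec(
            montage=mont, n_segments=n_segments, fs=fs, duration=duration,
            symmetry=0.5, mixing_decay=0.5, noise_sd=0.05, seed=run_seed,
        ))
        train_part, _val, test_part = split_dataset(segs, seed=run_seed)
        for d in n_dvs:
            model = _fit(train_part, mont, mechanism, d, epochs,
                         learning_rate, run_seed, gate_seed=run_seed)
            rep = curriculum_sweep_rmse(model, test_part)
            per_run[d].append(rep.overall_rmse)
    for d in n_dvs:
        means[d] = float(np.mean(per_run[d]))
    return {
        "mechanism": mechanism,
        "n_dvs": list(n_dvs),
        "mean_rmse": {str(d): means[d] for d in n_dvs},
        "accuracy_percent": {str(d): (1.0 - means[d]) * 100.0 for d in n_dvs},
        "per_run": {str(d): per_run[d] for d in n_dvs},
        "n_seeds": n_seeds,
    }
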