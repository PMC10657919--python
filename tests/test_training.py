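"""Training protocol: folds, augmentation, early stopping, the
weak-supervision firewall, and learnability on a separable toy task."""

from functools import partial

import numpy as np
import pytest

from wsunet.errors import LeakageError
from wsunet.models import WSUnetConfig, build_wsunet
from wsunet.patches import Patch, PatchDataset, PatchSamplingConfig
from wsunet.training import (
    EpochTrace,
    TrainingConfig,
    WeaklySupervisedImageModel,
    augment,
    crossvalidate,
    make_folds,
    train_model,
)

# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def test_folds_partition_subjects_evenly():
    ids = [f"P{i}" for i in range(10)]
    folds = make_folds(ids, 5, seed=0)
    sizes = [len(folds.subjects_in(k)) for k in range(5)]
    assert sizes == [2, 2, 2, 2, 2]
    assigned = [s for k in range(5) for s in folds.subjects_in(k)]
    assert sorted(assigned) == sorted(ids)


def test_folds_sizes_differ_by_at_most_one():
    folds = make_folds([f"P{i}" for i in range(13)], 4, seed=1)
    sizes = sorted(len(folds.subjects_in(k)) for k in range(4))
    assert sizes[-1] - sizes[0] <= 1


def test_too_few_subjects_raises():
    with pytest.raises(ValueError):
        make_folds(["a", "b"], 3, seed=0)


def test_all_patches_of_a_subject_share_a_fold(small_dataset):
    folds = make_folds(small_dataset.subject_ids, 3, seed=0)
    for p in small_dataset.patches:
        assert p.subject_id in folds.fold_of_subject


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _toy_patch(rng, n=8):
    mask = (rng.random((n, n)) < 0.2).astype(np.uint8)
    return Patch(rng.random((n, n)).astype(np.float32), int(mask.max() > 0),
                 mask, "P0", (0, n // 2, n // 2), "tumour_centred")


def test_augmentation_preserves_label_and_mask_count(rng):
    for _ in range(30):
        p = _toy_patch(rng)
        q = augment(p, rng)
        assert q.label == p.label
        assert q.mask.sum() == p.mask.sum()  # transform permutes pixels
        assert q.pixels.shape == p.pixels.shape


def test_rotation_four_times_is_identity(rng):
    from wsunet.training import _apply_transform

    grid = rng.random((6, 6))
    out = grid
    for _ in range(4):
        out = _apply_transform(out, False, False, 1)
    np.testing.assert_array_equal(out, grid)


def test_all_sixteen_flip_rotation_compositions_are_permutations(rng):
    from wsunet.training import _apply_transform

    grid = rng.random((6, 6))
    for hflip in (False, True):
        for vflip in (False, True):
            for k in range(4):
                out = _apply_transform(grid, hflip, vflip, k)
                assert sorted(out.ravel()) == sorted(grid.ravel())


def test_nonsquare_rotation_rejected(rng):
    mask = np.zeros((4, 8), dtype=np.uint8)
    p = Patch(np.zeros((4, 8), dtype=np.float32), 0, mask, "P", (0, 2, 4),
              "contralateral")

    class AlwaysRotate:
        def random(self):
            return 0.9

        def integers(self, n):
            return 1

    with pytest.raises(ValueError):
        augment(p, AlwaysRotate())


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------


def _oracle_stop_epoch(losses, patience, min_delta=1e-4, max_epochs=None):
    """Brute-force scan of the patience rule."""
    best = np.inf
    stale = 0
    for epoch, loss in enumerate(losses, start=1):
        if loss < best - min_delta:
            best, stale = loss, 0
        else:
            stale += 1
            if stale >= patience:
                return epoch
    return max_epochs or len(losses)


@pytest.mark.parametrize("losses,patience", [
    ([1.0, 1.1, 1.2, 1.3], 1),          # increases from epoch 1 -> stops at 2
    ([1.0, 0.9, 0.91, 0.92, 0.93], 2),
    ([1.0, 0.5, 0.4, 0.39995, 0.3999, 0.3998], 3),  # sub-min-delta plateau
    ([1.0, 0.9, 0.8, 0.7, 0.6], 2),     # never stops early
])
def test_early_stopping_matches_brute_force_scan(monkeypatch, losses, patience,
                                                 small_dataset):
    seq = iter(losses)
    monkeypatch.setattr("wsunet.training._epoch_validation",
                        lambda *a, **k: {"val_loss": next(seq)})
    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=1,
                       spatial_dropout_rate=0.0)
    handle = build_wsunet(cfg, seed=0)
    ids = small_dataset.subject_ids
    train = small_dataset.subset(ids[:4])
    val = small_dataset.subset(ids[4:])
    tcfg = TrainingConfig(max_epochs=len(losses), patience_epochs=patience,
                          batch_size=16, seed=0, augment=False)
    _, trace = train_model(handle, train, val, tcfg)
    assert len(trace) == _oracle_stop_epoch(losses, patience,
                                            max_epochs=len(losses))


def test_stopping_restores_best_epoch_weights(monkeypatch, small_dataset):
    losses = [0.5, 0.9, 0.95, 0.99]
    seq = iter(losses)
    snapshots = []
    import wsunet.training as tr

    def fake_val(handle, *a, **k):
        snapshots.append([w.copy() for w in handle.get_weights()])
        return {"val_loss": next(seq)}

    monkeypatch.setattr(tr, "_epoch_validation", fake_val)
    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=1,
                       spatial_dropout_rate=0.0)
    handle = build_wsunet(cfg, seed=0)
    ids = small_dataset.subject_ids
    tcfg = TrainingConfig(max_epochs=4, patience_epochs=3, batch_size=16, seed=0,
                          augment=False)
    handle, trace = train_model(handle, small_dataset.subset(ids[:4]),
                                small_dataset.subset(ids[4:]), tcfg)
    for got, best in zip(handle.get_weights(), snapshots[0]):
        np.testing.assert_array_equal(got, best)


# ---------------------------------------------------------------------------
# weak-supervision firewall and leakage
# ---------------------------------------------------------------------------


def _with_masks(dataset, new_mask_of):
    patches = []
    for p in dataset.patches:
        m = new_mask_of(p)
        patches.append(Patch(p.pixels, p.label, m, p.subject_id, p.centre,
                             p.origin, p.source_voxel, p.proposed_centre))
    return PatchDataset(patches, dataset.sampling_config, dataset.provenance)


def test_masks_never_influence_trained_weights(small_dataset):
    """Replacing every voxel mask with an arbitrary other mask changes the
    voxel-metric trace but leaves losses and learned weights bit-identical:
    the optimiser is blind to voxel-level truth."""
    ids = small_dataset.subject_ids
    train, val = small_dataset.subset(ids[:4]), small_dataset.subset(ids[4:])
    # scrambled masks: a fixed checkerboard scaled by the label (keeps the
    # Patch label==mask invariant but destroys all spatial truth)
    def scramble(p):
        m = np.zeros_like(p.mask)
        if p.label == 1:
            m[::2, ::2] = 1
        return m

    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=2,
                       spatial_dropout_rate=0.0)
    tcfg = TrainingConfig(max_epochs=2, patience_epochs=5, batch_size=16, seed=0)

    h1, t1 = train_model(build_wsunet(cfg, seed=1), train, val, tcfg)
    h2, t2 = train_model(build_wsunet(cfg, seed=1), _with_masks(train, scramble),
                         _with_masks(val, scramble), tcfg)
    for a, b in zip(h1.get_weights(), h2.get_weights()):
        np.testing.assert_array_equal(a, b)
    for r1, r2 in zip(t1.records, t2.records):
        assert r1["val_loss"] == r2["val_loss"]
    assert any(r1["aupr"] != r2["aupr"] for r1, r2 in zip(t1.records, t2.records))


def test_subject_overlap_raises_leakage_error(small_dataset):
    ids = small_dataset.subject_ids
    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=1)
    handle = build_wsunet(cfg, seed=0)
    with pytest.raises(LeakageError):
        train_model(handle, small_dataset.subset(ids[:4]),
                    small_dataset.subset(ids[3:]), TrainingConfig())


# ---------------------------------------------------------------------------
# learnability and determinism
# ---------------------------------------------------------------------------


def _separable_dataset(rng, n_subjects=8, per_subject=8, n=16):
    """Bright blob <=> positive; trivially separable by thresholding."""
    patches = []
    for s in range(n_subjects):
        for i in range(per_subject):
            pix = rng.normal(0.0, 0.05, (n, n)).astype(np.float32)
            mask = np.zeros((n, n), dtype=np.uint8)
            label = int(i % 2 == 0)
            if label:
                ci, cj = rng.integers(3, n - 3, 2)
                pix[ci - 2:ci + 2, cj - 2:cj + 2] += 1.0
                mask[ci - 2:ci + 2, cj - 2:cj + 2] = 1
            patches.append(Patch(pix, label, mask, f"P{s}", (0, n // 2, n // 2),
                                 "tumour_centred" if label else "contralateral"))
    prov = {f"P{s}": (per_subject // 2, per_subject // 2) for s in range(n_subjects)}
    return PatchDataset(patches, PatchSamplingConfig(patch_shape=(n, n)), prov)


def test_separable_toy_task_reaches_high_accuracy(rng):
    ds = _separable_dataset(rng)
    cfg = WSUnetConfig((16, 16, 1), depth=2, base_filters=4,
                       spatial_dropout_rate=0.0)
    tcfg = TrainingConfig(max_epochs=20, patience_epochs=5, batch_size=8, seed=2,
                          augment=True)
    model = WeaklySupervisedImageModel(ds, partial(build_wsunet, cfg), tcfg)
    res = model.fit()
    scores, labels = res.validation_image_scores()
    accuracy = ((scores >= 0.5) == labels).mean()
    assert accuracy > 0.95
    assert "validation accuracy" in res.summary()


def test_identical_seeds_give_identical_traces(small_dataset):
    ids = small_dataset.subject_ids
    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=2)
    tcfg = TrainingConfig(max_epochs=2, patience_epochs=5, batch_size=16, seed=3)
    traces = []
    for _ in range(2):
        _, trace = train_model(build_wsunet(cfg, seed=4),
                               small_dataset.subset(ids[:4]),
                               small_dataset.subset(ids[4:]), tcfg)
        traces.append(trace.to_frame())
    assert traces[0].equals(traces[1])


def test_crossvalidation_yields_one_model_per_fold(small_dataset):
    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=1,
                       spatial_dropout_rate=0.0)
    tcfg = TrainingConfig(max_epochs=1, patience_epochs=5, batch_size=16,
                          n_folds=3, seed=0, trace_voxel_metrics=False)
    results = crossvalidate(small_dataset, partial(build_wsunet, cfg), tcfg)
    assert len(results) == 3
    folds = make_folds(small_dataset.subject_ids, 3, seed=0)
    covered = [s for k in range(3) for s in folds.subjects_in(k)]
    assert sorted(covered) == sorted(small_dataset.subject_ids)
    for k, (_, trace) in enumerate(results):
        assert all(r["fold"] == k for r in trace.records)


def test_epoch_trace_records_voxel_metrics_per_epoch(small_dataset):
    ids = small_dataset.subject_ids
    cfg = WSUnetConfig((32, 32, 1), depth=2, base_filters=2)
    tcfg = TrainingConfig(max_epochs=2, patience_epochs=5, batch_size=16, seed=0)
    _, trace = train_model(build_wsunet(cfg, seed=0),
                           small_dataset.subset(ids[:4]),
                           small_dataset.subset(ids[4:]), tcfg)
    frame = trace.to_frame()
    assert list(frame["epoch"]) == [1, 2]
    for col in ("val_loss", "precision", "recall", "dice", "aupr"):
        assert col in frame.columns
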