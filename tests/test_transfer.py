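"""Checkpoint schedule, freeze/re-init mechanics and transfer reports."""

import numpy as np
import pandas as pd
import pytest

from mcpinn.dataset import CPIDataset
from mcpinn.model import ChannelConfig, PinnConfig, build_pinn
from mcpinn.nn import Adam
from mcpinn.training import TrainConfig, TrainingHistory, EpochRecord, train
from mcpinn.transfer import (
    Checkpoint,
    FinetuneStrategy,
    PretrainSchedule,
    compare_pretraining,
    finetune,
    load_checkpoint,
    pretrain_with_checkpoints,
    save_checkpoint,
)


def _dense_config(d=5):
    return PinnConfig(
        compound_channels=[ChannelConfig(kind="dense", feature_dim=d)],
        protein_channels=[ChannelConfig(kind="dense", feature_dim=d)],
        separated_layer_widths=[8], concatenated_layer_widths=[6],
        dropout_initial=0.0, dropout_hidden=0.1)


def _pair_task(n=600, d=5, seed=0, rule_shift=0.0):
    rng = np.random.default_rng(seed)
    x_c = rng.standard_normal((n, d))
    x_p = rng.standard_normal((n, d))
    logits = 3 * (x_c[:, 0] + x_p[:, 0] + rule_shift * x_c[:, 1])
    y = (logits + rng.normal(0, 0.5, n) > 0).astype(int)
    ds = CPIDataset(compounds={f"c{i}": "C" for i in range(n)},
                    proteins={f"p{i}": "MKV" for i in range(n)},
                    pairs=pd.DataFrame({"compound_id": [f"c{i}" for i in range(n)],
                                        "protein_id": [f"p{i}" for i in range(n)],
                                        "label": y}))
    ds.views = {"xc": x_c, "xp": x_p}
    ds.make_splits(seed=seed)
    return ds


class TestSchedule:
    def test_checkpoint_epochs(self):
        sched = PretrainSchedule(total_epochs=20, checkpoint_interval=5)
        assert sched.checkpoint_epochs == [0, 5, 10, 15, 20]

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            PretrainSchedule(total_epochs=0)

    def test_defaults_match_protocol(self):
        sched = PretrainSchedule()
        assert sched.total_epochs == 140
        assert sched.checkpoint_interval == 5
        assert len(sched.checkpoint_epochs) == 29


class TestPretrainCheckpoints:
    def test_all_scheduled_checkpoints_produced_and_pm0_is_init(self):
        ds = _pair_task(seed=1)
        model = build_pinn(_dense_config(), seed=3)
        init_state = model.network.state_dict()
        sched = PretrainSchedule(total_epochs=6, checkpoint_interval=2)
        config = TrainConfig(batch_size=64, max_epochs=6, early_stopping_patience=6, seed=1)
        checkpoints, history = pretrain_with_checkpoints(model, ds, sched, config, ["xc", "xp"])
        assert sorted(checkpoints) == [0, 2, 4, 6]
        assert len(history.records) == 6
        for name, value in init_state.items():
            np.testing.assert_array_equal(checkpoints[0].params[name], value)

    def test_restore_reproduces_live_outputs(self, rng):
        ds = _pair_task(seed=2)
        model = build_pinn(_dense_config(), seed=4)
        sched = PretrainSchedule(total_epochs=4, checkpoint_interval=2)
        config = TrainConfig(batch_size=64, max_epochs=4, early_stopping_patience=4, seed=2)
        checkpoints, _ = pretrain_with_checkpoints(model, ds, sched, config, ["xc", "xp"])
        # the live model is at epoch 4 == last checkpoint
        other = build_pinn(_dense_config(), seed=99)
        checkpoints[4].restore(other)
        xs = [rng.standard_normal((3, 5)), rng.standard_normal((3, 5))]
        np.testing.assert_array_equal(model.network.forward(xs), other.network.forward(xs))

    def test_checkpoint_disk_roundtrip_with_optimizer_state(self, tmp_path):
        model = build_pinn(_dense_config(), seed=5)
        opt = Adam(model.network.params(), lr=1e-3)
        for p in model.network.params():
            p.grad[...] = 0.5
        opt.step()
        cp = Checkpoint(epoch=7, params=model.network.state_dict(),
                        optimizer_state=opt.state_dict(), seed=5)
        save_checkpoint(cp, tmp_path / "pm_7")
        loaded = load_checkpoint(tmp_path / "pm_7")
        assert loaded.epoch == 7 and loaded.seed == 5
        for k, v in cp.params.items():
            np.testing.assert_array_equal(loaded.params[k], v)
        assert loaded.optimizer_state["t"] == 1
        for m1, m2 in zip(cp.optimizer_state["m"], loaded.optimizer_state["m"]):
            np.testing.assert_array_equal(m1, m2)


class TestStrategies:
    def test_scenario_masks(self):
        model = build_pinn(_dense_config(), seed=0)
        s1 = FinetuneStrategy.for_scenario(model, 1)
        assert s1.freeze_groups == [] and s1.reinitialize_groups == []
        s3 = FinetuneStrategy.for_scenario(model, 3)
        assert "output" not in s3.freeze_groups and "concatenated" in s3.freeze_groups
        s4 = FinetuneStrategy.for_scenario(model, 4)
        assert set(s4.reinitialize_groups) == {"concatenated", "output"}
        assert all(g not in s4.freeze_groups for g in ("concatenated", "output"))
        with pytest.raises(ValueError):
            FinetuneStrategy.for_scenario(model, 5)

    def test_unknown_group_rejected(self):
        model = build_pinn(_dense_config(), seed=0)
        bad = FinetuneStrategy(scenario=4, freeze_groups=["nope"])
        with pytest.raises(KeyError):
            bad.validate(model)


class TestFinetune:
    def _pretrained(self, seed=0):
        ds = _pair_task(seed=seed)
        model = build_pinn(_dense_config(), seed=seed)
        sched = PretrainSchedule(total_epochs=4, checkpoint_interval=4)
        config = TrainConfig(batch_size=64, max_epochs=4, early_stopping_patience=4, seed=seed)
        checkpoints, _ = pretrain_with_checkpoints(model, ds, sched, config, ["xc", "xp"])
        return checkpoints

    def test_frozen_layers_are_bit_identical_after_finetuning(self):
        checkpoints = self._pretrained(seed=6)
        target = _pair_task(seed=7, rule_shift=0.5)
        arch = _dense_config()
        template = build_pinn(arch, seed=0)
        strategy = FinetuneStrategy.for_scenario(template, 4)
        config = TrainConfig(batch_size=64, max_epochs=3, early_stopping_patience=3, seed=7)
        history, model = finetune(checkpoints[4], arch, target, strategy, config,
                                  ["xc", "xp"], reinit_seed=11)
        groups = model.network.layer_groups()
        for name in strategy.freeze_groups:
            for p in groups[name]:
                np.testing.assert_array_equal(p.value, checkpoints[4].params[p.name])
        assert len(history.records) == 3
        assert "test_mcc" in history.records[0].extras

    def test_reinitialized_layers_differ_from_checkpoint(self):
        checkpoints = self._pretrained(seed=8)
        target = _pair_task(seed=9)
        arch = _dense_config()
        template = build_pinn(arch, seed=0)
        strategy = FinetuneStrategy.for_scenario(template, 4)
        config = TrainConfig(batch_size=64, max_epochs=1, early_stopping_patience=1, seed=9)
        _, model = finetune(checkpoints[4], arch, target, strategy, config,
                            ["xc", "xp"], reinit_seed=12)
        w = model.network.layer_groups()["concatenated"][0]
        assert not np.array_equal(w.value, checkpoints[4].params[w.name])


class TestCompareReport:
    def _history(self, values):
        hist = TrainingHistory()
        for e, v in enumerate(values, start=1):
            hist.append(EpochRecord(e, 0.0, v, 0.5, 0.0))
        return hist

    def test_identical_histories_give_unit_pvalue_and_zero_deltas(self):
        h = [self._history([0.1, 0.2, 0.3]) for _ in range(2)]
        report = compare_pretraining({0: h, 5: [self._history([0.1, 0.2, 0.3])] * 2})
        assert np.allclose(report["p_vs_pm0"], 1.0)
        assert report["best_val_mcc"].nunique() == 1

    def test_initial_performance_column(self):
        report = compare_pretraining({
            0: [self._history([0.16, 0.3])],
            55: [self._history([0.11, 0.4])],
        })
        by_pm = report.set_index("pm_epoch")
        assert by_pm.loc[0, "initial_val_mcc"] == pytest.approx(0.16)
        assert by_pm.loc[55, "initial_val_mcc"] == pytest.approx(0.11)

    def test_requires_pm0(self):
        with pytest.raises(ValueError):
            compare_pretraining({5: [self._history([0.1])], 10: [self._history([0.2])]})
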