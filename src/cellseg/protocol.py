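"""Desk-scale replication of the three training regimes.

U-Base trains on manually (here: generator-) labeled mixed scenes;
U-Single trains only on auto-labeled single-kind scenes; U-Transfer
fine-tunes U-Single on a small labeled mixed set at half the learning
rate.  All stages run on seeded synthetic 64x64 scenes with a depth-3
U-Net (widths 8/16/32/64) so the full protocol fits in CPU minutes;
test metrics (mIoU, FWIoU, Dice) and per-class count accuracy are
computed on held-out mixed scenes against generator ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autolabel import autolabel_image, preset_for_kind
from .count import count_accuracy, count_cells
from .metrics import evaluate_split
from .synth import SynthConfig, generate_scene_retry
from .train import TrainConfig, evaluate_miou, finetune, train
from .unet import UNetConfig, build_unet, init_weights, predict_batch


@dataclass
class ProtocolConfig:
    """Scaled-down study conditions (sizes are package defaults, chosen
    to keep the protocol within CPU minutes while preserving the
    pretrain -> fine-tune structure)."""

    synth: SynthConfig = field(default_factory=SynthConfig.small)
    n_single: int = 200          # auto-labeled single-kind training scenes
    n_single_val: int = 20       # auto-labeled holdout used for checkpointing
    n_finetune: int = 10         # truth-labeled mixed fine-tune scenes
    n_finetune_val: int = 5
    n_test: int = 30             # held-out mixed test scenes
    n_base: int = 40             # truth-labeled mixed scenes for U-Base
    epochs: int = 20
    finetune_epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 4


def _scenes(cfg: SynthConfig, kind: str, n: int, seed_seq) -> list:
    return [generate_scene_retry(cfg, kind, s) for s in seed_seq.spawn(n)]


def _autolabeled_pairs(scenes, presets) -> list:
    pairs = []
    for sc in scenes:
        cls = 1 if sc.kind == "rbc" else 2
        label = autolabel_image(sc.image, presets[sc.kind], class_value=cls)
        pairs.append((sc.image, label))
    return pairs


def default_count_params(cfg: SynthConfig):
    """Per-class minimum areas: half the smallest true cell area."""
    min_area = {1: 0.5 * np.pi * cfg.rbc_radius[0] ** 2,
                2: 0.5 * np.pi * cfg.mac_radius[0] ** 2}
    typical = {1: np.pi * np.mean(cfg.rbc_radius) ** 2,
               2: np.pi * np.mean(cfg.mac_radius) ** 2}
    return min_area, typical


def run_protocol(seed: int, cfg: ProtocolConfig | None = None,
                 include_base: bool = False) -> dict:
    """Run U-Single -> U-Transfer (optionally U-Base) for one seed.

    Returns test-set metrics for each regime plus count accuracy of the
    fine-tuned model, all measured on the same held-out mixed scenes.
    """
    if cfg is None:
        cfg = ProtocolConfig()
    scfg = cfg.synth
    root = np.random.SeedSequence([int(seed), 0xCE11])
    (sq_single, sq_val, sq_ft, sq_ftval, sq_test, sq_base) = root.spawn(6)

    presets = {"rbc": preset_for_kind(scfg, "rbc"),
               "macrophage": preset_for_kind(scfg, "macrophage")}

    # --- auto-labeled single-kind training data
    half = cfg.n_single // 2
    singles = (_scenes(scfg, "rbc", half, sq_single.spawn(2)[0])
               + _scenes(scfg, "macrophage", cfg.n_single - half, sq_single.spawn(2)[1]))
    train_pairs = _autolabeled_pairs(singles, presets)
    vhalf = cfg.n_single_val // 2
    val_scenes = (_scenes(scfg, "rbc", vhalf, sq_val.spawn(2)[0])
                  + _scenes(scfg, "macrophage", cfg.n_single_val - vhalf,
                            sq_val.spawn(2)[1]))
    val_pairs = _autolabeled_pairs(val_scenes, presets)

    # --- held-out mixed sets with generator truth
    ft_scenes = _scenes(scfg, "mixed", cfg.n_finetune, sq_ft)
    ftval_scenes = _scenes(scfg, "mixed", cfg.n_finetune_val, sq_ftval)
    test_scenes = _scenes(scfg, "mixed", cfg.n_test, sq_test)
    ft_pairs = [(s.image, s.mask) for s in ft_scenes]
    ftval_pairs = [(s.image, s.mask) for s in ftval_scenes]
    test_imgs = [s.image for s in test_scenes]
    test_masks = [s.mask for s in test_scenes]

    ucfg = UNetConfig.tiny(in_channels=1, num_classes=3)
    tcfg = TrainConfig(batch_size=cfg.batch_size, epochs=cfg.epochs,
                       learning_rate=cfg.learning_rate, seed=seed, phase="single")

    def test_metrics(model):
        preds = predict_batch(model, test_imgs)
        m = evaluate_split(test_masks, preds, 3)
        m.pop("confusion", None)
        return m, preds

    out: dict = {"seed": seed}

    # --- U-Single: pretrain on auto-labels only
    model = init_weights(build_unet(ucfg), seed)
    train(model, train_pairs, tcfg, val_data=val_pairs)
    m_single, _ = test_metrics(model)
    out["single"] = m_single

    # --- U-Transfer: fine-tune on the small truth-labeled mixed set
    ft_tcfg = TrainConfig.transfer(batch_size=cfg.batch_size,
                                   epochs=cfg.finetune_epochs,
                                   learning_rate=cfg.learning_rate / 2.0,
                                   seed=seed + 1)
    finetune(model, ft_pairs, ft_tcfg, val_data=ftval_pairs)
    m_transfer, preds = test_metrics(model)
    out["transfer"] = m_transfer

    # --- counting on the fine-tuned predictions (default policy)
    min_area, typical = default_count_params(scfg)
    totals_true = {1: 0, 2: 0}
    totals_pred = {1: 0, 2: 0}
    for scene, pred in zip(test_scenes, preds):
        report = count_cells(pred, min_area, num_classes=3)
        for c in (1, 2):
            totals_true[c] += scene.true_counts[c]
            totals_pred[c] += report.counts.get(c, 0)
    out["counts"] = {
        "true": totals_true,
        "pred": totals_pred,
        "accuracy_pct": {
            c: (None if totals_true[c] == 0 else 100.0 * totals_pred[c] / totals_true[c])
            for c in (1, 2)
        },
    }

    if include_base:
        base_scenes = _scenes(scfg, "mixed", cfg.n_base, sq_base)
        base_model = init_weights(build_unet(ucfg), seed + 2)
        bcfg = TrainConfig(batch_size=cfg.batch_size, epochs=cfg.epochs,
                           learning_rate=cfg.learning_rate, seed=seed + 2,
                           phase="base")
        train(base_model, [(s.image, s.mask) for s in base_scenes], bcfg,
              val_data=ftval_pairs)
        m_base, _ = test_metrics(base_model)
        out["base"] = m_base
    return out


def run_protocol_seeds(seeds, cfg: ProtocolConfig | None = None,
                       include_base: bool = False) -> dict:
    """Run the protocol for several seeds and report per-seed results
    plus the across-seed median of each headline quantity."""
    runs = [run_protocol(s, cfg, include_base) for s in seeds]
    med = lambda key1, key2: float(np.median([r[key1][key2] for r in runs]))
    summary = {
        "miou_single": med("single", "miou"),
        "miou_transfer": med("transfer", "miou"),
        "fwiou_transfer": med("transfer", "fwiou"),
        "dice_transfer": med("transfer", "dice"),
        "macrophage_count_accuracy_pct": float(np.median(
            [r["counts"]["accuracy_pct"][2] for r in runs])),
        "rbc_count_accuracy_pct": float(np.median(
            [r["counts"]["accuracy_pct"][1] for r in runs])),
    }
    if include_base:
        summary["miou_base"] = med("base", "miou")
    return {"runs": runs, "median": summary}
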