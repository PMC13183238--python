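"""Train a tiny detector on synthetic scenes end to end (about two minutes).

Generates a small day-only dataset, trains a narrow kernel-team model for
twenty epochs with the standard optimizer protocol (SGD, momentum 0.937,
weight decay 5e-4), and prints the held-out detection quality per epoch.
For the full reduced-scale study (200 images, 30 epochs, three seeds) see
tests/test_acceptance.py.
"""

from ktyolo import ModelConfig, TrainConfig, evaluate, generate_scenes, train
from ktyolo.detector import dataset_from_scenes

tr = dataset_from_scenes(generate_scenes(96, seed=1, width=96, height=96,
                                         n_range=(2, 6), day_fraction=1.0))
va = dataset_from_scenes(generate_scenes(24, seed=2, width=96, height=96,
                                         n_range=(2, 6), day_fraction=1.0))

cfg = TrainConfig(
    model=ModelConfig(num_classes=4, widths=(8, 16, 24, 48, 96),
                      depths=(1, 1, 1, 1), fusion="ktf"),
    batch_size=16, max_epochs=20, early_stop_patience=19,
    input_size=96, seed=0, cls_loss="slide", eval_every=4,
)
result = train(cfg, tr, va)
for entry in result.log:
    line = f"epoch {entry['epoch']:2d}  loss {entry['loss']:6.3f}"
    if "val_map50" in entry:
        line += f"  val mAP50 {entry['val_map50']:.3f}"
    if entry.get("mu") is not None:
        line += f"  mu {entry['mu']:.3f}"
    print(line)

report = evaluate(result.detector, va)
print(f"\nbest val mAP50 {result.best_map50:.3f} at epoch {result.best_epoch}")
print("per-class AP50:", {k: round(v, 3) for k, v in report.overall.per_class_ap.items()})
print("mu is the running mean IoU of assigned samples; it rises as boxes improve.")
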