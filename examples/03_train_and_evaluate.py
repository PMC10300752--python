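"""Train a small model on synthetic windows and evaluate the held-out set.

Uses a one-block-per-stage architecture and a few epochs so the example
runs in seconds; the full recipe is 12 blocks per stage and 120 epochs."""

import numpy as np

from breathnet import (
    ArchitectureConfig,
    SplitSpec,
    TrainConfig,
    build_model,
    build_report,
    make_synthetic_dataset,
    select_channels,
    split_dataset,
    train,
)
from breathnet.nirs_io import windows_to_arrays

windows = select_channels(make_synthetic_dataset(60, seed=0), {"O2Hb"})
train_set, test_set = split_dataset(windows, SplitSpec(seed=0))
print(f"{len(train_set)} training / {len(test_set)} test windows "
      "(stratified 80:20)")

model = build_model(ArchitectureConfig(blocks_per_stage=1), seed=0)
x_train, y_train = windows_to_arrays(train_set)
model, history = train(model, (x_train, y_train),
                       TrainConfig(epochs=12, seed=0))
print(f"final epoch: loss {history[-1]['loss']:.3f}, "
      f"training accuracy {history[-1]['train_accuracy']:.1f}%")

x_test, y_test = windows_to_arrays(test_set)
report = build_report(model.predict(x_test), y_test)
print()
print(report.render())
print()
print("Accuracy is the percentage of correctly classified 6.4-s windows;")
print("balanced accuracy averages the three per-class recalls, so it is")
print("insensitive to the class imbalance of the window counts.")
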