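import numpy as np
import pytest

from breathnet import (
    ArchitectureConfig,
    Condition,
    make_synthetic_dataset,
    select_channels,
)


@pytest.fixture(scope="session")
def toy_arch() -> ArchitectureConfig:
    """Smallest legal architecture: one bottleneck per main stage."""
    return ArchitectureConfig(blocks_per_stage=1)


@pytest.fixture(scope="session")
def small_dataset():
    """60 windows/class of single-channel synthetic data, fixed seed."""
    windows = make_synthetic_dataset(60, seed=7)
    return select_channels(windows, {"O2Hb"})


def write_recording_csv(path, n_rows, channels=("O2Hb", "HHb"), seed=0):
    """Write a small well-formed CSV recording and return its path."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_rows, len(channels)))
    with open(path, "w") as f:
        f.write(",".join(channels) + "\n")
        for row in data:
            f.write(",".join(f"{v:.6f}" for v in row) + "\n")
    return path


def closed_form_counts(variant, blocks_per_stage, input_channels, input_length,
                       num_classes=3, width=16):
    """Independent per-layer ledger of parameter and FLOP totals.

    Written as plain arithmetic over the architecture table (stem 1x5 conv;
    optional front bottleneck 1x1/1xk/1x1 at width `width`, stride 2; three
    main stages of bottlenecks (w,w,4w), (2w,2w,8w), (4w,4w,16w) with
    stride 2 entering stages 3 and 4; classifier 16w -> classes). FLOPs are
    2 per multiply-accumulate on the main path; parameters are split into
    main-path and projection totals, with batch-norm scale/shift counted.
    """
    k_front = {"ds": None, "stage1_k3": 3, "stage1_k5": 5}[variant]
    conv_params = 0
    proj_params = 0
    bn_params = 0
    flops = 0
    length = input_length

    # stem: 1x5 conv input_channels -> width, stride 1, length preserved
    conv_params += 5 * input_channels * width
    flops += 2 * 5 * input_channels * width * length

    in_ch = width
    if k_front is not None:  # front stage: (w, w, w) bottleneck, stride 2
        length //= 2
        bn_params += 2 * in_ch
        conv_params += in_ch * width
        flops += 2 * in_ch * width * length
        bn_params += 2 * width
        conv_params += k_front * width * width
        flops += 2 * k_front * width * width * length
        bn_params += 2 * width
        conv_params += width * width
        flops += 2 * width * width * length
        proj_params += in_ch * width
        in_ch = width

    stages = [(width, 4 * width, 1), (2 * width, 8 * width, 2),
              (4 * width, 16 * width, 2)]
    for mid, out, stride in stages:
        for b in range(blocks_per_stage):
            s = stride if b == 0 else 1
            if s != 1:
                length //= s
            bn_params += 2 * in_ch
            conv_params += in_ch * mid
            flops += 2 * in_ch * mid * length
            bn_params += 2 * mid
            conv_params += 3 * mid * mid
            flops += 2 * 3 * mid * mid * length
            bn_params += 2 * mid
            conv_params += mid * out
            flops += 2 * mid * out * length
            if s != 1 or in_ch != out:
                proj_params += in_ch * out
            in_ch = out

    bn_params += 2 * in_ch  # final BN before pooling
    fc_params = in_ch * num_classes + num_classes
    flops += 2 * in_ch * num_classes

    main = conv_params + bn_params + fc_params
    return {"main_path_params": main, "total_params": main + proj_params,
            "flops": flops}


@pytest.fixture(scope="session")
def label_values():
    return [c for c in Condition]
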