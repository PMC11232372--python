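import numpy as np
import pytest

from slicetox import bleedthrough, coloc, detect, prep, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_stack():
    """A compact noise-free dual-channel acquisition with ground truth."""
    cfg = synthetic.stack_preset(
        "fig1", nx=192, ny=192, n_pi=10, n_filled=8, n_healthy=5, frac_coloc=0.25, noise_sd=0.0, seed=42
    )
    green, red, truth = synthetic.generate_stack(cfg)
    return cfg, green, red, truth


@pytest.fixture(scope="session")
def fig1_run():
    """Full-field noise-free baseline condition run end to end once per session."""
    cfg = synthetic.stack_preset("fig1", noise_sd=0.0, seed=7)
    green, red, truth = synthetic.generate_stack(cfg)
    (gmips, gstats), (rmips, rstats) = prep.preprocess_pair(green, red)
    dets = detect.detect_stack(
        gmips, rmips, [s.sd for s in gstats], [s.sd for s in rstats]
    )
    kept, eliminated = bleedthrough.apply_ratio_filter(dets[prep.RED], -0.4)
    pairs = coloc.match_centroids(kept, dets[prep.GREEN])
    return {
        "cfg": cfg,
        "truth": truth,
        "green_dets": dets[prep.GREEN],
        "red_raw": dets[prep.RED],
        "red_kept": kept,
        "red_eliminated": eliminated,
        "pairs": pairs,
    }
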