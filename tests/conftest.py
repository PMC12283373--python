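import numpy as np
import pytest

from dlvpm import (DLVPM, SimSpec, TrainConfig, generate_multiview,
                   split_views, validate_path_spec)

# study configuration for the linear-limit experiments: training length
# chosen so the linear models converge to the classical solution without
# over-adapting the weakly identified dimensions; the whitening variant
# needs a longer budget because its update couples all dimensions
# through one Gram matrix
LINEAR_CONFIG = dict(batch_size=64, epochs=100, lr_initial=1e-2,
                     lr_decay="exponential", seed=0)
LINEAR_EPOCHS = {"iterative": 100, "whiten": 200}


@pytest.fixture(scope="session")
def two_view_linear():
    """Linear two-view dataset: N=500 training samples, p=10 features per
    view, cross-view correlation spectrum (0.8, 0.5, 0.2), plus a large
    held-out set from the same generative maps."""
    spec = SimSpec(K=2, N=2500, p=[10, 10], n_latents=3,
                   spectrum=(0.8, 0.5, 0.2), seed=1)
    views, _, truth = generate_multiview(spec)
    (train, _, truth_tr), (test, _, truth_te) = split_views(
        views, 500, truth=truth)
    return {"train": train, "test": test, "truth_train": truth_tr,
            "truth_test": truth_te,
            "path": validate_path_spec([[0, 1], [1, 0]])}


@pytest.fixture(scope="session")
def fitted_linear(two_view_linear):
    """Both orthogonalization variants fitted on the linear dataset."""
    out = {}
    for variant in ("iterative", "whiten"):
        model = DLVPM(two_view_linear["train"], two_view_linear["path"],
                      variant=variant, n_dims=3)
        cfg = {**LINEAR_CONFIG, "epochs": LINEAR_EPOCHS[variant]}
        out[variant] = model.fit(TrainConfig(**cfg))
    return out
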