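"""Shared test utilities (kept importable from test modules)."""

import numpy as np


def make_disc_patches(n_per_class: int = 20, h: int = 48, w: int = 64, seed: int = 0):
    """Linearly separable toy patches: bright vs dark central discs."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = np.zeros((n, h, w, 3), dtype=np.float32)
    y = np.array(["benign"] * n_per_class + ["malignant"] * n_per_class)
    yy, xx = np.mgrid[:h, :w]
    disc = (((yy - h / 2) ** 2 + (xx - w / 2) ** 2) < (min(h, w) / 3) ** 2)[..., None]
    for i in range(n):
        base = 0.8 if y[i] == "malignant" else 0.2
        X[i] = np.clip(disc * base + rng.normal(0, 0.05, (h, w, 3)), 0, 1)
    return X, y
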