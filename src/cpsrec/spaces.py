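"""Hyperparameter search spaces for the three regressor families.

These are the published randomized-search grids for the boosted-tree,
kernel-SVR and feedforward-net families; sampling is uniform over the
cartesian grid (without replacement when the grid is small).
"""

XGB_SPACE = {
    "n_estimators": [100, 200, 300, 400, 500],
    "max_depth": [3, 5, 7, 9],
    "learning_rate": [0.01, 0.05, 0.1, 0.15, 0.2],
    "subsample": [0.7, 0.8, 0.9, 1.0],
    "colsample_bytree": [0.7, 0.8, 0.9, 1.0],
    "gamma": [0, 0.1, 0.2, 0.3],
    "reg_alpha": [0, 0.01, 0.1, 0.5, 1.0],
    "reg_lambda": [0.5, 1.0, 1.5, 2.0],
}

SVR_SPACE = {
    "kernel": ["rbf", "linear", "poly"],
    "C": [0.1, 1, 10, 50, 100, 200, 500],
    "gamma": ["scale", "auto", 0.001, 0.005, 0.01, 0.05, 0.1],
    "epsilon": [0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5],
    "degree": [2, 3, 4],
}

MLP_SPACE = {
    "hidden_dims": [(32,), (64,), (32, 16), (64, 32), (128, 64), (128, 64, 32)],
    "learning_rate": [0.0005, 0.001, 0.005],
    "batch_size": [16, 32, 64],
    "dropout_rate": [0.2, 0.3, 0.4, 0.5],
    "weight_decay": [1e-5, 1e-4, 5e-4, 1e-3, 2e-3],
}

#: Randomized-search iteration counts per family.
N_ITER = {"boosted-trees": 50, "kernel-svr": 50, "feedforward-net": 25}

SPACES = {
    "boosted-trees": XGB_SPACE,
    "kernel-svr": SVR_SPACE,
    "feedforward-net": MLP_SPACE,
}
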