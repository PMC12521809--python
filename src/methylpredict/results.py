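"""Shared result container for classifiers and regressors."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FitResult:
    """A trained predictor with its out-of-fold predictions and metrics.

    ``model`` is the final estimator refit on all samples; ``oof_pred`` holds
    the prediction each sample received from the model whose training fold
    excluded it; ``fold`` records the test-fold index of each sample.
    ``provenance`` captures hyperparameters, including any deviation from the
    library defaults.
    """

    model: object
    features: list[str]
    oof_pred: np.ndarray
    fold: np.ndarray
    metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        """Serialize predictions, features and metrics (model not included)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"oof_pred": self.oof_pred, "fold": self.fold}).to_csv(
            outdir / "oof_predictions.csv", index_label="sample_index"
        )
        (outdir / "features.txt").write_text("\n".join(self.features) + "\n")
        payload = {"metrics": self.metrics, "provenance": self.provenance}
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2, default=str))
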