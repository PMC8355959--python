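"""Score the trained model: the five fit statistics per phase plus the
per-sample relative deviations.

Writes results/metrics.csv (train/test/total rows of R^2, MRE%, MSE, RMSE,
STD on the physical TEAC scale) and results/deviations.csv, and prints the
metrics table.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from teacelm.datasets import Dataset
from teacelm.diagnostics import fit_metrics, relative_deviation
from teacelm.elm import ELMModel, predict
from teacelm.preprocessing import (NormalizationParams, denormalize_target,
                                   normalize, split)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_model():
    doc = json.loads((RESULTS / "model.json").read_text())
    norm = doc["normalization"]
    params = NormalizationParams(
        np.array(norm["feature_min"]), np.array(norm["feature_max"]),
        norm["target_min"], norm["target_max"], norm["scope"])
    return ELMModel.from_dict(doc), params, doc["split_seed"]


if __name__ == "__main__":
    data = Dataset.from_csv(RESULTS / "dataset.csv")
    model, params, split_seed = load_model()
    sp = split(data.n_samples, 0.75, seed=split_seed)
    pred = denormalize_target(
        predict(model, normalize(data, params).features), params)

    rows = [
        fit_metrics(data.target[sp.train_indices], pred[sp.train_indices], "train"),
        fit_metrics(data.target[sp.test_indices], pred[sp.test_indices], "test"),
        fit_metrics(data.target, pred, "total"),
    ]
    table = pd.DataFrame([m.to_dict() for m in rows])
    table.to_csv(RESULTS / "metrics.csv", index=False)

    phase = np.full(data.n_samples, "test", dtype=object)
    phase[sp.train_indices] = "train"
    pd.DataFrame({"row": np.arange(data.n_samples), "phase": phase,
                  "actual": data.target, "predicted": pred,
                  "deviation_percent": relative_deviation(data.target, pred)}
                 ).to_csv(RESULTS / "deviations.csv", index=False)

    print(table.round(4).to_string(index=False))
    print(f"\nmean absolute relative deviation "
          f"{relative_deviation(data.target, pred).mean():.2f}%")
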