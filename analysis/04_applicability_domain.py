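"""Williams-plot applicability domain of the trained model.

Leverage of every sample against the normalized six-feature-plus-intercept
training design versus its standardized residual; rows beyond the warning
leverage h* = 3(p+1)/n_train or outside +/-3 standardized residuals are
flagged. Writes the plot-ready table to results/williams.csv.
"""

import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

from teacelm.datasets import Dataset
from teacelm.diagnostics import fit_metrics, williams
from teacelm.elm import predict
from teacelm.preprocessing import denormalize_target, normalize, split

RESULTS = Path(__file__).resolve().parent.parent / "results"
_eval = importlib.util.spec_from_file_location(
    "evaluate_fit", Path(__file__).parent / "03_evaluate_fit.py")
evaluate_fit = importlib.util.module_from_spec(_eval)
_eval.loader.exec_module(evaluate_fit)

if __name__ == "__main__":
    data = Dataset.from_csv(RESULTS / "dataset.csv")
    model, params, split_seed = evaluate_fit.load_model()
    sp = split(data.n_samples, 0.75, seed=split_seed)
    norm = normalize(data, params)
    pred = denormalize_target(predict(model, norm.features), params)
    rmse = fit_metrics(data.target, pred, "total").rmse

    ad = williams(norm.features[sp.train_indices], norm.features,
                  data.target - pred, rmse)
    phase = np.full(data.n_samples, "test", dtype=object)
    phase[sp.train_indices] = "train"
    pd.DataFrame({"row": np.arange(data.n_samples), "phase": phase,
                  "leverage": ad.leverages, "std_residual": ad.std_residuals,
                  "flag": ad.flags}).to_csv(RESULTS / "williams.csv", index=False)

    print(f"warning leverage h* = {ad.warning_leverage:.4f} "
          f"(3 x 7 / {sp.n_train} training rows)")
    for flag, count in ad.counts().items():
        print(f"{flag:>16}: {count}")
    suspects = ad.suspicious_rows()
    print(f"{len(suspects)} suspicious rows of {data.n_samples}: {suspects}")
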