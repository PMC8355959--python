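"""Train the PSO-tuned extreme learning machine on the calibrated dataset.

Normalizes everything to [-1, 1], splits 129/43, runs the swarm (30
particles, 200 iterations) over the 12-neuron hidden layer with the
Moore-Penrose output solve inside the fitness, and writes the model to
results/model.json plus the incumbent fitness trace to
results/fitness_history.csv.
"""

import json
from pathlib import Path

import pandas as pd

from teacelm.datasets import Dataset
from teacelm.preprocessing import fit_normalizer, split
from teacelm.training import TrainerConfig, train

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    data = Dataset.from_csv(RESULTS / "dataset.csv")
    sp = split(data.n_samples, 0.75, seed=42)
    params = fit_normalizer(data)
    model, report = train(data, sp, params, TrainerConfig(seed=42))

    doc = model.to_dict()
    doc["normalization"] = {
        "feature_min": params.feature_min.tolist(),
        "feature_max": params.feature_max.tolist(),
        "target_min": params.target_min, "target_max": params.target_max,
        "scope": params.scope}
    doc["split_seed"] = 42
    (RESULTS / "model.json").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    pd.DataFrame({"iteration": range(len(report.fitness_history)),
                  "best_fitness": report.fitness_history}
                 ).to_csv(RESULTS / "fitness_history.csv", index=False)

    print(f"train rows {sp.n_train}, test rows {sp.n_test}")
    print(f"initial swarm best fitness {report.fitness_history[0]:.5f} "
          f"(normalized-scale RMSE)")
    print(f"final best fitness        {report.best_fitness:.5f} "
          f"after {len(report.fitness_history) - 1} iterations")
    print(f"model written to {RESULTS / 'model.json'}")
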