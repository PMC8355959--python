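"""Relevancy-factor sensitivity analysis of the composition variables.

The relevancy factor of each input is its Pearson correlation with the TEAC
target on the raw (unnormalized) data; the sign gives the direction of the
effect and the magnitude its strength. Writes results/sensitivity.csv.
"""

from pathlib import Path

import pandas as pd

from teacelm.datasets import Dataset
from teacelm.diagnostics import relevancy_factors

RESULTS = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    data = Dataset.from_csv(RESULTS / "dataset.csv")
    sens = relevancy_factors(data)
    table = pd.DataFrame({"feature": list(sens.relevancy),
                          "relevancy": list(sens.relevancy.values())})
    table.to_csv(RESULTS / "sensitivity.csv", index=False)
    print(table.round(3).to_string(index=False))
    print(f"\nstrongest effect: {sens.ranking_by_magnitude()[0]} "
          f"(r = {sens.relevancy[sens.ranking_by_magnitude()[0]]:.2f}); "
          f"only positive effect: "
          f"{sens.ranking_by_signed_effect()[0]} "
          f"(r = {sens.relevancy[sens.ranking_by_signed_effect()[0]]:.2f})")
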