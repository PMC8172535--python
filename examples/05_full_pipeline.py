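"""Run the complete pipeline on a simulated cohort.

simulate -> lesion loads -> NMF atoms -> design (volume correction,
covariates) -> sex-hierarchical posterior -> sex differences and
region-wise relevance maps, all written to a run directory with
provenance metadata.
"""

import tempfile
from pathlib import Path

import pandas as pd

import lesionatoms as la

config = {
    "simulate": {"n_patients": 400, "seed": 8,
                 "beta_female": [0.0] * 9 + [4.0],
                 "beta_male": [0.0] * 10},
    "embedding": {"n_atoms": 10, "seed": 0},
    "model": {"hierarchy": "by_sex", "draws": 2000, "seed": 2},
}

with tempfile.TemporaryDirectory() as tmp:
    out = la.run_pipeline(config, Path(tmp) / "run")
    print("artifacts:", ", ".join(sorted(p.name for p in out.iterdir())))

    diffs = pd.read_csv(out / "sex_differences.csv")
    flagged = diffs[diffs.flag]
    print("\nflagged sex differences (male minus female):")
    print(flagged.round(2).to_string(index=False))

    rel = pd.read_csv(out / "relevance_female.csv")
    top = rel.nlargest(5, "mean")[["parcel", "mean", "hpdi_low",
                                   "hpdi_high"]]
    print("\ntop region relevances in women (NIHSS units per unit "
          "score, back-projected):")
    print(top.round(2).to_string(index=False))

print("\nA planted female-only effect shows up as a negative flagged "
      "difference on (at least) one fitted atom, and the regions that "
      "atom spans carry the largest female relevance weights.")
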