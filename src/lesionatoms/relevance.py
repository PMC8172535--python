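"""Back-projection of atom-level posteriors to brain regions, cross-cohort
relevance comparison, and cohort summary tables.

An atom-level coefficient draw vector ``beta`` maps to parcel-level
relevance through the NMF basis: parcel ``j`` receives
``sum_k beta_k * W[k, j]`` per draw, so the full posterior (and its HPDI)
is available region-wise, not just a point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inference import hpdi

__all__ = ["RegionRelevance", "backproject_relevance", "compare_relevances",
           "cohort_summary_table"]


@dataclass
class RegionRelevance:
    """Posterior draws of parcel-wise relevance for one group."""

    draws: np.ndarray = field(repr=False)  # (n_draws, n_parcels)
    group: str = "all"
    parcel_names: list | None = None

    @property
    def means(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        rows = []
        for j in range(self.draws.shape[1]):
            lo, hi = hpdi(self.draws[:, j], mass)
            rows.append({
                "parcel": (self.parcel_names[j] if self.parcel_names
                           else j + 1),
                "group": self.group,
                "mean": float(self.draws[:, j].mean()),
                "hpdi_low": lo, "hpdi_high": hi,
                "relevant": not lo <= 0.0 <= hi,
            })
        return pd.DataFrame(rows)


def backproject_relevance(atom_draws: np.ndarray, basis: np.ndarray,
                          group: str = "all",
                          parcel_names: list | None = None
                          ) -> RegionRelevance:
    """Project atom-coefficient draws to parcel space through the basis.

    ``atom_draws`` is (n_draws, n_atoms), ``basis`` (n_atoms, n_parcels);
    the map is exactly linear per draw.
    """
    atom_draws = np.asarray(atom_draws, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if atom_draws.ndim != 2 or basis.ndim != 2:
        raise ValueError("atom_draws and basis must be 2-D")
    if atom_draws.shape[1] != basis.shape[0]:
        raise ValueError(
            f"atom dimension mismatch: draws have {atom_draws.shape[1]} "
            f"atoms, basis has {basis.shape[0]}")
    return RegionRelevance(draws=atom_draws @ basis, group=group,
                           parcel_names=parcel_names)


def compare_relevances(rel_a: RegionRelevance,
                       rel_b: RegionRelevance) -> dict:
    """Pearson correlation of parcel-wise posterior-mean relevances.

    Returns ``r`` and the two-sided p-value from the exact t transform.
    Constant mean vectors leave the correlation undefined and raise.
    """
    a, b = rel_a.means, rel_b.means
    if a.shape != b.shape:
        raise ValueError("relevance maps must share the parcel scheme")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant relevances")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p)}


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})"


def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q3 - q1:.1f})"


def cohort_summary_table(cohort: pd.DataFrame,
                         welch: bool = True) -> pd.DataFrame:
    """Patient-characteristics table with by-sex comparison p-values.

    Continuous variables are compared with a two-sample t test (Welch by
    default) and reported as mean (SD) — with median (IQR) added for
    NIHSS and lesion volume; binary variables with a two-sided Fisher
    exact test and reported as percentages.
    """
    if "sex" not in cohort.columns:
        raise ValueError("cohort needs a 'sex' column (female = 1)")
    women = cohort[cohort["sex"] == 1]
    men = cohort[cohort["sex"] == 0]
    if len(women) == 0 or len(men) == 0:
        raise ValueError("cohort must contain both sexes")

    continuous = [c for c in ("age", "nihss", "lesion_volume_ml",
                              "wmh_volume_ml") if c in cohort.columns]
    binary = [c for c in ("hypertension", "diabetes", "atrial_fibrillation",
                          "coronary_artery_disease") if c in cohort.columns]
    rows = []
    for var in continuous:
        w, m = women[var].to_numpy(float), men[var].to_numpy(float)
        _, p = stats.ttest_ind(w, m, equal_var=not welch)
        fmt = _fmt_mean_sd
        extra = ""
        if var in ("nihss", "lesion_volume_ml"):
            extra_all = f" (median(iqr): {_fmt_median_iqr(np.r_[w, m])})"
            extra = extra_all
        rows.append({
            "variable": var,
            "all": _fmt_mean_sd(np.r_[w, m]) + extra,
            "women": fmt(w), "men": fmt(m),
            "p_value": float(p), "test": "t",
        })
    for var in binary:
        w = women[var].to_numpy(int)
        m = men[var].to_numpy(int)
        table = [[int(w.sum()), int(len(w) - w.sum())],
                 [int(m.sum()), int(len(m) - m.sum())]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "variable": var,
            "all": f"{100 * np.r_[w, m].mean():.1f}%",
            "women": f"{100 * w.mean():.1f}%",
            "men": f"{100 * m.mean():.1f}%",
            "p_value": float(p), "test": "fisher",
        })
    return pd.DataFrame(rows)
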