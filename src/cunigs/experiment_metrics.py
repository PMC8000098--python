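"""Per-scenario experiment endpoints and summary tables.

For each replicate and genotyping strategy the experiment reports: mean
imputation accuracy and genotype yield, the accuracy of (g)EBVs (Pearson
correlation between EBV and true breeding value over the candidate does),
the accuracy gain over pedigree BLUP, the response to selection in trait
units (mean TBV of the EBV-top-n minus the cohort mean TBV), the
percentage of correctly selected animals (overlap between the EBV-top-n
and TBV-top-n sets) and the genotyping cost.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioOutcome",
    "gebv_accuracy",
    "selection_response",
    "percent_correctly_selected",
    "rank_top",
    "summarize",
]


@dataclass
class ScenarioOutcome:
    scenario_id: str
    replicate: int
    qtn_model: str
    mean_ia: float  # nan for the pedigree-only scenario
    mean_yield: float
    gebv_accuracy: float
    accuracy_vs_blup: float
    selection_response: float
    percent_correctly_selected: float
    cost_eur: float

    def __post_init__(self) -> None:
        if not np.isnan(self.gebv_accuracy) and not -1 <= self.gebv_accuracy <= 1:
            raise ValueError("accuracy must lie in [-1, 1]")
        if not 0 <= self.percent_correctly_selected <= 100:
            raise ValueError("percent correctly selected must lie in [0, 100]")
        if self.cost_eur < 0:
            raise ValueError("cost must be non-negative")


def gebv_accuracy(ebvs: np.ndarray, tbvs: np.ndarray) -> float:
    """Pearson correlation between estimated and true breeding values."""
    ebvs = np.asarray(ebvs, dtype=np.float64)
    tbvs = np.asarray(tbvs, dtype=np.float64)
    if ebvs.std() == 0 or tbvs.std() == 0:
        raise ValueError("zero variance in EBVs or TBVs: accuracy undefined")
    return float(np.corrcoef(ebvs, tbvs)[0, 1])


def rank_top(ids: list[int], values: dict[int, float], n: int) -> list[int]:
    """Top-n ids by value, ties broken by lower id."""
    if n > len(ids):
        raise ValueError(f"cannot take top {n} of {len(ids)} candidates")
    return sorted(ids, key=lambda i: (-values[i], i))[:n]


def selection_response(
    ids: list[int], ebvs: dict[int, float], tbvs: dict[int, float], n_selected: int = 150
) -> float:
    """Mean TBV of the EBV-selected top-n minus the cohort mean TBV (kits)."""
    selected = rank_top(ids, ebvs, n_selected)
    all_tbv = np.array([tbvs[i] for i in ids])
    sel_tbv = np.array([tbvs[i] for i in selected])
    return float(sel_tbv.mean() - all_tbv.mean())


def percent_correctly_selected(
    ids: list[int], ebvs: dict[int, float], tbvs: dict[int, float], n_selected: int = 150
) -> float:
    """100 x |top-n by EBV intersect top-n by TBV| / n."""
    by_ebv = set(rank_top(ids, ebvs, n_selected))
    by_tbv = set(rank_top(ids, tbvs, n_selected))
    return 100.0 * len(by_ebv & by_tbv) / n_selected


def summarize(outcomes: list[ScenarioOutcome] | pd.DataFrame) -> pd.DataFrame:
    """Per-scenario means with standard errors over replicates.

    Columns mirror the endpoint table of the experiment: selection response,
    %ACS, gEBV accuracy, accuracy gain over BLUP (with the fraction of
    replicates in which the scenario beats BLUP), imputation accuracy,
    genotype yield and cost.  SE columns are NaN for a single replicate.
    """
    df = outcomes if isinstance(outcomes, pd.DataFrame) else pd.DataFrame([asdict(o) for o in outcomes])
    if df.empty:
        raise ValueError("no outcomes to summarize")

    def se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    rows = []
    for (qtn, scen), grp in df.groupby(["qtn_model", "scenario_id"], sort=False):
        rows.append(
            {
                "qtn_model": qtn,
                "scenario_id": scen,
                "n_replicates": len(grp),
                "response": grp["selection_response"].mean(),
                "response_se": se(grp["selection_response"]),
                "pct_correctly_selected": grp["percent_correctly_selected"].mean(),
                "pct_correctly_selected_se": se(grp["percent_correctly_selected"]),
                "accuracy": grp["gebv_accuracy"].mean(),
                "accuracy_se": se(grp["gebv_accuracy"]),
                "delta_accuracy_vs_blup": grp["accuracy_vs_blup"].mean(),
                "frac_beats_blup": float((grp["accuracy_vs_blup"] > 0).mean()),
                "mean_ia": grp["mean_ia"].mean(),
                "mean_yield": grp["mean_yield"].mean(),
                "cost_eur": grp["cost_eur"].mean(),
            }
        )
    return pd.DataFrame(rows)
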