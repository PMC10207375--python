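"""Fragment-elaboration evaluation: the standardized ligand-efficiency gain.

A docked molecule's ligand efficiency (LE) is its docking score divided by
its heavy-atom count, compensating for the tendency of docking scores to
grow with molecular size.  For one (fragment, hotspot) pool — the generated
elaborations plus the ground-truth molecule the fragment was cut from — the
LEs are standardized to zero mean and unit variance, the standardized LEs
of the elaborations are sorted descending, and the mean of the top alpha
(default 20) minus the ground truth's standardized LE is the pool's
Delta-SLE_alpha.  Positive values mean the best elaborations improved on
the molecule the fragment came from.  Per hotspot, Delta-SLE_alpha is
averaged over the fragments successfully elaborated (those with at least
one elaboration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SCORE_TABLE_COLUMNS",
    "SleReport",
    "ligand_efficiency",
    "standardize_pool",
    "delta_sle",
    "hotspot_report",
    "validate_score_table",
    "QUASI_ACTIVE_THRESHOLDS",
]

SCORE_TABLE_COLUMNS = ("molecule_id", "fragment_id", "hotspot_rank",
                       "docking_score", "heavy_atoms", "is_ground_truth")

DEFAULT_ALPHA = 20

#: Quasi-active distance thresholds (Angstrom) applied upstream when
#: selecting docked elaborations that place a donor/acceptor near the
#: targeted hotspot: 2 A for pocket-point hotspots, 3 A for protein-atom
#: hotspots.  Recorded here as metadata for filtering score tables; the
#: docking and generation steps that apply them are external.
QUASI_ACTIVE_THRESHOLDS = {"pocket_point": 2.0, "protein_atom": 3.0}


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check columns, heavy-atom positivity, and one ground truth per pool."""
    missing = set(SCORE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("score table is empty")
    if (table["heavy_atoms"] < 1).any():
        raise ValueError("heavy_atoms must be >= 1")
    counts = table.groupby(["fragment_id", "hotspot_rank"],
                           sort=False)["is_ground_truth"].sum()
    bad = counts[counts != 1]
    if len(bad):
        raise ValueError("each (fragment, hotspot) pool needs exactly one "
                         f"ground-truth row; offending pools: "
                         f"{list(bad.index[:5])}")
    return table


def ligand_efficiency(score: float, heavy_atoms: int) -> float:
    """Docking score divided by heavy-atom count."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return score / heavy_atoms


def standardize_pool(les, population: bool = True) -> np.ndarray:
    """Shift/scale a pool of ligand efficiencies to mean 0, variance 1.

    Order is preserved.  Uses the population variance by default (a flag
    exposes the sample variance).  A zero-variance pool yields all zeros
    with a warning, so Delta-SLE degenerates to 0 rather than erroring.
    """
    values = np.asarray(les, dtype=float)
    if values.size < 2:
        raise ValueError("pool must contain at least 2 values")
    std = values.std(ddof=0 if population else 1)
    if std == 0:
        warnings.warn("zero-variance pool; standardized values set to 0")
        return np.zeros_like(values)
    return (values - values.mean()) / std


def delta_sle(pool: pd.DataFrame, alpha: int = DEFAULT_ALPHA,
              population: bool = True) -> float:
    """Delta-SLE_alpha for one (fragment, hotspot) pool of score-table rows.

    Computes LEs, standardizes the pooled elaborations + ground truth,
    sorts the elaborations' standardized values descending, takes the mean
    of the top min(alpha, count), and subtracts the ground truth's
    standardized value.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    gt_mask = pool["is_ground_truth"].astype(bool).to_numpy()
    if gt_mask.sum() != 1:
        raise ValueError("pool must contain exactly one ground-truth row")
    if (~gt_mask).sum() < 1:
        raise ValueError("pool has no elaboration rows")
    les = (pool["docking_score"] / pool["heavy_atoms"]).to_numpy(dtype=float)
    standardized = standardize_pool(les, population=population)
    elaborations = np.sort(standardized[~gt_mask])[::-1]
    top = elaborations[:min(alpha, elaborations.size)]
    return float(top.mean() - standardized[gt_mask][0])


@dataclass
class SleReport:
    per_pool: pd.DataFrame      # fragment_id, hotspot_rank, delta_sle, n_elaborations
    per_hotspot: pd.DataFrame   # hotspot_rank, mean_delta_sle, n_fragments_successful, mean_elaborations_per_fragment
    alpha: int


def hotspot_report(table: pd.DataFrame, alpha: int = DEFAULT_ALPHA,
                   population: bool = True) -> SleReport:
    """Delta-SLE_alpha per pool and its mean per hotspot.

    Hotspot means are computed only over fragments successfully elaborated
    (>= 1 elaboration row); a hotspot whose every pool is empty of
    elaborations is reported with n = 0 and a null mean.
    """
    validate_score_table(table)
    pool_rows = []
    for (fragment, hotspot), pool in table.groupby(
            ["fragment_id", "hotspot_rank"], sort=True):
        n_elab = int((~pool["is_ground_truth"].astype(bool)).sum())
        value = (delta_sle(pool, alpha=alpha, population=population)
                 if n_elab >= 1 else float("nan"))
        pool_rows.append({"fragment_id": fragment, "hotspot_rank": hotspot,
                          "delta_sle": value, "n_elaborations": n_elab})
    per_pool = pd.DataFrame(pool_rows)

    hotspot_rows = []
    for hotspot, group in per_pool.groupby("hotspot_rank", sort=True):
        success = group[group["n_elaborations"] >= 1]
        hotspot_rows.append({
            "hotspot_rank": hotspot,
            "mean_delta_sle": (float(success["delta_sle"].mean())
                               if len(success) else float("nan")),
            "n_fragments_successful": int(len(success)),
            "mean_elaborations_per_fragment": (
                float(success["n_elaborations"].mean())
                if len(success) else 0.0),
        })
    per_hotspot = pd.DataFrame(hotspot_rows)
    return SleReport(per_pool=per_pool, per_hotspot=per_hotspot, alpha=alpha)
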