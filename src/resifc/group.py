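"""Voxelwise group analysis: fatigue slope difference between conditions.

For one seed and one group, every retained run contributes one Fisher-z
map with a condition label, a run label, and the run's mean-centred
transformed fatigue score.  Per voxel the model

    z ~ condition + fatigue_c + condition:fatigue_c + run + (1 | subject)

is fitted by REML; the reported map is the condition-by-fatigue interaction
(the 2-back fatigue slope minus the 0-back fatigue slope), positive where
connectivity rises with fatigue more in the 2-back condition.  Groups are
always analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GridSpec
from .lme import RandomInterceptLME

__all__ = [
    "mean_center_by_group",
    "voxelwise_fatigue_lme",
    "contrast_sign_convention",
    "GroupStatMap",
]


def mean_center_by_group(run_fatigue: pd.DataFrame, column: str = "transformed") -> pd.DataFrame:
    """Subtract the within-group mean of the retained transformed scores.

    Adds a ``fatigue_c`` column; excluded runs keep NaN.  Idempotent up to
    floating error (centering centred values changes nothing).
    """
    if "group" not in run_fatigue.columns:
        raise ValueError("run_fatigue must carry a 'group' column")
    out = run_fatigue.copy()
    out["fatigue_c"] = np.nan
    for grp, sub in out.groupby("group"):
        retained = sub.loc[~sub["excluded"].astype(bool)]
        if retained.empty:
            raise ValueError(f"group {grp!r} has no retained runs")
        mean = retained[column].mean()
        out.loc[retained.index, "fatigue_c"] = retained[column] - mean
    return out


@dataclass
class GroupStatMap:
    seed_name: str
    group: str
    grid: GridSpec = field(repr=False)
    estimate: np.ndarray = field(repr=False)  # interaction slope, z units per fatigue unit
    tstat: np.ndarray = field(repr=False)
    df: np.ndarray = field(repr=False)
    pvalue: np.ndarray = field(repr=False)
    n_maps: int = 0
    n_subjects: int = 0
    singular_voxels: int = 0

    def signed_z(self) -> np.ndarray:
        return contrast_sign_convention(self)


def _build_group_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cond2 = (meta["condition"].to_numpy() == "2-back").astype(float)
    fat = meta["fatigue_c"].to_numpy(dtype=float)
    cols = {
        "Intercept": np.ones(len(meta)),
        "condition[2-back]": cond2,
        "fatigue_c": fat,
        "condition[2-back]:fatigue_c": cond2 * fat,
    }
    runs = sorted(meta["run_index"].unique())
    for r in runs[1:]:
        cols[f"run[{r}]"] = (meta["run_index"].to_numpy() == r).astype(float)
    names = list(cols)
    return np.column_stack(list(cols.values())), names


def voxelwise_fatigue_lme(
    zmaps,
    run_fatigue: pd.DataFrame,
    seed_name: str,
    group: str,
) -> GroupStatMap:
    """Fit the condition-by-fatigue mixed model at every voxel of one seed/group.

    ``zmaps`` is an iterable of :class:`~resifc.connectivity.ConnectivityMap`
    for one seed, restricted to subjects of ``group``; ``run_fatigue`` must
    carry ``fatigue_c`` (see :func:`mean_center_by_group`) and the exclusion
    flags.  Excluded runs are dropped before fitting.
    """
    zmaps = list(zmaps)
    if not zmaps:
        raise ValueError("no connectivity maps supplied")
    grid = zmaps[0].grid
    fat_lookup = {
        (r.subject_id, r.condition, r.run_index): r.fatigue_c
        for r in run_fatigue.itertuples()
        if not r.excluded and np.isfinite(r.fatigue_c)
    }
    rows, data = [], []
    for m in zmaps:
        key = (m.subject_id, m.condition, m.run_index)
        if key not in fat_lookup:
            continue  # excluded run
        rows.append(
            {
                "subject_id": m.subject_id,
                "condition": m.condition,
                "run_index": m.run_index,
                "fatigue_c": fat_lookup[key],
            }
        )
        data.append(m.zmap.reshape(-1))
    if not rows:
        raise ValueError("every supplied map was excluded by the zero-fatigue rule")
    meta = pd.DataFrame(rows)
    n_subjects = meta["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError(f"need >= 2 subjects, got {n_subjects}")
    Y = np.asarray(data)  # (n_maps, V)
    X, names = _build_group_design(meta)
    model = RandomInterceptLME(X, meta["subject_id"].to_numpy(), columns=names)
    fit = model.fit(Y, refine=False)
    c = np.zeros(len(names))
    c[names.index("condition[2-back]:fatigue_c")] = 1.0
    res = fit.contrast(c)
    return GroupStatMap(
        seed_name=seed_name,
        group=group,
        grid=grid,
        estimate=np.asarray(res.estimate).reshape(grid.shape),
        tstat=np.asarray(res.tstat).reshape(grid.shape),
        df=np.asarray(res.df).reshape(grid.shape),
        pvalue=np.asarray(res.pvalue).reshape(grid.shape),
        n_maps=len(meta),
        n_subjects=int(n_subjects),
        singular_voxels=int(fit.singular.sum()),
    )


def contrast_sign_convention(statmap: GroupStatMap) -> np.ndarray:
    """Signed Z-equivalent of the interaction test, table convention.

    Z carries the sign of the interaction estimate and reproduces the fit's
    two-sided p-value: |Z| = Phi^{-1}(1 - p/2).  Positive Z means
    connectivity increases with fatigue more in the 2-back condition.
    """
    p = np.clip(statmap.pvalue, 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0)
    return np.sign(statmap.estimate) * z
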