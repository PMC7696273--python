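"""Behavioral arm: run-level fatigue, Box-Cox, mixed models, post hocs.

Run-level fatigue is the mean of the VAS-F ratings taken before and after
each run; runs where both ratings are exactly zero are excluded (no
fatigue signal to correlate with).  Retained run means are Box-Cox
transformed (lambda maximizing the profile log-likelihood on [-2, 2],
estimated once on the pooled retained values).  Transformed fatigue and
task performance are analyzed with random-intercept linear mixed models
(REML, Satterthwaite df) and Tukey-adjusted pairwise post hocs via the
studentized-range distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .lme import RandomInterceptFit, RandomInterceptLME
from .synthetic import N_RATINGS, N_RUNS

__all__ = [
    "compute_run_fatigue",
    "boxcox",
    "BoxCoxResult",
    "add_transformed_fatigue",
    "fit_behavior_lme",
    "LmeFit",
    "pairwise_contrasts",
]


# ---------------------------------------------------------------------------
# run-level fatigue
# ---------------------------------------------------------------------------

def compute_run_fatigue(ratings: pd.DataFrame) -> pd.DataFrame:
    """Run-level fatigue table from the 5-rating VAS-F series.

    Run k (1..4) uses rating k-1 as the pre score and rating k as the post
    score; ``run_mean`` is their average and ``excluded`` flags runs where
    both are zero.
    """
    required = {"subject_id", "condition", "rating_index", "score"}
    missing_cols = required - set(ratings.columns)
    if missing_cols:
        raise ValueError(f"ratings table lacks columns {sorted(missing_cols)}")
    gaps = []
    rows = []
    keys = ["subject_id", "condition"] + (["group"] if "group" in ratings.columns else [])
    for key, sub in ratings.groupby(keys, sort=True):
        idx = set(sub["rating_index"])
        if idx != set(range(N_RATINGS)):
            gaps.append((key, sorted(set(range(N_RATINGS)) - idx)))
            continue
        scores = sub.sort_values("rating_index")["score"].to_numpy(dtype=float)
        for r in range(1, N_RUNS + 1):
            pre, post = scores[r - 1], scores[r]
            row = {
                "subject_id": key[0],
                "condition": key[1],
                "run_index": r,
                "pre_score": pre,
                "post_score": post,
                "run_mean": (pre + post) / 2.0,
                "excluded": bool(pre == 0.0 and post == 0.0),
            }
            if "group" in ratings.columns:
                row["group"] = key[2]
            rows.append(row)
    if gaps:
        raise ValueError(f"missing rating indices: {gaps}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxResult:
    lmbda: float
    transformed: np.ndarray = field(repr=False)
    loglik: float

    def transform(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("Box-Cox requires strictly positive values")
        return special.boxcox(values, self.lmbda)


LAMBDA_BOUNDS = (-2.0, 2.0)


def boxcox(values) -> BoxCoxResult:
    """Profile-likelihood Box-Cox over lambda in [-2, 2].

    Transform is (x^lambda - 1)/lambda, or log x at lambda = 0; strictly
    increasing in x for any lambda, so ordering is preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to estimate lambda")
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, values),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    return BoxCoxResult(lmbda=lam, transformed=special.boxcox(values, lam), loglik=float(-res.fun))


def add_transformed_fatigue(run_fatigue: pd.DataFrame) -> tuple[pd.DataFrame, BoxCoxResult]:
    """Box-Cox the retained run means (lambda pooled across groups/conditions).

    Adds a ``transformed`` column (NaN for excluded runs) and returns the
    fitted transform so the group analysis can reuse it.
    """
    out = run_fatigue.copy()
    retained = out.loc[~out["excluded"], "run_mean"].to_numpy(dtype=float)
    bc = boxcox(retained)
    out["transformed"] = np.nan
    out.loc[~out["excluded"], "transformed"] = bc.transformed
    return out, bc


# ---------------------------------------------------------------------------
# fixed-effects encoding
# ---------------------------------------------------------------------------

#: preferred reference levels so estimates read as "MS vs HC", "2-back vs 0-back"
_LEVEL_ORDER = {"group": ["HC", "MS"], "condition": ["0-back", "2-back"]}


@dataclass
class TermEncoder:
    """Treatment-coded full-factorial design from a ``a*b*c`` term spec."""

    variables: list[str]
    levels: dict[str, list]  # categorical levels, first is reference; covariates absent
    terms: list[tuple[str, ...]]

    @classmethod
    def from_spec(cls, spec: str, data: pd.DataFrame) -> "TermEncoder":
        variables = [v.strip() for v in spec.split("*")]
        levels: dict[str, list] = {}
        for v in variables:
            if v not in data.columns:
                raise ValueError(f"variable {v!r} not in table")
            if not pd.api.types.is_numeric_dtype(data[v]) or v == "run_index":
                obs = list(pd.unique(data[v].sort_values()))
                order = _LEVEL_ORDER.get(v)
                levels[v] = [l for l in order if l in obs] if order else obs
        terms: list[tuple[str, ...]] = [()]
        for r in range(1, len(variables) + 1):
            terms.extend(itertools.combinations(variables, r))
        return cls(variables=variables, levels=levels, terms=terms)

    def _columns_for_term(self, term: tuple[str, ...]) -> list[dict]:
        if not term:
            return [{"label": "Intercept", "parts": {}}]
        partlists = []
        for v in term:
            if v in self.levels:
                partlists.append([(v, lev) for lev in self.levels[v][1:]])
            else:
                partlists.append([(v, None)])
        out = []
        for combo in itertools.product(*partlists):
            label = ":".join(f"{v}[{lev}]" if lev is not None else v for v, lev in combo)
            out.append({"label": label, "parts": dict(combo)})
        return out

    def column_specs(self) -> list[dict]:
        return [c for term in self.terms for c in self._columns_for_term(term)]

    def encode(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(data)
        cols, names = [], []
        for spec in self.column_specs():
            col = np.ones(n)
            for v, lev in spec["parts"].items():
                if lev is None:
                    col = col * data[v].to_numpy(dtype=float)
                else:
                    col = col * (data[v].to_numpy() == lev).astype(float)
            cols.append(col)
            names.append(spec["label"])
        return np.column_stack(cols), names

    def reference_grid(self, covariate_values: dict[str, float] | None = None) -> pd.DataFrame:
        """Cartesian product of factor levels, covariates at fixed values."""
        covariate_values = covariate_values or {}
        factors = {v: self.levels[v] for v in self.variables if v in self.levels}
        rows = [dict(zip(factors, combo)) for combo in itertools.product(*factors.values())]
        grid = pd.DataFrame(rows if rows else [{}])
        for v in self.variables:
            if v not in self.levels:
                grid[v] = covariate_values.get(v, 0.0)
        return grid


# ---------------------------------------------------------------------------
# mixed-model fitting
# ---------------------------------------------------------------------------

@dataclass
class LmeFit:
    """A fitted behavioral mixed model with its encoder and data."""

    fit: RandomInterceptFit
    encoder: TermEncoder
    data: pd.DataFrame = field(repr=False)
    response: str
    formula: str
    singular: bool

    def summary(self) -> pd.DataFrame:
        return self.fit.fixed_effects()

    @property
    def sigma_u2(self) -> float:
        return float(self.fit.sigma_u2[0])

    @property
    def sigma_e2(self) -> float:
        return float(self.fit.sigma_e2[0])

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "response": self.response,
            "n_obs": int(len(self.data)),
            "n_subjects": int(self.data["subject_id"].nunique()),
            "singular": self.singular,
            "random_intercept_variance": self.sigma_u2,
            "residual_variance": self.sigma_e2,
            "fixed_effects": self.summary().to_dict(orient="records"),
        }


def fit_behavior_lme(
    table: pd.DataFrame,
    response: str,
    fixed: str = "group*condition*run_index",
) -> LmeFit:
    """REML random-intercept fit of ``response ~ fixed + (1 | subject)``.

    ``fixed`` is a ``*``-separated full factorial, e.g.
    ``"group*condition*run_index"`` or ``"group*condition*transformed"``;
    numeric variables enter as covariates.  Rows with a missing response or
    covariate (excluded runs) are dropped.
    """
    variables = [v.strip() for v in fixed.split("*")]
    cols = ["subject_id", response] + variables
    data = table.dropna(subset=[c for c in cols if c in table.columns]).copy()
    if "group" in data.columns:
        counts = data.groupby("group")["subject_id"].nunique()
        if (counts < 2).any():
            raise ValueError(f"need >= 2 subjects per group, got {counts.to_dict()}")
    encoder = TermEncoder.from_spec(fixed, data)
    X, names = encoder.encode(data)
    model = RandomInterceptLME(X, data["subject_id"].to_numpy(), columns=names)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rfit = model.fit(data[response].to_numpy(dtype=float))
    singular = bool(rfit.singular[0])
    if singular:
        warnings.warn(f"singular fit for response {response!r} (zero subject variance)", stacklevel=2)
    return LmeFit(
        fit=rfit,
        encoder=encoder,
        data=data,
        response=response,
        formula=f"{response} ~ {fixed} + (1 | subject_id)",
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Tukey post hocs
# ---------------------------------------------------------------------------

def _emm_rows(model: LmeFit, by: list[str], slopes_of: str | None) -> tuple[list[str], np.ndarray]:
    """Encoded contrast row (p,) for each level combination of ``by``.

    Rows are predictions averaged over the levels of the remaining factors
    (classic estimated-marginal-mean weighting, covariates at 0); with
    ``slopes_of`` they are d prediction / d covariate instead.
    """
    enc = model.encoder
    grid = enc.reference_grid()
    labels, rows = [], []
    combos = list(itertools.product(*[enc.levels[v] for v in by]))
    for combo in combos:
        sel = np.ones(len(grid), dtype=bool)
        for v, lev in zip(by, combo):
            sel &= (grid[v] == lev).to_numpy()
        sub = grid[sel]
        if slopes_of is None:
            row = enc.encode(sub)[0].mean(axis=0)
        else:
            hi = sub.copy()
            hi[slopes_of] = 1.0
            lo = sub.copy()
            lo[slopes_of] = 0.0
            row = (enc.encode(hi)[0] - enc.encode(lo)[0]).mean(axis=0)
        labels.append(", ".join(str(l) for l in combo))
        rows.append(row)
    return labels, np.asarray(rows)


def pairwise_contrasts(model: LmeFit, by: str, slopes_of: str | None = None) -> pd.DataFrame:
    """All pairwise Tukey-adjusted comparisons of marginal means (or slopes).

    ``by`` names one factor or a ``:``-joined combination (e.g.
    ``"group:condition"``).  With ``slopes_of`` set to a covariate name the
    comparisons are between the covariate's slopes at each ``by`` level.
    Adjustment uses the studentized-range distribution over the ``k``
    compared means with each contrast's Satterthwaite df.
    """
    by_vars = [v.strip() for v in by.split(":")]
    for v in by_vars:
        if v not in model.encoder.levels:
            raise ValueError(f"factor {v!r} is not in the fitted model")
    if slopes_of is not None and slopes_of in model.encoder.levels:
        raise ValueError(f"{slopes_of!r} is a factor, not a covariate")
    labels, rows = _emm_rows(model, by_vars, slopes_of)
    k = len(labels)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        c = rows[i] - rows[j]
        r = model.fit.contrast(c)
        tstat = float(r.tstat)
        df = float(r.df)
        p_tukey = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, df))
        out.append(
            {
                "contrast": f"({labels[i]}) - ({labels[j]})",
                "estimate": float(r.estimate),
                "se": float(r.se),
                "df": df,
                "tstat": tstat,
                "p_unadjusted": float(r.pvalue),
                "p_tukey": min(p_tukey, 1.0),
            }
        )
    return pd.DataFrame(out)
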