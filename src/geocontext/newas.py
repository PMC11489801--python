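"""Neighborhood Environment-Wide Association Study (NE-WAS) screen.

Many neighborhood measures, one binary outcome, no prior hypothesis: each
measure is standardized (z-score) and fit in its own univariable logistic
regression of the outcome; the Wald two-sided p-value gives the strength of
association as ``-log10 p``, and family-wise error over the ``m`` measures
actually tested is controlled by the Bonferroni threshold ``alpha / m``.

Standardization makes the reported coefficient a log-odds change per
standard deviation, so association strength is invariant to affine
rescaling of a measure (dollars vs thousands of dollars).

Degenerate cases are handled explicitly rather than producing spurious
output: constant measures and measures with fewer than ``min_n`` complete
cases are skipped with a recorded reason; complete separation (the measure
perfectly predicts the outcome) is flagged and the association strength is
capped at ``SEPARATION_CAP`` instead of diverging.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .errors import ValidationError

MIN_N = 10
SEPARATION_CAP = 300.0  # -log10 p cap reported for separated fits

RESULT_COLUMNS = [
    "measure",
    "n",
    "estimate",
    "std_err",
    "p_value",
    "assoc_strength",
    "rank",
    "bonferroni_significant",
    "separation",
    "skipped",
    "skip_reason",
]


def _fit_one(y: np.ndarray, z: np.ndarray):
    """Univariable logistic fit; returns (coef, se, p, separated)."""
    X = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:  # statsmodels signals separation in several ways
            if isinstance(exc, (PerfectSeparationWarning, np.linalg.LinAlgError)) or "eparation" in str(exc):
                return float("nan"), float("nan"), float("nan"), True
            raise
    coef, se = float(res.params[1]), float(res.bse[1])
    p = float(res.pvalues[1])
    # near-separation: the Wald statistic degenerates as the MLE diverges
    if not np.isfinite(p) or se > 1e3 or abs(coef) > 40:
        return coef, se, float("nan"), True
    return coef, se, p, False


def newas_screen(
    data: pd.DataFrame,
    outcome: str = "outcome",
    measures: list[str] | None = None,
    alpha: float = 0.05,
    min_n: int = MIN_N,
) -> pd.DataFrame:
    """Screen every measure column against the binary outcome.

    ``data`` holds one row per location with the outcome column (0/1) and
    one column per measure; missing values are handled complete-case per
    measure.  Returns one row per measure (skipped ones included, with a
    reason) ranked by association strength.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if outcome not in data.columns:
        raise ValidationError(f"outcome column {outcome!r} not in data")
    y_all = pd.to_numeric(data[outcome], errors="coerce")
    observed = set(y_all.dropna().unique())
    if not observed <= {0.0, 1.0}:
        raise ValidationError(f"outcome must be binary 0/1, saw values {sorted(observed)}")
    if len(observed) < 2:
        raise ValidationError("outcome is constant; no association can be estimated")

    if measures is None:
        measures = [c for c in data.columns if c not in (outcome, "location_id")]

    rows = []
    for name in measures:
        x = pd.to_numeric(data[name], errors="coerce")
        mask = x.notna() & y_all.notna()
        n = int(mask.sum())
        row = {
            "measure": name,
            "n": n,
            "estimate": float("nan"),
            "std_err": float("nan"),
            "p_value": float("nan"),
            "assoc_strength": float("nan"),
            "rank": pd.NA,
            "bonferroni_significant": False,
            "separation": False,
            "skipped": False,
            "skip_reason": "",
        }
        if n < min_n:
            row.update(skipped=True, skip_reason=f"fewer than {min_n} complete cases")
            rows.append(row)
            continue
        xv = x[mask].to_numpy(dtype=float)
        yv = y_all[mask].to_numpy(dtype=float)
        sd = xv.std(ddof=0)
        if sd == 0 or len(np.unique(xv)) < 2:
            row.update(skipped=True, skip_reason="constant")
            rows.append(row)
            continue
        if len(np.unique(yv)) < 2:
            row.update(skipped=True, skip_reason="outcome constant among complete cases")
            rows.append(row)
            continue
        z = (xv - xv.mean()) / sd
        coef, se, p, separated = _fit_one(yv, z)
        if separated:
            row.update(estimate=coef, std_err=se, separation=True, assoc_strength=SEPARATION_CAP,
                       p_value=10.0 ** (-SEPARATION_CAP))
        else:
            row.update(estimate=coef, std_err=se, p_value=p,
                       assoc_strength=float(-np.log10(max(p, 1e-300))))
        rows.append(row)

    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = ~out["skipped"]
    m = int(tested.sum())
    if m:
        threshold = alpha / m
        out.loc[tested, "bonferroni_significant"] = out.loc[tested, "p_value"] < threshold
        order = out.loc[tested, "assoc_strength"].rank(ascending=False, method="first")
        out.loc[tested, "rank"] = order.astype(int)
    out["rank"] = out["rank"].astype("Int64")
    out.attrs["m_tested"] = m
    out.attrs["alpha"] = alpha
    out.attrs["bonferroni_threshold"] = alpha / m if m else float("nan")
    return out


def manhattan_table(results: pd.DataFrame, meta: pd.DataFrame | dict | None = None) -> pd.DataFrame:
    """Plot-ready table: measures grouped by domain and count/proportion kind.

    ``meta`` maps measure name to ``domain`` and ``kind``; measures without
    metadata fall into an ``"other"`` group.  Rows are ordered by (group,
    original measure order) with a running ``x_index`` so any plotting front
    end can draw the Manhattan panel directly.
    """
    cols = ["x_index", "group", "domain", "kind", "measure", "assoc_strength", "bonferroni_significant"]
    if results is None or len(results) == 0:
        return pd.DataFrame(columns=cols)
    res = results[~results["skipped"]].copy() if "skipped" in results.columns else results.copy()
    if isinstance(meta, dict):
        meta = pd.DataFrame(
            [{"measure": k, **(v if isinstance(v, dict) else {"domain": v})} for k, v in meta.items()]
        )
    if meta is not None and len(meta):
        meta = meta.drop_duplicates("measure")
        res = res.merge(meta, on="measure", how="left")
    for col in ("domain", "kind"):
        if col not in res.columns:
            res[col] = "other"
        res[col] = res[col].fillna("other")
    res["group"] = res["domain"].astype(str) + " / " + res["kind"].astype(str)
    res["_orig"] = np.arange(len(res))
    res = res.sort_values(["group", "_orig"], kind="stable").reset_index(drop=True)
    res["x_index"] = np.arange(1, len(res) + 1)
    return res[cols]
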