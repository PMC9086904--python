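"""Screening rules, sleep-group classification, and partial correlations.

Eligibility and classification implement the study-style screening: subjects
with MMSE < 24, HAMA > 14, or HAMD > 17 are excluded; eligible ET subjects
with PSQI >= 6 are classified as the poor-sleep subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EligibilityRules:
    psqi_poor_sleep_min: int = 6
    mmse_exclude_below: int = 24
    hama_exclude_above: int = 14
    hamd_exclude_above: int = 17

    def __post_init__(self):
        if not (0 <= self.psqi_poor_sleep_min <= 21):
            raise ValueError("PSQI threshold outside instrument range 0-21")
        if not (0 <= self.mmse_exclude_below <= 30):
            raise ValueError("MMSE threshold outside instrument range 0-30")
        if self.hama_exclude_above < 0 or self.hamd_exclude_above < 0:
            raise ValueError("HAMA/HAMD thresholds must be non-negative")


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p_value: float
    n: int
    covariates: list


def _get_score(record, name: str) -> float:
    if isinstance(record, dict):
        value = record.get(name)
    elif isinstance(record, pd.Series):
        value = record.get(name)
    else:
        value = getattr(record, name, None)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"missing required score: {name}")
    return float(value)


def apply_eligibility(record, rules: EligibilityRules | None = None) -> tuple:
    """('include', None) or ('exclude', reason) for one subject record.

    Excludes iff MMSE < 24 (cognition), HAMA > 14 (anxiety), or HAMD > 17
    (depression); all three scores must be present.
    """
    rules = rules or EligibilityRules()
    mmse = _get_score(record, "MMSE")
    hama = _get_score(record, "HAMA")
    hamd = _get_score(record, "HAMD")
    if mmse < rules.mmse_exclude_below:
        return ("exclude", "cognition")
    if hama > rules.hama_exclude_above:
        return ("exclude", "anxiety")
    if hamd > rules.hamd_exclude_above:
        return ("exclude", "depression")
    return ("include", None)


def classify_sleep_group(psqi, rules: EligibilityRules | None = None) -> str:
    """'SleET' iff PSQI >= 6, else 'NorET'."""
    rules = rules or EligibilityRules()
    psqi = float(psqi)
    if not (0 <= psqi <= 21):
        raise ValueError(f"PSQI {psqi} outside instrument range 0-21")
    return "SleET" if psqi >= rules.psqi_poor_sleep_min else "NorET"


def encode_covariates(table: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Covariate matrix with sex encoded as a binary indicator."""
    cols = []
    for name in names:
        col = table[name]
        if name == "sex" or col.dtype == object:
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {name} has > 2 levels")
            cols.append((col.astype(str) == levels[-1]).astype(float).to_numpy())
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def partial_correlation(x, y, covariates=None, x_name: str = "x",
                        y_name: str = "y",
                        covariate_names: list | None = None) -> CorrelationResult:
    """Pearson correlation of x and y after residualizing on covariates.

    Both variables are regressed (least squares with intercept) on the
    covariate matrix; r is the correlation of the residuals and p comes from
    t = r * sqrt((n - k - 2) / (1 - r^2)) on n - k - 2 degrees of freedom,
    two-sided.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != x.size:
            raise ValueError("covariate rows must match x length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(cov))):
        raise ValueError("inputs must be finite")
    n, k = x.size, cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > covariates + 2, got n={n}, k={k}")

    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant residuals: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(x_name=x_name, y_name=y_name, r=r, p_value=p,
                             n=n, covariates=list(covariate_names or []))


def correlation_grid(table: pd.DataFrame, metric_values: dict,
                     clinical_vars: list[str],
                     covariate_names: list[str]) -> pd.DataFrame:
    """All (metric, clinical variable) partial correlations, uncorrected.

    ``metric_values``: name -> vector aligned with ``table`` rows. Rows with
    missing values in either member of a pair are dropped pairwise.
    """
    cov = encode_covariates(table, covariate_names)
    rows = []
    for m_name, m_vals in metric_values.items():
        m_vals = np.asarray(m_vals, dtype=float)
        for var in clinical_vars:
            v = table[var].to_numpy(dtype=float)
            ok = np.isfinite(m_vals) & np.isfinite(v)
            if cov.shape[1]:
                ok &= np.all(np.isfinite(cov), axis=1)
            if ok.sum() <= cov.shape[1] + 2:
                continue
            res = partial_correlation(m_vals[ok], v[ok], cov[ok],
                                      x_name=m_name, y_name=var,
                                      covariate_names=covariate_names)
            rows.append((m_name, var, res.r, res.p_value, res.n))
    return pd.DataFrame(rows, columns=["metric", "variable", "r", "p", "n"])
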