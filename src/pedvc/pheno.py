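"""Trait transformations, clinical derivations and descriptive epidemiology.

Covers the pre-modelling steps for a community renal study: log
transformation of skewed traits (urinary albumin:creatinine ratio, fasting
plasma glucose), albuminuria categories, MDRD-estimated glomerular
filtration rate, relative risks from 2x2 tables, and pairwise-complete
Pearson correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MICRO_LOW",
    "MACRO_LOW",
    "TwoByTwoTable",
    "log_transform",
    "classify_albuminuria",
    "egfr_mdrd",
    "relative_risk",
    "correlation_matrix",
    "fold_change_from_log10",
    "geometric_mean",
]

# albuminuria category thresholds in g/mol (UACR)
MICRO_LOW = 3.4
MACRO_LOW = 33.0


def log_transform(values, base10: bool = True, ids: Sequence | None = None):
    """Log-transform strictly positive trait values (base 10 by default).

    Base 10 is the package's convention for UACR and fasting glucose, so a
    model coefficient ``b`` converts to a multiplicative ``10**b``-fold
    effect on the raw scale.  Non-positive values raise, naming the
    offending ids when supplied.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0) & ~np.isnan(arr))
    if bad.size:
        labels = [ids[k] for k in bad] if ids is not None else bad.tolist()
        raise ValueError(f"non-positive values cannot be log-transformed: {labels}")
    out = np.log10(arr) if base10 else np.log(arr)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def geometric_mean(values) -> float:
    """exp10(mean(log10 x)): the scale Table-1-style UACR summaries use."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(10 ** np.mean(np.log10(arr)))


def classify_albuminuria(
    uacr, micro_low: float = MICRO_LOW, macro_low: float = MACRO_LOW
):
    """Categorise UACR (g/mol): < micro_low -> ``normo``; [micro_low,
    macro_low] -> ``micro``; > macro_low -> ``macro``.

    The macroalbuminuria cut defaults to 33 g/mol and is configurable.
    """
    arr = np.asarray(uacr, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("UACR must be positive")
    cats = np.where(arr < micro_low, "normo", np.where(arr > macro_low, "macro", "micro"))
    if np.isscalar(uacr) or arr.ndim == 0:
        return str(cats)
    if isinstance(uacr, pd.Series):
        return pd.Series(cats, index=uacr.index, name="albuminuria")
    return cats


def egfr_mdrd(serum_creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) by the re-expressed 4-variable MDRD
    equation.

    ``175 * (Scr/88.4)^-1.154 * age^-0.203 * (0.742 if female)`` with serum
    creatinine in umol/L (the /88.4 converts to mg/dL).  No ethnicity
    multiplier is applied.  ``sex`` is ``"male"``/``"female"`` (or an
    array of them).
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if np.any(~(scr > 0)) or np.any(~(age_arr > 0)):
        raise ValueError("creatinine and age must be positive")
    sex_arr = np.asarray(sex)
    female = sex_arr == "female"
    if sex_arr.dtype.kind not in "US":
        female = sex_arr == 0  # numeric coding: male=1, female=0
    egfr = 175.0 * (scr / 88.4) ** -1.154 * age_arr**-0.203
    egfr = egfr * np.where(female, 0.742, 1.0)
    if np.isscalar(serum_creatinine) and np.isscalar(age):
        return float(egfr)
    return egfr


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-outcome counts.

    ``a``: exposed with outcome;   ``b``: exposed without;
    ``c``: unexposed with outcome; ``d``: unexposed without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    def swap_reference(self) -> "TwoByTwoTable":
        """Exchange which group is the reference (exposed <-> unexposed)."""
        return TwoByTwoTable(self.c, self.d, self.a, self.b)


def relative_risk(table: TwoByTwoTable, ci_level: float = 0.95) -> dict:
    """Risk ratio with a log-scale Wald confidence interval.

    Swapping the reference group returns exactly the reciprocal RR.  A zero
    risk in the unexposed group makes the RR infinite and the CI undefined
    (flagged, not raised).
    """
    if table.n_exposed == 0 or table.n_unexposed == 0:
        raise ValueError("both exposure-group margins must be positive")
    risk1 = table.a / table.n_exposed
    risk0 = table.c / table.n_unexposed
    if risk0 == 0:
        return {
            "rr": float("inf"),
            "ci": (float("nan"), float("nan")),
            "ci_defined": False,
            "risk_exposed": risk1,
            "risk_unexposed": risk0,
        }
    rr = risk1 / risk0
    ci_defined = table.a > 0 and table.c > 0
    if ci_defined:
        from scipy.stats import norm

        se_log = np.sqrt(
            1 / table.a - 1 / table.n_exposed + 1 / table.c - 1 / table.n_unexposed
        )
        z = norm.ppf(0.5 + ci_level / 2.0)
        ci = (float(rr * np.exp(-z * se_log)), float(rr * np.exp(z * se_log)))
    else:
        ci = (float("nan"), float("nan"))
    return {
        "rr": float(rr),
        "ci": ci,
        "ci_defined": ci_defined,
        "risk_exposed": risk1,
        "risk_unexposed": risk0,
    }


def correlation_matrix(
    data, variables: Sequence[str], min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with the N behind each cell.

    Returns ``(r, n)``; cells with fewer than ``min_pairs`` complete pairs
    are NaN in ``r`` (the count matrix still reports the pairs seen).
    """
    from .vcmodel import _as_frame, _numeric_column

    df = _as_frame(data)
    cols = pd.concat([_numeric_column(df, v) for v in variables], axis=1)
    cols.columns = variables
    r = cols.corr(method="pearson", min_periods=min_pairs)
    notna = cols.notna().astype(int).to_numpy()
    n = pd.DataFrame(notna.T @ notna, index=variables, columns=variables)
    return r, n


def fold_change_from_log10(beta: float) -> float:
    """Multiplicative effect on the raw scale for a log10-scale coefficient."""
    if not np.isfinite(beta):
        raise ValueError("coefficient must be finite")
    return float(10.0**beta)
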