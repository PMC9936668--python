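"""Effect-size analysis: sum-of-squares variance partitioning and simple
linear regressions.

The variance explained by each stimulation factor (amplitude, intra-burst
frequency, mean pulse rate, their pairwise interactions, and animal) is
the factor's sum of squares divided by the corrected total sum of squares
(deviations from the grand mean), as a percentage; the residual is
reported as unaccounted variance.  Sequential (Type I) sums of squares
are used, which coincide with Types II/III on the balanced synthetic
designs this package generates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["variance_partition", "ols_fit", "DEFAULT_TERMS"]

#: Canonical term names and the factor columns they combine.
_TERM_FACTORS = {
    "amplitude": ("amplitude",),
    "frequency": ("intra_burst_frequency",),
    "mpr": ("mean_pulse_rate",),
    "amplitude:frequency": ("amplitude", "intra_burst_frequency"),
    "amplitude:mpr": ("amplitude", "mean_pulse_rate"),
    "frequency:mpr": ("intra_burst_frequency", "mean_pulse_rate"),
    "animal": ("animal",),
}

DEFAULT_TERMS = tuple(_TERM_FACTORS)


def variance_partition(
    table: pd.DataFrame,
    response: str,
    terms: tuple[str, ...] = DEFAULT_TERMS,
) -> pd.DataFrame:
    """Percent of total variance explained by each design term.

    Parameters
    ----------
    table : DataFrame
        One row per trial with the factor columns (``amplitude``,
        ``intra_burst_frequency``, ``mean_pulse_rate``, ``animal``) and
        the response.  Factors are treated as categorical.
    response : str
        Response column (e.g. ``hr_norm``, ``emg_norm``, ``effect_score``).
    terms : tuple of str
        Any of ``amplitude, frequency, mpr, amplitude:frequency,
        amplitude:mpr, frequency:mpr, animal``.

    Returns
    -------
    DataFrame with columns ``term``, ``ss``, ``percent``; the last row
    (``unaccounted``) is the residual.  Percentages sum to 100.
    """
    unknown = set(terms) - set(_TERM_FACTORS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    data = table.dropna(subset=[response]).copy()
    if data.empty:
        raise ValueError("no complete responses to analyse")

    kept = []
    for term in terms:
        factors = _TERM_FACTORS[term]
        if any(data[f].nunique() < 2 for f in factors):
            warnings.warn(
                f"term {term!r} has a single level and is excluded",
                stacklevel=2,
            )
            continue
        kept.append(term)

    rhs = " + ".join(
        ":".join(f"C(Q('{f}'))" for f in _TERM_FACTORS[t]) for t in kept
    )
    model = smf.ols(f"Q('{response}') ~ {rhs}", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=1)

    grand_ss = float(np.sum((data[response] - data[response].mean()) ** 2))
    rows = []
    for term, label in zip(
        kept, (idx for idx in anova.index if idx != "Residual")
    ):
        rows.append({"term": term, "ss": float(anova.loc[label, "sum_sq"])})
    rows.append(
        {"term": "unaccounted", "ss": float(anova.loc["Residual", "sum_sq"])}
    )
    out = pd.DataFrame(rows)
    out["percent"] = out["ss"] / grand_ss * 100.0
    return out


def ols_fit(x, y) -> dict:
    """Simple least-squares line fit with R^2 and the slope's p-value.

    Used to regress responses on the frequency statistics of random
    stimulation patterns.  The p-value is the F test of the line against
    the constant model (identical to the slope t test here).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_value": float(model.f_pvalue),
    }
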