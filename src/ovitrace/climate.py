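"""Per-breed climate summaries and climate-genetic correlation analysis.

Climate variables follow the bioclimatology convention for breeding-area
characterisation: Alti (altitude, m), m (mean minima of the coldest month,
degC), M (mean maxima of the hottest month, degC), R (annual rainfall,
mm), Tmax / Tmin (annual maxima / minima means, degC) and the pluviometric
coefficient Q3 = 3.43 R / (M - m), an aridity / vegetal-productivity
index (higher = wetter relative to thermal amplitude).

Before correlating with genetic diversity statistics, skewed variables
receive the stated transforms: square root for Alti, log10 for Tmax, M and
pi; test statistics (Tajima's D, Fu & Li's D*/F*, Fu's Fs, Shannon H') are
left untransformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "q3",
    "breed_climate_summary",
    "transform_variables",
    "climate_genetic_correlations",
]

CLIMATE_COLUMNS = ["Alti", "m", "M", "R", "Tmax", "Tmin"]
SQRT_VARS = ("Alti",)
LOG10_VARS = ("Tmax", "M", "pi")


def q3(R: float, M: float, m: float) -> float:
    """Pluviometric coefficient Q3 = 3.43 R / (M - m)."""
    if M == m:
        raise ValueError("Q3 undefined when M equals m")
    return 3.43 * R / (M - m)


def breed_climate_summary(localities: pd.DataFrame) -> pd.Series:
    """Mean climate parameters over a breed's recorded localities.

    ``localities`` has one row per locality with the standard climate
    columns; Q3 is computed from the mean R, M and m.
    """
    if localities.empty:
        raise ValueError("need at least one locality")
    means = localities[CLIMATE_COLUMNS].mean()
    means["Q3"] = q3(means["R"], means["M"], means["m"])
    return means


def transform_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the stated variable transforms column-wise.

    Square root for Alti, log10 for Tmax, M and pi; all other columns
    (including neutrality statistics and the Shannon index) pass through
    unchanged.  Raises on values outside the transform domain.
    """
    out = table.copy()
    for col in out.columns:
        if col in SQRT_VARS:
            if (out[col] < 0).any():
                raise ValueError(f"negative values in {col}: sqrt undefined")
            out[col] = np.sqrt(out[col].astype(float))
        elif col in LOG10_VARS:
            if (out[col] <= 0).any():
                raise ValueError(f"non-positive values in {col}: log10 undefined")
            out[col] = np.log10(out[col].astype(float))
    return out


def climate_genetic_correlations(
    climate: pd.DataFrame,
    genetics: pd.DataFrame,
    transform: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between climate and genetic variables.

    Rows of both tables are breeds (matched on index, >= 4 required).
    Returns a long-format table with r, two-sided p, a raw significance
    flag at ``alpha`` and a Benjamini-Hochberg flag across all pairs.
    Zero-variance columns are reported with NaN r (undefined).
    """
    common = climate.index.intersection(genetics.index)
    if len(common) < 4:
        raise ValueError("need at least four matched breeds")
    C = climate.loc[common]
    G = genetics.loc[common]
    if transform:
        C = transform_variables(C)
        G = transform_variables(G)
    rows = []
    for cv in C.columns:
        for gv in G.columns:
            x = C[cv].astype(float).to_numpy()
            y = G[gv].astype(float).to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((cv, gv, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append((cv, gv, r, p))
    table = pd.DataFrame(rows, columns=["climate", "genetic", "r", "p"])
    table["significant"] = table["p"] < alpha
    from statsmodels.stats.multitest import multipletests

    valid = table["p"].notna()
    flags = np.zeros(len(table), dtype=bool)
    if valid.any():
        flags[valid.to_numpy()] = multipletests(
            table.loc[valid, "p"], alpha=alpha, method="fdr_bh"
        )[0]
    table["significant_bh"] = flags
    return table
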