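"""Correlation of microbial features with host phenotypes.

Per-feature Pearson correlation against a named phenotype (e.g. plasma
cholesterol in mg/dl, fecal total SCFA in umol/g), with Benjamini-Hochberg
adjustment across the family of features tested in one call. Sample matching
is pairwise-complete: rows missing the phenotype are dropped per feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .indicator import bh_fdr
from .io import AbundanceTable

__all__ = ["pearson", "correlate_features", "PhenotypeCorrelator"]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("both vectors must have positive variance")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_features(features, phenotypes: pd.DataFrame,
                       phenotype: str) -> pd.DataFrame:
    """Pearson r of every feature against one phenotype, BH across features.

    ``features`` is an AbundanceTable or a samples x features DataFrame.
    Zero-variance features are flagged (``degenerate=True``) and excluded
    from the FDR family; their adjusted p is NaN.
    """
    feat = features.data if isinstance(features, AbundanceTable) else features
    if phenotype not in phenotypes.columns:
        raise KeyError(f"phenotype {phenotype!r} not in table")
    ph = phenotypes[phenotype]
    common = feat.index.intersection(ph.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between features and phenotypes")
    rows = []
    for name in feat.columns:
        pair = pd.DataFrame({"x": feat.loc[common, name],
                             "y": ph.loc[common]}).dropna()
        n = len(pair)
        if n < 3:
            raise ValueError(f"feature {name!r} has fewer than 3 paired samples")
        degenerate = pair["x"].nunique() == 1 or pair["y"].nunique() == 1
        if degenerate:
            rows.append({"feature": name, "phenotype": phenotype, "pearson_r": np.nan,
                         "p_value": np.nan, "n": n, "degenerate": True})
        else:
            r, p = pearson(pair["x"], pair["y"])
            rows.append({"feature": name, "phenotype": phenotype, "pearson_r": r,
                         "p_value": p, "n": n, "degenerate": False})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adjusted"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "p_adjusted"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    return out


class PhenotypeCorrelator(BaseEstimator):
    """Estimator interface for feature-phenotype correlation screening.

    Parameters
    ----------
    alpha : float
        Level used for the ``significant_`` flags on adjusted p-values.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : pandas.DataFrame
        Per-feature r, p, BH-adjusted p, n.
    significant_ : pandas.Index
        Features with adjusted p below ``alpha``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        """``X``: samples x features frame/AbundanceTable; ``y``: phenotype series."""
        feat = X.data if isinstance(X, AbundanceTable) else pd.DataFrame(X)
        ph = pd.DataFrame({"phenotype": pd.Series(np.asarray(y), index=feat.index)
                           if not isinstance(y, pd.Series) else y})
        self.results_ = correlate_features(feat, ph, "phenotype")
        sig = self.results_["p_adjusted"] < self.alpha
        self.significant_ = self.results_.index[sig.fillna(False)]
        return self
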