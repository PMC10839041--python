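"""Indicator-taxa classification via coded linear models.

The procedure asks, for each taxon, whether its abundance differs among the
three study groups (Kruskal-Wallis screen with Benjamini-Hochberg FDR) and,
if so, which treatment-response hypothesis best describes the pattern. Each
hypothesis is encoded as arbitrary units per group and scored by the Pearson
correlation between per-sample abundances and per-sample codes; the winning
model is the significant one with the largest effect size (r^2).

The six codings, for groups (control, disease, treatment):

====== ===================================================== ==============
model  interpretation                                        codes
====== ===================================================== ==============
1      treatment rescues beyond the control value            25 / 75 / 10
2      treatment restores the control value                  25 / 75 / 25
3      treatment partially restores the control value        25 / 75 / 50
4      treatment does not rescue the disease shift           25 / 75 / 75
5      treatment accentuates the disease shift               25 / 75 / 100
6      treatment alone induces a change                      100 / 100 / 10
====== ===================================================== ==============
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, StudyDesign

__all__ = [
    "CodedModel",
    "DEFAULT_MODELS",
    "ModelFit",
    "IndicatorResult",
    "bh_fdr",
    "screen_taxa",
    "fit_coded_models",
    "select_model",
    "classify_indicators",
    "IndicatorClassifier",
    "percent_change",
    "fb_ratio",
    "group_summary",
]


@dataclass(frozen=True)
class CodedModel:
    """A treatment-response hypothesis as arbitrary units per group role."""

    index: int
    label: str
    codes: tuple  # (control, disease, treatment)

    def code_samples(self, labels: np.ndarray, group_order: tuple) -> np.ndarray:
        mapping = dict(zip(group_order, self.codes))
        return np.array([mapping[g] for g in labels], dtype=float)


DEFAULT_MODELS: tuple[CodedModel, ...] = (
    CodedModel(1, "rescue beyond control", (25, 75, 10)),
    CodedModel(2, "return to control", (25, 75, 25)),
    CodedModel(3, "partial return to control", (25, 75, 50)),
    CodedModel(4, "no rescue", (25, 75, 75)),
    CodedModel(5, "accentuated disease effect", (25, 75, 100)),
    CodedModel(6, "treatment-only effect", (100, 100, 10)),
)


@dataclass(frozen=True)
class ModelFit:
    model_index: int
    pearson_r: float
    p_value: float
    effect_size: float  # r^2 of the coded fit


@dataclass(frozen=True)
class IndicatorResult:
    taxon: str
    kw_p: float
    kw_p_adjusted: float
    fits: tuple
    selected_model: int | None
    is_indicator: bool
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def screen_taxa(table: AbundanceTable, design: StudyDesign,
                alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis per taxon across the three groups, BH over all taxa.

    Returns a frame indexed by taxon with columns ``kw_p``, ``kw_p_adjusted``
    and ``passed`` (adjusted p < alpha). Taxa constant across all samples
    carry p = 1 and never pass.
    """
    from .diversity import kruskal_wallis

    labels = design.groups_of(table.sample_ids)
    sizes = design.group_sizes()
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    raw = np.array([kruskal_wallis(col, labels)[1] for col in table.values.T])
    adjusted = bh_fdr(raw)
    return pd.DataFrame(
        {"kw_p": raw, "kw_p_adjusted": adjusted, "passed": adjusted < alpha},
        index=pd.Index(table.taxon_ids, name="taxon"),
    )


def fit_coded_models(abundances, design: StudyDesign, sample_ids=None,
                     models: tuple = DEFAULT_MODELS) -> list[ModelFit]:
    """Pearson fit of one taxon's abundances against each model's codes.

    Codes are attached per sample, so unbalanced group sizes weight the
    correlation naturally. A zero-variance taxon has no defined correlation
    and is recorded as r = 0, p = 1, effect_size = 0.
    """
    x = np.asarray(abundances, dtype=float)
    if sample_ids is None:
        labels = design.assignments.to_numpy()
        if len(x) != len(labels):
            raise ValueError("abundances length does not match design")
    else:
        labels = design.groups_of(sample_ids)
    fits = []
    degenerate = np.ptp(x) == 0
    for model in models:
        codes = model.code_samples(labels, design.group_order)
        if degenerate or np.ptp(codes) == 0:
            fits.append(ModelFit(model.index, 0.0, 1.0, 0.0))
            continue
        r, p = scipy.stats.pearsonr(x, codes)
        fits.append(ModelFit(model.index, float(r), float(p), float(r * r)))
    return fits


def select_model(fits, alpha: float = 0.05) -> int | None:
    """Winning model: max effect size among significant fits; ties -> lowest index."""
    significant = [f for f in fits if f.p_value < alpha]
    if not significant:
        return None
    best = max(significant, key=lambda f: (f.effect_size, -f.model_index))
    return best.model_index


def group_summary(table: AbundanceTable, design: StudyDesign) -> pd.DataFrame:
    """Per-taxon per-group mean and SD of relative abundance (percent scale)."""
    labels = design.groups_of(table.sample_ids)
    frames = {}
    for g in design.group_order:
        sub = table.data.loc[labels == g] * 100.0
        frames[f"mean_{g}"] = sub.mean(axis=0)
        frames[f"sd_{g}"] = sub.std(axis=0, ddof=1)
    out = pd.DataFrame(frames)
    out.index.name = "taxon"
    return out


def classify_indicators(table: AbundanceTable, design: StudyDesign,
                        alpha: float = 0.05,
                        models: tuple = DEFAULT_MODELS) -> list[IndicatorResult]:
    """Full indicator procedure: screen, fit the six codings, select, classify.

    A taxon is an indicator iff its FDR-adjusted Kruskal-Wallis p is below
    ``alpha`` and at least one coded model fit has p below ``alpha``.
    Results follow the taxon order of the input table.
    """
    screen = screen_taxa(table, design, alpha=alpha)
    summary = group_summary(table, design)
    labels = design.groups_of(table.sample_ids)
    results = []
    for j, taxon in enumerate(table.taxon_ids):
        x = table.values[:, j]
        fits = fit_coded_models(x, design, sample_ids=table.sample_ids, models=models)
        passed = bool(screen.loc[taxon, "passed"])
        selected = select_model(fits, alpha=alpha) if passed else None
        is_indicator = passed and selected is not None
        results.append(IndicatorResult(
            taxon=taxon,
            kw_p=float(screen.loc[taxon, "kw_p"]),
            kw_p_adjusted=float(screen.loc[taxon, "kw_p_adjusted"]),
            fits=tuple(fits),
            selected_model=selected if is_indicator else None,
            is_indicator=is_indicator,
            group_means={g: float(summary.loc[taxon, f"mean_{g}"])
                         for g in design.group_order},
            group_sds={g: float(summary.loc[taxon, f"sd_{g}"])
                       for g in design.group_order},
        ))
    return results


def results_frame(results: list[IndicatorResult]) -> pd.DataFrame:
    """Tabular view of indicator results (one row per taxon)."""
    rows = []
    for r in results:
        row = {"taxon": r.taxon, "kw_p": r.kw_p, "kw_p_adjusted": r.kw_p_adjusted}
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        for g, s in r.group_sds.items():
            row[f"sd_{g}"] = s
        for f in r.fits:
            row[f"model{f.model_index}_r"] = f.pearson_r
            row[f"model{f.model_index}_p"] = f.p_value
        row["selected_model"] = r.selected_model
        row["is_indicator"] = r.is_indicator
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")


class IndicatorClassifier(BaseEstimator):
    """Estimator interface for the indicator-taxa procedure.

    Parameters
    ----------
    alpha : float
        Significance level for both the FDR-adjusted screen and the
        per-model fits.
    models : tuple of CodedModel
        Hypothesis codings; defaults to the six standard ones.
    group_order : tuple
        (control, disease, treatment) labels expected in ``y``.

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : list of IndicatorResult
    summary_ : pandas.DataFrame
        One row per taxon: screen p-values, per-model r and p, selection.
    indicator_taxa_ : list
        Taxa classified as indicators, in input column order.
    """

    def __init__(self, alpha: float = 0.05, models: tuple = DEFAULT_MODELS,
                 group_order: tuple = ("ND", "WD", "WD-T070")):
        self.alpha = alpha
        self.models = models
        self.group_order = group_order

    def fit(self, X, y):
        """Fit on a samples x taxa matrix ``X`` and group labels ``y``."""
        if isinstance(X, AbundanceTable):
            table = X
            sample_ids = table.sample_ids
        else:
            data = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
            total = data.to_numpy(dtype=float).sum(axis=1)
            rel = data.div(np.where(total == 0, 1, total), axis=0)
            table = AbundanceTable(data=rel, mode="relative")
            sample_ids = table.sample_ids
        if isinstance(y, StudyDesign):
            design = y
        else:
            labels = pd.Series(np.asarray(y), index=sample_ids)
            design = StudyDesign(assignments=labels, group_order=self.group_order)
        self.results_ = classify_indicators(table, design, alpha=self.alpha,
                                            models=self.models)
        self.summary_ = results_frame(self.results_)
        self.indicator_taxa_ = [r.taxon for r in self.results_ if r.is_indicator]
        self.n_features_in_ = len(table.taxon_ids)
        return self

    def predict(self, X=None):
        """Boolean indicator flag per taxon of the fitted table."""
        return self.summary_["is_indicator"].to_numpy()


def pairwise_tests(table: AbundanceTable, design: StudyDesign) -> pd.DataFrame:
    """Per-taxon two-group Kruskal-Wallis for each group pair, BH across taxa.

    With two groups the Kruskal-Wallis statistic is equivalent to a
    Mann-Whitney test. Adjustment is applied across taxa within each pair
    (the pairs themselves are not corrected against each other).
    """
    from .diversity import kruskal_wallis
    from .io import subset_groups

    order = design.group_order
    pairs = [(order[0], order[1]), (order[0], order[2]), (order[1], order[2])]
    out = pd.DataFrame(index=pd.Index(table.taxon_ids, name="taxon"))
    for g1, g2 in pairs:
        sub, labels = subset_groups(table, design, [g1, g2])
        raw = np.array([kruskal_wallis(col, labels.to_numpy())[1]
                        for col in sub.values.T])
        out[f"p_adj_{g1}_vs_{g2}"] = bh_fdr(raw)
    return out


def percent_change(mean_ref: float, mean_new: float) -> int:
    """Signed integer percent change, truncated toward zero.

    Truncation (not rounding) is the convention that reproduces the printed
    group-contrast percentages from table means.
    """
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return math.trunc(100.0 * (mean_new - mean_ref) / mean_ref)


def fb_ratio(table: AbundanceTable, design: StudyDesign,
             firmicutes: str = "Firmicutes",
             bacteroidetes: str = "Bacteroidetes") -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample Firmicutes/Bacteroidetes ratio and per-group mean +/- SD.

    The group summary is the mean of per-sample ratios, not the ratio of
    group means.
    """
    cols = {c.lower(): c for c in table.data.columns}
    try:
        f_col = cols[firmicutes.lower()]
        b_col = cols[bacteroidetes.lower()]
    except KeyError as e:
        raise KeyError(f"taxon {e.args[0]!r} not found in table") from None
    b = table.data[b_col]
    if (b <= 0).any():
        sid = b.index[int(np.argmax((b <= 0).to_numpy()))]
        raise ValueError(f"sample {sid!r} has zero Bacteroidetes abundance")
    ratio = table.data[f_col] / b
    ratio.name = "fb_ratio"
    labels = design.groups_of(table.sample_ids)
    rows = []
    for g in design.group_order:
        vals = ratio[labels == g]
        rows.append({"group": g, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "n": len(vals)})
    return ratio, pd.DataFrame(rows).set_index("group")
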