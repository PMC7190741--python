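"""Growth-promotion assay and extracellular-metabolome statistics.

Growth assays compare OD590 replicate measurements of a treated culture
against the untreated control with a two-sided Welch t test; significance is
reported with the two star levels used on the growth figures (p < 0.05 and
p < 0.001).  Metabolite time courses are summarized by per-compound fold
changes between timepoints and a one-way fixed-effects ANOVA across
timepoints ("accumulation"), both on raw intensities with uncorrected
p-values.  The heatmap ordering clusters z-scored compound profiles with Ward
linkage on (squared) Euclidean distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

#: Named fold-change comparisons (reference_h, target_h).  The
#: stationary-vs-exponential preset compares 24 h against the end of
#: exponential growth at 12 h.
FOLD_PRESETS = {"stationary_vs_exponential": (12.0, 24.0)}


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GrowthTestResult:
    statistic: float
    pvalue: float
    stars: str


def growth_test(treatment, control, equal_var: bool = True) -> GrowthTestResult:
    """Two-sided two-sample t test of treatment vs control OD replicates.

    With equal replicate counts the pooled and Welch statistics coincide;
    the pooled test (default) holds its nominal level exactly at triplicate
    sample sizes, where the Welch degrees-of-freedom correction is markedly
    conservative.  Pass ``equal_var=False`` for the Welch variant.

    Degenerate inputs with zero variance in both groups are handled by
    convention: equal means give p = 1, unequal means give p = 0 (logged).
    """
    t_arr = np.asarray(treatment, dtype=float)
    c_arr = np.asarray(control, dtype=float)
    if t_arr.size < 2 or c_arr.size < 2:
        raise ValueError("growth_test needs at least 2 replicates per group")
    if t_arr.std() == 0.0 and c_arr.std() == 0.0:
        if t_arr.mean() == c_arr.mean():
            return GrowthTestResult(0.0, 1.0, "")
        logger.info("zero variance in both groups with unequal means: p -> 0")
        sign = 1.0 if t_arr.mean() > c_arr.mean() else -1.0
        return GrowthTestResult(sign * float("inf"), 0.0, "***")
    res = stats.ttest_ind(t_arr, c_arr, equal_var=equal_var)
    return GrowthTestResult(float(res.statistic), float(res.pvalue),
                            significance_stars(float(res.pvalue)))


def assay_report(assay: pd.DataFrame, control: str = "control",
                 value_col: str = "od590") -> pd.DataFrame:
    """Welch tests of every condition against the control, per strain.

    ``assay`` is a long table with columns strain, condition, replicate and
    the OD value column.
    """
    rows = []
    for strain, sub in assay.groupby("strain", sort=True):
        ctrl = sub.loc[sub["condition"] == control, value_col].to_numpy()
        if ctrl.size < 2:
            raise ValueError(f"strain {strain!r}: control group needs >=2 replicates")
        for cond in sorted(set(sub["condition"]) - {control}):
            treat = sub.loc[sub["condition"] == cond, value_col].to_numpy()
            res = growth_test(treat, ctrl)
            rows.append({
                "strain": strain, "condition": cond,
                "mean_od": float(np.mean(treat)), "control_mean_od": float(np.mean(ctrl)),
                "statistic": res.statistic, "pvalue": res.pvalue, "stars": res.stars,
            })
    return pd.DataFrame(rows)


@dataclass
class MetaboliteProfile:
    """Compound x timepoint x replicate intensity tensor in long form.

    ``data`` has columns compound, timepoint_h, replicate, intensity.
    Timepoints must number at least two and every (compound, timepoint) cell
    must carry at least two replicates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound", "timepoint_h", "replicate", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metabolite table lacks columns {sorted(missing)}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        reps = self.data.groupby(["compound", "timepoint_h"])["replicate"].count()
        if (reps < 2).any():
            c, t = reps.index[int(np.argmax(reps.to_numpy() < 2))]
            raise ValueError(f"compound {c!r} at {t} h has fewer than 2 replicates")

    @property
    def compounds(self) -> list:
        return sorted(self.data["compound"].unique())

    @property
    def timepoints(self) -> list:
        return sorted(self.data["timepoint_h"].unique())

    def mean_matrix(self) -> pd.DataFrame:
        """Compound x timepoint matrix of replicate-mean intensities."""
        return (
            self.data.pivot_table(index="compound", columns="timepoint_h",
                                  values="intensity", aggfunc="mean")
            .sort_index()
        )

    @classmethod
    def from_tsv(cls, path) -> "MetaboliteProfile":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def fold_changes(profile: MetaboliteProfile, reference: float, target: float) -> pd.DataFrame:
    """Per-compound fold change: mean intensity at target / mean at reference.

    Compounds whose reference mean is zero get ``defined=False`` and NaN fold
    (excluded from any ranking) instead of an error.
    """
    means = profile.mean_matrix()
    for tp in (reference, target):
        if tp not in means.columns:
            raise ValueError(f"timepoint {tp} h not present in profile")
    ref = means[reference]
    tgt = means[target]
    defined = ref > 0
    if (~defined).any():
        logger.warning("%d compound(s) have zero reference mean: fold undefined",
                       int((~defined).sum()))
    fold = np.where(defined, tgt / ref.where(defined, np.nan), np.nan)
    return pd.DataFrame({"fold": fold, "defined": defined.to_numpy()}, index=means.index)


def accumulation_pvalues(profile: MetaboliteProfile) -> pd.Series:
    """One-way fixed-effects ANOVA p-value across timepoints, per compound.

    Compounds with zero variance (constant intensities) are never significant
    (p = 1 by convention).
    """
    pvals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for compound, sub in profile.data.groupby("compound", sort=True):
            groups = [g["intensity"].to_numpy(dtype=float)
                      for _, g in sub.groupby("timepoint_h", sort=True)]
            flat = np.concatenate(groups)
            if np.ptp(flat) == 0.0:
                pvals[compound] = 1.0
                continue
            p = stats.f_oneway(*groups).pvalue
            pvals[compound] = 1.0 if np.isnan(p) else float(p)
    return pd.Series(pvals, name="pvalue").sort_index()


def accumulation_filter(profile: MetaboliteProfile, alpha: float = 0.05) -> set:
    """Compounds significantly accumulated/depleted across timepoints (p < alpha).

    No multiplicity correction is applied by default (raw per-compound
    p-values).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    pvals = accumulation_pvalues(profile)
    return set(pvals.index[pvals < alpha])


def accumulation_report(
    profile: MetaboliteProfile,
    reference: float,
    target: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fold change plus across-timepoint ANOVA p per compound, one table."""
    folds = fold_changes(profile, reference, target)
    pvals = accumulation_pvalues(profile)
    out = folds.join(pvals)
    out["significant"] = out["pvalue"] < alpha
    return out


def _zscore_rows(matrix: pd.DataFrame) -> tuple:
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    scaled = (values - mean) / sd
    scaled[constant] = 0.0
    return scaled, constant


def cluster_order(matrix: pd.DataFrame) -> tuple:
    """Deterministic heatmap leaf orders for a compound x timepoint matrix.

    Rows are z-scored per compound, then rows and columns are clustered by
    agglomerative hierarchical clustering with Ward linkage on Euclidean
    distances (merge criteria equivalent to squared-Euclidean "d2"
    minimum-variance clustering).  Constant rows are scaled to zeros, warned
    about, and placed last in the row order.
    """
    row_z, col_z, scaled, constant = cluster_linkages(matrix)
    variable_rows = matrix.index[~constant]
    if row_z is None:
        row_order = list(variable_rows)
    else:
        row_order = [variable_rows[i] for i in hierarchy.leaves_list(row_z)]
    row_order += [r for r in matrix.index[constant]]
    if col_z is None:
        col_order = list(matrix.columns)
    else:
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_z)]
    return row_order, col_order


def cluster_linkages(matrix: pd.DataFrame):
    """Ward linkage matrices behind :func:`cluster_order`.

    Returns ``(row_linkage, col_linkage, scaled_rows, constant_row_mask)``;
    a linkage is None when fewer than two items are available for clustering.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("matrix must be finite")
    scaled, constant = _zscore_rows(matrix)
    if constant.any():
        logger.warning("%d constant row(s) scaled to zeros and ordered last",
                       int(constant.sum()))
    variable = scaled[~constant]
    row_z = hierarchy.linkage(variable, method="ward") if variable.shape[0] >= 2 else None
    col_z = hierarchy.linkage(scaled.T, method="ward") if scaled.shape[1] >= 2 else None
    return row_z, col_z, scaled, constant
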