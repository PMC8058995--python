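"""Cross-library normalization, ANOVA differential expression, clustering,
and the 2^-ddCt qPCR utility.

Normalization follows a median-reference regression scheme: a reference
profile is the per-sequence median copy number over the sequences common
to (nonzero in) all samples; each sample's log2 counts are regressed on
the reference log2 counts over the subset with |delta log2| < 2, and the
fitted line is inverted (subtract intercept, divide by slope) to give the
sample's expected log2 copy numbers.  Differential expression is a
per-miRNA one-way ANOVA across stages on the expected log2 scale, with
raw p <= 0.05 as the significance rule (BH-adjusted q-values are reported
alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform


@dataclass
class NormalizationFit:
    sample: str
    intercept: float
    slope: float
    subset_size: int
    flagged: bool  # subset smaller than 10 or degenerate fit


def build_reference_profile(counts: pd.DataFrame) -> pd.Series:
    """Per-sequence median copy number over sequences nonzero in all samples."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to build a reference")
    common = counts.index[(counts > 0).all(axis=1)]
    if len(common) == 0:
        raise ValueError("no common (all-sample nonzero) sequences; "
                         "cannot build a reference profile")
    return counts.loc[common].median(axis=1)


def normalize_library(
    sample_counts: pd.Series,
    reference: pd.Series,
    pseudocount: float = 1.0,
    max_abs_delta: float = 2.0,
    sample_name: str = "sample",
    mean_offset_only: bool = False,
) -> tuple[pd.Series, NormalizationFit]:
    """Expected log2 copy numbers for one sample against the reference.

    OLS of log2(sample) on log2(reference) over the |delta log2| <
    ``max_abs_delta`` subset of reference sequences; every sequence is then
    corrected as (log2(observed) - intercept) / slope.  With
    ``mean_offset_only`` the slope is fixed at 1 and only the mean offset
    is removed (sensitivity variant).
    """
    common = reference.index.intersection(sample_counts.index)
    logref = np.log2(reference.loc[common] + pseudocount)
    logobs = np.log2(sample_counts.loc[common] + pseudocount)
    delta = logobs - logref
    subset = delta.abs() < max_abs_delta
    nsub = int(subset.sum())
    flagged = nsub < 10
    if nsub < 2:
        # a uniform shift of exactly max_abs_delta empties the subset;
        # fall back to fitting on every common sequence
        warnings.warn(f"{sample_name}: fewer than 2 sequences inside "
                      f"|delta log2| < {max_abs_delta}; fitting on all "
                      "common sequences")
        subset = pd.Series(True, index=delta.index)
        nsub = int(subset.sum())

    if nsub < 2 or np.isclose(logref[subset].var(), 0):
        warnings.warn(f"{sample_name}: degenerate normalization fit; "
                      "applying identity correction")
        a, b, flagged = 0.0, 1.0, True
    elif mean_offset_only:
        a, b = float(delta[subset].mean()), 1.0
    else:
        x = logref[subset].to_numpy()
        y = logobs[subset].to_numpy()
        b = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
        a = float(y.mean() - b * x.mean())

    expected = (np.log2(sample_counts + pseudocount) - a) / b
    return expected, NormalizationFit(sample_name, a, b, nsub, flagged)


def normalize_matrix(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    max_abs_delta: float = 2.0,
    mean_offset_only: bool = False,
) -> tuple[pd.DataFrame, list[NormalizationFit]]:
    """Normalize every sample column against the median reference."""
    reference = build_reference_profile(counts)
    cols, fits = {}, []
    for sample in counts.columns:
        expected, fit = normalize_library(
            counts[sample], reference, pseudocount, max_abs_delta,
            sample_name=str(sample), mean_offset_only=mean_offset_only,
        )
        cols[sample] = expected
        fits.append(fit)
    return pd.DataFrame(cols), fits


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Textbook one-way fixed-effects ANOVA: (F, p).

    Zero between- and within-group variance gives p = 1 by convention.
    """
    labels = np.unique(groups)
    n = len(values)
    k = len(labels)
    grand = values.mean()
    ssb = ssw = 0.0
    for g in labels:
        v = values[groups == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    dfb, dfw = k - 1, n - k
    if ssw <= 0 and ssb <= 0:
        return 0.0, 1.0
    if ssw <= 0:
        return np.inf, 0.0
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), float(stats.f.sf(F, dfb, dfw))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return stats.false_discovery_control(p, method="bh")


def anova_de(
    expr: pd.DataFrame,
    design: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA one-way ANOVA across stages on the expected log2 matrix.

    ``design`` maps sample column -> stage label.  Returns a table with
    stage means, F, p, BH q and the raw-p significance flag.
    """
    stages = [design[c] for c in expr.columns]
    stage_labels = list(dict.fromkeys(stages))
    if len(stage_labels) < 2:
        raise ValueError("need at least 2 stages for differential expression")
    counts_per_stage = pd.Series(stages).value_counts()
    if (counts_per_stage < 2).any():
        raise ValueError("need at least 2 replicates per stage")

    groups = np.array(stages)
    rows = []
    for mirna, vals in expr.iterrows():
        v = vals.to_numpy(float)
        F, p = one_way_anova(v, groups)
        means = [v[groups == s].mean() for s in stage_labels]
        rows.append([mirna, *means, F, p])
    out = pd.DataFrame(
        rows, columns=["mirna", *[f"mean_{s}" for s in stage_labels], "F", "p"]
    ).set_index("mirna")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] <= alpha
    return out


def hierarchical_cluster(
    stage_means: pd.DataFrame, k: int = 3
) -> tuple[list, pd.Series]:
    """Average-linkage clustering of z-scored stage means, correlation distance.

    Returns (leaf order, profile class per miRNA, 1..k).  Rows with zero
    variance get z-score 0 and cluster together.
    """
    X = stage_means.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n = len(Z)
    if n < 2:
        return list(stage_means.index), pd.Series(1, index=stage_means.index)
    C = np.corrcoef(Z)
    C = np.nan_to_num(C, nan=0.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    link = average(squareform(D, checks=False))
    order = [stage_means.index[i] for i in leaves_list(link)]
    classes = fcluster(link, t=min(k, n), criterion="maxclust")
    return order, pd.Series(classes, index=stage_means.index, name="profile_class")


def ddct(
    ct: pd.DataFrame,
    reference_genes,
    calibrator_sample: str,
    design: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` is gene x sample Ct values.  dCt = Ct_target - mean Ct of the
    reference genes per sample; ddCt subtracts the calibrator's dCt
    (``calibrator_sample`` is a sample column, or a stage label if
    ``design`` maps samples to stages, in which case the calibrator dCt is
    the mean over that stage's samples).  The calibrator column of the
    result is exactly 1 for every target.
    """
    reference_genes = list(reference_genes)
    missing = [g for g in reference_genes if g not in ct.index]
    if missing:
        raise ValueError(f"reference genes not in Ct table: {missing}")
    ref_ct = ct.loc[reference_genes].mean(axis=0)
    dct = ct.drop(index=reference_genes).sub(ref_ct, axis=1)
    if calibrator_sample in dct.columns:
        cal = dct[calibrator_sample]
    elif design is not None:
        cal_samples = [s for s in dct.columns if design.get(s) == calibrator_sample]
        if not cal_samples:
            raise ValueError(f"no samples for calibrator {calibrator_sample!r}")
        cal = dct[cal_samples].mean(axis=1)
    else:
        raise ValueError(f"calibrator {calibrator_sample!r} not found")
    ddct_ = dct.sub(cal, axis=0)
    return 2.0 ** (-ddct_)
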