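"""ROI quantification, time courses, control normalization and group statistics.

The statistical unit is the per-sample (per-organ / per-ROI) mean ratio.
Two-group comparisons use Student's t when both groups pass Shapiro-Wilk
normality at alpha, otherwise Mann-Whitney.  Multi-group comparisons test
normality per group and variance homogeneity with Levene, apply a Box-Cox
transform when either is violated, then run one-way ANOVA with two-sided
Dunnett many-to-one comparisons against the named control group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .image_io import AcquisitionSet, LabelMask
from .unmixing import FretMap, MixingMatrix, compute_fret_map, unmix_image

__all__ = [
    "RoiRecord",
    "GroupComparison",
    "Trajectory",
    "quantify_rois",
    "normalize_to_control",
    "compare_two_groups",
    "compare_multi",
    "timecourse",
]

#: alpha used for the Shapiro-Wilk / Levene branch decisions
ASSUMPTION_ALPHA = 0.05

#: Box-Cox lambda grid searched by maximum likelihood
_BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


@dataclass
class RoiRecord:
    roi_id: int
    n_valid: int
    mean_ratio: float
    sd_ratio: float

    def __post_init__(self) -> None:
        if self.roi_id <= 0:
            raise ValueError("roi_id must be positive")
        if self.n_valid < 1:
            raise ValueError("reported ROIs must have >= 1 valid pixel")
        if self.sd_ratio < 0:
            raise ValueError("sd_ratio must be non-negative")


@dataclass
class GroupComparison:
    test_name: str  # student_t | mann_whitney | anova_dunnett
    transform: str  # none | box_cox
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    variance_homogeneity_p: float | None = None
    comparisons: dict[str, float] | None = None  # Dunnett-adjusted p per group vs control
    boxcox_lambda: float | None = None
    boxcox_shift: float = 0.0
    assumptions_met: bool = True

    def __post_init__(self) -> None:
        if self.test_name not in ("student_t", "mann_whitney", "anova_dunnett"):
            raise ValueError(f"unknown test {self.test_name!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class Trajectory:
    time_indices: list[int]
    mean_ratios: list[float]
    n_valid_per_frame: list[int]

    def __post_init__(self) -> None:
        if not len(self.time_indices) == len(self.mean_ratios) == len(self.n_valid_per_frame):
            raise ValueError("trajectory columns must have equal length")
        if any(b <= a for a, b in zip(self.time_indices, self.time_indices[1:])):
            raise ValueError("time indices must be strictly increasing")


def quantify_rois(fret_map: FretMap, mask: LabelMask) -> list[RoiRecord]:
    """Mean and SD of the ratio over valid pixels of every ROI in the mask.

    ROIs without a single valid pixel are omitted with a warning.
    """
    if mask.shape != fret_map.shape:
        raise ValueError("mask dimensions must match the FRET map")
    roi_ids = mask.roi_ids()
    if roi_ids.size == 0:
        raise ValueError("mask contains no ROIs")
    records = []
    for roi in roi_ids:
        sel = (mask.labels == roi) & fret_map.valid
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"ROI {roi} has no valid pixels; omitted", stacklevel=2)
            continue
        values = fret_map.ratio[sel]
        sd = float(values.std(ddof=1)) if n > 1 else 0.0
        records.append(RoiRecord(roi_id=int(roi), n_valid=n, mean_ratio=float(values.mean()), sd_ratio=sd))
    return records


def normalize_to_control(values, control_mean: float):
    """Divide values (array or RoiRecord list) by the control-group mean."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    if isinstance(values, (list, tuple)) and values and isinstance(values[0], RoiRecord):
        return [
            RoiRecord(
                roi_id=r.roi_id,
                n_valid=r.n_valid,
                mean_ratio=r.mean_ratio / control_mean,
                sd_ratio=r.sd_ratio / control_mean,
            )
            for r in values
        ]
    return np.asarray(values, dtype=float) / control_mean


def _shapiro_p(values: np.ndarray) -> float | None:
    """Shapiro-Wilk p, or None when undefined (constant sample)."""
    if np.ptp(values) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(scipy.stats.shapiro(values).pvalue)


def compare_two_groups(a, b, alpha: float = ASSUMPTION_ALPHA) -> GroupComparison:
    """Two-condition comparison with normality-gated test choice.

    Shapiro-Wilk on each group; when both pass at ``alpha`` a two-sample
    Student's t-test (equal variances) is used, otherwise the two-sided
    Mann-Whitney test.  Constant groups, for which normality testing is
    undefined, fall through to Mann-Whitney with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    p_a, p_b = _shapiro_p(a), _shapiro_p(b)
    normality = {"a": np.nan if p_a is None else p_a, "b": np.nan if p_b is None else p_b}
    if p_a is None or p_b is None:
        warnings.warn("constant group: normality test undefined, using Mann-Whitney", stacklevel=2)
        both_normal = False
    else:
        both_normal = p_a > alpha and p_b > alpha
    if both_normal:
        res = scipy.stats.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    return GroupComparison(
        test_name=name,
        transform="none",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=normality,
    )


def _boxcox_mle_lambda(groups: list[np.ndarray]) -> float:
    """Lambda on a fixed grid maximizing the summed per-group Box-Cox
    log-likelihood (shared transform keeps groups comparable)."""
    best_lmbda, best_llf = 0.0, -np.inf
    for lmbda in _BOXCOX_GRID:
        llf = sum(float(scipy.stats.boxcox_llf(lmbda, g)) for g in groups)
        if llf > best_llf:
            best_llf, best_lmbda = llf, float(lmbda)
    return best_lmbda


def _boxcox_transform(groups: list[np.ndarray]) -> tuple[list[np.ndarray], float, float]:
    pooled_min = min(float(g.min()) for g in groups)
    shift = 0.0 if pooled_min > 0 else 1.0 - pooled_min
    shifted = [g + shift for g in groups]
    lmbda = _boxcox_mle_lambda(shifted)
    transformed = [scipy.stats.boxcox(g, lmbda=lmbda) for g in shifted]
    return transformed, lmbda, shift


def _assumptions_ok(groups: list[np.ndarray], alpha: float) -> tuple[bool, dict[str, float], float]:
    normality, ok = {}, True
    for i, g in enumerate(groups):
        p = _shapiro_p(g)
        normality[str(i)] = np.nan if p is None else p
        if p is None or p <= alpha:
            ok = False
    levene_p = float(scipy.stats.levene(*groups).pvalue)
    return ok and levene_p > alpha, normality, levene_p


def compare_multi(
    groups: dict[str, "np.ndarray | list[float]"],
    control_name: str,
    alpha: float = ASSUMPTION_ALPHA,
    random_state: int | None = 0,
) -> GroupComparison:
    """One-way ANOVA with two-sided Dunnett many-to-one comparisons.

    Normality (Shapiro-Wilk per group) and variance homogeneity (Levene)
    are tested first; on violation a shared maximum-likelihood Box-Cox
    transform (data shifted positive if needed, shift recorded) is applied
    and the assumptions retested — persistent violation is flagged and the
    analysis proceeds with a warning.  Dunnett adjusted p-values come from
    the multivariate-t formulation.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use compare_two_groups for two conditions")
    if control_name not in groups:
        raise ValueError(f"control group {control_name!r} not found")
    names = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 3:
            raise ValueError(f"group {k!r} needs n >= 3")

    ordered = [data[k] for k in names]
    ok, _, levene_p = _assumptions_ok(ordered, alpha)
    transform, lmbda, shift = "none", None, 0.0
    if not ok:
        ordered, lmbda, shift = _boxcox_transform(ordered)
        transform = "box_cox"
        ok, _, levene_p = _assumptions_ok(ordered, alpha)
        if not ok:
            warnings.warn(
                "normality/homoscedasticity still violated after Box-Cox; proceeding",
                stacklevel=2,
            )
    normality = {}
    for name, g in zip(names, ordered):
        p = _shapiro_p(g)
        normality[name] = np.nan if p is None else p

    transformed = dict(zip(names, ordered))
    anova = scipy.stats.f_oneway(*ordered)
    treat_names = [n for n in names if n != control_name]
    dunnett = scipy.stats.dunnett(
        *[transformed[n] for n in treat_names],
        control=transformed[control_name],
        alternative="two-sided",
        random_state=random_state,
    )
    comparisons = {n: float(p) for n, p in zip(treat_names, dunnett.pvalue)}
    return GroupComparison(
        test_name="anova_dunnett",
        transform=transform,
        statistic=float(anova.statistic),
        p_value=min(comparisons.values()),
        normality_p=normality,
        variance_homogeneity_p=levene_p,
        comparisons=comparisons,
        boxcox_lambda=lmbda,
        boxcox_shift=shift,
        assumptions_met=ok,
    )


def timecourse(
    series: list[AcquisitionSet],
    M: MixingMatrix,
    mask: LabelMask,
    min_intensity: float = 10.0,
    nonneg: str = "nnls",
) -> Trajectory:
    """Mean valid ratio inside the mask for every frame of an ordered series.

    Frames without any valid pixel record NaN with n_valid 0.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 frames")
    shape = series[0].shape
    times, means, counts = [], [], []
    for i, acq in enumerate(series):
        if acq.shape != shape:
            raise ValueError(f"frame {i} dimensions {acq.shape} differ from {shape}")
        if mask.shape != shape:
            raise ValueError("mask dimensions must match the frames")
        fmap = compute_fret_map(unmix_image(acq, M, nonneg=nonneg), min_intensity)
        sel = fmap.valid & (mask.labels > 0)
        n = int(sel.sum())
        times.append(acq.time_index if acq.time_index is not None else i)
        means.append(float(fmap.ratio[sel].mean()) if n else float("nan"))
        counts.append(n)
    return Trajectory(time_indices=times, mean_ratios=means, n_valid_per_frame=counts)
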