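"""Normality-gated group comparisons against a control.

Test-selection logic:

* two groups -> unpaired two-sided Student's t-test;
* more than two groups -> Shapiro-Wilk on every group at ``alpha_normality``;
  all pass -> one-way ANOVA with Dunnett's many-to-one post hoc versus the
  control; any fail -> Kruskal-Wallis with Dunn's rank test versus the
  control, Bonferroni-adjusted over the k-1 comparisons.

Adjusted p-values map to stars with strict thresholds:
``***`` p < 0.001, ``**`` p < 0.01, ``*`` p < 0.05, else ``ns``.

The omnibus statistics themselves come from scipy; the contribution of
this module is the gating/annotation logic and the Dunn many-to-one
comparison (implemented here with tie correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError, ValidationError

__all__ = [
    "GroupedMeasurements",
    "ComparisonResult",
    "significance_stars",
    "shapiro_gate",
    "dunn_vs_control",
    "choose_and_run_test",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupedMeasurements:
    """Replicate values per treatment group with a designated control.

    Each group needs at least 3 experiment-level replicates and at least
    two groups must be present.
    """

    groups: dict[str, tuple[float, ...]]
    control_label: str

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 groups")
        if self.control_label not in self.groups:
            raise ValidationError(
                f"control label {self.control_label!r} not among groups"
            )
        small = [g for g, v in self.groups.items() if len(v) < 3]
        if small:
            raise ValidationError(f"groups with n < 3: {small}")
        for g, v in self.groups.items():
            if not all(math.isfinite(x) for x in v):
                raise ValidationError(f"group {g!r} contains non-finite values")
        # freeze values as tuples for hashability/immutability
        object.__setattr__(
            self, "groups", {g: tuple(float(x) for x in v) for g, v in self.groups.items()}
        )

    @property
    def treatment_labels(self) -> list[str]:
        return [g for g in self.groups if g != self.control_label]


@dataclass
class ComparisonResult:
    """Outcome of one gated comparison run."""

    test_used: str  # anova_dunnett | kruskal_dunn | t_test
    p_values: dict[str, float]  # treatment label -> adjusted p vs control
    stars: dict[str, str]
    normality_pass: dict[str, bool] = field(default_factory=dict)
    omnibus_p: float | None = None


def significance_stars(p: float) -> str:
    """Map an adjusted p-value to a star annotation (strict thresholds)."""
    if not (0 <= p <= 1) or not math.isfinite(p):
        raise DomainError(f"p-value outside [0, 1]: {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def shapiro_gate(
    data: GroupedMeasurements, alpha: float = 0.05
) -> dict[str, bool]:
    """Shapiro-Wilk normality check per group at level ``alpha``.

    A group passes when the test does not reject normality (p >= alpha).
    Constant groups cannot be confirmed normal and fail the gate.
    """
    outcome: dict[str, bool] = {}
    for label, values in data.groups.items():
        arr = np.asarray(values, dtype=float)
        if np.ptp(arr) == 0:
            outcome[label] = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.shapiro(arr).pvalue)
        outcome[label] = p >= alpha
    return outcome


def dunn_vs_control(data: GroupedMeasurements) -> dict[str, float]:
    """Dunn's rank-based many-to-one comparisons with Bonferroni adjustment.

    Pooled-rank z statistics with tie correction; two-sided p-values are
    multiplied by the number of treatment groups (k-1) and clipped at 1.
    """
    labels = list(data.groups)
    samples = [np.asarray(data.groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction: sum of (t^3 - t) over tied-value groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    if var_factor <= 0:
        raise DegenerateDataError("all pooled values tied: rank test undefined")
    mean_ranks: dict[str, float] = {}
    start = 0
    for label, sample in zip(labels, samples):
        mean_ranks[label] = float(ranks[start : start + sample.size].mean())
        start += sample.size
    n_ctrl = len(data.groups[data.control_label])
    k_comp = len(data.treatment_labels)
    adjusted: dict[str, float] = {}
    for label in data.treatment_labels:
        n_i = len(data.groups[label])
        se = math.sqrt(var_factor * (1.0 / n_i + 1.0 / n_ctrl))
        z = (mean_ranks[label] - mean_ranks[data.control_label]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        adjusted[label] = min(1.0, p * k_comp)
    return adjusted


def choose_and_run_test(
    data: GroupedMeasurements, alpha_normality: float = 0.05
) -> ComparisonResult:
    """Select and run the appropriate comparison, annotating stars.

    See the module docstring for the decision rule.  Raises
    DegenerateDataError when every value in every group is identical.
    """
    all_values = np.concatenate([np.asarray(v, float) for v in data.groups.values()])
    if np.ptp(all_values) == 0:
        raise DegenerateDataError("all groups constant and identical")

    labels = data.treatment_labels
    if len(data.groups) == 2:
        # two-group case: unpaired Student's t-test, no normality gate
        treated = np.asarray(data.groups[labels[0]], float)
        control = np.asarray(data.groups[data.control_label], float)
        p = float(stats.ttest_ind(treated, control, equal_var=True).pvalue)
        if math.isnan(p):  # both samples constant (but unequal means caught above)
            p = 1.0 if treated.mean() == control.mean() else 0.0
        p_values = {labels[0]: p}
        return ComparisonResult(
            test_used="t_test",
            p_values=p_values,
            stars={g: significance_stars(p) for g, p in p_values.items()},
            omnibus_p=p,
        )

    normality = shapiro_gate(data, alpha=alpha_normality)
    control = np.asarray(data.groups[data.control_label], float)
    treatments = [np.asarray(data.groups[g], float) for g in labels]

    if all(normality.values()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omnibus = float(stats.f_oneway(control, *treatments).pvalue)
            dunnett = stats.dunnett(*treatments, control=control)
        p_values = {g: float(p) for g, p in zip(labels, dunnett.pvalue)}
        test_used = "anova_dunnett"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omnibus = float(stats.kruskal(control, *treatments).pvalue)
        p_values = dunn_vs_control(data)
        test_used = "kruskal_dunn"

    return ComparisonResult(
        test_used=test_used,
        p_values=p_values,
        stars={g: significance_stars(p) for g, p in p_values.items()},
        normality_pass=normality,
        omnibus_p=omnibus,
    )
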