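"""Normality-gated group comparisons and their validation harness.

All condition-level comparisons in the pipeline run through one selection
procedure: each group is tested for normality with the Shapiro-Wilk test at
the gate alpha; if every group looks Gaussian, two groups are compared with
the (paired or unpaired) t-test and more than two with one-way ANOVA
followed by Bonferroni-adjusted pairwise t-tests; otherwise the
Mann-Whitney U test (two groups) or the Kruskal-Wallis test (more) is
used.  The full decision path — every gate p-value and the branch taken —
is recorded alongside the result.

`type_I_check` validates the gated procedure empirically by simulating
null data and measuring the rejection rate, including the family-wise rate
of the Bonferroni-adjusted multi-group branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

DEFAULT_ALPHA = 0.05
DEFAULT_GATE_ALPHA = 0.05
MIN_N_FOR_GATE = 3


@dataclass
class DecisionPath:
    shapiro_p: dict[str, float]
    all_normal: bool
    gate_skipped: bool
    branch: str

    def describe(self) -> str:
        gates = ", ".join(f"{k}: p={v:.3g}" for k, v in self.shapiro_p.items())
        skip = " (gate skipped: n < 3, nonparametric forced)" if self.gate_skipped else ""
        return f"shapiro[{gates}] -> {self.branch}{skip}"


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    decision_path: DecisionPath
    adjusted_p: float | None = None
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < DEFAULT_ALPHA


@dataclass
class ComparisonRequest:
    groups: dict[str, np.ndarray]
    alpha: float = DEFAULT_ALPHA
    paired: bool = False
    gate_alpha: float = DEFAULT_GATE_ALPHA

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups to compare")
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for name, v in self.groups.items():
            if v.size < 2:
                raise ValueError(f"group {name!r} has fewer than 2 observations")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m*p); never below the raw p."""
    return min(1.0, m * p)


def select_and_run(request: ComparisonRequest) -> ComparisonResult:
    """Run the normality-gated comparison on the requested groups.

    When any group is too small for the Shapiro-Wilk gate (n < 3), the gate
    is skipped and the nonparametric branch is forced; this is flagged in
    the decision path.
    """
    groups = request.groups
    names = list(groups)
    values = list(groups.values())

    gate_skipped = any(v.size < MIN_N_FOR_GATE for v in values)
    shapiro_p: dict[str, float] = {}
    if gate_skipped:
        all_normal = False
    else:
        for name, v in groups.items():
            if np.ptp(v) == 0:
                shapiro_p[name] = 0.0  # a constant sample is not Gaussian
            else:
                shapiro_p[name] = float(sps.shapiro(v).pvalue)
        all_normal = all(p > request.gate_alpha for p in shapiro_p.values())

    if len(values) == 2:
        a, b = values
        if all_normal:
            if request.paired:
                res = sps.ttest_rel(a, b)
                test_name = "paired t-test"
            else:
                res = sps.ttest_ind(a, b)
                test_name = "unpaired t-test"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            test_name = "mann-whitney"
        path = DecisionPath(shapiro_p, all_normal, gate_skipped, test_name)
        return ComparisonResult(
            test_name=test_name,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            decision_path=path,
        )

    if all_normal:
        res = sps.f_oneway(*values)
        test_name = "one-way anova + bonferroni"
        pairs = list(itertools.combinations(range(len(values)), 2))
        m = len(pairs)
        pairwise = {}
        for i, j in pairs:
            p = float(sps.ttest_ind(values[i], values[j]).pvalue)
            pairwise[(names[i], names[j])] = bonferroni(p, m)
        adjusted = min(pairwise.values())
    else:
        res = sps.kruskal(*values)
        test_name = "kruskal-wallis"
        pairwise = {}
        adjusted = None
    path = DecisionPath(shapiro_p, all_normal, gate_skipped, test_name)
    return ComparisonResult(
        test_name=test_name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        decision_path=path,
        adjusted_p=adjusted,
        pairwise=pairwise,
    )


def type_I_check(
    branch: str = "two_group",
    n_reps: int = 2000,
    n_per_group: int = 20,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    distribution: str = "normal",
) -> float:
    """Empirical type-I error of the gated procedure under null data.

    Simulates ``n_reps`` replicates of identical-distribution groups
    (``two_group``: two groups, reject when p < alpha; ``three_group``:
    three groups, reject when any Bonferroni-adjusted pairwise comparison —
    or the omnibus nonparametric test — falls below alpha, i.e. the
    family-wise rate) and returns the rejection fraction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n_groups = {"two_group": 2, "three_group": 3}[branch]

    def draw() -> np.ndarray:
        if distribution == "normal":
            return rng.normal(0.0, 1.0, size=n_per_group)
        if distribution == "lognormal":
            return rng.lognormal(0.0, 1.0, size=n_per_group)
        raise ValueError(f"unknown null distribution {distribution!r}")

    req_alpha = alpha if 0.0 < alpha < 1.0 else DEFAULT_ALPHA
    rejections = 0
    for _ in range(n_reps):
        groups = {f"g{i}": draw() for i in range(n_groups)}
        result = select_and_run(ComparisonRequest(groups=groups, alpha=req_alpha))
        if alpha <= 0:
            continue
        if n_groups == 2:
            reject = result.p_value < alpha
        else:
            if result.pairwise:
                reject = min(result.pairwise.values()) < alpha
            else:
                reject = result.p_value < alpha
        rejections += bool(reject)
    return rejections / n_reps
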