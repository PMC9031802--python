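"""Group comparison and normalization to control = 100%.

The statistical unit is the recording (one mean metric value per video),
never the individual event, to avoid pseudoreplication. Two groups are
compared with a two-tailed two-sample t-test (Welch by default); more than
two with one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "compare_multi"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    control_mean: float
    control_sem: float
    control_n: int
    treated_mean: float
    treated_sem: float
    treated_n: int
    normalized_pct: float
    p_value: float
    significant: bool


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size))


def compare_groups(
    control,
    treated,
    metric: str = "metric",
    welch: bool = True,
) -> GroupComparison:
    """Compare per-recording metric values between two groups.

    The treated mean is expressed as a percentage of the control mean
    (control = 100%); significance is a two-tailed two-sample t-test at
    p <= 0.05.
    """
    control = np.asarray(control, dtype=np.float64)
    treated = np.asarray(treated, dtype=np.float64)
    if control.size < 2 or treated.size < 2:
        raise ValueError("each group needs at least 2 recordings")
    c_mean = float(control.mean())
    if c_mean == 0:
        raise ValueError("control mean is zero; normalization undefined")
    t_res = sps.ttest_ind(treated, control, equal_var=not welch)
    p = float(t_res.pvalue)
    return GroupComparison(
        metric=metric,
        control_mean=c_mean,
        control_sem=_sem(control),
        control_n=control.size,
        treated_mean=float(treated.mean()),
        treated_sem=_sem(treated),
        treated_n=treated.size,
        normalized_pct=100.0 * float(treated.mean()) / c_mean,
        p_value=p,
        significant=bool(p <= ALPHA),
    )


def compare_multi(groups: list, metric: str = "metric") -> dict:
    """One-way ANOVA across more than two groups.

    Returns per-group means/SEMs normalized to the first group (= 100%)
    and the ANOVA p-value.
    """
    if len(groups) < 3:
        raise ValueError("compare_multi needs more than two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 recordings")
    ref = arrays[0].mean()
    if ref == 0:
        raise ValueError("reference group mean is zero")
    p = float(sps.f_oneway(*arrays).pvalue)
    return dict(
        metric=metric,
        p_value=p,
        significant=bool(p <= ALPHA),
        groups=[
            dict(
                mean=float(a.mean()),
                sem=_sem(a),
                n=int(a.size),
                normalized_pct=100.0 * float(a.mean()) / ref,
            )
            for a in arrays
        ],
    )
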