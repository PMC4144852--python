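"""Two-sample comparison following the classic Student's t-test.

Pooled-variance, two-sided by default (Welch available behind a flag);
significance declared at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "students_t_test"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    dispersion_a: float
    dispersion_b: float
    dispersion_kind: str  # "se" or "sd"
    t_statistic: float
    df: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _dispersion(x: np.ndarray, kind: str) -> float:
    sd = float(np.std(x, ddof=1))
    if kind == "sd":
        return sd
    if kind == "se":
        return sd / np.sqrt(len(x))
    raise ValueError(f"unknown dispersion kind {kind!r}")


def students_t_test(
    group_a,
    group_b,
    label_a: str = "A",
    label_b: str = "B",
    dispersion_kind: str = "se",
    welch: bool = False,
) -> GroupComparison:
    """Two-sample two-sided t-test (pooled variance unless ``welch``).

    Degenerate case: if the pooled variance is zero the test statistic is
    undefined; equal means are reported as t = 0, p = 1, while unequal
    means raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2 if not welch else None

    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p, df_out = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            raise ValueError("zero pooled variance with unequal means: t undefined")
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df_out = float(res.df)

    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        dispersion_a=_dispersion(a, dispersion_kind),
        dispersion_b=_dispersion(b, dispersion_kind),
        dispersion_kind=dispersion_kind,
        t_statistic=t_stat,
        df=df_out,
        p_value=p,
        significant=bool(p < ALPHA),
    )
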