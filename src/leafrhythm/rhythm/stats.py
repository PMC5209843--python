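"""Group comparison of recovered periods (classical Student's t test)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import GroupSizeError


@dataclass
class GroupResult:
    """Two-group comparison of period estimates."""

    labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]       # hours
    sd: tuple[float, float]         # hours
    t_statistic: float
    df: int
    p_value: float


def compare_groups(periods_by_group: dict[str, "np.ndarray | list[float]"]) -> GroupResult:
    """Two-sample, two-sided, equal-variance Student's t test on periods.

    The degenerate zero-pooled-variance case is handled explicitly: equal
    means give t = 0, p = 1; different means are exact separation, t = +/-inf,
    p = 0.

    Raises
    ------
    GroupSizeError
        Unless exactly two groups with at least two observations each are
        supplied.
    """
    if len(periods_by_group) != 2:
        raise GroupSizeError(
            f"exactly 2 groups required, got {len(periods_by_group)}")
    (la, xa), (lb, xb) = periods_by_group.items()
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    na, nb = len(xa), len(xb)
    if na < 2 or nb < 2:
        raise GroupSizeError("each group needs n >= 2 observations")

    ma, mb = xa.mean(), xb.mean()
    sa, sb = xa.std(ddof=1), xb.std(ddof=1)
    df = na + nb - 2
    pooled_var = ((na - 1) * sa ** 2 + (nb - 1) * sb ** 2) / df
    if pooled_var == 0.0:
        if ma == mb:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(np.sign(ma - mb)) * np.inf, 0.0
    else:
        t_stat = (ma - mb) / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    return GroupResult(labels=(la, lb), n=(na, nb),
                       mean=(float(ma), float(mb)), sd=(float(sa), float(sb)),
                       t_statistic=float(t_stat), df=df, p_value=float(p))
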