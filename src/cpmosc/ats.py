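"""Rank-based ANOVA-type statistic (ATS) for two-factor longitudinal data.

Implements the nonparametric ANOVA-type test for a design with one
between-subject factor (group, ``a`` levels) and one within-subject
factor (condition, ``t`` levels), complete profiles, following the
Brunner-Domhof-Langer construction:

* all ``N x t`` observations are mid-ranked together;
* the relative treatment effect of cell (i, j) is
  ``p_ij = (mean rank - 1/2) / (N t)`` -- the probability that a random
  observation from the pooled distribution is smaller than one from
  cell (i, j); all 0.5 under exchangeability;
* for a hypothesis contrast C with projection ``T = C'(CC')^- C`` the
  statistic is ``F = N p'Tp / tr(TV)`` with V the estimated covariance
  of the relative-effect vector, compared to an F distribution with
  Box-approximated numerator degrees of freedom
  ``f = tr(TV)^2 / tr(TVTV)`` and denominator infinity (the convention
  of the standard ATS output table).  For the between-subject effect a
  finite Box-approximated denominator ``f0`` is also reported.

The test is invariant under strictly monotone transforms of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["AtsEffect", "AtsResult", "ats_f1_ld_f1", "LongitudinalData"]


@dataclass
class LongitudinalData:
    """Complete two-factor longitudinal layout.

    ``y`` has shape (n_subjects, n_conditions); ``group`` labels each
    subject (row).  Condition order is the within-subject factor order.
    """

    y: np.ndarray
    group: np.ndarray
    conditions: tuple[str, ...]
    groups: tuple[str, ...]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        y: str = "y",
        subject: str = "subject",
        group: str = "group",
        condition: str = "condition",
        condition_order: list[str] | None = None,
        group_order: list[str] | None = None,
    ) -> "LongitudinalData":
        conds = condition_order or list(pd.unique(df[condition]))
        wide = df.pivot_table(index=subject, columns=condition, values=y, sort=False)
        if wide.isna().any().any():
            missing = wide.isna().sum().sum()
            raise ValueError(f"incomplete design: {int(missing)} missing cell(s)")
        wide = wide[conds]
        subj_group = df.drop_duplicates(subject).set_index(subject)[group]
        groups = group_order or list(pd.unique(subj_group))
        order = subj_group.loc[wide.index]
        return cls(
            y=wide.to_numpy(dtype=float),
            group=order.to_numpy(),
            conditions=tuple(conds),
            groups=tuple(groups),
        )


@dataclass
class AtsEffect:
    statistic: float
    df_num: float
    p: float
    df_den: float = math.inf
    p_box: float | None = None
    df_den_box: float | None = None


@dataclass
class AtsResult:
    group: AtsEffect
    condition: AtsEffect
    interaction: AtsEffect
    relative_effects: pd.DataFrame  # groups x conditions, values in (0, 1)
    degenerate: bool = False
    denominator_convention: str = (
        "F(f, inf) for all effects; Box-approximated finite denominator "
        "reported additionally for the between-subject effect"
    )

    def effects(self) -> dict[str, AtsEffect]:
        return {
            "group": self.group,
            "condition": self.condition,
            "interaction": self.interaction,
        }


def _projection(c: np.ndarray) -> np.ndarray:
    return c.T @ np.linalg.pinv(c @ c.T) @ c


def ats_f1_ld_f1(data: LongitudinalData) -> AtsResult:
    """ANOVA-type tests for group, condition and their interaction.

    Parameters
    ----------
    data : LongitudinalData
        Complete (no missing cells) subject x condition responses with
        a group label per subject.

    Returns
    -------
    AtsResult with one :class:`AtsEffect` per hypothesis and the table
    of relative treatment effects.
    """
    y = np.asarray(data.y, dtype=float)
    n_subj, t = y.shape
    groups = list(data.groups)
    a = len(groups)
    group_idx = [np.nonzero(np.asarray(data.group) == g)[0] for g in groups]
    sizes = np.array([len(ix) for ix in group_idx])
    if np.any(sizes < 2):
        empty = [g for g, n in zip(groups, sizes) if n < 2]
        raise ValueError(f"each group needs >= 2 subjects; too few in {empty}")
    if sizes.sum() != n_subj:
        raise ValueError("group labels do not partition the subjects")
    total = n_subj * t

    ranks = sstats.rankdata(y, axis=None).reshape(y.shape)  # mid-ranks

    # Relative treatment effects per cell, group-major ordering.
    p_hat = np.empty(a * t)
    for i, ix in enumerate(group_idx):
        p_hat[i * t : (i + 1) * t] = (ranks[ix].mean(axis=0) - 0.5) / total

    rel = pd.DataFrame(
        p_hat.reshape(a, t), index=list(groups), columns=list(data.conditions)
    )

    # Covariance of sqrt(N) * (p_hat - p): block diagonal over groups.
    v_blocks = []
    for i, ix in enumerate(group_idx):
        s_i = np.cov(ranks[ix], rowvar=False, ddof=1).reshape(t, t)
        v_blocks.append(n_subj * s_i / (sizes[i] * total**2))
    v_hat = np.zeros((a * t, a * t))
    for i, b in enumerate(v_blocks):
        v_hat[i * t : (i + 1) * t, i * t : (i + 1) * t] = b

    degenerate = not np.any(v_hat)

    p_a = np.eye(a) - np.ones((a, a)) / a
    p_t = np.eye(t) - np.ones((t, t)) / t
    contrasts = {
        "group": np.kron(p_a, np.ones((1, t)) / t),
        "condition": np.kron(np.ones((1, a)) / a, p_t),
        "interaction": np.kron(p_a, p_t),
    }

    effects: dict[str, AtsEffect] = {}
    for name, c in contrasts.items():
        t_mat = _projection(c)
        tv = t_mat @ v_hat
        tr_tv = float(np.trace(tv))
        if degenerate or tr_tv <= 0:
            effects[name] = AtsEffect(statistic=0.0, df_num=float("nan"), p=1.0)
            continue
        stat = float(n_subj * p_hat @ t_mat @ p_hat / tr_tv)
        df_num = tr_tv**2 / float(np.trace(tv @ tv))
        p_val = float(sstats.chi2.sf(stat * df_num, df_num))
        eff = AtsEffect(statistic=stat, df_num=df_num, p=p_val)
        if name == "group":
            # Finite Box-approximated denominator for the whole-plot factor.
            contrib = np.array(
                [
                    float(np.trace(t_mat[i * t : (i + 1) * t, i * t : (i + 1) * t] @ b))
                    for i, b in enumerate(v_blocks)
                ]
            )
            denom = float(np.sum(contrib**2 / (sizes - 1)))
            if denom > 0:
                eff.df_den_box = tr_tv**2 / denom
                eff.p_box = float(sstats.f.sf(stat, df_num, eff.df_den_box))
        effects[name] = eff

    return AtsResult(
        group=effects["group"],
        condition=effects["condition"],
        interaction=effects["interaction"],
        relative_effects=rel,
        degenerate=degenerate,
    )
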