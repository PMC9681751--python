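"""Standardized mean differences and their variances.

Effect sizes for continuous outcomes in preclinical meta-analysis are
standardized mean differences (SMD): the between-group difference in
means divided by the pooled standard deviation. Cohen's d overestimates
the population SMD in small samples — the norm in animal experiments —
so Hedges' small-sample correction ``J = 1 - 3/(4*(n_t+n_c-2)-1)`` is
applied by default (Hedges' g).

The module also provides direction alignment (flipping SMDs so a
positive value always means benefit, a prerequisite for pooling
heterogeneous outcomes) and splitting of control groups shared by
several experimental arms of the same study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy import stats

from .exceptions import (
    DegenerateInputError,
    UnclearDirectionError,
    ValidationError,
)

__all__ = [
    "ArmSummary",
    "EffectSize",
    "compute_smd",
    "smd_from_ci",
    "align_direction",
    "split_shared_control",
]


@dataclass(frozen=True)
class ArmSummary:
    """Arm-level summary statistics of one two-group comparison.

    Parameters
    ----------
    mean_treated, mean_control : float
        Group means on the outcome scale.
    sd_treated, sd_control : float
        Group standard deviations; must be strictly positive.
    n_treated, n_control : int
        Group sizes; at least 2 animals per group.
    """

    mean_treated: float
    sd_treated: float
    n_treated: int
    mean_control: float
    sd_control: float
    n_control: int

    def __post_init__(self) -> None:
        if self.n_treated < 2 or self.n_control < 2:
            raise ValidationError(
                f"group sizes must be >= 2, got n_treated={self.n_treated}, "
                f"n_control={self.n_control}"
            )
        if self.sd_treated <= 0 or self.sd_control <= 0:
            raise ValidationError(
                f"standard deviations must be > 0, got sd_treated="
                f"{self.sd_treated}, sd_control={self.sd_control}"
            )


@dataclass(frozen=True)
class EffectSize:
    """A standardized mean difference with its sampling variance.

    ``direction_aligned`` records whether the SMD has been transformed
    so that positive values mean benefit in the expected direction.
    """

    smd: float
    variance: float
    direction_aligned: bool = False

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValidationError(f"variance must be > 0, got {self.variance}")


def hedges_correction(n_treated: int, n_control: int) -> float:
    """Small-sample correction factor J converting Cohen's d to Hedges' g."""
    df = n_treated + n_control - 2
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def compute_smd(arms: ArmSummary, bias_corrected: bool = True) -> EffectSize:
    """Standardized mean difference of one arm against its control.

    Cohen's d is ``(mean_treated - mean_control) / s_pooled`` with the
    usual pooled SD; when ``bias_corrected`` (the default) d is
    multiplied by Hedges' factor J. The large-sample variance is

        var = (n_t + n_c) / (n_t * n_c) + smd^2 / (2 * (n_t + n_c))

    evaluated at the returned (possibly corrected) SMD.

    Raises
    ------
    DegenerateInputError
        If the pooled standard deviation is zero.
    """
    n_t, n_c = arms.n_treated, arms.n_control
    pooled_var = (
        (n_t - 1) * arms.sd_treated**2 + (n_c - 1) * arms.sd_control**2
    ) / (n_t + n_c - 2)
    if pooled_var <= 0:
        raise DegenerateInputError("pooled standard deviation is zero")
    smd = (arms.mean_treated - arms.mean_control) / math.sqrt(pooled_var)
    if bias_corrected:
        smd *= hedges_correction(n_t, n_c)
    n_tot = n_t + n_c
    variance = n_tot / (n_t * n_c) + smd**2 / (2.0 * n_tot)
    return EffectSize(smd=smd, variance=variance, direction_aligned=False)


def smd_from_ci(
    smd: float, ci_low: float, ci_high: float, level: float = 0.95
) -> EffectSize:
    """Recover the sampling variance of an SMD from its Wald confidence
    interval: ``var = ((ci_high - ci_low) / (2 * z))^2`` with z the
    two-sided normal quantile at ``level``.

    The interval is assumed normal (Wald); t-based intervals are not
    auto-detected.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if ci_low > ci_high:
        raise ValidationError(f"inverted CI: ({ci_low}, {ci_high})")
    if ci_high == ci_low:
        raise DegenerateInputError("zero-width confidence interval")
    if not ci_low <= smd <= ci_high:
        raise ValidationError(
            f"point estimate {smd} outside CI ({ci_low}, {ci_high})"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    variance = ((ci_high - ci_low) / (2.0 * z)) ** 2
    return EffectSize(smd=smd, variance=variance, direction_aligned=False)


def align_direction(
    effects: Iterable[EffectSize],
    expected_direction: str,
    fallback_sign: float | None = None,
) -> list[EffectSize]:
    """Transform SMDs so positive values mean benefit.

    ``benefit_negative`` flips every sign, ``benefit_positive`` leaves
    values unchanged; both mark results as direction-aligned. For
    ``unclear`` the caller must supply ``fallback_sign`` (e.g. the sign
    of the meta-analysis's pooled estimate) or an
    :class:`UnclearDirectionError` is raised so the pipeline can exclude
    the meta-analysis.
    """
    effects = list(effects)
    if expected_direction == "benefit_positive":
        sign = 1.0
    elif expected_direction == "benefit_negative":
        sign = -1.0
    elif expected_direction == "unclear":
        if fallback_sign is None or fallback_sign == 0:
            raise UnclearDirectionError(
                "expected direction unclear and no fallback sign given"
            )
        sign = 1.0 if fallback_sign > 0 else -1.0
    else:
        raise ValidationError(
            f"unknown expected_direction {expected_direction!r}"
        )
    return [
        replace(e, smd=sign * e.smd, direction_aligned=True) for e in effects
    ]


def split_shared_control(
    records: Sequence[ArmSummary], k: int | None = None
) -> list[ArmSummary]:
    """Split a control group shared by ``k`` experimental arms.

    Each returned arm keeps its means and SDs but gets
    ``n_control // k`` control animals, preventing the shared animals
    from being counted k times in the meta-analysis. Remainder animals
    are dropped (floor division).

    ``k`` defaults to ``len(records)``.
    """
    records = list(records)
    if k is None:
        k = len(records)
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k == 1:
        return records
    n_controls = {r.n_control for r in records}
    if len(n_controls) > 1:
        raise ValidationError(
            "arms said to share a control have differing n_control"
        )
    n_split = next(iter(n_controls)) // k
    if n_split < 2:
        raise DegenerateInputError(
            f"splitting control of n={next(iter(n_controls))} across {k} "
            f"arms leaves fewer than 2 animals per arm"
        )
    return [replace(r, n_control=n_split) for r in records]
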