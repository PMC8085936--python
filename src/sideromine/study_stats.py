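"""Scalar inference steps: species delineation and the summary t-test.

Species delineation uses the accepted genome-similarity cutoffs: 95%
average nucleotide identity (ANI) and 70% in-silico DNA-DNA
hybridization (isDDH). A strain strictly below both thresholds against
its nearest named relative supports a novel species; at or above both,
the same species; a split verdict is reported as discordant rather than
forced either way.

The plant-growth comparison is an unpaired two-sample t-test computed
from summary statistics (mean, sample SD, n per group), pooled-variance
by default with Welch-Satterthwaite available. The "±" values of the
foliar-area summaries are interpreted as sample standard deviations,
not standard errors: only that reading is internally consistent with
the reported two-tailed p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

ANI_THRESHOLD = 95.0
ISDDH_THRESHOLD = 70.0


@dataclass(frozen=True)
class TaxonomyMetrics:
    ani_percent: float
    isddh_percent: float
    delta_gc_percent: float | None = None
    mlsa_identity_percent: float | None = None

    def __post_init__(self) -> None:
        for name, value in (("ani", self.ani_percent),
                            ("isddh", self.isddh_percent)):
            if value is None:
                raise ValueError(f"missing metric {name}")
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} {value} outside [0, 100]")


@dataclass(frozen=True)
class SummaryGroup:
    """Mean, sample SD and n of one measurement group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def delineate_species(
    metrics: TaxonomyMetrics,
    ani_threshold: float = ANI_THRESHOLD,
    isddh_threshold: float = ISDDH_THRESHOLD,
) -> str:
    """Species call from ANI/isDDH against the accepted cutoffs.

    Returns ``"novel_species"`` when both metrics are strictly below
    their thresholds, ``"same_species"`` when both are at or above, and
    ``"discordant"`` otherwise (boundary equality falls on the >= side).
    """
    below_ani = metrics.ani_percent < ani_threshold
    below_isddh = metrics.isddh_percent < isddh_threshold
    if below_ani and below_isddh:
        return "novel_species"
    if not below_ani and not below_isddh:
        return "same_species"
    return "discordant"


def unpaired_t_from_summary(
    a: SummaryGroup, b: SummaryGroup, variant: str = "pooled"
) -> dict[str, float]:
    """Two-sided unpaired t-test from group summaries.

    pooled: t = (m_a - m_b) / sqrt(s_p^2 (1/n_a + 1/n_b)) with
    s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2) and
    df = n_a + n_b - 2. welch: the usual Satterthwaite approximation.
    """
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    elif variant == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": t, "df": float(df), "p_two_tailed": p}
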