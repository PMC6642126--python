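"""Statistical comparisons for TFRs, waveforms and time-domain parameters.

Three procedures, matching the three levels of the analysis:

* paired permutation test on per-subject TFRs, based on the per-cell
  paired t-statistic with max-statistic (t-max) correction for multiple
  comparisons (family-wise error control across all cells);
* per-sample Wilcoxon rank-sum comparison of waveforms with
  Benjamini-Hochberg false-discovery-rate correction;
* two-way ANOVA (burst duration x gap duration) on time-domain
  parameters with Tukey HSD post-hoc comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .tfr import TimeFrequencyRepresentation

__all__ = [
    "SignificanceMask",
    "AnovaResult",
    "paired_permutation_tfr",
    "wilcoxon_fdr_waveforms",
    "anova_time_domain",
]


@dataclass
class SignificanceMask:
    """Boolean significance mask aligned to the tested axes."""

    mask: np.ndarray
    alpha: float
    n_permutations: int
    method: str
    statistic: np.ndarray | None = None
    threshold: float | None = None


def _as_power_stack(tfrs: Sequence) -> np.ndarray:
    arrays = [
        t.power if isinstance(t, TimeFrequencyRepresentation) else np.asarray(t, float)
        for t in tfrs
    ]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("all TFRs must share the same shape")
    return np.stack(arrays)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Per-cell paired t; cells with zero variance get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def _sign_patterns(n_pairs: int, n_permutations: int, rng: np.random.Generator):
    """Sign-flip patterns: exact enumeration when the space is small."""
    if 2**n_pairs <= n_permutations:
        codes = np.arange(2**n_pairs)
        bits = (codes[:, None] >> np.arange(n_pairs)[None, :]) & 1
        return 2.0 * bits - 1.0, True
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_pairs))
    signs[0] = 1.0  # include the observed labelling in the null
    return signs, False


def paired_permutation_tfr(
    tfrs_a: Sequence,
    tfrs_b: Sequence,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SignificanceMask:
    """Paired sign-flip permutation test on TFR cells, t-max corrected.

    The null distribution is built by randomly flipping the sign of each
    subject's paired difference; the maximum absolute t-statistic across
    all cells per permutation gives the corrected threshold, so the
    family-wise error rate over the whole time-frequency plane is at most
    ``alpha``.  With few subjects the sign-flip space is enumerated
    exactly.
    """
    A = _as_power_stack(tfrs_a)
    B = _as_power_stack(tfrs_b)
    if A.shape != B.shape:
        raise ValueError("paired TFR sets must have matching shapes")
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = A - B
    if np.allclose(diffs, 0):
        warnings.warn("all paired differences are zero; empty mask", stacklevel=2)
        return SignificanceMask(
            mask=np.zeros(A.shape[1:], dtype=bool),
            alpha=alpha,
            n_permutations=0,
            method="tmax-permutation",
            statistic=np.zeros(A.shape[1:]),
            threshold=np.inf,
        )
    t_obs = _paired_t(diffs)
    flat = diffs.reshape(n, -1)
    # sum of squares is sign-flip invariant, so each permutation only
    # needs the flipped mean: t = m / sqrt((ss/n - m^2) / (n-1) / n)
    ss = np.sum(flat**2, axis=0)
    rng = np.random.default_rng(seed)
    signs, exact = _sign_patterns(n, n_permutations, rng)
    means = signs @ flat / n
    var = (ss[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n)
    t_null = np.where(var > 0, t_null, 0.0)
    max_t = np.max(np.abs(t_null), axis=1)
    threshold = float(np.quantile(max_t, 1.0 - alpha))
    return SignificanceMask(
        mask=np.abs(t_obs) > threshold,
        alpha=alpha,
        n_permutations=len(signs),
        method="tmax-permutation-exact" if exact else "tmax-permutation",
        statistic=t_obs,
        threshold=threshold,
    )


def wilcoxon_fdr_waveforms(
    waves_a: Sequence,
    waves_b: Sequence,
    alpha: float = 0.01,
) -> SignificanceMask:
    """Per-sample two-sided rank-sum test with Benjamini-Hochberg FDR.

    Each time sample is compared across the two groups of waveforms; the
    resulting p-values are FDR-adjusted across samples and the mask marks
    samples with adjusted p below ``alpha``.
    """
    A = np.stack([np.asarray(getattr(w, "samples_uv", w), float) for w in waves_a])
    B = np.stack([np.asarray(getattr(w, "samples_uv", w), float) for w in waves_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError("waveform groups must share the sample grid")
    if min(A.shape[0], B.shape[0]) < 2:
        raise ValueError("each group needs at least 2 waveforms")
    _, pvals = sps.ranksums(A, B, axis=0)
    rejected, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return SignificanceMask(
        mask=rejected,
        alpha=alpha,
        n_permutations=0,
        method="ranksum-fdr_bh",
        statistic=pvals,
    )


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus per-factor Tukey HSD post-hoc tables."""

    table: pd.DataFrame
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "PR(>F)"])


def anova_time_domain(
    values: Sequence[float],
    nb1_ms: Sequence[float],
    gap_ms: Sequence[float],
    alpha: float = 0.05,
    posthoc: bool = True,
) -> AnovaResult:
    """Two-way ANOVA of a time-domain parameter on the stimulus factors.

    Factors are NB1 duration and gap duration (categorical); the model
    includes their interaction.  Post-hoc Tukey HSD comparisons are
    reported per factor at ``alpha``.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "nb1": pd.Categorical([f"{v:g}" for v in nb1_ms]),
            "gap": pd.Categorical([f"{v:g}" for v in gap_ms]),
        }
    )
    for factor in ("nb1", "gap"):
        counts = df.groupby(factor, observed=False)["value"].count()
        if (counts == 0).any():
            raise ValueError(f"factor {factor} has empty levels")
        if len(counts) < 2:
            raise ValueError(f"factor {factor} needs at least two levels")
    model = ols("value ~ C(nb1) * C(gap)", data=df).fit()
    table = anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(nb1)": "nb1",
            "C(gap)": "gap",
            "C(nb1):C(gap)": "nb1:gap",
            "Residual": "residual",
        }
    )
    # degenerate guard: an effect with (numerically) zero sum of squares
    # explains nothing — report F = 0, p = 1 instead of 0/0 artifacts
    vals = df["value"].to_numpy()
    scale = float(np.sum((vals - vals.mean()) ** 2))
    floor = 1e-12 * max(scale, len(vals) * np.finfo(float).eps * (1 + vals.mean() ** 2))
    negligible = table["sum_sq"] <= floor
    for effect in table.index:
        if effect != "residual" and negligible.loc[effect]:
            table.loc[effect, "F"] = 0.0
            table.loc[effect, "PR(>F)"] = 1.0
    posthoc_tables = {}
    if posthoc:
        for factor in ("nb1", "gap"):
            if df[factor].nunique() > 1:
                res = pairwise_tukeyhsd(df["value"], df[factor], alpha=alpha)
                posthoc_tables[factor] = pd.DataFrame(
                    res.summary().data[1:], columns=res.summary().data[0]
                )
    return AnovaResult(table=table, posthoc=posthoc_tables)
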