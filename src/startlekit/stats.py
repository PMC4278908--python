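"""Group-level statistics for a 2 (group) × 2 (CS type) startle design.

The core test is a mixed (split-plot) ANOVA with one between-subject
factor (patient vs control) and one two-level within-subject factor
(CS+ vs CS−), reported with partial eta squared
η_p² = SS_effect / (SS_effect + SS_error).  With a two-level within factor
the design collapses onto subject means (between part) and CS+ − CS−
differences (within part); sums of squares follow the classical split-plot
decomposition, with the CS-type main effect tested on the unweighted mean
of the group difference-means (Type-III convention) so that unbalanced
groups are handled the way standard GLM software reports them.

t-tests (raw-data and summary-statistic forms), Pearson correlation and
the 2×2 Pearson chi-square are thin validated wrappers over scipy.stats.
No multiple-testing correction is applied anywhere; all p-values are
two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

from .paradigm import ACQUISITION, EXTINCTION


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p_sq: float
    ss_effect: float
    ss_error: float
    n: int
    n_dropped: int = 0


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    kind: str  # "paired" | "independent_pooled" | "independent_welch"


@dataclass(frozen=True)
class CorrResult:
    r: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class ChiSqResult:
    chi2: float
    df: int
    p: float
    n: int


class DegenerateDataError(ValueError):
    """Raised when a test's variance/margin precondition fails."""


# ---------------------------------------------------------------------------
# mixed 2x2 ANOVA

_PHASE_PREFIX = {ACQUISITION: "acq", EXTINCTION: "ext"}


def mixed_anova_2x2(table: pd.DataFrame, phase: str | None = None,
                    group_col: str = "group", cs_plus_col: str = "cs_plus",
                    cs_minus_col: str = "cs_minus") -> list[AnovaResult]:
    """Group × CS-type split-plot ANOVA on one phase's proportional scores.

    ``table`` holds one row per participant.  When ``phase`` is given the
    score columns are ``{acq|ext}_cs_plus`` / ``..._cs_minus`` as emitted
    by the cohort pipeline; otherwise ``cs_plus_col``/``cs_minus_col`` name
    them directly.  Participants with a missing cell are dropped listwise
    (count reported on every result).

    Returns results for the Group main effect, the CS-type main effect and
    the CS-type × Group interaction, in that order.
    """
    if phase is not None:
        prefix = _PHASE_PREFIX[phase]
        cs_plus_col = f"{prefix}_cs_plus"
        cs_minus_col = f"{prefix}_cs_minus"
    cols = [group_col, cs_plus_col, cs_minus_col]
    data = table[cols].copy()
    n_total = len(data)
    data = data.dropna()
    n_dropped = n_total - len(data)

    groups = sorted(data[group_col].unique())
    g = len(groups)
    if g < 1 or len(data) < g + 1:
        raise DegenerateDataError("too few participants for the ANOVA")

    plus = data[cs_plus_col].to_numpy(float)
    minus = data[cs_minus_col].to_numpy(float)
    m = (plus + minus) / 2.0            # subject means  (between part)
    d = plus - minus                    # CS+ − CS− differences (within part)
    glab = data[group_col].to_numpy()

    n_j = np.array([(glab == lv).sum() for lv in groups], float)
    m_j = np.array([m[glab == lv].mean() for lv in groups])
    d_j = np.array([d[glab == lv].mean() for lv in groups])
    N = int(n_j.sum())

    ss_subj = 2.0 * sum(((m[glab == lv] - m_j[i]) ** 2).sum()
                        for i, lv in enumerate(groups))
    ss_werr = 0.5 * sum(((d[glab == lv] - d_j[i]) ** 2).sum()
                        for i, lv in enumerate(groups))
    df_err = N - g
    if df_err <= 0:
        raise DegenerateDataError("no error degrees of freedom")
    ms_subj = ss_subj / df_err
    ms_werr = ss_werr / df_err

    def make(effect: str, ss_eff: float, df_num: int, ss_err: float,
             ms_err: float) -> AnovaResult:
        ms_eff = ss_eff / df_num
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0
                                                else np.inf)
        p = float(ss.f.sf(F, df_num, df_err)) if np.isfinite(F) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return AnovaResult(effect, float(F), df_num, df_err, p, float(eta),
                           float(ss_eff), float(ss_err), N, n_dropped)

    results: list[AnovaResult] = []
    if g >= 2:
        gm = m.mean()                   # weighted grand mean
        ss_group = 2.0 * float((n_j * (m_j - gm) ** 2).sum())
        results.append(make("group", ss_group, g - 1, ss_subj, ms_subj))

    u = d_j.mean()                      # unweighted mean difference
    ss_cs = u ** 2 * g ** 2 / (2.0 * float((1.0 / n_j).sum()))
    results.append(make("cs_type", ss_cs, 1, ss_werr, ms_werr))

    if g >= 2:
        dw = d.mean()                   # weighted mean difference
        ss_inter = 0.5 * float((n_j * (d_j - dw) ** 2).sum())
        results.append(make("cs_type_x_group", ss_inter, g - 1, ss_werr,
                            ms_werr))
    return results


def anova_by_effect(results: Sequence[AnovaResult]) -> dict[str, AnovaResult]:
    return {r.effect: r for r in results}


# ---------------------------------------------------------------------------
# t-tests

def paired_t(x, y) -> TTestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired samples must match and have n >= 2")
    if np.std(x - y) == 0:
        raise DegenerateDataError("zero variance of paired differences")
    res = ss.ttest_rel(x, y)
    return TTestResult(float(res.statistic), float(x.size - 1),
                       float(res.pvalue), "paired")


def independent_t(x, y, welch: bool = False) -> TTestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per sample")
    if np.std(x) == 0 and np.std(y) == 0:
        raise DegenerateDataError("both samples have zero variance")
    res = ss.ttest_ind(x, y, equal_var=not welch)
    df = res.df if hasattr(res, "df") else x.size + y.size - 2
    kind = "independent_welch" if welch else "independent_pooled"
    return TTestResult(float(res.statistic), float(df), float(res.pvalue),
                       kind)


def independent_t_from_stats(mean1: float, sd1: float, n1: int,
                             mean2: float, sd2: float, n2: int,
                             welch: bool = False) -> TTestResult:
    """Independent-samples t from printed summary statistics.

    Lets published group mean ± SD tables be re-tested without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per sample")
    res = ss.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                  equal_var=not welch)
    if welch:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
        kind = "independent_welch"
    else:
        df = n1 + n2 - 2
        kind = "independent_pooled"
    return TTestResult(float(res.statistic), float(df), float(res.pvalue),
                       kind)


# ---------------------------------------------------------------------------
# correlation and chi-square

def pearson_r(x, y) -> CorrResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("constant input has no correlation")
    res = ss.pearsonr(x, y)
    return CorrResult(float(res.statistic), int(x.size - 2),
                      float(res.pvalue), int(x.size))


def chi_square_2x2(counts) -> ChiSqResult:
    """Pearson chi-square on a 2×2 contingency table, no continuity
    correction, df = 1."""
    obs = np.asarray(counts, float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero margin in contingency table")
    chi2, p, df, expected = ss.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise DegenerateDataError("non-positive expected count")
    return ChiSqResult(float(chi2), int(df), float(p), int(obs.sum()))


# ---------------------------------------------------------------------------
# contingency awareness

FULLY_AWARE = "fully_aware"
PARTIALLY_AWARE = "partially_aware"
UNAWARE = "unaware"


def classify_awareness(cs_plus_correct: bool,
                       cs_minus_correct: bool) -> str:
    """Awareness category from the two CS-identification answers:
    both correct → fully aware; at least one → partially aware;
    none → unaware."""
    if cs_plus_correct and cs_minus_correct:
        return FULLY_AWARE
    if cs_plus_correct or cs_minus_correct:
        return PARTIALLY_AWARE
    return UNAWARE
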