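"""Segregation and gamete-transmission genetics, plus qPCR quantification.

A plant monosomic for one chromosome produces chromosome-bearing and
null gametes in equal numbers at meiosis, but the two types need not be
transmitted equally.  With null:normal transmission ratios f (female)
and m (male), a transmitted gamete is null with probability f/(1+f) or
m/(1+m), and selfed progeny fall into the disomic (T), monosomic (M) and
nullisomic (D) classes with the product probabilities implemented here.
The module also provides the chi-square goodness-of-fit test for observed
segregation tables, transmission-rate estimation from a euploid-female x
monosomic-male cross, and relative qPCR expression by the 2^-ddCt method.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ParameterError

__all__ = ["SegregationTable", "chisq_gof", "estimate_transmission",
           "expected_progeny", "estimate_transmission_selfed", "QpcrSet", "ddct"]

logger = logging.getLogger(__name__)


@dataclass
class SegregationTable:
    """Observed progeny class counts against a hypothesized ratio."""

    labels: list[str]
    observed: list[int]
    ratio: list[float]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.observed) == len(self.ratio)):
            raise ParameterError("labels, observed and ratio must have equal length")
        if any(o < 0 for o in self.observed):
            raise ParameterError("observed counts must be nonnegative")
        if any(r < 0 for r in self.ratio) or sum(self.ratio) == 0:
            raise ParameterError("ratio must be nonnegative and not all zero")


def chisq_gof(table: SegregationTable) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit of observed counts to a ratio.

    Expected counts scale the ratio to the observed total; no continuity
    correction.  Returns (chi2, df, p).
    """
    obs = np.asarray(table.observed, dtype=float)
    total = obs.sum()
    if total == 0:
        raise ParameterError("empty segregation table")
    ratio = np.asarray(table.ratio, dtype=float)
    expected = ratio / ratio.sum() * total
    if (expected == 0).any():
        raise ParameterError("a class with expected count 0 cannot be tested")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def estimate_transmission(t_count: int, m_count: int,
                          conf_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Male null:normal transmission ratio from a euploid-female x
    monosomic-male F1.

    Disomic offspring (T) received a normal pollen grain and monosomic
    offspring (M) a null one, so the odds M/T estimate the null:normal
    success ratio.  The confidence interval is the exact (Clopper-Pearson)
    binomial interval on M/(T+M), transformed to the odds scale.
    """
    if t_count <= 0:
        raise ParameterError("T count must be positive (ratio undefined otherwise)")
    if m_count < 0:
        raise ParameterError("M count must be nonnegative")
    estimate = m_count / t_count
    ci = stats.binomtest(m_count, m_count + t_count).proportion_ci(
        confidence_level=conf_level, method="exact")
    lo = ci.low / (1.0 - ci.low) if ci.low < 1 else np.inf
    hi = ci.high / (1.0 - ci.high) if ci.high < 1 else np.inf
    return estimate, (float(lo), float(hi))


def expected_progeny(female_null_rate: float, male_null_rate: float) -> tuple[float, float, float]:
    """Expected (P_T, P_M, P_D) class probabilities of a selfed monosomic.

    With null:normal transmission ratios f and m, the transmitted gamete
    is null with probability q = rate/(1+rate) on each side; T needs two
    normal gametes, D two null ones, M the remainder.  Always a simplex.
    """
    for r in (female_null_rate, male_null_rate):
        if not 0.0 <= r <= 1.0:
            raise ParameterError("transmission rates must lie in [0, 1]")
    q_f = female_null_rate / (1.0 + female_null_rate)
    q_m = male_null_rate / (1.0 + male_null_rate)
    p_t = (1.0 - q_f) * (1.0 - q_m)
    p_d = q_f * q_m
    p_m = max(1.0 - p_t - p_d, 0.0)  # guard float round-off at the corners
    return p_t, p_m, p_d


def estimate_transmission_selfed(t_count: int, m_count: int, d_count: int,
                                 grid: int = 400) -> tuple[float, float]:
    """Joint maximum-likelihood (female, male) transmission ratios from
    selfed-monosomic T/M/D counts, by multinomial likelihood over a grid.

    The two rates are only weakly identified from three class counts (the
    likelihood is symmetric in f and m); the returned pair is the grid
    maximizer with f >= m ties resolved toward equal rates.
    """
    counts = np.array([t_count, m_count, d_count], dtype=float)
    if counts.sum() == 0:
        raise ParameterError("empty progeny table")
    rates = np.linspace(0.0, 1.0, grid + 1)
    best, best_ll = (1.0, 1.0), -np.inf
    for f in rates:
        for m in rates[rates <= f + 1e-12]:
            p = np.array(expected_progeny(f, m))
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(np.where(counts > 0, counts * np.log(p), 0.0).sum())
            if ll > best_ll or (ll == best_ll and abs(f - m) < abs(best[0] - best[1])):
                best_ll, best = ll, (float(f), float(m))
    return best


@dataclass
class QpcrSet:
    """Replicate Ct measurements of target and reference genes.

    ``data`` columns: gene, sample, replicate, ct_target, ct_reference.
    ``calibrator`` names the sample against which expression is scaled.
    """

    data: pd.DataFrame
    calibrator: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct_target", "ct_reference"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"qPCR table missing columns: {sorted(missing)}")
        if self.calibrator not in set(self.data["sample"]):
            raise ParameterError(f"calibrator sample {self.calibrator!r} not present")
        reps = self.data.dropna(subset=["ct_target", "ct_reference"]).groupby(
            ["gene", "sample"]).size()
        if (reps < 3).any():
            raise ParameterError("need >= 3 usable replicates per gene and sample")


def ddct(qpcr: QpcrSet) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per replicate; ddCt subtracts the mean
    calibrator dCt of the same gene; relative expression is 2^-ddCt.
    Rows lacking either Ct are dropped (logged).  Each non-calibrator
    sample is compared with the calibrator by a two-sample t-test on the
    replicate dCt values.

    Returns one row per (gene, sample): rel_expression, sd (SD of the
    per-replicate 2^-ddCt values), n, p_vs_calibrator (NaN for the
    calibrator itself) and significance stars at P = 0.01.
    """
    d = qpcr.data.copy()
    bad = d["ct_target"].isna() | d["ct_reference"].isna()
    if bad.any():
        logger.info("dropping %d qPCR replicates lacking a Ct value", int(bad.sum()))
        d = d[~bad]
    d["dct"] = d["ct_target"] - d["ct_reference"]
    cal_mean = d[d["sample"] == qpcr.calibrator].groupby("gene")["dct"].mean()
    rows = []
    for (gene, sample), sub in d.groupby(["gene", "sample"]):
        if gene not in cal_mean.index:
            logger.warning("gene %s lacks calibrator measurements; skipped", gene)
            continue
        ddct_reps = sub["dct"] - cal_mean[gene]
        rel = np.power(2.0, -ddct_reps)
        if sample == qpcr.calibrator:
            p = np.nan
        else:
            cal_reps = d[(d["gene"] == gene) & (d["sample"] == qpcr.calibrator)]["dct"]
            p = float(stats.ttest_ind(sub["dct"], cal_reps).pvalue)
        rows.append((gene, sample, float(rel.mean()), float(rel.std(ddof=1)),
                     len(sub), p, "**" if (p == p and p <= 0.01) else ""))
    return pd.DataFrame(rows, columns=["gene", "sample", "rel_expression", "sd",
                                       "n", "p_vs_calibrator", "stars"])
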