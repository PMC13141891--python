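"""Sloan neutral community model: fit, classification, stringent filtering.

The Sloan neutral community model (SNCM) predicts how often a taxon is
detected across local communities from its mean relative abundance in the
metacommunity, assuming only stochastic birth-death drift and immigration at
a migration probability m. Under the model the local relative abundance x of
a taxon with metacommunity abundance p follows

    x ~ Beta(N*m*p, N*m*(1-p)),

where N is the local community size (taken as mean reads per sample). With a
detection limit d (by default one read, d = 1/N) the predicted detection
frequency is the upper tail P(x > d) = 1 - I_d(N*m*p, N*m*(1-p)), where I is
the regularized incomplete beta function. m is estimated by non-linear least
squares of observed on predicted frequencies; 95% Wilson score intervals
around the predictions partition taxa into Neutral (within the envelope),
Above (detected more often than predicted) and Below (less often). A
stringent four-stage filter then isolates high-confidence deviant taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .features import FeatureTable, relative_abundance

logger = logging.getLogger(__name__)

PARTITIONS = ("Neutral", "Above", "Below")


@dataclass(frozen=True)
class TaxonNeutralRecord:
    """Per-taxon SNCM outcome.

    p: mean relative abundance across samples; freq: observed detection
    frequency; freq_pred: model-predicted detection frequency; ci bounds:
    Wilson envelope around the prediction; partition: Neutral/Above/Below.
    """

    taxon_id: str
    p: float
    freq: float
    freq_pred: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    partition: Optional[str] = None


@dataclass
class NeutralFit:
    """Fitted SNCM for one group of samples."""

    m: float
    N: float
    d: float
    r_squared: float
    rmse: float
    aic: float
    bic: float
    n_samples: int
    records: list[TaxonNeutralRecord] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    def partition_counts(self) -> dict[str, int]:
        out = {k: 0 for k in PARTITIONS}
        for r in self.records:
            if r.partition is not None:
                out[r.partition] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon_id": r.taxon_id,
                    "p": r.p,
                    "freq": r.freq,
                    "freq_pred": r.freq_pred,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "partition": r.partition,
                }
                for r in self.records
            ]
        )


@dataclass(frozen=True)
class FilterConfig:
    """Stringent-filter thresholds, applied in order.

    1. mean relative abundance strictly greater than min_abundance;
    2. partition in keep_partitions;
    3. detection frequency >= min_freq;
    4. |freq - freq_pred| > min_deviation (or freq_pred > min_deviation when
       literal_stage4 is set, the alternative literal reading).
    """

    min_abundance: float = 0.01
    keep_partitions: frozenset = frozenset({"Above", "Below"})
    min_freq: float = 0.2
    min_deviation: float = 0.05
    literal_stage4: bool = False

    def __post_init__(self) -> None:
        for name in ("min_abundance", "min_freq", "min_deviation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        object.__setattr__(self, "keep_partitions", frozenset(self.keep_partitions))


def filter_zero_taxa(table: FeatureTable) -> FeatureTable:
    """Drop taxa with zero counts across all samples; samples are unchanged."""
    keep = table.counts.sum(axis=1) > 0
    if keep.all():
        return table
    idx = np.flatnonzero(keep)
    return FeatureTable(
        table.counts[idx], [table.taxon_ids[i] for i in idx], list(table.sample_ids), table.metadata
    )


def summarize_table(table: FeatureTable):
    """Per-taxon (p, freq) plus community size N and sample count.

    p_i is the mean over samples of the per-sample relative abundance of taxon
    i; freq_i is the fraction of samples where taxon i has a nonzero count; N
    is the mean per-sample total count.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("empty feature table")
    rel = relative_abundance(table)
    p = rel.mean(axis=1)
    freq = (table.counts > 0).mean(axis=1)
    N = float(table.counts.sum(axis=0).mean())
    return p, freq, N, table.n_samples


def predict_freq(p, m: float, N: float, d: float):
    """SNCM-predicted detection frequency: P(Beta(N*m*p, N*m*(1-p)) > d).

    Vectorized over p. Monotone non-decreasing in p for fixed (m, N, d), and
    in m whenever p > d (larger m concentrates local abundance around p, which
    pushes detection toward 1 when p is above the detection limit and toward 0
    when it is below).
    """
    p = np.asarray(p, dtype=float)
    if not 0 < m < 1:
        raise ValueError("m must be in (0, 1)")
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 < d < 1:
        raise ValueError("d must be in (0, 1)")
    a = N * m * p
    b = N * m * (1.0 - p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta shape parameters must be positive (need 0 < p < 1)")
    out = 1.0 - special.betainc(a, b, d)
    return float(out) if out.ndim == 0 else out


def wilson_interval(successes: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    `successes` may be non-integer: the classification step passes the
    model-expected count freq_pred * n_samples without rounding.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    # at the boundaries the exact bound is the boundary itself; avoid rounding dust
    lo = 0.0 if successes == 0 else float(max(0.0, center - half))
    hi = 1.0 if successes == n else float(min(1.0, center + half))
    return lo, hi


def classify(
    records: list[TaxonNeutralRecord], n_samples: int, alpha: float = 0.05
) -> list[TaxonNeutralRecord]:
    """Partition taxa against the Wilson envelope around their predictions.

    A taxon is Above when its observed frequency strictly exceeds the upper
    bound, Below when strictly under the lower bound, and Neutral on the
    closed interval (an observed frequency exactly on a bound falls within
    the CI).
    """
    out = []
    for r in records:
        if r.freq_pred is None:
            raise ValueError(f"taxon {r.taxon_id}: freq_pred not set; fit the model first")
        lo, hi = wilson_interval(r.freq_pred * n_samples, n_samples, alpha)
        if r.freq > hi:
            part = "Above"
        elif r.freq < lo:
            part = "Below"
        else:
            part = "Neutral"
        out.append(replace(r, ci_lower=lo, ci_upper=hi, partition=part))
    return out


_MULTISTART = (0.001, 0.01, 0.1, 0.5)
_M_BOUNDS = (1e-6, 1 - 1e-6)


def fit_m(p, freq, N: float, d: float) -> float:
    """Estimate the migration probability m by bounded least squares.

    Minimizes sum_i (freq_i - predict_freq(p_i, m, N, d))^2 over
    m in (1e-6, 1 - 1e-6). One-dimensional and deterministic; multistart
    guards against flat regions of the loss.
    """
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)

    def residuals(m_arr):
        return predict_freq(p, float(m_arr[0]), N, d) - freq

    best = None
    for m0 in _MULTISTART:
        try:
            sol = optimize.least_squares(residuals, x0=[m0], bounds=([_M_BOUNDS[0]], [_M_BOUNDS[1]]))
        except Exception:  # singular start; other starts cover it
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("SNCM optimizer failed to converge from all starts")
    return float(best.x[0])


def fit_neutral(
    table: FeatureTable, d: Optional[float] = None, alpha: float = 0.05, min_taxa: int = 10
) -> NeutralFit:
    """Fit the SNCM to a feature table and classify every taxon.

    Estimates the migration probability m by bounded non-linear least squares
    of observed on predicted detection frequencies (multistart to avoid local
    minima; the problem is one-dimensional and deterministic). The detection
    limit d defaults to one read, 1/N. Fit quality is summarized by R^2 on
    the frequency scale, RMSE = sqrt(SSE/(n_taxa - 1)), and AIC/BIC from a
    Gaussian residual log-likelihood with k = 2 (m and residual sigma).
    """
    table = filter_zero_taxa(table)
    p, freq, N, n_samples = summarize_table(table)
    n = len(p)
    if n < min_taxa:
        raise ValueError(f"need at least {min_taxa} taxa after zero-count exclusion, got {n}")
    if d is None:
        d = 1.0 / N

    m = fit_m(p, freq, N, d)
    pred = predict_freq(p, m, N, d)
    resid = freq - pred
    sse = float(resid @ resid)
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / (n - 1)))
    # Gaussian residual likelihood, k = 2 (m, sigma)
    sigma2 = max(sse / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = 2
    aic = 2 * k - 2 * loglik
    bic = k * np.log(n) - 2 * loglik

    records = [
        TaxonNeutralRecord(table.taxon_ids[i], float(p[i]), float(freq[i]), float(pred[i]))
        for i in range(n)
    ]
    records = classify(records, n_samples, alpha)
    return NeutralFit(m, N, float(d), float(r2), rmse, float(aic), float(bic), n_samples, records)


def stringent_filter(
    records: list[TaxonNeutralRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[TaxonNeutralRecord], dict[str, int]]:
    """Apply the four-stage stringent filter cascade to classified records.

    Returns (survivors, audit) where audit counts records removed at each
    stage plus the survivor count; the counts sum to the input size.
    """
    audit = {"input": len(records), "removed_abundance": 0, "removed_partition": 0,
             "removed_freq": 0, "removed_deviation": 0, "survivors": 0}
    survivors = []
    for r in records:
        if r.partition is None:
            raise ValueError(f"taxon {r.taxon_id}: unclassified record")
        if not (r.p > config.min_abundance):
            audit["removed_abundance"] += 1
            continue
        if r.partition not in config.keep_partitions:
            audit["removed_partition"] += 1
            continue
        if not (r.freq >= config.min_freq):
            audit["removed_freq"] += 1
            continue
        if config.literal_stage4:
            dev_ok = r.freq_pred > config.min_deviation
        else:
            dev_ok = abs(r.freq - r.freq_pred) > config.min_deviation
        if not dev_ok:
            audit["removed_deviation"] += 1
            continue
        survivors.append(r)
    audit["survivors"] = len(survivors)
    return survivors, audit


def run_sncm(
    table: FeatureTable,
    group_by: Optional[str] = None,
    d: Optional[float] = None,
    alpha: float = 0.05,
    filter_config: FilterConfig = FilterConfig(),
    min_samples: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, NeutralFit]]:
    """Fit, classify and stringently filter the SNCM per metadata group.

    When group_by is None the whole table is one group ("all"). Groups with
    fewer than min_samples samples are skipped with a warning. Returns a tidy
    per-taxon records frame, a one-row-per-group summary frame, and the
    NeutralFit objects keyed by group label.
    """
    if group_by is None:
        groups = [("all", table)]
    else:
        groups = list(table.groupby_metadata(group_by))

    fits: dict[str, NeutralFit] = {}
    rec_rows = []
    sum_rows = []
    for label, sub in groups:
        label = str(label)
        if sub.n_samples < min_samples:
            logger.warning("group %s skipped: only %d samples (< %d)", label, sub.n_samples, min_samples)
            continue
        fit = fit_neutral(sub, d=d, alpha=alpha)
        survivors, audit = stringent_filter(fit.records, filter_config)
        passed = {r.taxon_id for r in survivors}
        fits[label] = fit
        for r in fit.records:
            rec_rows.append(
                {
                    "taxon_id": r.taxon_id,
                    "group": label,
                    "p": r.p,
                    "freq": r.freq,
                    "freq_pred": r.freq_pred,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "partition": r.partition,
                    "passed_stringent": r.taxon_id in passed,
                }
            )
        counts = fit.partition_counts()
        sum_rows.append(
            {
                "group": label,
                "n_taxa": fit.n_taxa,
                "n_samples": fit.n_samples,
                "m": fit.m,
                "N": fit.N,
                "d": fit.d,
                "r2": fit.r_squared,
                "rmse": fit.rmse,
                "aic": fit.aic,
                "bic": fit.bic,
                "n_neutral": counts["Neutral"],
                "n_above": counts["Above"],
                "n_below": counts["Below"],
                "n_stringent": audit["survivors"],
            }
        )
    return pd.DataFrame(rec_rows), pd.DataFrame(sum_rows), fits
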