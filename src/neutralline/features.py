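"""Feature-table model, core-microbiota prevalence, and diversity statistics.

The FeatureTable is a taxon-by-sample integer count matrix with per-sample
metadata (sub-line, generation, day, replicate). On top of it this module
provides relative abundance, prevalence-threshold core-taxon selection,
Shannon alpha diversity, pairwise Wilcoxon rank-sum tests with
Benjamini-Hochberg correction, and tie-aware Spearman correlations with
Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("sub_line", "generation", "day", "replicate")


@dataclass
class FeatureTable:
    """Taxon-by-sample count table with per-sample metadata.

    counts[i, j] is the number of reads of taxon i in sample j. Metadata is a
    DataFrame indexed by sample_id; any columns are allowed but grouping
    operations typically use sub_line / generation / day / replicate.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxon-by-sample matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            missing = set(self.sample_ids) - set(self.metadata.index)
            if missing:
                raise ValueError(f"metadata missing for samples: {sorted(missing)}")
            self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(
            self.counts[:, idx], list(self.taxon_ids), list(sample_ids), self.metadata.loc[list(sample_ids)]
        )

    def groupby_metadata(self, column: str):
        """Yield (group label, sub-table) pairs for a metadata column."""
        if column not in self.metadata.columns:
            raise KeyError(f"metadata column {column!r} not found")
        for label, sub in self.metadata.groupby(column, sort=True, observed=True):
            yield label, self.select_samples(list(sub.index))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="taxon_id"), columns=self.sample_ids)

    def write_tsv(self, counts_path, metadata_path=None) -> None:
        self.to_frame().to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path, metadata_path=None) -> "FeatureTable":
        """Read a taxa-as-rows table (first column taxon_id) and optional metadata TSV."""
        sep = "," if str(counts_path).endswith(".csv") else "\t"
        df = pd.read_csv(counts_path, sep=sep, index_col=0)
        meta = None
        if metadata_path is not None:
            msep = "," if str(metadata_path).endswith(".csv") else "\t"
            meta = pd.read_csv(metadata_path, sep=msep, index_col=0, dtype=str)
        return cls(df.to_numpy(), [str(t) for t in df.index], [str(s) for s in df.columns], meta)


@dataclass(frozen=True)
class PrevalenceRecord:
    taxon_id: str
    prevalence: float
    mean_rel_abundance: float


def relative_abundance(table: FeatureTable) -> np.ndarray:
    """Column-normalized counts; every sample column sums to 1.

    Raises if any sample has zero total count, naming the offending samples.
    """
    totals = table.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [table.sample_ids[j] for j in np.flatnonzero(zero)]
        raise ValueError(f"samples with zero total count: {bad}")
    return table.counts / totals


def core_taxa(table: FeatureTable, threshold: float) -> list[PrevalenceRecord]:
    """Taxa detected in at least `threshold` of samples (the core microbiota).

    Prevalence is the fraction of samples with a nonzero count. Results are
    sorted by prevalence descending then taxon_id ascending.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    rel = relative_abundance(table)
    mean_rel = rel.mean(axis=1)
    records = [
        PrevalenceRecord(table.taxon_ids[i], float(prevalence[i]), float(mean_rel[i]))
        for i in np.flatnonzero(prevalence >= threshold)
    ]
    return sorted(records, key=lambda r: (-r.prevalence, r.taxon_id))


def shannon(counts, base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum q_i log q_i over taxa with q_i > 0.

    Natural log by default; pass `base` for other conventions.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero vector")
    q = counts[counts > 0] / total
    h = float(-(q * np.log(q)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def pairwise_wilcoxon_bh(values, groups) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with BH-adjusted q values.

    Returns one row per unordered group pair: (group_a, group_b, n_a, n_b, p, q).
    Groups with fewer than 2 observations are skipped with a warning. The exact
    null distribution is used for small tie-free samples, otherwise the normal
    approximation with tie correction (scipy's default policy).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        va, vb = values[groups == a], values[groups == b]
        if len(va) < 2 or len(vb) < 2:
            logger.warning("skipping pair (%s, %s): group with < 2 observations", a, b)
            continue
        stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
        rows.append({"group_a": a, "group_b": b, "n_a": len(va), "n_b": len(vb), "p": float(p)})
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "p"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def spearman_bonferroni(x, y_matrix, taxon_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Tie-aware Spearman correlation of each taxon's abundances against x.

    rho is the Pearson correlation of mid-ranks; significance via the
    t-approximation t = rho*sqrt((n-2)/(1-rho^2)) with n-2 df; p_bonferroni =
    min(1, p * number of taxa tested). Constant x or constant taxon rows give
    undefined rho, reported as NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.atleast_2d(np.asarray(y_matrix, dtype=float))
    n = len(x)
    if y.shape[1] != n:
        raise ValueError("y_matrix columns must match length of x")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if taxon_ids is None:
        taxon_ids = [f"taxon_{i}" for i in range(y.shape[0])]

    n_tests = y.shape[0]
    x_const = np.ptp(x) == 0
    rx = stats.rankdata(x)
    rows = []
    for i in range(n_tests):
        row = y[i]
        if x_const or np.ptp(row) == 0:
            logger.warning("rho undefined for taxon %s (constant input)", taxon_ids[i])
            rows.append({"taxon": taxon_ids[i], "rho": np.nan, "p": np.nan, "p_bonferroni": np.nan})
            continue
        ry = stats.rankdata(row)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(stats.pearsonr(rx, ry).statistic)
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append(
            {"taxon": taxon_ids[i], "rho": rho, "p": p, "p_bonferroni": min(1.0, p * n_tests)}
        )
    return pd.DataFrame(rows, columns=["taxon", "rho", "p", "p_bonferroni"])
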