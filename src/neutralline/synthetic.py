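"""Synthetic data generators with known ground truth.

Three generators produce every input the pipeline consumes:

* neutral/non-neutral feature tables, where local relative abundances follow
  the same Beta(N*m*p, N*m*(1-p)) detection process the SNCM fit assumes —
  deliberately, so parameter recovery is a well-posed oracle — with optional
  injected over-represented ("Above") and under-represented ("Below") taxa;
* barcoded long reads with controllable contamination classes (missing
  barcodes, off-length inserts) and strand mixing;
* additive-genetic pedigrees where mean offspring phenotype regresses on the
  mid-parent value with slope h^2.

All generators are seed-deterministic: the same config and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .demux import BarcodeSpec, reverse_complement
from .features import FeatureTable
from .heritability import Family, PedigreeTable
from .sncm import predict_freq

SUB_LINES = ("CF", "WILC", "WIL1", "WIL2", "WIL3", "WIL4")


@dataclass(frozen=True)
class CommunitySimConfig:
    """Conditions for the neutral community simulation.

    Depth defaults mirror a realistic nanopore 16S per-sample yield
    (~15,000 +/- 5,500 reads). The metacommunity abundance distribution is
    log-normal, the standard heavy-tailed shape of microbial rank-abundance
    curves.
    """

    n_taxa: int = 1500
    n_samples: int = 60
    depth_mean: float = 15000.0
    depth_sd: float = 5500.0
    m_true: float = 0.05
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    n_above: int = 0
    n_below: int = 0
    seed: int = 0
    generating_model: str = "beta_binomial"  # or "dirichlet_multinomial" (misspecified)

    def __post_init__(self) -> None:
        if self.n_above + self.n_below > self.n_taxa:
            raise ValueError("n_above + n_below must not exceed n_taxa")
        if not 0 < self.m_true < 1:
            raise ValueError("m_true must be in (0, 1)")
        if self.generating_model not in ("beta_binomial", "dirichlet_multinomial"):
            raise ValueError("unknown generating_model")


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads_per_sample: int = 200
    insert_length_range: tuple[int, int] = (1200, 1800)
    fraction_missing_barcode: float = 0.0
    fraction_off_length: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_missing_barcode + self.fraction_off_length > 1:
            raise ValueError("contamination fractions must sum to <= 1")
        lo, hi = self.insert_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid insert_length_range")


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Additive model: offspring = mu + h2*(midparent - mu) + e.

    residual_sd is the per-offspring environmental standard deviation; None
    sets it so the offspring phenotypic variance matches pheno_sd^2
    (sd * sqrt(1 - h2^2/2)), 0 gives the noise-free deterministic limit.
    Phenotype defaults are plausible black-soldier-fly pupal weights in grams.
    """

    n_families: int = 200
    h2_true: float = 0.2
    pheno_mean: float = 0.20
    pheno_sd: float = 0.03
    offspring_per_family: int = 10
    residual_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2_true <= 1:
            raise ValueError("h2_true must be in [0, 1]")


def _sample_depths(rng, config) -> np.ndarray:
    depths = np.round(rng.normal(config.depth_mean, config.depth_sd, size=config.n_samples))
    return np.maximum(depths, 1000).astype(np.int64)


def _pick_deviants(rng, expected_freq: np.ndarray, n_above: int, n_below: int):
    """Choose which taxa to perturb.

    Above taxa are drawn from taxa the neutral model expects at low-to-middle
    detection frequency (forcing them near-ubiquitous then makes them exceed
    the Wilson envelope); Below taxa from taxa expected at high frequency
    (zeroing them out drops them under it). Bands widen if too few candidates.
    """
    chosen_above = chosen_below = np.array([], dtype=int)
    if n_above:
        for lo, hi in ((0.15, 0.6), (0.05, 0.75), (0.0, 0.9)):
            cand = np.flatnonzero((expected_freq >= lo) & (expected_freq <= hi))
            if len(cand) >= n_above:
                break
        if len(cand) < n_above:
            raise ValueError("not enough taxa in the Above-injectable frequency band")
        chosen_above = rng.choice(cand, size=n_above, replace=False)
    if n_below:
        for lo, hi in ((0.85, 1.0), (0.7, 1.0), (0.5, 1.0)):
            cand = np.flatnonzero(
                (expected_freq >= lo) & (expected_freq <= hi) & ~np.isin(np.arange(len(expected_freq)), chosen_above)
            )
            if len(cand) >= n_below:
                break
        if len(cand) < n_below:
            raise ValueError("not enough taxa in the Below-injectable frequency band")
        chosen_below = rng.choice(cand, size=n_below, replace=False)
    return chosen_above, chosen_below


def simulate_neutral_table(config: CommunitySimConfig) -> tuple[FeatureTable, pd.Series]:
    """Simulate a taxon-by-sample count table under the neutral model.

    Metacommunity abundances p are log-normal draws normalized to sum to 1.
    Per sample s with depth D_s ~ round(Normal(depth_mean, depth_sd)) >= 1000,
    each taxon's local relative abundance is x ~ Beta(N*m*p, N*m*(1-p)) with
    N = depth_mean, and its count is Binomial(D_s, x). Injected "Above" taxa
    are forced present in ~98% of samples; "Below" taxa are zeroed in a random
    60% of the samples where they occurred. Returns the table and a per-taxon
    truth label Series (Neutral/Above/Below).
    """
    rng = np.random.default_rng(config.seed)
    nt, ns = config.n_taxa, config.n_samples
    raw = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=nt)
    p = raw / raw.sum()
    N = config.depth_mean
    depths = _sample_depths(rng, config)

    if config.generating_model == "beta_binomial":
        a = N * config.m_true * p
        b = N * config.m_true * (1.0 - p)
        x = rng.beta(a[:, None], b[:, None], size=(nt, ns))
        counts = rng.binomial(depths[None, :], x)
    else:
        # misspecified alternative: one Dirichlet composition per sample
        comp = rng.dirichlet(N * config.m_true * p, size=ns).T
        counts = rng.binomial(depths[None, :], comp)

    truth = np.array(["Neutral"] * nt, dtype=object)
    d = 1.0 / N
    exp_freq = predict_freq(np.clip(p, 1e-12, 1 - 1e-12), config.m_true, N, d)
    above_idx, below_idx = _pick_deviants(rng, exp_freq, config.n_above, config.n_below)

    for i in above_idx:
        truth[i] = "Above"
        n_force = int(round(0.98 * ns))
        present = rng.choice(ns, size=n_force, replace=False)
        zero_here = present[counts[i, present] == 0]
        counts[i, zero_here] = 1
    for i in below_idx:
        truth[i] = "Below"
        occupied = np.flatnonzero(counts[i] > 0)
        n_zero = int(round(0.6 * len(occupied)))
        if n_zero:
            kill = rng.choice(occupied, size=n_zero, replace=False)
            counts[i, kill] = 0

    taxon_ids = [f"taxon_{i:05d}" for i in range(nt)]
    sample_ids = [f"sample_{j:03d}" for j in range(ns)]
    meta = pd.DataFrame(
        {
            "sub_line": [SUB_LINES[j % len(SUB_LINES)] for j in range(ns)],
            "generation": [f"G{(j // len(SUB_LINES)) % 4 + 1}" for j in range(ns)],
            "day": ["D10"] * ns,
            "replicate": [f"R{j % 3 + 1}" for j in range(ns)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = FeatureTable(counts, taxon_ids, sample_ids, meta)
    return table, pd.Series(truth, index=taxon_ids, name="truth")


_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reads(
    specs: list[BarcodeSpec], config: ReadSimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate dual-barcoded amplicon reads with known truth.

    Clean reads are fwd_barcode + random insert + revcomp(rev_barcode); half
    of all reads are emitted reverse-complemented (nanopore strand mixing).
    Contaminant classes: reads missing one barcode (expected statuses
    no_forward / no_reverse) and reads whose insert length falls outside the
    1,000-2,000 bp retention window (too_short / too_long). Returns a list of
    (read_id, sequence) and a truth DataFrame with the intended sample,
    contamination class and expected demux status per read.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.insert_length_range
    reads = []
    truth_rows = []
    idx = 0
    for spec in specs:
        for _ in range(config.n_reads_per_sample):
            u = rng.random()
            if u < config.fraction_missing_barcode:
                cls = "missing_barcode"
                insert = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                if rng.random() < 0.5:
                    seq = insert + reverse_complement(spec.rev_barcode)
                    expected = "no_forward"
                else:
                    seq = spec.fwd_barcode + insert
                    expected = "no_reverse"
            elif u < config.fraction_missing_barcode + config.fraction_off_length:
                cls = "off_length"
                if rng.random() < 0.5:
                    ins_len = int(rng.integers(400, 1000))
                    expected = "too_short"
                else:
                    ins_len = int(rng.integers(2001, 2400))
                    expected = "too_long"
                insert = _random_seq(rng, ins_len)
                seq = spec.fwd_barcode + insert + reverse_complement(spec.rev_barcode)
            else:
                cls = "clean"
                expected = "assigned"
                insert = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                seq = spec.fwd_barcode + insert + reverse_complement(spec.rev_barcode)
            flipped = bool(rng.random() < 0.5)
            if flipped:
                seq = reverse_complement(seq)
            read_id = f"read_{idx:06d}"
            idx += 1
            reads.append((read_id, seq))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample_id": spec.sample_id,
                    "class": cls,
                    "expected_status": expected,
                    "flipped": flipped,
                }
            )
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_pedigree(config: PedigreeSimConfig) -> PedigreeTable:
    """Simulate an additive-genetic pedigree.

    Parents are Normal(pheno_mean, pheno_sd); each offspring is
    mu + h2*(midparent - mu) + e with e ~ Normal(0, residual_sd). The OLS
    slope of mean offspring on mid-parent is then an unbiased estimate of
    h2_true. Weights are floored at a small positive value (they are masses).
    """
    rng = np.random.default_rng(config.seed)
    if config.residual_sd is None:
        res_sd = config.pheno_sd * np.sqrt(max(0.0, 1.0 - config.h2_true**2 / 2.0))
    else:
        res_sd = config.residual_sd
    fams = []
    for i in range(config.n_families):
        sire = max(1e-6, rng.normal(config.pheno_mean, config.pheno_sd))
        dam = max(1e-6, rng.normal(config.pheno_mean, config.pheno_sd))
        mp = (sire + dam) / 2.0
        expect = config.pheno_mean + config.h2_true * (mp - config.pheno_mean)
        kids = expect + rng.normal(0.0, res_sd, size=config.offspring_per_family)
        kids = np.maximum(kids, 1e-6)
        fams.append(Family(f"fam_{i:04d}", float(sire), float(dam), tuple(float(k) for k in kids)))
    return PedigreeTable(fams)
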