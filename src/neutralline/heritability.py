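"""Narrow-sense heritability by mid-parent-offspring regression.

h^2 is estimated as the slope b_op of the ordinary least-squares regression of
mean offspring phenotype on mid-parent phenotype (the average of the two
parents), following the classic quantitative-genetics result that the
expected slope of this regression equals the additive-genetic fraction of
phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Family:
    family_id: str
    sire_weight: float
    dam_weight: float
    offspring_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        weights = (self.sire_weight, self.dam_weight, *self.offspring_weights)
        if any(w <= 0 for w in weights):
            raise ValueError(f"family {self.family_id}: all weights must be positive")
        if not self.offspring_weights:
            raise ValueError(f"family {self.family_id}: at least one offspring required")

    @property
    def midparent(self) -> float:
        return midparent(self.sire_weight, self.dam_weight)

    @property
    def offspring_mean(self) -> float:
        return float(np.mean(self.offspring_weights))


@dataclass
class PedigreeTable:
    families: list[Family] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate family_id in pedigree")

    @classmethod
    def read_tsv(cls, path) -> "PedigreeTable":
        """Read a TSV with columns family_id, sire_weight, dam_weight,
        offspring_weight — one row per offspring."""
        df = pd.read_csv(path, sep="\t")
        required = {"family_id", "sire_weight", "dam_weight", "offspring_weight"}
        if not required.issubset(df.columns):
            raise ValueError(f"pedigree table needs columns {sorted(required)}")
        fams = []
        for fid, sub in df.groupby("family_id", sort=True):
            sires = sub["sire_weight"].unique()
            dams = sub["dam_weight"].unique()
            if len(sires) != 1 or len(dams) != 1:
                raise ValueError(f"family {fid}: inconsistent parental weights across rows")
            fams.append(Family(str(fid), float(sires[0]), float(dams[0]),
                               tuple(float(w) for w in sub["offspring_weight"])))
        return cls(fams)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family_id": f.family_id, "sire_weight": f.sire_weight,
             "dam_weight": f.dam_weight, "offspring_weight": w}
            for f in self.families for w in f.offspring_weights
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """h2 is the regression slope b_op; slope_se is an OLS addition beyond
    the classic estimate, for completeness."""

    h2: float
    intercept: float
    r_squared: float
    n_families: int
    slope_se: float


def midparent(sire: float, dam: float) -> float:
    """Mid-parent value: the mean of the two parental phenotypes."""
    if sire <= 0 or dam <= 0:
        raise ValueError("parental weights must be positive")
    return (sire + dam) / 2.0


def estimate_h2(pedigree: PedigreeTable, weight_by_offspring: bool = False) -> HeritabilityEstimate:
    """OLS of family mean offspring weight on mid-parent weight; h2 = slope.

    Unweighted by default (each family mean counts once); set
    weight_by_offspring to weight families by their offspring count.
    """
    fams = pedigree.families
    if len(fams) < 3:
        raise ValueError("need at least 3 families")
    x = np.array([f.midparent for f in fams])
    y = np.array([f.offspring_mean for f in fams])
    if np.ptp(x) == 0:
        raise ValueError("all mid-parent values identical; slope undefined")
    if weight_by_offspring:
        w = np.array([len(f.offspring_weights) for f in fams], dtype=float)
        sw = np.sqrt(w)
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        yhat = intercept + slope * x
        ybar = np.average(y, weights=w)
        r2 = 1 - np.sum(w * (y - yhat) ** 2) / np.sum(w * (y - ybar) ** 2)
        dof = len(fams) - 2
        s2 = np.sum(w * (y - yhat) ** 2) / dof
        se = float(np.sqrt(s2 / np.sum(w * (x - np.average(x, weights=w)) ** 2)))
        return HeritabilityEstimate(slope, intercept, float(r2), len(fams), se)
    res = stats.linregress(x, y)
    return HeritabilityEstimate(
        float(res.slope), float(res.intercept), float(res.rvalue**2), len(fams), float(res.stderr)
    )
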