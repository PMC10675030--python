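"""Trial-level statistics: variance components, broad-sense heritability,
treatment reductions, variety-mean correlations and soil-water conversions.

Heritability on an entry-mean basis uses the printed single-environment
form H² = σ²g / (σ²g + σ²/r); a multi-environment form adding the
genotype-by-environment term, H² = σ²g / (σ²g + σ²ge/e + σ²/(r·e)), is
available behind a flag.  Variance components come from the balanced
ANOVA method of moments with negative estimates truncated at zero; REML is
deliberately not used to keep the module dependency-light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VarianceComponents",
    "variance_components",
    "broad_sense_heritability",
    "treatment_reduction",
    "variety_mean_correlation",
    "volumetric_soil_water",
    "soil_water_depletion",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components of a variety trial.

    ``sigma2_g``: genotypic variance; ``sigma2_e``: error variance;
    ``sigma2_ge``: genotype-by-environment variance (0 for a single
    environment); ``r`` replicates per genotype and environment; ``e``
    number of environments.
    """

    sigma2_g: float
    sigma2_e: float
    sigma2_ge: float = 0.0
    r: int = 1
    e: int = 1

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_e, self.sigma2_ge) < 0:
            raise ValueError("variance components must be >= 0")
        if self.r < 1 or self.e < 1:
            raise ValueError("need r >= 1 and e >= 1")


def variance_components(
    table: pd.DataFrame,
    trait: str,
    variety_col: str = "variety",
    environment_col: str | None = None,
) -> VarianceComponents:
    """Estimate variance components for one trait from a balanced trial.

    Single environment: one-way variety ANOVA mean squares give
    σ² = MS_error and σ²g = max(0, (MS_variety − MS_error)/r).
    With ``environment_col`` and ≥ 2 environments, the two-way crossed
    layout additionally yields
    σ²ge = max(0, (MS_GE − MS_error)/r) and
    σ²g = max(0, (MS_variety − MS_GE)/(r·e)).
    """
    df = table.dropna(subset=[trait, variety_col]).copy()
    if df[variety_col].isna().any():
        raise ValueError("missing variety labels")
    g = df[variety_col].nunique()
    if g < 2:
        raise ValueError("need >= 2 varieties")

    envs = (
        df[environment_col].unique() if environment_col is not None else [None]
    )
    e = len(envs)
    counts = (
        df.groupby([variety_col] + ([environment_col] if e > 1 else []))[trait]
        .size()
    )
    r = int(counts.iloc[0])
    if counts.nunique() > 1:
        raise ValueError("unbalanced table: unequal replicate counts")
    if r < 2:
        raise ValueError("single replicate: genotypic variance unidentifiable")

    y = df[trait].to_numpy(dtype=float)
    grand = y.mean()

    if e == 1:
        cell_means = df.groupby(variety_col)[trait].mean().to_numpy()
        ss_g = r * float(((cell_means - grand) ** 2).sum())
        ms_g = ss_g / (g - 1)
        resid = y - df.groupby(variety_col)[trait].transform("mean").to_numpy()
        ms_e = float((resid ** 2).sum()) / (g * (r - 1))
        return VarianceComponents(
            sigma2_g=max(0.0, (ms_g - ms_e) / r),
            sigma2_e=ms_e,
            sigma2_ge=0.0,
            r=r,
            e=1,
        )

    cell = df.groupby([variety_col, environment_col])[trait].mean()
    gm = df.groupby(variety_col)[trait].mean()
    em = df.groupby(environment_col)[trait].mean()
    ms_g = r * e * float(((gm - grand) ** 2).sum()) / (g - 1)
    inter = (
        cell
        - gm.reindex(cell.index.get_level_values(0)).to_numpy()
        - em.reindex(cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ms_ge = r * float((inter ** 2).sum()) / ((g - 1) * (e - 1))
    resid = (
        y
        - df.groupby([variety_col, environment_col])[trait]
        .transform("mean")
        .to_numpy()
    )
    ms_e = float((resid ** 2).sum()) / (g * e * (r - 1))
    return VarianceComponents(
        sigma2_g=max(0.0, (ms_g - ms_ge) / (r * e)),
        sigma2_e=ms_e,
        sigma2_ge=max(0.0, (ms_ge - ms_e) / r),
        r=r,
        e=e,
    )


def broad_sense_heritability(
    components: VarianceComponents, multi_environment: bool = False
) -> float:
    """Broad-sense heritability H² in [0, 1] on an entry-mean basis.

    Default form: H² = σ²g / (σ²g + σ²/r).  With
    ``multi_environment=True`` the genotype-by-environment variance enters
    the denominator: H² = σ²g / (σ²g + σ²ge/e + σ²/(r·e)).
    """
    c = components
    if multi_environment:
        denom = c.sigma2_g + c.sigma2_ge / c.e + c.sigma2_e / (c.r * c.e)
    else:
        denom = c.sigma2_g + c.sigma2_e / c.r
    if denom <= 0:
        raise ValueError("all variance components are zero: H² undefined")
    return c.sigma2_g / denom


def treatment_reduction(mean_reference: float, mean_other: float) -> float:
    """Percent reduction of ``mean_other`` relative to ``mean_reference``."""
    if mean_reference <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_reference - mean_other) / mean_reference


def variety_mean_correlation(
    table: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    variety_col: str | None = None,
) -> float:
    """Pearson correlation between two traits over variety means.

    If ``variety_col`` is given the table is first reduced to variety
    means; otherwise each row is already one variety.
    """
    df = table
    if variety_col is not None:
        df = table.groupby(variety_col)[[trait_x, trait_y]].mean()
    x = df[trait_x].to_numpy(dtype=float)
    y = df[trait_y].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 variety means")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a trait")
    return float(sps.pearsonr(x, y).statistic)


def volumetric_soil_water(gravimetric_pct, bulk_density: float = 1.4):
    """Gravimetric (%) to volumetric (%) soil water: θv = θg·ρb."""
    theta = np.asarray(gravimetric_pct, dtype=float)
    if (theta < 0).any() or bulk_density < 0:
        raise ValueError("inputs must be >= 0")
    out = theta * bulk_density
    return float(out) if out.ndim == 0 else out


def soil_water_depletion(reading_t1, reading_t2):
    """Percent soil-water depletion between two dates, per depth.

    100·(t1 − t2)/t1, vectorised over measurement depths.
    """
    r1 = np.asarray(reading_t1, dtype=float)
    r2 = np.asarray(reading_t2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("depth profiles differ in length")
    if (r1 <= 0).any():
        raise ValueError("baseline readings must be positive")
    out = 100.0 * (r1 - r2) / r1
    return float(out) if out.ndim == 0 else out
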