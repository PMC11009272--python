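"""The abundance-balance statistics: theoretical AOA:NOB band, per-sample
ratios, raw-scale regression, bootstrap median CI, and the reattribution
comparison.

The theoretical band comes from two trait ratios of marine nitrifier
isolates: ammonia-oxidizing archaea have roughly 1.6-3.1x (mean 2.3) the
biomass yield of nitrite-oxidizing bacteria but only 0.20-0.63x (mean 0.30)
their per-cell carbon quota. With ammonia and nitrite oxidation rates
balanced (no nitrite accumulation), the expected AOA:NOB cell ratio is
yield_ratio / quota_ratio: the published band is 2.6-15.8 with a central
value of ~6.9. Recomputing the band from the printed, rounded traits gives
(2.540, 7.667, 15.500) instead — the small discrepancy presumably reflects
unrounded trait values, and reports flag it whenever the computed mode is
used.

Regressions are ordinary least squares of AOA on NOB on raw (untransformed)
abundances; the median's confidence interval is a seeded percentile
bootstrap. Samples with zero NOB are excluded from ratio statistics but kept
in regressions (a zero is a legitimate regression point).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError
from .guilds import CANONICAL_NOB, GUILD_AOA, GUILD_CANDIDATE
from .profiles import AbundanceMatrix, RedoxZones

BAND_MODES = ("published", "computed")


@dataclasses.dataclass(frozen=True)
class TraitSet:
    """(low, mean, high) trait ratios of AOA relative to NOB."""

    yield_ratio: tuple[float, float, float] = (1.6, 2.3, 3.1)
    quota_ratio: tuple[float, float, float] = (0.20, 0.30, 0.63)

    def validate(self) -> None:
        for name in ("yield_ratio", "quota_ratio"):
            low, mean, high = getattr(self, name)
            if not 0 < low <= mean <= high:
                raise ParameterError(f"{name} must satisfy 0 < low <= mean <= high")


@dataclasses.dataclass(frozen=True)
class Band:
    """Theoretical AOA:NOB cell-abundance ratio band."""

    low: float
    central: float
    high: float
    provenance: str = "published"

    def __post_init__(self) -> None:
        if not self.low <= self.central <= self.high:
            raise ParameterError("band must satisfy low <= central <= high")


#: The published band for marine AOA vs NOB under balanced oxidation rates.
PUBLISHED_BAND = Band(low=2.6, central=6.9, high=15.8, provenance="published")


def theoretical_band(traits: TraitSet | None = None, mode: str = "published") -> Band:
    """Theoretical AOA:NOB cell ratio band.

    ``published`` returns the literature band (2.6, 6.9, 15.8). ``computed``
    derives the band from the trait ratios: low = yield.low / quota.high,
    central = yield.mean / quota.mean, high = yield.high / quota.low.
    """
    if mode not in BAND_MODES:
        raise ParameterError(f"band mode must be one of {BAND_MODES}, got {mode!r}")
    if mode == "published":
        return PUBLISHED_BAND
    traits = traits or TraitSet()
    traits.validate()
    if traits.quota_ratio[0] <= 0:
        raise ParameterError("quota_ratio low bound must be positive")
    return Band(
        low=traits.yield_ratio[0] / traits.quota_ratio[2],
        central=traits.yield_ratio[1] / traits.quota_ratio[1],
        high=traits.yield_ratio[2] / traits.quota_ratio[0],
        provenance="computed_from_traits",
    )


@dataclasses.dataclass
class RegressionFit:
    slope: float
    intercept: float | None
    r_squared: float
    n: int
    with_intercept: bool


@dataclasses.dataclass
class RatioSummary:
    n: int
    ratios: pd.Series
    median: float
    ci_level: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_above_band: int
    n_below_band: int
    excluded_samples: list[str]

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())


def sample_ratios(
    aoa: pd.Series, nob: pd.Series
) -> tuple[pd.Series, list[str]]:
    """Per-sample AOA:NOB ratios; samples with zero NOB are excluded and listed."""
    aoa, nob = aoa.align(nob, join="inner")
    if len(aoa) == 0:
        raise ParameterError("no paired samples for ratio computation")
    excluded = list(nob.index[nob == 0])
    valid = nob > 0
    if not valid.any():
        raise ParameterError("every sample has zero NOB; no ratios computable")
    return (aoa[valid] / nob[valid]), excluded


def fit_abundance_regression(
    aoa: Sequence[float], nob: Sequence[float], with_intercept: bool = True
) -> RegressionFit:
    """OLS of AOA on NOB on raw abundances, with or without an intercept."""
    y = np.asarray(aoa, dtype=float)
    x = np.asarray(nob, dtype=float)
    if y.shape != x.shape:
        raise ParameterError("aoa and nob must have equal length")
    n = len(y)
    if n < 3:
        raise ParameterError(f"regression needs n >= 3, got n = {n}")
    if with_intercept and np.ptp(x) == 0:
        raise ParameterError("nob abundances have zero variance; slope is undefined")
    if not with_intercept and not np.any(x != 0):
        raise ParameterError("all nob abundances are zero; through-origin slope undefined")
    X = sm.add_constant(x) if with_intercept else x[:, None]
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[-1])
    intercept = float(fit.params[0]) if with_intercept else None
    r2 = float(min(max(fit.rsquared, 0.0), 1.0))
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r2, n=n,
                         with_intercept=with_intercept)


def summarize_ratios(
    ratios: pd.Series | Sequence[float],
    band: Band,
    ci_level: float = 0.99,
    n_boot: int = 10000,
    seed: int | None = None,
    excluded_samples: Sequence[str] = (),
) -> RatioSummary:
    """Median with a seeded percentile-bootstrap CI, plus band exceedance counts.

    ``n_above_band``/``n_below_band`` count ratios strictly above ``band.high``
    and strictly below ``band.low``.
    """
    if not isinstance(ratios, pd.Series):
        ratios = pd.Series(np.asarray(ratios, dtype=float))
    if len(ratios) < 1:
        raise ParameterError("summarize_ratios needs at least one ratio")
    if not 0 < ci_level < 1:
        raise ParameterError("ci_level must be in (0, 1)")
    values = ratios.to_numpy(dtype=float)
    median = float(np.median(values))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot_medians = np.median(values[idx], axis=1)
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(boot_medians, [alpha / 2, 1.0 - alpha / 2])
    return RatioSummary(
        n=len(values),
        ratios=ratios,
        median=median,
        ci_level=ci_level,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        ci_method="percentile_bootstrap",
        n_above_band=int((values > band.high).sum()),
        n_below_band=int((values < band.low).sum()),
        excluded_samples=list(excluded_samples),
    )


@dataclasses.dataclass
class ArmResult:
    """One arm of the reattribution comparison (NOB with or without the candidate)."""

    summary: RatioSummary
    fit: RegressionFit
    fit_origin: RegressionFit
    mean_ratio: float


@dataclasses.dataclass
class ReattributionResult:
    without_candidate: ArmResult
    with_candidate: ArmResult
    median_ratio: float  # median(without) / median(with)
    excluded_samples: list[str]
    n_oxic: int


def reattribution_analysis(
    absolute: AbundanceMatrix,
    zones: RedoxZones,
    band: Band,
    aoa_col: str = GUILD_AOA,
    canonical_cols: Sequence[str] = CANONICAL_NOB,
    candidate_col: str = GUILD_CANDIDATE,
    ci_level: float = 0.99,
    n_boot: int = 10000,
    seed: int | None = None,
) -> ReattributionResult:
    """Compare AOA:NOB ratio statistics with and without the candidate lineage
    counted as NOB, over oxic samples only.

    Both arms use the identical sample set: samples whose canonical NOB sum is
    zero are excluded from the ratio statistics of *both* arms (they stay in
    the regressions, where a zero is legitimate). Reports the ratio of the two
    medians, which on noise-free data equals 1/(1 - f_candidate).
    """
    if absolute.kind != "absolute":
        raise ParameterError("reattribution_analysis expects an absolute AbundanceMatrix")
    for colname in (aoa_col, candidate_col, *canonical_cols):
        if colname not in absolute.values.columns:
            raise ParameterError(f"abundance matrix lacks column {colname!r}")
    oxic = [s for s in absolute.values.index if s in set(zones.sample_ids("oxic"))]
    if not oxic:
        raise ParameterError("no oxic samples to analyze")
    sub = absolute.values.loc[oxic]
    aoa = sub[aoa_col]
    canonical = sub[list(canonical_cols)].sum(axis=1)
    combined = canonical + sub[candidate_col]
    if (sub[candidate_col] == 0).all():
        warnings.warn("candidate guild has zero abundance everywhere; both arms identical")

    excluded = list(canonical.index[canonical == 0])
    valid = canonical > 0
    if not valid.any():
        raise ParameterError("canonical NOB abundance is zero in every oxic sample")

    seed_wo, seed_wi = _spawn_seeds(seed, 2)
    arms = {}
    for name, nob, boot_seed in (
        ("without", canonical, seed_wo),
        ("with", combined, seed_wi),
    ):
        ratios = aoa[valid] / nob[valid]
        summary = summarize_ratios(
            ratios, band, ci_level=ci_level, n_boot=n_boot, seed=boot_seed,
            excluded_samples=excluded,
        )
        fit = fit_abundance_regression(aoa, nob, with_intercept=True)
        fit0 = fit_abundance_regression(aoa, nob, with_intercept=False)
        arms[name] = ArmResult(
            summary=summary, fit=fit, fit_origin=fit0, mean_ratio=float(ratios.mean())
        )
    return ReattributionResult(
        without_candidate=arms["without"],
        with_candidate=arms["with"],
        median_ratio=arms["without"].summary.median / arms["with"].summary.median,
        excluded_samples=excluded,
        n_oxic=len(oxic),
    )


def _spawn_seeds(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0]) % (2**31) for c in children]
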