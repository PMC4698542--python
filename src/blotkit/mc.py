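"""Parametric-bootstrap Monte-Carlo group comparison.

The procedure, per measure and ordered (reference, comparator) pair:

1. simulate a large pool of draws from Normal(reference mean, reference SD);
2. resample n-sized subsets (n = comparator group size) from the pool,
   10,000 times by default, collecting the mean of each subset — the
   simulated sampling distribution of the mean at the comparator's n;
3. take the central (1 - alpha) empirical percentile interval of those
   means as the confidence interval;
4. flag the comparator as significantly different when its observed sample
   mean falls outside the interval (boundaries count as inside), with a
   two-sided empirical p-value floored at 1/reps.

This is the small-cohort alternative to a t-test used by the study the
package emulates: the null is fully parametric (normal with the reference
group's sample moments) and the Monte-Carlo step supplies the finite-n
sampling distribution.  Note that the reference mean and SD enter as
plug-in constants — the procedure does not propagate their own sampling
error, which makes it anti-conservative when the reference n is small
(see the methods note for measured magnitudes).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalization import GroupSummary

__all__ = [
    "MCConfig",
    "ComparisonResult",
    "simulate_pool",
    "sampling_distribution_of_means",
    "compare",
    "comparison_matrix",
    "table1_layout",
    "significance_stars",
]

#: star convention from the figure legends; p-values are compared with <=
#: so the floor at 1/reps (= 1e-4 at default reps) still earns four stars.
_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo settings: pool size, repetitions, level, seed."""

    pool_size: int = 1_000_000
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pool_size >= self.reps >= 100):
            raise ValueError("require pool_size >= reps >= 100")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    def replace(self, **kw) -> "MCConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ComparisonResult:
    """One reference-vs-comparator test on one measure."""

    measure: str
    reference: str
    comparator: str
    ref_mean: float
    ref_sd: float
    n: int
    observed: float
    ci_low: float
    ci_high: float
    significant: bool
    p_empirical: float
    stars: str

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if not (0.0 <= self.p_empirical <= 1.0):
            raise ValueError("p_empirical must lie in [0, 1]")


def significance_stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p <= level:
            return mark
    return ""


def _rng_for(config: MCConfig, *names: str) -> np.random.Generator:
    """Deterministic per-comparison stream, independent of evaluation order."""
    key = zlib.crc32("|".join(names).encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def simulate_pool(
    mean: float,
    sd: float,
    config: MCConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``pool_size`` draws from Normal(mean, sd); seeded and reproducible."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return rng.normal(mean, sd, config.pool_size)


def sampling_distribution_of_means(
    pool: np.ndarray,
    n: int,
    config: MCConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``reps`` means of n points drawn with replacement from *pool*."""
    if n < 2:
        raise ValueError("comparator group size must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    idx = rng.integers(0, len(pool), size=(config.reps, n))
    return pool[idx].mean(axis=1)


def compare(
    ref: GroupSummary,
    comp: GroupSummary,
    config: MCConfig,
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Test *comp*'s observed mean against the simulated null seeded by *ref*.

    The reference supplies (mean, SD) for the pool; the comparator supplies
    its group size and observed mean.  Boundary values count as inside the
    interval, so a degenerate SD=0 self-comparison is never significant.
    """
    if ref.measure != comp.measure:
        raise ValueError(f"measure mismatch: {ref.measure!r} vs {comp.measure!r}")
    if rng is None:
        rng = _rng_for(config, ref.measure, ref.group, comp.group)
    pool = simulate_pool(ref.mean, ref.sd, config, rng=rng)
    means = sampling_distribution_of_means(pool, comp.n, config, rng=rng)
    ci_low, ci_high = np.quantile(means, [config.alpha / 2.0, 1.0 - config.alpha / 2.0])
    observed = comp.mean
    # epsilon-scale guard so a degenerate sd=0 interval is not breached by
    # float round-off accumulated upstream; invisible at any stochastic width
    tol = 1e-9 * max(1.0, abs(ci_low), abs(ci_high))
    significant = bool(observed < ci_low - tol or observed > ci_high + tol)
    p = 2.0 * min(np.mean(means <= observed), np.mean(means >= observed))
    p = float(min(1.0, max(p, 1.0 / config.reps)))
    return ComparisonResult(
        measure=ref.measure,
        reference=ref.group,
        comparator=comp.group,
        ref_mean=ref.mean,
        ref_sd=ref.sd,
        n=comp.n,
        observed=observed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=significant,
        p_empirical=p,
        stars=significance_stars(p),
    )


def comparison_matrix(
    summaries: pd.DataFrame | Iterable[GroupSummary],
    config: MCConfig,
    references: Sequence[str] | None = None,
    comparators: Sequence[str] | None = None,
    measures: Sequence[str] | None = None,
    include_self: bool = True,
) -> pd.DataFrame:
    """All ordered (reference, comparator) comparisons for every measure.

    Returns a long frame, one row per comparison.  With the defaults the
    matrix covers every ordered group pair including self-comparisons, so a
    four-group study yields a measures x 4 x 4 grid whose wide rendering
    (:func:`table1_layout`) has one CI column per reference group.
    """
    if isinstance(summaries, pd.DataFrame):
        from .normalization import to_summaries

        summaries = to_summaries(summaries)
    else:
        summaries = list(summaries)
    by_key = {(s.measure, s.group): s for s in summaries}
    all_measures = list(dict.fromkeys(s.measure for s in summaries))
    all_groups = list(dict.fromkeys(s.group for s in summaries))
    measures = all_measures if measures is None else list(measures)
    references = all_groups if references is None else list(references)
    comparators = all_groups if comparators is None else list(comparators)

    rows = []
    for measure in measures:
        for ref_group in references:
            for comp_group in comparators:
                if not include_self and ref_group == comp_group:
                    continue
                try:
                    ref = by_key[(measure, ref_group)]
                    comp = by_key[(measure, comp_group)]
                except KeyError as e:
                    raise ValueError(f"no summary for (measure, group) = {e.args[0]}") from None
                res = compare(ref, comp, config)
                rows.append({**dataclasses.asdict(res), "is_self": ref_group == comp_group})
    return pd.DataFrame.from_records(rows)


def table1_layout(matrix: pd.DataFrame, decimals: int = 4) -> pd.DataFrame:
    """Render the long comparison matrix in the study's statistical-table shape.

    Rows are measure x comparator; one ``ci_vs_<reference>`` column per
    reference group holds the interval (with the comparison's significance
    stars), plus the comparator's observed mean.
    """
    df = matrix.copy()
    fmt = f"{{:.{decimals}f}}"
    df["cell"] = [
        f"{fmt.format(lo)}–{fmt.format(hi)}{'' if not sig else ' ' + stars}"
        for lo, hi, sig, stars in zip(
            df["ci_low"], df["ci_high"], df["significant"], df["stars"]
        )
    ]
    wide = df.pivot_table(
        index=["measure", "comparator"],
        columns="reference",
        values="cell",
        aggfunc="first",
    )
    wide.columns = [f"ci_vs_{c}" for c in wide.columns]
    observed = df.groupby(["measure", "comparator"])["observed"].first()
    wide.insert(0, "observed_mean", observed.round(decimals))
    # preserve input measure/comparator order rather than lexicographic
    order = pd.MultiIndex.from_tuples(
        list(dict.fromkeys(zip(df["measure"], df["comparator"])))
    )
    return wide.loc[order]
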