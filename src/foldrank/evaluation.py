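"""CASP-style evaluation: GDT-TS to Z-score conversion with outlier
re-standardisation, positive-sum accumulation over domains with
alternative-conformation pair averaging, TM-score threshold summaries,
head-to-head comparison, and the paired one-sided Wilcoxon test.

The Z-score protocol standardises each domain column across predictors,
drops entries below an outlier cutoff (default -2), re-standardises
every present entry against the survivors' mean and standard deviation,
and accumulates only positive Z-scores per predictor.  Alternative
conformations of one domain (e.g. v1/v2 releases) would contribute
twice, so configured pairs are averaged into a single virtual domain
before accumulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .containers import EvalTable
from .errors import ArgumentError, ConfigError

__all__ = [
    "ZscoreConfig",
    "ZscoreReport",
    "domain_zscores",
    "cumulative_zscore",
    "TmSummary",
    "summarize_tm",
    "HeadToHead",
    "head_to_head",
    "paired_onesided_test",
]


@dataclass
class ZscoreConfig:
    outlier_cutoff: float = -2.0
    clip_at_zero: bool = True
    alt_pairs: list[tuple[str, str]] = field(default_factory=list)
    sd_mode: str = "population"  # or "sample"
    #: if True, clip each member at zero before pair averaging
    #: (sensitivity mode); default averages raw z first, then clips.
    clip_before_pair_average: bool = False

    def __post_init__(self) -> None:
        if self.outlier_cutoff >= 0:
            raise ArgumentError("outlier_cutoff must be negative")
        if self.sd_mode not in ("population", "sample"):
            raise ArgumentError("sd_mode must be 'population' or 'sample'")

    @property
    def ddof(self) -> int:
        return 0 if self.sd_mode == "population" else 1


def _standardize(values: np.ndarray, reference: np.ndarray, ddof: int) -> np.ndarray:
    mean = reference.mean()
    sd = reference.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(values)
    return (values - mean) / sd


def domain_zscores(
    scores: np.ndarray | Sequence[float], config: ZscoreConfig | None = None
) -> np.ndarray:
    """Two-pass Z-scores of one domain's per-predictor accuracy scores.

    Pass 1 standardises against all present scores and drops entries
    with z below the outlier cutoff; pass 2 re-standardises every
    present entry (dropped ones included) against the survivors.  NaN
    marks predictors with no submission and stays NaN.  Fewer than two
    present scores leaves everything NaN with a warning; if outlier
    removal leaves fewer than two survivors the pass-1 scores stand.
    """
    config = config or ZscoreConfig()
    x = np.asarray(scores, dtype=np.float64)
    out = np.full_like(x, np.nan)
    present = np.isfinite(x)
    if present.sum() < 2:
        warnings.warn("fewer than 2 present scores; Z-scores undefined", stacklevel=2)
        return out
    z1 = _standardize(x[present], x[present], config.ddof)
    survivors = z1 >= config.outlier_cutoff
    if survivors.sum() < 2:
        out[present] = z1
        return out
    out[present] = _standardize(x[present], x[present][survivors], config.ddof)
    return out


@dataclass
class ZscoreReport:
    predictors: list[str]
    domains: list[str]
    per_domain_z: np.ndarray  # (n_predictors, n_domains), NaN = absent
    unit_names: list[str]  # unique domains after pair merging
    unit_z: np.ndarray  # (n_predictors, n_units), raw (unclipped)
    cumulative: np.ndarray  # (n_predictors,)
    mean_z: np.ndarray  # mean raw z over units with a submission
    unique_domain_count: int


def cumulative_zscore(table: EvalTable, config: ZscoreConfig | None = None) -> ZscoreReport:
    """Accumulate per-domain Z-scores into one number per predictor.

    Alternative-conformation pairs are averaged into one virtual domain
    (a predictor absent from one member inherits the other's value);
    with clipping on, each unique domain then contributes
    ``max(0, z)``, absences contributing 0.
    """
    config = config or ZscoreConfig()
    n_pred, n_dom = table.gdt.shape
    per_domain_z = np.column_stack(
        [domain_zscores(table.gdt[:, j], config) for j in range(n_dom)]
    ) if n_dom else np.empty((n_pred, 0))

    dom_index = {d: j for j, d in enumerate(table.domains)}
    in_pair: set[str] = set()
    for a, b in config.alt_pairs:
        for d in (a, b):
            if d not in dom_index:
                raise ConfigError(f"alternative-domain pair references unknown domain {d!r}")
            if d in in_pair:
                raise ConfigError(f"domain {d!r} appears in more than one pair")
            in_pair.add(d)
        if a == b:
            raise ConfigError(f"pair ({a!r}, {b!r}) must name two distinct domains")

    def pair_average(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
        if config.clip_before_pair_average:
            za = np.where(np.isfinite(za), np.maximum(za, 0.0), np.nan)
            zb = np.where(np.isfinite(zb), np.maximum(zb, 0.0), np.nan)
        both = np.isfinite(za) & np.isfinite(zb)
        merged = np.where(both, 0.5 * (za + zb), np.where(np.isfinite(za), za, zb))
        return merged

    unit_names: list[str] = []
    unit_cols: list[np.ndarray] = []
    for d in table.domains:
        if d not in in_pair:
            unit_names.append(d)
            unit_cols.append(per_domain_z[:, dom_index[d]])
    for a, b in config.alt_pairs:
        unit_names.append(f"{a}+{b}")
        unit_cols.append(pair_average(per_domain_z[:, dom_index[a]],
                                      per_domain_z[:, dom_index[b]]))
    unit_z = np.column_stack(unit_cols) if unit_cols else np.empty((n_pred, 0))

    contrib = np.where(np.isfinite(unit_z), unit_z, 0.0)
    if config.clip_at_zero:
        contrib = np.maximum(contrib, 0.0)
    cumulative = contrib.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_z = np.nanmean(unit_z, axis=1) if unit_z.shape[1] else np.full(n_pred, np.nan)
    return ZscoreReport(
        predictors=list(table.predictors),
        domains=list(table.domains),
        per_domain_z=per_domain_z,
        unit_names=unit_names,
        unit_z=unit_z,
        cumulative=cumulative,
        mean_z=mean_z,
        unique_domain_count=len(unit_names),
    )


@dataclass
class TmSummary:
    n: int
    mean: float
    n_above_090: int
    n_above_050: int
    fraction_above_090: float
    fraction_above_050: float
    below_090: list[str]
    below_050: list[str]


def summarize_tm(per_domain_tm: Mapping[str, float]) -> TmSummary:
    """Mean TM-score plus the near-native (>0.9) and correct-fold
    (>0.5) counts and fractions over a set of domains."""
    if not per_domain_tm:
        raise ArgumentError("summarize_tm needs a non-empty mapping")
    domains = list(per_domain_tm)
    values = np.array([per_domain_tm[d] for d in domains], dtype=float)
    above9 = values > 0.9
    above5 = values > 0.5
    return TmSummary(
        n=len(values),
        mean=float(values.mean()),
        n_above_090=int(above9.sum()),
        n_above_050=int(above5.sum()),
        fraction_above_090=float(above9.mean()),
        fraction_above_050=float(above5.mean()),
        below_090=[d for d, keep in zip(domains, ~above9) if keep],
        below_050=[d for d, keep in zip(domains, ~above5) if keep],
    )


@dataclass
class HeadToHead:
    domains: list[str]
    differences: dict[str, float]  # a - b per shared domain
    a_better: list[str]  # a - b > gap
    b_better: list[str]  # b - a > gap
    mean_a: float
    mean_b: float


def head_to_head(
    a: Mapping[str, float], b: Mapping[str, float], gap: float = 0.1
) -> HeadToHead:
    """Per-domain score differences between two predictors, with the
    domains where either side leads by more than ``gap``."""
    shared = [d for d in a if d in b]
    if not shared:
        raise ArgumentError("no shared domains between the two predictors")
    diffs = {d: a[d] - b[d] for d in shared}
    return HeadToHead(
        domains=shared,
        differences=diffs,
        a_better=[d for d in shared if diffs[d] > gap],
        b_better=[d for d in shared if -diffs[d] > gap],
        mean_a=float(np.mean([a[d] for d in shared])),
        mean_b=float(np.mean([b[d] for d in shared])),
    )


def paired_onesided_test(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> float:
    """One-sided Wilcoxon signed-rank p-value (alternative: a > b).

    Zero differences are dropped first.  The exact null distribution is
    used up to ``exact_max_n`` untied differences; beyond that (or with
    tied magnitudes) the normal approximation with tie correction
    applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ArgumentError("paired test needs equal-length samples")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise ArgumentError("all differences are zero; the test is undefined")
    if nz.size < 5:
        raise ArgumentError(
            f"only {nz.size} non-zero differences; need at least 5"
        )
    untied = len(np.unique(np.abs(nz))) == nz.size
    if nz.size <= exact_max_n and untied:
        method = "exact"
    elif nz.size <= 16:
        # ties break the exact recursion; enumerate sign flips instead
        method = stats.PermutationMethod(n_resamples=2 ** nz.size)
    else:
        method = "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="greater", method=method
    )
    return float(res.pvalue)
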