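"""Bayesian skyline reconstruction and split-time estimation.

The piecewise-linear Bayesian skyline model groups the n-1 coalescent
intervals of the genealogy into a fixed number of groups (10 in the study
configuration) and linearly interpolates the effective population size
between the group-boundary coalescent times.  The joint MCMC reuses the
phylogenetic sampler with the skyline coalescent prior; the molecular rate
enters as a sampled parameter under the CDT log-normal prior (or a fixed
conventional rate), converting mutation-scaled node times into calendar
years.  Posterior tree samples further yield a maximum clade credibility
tree with median node heights and the split-time posterior of a designated
taxon set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .cdt_calibration import RateDistributionFit
from .tem_inference import (
    MCMCTrace,
    PhyloSampler,
    _finalize_trace,
    _prior_lp,
    default_priors,
    hpd_interval,
)
from .trees import Genealogy

__all__ = [
    "SkylineModel",
    "SkylineTrajectory",
    "SplitTimePosterior",
    "skyline_loglik",
    "run_bsp_mcmc",
    "summarize_trajectory",
    "mcc_tree",
    "clade_tmrca_posterior",
]


@dataclass
class SkylineModel:
    """Grouped coalescent intervals with piecewise-linear size interpolation.

    ``group_sizes`` are the numbers of coalescent intervals per group
    (summing to n-1, youngest group first); ``sizes`` are the population
    sizes at the group boundaries, from the present (index 0) to the root
    (index n_groups), so there are n_groups + 1 of them.
    """

    group_sizes: list[int]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be positive integers")
        if self.sizes.size != len(self.group_sizes) + 1:
            raise ValueError("need n_groups + 1 boundary sizes")
        if np.any(self.sizes <= 0):
            raise ValueError("population sizes must be positive")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class SkylineTrajectory:
    times: np.ndarray  # years BP
    median: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    tmrca_median: float
    tmrca_hpd: tuple[float, float]
    generation_time: float

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_yr_bp": self.times,
                "ne_median": self.median,
                "ne_hpd_lo": self.hpd_lower,
                "ne_hpd_hi": self.hpd_upper,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SplitTimePosterior:
    samples: np.ndarray  # years BP
    median: float
    ci_lower: float
    ci_upper: float
    monophyly_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.monophyly_frequency <= 1.0:
            raise ValueError("monophyly frequency outside [0,1]")


# ---------------------------------------------------------------------------
# skyline coalescent density
# ---------------------------------------------------------------------------

def even_group_sizes(n_intervals: int, n_groups: int) -> list[int]:
    """Partition n-1 coalescent intervals as evenly as possible; the
    remainder goes to the oldest groups."""
    if n_groups < 1 or n_groups > n_intervals:
        raise ValueError("need 1 <= n_groups <= n-1")
    q, r = divmod(n_intervals, n_groups)
    return [q] * (n_groups - r) + [q + 1] * r


def _skyline_knots(events: np.ndarray, group_sizes: list[int], sizes: np.ndarray):
    cum = np.cumsum(group_sizes)
    knot_t = np.concatenate(([0.0], events[cum - 1]))
    return knot_t, sizes


def _linear_inverse_integral(a: float, b: float, na: float, nb: float) -> float:
    """Integral of dt/N over [a,b] with N linear from na at a to nb at b."""
    if b <= a:
        return 0.0
    m = (nb - na) / (b - a)
    if abs(m) < 1e-300 or abs(nb - na) < 1e-12 * max(na, nb):
        return (b - a) / (0.5 * (na + nb))
    return math.log(nb / na) / m


def _skyline_loglik_times(events: np.ndarray, n: int, group_sizes, sizes) -> float:
    if len(events) != n - 1:
        raise ValueError("events inconsistent with sample size")
    if sum(group_sizes) != n - 1:
        raise ValueError("group sizes must sum to n-1 coalescent intervals")
    knot_t, knot_s = _skyline_knots(events, list(group_sizes), np.asarray(sizes, float))
    if np.any(knot_s <= 0):
        return -np.inf

    def size_at(t: float, seg: int) -> float:
        t0, t1 = knot_t[seg], knot_t[seg + 1]
        s0, s1 = knot_s[seg], knot_s[seg + 1]
        if t1 <= t0:
            return s1
        return s0 + (s1 - s0) * (t - t0) / (t1 - t0)

    lp = 0.0
    t_prev = 0.0
    k = n
    seg = 0
    for t in events:
        while seg < len(knot_t) - 2 and knot_t[seg + 1] <= t_prev:
            seg += 1
        na, nb = size_at(t_prev, seg), size_at(t, seg)
        lp -= k * (k - 1) / 2.0 * _linear_inverse_integral(t_prev, t, na, nb)
        lp -= math.log(nb)
        t_prev = t
        k -= 1
    return lp


def skyline_loglik(gen: Genealogy, model: SkylineModel) -> float:
    """Coalescent log-density of a genealogy under the piecewise-linear
    skyline.  With one group and equal boundary sizes this is exactly the
    Kingman constant-size density."""
    n = gen.n_tips
    events = np.sort(gen.times[n:])
    return _skyline_loglik_times(events, n, model.group_sizes, model.sizes)


class SkylineDemography:
    """Skyline coalescent prior plug-in for the phylogenetic sampler.

    Sizes carry a Markov smoothing prior in the skyline tradition: the
    present-day size follows the marginal ``skyline_size`` prior and each
    older boundary size is log-normally centred on its younger neighbour
    (SD ``smoothing_sd`` log units).  Without smoothing, sizes of deep
    groups — informed by a single coalescent interval — are prior-dominated
    and drag the root height toward the prior scale.
    """

    def __init__(
        self,
        n_tips: int,
        n_groups: int,
        priors: dict,
        init_size: float = 1e-3,
        smoothing_sd: float = 1.25,
    ):
        self.group_sizes = even_group_sizes(n_tips - 1, n_groups)
        self.n_tips = n_tips
        self.prior = priors.get("skyline_size", ("lognormal", math.log(1e-3), 1.5))
        self.smoothing_sd = smoothing_sd
        self.sizes = np.full(n_groups + 1, init_size, dtype=float)

    def log_prior(self) -> float:
        if np.any(self.sizes <= 0):
            return -np.inf
        lp = _prior_lp(self.prior, self.sizes[0])
        s = self.smoothing_sd
        logs = np.log(self.sizes)
        steps = logs[1:] - logs[:-1]
        lp += float(
            -logs[1:].sum()
            - steps.size * (math.log(s) + 0.5 * math.log(2 * math.pi))
            - 0.5 * ((steps / s) ** 2).sum()
        )
        return lp

    def coal_loglik(self, events: np.ndarray, n_tips: int) -> float:
        return _skyline_loglik_times(events, n_tips, self.group_sizes, self.sizes)

    def propose(self, rng: np.random.Generator, delta: float = 1.2):
        i = int(rng.integers(self.sizes.size))
        old = self.sizes[i]
        s = math.exp(delta * (rng.random() - 0.5))
        self.sizes[i] = old * s

        def undo():
            self.sizes[i] = old

        return math.log(s), undo, "demography_skyline_size"

    def scale_all(self, s: float):
        old = self.sizes.copy()
        self.sizes = self.sizes * s

        def undo():
            self.sizes = old

        return old.size, undo

    def record(self) -> dict:
        return {f"skyline_size_{i}": float(v) for i, v in enumerate(self.sizes)}

    def sample_from_prior(self, rng: np.random.Generator) -> None:
        from .tem_inference import _prior_sample

        self.sizes = np.array([_prior_sample(self.prior, rng) for _ in self.sizes])


# ---------------------------------------------------------------------------
# joint skyline MCMC
# ---------------------------------------------------------------------------

def run_bsp_mcmc(
    aln,
    clock_prior,
    clock_kind: str = "strict",
    n_groups: int = 10,
    chain: dict | None = None,
    priors: dict | None = None,
    seed: int = 0,
    keep_trees: bool = True,
) -> MCMCTrace:
    """Joint MCMC over genealogy, substitution parameters and skyline sizes.

    ``clock_prior`` is either a :class:`RateDistributionFit` (the CDT rate
    model: the per-sample rate is drawn from the fitted density, units
    substitutions/site/year) or a fixed rate in substitutions/site/year.
    The genealogy is sampled in mutation-scaled time (sequence data alone
    cannot separate rate from time), so the rate's posterior equals its
    prior and each recorded state carries an independent rate draw used to
    convert that state's times to years.  A ``clock_rate`` column is added
    to the trace.
    """
    from .tem_inference import DEFAULT_CHAIN

    if aln.n < n_groups + 1:
        raise ValueError("need at least n_groups + 1 sequences")
    cfg = {**DEFAULT_CHAIN, **(chain or {})}
    priors_full = {**default_priors(), **(priors or {})}
    from .tem_inference import _data_driven_init

    rng = np.random.default_rng(seed)
    theta_w = _data_driven_init(aln)["theta_modern"] / 5.0
    demog = SkylineDemography(aln.n, n_groups, priors_full, init_size=theta_w)
    sampler = PhyloSampler(
        aln,
        demog,
        clock_kind=clock_kind,
        priors=priors_full,
        seed=int(rng.integers(2**31)),
    )
    params, trees = sampler.run(cfg["length"], cfg["sample_interval"], keep_trees=keep_trees)
    n_rec = len(params)
    if isinstance(clock_prior, RateDistributionFit):
        u = rng.random(n_rec)
        rates = np.array([clock_prior.rate_quantile(q) for q in u])
    else:
        rates = np.full(n_rec, float(clock_prior))
        if rates[0] <= 0:
            raise ValueError("fixed clock rate must be positive")
    params = params.assign(clock_rate=rates)
    return _finalize_trace(params, trees, cfg, seed, sampler)


def summarize_trajectory(
    trace: MCMCTrace,
    grid: int = 200,
    burn_in_fraction: float = 0.1,
    generation_time: float = 1.0,
) -> SkylineTrajectory:
    """Per-time-point posterior of Ne on a common calendar-year grid.

    For each recorded state the skyline size function is evaluated at
    t_mut = t_year * rate and converted to individuals via
    Ne = theta / (rate * generation_time); the grid spans 0 to the 97.5%
    quantile of the TMRCA in years.  Beyond a sample's own TMRCA its root
    size is held constant.
    """
    if grid < 2:
        raise ValueError("grid must have at least 2 points")
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    burn = int(len(trace.params) * burn_in_fraction)
    rec = trace.params.iloc[burn:]
    trees = trace.trees[burn:]
    if not trees or "clock_rate" not in rec.columns:
        raise ValueError("trace must carry trees and clock rates (run_bsp_mcmc)")
    size_cols = sorted(
        (c for c in rec.columns if c.startswith("skyline_size_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not size_cols:
        raise ValueError("trace carries no skyline parameters")
    rates = rec["clock_rate"].to_numpy()
    tmrca_years = np.array([g.tmrca for g in trees]) / rates
    horizon = float(np.quantile(tmrca_years, 0.975))
    tgrid = np.linspace(0.0, horizon, grid)
    ne = np.empty((len(trees), grid))
    sizes_all = rec[size_cols].to_numpy()
    group_sizes = None
    for r, (g, rate) in enumerate(zip(trees, rates)):
        n = g.n_tips
        if group_sizes is None:
            group_sizes = even_group_sizes(n - 1, len(size_cols) - 1)
        events = np.sort(g.times[n:])
        knot_t, knot_s = _skyline_knots(events, group_sizes, sizes_all[r])
        theta = np.interp(tgrid * rate, knot_t, knot_s)
        ne[r] = theta / (rate * generation_time)
    med = np.median(ne, axis=0)
    lo = np.empty(grid)
    hi = np.empty(grid)
    for j in range(grid):
        lo[j], hi[j] = hpd_interval(ne[:, j])
    t_lo, t_hi = hpd_interval(tmrca_years)
    return SkylineTrajectory(
        tgrid, med, lo, hi, float(np.median(tmrca_years)), (t_lo, t_hi), generation_time
    )


# ---------------------------------------------------------------------------
# posterior tree summaries
# ---------------------------------------------------------------------------

def _clade_heights(trees: list[Genealogy]):
    freq: Counter = Counter()
    heights: dict = {}
    for g in trees:
        for node, tips in g.clade_tipsets().items():
            freq[tips] += 1
            heights.setdefault(tips, []).append(float(g.times[node]))
    return freq, heights


def mcc_tree(trees: list[Genealogy], burn_in_fraction: float = 0.0) -> Genealogy:
    """Maximum clade credibility tree with median node heights.

    The sampled tree maximizing the product of its clades' posterior
    frequencies is selected; each of its internal nodes is assigned the
    median height of that clade across all trees containing it.  Median
    heights can produce locally negative branches (a known property of this
    summary), so the returned genealogy is not re-validated.
    """
    trees = trees[int(len(trees) * burn_in_fraction) :]
    if not trees:
        raise ValueError("no post-burn-in trees")
    tipset = set(trees[0].labels)
    if any(set(g.labels) != tipset for g in trees):
        raise ValueError("trees have inconsistent tip sets")
    freq, heights = _clade_heights(trees)
    n_trees = len(trees)
    best, best_score = None, -np.inf
    for g in trees:
        score = sum(math.log(freq[tips] / n_trees) for tips in g.clade_tipsets().values())
        if score > best_score:
            best, best_score = g, score
    out = best.copy()
    for node, tips in best.clade_tipsets().items():
        out.times[node] = float(np.median(heights[tips]))
    return out


def _as_rate_array(rate_samples, n: int, seed: int) -> np.ndarray:
    if isinstance(rate_samples, RateDistributionFit):
        rng = np.random.default_rng(seed)
        return np.array([rate_samples.rate_quantile(u) for u in rng.random(n)])
    arr = np.asarray(rate_samples, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.size != n:
        raise ValueError("need one rate per tree")
    if np.any(arr <= 0):
        raise ValueError("rates must be positive")
    return arr


def clade_tmrca_posterior(
    trees: list[Genealogy],
    taxa: list[str],
    rate_samples,
    seed: int = 0,
    burn_in_fraction: float = 0.0,
) -> SplitTimePosterior:
    """Posterior of the MRCA age (years BP) of a taxon set.

    Per tree, the mutation-scaled MRCA height of ``taxa`` is divided by that
    tree's rate — supplied per tree, as a fixed value, or drawn from a CDT
    :class:`RateDistributionFit`.  The MRCA height is used whether or not
    the set is monophyletic in that tree; the monophyly frequency is
    reported alongside.  The credibility interval is the central 95%.
    """
    trees = trees[int(len(trees) * burn_in_fraction) :]
    if not trees:
        raise ValueError("no post-burn-in trees")
    if not taxa:
        raise ValueError("empty taxon set")
    for t in taxa:
        if t not in trees[0].labels:
            raise ValueError(f"unknown taxon {t!r}")
    rates = _as_rate_array(rate_samples, len(trees), seed)
    heights = np.array([float(g.times[g.mrca(taxa)]) for g in trees])
    mono = float(np.mean([g.is_monophyletic(taxa) for g in trees]))
    years = heights / rates
    lo, hi = np.quantile(years, [0.025, 0.975])
    return SplitTimePosterior(years, float(np.median(years)), float(lo), float(hi), mono)
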