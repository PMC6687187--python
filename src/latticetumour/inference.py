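"""Likelihood-free inference of tumour evolutionary parameters.

The model has no tractable likelihood, so parameters
theta = (u, t_driver, s, d, a) are recovered by Approximate Bayesian
Computation: simulate tumours at proposed parameters, summarise them the
same way as the target (multi-bulk VAF histograms, whole-tumour VAFs, or
single-cell tree branch lengths / branching times), and keep proposals
whose distance to the target falls below a shrinking threshold.  The SMC
sampler resamples accepted particles with importance weights, perturbs
them with a per-parameter uniform kernel of half-range
sigma_i = (max_i - min_i)/2 over the previous round's accepted values, and
updates the threshold to the Q-th percentile of accepted distances each
round.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import run_with_restarts
from .params import SimulationParams
from . import phylogeny, sampling, sequencing

DEFAULT_PRIORS = {
    "u": (0.0, 100.0),
    "t_driver": (0.0, 15.0),
    "s": (0.0, 1.0),
    "d": (0.0, 1.0),
    "a": (0.0, 1.0),
}

SCHEMES = ("bulks", "whole_tumour", "tree_branch_lengths", "tree_branching_times")


# -- distances ------------------------------------------------------------


def euclidean_vaf_distance(sim_samples, target_samples, n_bins: int = 100) -> float:
    """Euclidean distance between multivariate VAF distributions.

    Each bulk's VAFs are binned into ``n_bins`` equal bins on [0, 1] and
    normalised; the per-bulk histograms are concatenated and compared by
    the Euclidean norm.
    """
    if len(sim_samples) != len(target_samples):
        raise ValueError(
            f"sample-set sizes differ: {len(sim_samples)} vs {len(target_samples)}"
        )
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def hist(v):
        v = np.asarray(v, dtype=float)
        h, _ = np.histogram(v, bins=edges)
        total = h.sum()
        return h / total if total else h.astype(float)

    a = np.concatenate([hist(v) for v in sim_samples])
    b = np.concatenate([hist(v) for v in target_samples])
    return float(np.sqrt(((a - b) ** 2).sum()))


def wasserstein_distance(x, y, p: int = 1) -> float:
    """Order-p Wasserstein distance between empirical distributions with
    uniform weights 1/m and 1/n: the L^p norm of the difference of the
    quantile functions."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input vector")
    # breakpoints of both quantile functions on (0, 1)
    qs = np.union1d(np.arange(1, len(x)) / len(x), np.arange(1, len(y)) / len(y))
    qs = np.concatenate([[0.0], qs, [1.0]])
    widths = np.diff(qs)
    mids = (qs[:-1] + qs[1:]) / 2.0
    xi = x[np.minimum((mids * len(x)).astype(int), len(x) - 1)]
    yi = y[np.minimum((mids * len(y)).astype(int), len(y) - 1)]
    return float((widths * np.abs(xi - yi) ** p).sum() ** (1.0 / p))


def distance_for_scheme(scheme: str, sim_summary, target_summary,
                        n_bins: int = 100) -> float:
    if scheme == "bulks":
        return euclidean_vaf_distance(sim_summary, target_summary, n_bins=n_bins)
    return wasserstein_distance(sim_summary, target_summary, p=1)


# -- configuration and particles ------------------------------------------


@dataclass
class ABCConfig:
    """ABC(-SMC) settings.

    ``fixed`` pins parameters at known values; the rest are free with
    uniform priors.  ``n_particles`` is the accepted-set size per round
    (round 1 draws n_particles / quantile prior samples and keeps the top
    quantile, so every round carries the same population size).
    """

    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    fixed: dict = field(default_factory=dict)
    n_particles: int = 100
    rounds: int = 10
    quantile: float = 0.5
    scheme: str = "whole_tumour"
    eps_min: float = 0.0
    n_bins: int = 100
    seed: int = 0
    max_attempts_factor: int = 40

    def __post_init__(self):
        if not 0 < self.quantile <= 1:
            raise ValueError(f"quantile must be in (0, 1], got {self.quantile}")
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        for k, (lo, hi) in self.priors.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and hi > lo):
                raise ValueError(f"prior bounds for {k!r} must be finite with hi > lo")

    @property
    def free_params(self) -> list[str]:
        return [k for k in self.priors if k not in self.fixed]


def _particle_seed(master: int, round_idx: int, particle_idx: int) -> int:
    ss = np.random.SeedSequence([int(master), int(round_idx), int(particle_idx)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class Posterior:
    """Accepted particle sets per SMC round, with weights and thresholds."""

    rounds: list  # list of DataFrames: free params + distance + weight
    eps_schedule: list
    config: ABCConfig
    aborted: bool = False

    @property
    def particles(self) -> pd.DataFrame:
        return self.rounds[-1]

    def mode(self, param: str) -> float:
        df = self.particles
        lo, hi = self.config.priors[param]
        return _posterior_mode(df[param].to_numpy(), df["weight"].to_numpy(), lo, hi)

    def modes(self) -> dict:
        return {p: self.mode(p) for p in self.config.free_params}

    def write_rounds(self, out_dir, prefix: str = "smc") -> list:
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for r, df in enumerate(self.rounds, start=1):
            path = out_dir / f"{prefix}_round{r}.tsv"
            df.assign(particle=np.arange(len(df))).to_csv(path, sep="\t", index=False)
            paths.append(path)
        return paths


def _posterior_mode(values: np.ndarray, weights: np.ndarray,
                    lo: float, hi: float) -> float:
    w = weights / weights.sum()
    if np.ptp(values) < 1e-12 * max(1.0, hi - lo):
        return float(np.average(values, weights=w))
    try:
        kde = sps.gaussian_kde(values, weights=w)
        grid = np.linspace(lo, hi, 256)
        return float(grid[int(np.argmax(kde(grid)))])
    except np.linalg.LinAlgError:
        order = np.argsort(values)
        cw = np.cumsum(w[order])
        return float(values[order][np.searchsorted(cw, 0.5)])


# -- simulator ------------------------------------------------------------


class TumourSimulator:
    """Maps a parameter vector theta to the summary the ABC scheme compares.

    The same object simulates synthetic targets (call with the true theta)
    and proposal particles.  Extinct runs restart with derived seeds.
    """

    def __init__(self, scheme: str = "whole_tumour", base_params: dict | None = None,
                 max_cells: int = 5000, depth: float = 100.0, min_alt: int = 5,
                 n_punches: int = 6, n_single_cells: int = 50, n_bins: int = 100,
                 fixed_seed: int | None = None):
        if scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        self.scheme = scheme
        self.base_params = dict(base_params or {})
        self.max_cells = max_cells
        self.depth = depth
        self.min_alt = min_alt
        self.n_punches = n_punches
        self.n_single_cells = n_single_cells
        self.n_bins = n_bins
        # common random numbers: with fixed_seed set, every call reuses the
        # same stochastic trajectory, making theta -> summary deterministic.
        # This removes growth-drift variance from the distance (the
        # dominant noise at small problem sizes; at full scale independent
        # seeds marginalise over drift instead).
        self.fixed_seed = fixed_seed

    def _params(self, theta: dict, seed: int) -> SimulationParams:
        cfg = dict(self.base_params)
        cfg.update(theta)
        cfg.setdefault("record_event_log", False)
        cfg["max_cells"] = self.max_cells
        cfg["seed"] = seed
        return SimulationParams.from_dict(cfg)

    def __call__(self, theta: dict, seed: int):
        if self.fixed_seed is not None:
            seed = self.fixed_seed
        state = run_with_restarts(self._params(theta, seed))
        if state.extinct or state.n_cells < 2:
            return None
        rng = np.random.default_rng(seed + 1)
        if self.scheme == "whole_tumour":
            spec = sequencing.sequence_bulk(
                sampling.whole_tumour(state), Z=self.depth,
                min_alt=self.min_alt, rng=rng,
            )
            return spec.vafs
        if self.scheme == "bulks":
            bulks = sampling.default_multiregion_design(
                state, n_punches=self.n_punches
            )[:-1]  # punches + needles, not the whole tumour
            return [
                sequencing.sequence_bulk(b, Z=self.depth, min_alt=self.min_alt, rng=rng).vafs
                for b in bulks
            ]
        n_cells = min(self.n_single_cells, state.n_cells)
        ids = sampling.sample_single_cells_random(state, n_cells, rng=rng)
        tree = phylogeny.true_sampled_tree(state, ids)
        if self.scheme == "tree_branch_lengths":
            return phylogeny.branch_lengths(tree)
        return phylogeny.branching_times(tree)


# -- ABC rejection and SMC ------------------------------------------------


def _draw_prior(config: ABCConfig, rng) -> dict:
    theta = dict(config.fixed)
    for p in config.free_params:
        lo, hi = config.priors[p]
        theta[p] = float(rng.uniform(lo, hi))
    return theta


def _simulate_particle(simulator, theta, seed, max_redraws: int = 10):
    for k in range(max_redraws):
        summary = simulator(theta, (seed + k * 104729) % (2**31 - 1))
        if summary is not None:
            return summary
    return None


def abc_rejection(config: ABCConfig, target, simulator) -> tuple[pd.DataFrame, float]:
    """Plain rejection ABC: draw from the prior, simulate, score, keep the
    top ``quantile`` fraction.  Returns the accepted set and the implied
    threshold (the largest accepted distance)."""
    rng = np.random.default_rng(_particle_seed(config.seed, 0, 0))
    n_draws = int(math.ceil(config.n_particles / config.quantile))
    rows = []
    for i in range(n_draws):
        theta = _draw_prior(config, rng)
        summary = _simulate_particle(simulator, theta, _particle_seed(config.seed, 1, i + 1))
        if summary is None:
            continue
        dist = distance_for_scheme(config.scheme, summary, target, config.n_bins)
        rows.append({**{p: theta[p] for p in config.free_params}, "distance": dist})
    if len(rows) < 2:
        raise RuntimeError("rejection ABC produced fewer than 2 scored particles")
    df = pd.DataFrame(rows).sort_values("distance").reset_index(drop=True)
    keep = min(config.n_particles, len(df))
    df = df.head(keep).copy()
    df["weight"] = 1.0  # round-1 weights are all 1
    eps = float(df["distance"].max())
    return df, eps


def _kernel_density(theta_row: np.ndarray, prev: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Product uniform-kernel density K(theta | prev_l) for every previous
    particle l (rows of ``prev``)."""
    dens = np.ones(len(prev))
    for i, s in enumerate(sigma):
        diff = np.abs(prev[:, i] - theta_row[i])
        if s > 0:
            dens *= np.where(diff <= s + 1e-12, 1.0 / (2.0 * s), 0.0)
        else:
            dens *= np.where(diff <= 1e-12, 1.0, 0.0)
    return dens


def abc_smc(config: ABCConfig, target, simulator) -> Posterior:
    """ABC-SMC: rejection round, then importance resampling with uniform
    perturbation kernels and a threshold shrinking to the Q-th percentile
    of each round's accepted distances."""
    free = config.free_params
    df, eps = abc_rejection(config, target, simulator)
    rounds = [df]
    eps_schedule = [eps]
    eps = float(np.quantile(df["distance"], config.quantile))
    aborted = False
    for r in range(2, config.rounds + 1):
        prev = rounds[-1]
        prev_theta = prev[free].to_numpy()
        prev_w = prev["weight"].to_numpy()
        prev_w = prev_w / prev_w.sum()
        sigma = np.asarray(
            [0.5 * (prev[p].max() - prev[p].min()) for p in free]
        )
        accepted = []
        attempts = 0
        max_attempts = config.max_attempts_factor * config.n_particles
        rng = np.random.default_rng(_particle_seed(config.seed, r, 0))
        while len(accepted) < config.n_particles and attempts < max_attempts:
            attempts += 1
            base = prev_theta[rng.choice(len(prev_theta), p=prev_w)]
            for _ in range(200):  # re-perturb until inside the prior support
                prop = base + rng.uniform(-sigma, sigma)
                if all(
                    config.priors[p][0] <= v <= config.priors[p][1]
                    for p, v in zip(free, prop)
                ):
                    break
            else:
                continue
            theta = dict(config.fixed)
            theta.update({p: float(v) for p, v in zip(free, prop)})
            summary = _simulate_particle(
                simulator, theta, _particle_seed(config.seed, r, attempts)
            )
            if summary is None:
                continue
            dist = distance_for_scheme(config.scheme, summary, target, config.n_bins)
            if dist < eps:
                accepted.append((prop, dist))
        if len(accepted) < 2:
            warnings.warn(f"SMC round {r}: fewer than 2 acceptances; aborting")
            aborted = True
            break
        theta_mat = np.asarray([a[0] for a in accepted])
        dists = np.asarray([a[1] for a in accepted])
        weights = np.empty(len(accepted))
        for j in range(len(accepted)):
            denom = float(np.dot(prev_w, _kernel_density(theta_mat[j], prev_theta, sigma)))
            weights[j] = 1.0 / denom if denom > 0 else 0.0  # uniform prior: pi = const
        if weights.sum() == 0:
            warnings.warn(f"SMC round {r}: degenerate weights; aborting")
            aborted = True
            break
        weights = weights / weights.sum()
        ess = 1.0 / float((weights**2).sum())
        if ess < 2.0:
            warnings.warn(f"SMC round {r}: effective sample size {ess:.2f} < 2; aborting")
            aborted = True
            break
        df_r = pd.DataFrame(theta_mat, columns=free)
        df_r["distance"] = dists
        df_r["weight"] = weights
        rounds.append(df_r)
        eps_schedule.append(eps)
        eps = float(np.quantile(dists, config.quantile))
        if eps < config.eps_min:
            break
    return Posterior(rounds, eps_schedule, config, aborted=aborted)


# -- sequential fixing and evaluation -------------------------------------


def _converged_params(post: Posterior) -> list[str]:
    """A parameter has converged when its posterior mode moved < 5%
    (relative, on the prior-range scale) between the last two rounds and
    its interquartile range is below 25% of the prior range."""
    if len(post.rounds) < 2:
        return []
    out = []
    cfg = post.config
    prev, last = post.rounds[-2], post.rounds[-1]
    for p in cfg.free_params:
        lo, hi = cfg.priors[p]
        span = hi - lo
        m_prev = _posterior_mode(prev[p].to_numpy(), prev["weight"].to_numpy(), lo, hi)
        m_last = _posterior_mode(last[p].to_numpy(), last["weight"].to_numpy(), lo, hi)
        scale = max(abs(m_last), 0.05 * span)
        q25, q75 = np.percentile(last[p], [25, 75])
        iqr = float(q75 - q25)
        if abs(m_last - m_prev) < 0.05 * scale and iqr < 0.25 * span:
            out.append(p)
    return out


@dataclass
class SequentialFixingResult:
    fixed_values: dict
    history: list  # Posterior per outer iteration
    order: list  # parameter groups in the order they were fixed


def sequential_fixing(config: ABCConfig, target, simulator,
                      preset_order: list | None = None) -> SequentialFixingResult:
    """Run ABC-SMC, fix converged parameters at their posterior modes,
    rerun on the remainder, and repeat until every parameter is fixed.

    ``preset_order`` optionally restricts which parameters may be fixed at
    each outer iteration (e.g. [["u"], ["t_driver", "s"], ["d", "a"]]).
    """
    fixed = dict(config.fixed)
    history = []
    order = []
    outer = 0
    free = [p for p in config.priors if p not in fixed]
    while free:
        outer += 1
        cfg = ABCConfig(
            priors=config.priors, fixed=fixed, n_particles=config.n_particles,
            rounds=config.rounds, quantile=config.quantile, scheme=config.scheme,
            eps_min=config.eps_min, n_bins=config.n_bins,
            seed=config.seed + outer, max_attempts_factor=config.max_attempts_factor,
        )
        post = abc_smc(cfg, target, simulator)
        history.append(post)
        modes = post.modes()
        converged = _converged_params(post)
        if preset_order is not None:
            group = next((g for g in preset_order if any(p not in fixed for p in g)), None)
            candidates = [p for p in (group or free) if p in free]
            converged = [p for p in converged if p in candidates] or None
            if converged is None:
                converged = candidates  # fix the scheduled group to guarantee progress
        elif not converged:
            # guarantee progress: fix the most concentrated posterior
            spans = {
                p: np.subtract(*np.percentile(post.particles[p], [75, 25]))
                / (config.priors[p][1] - config.priors[p][0])
                for p in free
            }
            converged = [min(spans, key=lambda p: abs(spans[p]))]
        for p in converged:
            fixed[p] = modes[p]
        order.append(list(converged))
        free = [p for p in config.priors if p not in fixed]
    return SequentialFixingResult(fixed_values=fixed, history=history, order=order)


@dataclass
class PercentError:
    percent: float
    absolute: float
    flagged: bool  # True when the truth is 0 and percent error is undefined


def percent_error(truth: dict, modes: dict) -> dict:
    """|true - inferred| / |true| * 100 per parameter; a zero truth is
    reported as an absolute error with a flag."""
    out = {}
    for p, t in truth.items():
        if p not in modes:
            continue
        m = modes[p]
        if t == 0:
            out[p] = PercentError(percent=float("nan"), absolute=abs(m), flagged=True)
        else:
            out[p] = PercentError(
                percent=abs(t - m) / abs(t) * 100.0, absolute=abs(t - m), flagged=False
            )
    return out


# -- entry points mirroring the sampling strategies ------------------------


def _posterior_entry(scheme, target_summary, config, simulator, out_dir):
    cfg_scheme = config.scheme
    if cfg_scheme != scheme:
        raise ValueError(f"config.scheme is {cfg_scheme!r}; expected {scheme!r}")
    post = abc_smc(config, target_summary, simulator)
    if out_dir is not None:
        post.write_rounds(out_dir)
    return post


def abc_smc_with_bulk_samples(target_tables, config: ABCConfig,
                              simulator: TumourSimulator, out_dir=None) -> Posterior:
    """ABC-SMC against a list of bulk mutation tables (clone, alt, depth, id)."""
    target = [
        (t["alt"].to_numpy() / t["depth"].to_numpy()) for t in target_tables
    ]
    return _posterior_entry("bulks", target, config, simulator, out_dir)


def abc_smc_with_whole_tumour(target_vafs, config: ABCConfig,
                              simulator: TumourSimulator, out_dir=None) -> Posterior:
    return _posterior_entry(
        "whole_tumour", np.asarray(target_vafs, dtype=float), config, simulator, out_dir
    )


def abc_smc_with_tree_branch_lengths(target_tree, config: ABCConfig,
                                     simulator: TumourSimulator, out_dir=None) -> Posterior:
    target = phylogeny.branch_lengths(target_tree)
    return _posterior_entry("tree_branch_lengths", target, config, simulator, out_dir)


def abc_smc_with_tree_branching_times(target_tree, config: ABCConfig,
                                      simulator: TumourSimulator, out_dir=None) -> Posterior:
    target = phylogeny.branching_times(target_tree)
    return _posterior_entry("tree_branching_times", target, config, simulator, out_dir)
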