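"""Observables computed from spectra, genotype matrices and lattice states.

Under neutral exponential growth the expected number of subclonal
mutations with VAF >= f follows M(f) = u * (1/f - 1/f_max): a 1/f^2
density.  Fitting this cumulative form recovers the per-division mutation
rate (exact without cell death); the area between the normalised empirical
and theoretical cumulative curves gives the AUC neutrality statistic, with
a parametric Monte-Carlo p-value (p < 0.05 rejects neutrality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import MUT, TumourState
from .sampling import BulkSample
from .sequencing import CellGenotypeMatrix, VAFSpectrum

DEFAULT_WINDOW = (0.05, 0.25)
CLONAL_CUTOFF = 0.35  # VAFs above this are treated as the clonal band


class InsufficientSpectrumError(ValueError):
    pass


@dataclass
class CumulativeSpectrum:
    """Subclonal VAFs with the cumulative count M(f) = #{vaf >= f}."""

    vafs: np.ndarray  # sorted ascending, subclonal only
    f_min: float
    f_max: float
    depth: float | None = None  # nominal sequencing depth, for the test's null

    def M(self, f) -> np.ndarray:
        """Number of subclonal mutations with VAF >= f (and <= f_max)."""
        f = np.atleast_1d(f)
        upper = np.searchsorted(self.vafs, self.f_max, side="right")
        lower = np.searchsorted(self.vafs, f, side="left")
        return upper - lower

    def points(self):
        """(f_i, M(f_i)) at the distinct observed frequencies in the window."""
        in_win = self.vafs[(self.vafs >= self.f_min) & (self.vafs <= self.f_max)]
        f = np.unique(in_win)
        return f, np.asarray(self.M(f))


def cumulative_spectrum(spectrum: VAFSpectrum, f_min: float = DEFAULT_WINDOW[0],
                        f_max: float = DEFAULT_WINDOW[1],
                        clonal_cutoff: float = CLONAL_CUTOFF) -> CumulativeSpectrum:
    """Empirical cumulative distribution of subclonal VAFs.

    Mutations at or above ``clonal_cutoff`` belong to the clonal band and
    are excluded; [f_min, f_max] is the fit window.
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    v = spectrum.vafs
    sub = np.sort(v[v < clonal_cutoff])
    if len(sub[(sub >= f_min) & (sub <= f_max)]) == 0:
        raise InsufficientSpectrumError(
            f"no subclonal mutations in the window [{f_min}, {f_max}]"
        )
    return CumulativeSpectrum(sub, f_min, f_max, depth=spectrum.depth_nominal)


def fit_neutral_tail(cum: CumulativeSpectrum):
    """Least-squares fit of M(f) = mu * (1/f - 1/f_max) on the window.

    Returns (u_hat, r_squared); u_hat is the recovered mutation rate per
    effective division (equal to the simulator's u when d = 0).
    """
    f, M = cum.points()
    if len(f) < 5:
        raise InsufficientSpectrumError(
            f"need >= 5 distinct frequencies in the window, got {len(f)}"
        )
    x = 1.0 / f - 1.0 / cum.f_max
    denom = float(np.dot(x, x))
    mu = float(np.dot(x, M)) / denom
    resid = M - mu * x
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(M - M.mean(), M - M.mean()))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return mu, r2


@dataclass
class NeutralityResult:
    u_hat: float
    auc: float
    p_value: float
    f_min: float
    f_max: float
    n_subclonal: int
    neutral: bool  # neutrality not rejected iff p >= 0.05

    def __iter__(self):
        yield self.auc
        yield self.p_value


def _normalised_curves(cum: CumulativeSpectrum, grid: np.ndarray):
    # both curves normalised to 1 at f_min; the theoretical 1/f curve
    # reaches 0 at f_max while the empirical one need not, so an excess of
    # high-window mutations (a subclonal cluster) remains visible
    m_lo = float(cum.M(cum.f_min)[0])
    emp = np.asarray(cum.M(grid)) / m_lo if m_lo > 0 else np.zeros_like(grid)
    theo = (1.0 / grid - 1.0 / cum.f_max) / (1.0 / cum.f_min - 1.0 / cum.f_max)
    return emp, theo


def _auc_statistic(cum: CumulativeSpectrum, n_grid: int = 512) -> float:
    grid = np.linspace(cum.f_min, cum.f_max, n_grid)
    emp, theo = _normalised_curves(cum, grid)
    return float(np.trapezoid(np.abs(emp - theo), grid) / (cum.f_max - cum.f_min))


def _sample_neutral_vafs(rng, n: int, f_min: float, f_max: float) -> np.ndarray:
    # inverse CDF of the 1/f^2 density restricted to [f_min, f_max]
    u = rng.random(n)
    return 1.0 / (1.0 / f_min - u * (1.0 / f_min - 1.0 / f_max))


def _null_resample(rng, cum: CumulativeSpectrum, n_muts: float,
                   block_size: float) -> np.ndarray:
    """One parametric draw from the neutral null, mirroring the generative
    process: mutations arise in bursts of ~Pois(u) per division that share
    a single lineage frequency, and observed VAFs carry binomial read
    noise at the nominal depth."""
    n_blocks = max(1, int(round(n_muts / max(block_size, 1.0))))
    freqs = _sample_neutral_vafs(rng, n_blocks, cum.f_min, cum.f_max)
    copies = rng.poisson(max(block_size, 1.0), n_blocks)
    copies[copies == 0] = 1
    v = np.repeat(freqs, copies)
    if cum.depth:
        depth = rng.poisson(cum.depth, len(v))
        depth[depth == 0] = 1
        v = rng.binomial(depth, v) / depth
        v = v[(v >= cum.f_min) & (v <= cum.f_max)]
    return np.sort(v)


def auc_neutrality_test(cum: CumulativeSpectrum, rng=None,
                        n_resamples: int = 1000,
                        block_size: float = 1.0) -> NeutralityResult:
    """Area between the normalised empirical and theoretical 1/f cumulative
    curves; the p-value is the upper tail over parametric neutral-model
    resamples at the observed mutation count, with the sequencing read
    noise reproduced in each null draw.  ``block_size`` > 1 additionally
    reproduces the burst structure of the generative model (Pois(u)
    mutations per division sharing one lineage frequency)."""
    rng = np.random.default_rng() if rng is None else rng
    f, M = cum.points()
    if len(f) < 5:
        raise InsufficientSpectrumError(
            f"AUC test undefined with {len(f)} distinct subclonal frequencies"
        )
    obs = _auc_statistic(cum)
    n_muts = int(cum.M(cum.f_min)[0])
    try:
        u_hat, _ = fit_neutral_tail(cum)
    except InsufficientSpectrumError:
        u_hat = float("nan")
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        v = _null_resample(rng, cum, n_muts, block_size)
        if len(v) < 2:
            null[i] = 0.0
            continue
        null[i] = _auc_statistic(CumulativeSpectrum(v, cum.f_min, cum.f_max))
    p = float((1 + np.sum(null >= obs)) / (1 + n_resamples))
    return NeutralityResult(
        u_hat=u_hat, auc=obs, p_value=p, f_min=cum.f_min, f_max=cum.f_max,
        n_subclonal=n_muts, neutral=p >= 0.05,
    )


POWERLAW_WINDOW = (0.10, 0.30)


def powerlaw_exponent(spectrum: VAFSpectrum, window=POWERLAW_WINDOW,
                      n_bins: int = 10) -> float:
    """Negated slope of log(density) vs log(f) on binned subclonal VAFs
    (2 for a neutral 1/f^2 tail, 0 for a uniform density).

    The default window starts two read-noise standard deviations above the
    detection floor (0.05 at 100x): binned density estimates, unlike the
    cumulative fit, are strongly biased by sub-floor mutations whose noisy
    VAFs leak upward across the floor.
    """
    v = spectrum.vafs
    f_min, f_max = window
    v = v[(v >= f_min) & (v <= f_max)]
    if len(v) < n_bins:
        raise InsufficientSpectrumError("too few mutations in window for binning")
    edges = np.logspace(np.log10(f_min), np.log10(f_max), n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    widths = np.diff(edges)
    centres = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    dens = counts[keep] / widths[keep]
    slope, _ = np.polyfit(np.log(centres[keep]), np.log(dens), 1)
    return -float(slope)


def site_frequency_spectrum(matrix: CellGenotypeMatrix,
                            diploid: bool = True) -> pd.DataFrame:
    """Per-mutation frequency across sampled cells, halved under the
    diploid-reporting convention so it is comparable with bulk VAF."""
    freq = matrix.column_frequencies()
    if diploid:
        freq = freq / 2.0
    return pd.DataFrame({"id": matrix.mutation_ids, "frequency": freq})


def mutational_load_by_distance(ring_samples: list[BulkSample]) -> pd.DataFrame:
    """Mutation counts per concentric-ring sample, ordered by ring index."""
    rows = []
    for s in ring_samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "ring_index": s.region.ring_index,
                "direction": s.region.direction or "C",
                "n_cells": s.n_cells,
                "n_mutations": len(s.mutations),
                "mutations_per_cell": len(s.mutations) / s.n_cells,
            }
        )
    return pd.DataFrame(rows).sort_values(["ring_index", "direction"]).reset_index(drop=True)


class SingleCloneError(ValueError):
    """Moran's I is undefined when only one clone label is present."""


def moran_i(labels: np.ndarray, pair_i: np.ndarray, pair_j: np.ndarray,
            rng=None, n_permutations: int = 199):
    """Moran's I of a binary label over an adjacency given as index pairs
    (each undirected edge listed once); p-value by label permutation."""
    labels = np.asarray(labels, dtype=float)
    if np.all(labels == labels[0]):
        raise SingleCloneError("all cells carry the same label")
    n = len(labels)
    z = labels - labels.mean()
    denom = float(np.dot(z, z))
    w_total = 2.0 * len(pair_i)  # symmetric weights
    cross = 2.0 * float(np.dot(z[pair_i], z[pair_j]))
    I = (n / w_total) * cross / denom
    if n_permutations <= 0:
        return I, float("nan")
    rng = np.random.default_rng() if rng is None else rng
    count = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        Ip = (n / w_total) * 2.0 * float(np.dot(zp[pair_i], zp[pair_j])) / denom
        if Ip >= I:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return I, float(p)


def _adjacency_pairs(state: TumourState):
    """Moore-neighbour index pairs among occupied sites (each edge once)."""
    _, pos, clone, _, _ = state.as_arrays()
    dims = state.params.dims
    L = state.params.grid_extent
    index = np.full((L,) * dims, -1, dtype=np.int64)
    index[tuple(pos.T)] = np.arange(len(pos))
    offs = []
    from .engine import _moore_offsets

    for off in _moore_offsets(dims):
        if off > tuple([0] * dims):  # half of the offsets: each pair once
            offs.append(off)
    pis, pjs = [], []
    for off in offs:
        q = pos + np.asarray(off)
        ok = np.all((q >= 0) & (q < L), axis=1)
        nbr = np.full(len(pos), -1, dtype=np.int64)
        nbr[ok] = index[tuple(q[ok].T)]
        hit = nbr >= 0
        pis.append(np.nonzero(hit)[0])
        pjs.append(nbr[hit])
    return np.concatenate(pis), np.concatenate(pjs), clone.astype(float)


def intermixing_statistic(state: TumourState, rng=None, n_permutations: int = 199):
    """Spatial autocorrelation (Moran's I) of the clone label over occupied
    lattice sites with Moore-neighbour weights.  High values mean the two
    clones are spatially segregated; low values mean intermixing."""
    pair_i, pair_j, labels = _adjacency_pairs(state)
    rng = rng or state.rng
    return moran_i(labels, pair_i, pair_j, rng=rng, n_permutations=n_permutations)
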