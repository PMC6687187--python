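"""Synthetic sequencing: dispersed coverage, binomial allele sampling,
detection limits, single-cell WGS and bulk-guided genotyping.

The read model is the standard one for a pure diploid tumour: depth is
drawn per mutation from Poisson(Z) (zero draws redrawn, since an unread
site has no record), and the variant read count from Binomial(depth, n/2)
where n is the cellular fraction — a clonal mutation therefore clusters
around VAF 0.5.  Mutations supported by fewer than ``min_alt`` reads are
discarded, giving a detection floor of min_alt/Z (0.05 at the default
5 reads / 100x).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import TumourState
from .sampling import BulkSample

SPECTRUM_COLUMNS = ("id", "alt", "depth", "vaf", "clone")


@dataclass
class VAFSpectrum:
    """Per-mutation read counts and VAFs for one sample."""

    df: pd.DataFrame  # columns: id, alt, depth, vaf, clone
    sample_id: str = ""
    depth_nominal: float = 100.0
    min_alt: int = 0

    def __post_init__(self):
        missing = [c for c in SPECTRUM_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"spectrum missing columns {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def vafs(self) -> np.ndarray:
        return self.df["vaf"].to_numpy()

    @property
    def detection_floor(self) -> float:
        return self.min_alt / self.depth_nominal


@dataclass
class CellGenotypeMatrix:
    """Binary cells x mutations matrix (rows follow ``cell_ids``)."""

    cell_ids: np.ndarray
    mutation_ids: np.ndarray
    data: np.ndarray  # uint8, shape (n_cells, n_mutations)
    kind: str = "wgs"  # wgs | genotyped
    bulk_tags: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def column_frequencies(self) -> np.ndarray:
        """Fraction of sampled cells carrying each mutation."""
        return self.data.sum(axis=0) / self.n_cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.cell_ids, columns=self.mutation_ids)


def _poisson_nonzero(rng, lam: float, size: int) -> np.ndarray:
    depth = rng.poisson(lam, size)
    while True:
        zero = depth == 0
        if not zero.any():
            return depth
        depth[zero] = rng.poisson(lam, int(zero.sum()))


def simulate_read_counts(n, Z: float, rng, ploidy: str = "diploid"):
    """Sequencing read counts for cellular fraction(s) ``n`` at depth Z.

    depth ~ Poisson(Z) (resampled if 0); alt ~ Binomial(depth, n/2) under
    the diploid-heterozygous convention (``ploidy='haploid'`` uses p = n).
    """
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any((n <= 0) | (n > 1)):
        raise ValueError("cellular fractions must lie in (0, 1]")
    if Z <= 0:
        raise ValueError(f"nominal depth Z must be > 0, got {Z}")
    p = n if ploidy == "haploid" else n / 2.0
    depth = _poisson_nonzero(rng, Z, len(n))
    alt = rng.binomial(depth, p)
    if np.isscalar(n) or n.shape == (1,):
        return int(alt[0]), int(depth[0])
    return alt, depth


def apply_detection_filter(spectrum: VAFSpectrum, min_alt: int = 5) -> VAFSpectrum:
    """Discard mutations supported by fewer than ``min_alt`` variant reads."""
    keep = spectrum.df["alt"].to_numpy() >= min_alt
    return replace(
        spectrum,
        df=spectrum.df.loc[keep].reset_index(drop=True),
        min_alt=max(min_alt, spectrum.min_alt),
    )


def sequence_bulk(sample: BulkSample, Z: float = 100.0, min_alt: int = 5,
                  rng=None, ploidy: str = "diploid") -> VAFSpectrum:
    """Sequence every mutation of a bulk sample at nominal depth Z and
    apply the detection filter; clone annotations carry through."""
    rng = np.random.default_rng() if rng is None else rng
    muts = sample.mutations
    if len(muts) == 0:
        empty = pd.DataFrame(columns=list(SPECTRUM_COLUMNS))
        return VAFSpectrum(empty, sample.sample_id, Z, min_alt)
    frac = muts["n"].to_numpy()
    alt, depth = simulate_read_counts(frac, Z, rng, ploidy=ploidy)
    alt = np.atleast_1d(alt)
    depth = np.atleast_1d(depth)
    df = pd.DataFrame(
        {
            "id": muts["id"].to_numpy(),
            "alt": alt,
            "depth": depth,
            "vaf": alt / depth,
            "clone": muts["clone"].to_numpy(),
        }
    )
    spec = VAFSpectrum(df, sample.sample_id, Z, 0)
    return apply_detection_filter(spec, min_alt) if min_alt > 0 else spec


def _cell_mutation_sets(state: TumourState, cell_ids) -> list[np.ndarray]:
    return [state.lineage.mutation_ids(state.cells[int(c)].node) for c in cell_ids]


def sequence_single_cells_wgs(state: TumourState, cell_ids, dropout: float = 0.0,
                              rng=None) -> CellGenotypeMatrix:
    """Exact binary genotypes from the lineage tree for the sampled cells.

    Noise-free by default; ``dropout`` flips a present allele to absent
    independently with the given probability (allele dropout knob).
    """
    cell_ids = np.asarray(cell_ids)
    sets = _cell_mutation_sets(state, cell_ids)
    if sets:
        universe = np.unique(np.concatenate([s for s in sets] + [np.empty(0, np.int64)]))
    else:
        universe = np.empty(0, dtype=np.int64)
    col = {int(m): j for j, m in enumerate(universe)}
    data = np.zeros((len(cell_ids), len(universe)), dtype=np.uint8)
    for i, s in enumerate(sets):
        for m in s:
            data[i, col[int(m)]] = 1
    if dropout > 0:
        rng = np.random.default_rng() if rng is None else rng
        drop = rng.random(data.shape) < dropout
        data = np.where(drop, 0, data).astype(np.uint8)
    return CellGenotypeMatrix(cell_ids, universe, data, kind="wgs")


class EmptyReferenceError(ValueError):
    pass


def genotype_cells(state: TumourState, cell_ids, reference_spectrum: VAFSpectrum,
                   vaf_floor: float = 0.05) -> CellGenotypeMatrix:
    """Check each reference mutation (VAF > ``vaf_floor`` in one bulk) for
    presence/absence in every sampled cell — targeted genotyping."""
    ref = reference_spectrum.df
    ref_ids = np.unique(ref.loc[ref["vaf"].to_numpy() > vaf_floor, "id"].to_numpy())
    if len(ref_ids) == 0:
        raise EmptyReferenceError(
            f"no reference mutations above VAF floor {vaf_floor} in sample "
            f"{reference_spectrum.sample_id!r}"
        )
    cell_ids = np.asarray(cell_ids)
    ref_set = set(int(m) for m in ref_ids)
    data = np.zeros((len(cell_ids), len(ref_ids)), dtype=np.uint8)
    col = {int(m): j for j, m in enumerate(ref_ids)}
    for i, s in enumerate(_cell_mutation_sets(state, cell_ids)):
        for m in s:
            m = int(m)
            if m in ref_set:
                data[i, col[m]] = 1
    return CellGenotypeMatrix(cell_ids, ref_ids, data, kind="genotyped")
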