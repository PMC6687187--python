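"""Simulation parameters and validation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

DRIVER_MODES = ("birth_increase", "death_decrease", "push_increase")
PUSH_RULES = ("rim", "bernoulli")


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the offending field."""


@dataclass
class SimulationParams:
    """Parameters of the lattice tumour growth model.

    Attributes
    ----------
    dims:
        Lattice dimensionality, 2 or 3.
    grid_extent:
        Number of lattice sites per axis (default 400 in 2D).
    b, d:
        Wild-type birth and death rates, in events per unit Gillespie time.
    u:
        Mean number of new mutations per daughter cell per division
        (Poisson distributed, infinite-sites).
    a:
        Boundary-proliferation parameter in [0, 1]: the fraction of the
        tumour radius, measured inward from the growing front, within which
        a space-less cell may still divide by pushing neighbours outward.
        ``a = 1`` gives homogeneous (exponential) growth.
    t_driver:
        Gillespie-clock time at which a single wild-type cell is converted
        into the selected mutant. ``inf`` disables the driver.
    s:
        Driver selection coefficient, via 1 + s = (b_mut - d_mut)/(b_wt - d_wt).
    driver_mode:
        How the fitness advantage is realised: ``birth_increase``,
        ``death_decrease`` or ``push_increase`` (mutant always allowed to push).
    kill_fraction:
        Optional fraction of cells removed by a treatment event, in [0, 1).
    max_cells:
        Optional population cap; the run stops once reached (in addition to
        the always-on stop rule of a cell touching the grid boundary).
    push_rule:
        ``rim`` (deterministic: a cell may push iff it lies within a fraction
        ``a`` of the current tumour radius from the front, Chebyshev metric)
        or ``bernoulli`` (push permitted with probability ``a``).
    founder_mutations:
        If True the founder cell itself carries Pois(u) mutations
        (default False: truncal mutations arise from early divisions).
    seed:
        RNG seed for the single per-simulation generator.
    """

    dims: int = 2
    grid_extent: int = 400
    b: float = 1.0
    d: float = 0.0
    u: float = 10.0
    a: float = 1.0
    t_driver: float = math.inf
    s: float = 0.0
    driver_mode: str = "birth_increase"
    kill_fraction: float | None = None
    max_cells: int | None = None
    max_events: int | None = None
    push_rule: str = "rim"
    founder_mutations: bool = False
    record_event_log: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ParameterError(f"dims must be 2 or 3, got {self.dims}")
        if self.grid_extent < 3:
            raise ParameterError(
                f"grid_extent must be >= 3 (no well-defined interior centre "
                f"otherwise), got {self.grid_extent}"
            )
        if not self.b > 0:
            raise ParameterError(f"b (birth rate) must be > 0, got {self.b}")
        if self.d < 0:
            raise ParameterError(f"d (death rate) must be >= 0, got {self.d}")
        if self.u < 0:
            raise ParameterError(f"u (mutation rate) must be >= 0, got {self.u}")
        if not 0.0 <= self.a <= 1.0:
            raise ParameterError(f"a must be in [0, 1], got {self.a}")
        if self.s < 0:
            raise ParameterError(f"s (selection coefficient) must be >= 0, got {self.s}")
        if self.t_driver < 0:
            raise ParameterError(f"t_driver must be >= 0, got {self.t_driver}")
        if self.driver_mode not in DRIVER_MODES:
            raise ParameterError(
                f"driver_mode must be one of {DRIVER_MODES}, got {self.driver_mode!r}"
            )
        if self.kill_fraction is not None and not 0.0 <= self.kill_fraction < 1.0:
            raise ParameterError(
                f"kill_fraction must be in [0, 1), got {self.kill_fraction}"
            )
        if self.max_cells is not None and self.max_cells < 1:
            raise ParameterError(f"max_cells must be >= 1, got {self.max_cells}")
        if self.push_rule not in PUSH_RULES:
            raise ParameterError(
                f"push_rule must be one of {PUSH_RULES}, got {self.push_rule!r}"
            )
        if self.driver_mode == "death_decrease" and math.isfinite(self.t_driver):
            d_mut = self.b - (1.0 + self.s) * (self.b - self.d)
            if d_mut < 0:
                raise ParameterError(
                    "s too large for death_decrease mode: implied mutant death "
                    f"rate {d_mut:.3f} < 0 (b={self.b}, d={self.d}, s={self.s})"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimulationParams":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(cfg) - known
        if extra:
            raise ParameterError(f"unknown parameter field(s): {sorted(extra)}")
        return cls(**cfg)
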