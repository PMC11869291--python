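"""Bookkeeping helpers for umbrella-sampling campaigns and dataset splits.

These encode the arithmetic of a sampling plan (windows x replicates x
trajectory length) and of per-system dataset splits, so that campaign
sizes are computed rather than hard-coded at call sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import cumulative_sampling_ns


@dataclass(frozen=True)
class SamplingProtocol:
    """One umbrella campaign: equidistant windows along the reaction
    coordinate, several replicates per window with distinct velocity
    seeds, fixed production length per replicate."""

    n_windows: int
    n_replicates: int
    t_ns: float
    lo: float = 2.0        # first window center (A or deg)
    hi: float = 20.0       # last window center

    @property
    def cumulative_ns(self) -> float:
        return cumulative_sampling_ns(self.n_windows, self.n_replicates,
                                      self.t_ns)


#: 1-D metal-ligand dissociation campaign (distance 2-20 A)
DISSOCIATION_45 = SamplingProtocol(45, 3, 1.0)

#: 1-D dimer dissociation campaign (distance 2-20 A)
DISSOCIATION_42 = SamplingProtocol(42, 3, 1.0)

#: 2-D backbone-dihedral grid: windows per angle (10 x 10 = 100 total)
DIHEDRAL_GRID_N = 10


def dataset_split_size(n_systems: int, examples_per_system: int) -> int:
    """Number of examples in a split drawn per molecular system."""
    if n_systems < 0 or examples_per_system < 0:
        raise ValueError("counts must be nonnegative")
    return n_systems * examples_per_system
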