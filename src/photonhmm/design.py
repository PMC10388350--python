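"""Closed-form experiment-design calculations.

Stoichiometric reassembly statistics: when labeled monomers are mixed with
unlabeled ones at ratio 1:N before ring reassembly, the number of labeled
subunits per n-mer complex is Binomial(n, p) with p = 1/(N+1); the quantity
of interest is the fraction of *labeled* complexes carrying exactly one
labeled subunit.  Also the standard Foerster relation between dye-pair
distance and FRET efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

__all__ = [
    "LabelingScheme",
    "DyePairSpec",
    "single_label_fraction",
    "forster_efficiency",
    "distance_from_efficiency",
]


@dataclass
class LabelingScheme:
    labeled_fraction: float  # p; ratio 1:N gives p = 1/(N+1)
    n_subunits: int = 7

    @classmethod
    def from_ratio(cls, labeled: float, unlabeled: float, n_subunits: int = 7):
        return cls(labeled / (labeled + unlabeled), n_subunits)

    def __post_init__(self):
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")


def single_label_fraction(scheme: LabelingScheme) -> float:
    """P(exactly one labeled subunit | at least one), X ~ Binomial(n, p)."""
    p, n = scheme.labeled_fraction, scheme.n_subunits
    if p == 0:
        raise ValueError("no labeled complexes at p = 0; fraction undefined")
    p1 = binom.pmf(1, n, p)
    p_any = 1.0 - binom.pmf(0, n, p)
    return float(p1 / p_any)


@dataclass
class DyePairSpec:
    forster_radius: float  # R0, Angstrom
    distance: float  # R, Angstrom

    def __post_init__(self):
        if self.forster_radius <= 0 or self.distance <= 0:
            raise ValueError("R0 and R must be positive")


def forster_efficiency(spec: DyePairSpec) -> float:
    """E = 1 / (1 + (R/R0)^6)."""
    return 1.0 / (1.0 + (spec.distance / spec.forster_radius) ** 6)


def distance_from_efficiency(efficiency: float, forster_radius: float) -> float:
    """Inverse Foerster relation; defined only for 0 < E < 1."""
    if not 0 < efficiency < 1:
        raise ValueError("inverse requires 0 < E < 1 (finite, nonzero distance)")
    if forster_radius <= 0:
        raise ValueError("R0 must be positive")
    return forster_radius * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0)
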