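"""Seed-setting phenotype model.

Seed setting (% filled grains) is drawn per plant from a truncated
Gaussian whose mean and SD depend on the genotype class at the restorer
loci and on the temperature regime during flowering.  Defaults follow the
field observations for BT-type CMS testcross material: heterozygous
single-restorer plants lose fertility under heat stress (more severely
for Rf5 than Rf6), while Rf homozygotes and double heterozygotes stay
near-normal.  Sterile plants set no seed when bagged; their natural seed
set is low-level outcrossing, drawn Uniform[0, 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plants import Plant

__all__ = ["FertilityModelParams", "genotype_class", "seed_setting"]

REGIMES = ("normal", "heat")
MODES = ("bagged", "natural")

# (mean, SD) of seed-setting % per (class, regime).  Normal-regime and
# heat-regime defaults are early-sowing observations in a cool year and in
# the 37-degree heat-wave year respectively.
_DEFAULT_CELLS: dict[tuple[str, str], tuple[float, float]] = {
    ("het_Rf6", "normal"): (87.41, 2.30),
    ("het_Rf6", "heat"): (67.22, 10.02),
    ("het_Rf5", "normal"): (85.45, 3.02),
    ("het_Rf5", "heat"): (36.85, 13.12),
    ("double_het", "normal"): (88.00, 5.00),
    ("double_het", "heat"): (75.10, 12.91),
    ("hom_Rf", "normal"): (90.12, 4.24),
    ("hom_Rf", "heat"): (82.46, 3.87),
}


@dataclass
class FertilityModelParams:
    """Per-(genotype class, regime) seed-setting means and SDs.

    ``cells`` maps (class, regime) -> (mean %, SD).  Classes: 'sterile'
    (implicit; bagged mean 0), 'het_<locusname>' for single-restorer
    heterozygotes, 'double_het', 'hom_Rf'.  ``outcrossing_max`` bounds the
    natural seed set of sterile plants.
    """

    cells: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CELLS)
    )
    outcrossing_max: float = 5.0

    def __post_init__(self) -> None:
        for (cls, regime), (mean, sd) in self.cells.items():
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}")
            if not 0.0 <= mean <= 100.0:
                raise ValueError(f"mean out of [0,100] for {(cls, regime)}")
            if sd < 0:
                raise ValueError(f"negative SD for {(cls, regime)}")
        if not 0.0 <= self.outcrossing_max <= 100.0:
            raise ValueError("outcrossing_max out of range")

    def cell(self, cls: str, regime: str) -> tuple[float, float]:
        try:
            return self.cells[(cls, regime)]
        except KeyError:
            raise ValueError(f"unknown genotype class/regime {(cls, regime)!r}") from None


def genotype_class(plant: Plant) -> str:
    """Map a plant's restorer-locus genotypes to a fertility class."""
    dosages = plant.rf_genotype()
    carried = {name: d for name, d in dosages.items() if d > 0}
    if not carried:
        return "sterile"
    if any(d == 2 for d in carried.values()):
        return "hom_Rf"
    if len(carried) == 1:
        (name,) = carried
        return f"het_{name}"
    return "double_het"


def seed_setting(
    plant: Plant,
    regime: str,
    mode: str,
    params: FertilityModelParams,
    rng: np.random.Generator,
) -> float:
    """One seed-setting % draw for a plant under a regime and scoring mode."""
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    cls = genotype_class(plant)
    if cls == "sterile":
        if mode == "bagged":
            return 0.0
        return float(rng.uniform(0.0, params.outcrossing_max))
    mean, sd = params.cell(cls, regime)
    if sd == 0:
        return mean
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
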