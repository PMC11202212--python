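"""Closed-form striatal geometry arithmetic.

These operations combine measured quantities (volume percentages, the
chemoattraction-distance ratio) with literature constants (arbor coverage of
a single dopamine axon, striatal neuron counts and subtype fractions) into
derived geometric quantities: the effective interaction volume of the
GDNF-interneuron system, the number of GDNF neurons inside one dopamine
arbor, the number of dopamine arbors covering any striatal point, and the
MSN/PV abundance ratio.

Unit discipline: arguments named ``*_fraction``/``*_frac`` are fractions in
(0, 1]; arguments named ``*_pct`` are percentages.  Passing a percentage
where a fraction is required raises, because silently mixing the two is the
classic failure mode of this arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

__all__ = [
    "GeometryConstants",
    "effective_volume_pct",
    "gdnf_neurons_per_arbor",
    "overlapping_arbors",
    "abundance_ratio",
    "derived_table",
]


def _check_fraction(x: float, name: str) -> None:
    if not 0.0 < x <= 1.0:
        raise DomainError(
            f"{name}={x} is not a fraction in (0, 1]; percentages are not accepted here"
        )


def _check_positive(x: float, name: str) -> None:
    if not x > 0:
        raise DomainError(f"{name} must be positive, got {x}")


@dataclass(frozen=True)
class GeometryConstants:
    """Literature constants and measured percentages for the derived table.

    arbor_fraction:
        Fraction of the striatal volume covered by the axonal tree of a
        single dopamine neuron (~2.7%).
    neurons_per_arbor_volume:
        Striatal neurons contained in one arbor's volume (~75,000).
    gdnf_neuron_fraction:
        Fraction of striatal neurons expressing GDNF (~0.6%).
    n_da_neurons_sn:
        Dopamine neurons in one substantia nigra (~7,600).
    msn_fraction / pv_fraction:
        Striatal abundance of medium spiny neurons (~95%) and parvalbumin
        interneurons (~0.7%), as fractions.
    pv_volume_pct / msn_volume_pct:
        Measured arborization volume split (percent, summing to 100).
    distance_ratio:
        Chemoattraction-radius ratio between GDNF neurons and MSNs (~7).
    """

    arbor_fraction: float = 0.027
    neurons_per_arbor_volume: int = 75_000
    gdnf_neuron_fraction: float = 0.006
    n_da_neurons_sn: int = 7_600
    msn_fraction: float = 0.95
    pv_fraction: float = 0.007
    pv_volume_pct: float = 7.61
    msn_volume_pct: float = 92.39
    distance_ratio: float = 7.0

    def __post_init__(self) -> None:
        _check_fraction(self.arbor_fraction, "arbor_fraction")
        _check_fraction(self.gdnf_neuron_fraction, "gdnf_neuron_fraction")
        _check_fraction(self.msn_fraction, "msn_fraction")
        _check_fraction(self.pv_fraction, "pv_fraction")
        _check_positive(self.neurons_per_arbor_volume, "neurons_per_arbor_volume")
        _check_positive(self.n_da_neurons_sn, "n_da_neurons_sn")
        _check_positive(self.distance_ratio, "distance_ratio")
        if abs(self.pv_volume_pct + self.msn_volume_pct - 100.0) > 1e-6:
            raise DomainError("pv_volume_pct + msn_volume_pct must equal 100")


def effective_volume_pct(distance_ratio: float, volume_pct: float) -> float:
    """Effective interaction volume: distance ratio × occupied volume percent.

    A cell type that chemoattracts over ``distance_ratio`` times the range
    of a reference type has an effective reach of its volume percentage
    scaled by that ratio.
    """
    _check_positive(distance_ratio, "distance_ratio")
    _check_positive(volume_pct, "volume_pct")
    return distance_ratio * volume_pct


def gdnf_neurons_per_arbor(neurons_per_arbor_volume: int, gdnf_fraction: float) -> int:
    """GDNF neurons inside the volume innervated by one dopamine arbor."""
    _check_positive(neurons_per_arbor_volume, "neurons_per_arbor_volume")
    if gdnf_fraction == 0:
        return 0
    _check_fraction(gdnf_fraction, "gdnf_fraction")
    return int(round(neurons_per_arbor_volume * gdnf_fraction))


def overlapping_arbors(n_da_neurons: int, arbor_fraction: float) -> float:
    """Expected number of dopamine arbors covering any striatal point."""
    if n_da_neurons == 0:
        return 0.0
    _check_positive(n_da_neurons, "n_da_neurons")
    _check_fraction(arbor_fraction, "arbor_fraction")
    return n_da_neurons * arbor_fraction


def abundance_ratio(frac_a: float, frac_b: float) -> float:
    """Abundance ratio of two neuron populations given as fractions."""
    _check_fraction(frac_b, "frac_b")
    _check_fraction(frac_a, "frac_a")
    return frac_a / frac_b


def derived_table(constants: GeometryConstants = GeometryConstants()) -> pd.DataFrame:
    """All derived geometric quantities from one constants set."""
    c = constants
    rows = [
        ("effective_volume_pct",
         effective_volume_pct(c.distance_ratio, c.pv_volume_pct),
         "distance ratio × PV volume %"),
        ("gdnf_neurons_per_arbor",
         gdnf_neurons_per_arbor(c.neurons_per_arbor_volume, c.gdnf_neuron_fraction),
         "GDNF neurons inside one dopamine arbor"),
        ("overlapping_arbors",
         overlapping_arbors(c.n_da_neurons_sn, c.arbor_fraction),
         "dopamine arbors covering any striatal point"),
        ("msn_pv_abundance_ratio",
         abundance_ratio(c.msn_fraction, c.pv_fraction),
         "MSN / PV abundance"),
        ("msn_pv_volume_ratio",
         c.msn_volume_pct / c.pv_volume_pct,
         "MSN / PV arborization volume"),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value", "meaning"])
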