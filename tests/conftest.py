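import numpy as np
import pytest

from claysorb.isotherm import (
    Conditions,
    Isotherm,
    IsothermPoint,
    MineralSpec,
    NucleotideSpec,
)


@pytest.fixture
def nucleotide():
    return NucleotideSpec(
        "dGMP", molecular_weight=347.2, solubility=0.02,
        pka_values=(2.9, 6.1, 9.4), extinction_coefficient=1.2e4, wavelength=253.0,
    )


@pytest.fixture
def mineral():
    return MineralSpec(
        "nontronite", swelling=True, ssa_total=60.0, ssa_basal=50.0,
        ssa_edge=10.0, point_of_zero_charge=None,
    )


@pytest.fixture
def conditions():
    return Conditions.from_mapping(7.0, 25.0, {"NaCl": 0.5, "MgCl2": 0.05})


@pytest.fixture
def make_isotherm(nucleotide, mineral, conditions):
    """Factory for an Isotherm from (c_eq, q) arrays."""

    def _make(c_eq, q, sd=None):
        sd = np.zeros_like(np.asarray(q, dtype=float)) if sd is None else sd
        pts = tuple(
            IsothermPoint(float(c), float(v), float(s)) for c, v, s in zip(c_eq, q, sd)
        )
        return Isotherm(pts, nucleotide, mineral, conditions)

    return _make
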