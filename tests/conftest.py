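"""Shared fixtures: small synthetic systems and one session-scoped sampled
cylinder trajectory reused by the slower pipeline tests."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from poreclog import conductance as cond
from poreclog import occupancy as occ
from poreclog import synthetic as syn
from poreclog import trajio


CYL_RADIUS = 5.0
CYL_LENGTH = 50.0
ANALYTIC_R = CYL_LENGTH / (np.pi * CYL_RADIUS**2)  # rho = 1


@pytest.fixture(scope="session")
def cylinder_system() -> syn.SyntheticSystem:
    return syn.make_pore(syn.cylinder_pore(radius=CYL_RADIUS, length=CYL_LENGTH))


def electrolyte_at_density(volume: float, water_fraction: float = 1.0, seed: int = 0, **kw):
    """ElectrolyteSpec with liquid-water + 2 M KCl counts for ``volume`` Å³."""
    return syn.ElectrolyteSpec(
        n_water=int(round(syn.WATER_NUMBER_DENSITY * water_fraction * volume)),
        n_k=max(1, int(round(syn.ION_DENSITY_2M * volume))),
        n_cl=max(1, int(round(syn.ION_DENSITY_2M * volume))),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def sampled_cylinder(cylinder_system) -> trajio.Trajectory:
    """Equilibrium-resampled electrolyte in the reference cylinder; used by
    the occupancy-closure and resistance-recovery tests.

    Half-liquid water density keeps the ideal-bead fluid in the dilute
    regime where the occupancy estimator is unbiased (see docs/methods.md);
    4000 independent frames push the Monte-Carlo noise per slice well below
    the closure tolerances.
    """
    volume = np.pi * CYL_RADIUS**2 * CYL_LENGTH
    spec = electrolyte_at_density(volume, water_fraction=0.5, seed=2026)
    return syn.make_trajectory(cylinder_system, spec, n_frames=4000, mode="resample")


@pytest.fixture(scope="session")
def tiny_species_rules() -> trajio.SpeciesRules:
    return syn.synthetic_species_rules()


def analytic_profile(system: syn.SyntheticSystem, dz: float = 1.0) -> cond.AreaProfile:
    zs = np.arange(dz / 2.0, system.geometry.length, dz)
    return cond.AreaProfile(z=zs, area=system.analytic_area(zs), dz=dz)
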