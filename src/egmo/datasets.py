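"""Packaged data fixtures and a synthetic stress-strength generator.

Fixtures ship verbatim as CSV inside the package:

* ``fiber_1`` — breaking strengths of 69 single carbon fibres at 20 mm
  gauge length (Badar & Priest data, the stress sample in the application).
* ``fiber_2`` — breaking strengths of 63 single carbon fibres at 10 mm
  gauge length (the strength sample).
* ``covid`` — 45 daily (confirmed, recovered, deaths) counts for Saudi
  Arabia, 1 April – 15 May 2020, from which death and recovery rates are
  derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .family import EGMODistribution
from .frequentist import StressStrengthData

__all__ = ["Fixture", "load_fixture", "load_fiber", "load_covid_rates",
           "make_synthetic"]


@dataclass
class Fixture:
    name: str
    values: object            # ndarray for single-sample fixtures, DataFrame for covid
    source: str


def _read(name):
    with resources.files("egmo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_fixture(name):
    """Load a packaged fixture by name: ``fiber_1``, ``fiber_2`` or ``covid``."""
    if name == "fiber_1":
        v = _read("fiber_20mm.csv")["strength"].to_numpy()
        return Fixture(name, v, "carbon fibre strengths, 20 mm gauge (n=69)")
    if name == "fiber_2":
        v = _read("fiber_10mm.csv")["strength"].to_numpy()
        return Fixture(name, v, "carbon fibre strengths, 10 mm gauge (m=63)")
    if name == "covid":
        df = _read("covid_saudi.csv")
        return Fixture(name, df, "COVID-19 Saudi Arabia daily counts, "
                                 "2020-04-01 to 2020-05-15 (45 days)")
    raise KeyError(f"unknown fixture {name!r}; known: fiber_1, fiber_2, covid")


def load_fiber():
    """The two fibre samples as a :class:`StressStrengthData` (x=20 mm, y=10 mm)."""
    return StressStrengthData(load_fixture("fiber_1").values,
                              load_fixture("fiber_2").values)


def load_covid_rates():
    """Death-rate (stress) and recovery-rate (strength) series from the counts."""
    from .gof import compute_rates
    df = load_fixture("covid").values
    death, recovery = compute_rates(df["confirmed"].to_numpy(),
                                    df["recovered"].to_numpy(),
                                    df["deaths"].to_numpy())
    return StressStrengthData(death, recovery)


def make_synthetic(a, b1, b2, theta, baseline, baseline_params, n, m, seed=0):
    """Simulate a stress-strength pair with known truth R = b1/(b1+b2)."""
    rng = np.random.default_rng(seed)
    dx = EGMODistribution(a, b1, theta, baseline, baseline_params)
    dy = EGMODistribution(a, b2, theta, baseline, baseline_params)
    return StressStrengthData(dx.rvs(n, rng=rng), dy.rvs(m, rng=rng))
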