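"""Bundled study data: the published census and productivity tables.

Two nest-box populations of Siberian flying squirrels in western Finland:
Vaasa (monitored 2002-2014) and Luoto (1995-2014).  The capture histories
behind the survival component were never released, so only the census
(broods found, ``y``) and productivity (tagged daughters ``J`` per ``R``
identified reproductive females) layers ship here; capture data are
produced by :mod:`flypop.simulate` when needed.
"""

from importlib import resources

from .data import CensusSeries, ProductivityTable, read_census, read_productivity

__all__ = ["load_census", "load_productivity", "POPULATIONS",
           "TAG_LOSS_EVENTS", "TAG_LOSS_RECAPTURES"]

POPULATIONS = ("vaasa", "luoto")

#: identity-loss events over interannual recaptures in the double-checked
#: subset of the field data (broken-eared adults / all recaptured adults)
TAG_LOSS_EVENTS = 8
TAG_LOSS_RECAPTURES = 266


def _table_path(name: str):
    return resources.files("flypop") / "tables" / name


def load_census(population: str) -> CensusSeries:
    """Census series for ``"vaasa"`` or ``"luoto"``."""
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    with resources.as_file(_table_path(f"{population}_census.csv")) as p:
        return read_census(p, population_id=population)


def load_productivity(population: str) -> ProductivityTable:
    """Productivity table (J, R) for ``"vaasa"`` or ``"luoto"``."""
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    with resources.as_file(_table_path(f"{population}_productivity.csv")) as p:
        return read_productivity(p, population_id=population)
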