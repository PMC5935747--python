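"""Bundled reference parameter sets for eight crop species.

The package ships the published NSG and BSG parameter estimates (and the
corresponding reported maximum-biomass values) for sunflower, peanut, black
soybean, garden pea, adzuki bean, mung bean, cotton and sweet sorghum as a
plain-text table.  The raw field datasets behind those estimates are not
publicly deposited, so these fixtures are the package's reference inputs:
they seed simulations, demos and consistency checks (recomputing w_max from
the parameters reproduces the reported values to within the precision the
parameters are printed at -- 3 decimals, which w_max ~ c^2 amplifies for
the NSG).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .curves import BSGParameters, NSGParameters
from .exceptions import UnknownSpeciesError

__all__ = ["CropFixture", "crop_fixture", "list_crops", "load_crop_table"]

#: relative reproduction tolerance of the reported w_max values; the NSG one
#: is looser because w_max scales with c^2 and c is printed to 3 decimals
WMAX_TOL_NSG = 0.035
WMAX_TOL_BSG = 0.005


@dataclass(frozen=True)
class CropFixture:
    """One crop's published parameter sets and reported maxima."""

    species: str
    latin_name: str
    nsg_params: NSGParameters
    bsg_params: BSGParameters
    reference_wmax_nsg: float
    reference_wmax_bsg: float


def load_crop_table() -> pd.DataFrame:
    """The raw eight-row crop parameter table as a dataframe."""
    path = resources.files("sigrow").joinpath("data/crop_parameters.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def _fixture_index() -> dict[str, CropFixture]:
    index: dict[str, CropFixture] = {}
    for row in load_crop_table().itertuples(index=False):
        fixture = CropFixture(
            species=row.english_name,
            latin_name=row.latin_name,
            nsg_params=NSGParameters(row.nsg_c, row.nsg_k, row.nsg_t_b,
                                     row.nsg_t_e),
            bsg_params=BSGParameters(row.bsg_c_m, row.bsg_t_m, row.bsg_t_b,
                                     row.bsg_t_e),
            reference_wmax_nsg=float(row.wmax_nsg_ref),
            reference_wmax_bsg=float(row.wmax_bsg_ref),
        )
        index[row.english_name.lower()] = fixture
        index[row.latin_name.lower()] = fixture
    return index


_INDEX: dict[str, CropFixture] | None = None


def crop_fixture(species: str) -> CropFixture:
    """Look up a crop by English or Latin name, case-insensitively."""
    global _INDEX
    if _INDEX is None:
        _INDEX = _fixture_index()
    try:
        return _INDEX[species.strip().lower()]
    except KeyError:
        known = ", ".join(sorted({f.species for f in _INDEX.values()}))
        raise UnknownSpeciesError(
            f"unknown species {species!r}; known crops: {known}"
        ) from None


def list_crops() -> list[CropFixture]:
    """All eight crop fixtures, in table order."""
    seen: list[CropFixture] = []
    for row in load_crop_table().itertuples(index=False):
        seen.append(crop_fixture(row.english_name))
    return seen
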