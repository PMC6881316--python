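"""The packaged market-survey fixture: 34 commercial truffles.

The roster lists each specimen's marketed (commercial) species name, origin
and harvest season, together with the species assignment established by ITS
barcode phylogeny — the ground truth the mass-spectrometry arm is audited
against. Seven Tuber species occur among the 34 specimens; the three Asian
black truffle lineages (T. indicum, T. longispinosum, T. himalayense) form
the morphologically intractable "T. indicum" species complex.
"""
from __future__ import annotations

from typing import Sequence

from .simulate import DesignRow, SimulationConfig
from .types import SpecimenRecord

__all__ = [
    "SPECIES",
    "INDICUM_COMPLEX",
    "commercial_truffle_records",
    "study_design",
    "blind_query_design",
    "default_study_config",
]

MELANOSPORUM = "T. melanosporum"
INDICUM = "T. indicum"
HIMALAYENSE = "T. himalayense"
LONGISPINOSUM = "T. longispinosum"
BRUMALE = "T. brumale"
AESTIVUM = "T. aestivum"
UNCINATUM = "T. uncinatum"
MESENTERICUM = "T. mesentericum"
MAGNATUM = "T. magnatum"

#: the seven species actually present, alphabetical (panel order).
SPECIES = (
    AESTIVUM,
    BRUMALE,
    HIMALAYENSE,
    INDICUM,
    LONGISPINOSUM,
    MAGNATUM,
    MELANOSPORUM,
)

#: sister lineages of the Asian black truffle complex (indices into SPECIES).
INDICUM_COMPLEX = tuple(SPECIES.index(s) for s in (HIMALAYENSE, INDICUM, LONGISPINOSUM))

# (specimen_id, marketed_species, origin, season, assigned_species)
_ROSTER = (
    # marketed T. melanosporum (7): all confirmed
    ("Tmel1", MELANOSPORUM, "Australia", "Summer", MELANOSPORUM),
    ("Tme22", MELANOSPORUM, "France", "Winter", MELANOSPORUM),
    ("Tme33", MELANOSPORUM, "France", "Winter", MELANOSPORUM),
    ("Tme44", MELANOSPORUM, "France", "Winter", MELANOSPORUM),
    ("Tme55", MELANOSPORUM, "France", "Winter", MELANOSPORUM),
    ("Tme66", MELANOSPORUM, "France", "Winter", MELANOSPORUM),
    ("Tme77", MELANOSPORUM, "France", "Winter", MELANOSPORUM),
    # marketed T. indicum (6): a mix of three complex lineages
    ("Tind11", INDICUM, "China", "Winter", INDICUM),
    ("Tind22", INDICUM, "China", "Winter", INDICUM),
    ("Tind33", INDICUM, "China", "Winter", HIMALAYENSE),
    ("Tind44", INDICUM, "China", "Winter", HIMALAYENSE),
    ("Tind55", INDICUM, "China", "Winter", HIMALAYENSE),
    ("Tind66", INDICUM, "China", "Winter", LONGISPINOSUM),
    # marketed T. brumale (5): all confirmed
    ("Tbr11", BRUMALE, "France", "Winter", BRUMALE),
    ("Tbr22", BRUMALE, "France", "Winter", BRUMALE),
    ("Tbr33", BRUMALE, "France", "Winter", BRUMALE),
    ("Tbr44", BRUMALE, "France", "Winter", BRUMALE),
    ("Tbr55", BRUMALE, "France", "Winter", BRUMALE),
    # marketed T. aestivum (4): all confirmed
    ("Taes1", AESTIVUM, "France/Spain", "Summer", AESTIVUM),
    ("Taes2", AESTIVUM, "France/Spain", "Summer", AESTIVUM),
    ("Taes3", AESTIVUM, "France/Spain", "Summer", AESTIVUM),
    ("Taes4", AESTIVUM, "France/Spain", "Summer", AESTIVUM),
    # marketed T. uncinatum (4): conspecific with T. aestivum
    ("Tunc1", UNCINATUM, "Bulgaria", "Autumn", AESTIVUM),
    ("Tunc22", UNCINATUM, "Bulgaria", "Autumn", AESTIVUM),
    ("Tunc33", UNCINATUM, "Bulgaria", "Autumn", AESTIVUM),
    ("Tunc44", UNCINATUM, "Bulgaria", "Autumn", AESTIVUM),
    # marketed T. mesentericum (6): all actually T. aestivum
    ("Tmes1", MESENTERICUM, "France", "Autumn", AESTIVUM),
    ("Tmes22", MESENTERICUM, "France", "Autumn", AESTIVUM),
    ("Tmes33", MESENTERICUM, "France", "Autumn", AESTIVUM),
    ("Tmes44", MESENTERICUM, "France", "Autumn", AESTIVUM),
    ("Tmes55", MESENTERICUM, "France", "Autumn", AESTIVUM),
    ("Tmes66", MESENTERICUM, "France", "Autumn", AESTIVUM),
    # marketed T. magnatum (2): all confirmed
    ("Tmg1", MAGNATUM, "France", "Autumn", MAGNATUM),
    ("Tmg22", MAGNATUM, "France", "Autumn", MAGNATUM),
)


def commercial_truffle_records() -> list[SpecimenRecord]:
    """The 34 specimens of the market survey, with molecular assignments."""
    return [
        SpecimenRecord(
            specimen_id=sid,
            marketed_species=marketed,
            origin=origin,
            season=season,
            assigned_species=assigned,
        )
        for sid, marketed, origin, season, assigned in _ROSTER
    ]


def study_design() -> list[DesignRow]:
    """The fixture as a simulation design: true species = molecular assignment."""
    return [
        DesignRow(
            specimen_id=sid,
            marketed_species=marketed,
            true_species=assigned,
            origin=origin,
            season=season,
        )
        for sid, marketed, origin, season, assigned in _ROSTER
    ]


#: species composition of the ten blind-coded queries (held-out specimens).
_BLIND = (
    ("unknown_T1", MELANOSPORUM),
    ("unknown_T2", MELANOSPORUM),
    ("unknown_T3", BRUMALE),
    ("unknown_T4", BRUMALE),
    ("unknown_T5", AESTIVUM),
    ("unknown_T6", AESTIVUM),
    ("unknown_T7", AESTIVUM),
    ("unknown_T8", MAGNATUM),
    ("unknown_T9", INDICUM),
    ("unknown_T10", HIMALAYENSE),
)


def blind_query_design() -> list[DesignRow]:
    """Ten blind-coded specimens spanning six of the seven species."""
    return [
        DesignRow(specimen_id=sid, marketed_species="unknown", true_species=sp)
        for sid, sp in _BLIND
    ]


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Simulation settings for the study-scale fixture: 7 species, 34
    specimens, 2 x 3 replicates (204 spectra), default noise."""
    counts = [sum(1 for r in _ROSTER if r[4] == sp) for sp in SPECIES]
    return SimulationConfig(
        n_species=len(SPECIES),
        specimens_per_species=counts,
        complex_groups=(INDICUM_COMPLEX,),
        seed=seed,
    )
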