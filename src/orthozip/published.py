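"""Published family-wide tallies for wheat and its relatives.

These constants reproduce the printed bZIP-family ortholog count table
for bread wheat, its diploid progenitors *T. urartu* (A genome) and
*Ae. tauschii* (D genome), barley and *Brachypodium*: per species the
total number of catalogued family members, and per species pair how
many of the row species' genes have an ortholog in the column species
together with the number of shared ortholog groups.  They serve as
inputs to the statistics in :mod:`orthozip.orthostats`; the original
underlying genomes and proteomes are not redistributed here.
"""

from __future__ import annotations

from .orthostats import OrthologCountMatrix

SPECIES = ["wheat", "urartu", "tauschii", "barley", "brachypodium"]

#: catalogued bZIP family sizes (non-redundant scan catalogues)
TOTALS = {
    "wheat": 182,
    "urartu": 98,
    "tauschii": 96,
    "barley": 107,
    "brachypodium": 88,
}

#: row species' genes having orthologs in the column species
N_ORTHOLOGOUS = {
    ("wheat", "urartu"): 76, ("wheat", "tauschii"): 78,
    ("wheat", "barley"): 110, ("wheat", "brachypodium"): 113,
    ("urartu", "wheat"): 52, ("urartu", "tauschii"): 68,
    ("urartu", "barley"): 63, ("urartu", "brachypodium"): 50,
    ("tauschii", "wheat"): 54, ("tauschii", "urartu"): 66,
    ("tauschii", "barley"): 61, ("tauschii", "brachypodium"): 51,
    ("barley", "wheat"): 70, ("barley", "urartu"): 65,
    ("barley", "tauschii"): 69, ("barley", "brachypodium"): 78,
    ("brachypodium", "wheat"): 55, ("brachypodium", "urartu"): 53,
    ("brachypodium", "tauschii"): 54, ("brachypodium", "barley"): 72,
}

#: ortholog groups shared by each species pair
N_GROUPS = {
    frozenset(("wheat", "urartu")): 49,
    frozenset(("wheat", "tauschii")): 54,
    frozenset(("wheat", "barley")): 64,
    frozenset(("wheat", "brachypodium")): 54,
    frozenset(("urartu", "tauschii")): 65,
    frozenset(("urartu", "barley")): 60,
    frozenset(("urartu", "brachypodium")): 45,
    frozenset(("tauschii", "barley")): 61,
    frozenset(("tauschii", "brachypodium")): 49,
    frozenset(("barley", "brachypodium")): 72,
}

#: curated wheat family members added from the literature on top of the
#: 182-gene scan catalogue (names, not recomputable from sequence here)
CURATED_WHEAT_ADDITIONS = ["TaOBF1a", "WABI5", "TaABP1", "TaABI5", "TaABL1"]


def published_count_matrix() -> OrthologCountMatrix:
    """The published family-wide ortholog count matrix."""
    return OrthologCountMatrix(
        species=list(SPECIES),
        totals=dict(TOTALS),
        n_orthologous=dict(N_ORTHOLOGOUS),
        n_groups=dict(N_GROUPS),
    )
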