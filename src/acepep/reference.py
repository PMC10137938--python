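"""Bundled reference measurements for ACE-tetrapeptide complexes.

Published AS-GBIE binding free energies of the twelve complexes studied by
MD (the top-10 and bottom-2 of the docked library), experimental IC50s of
the same peptides, chymotryptic-hydrolysate inhibition rates, and the
top-5000 Trp positional percentages.  These serve as worked-example inputs
and qualitative anchors; the docking scores and wet-lab measurements behind
them are not reproducible from sequence alone.

Note the printed ACE-RWWD row carries a rounding inconsistency of ~0.1
kcal/mol between its components and its dH/dG_bind; it is kept verbatim.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Trp percentage at P1..P4 within the top-5000 slice of the docked library.
TRP_TOP5000_PCT: dict[str, float] = {
    "P1": 27.32, "P2": 20.54, "P3": 15.86, "P4": 20.86,
}

#: Printed rows whose dH/dG_bind disagree with their own components by more
#: than the two-decimal rounding bound of 0.02 kcal/mol.
ROUNDING_OUTLIERS: dict[str, float] = {"ACE-RWWD": 0.10}


def _load_csv(name: str) -> pd.DataFrame:
    path = resources.files("acepep.data") / name
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_binding_energies() -> pd.DataFrame:
    """AS-GBIE free-energy table: components, dH, -TdS, dG_bind (kcal/mol)."""
    return _load_csv("ace_complex_energies.csv")


def load_ic50_table() -> pd.DataFrame:
    """Experimental IC50s (uM) of the twelve assayed tetrapeptides.

    Censored rows (``censored == True``) are lower bounds: no measurable
    inhibition below 5000 uM.
    """
    return _load_csv("ace_ic50.csv")


def load_hydrolysate_rates() -> pd.DataFrame:
    """ACE inhibition (%) of chymotryptic hydrolysates vs Trp content."""
    return _load_csv("hydrolysate_inhibition.csv")
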