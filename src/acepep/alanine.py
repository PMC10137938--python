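"""Alanine-scan free-energy decomposition and hotspot calling.

Each receptor residue x near the bound peptide is mutated to alanine and its
contribution is the difference of binding free energies before and after the
mutation, ddG(x->a) = dG(x) - dG(a); the contributions of all scanned
residues sum to the total binding free energy.  A residue is a hotspot in a
given complex when its mean contribution is favourable by at least a
threshold (default 1 kcal/mol, i.e. contribution <= -1); recurrent hotspots
are residues passing in at least a minimum fraction (default 50%) of the
complexes studied.

Note on sign: favourable contributions are negative, so "contributing more
than 1 kcal/mol" is tested as contribution <= -threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_KCAL: float = 1.0
DEFAULT_MIN_OCCURRENCE: float = 0.5


def residue_ddg(dg_wildtype: float, dg_alanine: float) -> float:
    """Per-residue contribution dG(x) - dG(a) in kcal/mol."""
    if not (np.isfinite(dg_wildtype) and np.isfinite(dg_alanine)):
        raise ValueError("binding free energies must be finite")
    return dg_wildtype - dg_alanine


def total_from_decomposition(contributions) -> float:
    """Total binding free energy as the sum of per-residue contributions."""
    values = np.asarray(list(contributions), dtype=float)
    if values.size == 0:
        raise ValueError("empty decomposition")
    if not np.all(np.isfinite(values)):
        raise ValueError("contributions must be finite")
    return float(values.sum())


@dataclass
class HotspotCall:
    residue_id: str
    mean_contribution: float  # kcal/mol, across complexes
    sd_contribution: float
    occurrence_fraction: float
    is_hotspot: bool


def summarize_replicas(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of ddg across replicas per (complex, residue).

    ``table`` is long-format with columns complex_id, residue_id, replica, ddg.
    """
    required = {"complex_id", "residue_id", "replica", "ddg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    grouped = table.groupby(["complex_id", "residue_id"])["ddg"]
    out = grouped.agg(mean="mean", sd="std", n_replicas="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def call_hotspots(
    table: pd.DataFrame,
    threshold_kcal: float = DEFAULT_THRESHOLD_KCAL,
    min_occurrence: float = DEFAULT_MIN_OCCURRENCE,
    over: str = "complexes",
) -> list[HotspotCall]:
    """Identify recurrent hotspot residues across complexes.

    A residue passes in a complex when its replica-mean contribution is
    <= -``threshold_kcal``; its occurrence fraction is the share of
    complexes in which it passes, and it is a hotspot when that fraction is
    >= ``min_occurrence``.  With ``over='replicas'`` the occurrence is
    instead counted over individual replica values pooled across complexes.

    Every complex must report the same residue universe, otherwise the
    occurrence denominator would be ambiguous.
    """
    if threshold_kcal <= 0:
        raise ValueError("threshold must be positive (magnitude of contribution)")
    if not 0 <= min_occurrence <= 1:
        raise ValueError("min_occurrence must be in [0, 1]")
    if over not in ("complexes", "replicas"):
        raise ValueError("over must be 'complexes' or 'replicas'")

    per = summarize_replicas(table)
    universes = per.groupby("complex_id")["residue_id"].agg(frozenset)
    if len(set(universes)) != 1:
        raise ValueError("complexes report inconsistent residue universes")

    calls: list[HotspotCall] = []
    for residue, sub in per.groupby("residue_id"):
        if over == "complexes":
            passed = (sub["mean"] <= -threshold_kcal).sum()
            total = len(sub)
        else:
            raw = table.loc[table["residue_id"] == residue, "ddg"]
            passed = (raw <= -threshold_kcal).sum()
            total = len(raw)
        occurrence = passed / total
        calls.append(
            HotspotCall(
                residue_id=str(residue),
                mean_contribution=float(sub["mean"].mean()),
                sd_contribution=float(sub["mean"].std(ddof=1))
                if len(sub) > 1 else 0.0,
                occurrence_fraction=float(occurrence),
                is_hotspot=bool(occurrence >= min_occurrence),
            )
        )
    calls.sort(key=lambda c: (c.mean_contribution, c.residue_id))
    return calls


def hotspot_report(calls: list[HotspotCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": [c.residue_id for c in calls],
            "mean_kcal": [c.mean_contribution for c in calls],
            "sd_kcal": [c.sd_contribution for c in calls],
            "occurrence": [c.occurrence_fraction for c in calls],
            "is_hotspot": [c.is_hotspot for c in calls],
        }
    )
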