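"""Ranked-library statistics: positional residue frequencies and enrichment.

A docking-scored peptide library is ranked (more negative score = stronger
predicted binding) and the residue composition of its top-N and bottom-N
slices is tabulated per position, the analysis that exposes the
aromatic/basic residue preference of ACE-inhibitory tetrapeptides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .peptides import PEPTIDE_LENGTH, POSITIONS, STANDARD_ALPHABET


def rank_peptides(library: pd.DataFrame) -> pd.DataFrame:
    """Sort a library ascending by score, ties broken lexicographically.

    Parameters
    ----------
    library : DataFrame with columns ``peptide`` and ``score``.

    Returns a new DataFrame with rank 1 = most negative (strongest) score.
    """
    if library.empty:
        raise ValueError("peptide library is empty")
    missing = {"peptide", "score"} - set(library.columns)
    if missing:
        raise ValueError(f"library missing columns: {sorted(missing)}")
    if not np.isfinite(library["score"]).all():
        raise ValueError("library contains non-finite scores")
    ranked = library.sort_values(
        ["score", "peptide"], kind="mergesort"
    ).reset_index(drop=True)
    return ranked


def positional_frequencies(
    ranked: pd.DataFrame,
    n: int = 5000,
    end: str = "top",
    alphabet: str = STANDARD_ALPHABET,
) -> pd.DataFrame:
    """Residue percentage at each position within the top-n or bottom-n slice.

    Entry (r, p) is ``100 * count(residue r at position p in slice) / n``,
    so every column sums to 100.  ``end`` selects the strongest-binding
    ("top") or weakest-binding ("bottom") end of the ranking.
    """
    if n <= 0 or n > len(ranked):
        raise ValueError(f"slice size n={n} outside 1..{len(ranked)}")
    if end not in ("top", "bottom"):
        raise ValueError("end must be 'top' or 'bottom'")
    seqs = ranked["peptide"].iloc[:n] if end == "top" else ranked["peptide"].iloc[-n:]
    rows = sorted(alphabet)
    # 2-D residue x position count via a single codes array
    codes = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, PEPTIDE_LENGTH)
    table = pd.DataFrame(0.0, index=rows, columns=list(POSITIONS))
    for j, pos in enumerate(POSITIONS):
        letters, counts = np.unique(codes[:, j], return_counts=True)
        for letter, count in zip(letters.astype(str), counts):
            table.loc[letter, pos] = 100.0 * count / n
    table.attrs["slice_size"] = n
    table.attrs["slice_end"] = end
    return table


def preference_summary(
    top_table: pd.DataFrame, bottom_table: pd.DataFrame
) -> pd.DataFrame:
    """Per residue/position enrichment of the top slice over the bottom slice.

    Returns a long-format frame with top/bottom percentages and a smoothed
    log2 ratio (0.5 pseudo-count added to each slice count before the ratio,
    so residues absent from one slice do not divide by zero).  Ratio > 0 is
    flagged ``preferred``, < 0 ``avoided``.
    """
    n_top = top_table.attrs.get("slice_size")
    n_bot = bottom_table.attrs.get("slice_size")
    if n_top is None or n_bot is None or n_top != n_bot:
        raise ValueError("top and bottom tables must share slice_size")
    if not (top_table.index.equals(bottom_table.index)
            and top_table.columns.equals(bottom_table.columns)):
        raise ValueError("top and bottom tables must share shape and labels")
    n = n_top
    records = []
    for pos in top_table.columns:
        for residue in top_table.index:
            top_pct = top_table.loc[residue, pos]
            bot_pct = bottom_table.loc[residue, pos]
            top_count = top_pct * n / 100.0
            bot_count = bot_pct * n / 100.0
            log2_ratio = np.log2((top_count + 0.5) / (bot_count + 0.5))
            records.append(
                {
                    "residue": residue,
                    "position": pos,
                    "top_pct": top_pct,
                    "bottom_pct": bot_pct,
                    "log2_enrichment": log2_ratio,
                    "call": "preferred" if log2_ratio > 0
                    else ("avoided" if log2_ratio < 0 else "neutral"),
                }
            )
    return pd.DataFrame.from_records(records)


def read_scored_library(path) -> pd.DataFrame:
    """Read a peptide,score CSV into a library frame."""
    df = pd.read_csv(path)
    return df[["peptide", "score"]]
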