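"""Tetrapeptide sequence space: enumeration and residue-property encoding.

The screening library is the complete space of linear tetrapeptides over the
20 canonical amino acids, 20**4 = 160,000 sequences.  Each peptide can be
encoded as a transaction of positional property items (``P1:aromatic``, ...)
for association-rule mining of sequence characteristics.
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

#: Canonical one-letter codes in alphabetical order.  This ordering defines
#: the enumeration order and the row order of every frequency table.
STANDARD_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

PEPTIDE_LENGTH: int = 4

#: Positional labels, N-terminus (P1) to C-terminus (P4).
POSITIONS: tuple[str, ...] = tuple(f"P{i}" for i in range(1, PEPTIDE_LENGTH + 1))


class AlphabetError(ValueError):
    """Raised for an alphabet that is not 20 distinct uppercase letters."""


class EncodingError(KeyError):
    """Raised when a residue has no class in the property scheme."""


def validate_alphabet(alphabet: str | Iterable[str]) -> str:
    """Return the alphabet as a string after checking its invariants.

    Exactly 20 symbols, all uppercase letters, no duplicates.
    """
    codes = "".join(alphabet)
    if len(codes) != 20:
        raise AlphabetError(f"alphabet must have exactly 20 codes, got {len(codes)}")
    if len(set(codes)) != len(codes):
        raise AlphabetError("alphabet contains duplicate codes")
    if not all(c.isalpha() and c.isupper() for c in codes):
        raise AlphabetError("alphabet codes must be uppercase letters")
    return codes


def validate_peptide(sequence: str, alphabet: str = STANDARD_ALPHABET) -> str:
    """Check a sequence is a length-4 peptide over ``alphabet``."""
    if len(sequence) != PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide must have length {PEPTIDE_LENGTH}, got {sequence!r}"
        )
    bad = set(sequence) - set(alphabet)
    if bad:
        raise ValueError(f"peptide {sequence!r} has residues outside alphabet: {bad}")
    return sequence


def enumerate_tetrapeptides(alphabet: str = STANDARD_ALPHABET) -> list[str]:
    """Enumerate all 160,000 tetrapeptides in lexicographic order.

    With the standard alphabetical ordering the first sequence is ``AAAA``
    and the last is ``YYYY``.  Every residue occurs exactly 20**3 = 8,000
    times at each of the four positions.
    """
    codes = validate_alphabet(alphabet)
    ordered = sorted(codes)
    return ["".join(p) for p in itertools.product(ordered, repeat=PEPTIDE_LENGTH)]


# ---------------------------------------------------------------------------
# Property scheme
# ---------------------------------------------------------------------------

class PropertyScheme:
    """Residue -> property-class mapping used to build transactions.

    A residue may carry several classes (His is both aromatic and positively
    charged).  Schemes are plain mappings loadable from a YAML config so users
    can substitute their own classification.
    """

    def __init__(self, classes: dict[str, list[str]], scheme_id: str = "custom"):
        self.classes = {aa: list(props) for aa, props in classes.items()}
        self.scheme_id = scheme_id

    def properties_of(self, residue: str) -> list[str]:
        try:
            return self.classes[residue]
        except KeyError:
            raise EncodingError(
                f"residue {residue!r} is not classified by scheme {self.scheme_id!r}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertyScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        scheme_id = data.pop("scheme_id", Path(path).stem)
        return cls(data, scheme_id=scheme_id)

    _default_cache: "PropertyScheme | None" = None

    @classmethod
    def default(cls) -> "PropertyScheme":
        """The built-in scheme.

        Classes: aromatic {F,W,Y,H}; positive {R,K,H}; negative {D,E};
        polar {S,T,N,Q,C}; aliphatic {A,V,L,I,M,P,G}; small {G,A,S,C,T}.
        These are the categories in which ACE-inhibitory preference shows up:
        aromatic stacking residues, salt-bridge-capable basic residues, and
        short side chains that fail to anchor in the active-site pocket.
        """
        if cls._default_cache is None:
            path = resources.files("acepep.data") / "default_scheme.yaml"
            with resources.as_file(path) as p:
                cls._default_cache = cls.from_yaml(p)
        return cls._default_cache


def encode_properties(
    peptide: str,
    scheme: PropertyScheme | None = None,
    positional: bool = True,
) -> frozenset[str]:
    """Encode a peptide as a transaction of property items.

    With ``positional=True`` (default) items are ``P<i>:<class>``; with
    ``positional=False`` the items are the bag of classes present anywhere
    in the sequence.  Deterministic: equal peptides give equal itemsets.
    """
    scheme = scheme or PropertyScheme.default()
    validate_peptide(peptide)
    items: set[str] = set()
    for pos, residue in zip(POSITIONS, peptide):
        for prop in scheme.properties_of(residue):
            items.add(f"{pos}:{prop}" if positional else prop)
    return frozenset(items)


# ---------------------------------------------------------------------------
# Plain-text / FASTA I/O
# ---------------------------------------------------------------------------

def write_peptides(peptides: Iterable[str], path: str | Path, fasta: bool = False) -> None:
    with open(path, "w") as fh:
        for seq in peptides:
            fh.write(f">{seq}\n{seq}\n" if fasta else f"{seq}\n")


def read_peptides(path: str | Path) -> list[str]:
    """Read a peptide list from plain text (one per line) or FASTA."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            out.append(line)
    return out
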