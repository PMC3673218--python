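"""The 20-letter amino acid alphabet used throughout the package.

The residue order matches the HMMER3 amino alphabet (alphabetical by
one-letter code), so emission vectors read from ``.hmm`` files can be
indexed directly. Ambiguity/nonstandard codes (B, Z, X, U, O, J) are
rejected at the boundary rather than redistributed over the alphabet.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AMINO_ACIDS: int = 20


class AlphabetError(ValueError):
    """A residue letter outside the 20 standard amino acids."""


def check_residue(residue: str) -> str:
    """Validate a one-letter residue code, returning it uppercased."""
    r = residue.upper()
    if len(r) != 1 or r not in AA_INDEX:
        raise AlphabetError(
            f"{residue!r} is not one of the 20 standard amino acids "
            f"({AMINO_ACIDS}); ambiguity codes are not accepted"
        )
    return r
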