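"""Frozen token alphabets for proteins and SMILES.

Both alphabets are stored as plain-text constant files (one symbol per
line, file order = token id order starting at 1) so that token ids are
bit-exact across versions and environments.  Id 0 is reserved for padding
in every vocabulary and is never assigned to a symbol.

* Residue alphabet: the 20 standard amino acids plus ``U`` (selenocysteine)
  and ``X``; 22 symbols.  Any character outside the set maps to ``X``.
* SMILES alphabet: a 64-character label-encoding set covering digits,
  organic-subset element letters (upper and lower case for aromaticity),
  and bond/ring/branch/charge punctuation.
"""

from __future__ import annotations

from importlib import resources
from functools import lru_cache

PAD_ID = 0
FALLBACK_RESIDUE = "X"


def _load_symbols(filename: str) -> tuple[str, ...]:
    text = (resources.files("dtifuse") / "data" / filename).read_text()
    symbols = tuple(line for line in text.splitlines() if line != "")
    return symbols


class ResidueAlphabet:
    """22-symbol protein residue vocabulary with ids 1..22."""

    def __init__(self) -> None:
        self.symbols = _load_symbols("residue_alphabet.txt")
        if len(self.symbols) != 22 or len(set(self.symbols)) != 22:
            raise RuntimeError("residue alphabet must hold 22 distinct symbols")
        self.pad_id = PAD_ID
        self.index = {s: i + 1 for i, s in enumerate(self.symbols)}
        self.fallback_id = self.index[FALLBACK_RESIDUE]

    def __len__(self) -> int:
        return len(self.symbols)

    def encode_char(self, c: str) -> int:
        return self.index.get(c, self.fallback_id)

    def decode_id(self, i: int) -> str:
        if not 1 <= i <= len(self.symbols):
            raise ValueError(f"residue id {i} outside 1..{len(self.symbols)}")
        return self.symbols[i - 1]


class SmilesAlphabet:
    """64-character SMILES vocabulary with ids 1..64.

    ``unk_policy`` controls what happens on a character outside the set:
    ``"error"`` (default) raises :class:`KeyError` naming the character;
    ``"map_to_reserved"`` maps it to the last id (64).
    """

    def __init__(self, unk_policy: str = "error") -> None:
        if unk_policy not in ("error", "map_to_reserved"):
            raise ValueError(f"unknown unk_policy {unk_policy!r}")
        self.chars = _load_symbols("smiles_alphabet.txt")
        if len(self.chars) != 64 or len(set(self.chars)) != 64:
            raise RuntimeError("SMILES alphabet must hold 64 distinct characters")
        self.pad_id = PAD_ID
        self.unk_policy = unk_policy
        self.index = {c: i + 1 for i, c in enumerate(self.chars)}

    def __len__(self) -> int:
        return len(self.chars)

    def encode_char(self, c: str) -> int:
        try:
            return self.index[c]
        except KeyError:
            if self.unk_policy == "map_to_reserved":
                return len(self.chars)
            raise KeyError(
                f"character {c!r} is not in the 64-symbol SMILES alphabet"
            ) from None

    def decode_id(self, i: int) -> str:
        if not 1 <= i <= len(self.chars):
            raise ValueError(f"SMILES token id {i} outside 1..{len(self.chars)}")
        return self.chars[i - 1]


@lru_cache(maxsize=None)
def residue_alphabet() -> ResidueAlphabet:
    return ResidueAlphabet()


@lru_cache(maxsize=None)
def smiles_alphabet(unk_policy: str = "error") -> SmilesAlphabet:
    return SmilesAlphabet(unk_policy)
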