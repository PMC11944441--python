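"""Reduced amino-acid alphabets for seeding.

Seeding on a many-to-one reduction of the 20 standard residues trades a small
amount of specificity for much cheaper exact k-mer matching: residues that
substitute freely for one another (e.g. I/L/V, or the charged/polar group
K/R/E/D/Q/N) collapse to one symbol, so homologous segments that differ only
within a group still share seeds.  The default here is the 11-group partition
[KREDQN] [C] [G] [H] [ILV] [M] [F] [Y] [W] [P] [STA].
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import STANDARD_AA

#: 11-group reduction used for seeding (group symbol = first member).
DEFAULT_GROUPS: tuple[str, ...] = (
    "KREDQN",
    "C",
    "G",
    "H",
    "ILV",
    "M",
    "F",
    "Y",
    "W",
    "P",
    "STA",
)


@dataclass(frozen=True)
class ReducedAlphabet:
    """An ordered partition of the 20 standard residues into groups.

    Each group is written as a string of its member residues; the group's
    symbol is its first member.  The partition must be disjoint and cover all
    20 standard letters.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    _mapping: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        covered: dict[str, str] = {}
        for group in self.groups:
            if not group:
                raise ValueError("empty residue group")
            symbol = group[0]
            for residue in group:
                if residue in covered:
                    raise ValueError(f"residue {residue} appears in two groups")
                covered[residue] = symbol
        if set(covered) != STANDARD_AA:
            missing = "".join(sorted(STANDARD_AA - set(covered)))
            extra = "".join(sorted(set(covered) - STANDARD_AA))
            raise ValueError(
                f"groups must partition the 20 standard residues"
                f" (missing: {missing!r}, extra: {extra!r})"
            )
        object.__setattr__(self, "_mapping", covered)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self._mapping)

    def reduce(self, sequence: str) -> str:
        """Map a standard-alphabet sequence to its reduced image.

        Length is preserved; a residue outside the 20-letter alphabet is a
        contract violation (validate first).
        """
        try:
            return "".join(self._mapping[c] for c in sequence)
        except KeyError as exc:
            raise ValueError(
                f"residue {exc.args[0]!r} is outside the standard alphabet"
            ) from None


DIAMOND_11 = ReducedAlphabet()


def reduce_alphabet(sequence: str, alphabet: ReducedAlphabet = DIAMOND_11) -> str:
    """Module-level convenience wrapper over :meth:`ReducedAlphabet.reduce`."""
    return alphabet.reduce(sequence)
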