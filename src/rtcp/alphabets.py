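"""Reduced amino-acid alphabets (RAAAs).

A reduced alphabet partitions the 20 standard amino acids into K classes of
residues sharing a physicochemical property, so a protein sequence can be
rewritten as a K-symbol sequence. Six canonical alphabets are provided, each
derived from a pair of properties among hydrophobicity (HP), surface tension
(ST), solvent solubility (SS), and charged polarity (CP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes dropped before reduction.
NON_STANDARD_LETTERS = frozenset("BJOUXZ")


@dataclass(frozen=True)
class PhysicoChemicalProperty:
    """A three-way classification of the amino acids by one property.

    These four classifications are kept as published even though the
    solvent-solubility row is internally inconsistent (S, T, C listed twice;
    D, N, Q, R in no class) -- see :func:`build_alphabet` for how collisions
    and gaps are resolved when intersecting two properties.
    """

    name: str
    classes: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.classes) != 3:
            raise ValueError(f"property {self.name!r} must have exactly 3 classes")


HYDROPHOBICITY = PhysicoChemicalProperty(
    "hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")
)
SURFACE_TENSION = PhysicoChemicalProperty(
    "surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")
)
SOLVENT_SOLUBILITY = PhysicoChemicalProperty(
    "solvent_solubility", ("ALFCGIVW", "KTSEC", "MPSTHY")
)
CHARGED_POLARITY = PhysicoChemicalProperty(
    "charged_polarity", ("LIFWCMVY", "PATGS", "HQRKEND")
)

PROPERTIES: Mapping[str, PhysicoChemicalProperty] = {
    p.name: p
    for p in (HYDROPHOBICITY, SURFACE_TENSION, SOLVENT_SOLUBILITY, CHARGED_POLARITY)
}


@dataclass(frozen=True)
class ReducedAlphabet:
    """A named total partition of the 20 standard letters into K classes.

    ``classes`` keeps the published top-to-bottom cell order; the class index
    of a letter under that order fixes the coordinate system of tripeptide
    features, so it must never be reordered.
    """

    name: str
    classes: tuple[str, ...]
    letter_map: Mapping[str, int] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (2 <= len(self.classes) <= 20):
            raise ValueError("alphabet must have between 2 and 20 classes")
        seen: dict[str, int] = {}
        for idx, cls in enumerate(self.classes):
            if not cls:
                raise ValueError("empty class in alphabet")
            for letter in cls:
                if letter in seen:
                    raise ValueError(
                        f"letter {letter} appears in classes {seen[letter]} and {idx}"
                    )
                seen[letter] = idx
        if set(seen) != set(STANDARD_LETTERS):
            missing = sorted(set(STANDARD_LETTERS) - set(seen))
            extra = sorted(set(seen) - set(STANDARD_LETTERS))
            raise ValueError(
                f"alphabet {self.name!r} is not a partition of the 20 letters "
                f"(missing {missing}, extra {extra})"
            )
        object.__setattr__(self, "letter_map", seen)

    @property
    def size(self) -> int:
        """Number of classes K."""
        return len(self.classes)

    def __len__(self) -> int:
        return len(self.classes)


def _dedupe_cells(name: str, cells: Sequence[str]) -> tuple[str, ...]:
    """Resolve duplicated letters by first occurrence in cell order.

    The published SS_CP column lists L both in ICWFLV and LH; the first
    (topmost) cell wins, which preserves the printed class count.
    """
    assigned: set[str] = set()
    out: list[str] = []
    for cell in cells:
        kept = "".join(c for c in cell if c not in assigned)
        dropped = [c for c in cell if c in assigned]
        if dropped:
            logger.debug("alphabet %s: dropped duplicate letters %s", name, dropped)
        assigned.update(kept)
        if kept:
            out.append(kept)
    return tuple(out)


# Column cells of the published RAAA table, top-to-bottom (non-empty only).
_CANONICAL_CELLS: dict[str, tuple[str, ...]] = {
    "HP_ST": ("RQND", "EK", "AGH", "ST", "PY", "C", "WIFLMV"),
    "HP_SS": ("NEQRDK", "AG", "SPYHT", "CFIVWL", "M"),
    "HP_CP": ("RKDQEN", "Y", "GPSTA", "H", "LFVCIWM"),
    "ST_SS": ("AG", "RNDQH", "C", "ST", "KE", "MYVLFWI", "P"),
    "ST_CP": ("GA", "NQDR", "H", "C", "EK", "TS", "FLWIV", "MYP"),
    "SS_CP": ("ICWFLV", "AG", "RDENQK", "MY", "SPT", "LH"),
}

#: Expected class count per canonical alphabet.
CANONICAL_SIZES = {"HP_ST": 7, "HP_SS": 5, "HP_CP": 5, "ST_SS": 7, "ST_CP": 8, "SS_CP": 6}


def canonical_alphabets() -> dict[str, ReducedAlphabet]:
    """Return the six canonical reduced alphabets, keyed by name.

    Classes come verbatim from the published table; a letter printed in two
    cells is assigned to the topmost cell. Class counts are HP_ST 7, HP_SS 5,
    HP_CP 5, ST_SS 7, ST_CP 8, SS_CP 6.
    """
    out = {}
    for name, cells in _CANONICAL_CELLS.items():
        out[name] = ReducedAlphabet(name, _dedupe_cells(name, cells))
    return out


def build_alphabet(
    prop_a: PhysicoChemicalProperty,
    prop_b: PhysicoChemicalProperty,
    name: str | None = None,
) -> ReducedAlphabet:
    """Intersect two physicochemical classifications into a reduced alphabet.

    Classes are the non-empty pairwise intersections of prop_a's class i with
    prop_b's class j, ordered by (i, j). Letters claimed by more than one cell
    (possible when a property lists a letter twice) go to the first cell in
    that order; letters covered by neither property are appended as a final
    overflow class.

    Raises ``ValueError`` for ``prop_a == prop_b`` (self-intersection merely
    reproduces the property) and if no total cover of the 20 letters results.
    """
    if prop_a == prop_b:
        raise ValueError("cannot intersect a property with itself")
    cells = []
    for ca in prop_a.classes:
        for cb in prop_b.classes:
            inter = "".join(c for c in ca if c in cb)
            if inter:
                cells.append(inter)
    classes = list(_dedupe_cells(f"{prop_a.name}x{prop_b.name}", cells))
    covered = set("".join(classes))
    leftovers = "".join(c for c in STANDARD_LETTERS if c not in covered)
    if leftovers:
        logger.warning(
            "letters %s covered by neither property; appended as overflow class",
            leftovers,
        )
        classes.append(leftovers)
    alpha_name = name or f"{prop_a.name}_x_{prop_b.name}"
    try:
        return ReducedAlphabet(alpha_name, tuple(classes))
    except ValueError as exc:  # pragma: no cover - malformed user properties
        raise ValueError(
            f"properties {prop_a.name!r} and {prop_b.name!r} do not produce a "
            f"total partition: {exc}"
        ) from exc


def sanitize_sequence(seq: str) -> str:
    """Uppercase and strip non-standard residue codes (B, J, O, U, X, Z).

    Whitespace and ``*`` stop codons are removed silently; dropped residue
    letters are logged because they shorten the sequence.
    """
    seq = "".join(seq.split()).upper().replace("*", "")
    dropped = [c for c in seq if c in NON_STANDARD_LETTERS]
    if dropped:
        logger.warning("dropping %d non-standard residues: %s", len(dropped), dropped)
    cleaned = []
    for c in seq:
        if c in NON_STANDARD_LETTERS:
            continue
        if c not in STANDARD_LETTERS:
            raise ValueError(f"unrecognized residue letter {c!r}")
        cleaned.append(c)
    return "".join(cleaned)


def reduce_sequence(seq: str, alphabet: ReducedAlphabet) -> list[int]:
    """Map an amino-acid sequence to a list of class indices.

    Non-standard letters are dropped first; the result has one symbol per
    retained residue. Raises ``ValueError`` if nothing remains.
    """
    clean = sanitize_sequence(seq)
    if not clean:
        raise ValueError("sequence is empty after removing non-standard residues")
    lm = alphabet.letter_map
    return [lm[c] for c in clean]


# ---------------------------------------------------------------------------
# plain-text serialization: one class per line, letters concatenated


def write_alphabet(alphabet: ReducedAlphabet, path: str | Path) -> None:
    Path(path).write_text(
        f"# {alphabet.name}\n" + "\n".join(alphabet.classes) + "\n"
    )


def read_alphabet(path: str | Path, name: str | None = None) -> ReducedAlphabet:
    lines = Path(path).read_text().splitlines()
    alpha_name = name
    classes: list[str] = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if alpha_name is None:
                alpha_name = line.lstrip("# ").strip()
            continue
        classes.append(line.upper())
    return ReducedAlphabet(alpha_name or Path(path).stem, tuple(classes))
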