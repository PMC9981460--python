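"""Monoisotopic mass model for peptides under per-residue 13C labelling.

In a DILAC experiment, cells are grown on fully 13C-labelled glucose with an
unlabelled (12C) amino-acid supplement.  Every residue a cell synthesizes
de novo is therefore heavy at all its carbons, while the supplemented amino
acid (lysine in the reference workflow) is heavy only when the cell produced
it itself.  This module computes the masses and m/z values of peptides, free
amino acids and y/b fragment ions under arbitrary combinations of fixed
(always-heavy) residues and a variable *target* residue whose per-site
labelling state is given by a boolean pattern, and it enumerates the full set
of labelling patterns of a peptide (2**n for n target sites).

All masses are monoisotopic and in daltons; m/z in thomson.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from math import copysign, floor
from typing import Iterator, Literal, Optional, Sequence

from .errors import FragmentOrdinalError, PatternLengthError, UnknownResidueError

#: 13C - 12C mass difference (Da), CODATA.
C13_C12_MASS_SHIFT = 1.0033548378
PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.000548579909

_ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

IonSeries = Literal["y", "b"]


class ElementalComposition(Counter):
    """Element symbol -> atom count, with element-wise addition.

    Counts must stay non-negative; arithmetic via ``+`` preserves the type.
    """

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] += n
        return out

    @property
    def monoisotopic_mass(self) -> float:
        return sum(_ELEMENT_MASS[el] * n for el, n in self.items() if n)


def _load_residue_table() -> dict[str, ElementalComposition]:
    table: dict[str, ElementalComposition] = {}
    src = resources.files("dilac.data").joinpath("residue_compositions.tsv")
    with src.open("r") as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    for rec in csv.DictReader(rows, delimiter="\t"):
        comp = ElementalComposition(
            {el: int(rec[el]) for el in ("C", "H", "N", "O", "S") if int(rec[el])}
        )
        table[rec["residue"]] = comp
    return table


RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = _load_residue_table()

WATER = ElementalComposition({"H": 2, "O": 1})


def residue_composition(residue: str) -> ElementalComposition:
    try:
        return RESIDUE_COMPOSITIONS[residue]
    except KeyError:
        raise UnknownResidueError(f"unknown residue code {residue!r}") from None


def residue_carbon_count(residue: str) -> int:
    """Number of carbon atoms in a residue's elemental formula (e.g. K -> 6)."""
    return residue_composition(residue)["C"]


def peptide_composition(sequence: str, as_free_amino_acid: bool = False) -> ElementalComposition:
    """Neutral composition of a peptide (residues + water).

    A free amino acid is the single-residue case: residue formula plus water.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if as_free_amino_acid and len(sequence) != 1:
        raise ValueError("a free amino acid is a single residue")
    comp = ElementalComposition(WATER)
    for res in sequence:
        comp = comp + residue_composition(res)
    return comp


@dataclass(frozen=True)
class LabelScheme:
    """Which residue is the variable (diagnostic) residue and which are fixed-heavy.

    ``target_residue`` is the amino acid whose labelling state varies between
    producer and consumer cells.  ``fixed_labelled_residues`` always carry
    13C at every carbon (all standard residues except the target by default:
    they are synthesized from labelled glucose by every cell).  A scheme with
    ``target_residue=None`` and an empty fixed set describes fully unlabelled
    material.
    """

    target_residue: Optional[str] = "K"
    fixed_labelled_residues: frozenset = None  # type: ignore[assignment]
    label_mass_shift_per_carbon: float = C13_C12_MASS_SHIFT

    def __post_init__(self):
        if self.fixed_labelled_residues is None:
            fixed = frozenset(STANDARD_RESIDUES) - {self.target_residue}
            object.__setattr__(self, "fixed_labelled_residues", fixed)
        else:
            object.__setattr__(
                self, "fixed_labelled_residues", frozenset(self.fixed_labelled_residues)
            )
        if self.target_residue is not None and self.target_residue in self.fixed_labelled_residues:
            raise ValueError("target residue cannot also be fixed-labelled")
        if self.label_mass_shift_per_carbon <= 0:
            raise ValueError("label mass shift must be positive")

    def target_sites(self, sequence: str) -> tuple[int, ...]:
        """1-based positions of the target residue in ``sequence``."""
        if self.target_residue is None:
            return ()
        return tuple(i + 1 for i, r in enumerate(sequence) if r == self.target_residue)


def lysine_13c_scheme() -> LabelScheme:
    """The reference scheme: 13C glucose feed, variable 13C6-lysine."""
    return LabelScheme(target_residue="K")


#: Per-target-site labelling state, True = heavy (13C) at that site.
LabellingPattern = tuple[bool, ...]


def _check_pattern(sequence: str, pattern: Sequence[bool], scheme: LabelScheme) -> tuple[int, ...]:
    sites = scheme.target_sites(sequence)
    if len(pattern) != len(sites):
        raise PatternLengthError(
            f"pattern length {len(pattern)} != {len(sites)} target sites in {sequence!r}"
        )
    return sites


def species_mass(
    sequence: str,
    pattern: Sequence[bool],
    scheme: LabelScheme,
    as_free_amino_acid: bool = False,
) -> float:
    """Monoisotopic mass of a (possibly partially labelled) peptide or free amino acid.

    mass = unlabelled mass + shift * (carbons of fixed-labelled residues
    + carbons of pattern-true target sites).
    """
    _check_pattern(sequence, pattern, scheme)
    comp = peptide_composition(sequence, as_free_amino_acid=as_free_amino_acid)
    mass = comp.monoisotopic_mass
    shift = scheme.label_mass_shift_per_carbon
    for res in sequence:
        if res in scheme.fixed_labelled_residues:
            mass += residue_carbon_count(res) * shift
    if scheme.target_residue is not None:
        target_c = residue_carbon_count(scheme.target_residue)
        mass += target_c * shift * sum(bool(p) for p in pattern)
    return mass


def mz_from_mass(mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def nominal_mz(mz: float) -> int:
    """Round half away from zero; used only for MRM-style worked examples."""
    return int(floor(abs(mz) + 0.5) * copysign(1, mz))


@dataclass(frozen=True)
class LabelledSpecies:
    """An ionized peptide (or fragment) at a given charge and labelling pattern."""

    sequence: str
    charge: int
    pattern: LabellingPattern
    mass: float
    mz: float


def precursor_species(
    sequence: str, pattern: Sequence[bool], scheme: LabelScheme, charge: int
) -> LabelledSpecies:
    mass = species_mass(sequence, pattern, scheme)
    return LabelledSpecies(sequence, charge, tuple(bool(p) for p in pattern), mass, mz_from_mass(mass, charge))


def enumerate_states(sequence: str, scheme: LabelScheme) -> list[LabellingPattern]:
    """All 2**n labelling patterns of the peptide's n target sites.

    Deterministic lexicographic order over the boolean vector (light before
    heavy at each site).  A peptide with no target sites yields one empty
    pattern.
    """
    n = len(scheme.target_sites(sequence))
    return [tuple(bits) for bits in product((False, True), repeat=n)]


def fragment_sequence(sequence: str, ion_series: IonSeries, ordinal: int) -> str:
    """Subsequence of a y (C-terminal) or b (N-terminal) fragment, 1-based ordinal."""
    if not 1 <= ordinal <= len(sequence) - 1:
        raise FragmentOrdinalError(
            f"{ion_series}{ordinal} out of range for peptide of length {len(sequence)}"
        )
    if ion_series == "y":
        return sequence[len(sequence) - ordinal :]
    if ion_series == "b":
        return sequence[:ordinal]
    raise ValueError(f"unknown ion series {ion_series!r}")


def fragment_covered_sites(
    sequence: str, ion_series: IonSeries, ordinal: int, scheme: LabelScheme
) -> tuple[int, ...]:
    """Target-site positions (1-based in the peptide) covered by the fragment."""
    sites = scheme.target_sites(sequence)
    if ion_series == "y":
        lo = len(sequence) - ordinal + 1
        return tuple(s for s in sites if s >= lo)
    fragment_sequence(sequence, ion_series, ordinal)  # range check
    return tuple(s for s in sites if s <= ordinal)


def fragment_species(
    sequence: str,
    ion_series: IonSeries,
    ordinal: int,
    pattern: Sequence[bool],
    scheme: LabelScheme,
    charge: int = 1,
) -> LabelledSpecies:
    """Mass/m/z of a y or b fragment under the restriction of ``pattern``.

    Conventions (applied consistently throughout the package): the neutral y
    fragment is its residues plus water; the neutral b fragment is its
    residues alone (an acylium-type species once protonated); observed
    m/z = (neutral + z * proton) / z.
    """
    sites = _check_pattern(sequence, pattern, scheme)
    frag = fragment_sequence(sequence, ion_series, ordinal)
    covered = set(fragment_covered_sites(sequence, ion_series, ordinal, scheme))
    sub_pattern = tuple(bool(p) for s, p in zip(sites, pattern) if s in covered)

    comp = ElementalComposition(WATER) if ion_series == "y" else ElementalComposition()
    for res in frag:
        comp = comp + residue_composition(res)
    mass = comp.monoisotopic_mass
    shift = scheme.label_mass_shift_per_carbon
    for res in frag:
        if res in scheme.fixed_labelled_residues:
            mass += residue_carbon_count(res) * shift
    if scheme.target_residue is not None:
        mass += residue_carbon_count(scheme.target_residue) * shift * sum(sub_pattern)
    return LabelledSpecies(frag, charge, sub_pattern, mass, mz_from_mass(mass, charge))


def free_lysine_mrm(shift: float = C13_C12_MASS_SHIFT) -> dict[str, tuple[int, int]]:
    """Nominal MRM transitions (precursor -> product) for free lysine.

    The protonated precursor is the intact amino acid; the diagnostic product
    ion is the five-carbon C5H10N+ cation formed by loss of ammonia plus
    formic acid.  Full 13C labelling shifts the precursor by six carbons and
    the product by five, reproducing the classic 147->84 (light) and 153->89
    (heavy) transition pair.
    """
    scheme_unlabelled = LabelScheme(target_residue="K", fixed_labelled_residues=frozenset(),
                                    label_mass_shift_per_carbon=shift)
    product_comp = ElementalComposition({"C": 5, "H": 10, "N": 1})

    out = {}
    for name, heavy in (("light", False), ("heavy", True)):
        precursor_mass = species_mass("K", (heavy,), scheme_unlabelled, as_free_amino_acid=True)
        precursor = nominal_mz(mz_from_mass(precursor_mass, 1))
        product_mass = product_comp.monoisotopic_mass - ELECTRON_MASS
        if heavy:
            product_mass += product_comp["C"] * shift
        out[name] = (precursor, nominal_mz(product_mass))
    return out
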