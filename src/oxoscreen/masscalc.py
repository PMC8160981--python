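"""Theoretical mass engine for TMT-labeled (glyco)peptides.

Provides elemental and glycan compositions, monoisotopic masses of labeled
peptides, precursor m/z, backbone fragment ladders (b/y/c/z-dot), glycan
Y-ion ladders, and the reference table of the six HexNAc-derived diagnostic
oxonium ions used to recognize glycopeptide MS/MS spectra.

Conventions
-----------
* All masses are monoisotopic, in Da.
* Cation m/z of a protonated species: ``(neutral + z * PROTON_MASS) / z``.
* Even-electron cations derived from an elemental formula (the oxonium
  ions) have one electron mass subtracted.
* z ions follow the radical z-dot (z+1) convention produced by ETD/EThcD:
  ``neutral(z·_k) = neutral(y_k) - NH3 + H``.
* TMT labels sit on the peptide N-terminus and on every lysine;
  carbamidomethyl sits on every cysteine. Neither is ever placed on a
  glycan, and glycans attach only to Ser/Thr (O-linked).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER",
    "AMMONIA",
    "HYDROGEN_ATOM",
    "TMT10_TAG",
    "CARBAMIDOMETHYL",
    "GLYCAN_RESIDUE_MASSES",
    "ElementalComposition",
    "GlycanComposition",
    "GlycanParseError",
    "LabeledPeptide",
    "DiagnosticIon",
    "FragmentIon",
    "parse_glycan_composition",
    "glycan_mass",
    "peptide_neutral_mass",
    "precursor_mz",
    "oxonium_reference_table",
    "backbone_fragments",
    "glycan_y_ladder",
]

# ---------------------------------------------------------------------------
# Physical constants (CODATA / NIST monoisotopic values)
# ---------------------------------------------------------------------------

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054858

#: Monoisotopic atomic masses for the elements used here.
_ATOMIC_MASS: Dict[str, float] = {
    e: _pmass.nist_mass[e][0][0] for e in ("C", "H", "N", "O", "S")
}

HYDROGEN_ATOM = _ATOMIC_MASS["H"]
WATER = 2 * _ATOMIC_MASS["H"] + _ATOMIC_MASS["O"]
AMMONIA = 3 * _ATOMIC_MASS["H"] + _ATOMIC_MASS["N"]

#: TMT10/TMT6 isobaric tag, amine-reactive (N-terminus and Lys side chain).
TMT10_TAG = 229.162932
#: Carbamidomethylation of cysteine (iodoacetamide alkylation).
CARBAMIDOMETHYL = 57.021464

#: Monoisotopic residue (dehydrated) masses of glycan building blocks.
GLYCAN_RESIDUE_MASSES: Dict[str, float] = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
}

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Monoisotopic residue masses of the 20 standard amino acids.
AMINO_ACID_MASSES: Dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in _STANDARD_RESIDUES
}


# ---------------------------------------------------------------------------
# Elemental composition
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Counts of C/H/N/O/S atoms; supports addition, subtraction and mass."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "S"):
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"element count {el}={n!r} must be a non-negative integer")

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``"C2H6O3"`` (CHNOS only)."""
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"malformed formula {formula!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            if el not in _ATOMIC_MASS:
                raise ValueError(f"unsupported element {el!r} in {formula!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValueError(f"malformed formula {formula!r}")
        return cls(**counts)

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return sum(getattr(self, el) * m for el, m in _ATOMIC_MASS.items())

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ATOMIC_MASS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) - getattr(other, el) for el in _ATOMIC_MASS}
        )


# ---------------------------------------------------------------------------
# Glycan composition
# ---------------------------------------------------------------------------


class GlycanParseError(ValueError):
    """Raised when a glycan composition string cannot be interpreted."""


@dataclass(frozen=True)
class GlycanComposition:
    """Topology-free monosaccharide counts (HexNAc / Hex / Fuc / NeuAc)."""

    hexnac: int = 0
    hexose: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hexose", "fuc", "neuac"):
            n = getattr(self, name)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {n!r}")

    # field name -> residue-mass key
    _KEYS = (("hexnac", "HexNAc"), ("hexose", "Hex"), ("fuc", "Fuc"), ("neuac", "NeuAc"))

    @property
    def mass(self) -> float:
        """Total glycan residue mass (additive in counts; empty -> 0)."""
        return sum(
            getattr(self, f) * GLYCAN_RESIDUE_MASSES[k] for f, k in self._KEYS
        )

    @property
    def total_residues(self) -> int:
        return self.hexnac + self.hexose + self.fuc + self.neuac

    def __bool__(self) -> bool:
        return self.total_residues > 0

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hexose + other.hexose,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
        )

    def __le__(self, other: "GlycanComposition") -> bool:
        return all(getattr(self, f) <= getattr(other, f) for f, _ in self._KEYS)

    def to_string(self) -> str:
        """Long-form composition string, e.g. ``"HexNAc(3)Hex(1)Fuc(1)NeuAc(1)"``."""
        parts = [f"{k}({getattr(self, f)})" for f, k in self._KEYS if getattr(self, f)]
        return "".join(parts)

    def subsets(self) -> Iterator["GlycanComposition"]:
        """All compositional sub-multisets, including empty and full."""
        for n, h, f, s in itertools.product(
            range(self.hexnac + 1),
            range(self.hexose + 1),
            range(self.fuc + 1),
            range(self.neuac + 1),
        ):
            yield GlycanComposition(n, h, f, s)


_COMPACT_CODES = {"N": "hexnac", "H": "hexose", "F": "fuc", "S": "neuac"}
_LONG_CODES = {"HexNAc": "hexnac", "Hex": "hexose", "Fuc": "fuc", "dHex": "fuc", "NeuAc": "neuac"}
_COMPACT_RE = re.compile(r"([A-Za-z])(\d+)")
_LONG_RE = re.compile(r"(HexNAc|Hex|Fuc|dHex|NeuAc)\((\d+)\)")


def parse_glycan_composition(text: str) -> GlycanComposition:
    """Parse a glycan composition string.

    Two syntaxes are accepted:

    * compact letter codes, one letter per monosaccharide followed by its
      count, in any order and case-insensitive: ``"N1"``, ``"H1N3F1S1"``
      (N = HexNAc, H = hexose, F = fucose, S = NeuAc / sialic acid);
    * long form with parenthesized counts, e.g. ``"HexNAc(1)Hex(1)NeuAc(2)"``
      (absent monosaccharides omitted; ``dHex`` is accepted for fucose).

    The empty string parses to the empty composition.
    """
    text = text.strip()
    if not text:
        return GlycanComposition()
    counts = {"hexnac": 0, "hexose": 0, "fuc": 0, "neuac": 0}
    if "(" in text or ")" in text:
        matcher, codes = _LONG_RE, _LONG_CODES
    else:
        matcher, codes = _COMPACT_RE, _COMPACT_CODES
    pos = 0
    for m in matcher.finditer(text):
        if m.start() != pos:
            raise GlycanParseError(f"cannot parse glycan composition {text!r}")
        pos = m.end()
        code, num = m.group(1), int(m.group(2))
        if matcher is _COMPACT_RE:
            code = code.upper()
        if code not in codes:
            raise GlycanParseError(f"unknown monosaccharide code {code!r} in {text!r}")
        counts[codes[code]] += num
    if pos != len(text):
        raise GlycanParseError(f"cannot parse glycan composition {text!r}")
    return GlycanComposition(**counts)


def glycan_mass(glycan: GlycanComposition) -> float:
    """Monoisotopic residue mass of a glycan composition in Da."""
    return glycan.mass


# ---------------------------------------------------------------------------
# Labeled peptides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide with fixed TMT / carbamidomethyl rules and O-glycans.

    Parameters
    ----------
    sequence:
        Amino-acid sequence over the 20 standard residues.
    glycans:
        Mapping from zero-based residue index to the attached
        :class:`GlycanComposition`. O-glycan attachment sites must be
        serine or threonine.
    tmt:
        Apply the TMT10 tag (+229.162932 Da) to the N-terminus and to
        every lysine. The number of labels is therefore ``Lys count + 1``.
    carbamidomethyl:
        Apply carbamidomethylation (+57.021464 Da) to every cysteine.
    """

    sequence: str
    glycans: Mapping[int, GlycanComposition] = field(default_factory=dict)
    tmt: bool = True
    carbamidomethyl: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for aa in self.sequence:
            if aa not in AMINO_ACID_MASSES:
                raise ValueError(f"unknown residue {aa!r} in sequence {self.sequence!r}")
        for idx, glycan in self.glycans.items():
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"glycan index {idx} outside peptide of length {len(self.sequence)}")
            if self.sequence[idx] not in "ST":
                raise ValueError(
                    f"O-glycan attachment at index {idx} ({self.sequence[idx]!r}) "
                    "must be Ser or Thr"
                )
            if not isinstance(glycan, GlycanComposition):
                raise TypeError("glycan attachments must be GlycanComposition instances")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_tmt(self) -> int:
        return (1 + self.sequence.count("K")) if self.tmt else 0

    @property
    def total_glycan(self) -> GlycanComposition:
        total = GlycanComposition()
        for g in self.glycans.values():
            total = total + g
        return total

    def deglycosylated(self) -> "LabeledPeptide":
        return LabeledPeptide(self.sequence, {}, self.tmt, self.carbamidomethyl)

    def with_glycan(self, index: int, glycan: GlycanComposition) -> "LabeledPeptide":
        new = dict(self.glycans)
        new[index] = glycan
        return LabeledPeptide(self.sequence, new, self.tmt, self.carbamidomethyl)

    # per-residue modified mass (side-chain mods only; N-terminal TMT excluded)
    def _residue_mass(self, idx: int) -> float:
        aa = self.sequence[idx]
        m = AMINO_ACID_MASSES[aa]
        if self.tmt and aa == "K":
            m += TMT10_TAG
        if self.carbamidomethyl and aa == "C":
            m += CARBAMIDOMETHYL
        if idx in self.glycans:
            m += self.glycans[idx].mass
        return m


def peptide_neutral_mass(peptide: LabeledPeptide) -> float:
    """Neutral monoisotopic mass including water, fixed mods and glycans."""
    m = sum(peptide._residue_mass(i) for i in range(len(peptide))) + WATER
    if peptide.tmt:
        m += TMT10_TAG  # N-terminal label
    return m


def precursor_mz(peptide: LabeledPeptide, charge: int) -> float:
    """m/z of the ``[M + zH]^z+`` precursor ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (peptide_neutral_mass(peptide) + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# Diagnostic oxonium ions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticIon:
    """One HexNAc-derived diagnostic oxonium ion.

    ``mz`` is the theoretical m/z of the singly charged even-electron
    cation (elemental mass minus one electron); ``nominal_mz`` is the
    3-decimal value conventionally quoted for it.
    """

    label: str
    loss: ElementalComposition
    nominal_mz: float
    mz: float


#: Elemental composition of the [HexNAc]+ oxonium cation (protonated,
#: dehydrated N-acetylhexosamine): C8H14NO5.
_HEXNAC_OXONIUM = ElementalComposition(C=8, H=14, N=1, O=5)

_OXONIUM_DEFS: Sequence[Tuple[str, str, float]] = (
    ("HexNAc-C2H6O3", "C2H6O3", 126.055),
    ("HexNAc-CH6O3", "CH6O3", 138.055),
    ("HexNAc-C2H4O2", "C2H4O2", 144.066),
    ("HexNAc-2H2O", "H4O2", 168.066),
    ("HexNAc-H2O", "H2O", 186.076),
    ("HexNAc", "", 204.087),
)


def oxonium_reference_table() -> List[DiagnosticIon]:
    """The six diagnostic HexNAc oxonium ions, ascending in m/z.

    Each theoretical m/z is derived from the elemental composition of the
    [HexNAc]+ cation minus the indicated neutral loss, with one electron
    mass subtracted, and lands within 0.002 of the nominal quoted value.
    """
    ions = []
    for label, loss_formula, nominal in _OXONIUM_DEFS:
        loss = ElementalComposition.from_formula(loss_formula)
        mz = (_HEXNAC_OXONIUM - loss).mass - ELECTRON_MASS
        ions.append(DiagnosticIon(label=label, loss=loss, nominal_mz=nominal, mz=mz))
    return ions


# ---------------------------------------------------------------------------
# Fragment ions
# ---------------------------------------------------------------------------

BACKBONE_SERIES = ("b", "y", "c", "z")


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical fragment ion.

    ``series`` is one of b/y/c/z for backbone ions (z means the z-dot
    radical) or ``"Y"`` for glycan Y ions; ``ordinal`` is the cleavage
    index for backbone ions and the retained-glycan descriptor string for
    Y ions; ``glycan`` is the glycan composition retained by the fragment.
    """

    series: str
    ordinal: object
    charge: int
    mz: float
    neutral_mass: float
    glycan: GlycanComposition = GlycanComposition()


def _ion_mz(neutral: float, charge: int) -> float:
    return (neutral + charge * PROTON_MASS) / charge


def backbone_fragments(
    peptide: LabeledPeptide,
    series: Iterable[str] = BACKBONE_SERIES,
    max_charge: int = 1,
) -> List[FragmentIon]:
    """Complete b/y/c/z-dot ladders for charges 1..max_charge.

    Fragments inherit the fixed modifications and the full glycan of every
    residue they span (glycans are treated as staying intact on backbone
    fragments, as observed in EThcD spectra of O-glycopeptides).
    """
    series = tuple(series)
    for s in series:
        if s not in BACKBONE_SERIES:
            raise ValueError(f"unknown ion series {s!r}; expected subset of {BACKBONE_SERIES}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    n = len(peptide)
    residue = [peptide._residue_mass(i) for i in range(n)]
    nterm_mod = TMT10_TAG if peptide.tmt else 0.0

    fragments: List[FragmentIon] = []
    prefix_mass = nterm_mod
    prefix_glycan = GlycanComposition()
    # cumulative sums per cleavage index i = 1..n-1
    prefixes = []
    for i in range(1, n):
        prefix_mass += residue[i - 1]
        if (i - 1) in peptide.glycans:
            prefix_glycan = prefix_glycan + peptide.glycans[i - 1]
        prefixes.append((i, prefix_mass, prefix_glycan))

    total_mass = prefix_mass + residue[n - 1] + WATER
    total_glycan = peptide.total_glycan

    for i, pmass_, pglyc in prefixes:
        k = n - i  # ordinal of the complementary C-terminal ion
        suffix_neutral_y = total_mass - pmass_  # includes water
        sglyc = GlycanComposition(
            total_glycan.hexnac - pglyc.hexnac,
            total_glycan.hexose - pglyc.hexose,
            total_glycan.fuc - pglyc.fuc,
            total_glycan.neuac - pglyc.neuac,
        )
        neutral = {
            "b": (i, pmass_, pglyc),
            "c": (i, pmass_ + AMMONIA, pglyc),
            "y": (k, suffix_neutral_y, sglyc),
            "z": (k, suffix_neutral_y - AMMONIA + HYDROGEN_ATOM, sglyc),
        }
        for s in series:
            ordinal, neut, glyc = neutral[s]
            for z in range(1, max_charge + 1):
                fragments.append(
                    FragmentIon(
                        series=s,
                        ordinal=ordinal,
                        charge=z,
                        mz=_ion_mz(neut, z),
                        neutral_mass=neut,
                        glycan=glyc,
                    )
                )
    return fragments


def glycan_y_ladder(
    peptide: LabeledPeptide, charges: Iterable[int] = (1, 2, 3)
) -> List[FragmentIon]:
    """Topology-free glycan Y-ion ladder: peptide + every glycan subset.

    Enumerates all compositional sub-multisets of the attached glycan
    (every count vector less than or equal to the full composition) and
    returns the corresponding ``peptide + subset`` ions at each requested
    charge, deduplicated by (neutral mass, charge). The empty subset is the
    bare labeled peptide (Y0).
    """
    if not peptide.glycans:
        raise ValueError("peptide carries no glycan; Y ladder undefined")
    charges = sorted(set(int(z) for z in charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be >= 1")
    bare = peptide_neutral_mass(peptide.deglycosylated())
    out: List[FragmentIon] = []
    seen = set()
    for subset in peptide.total_glycan.subsets():
        neutral = bare + subset.mass
        for z in charges:
            key = (round(neutral, 6), z)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                FragmentIon(
                    series="Y",
                    ordinal=subset.to_string() or "peptide",
                    charge=z,
                    mz=_ion_mz(neutral, z),
                    neutral_mass=neutral,
                    glycan=subset,
                )
            )
    out.sort(key=lambda f: (f.glycan.total_residues, f.mz))
    return out
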