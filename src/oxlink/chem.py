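"""Mass arithmetic for peptides, modifications, cross-links and ¹⁸O labels.

All masses are neutral monoisotopic masses in daltons unless a function
says otherwise. Residue masses come from the standard monoisotopic amino
acid table (pyteomics); a peptide's neutral mass is the sum of its residue
masses plus one water, plus any modification deltas, plus the ¹⁸O label
shift at its C-terminus.

A radical Tyr–Tyr, Trp–Trp or Tyr–Trp side-chain cross-link joins two
peptides with the net loss of two hydrogen atoms, so the mass of the
cross-linked species is the sum of the two parent peptide masses minus
2.015650 Da. Digestion in heavy-oxygen water incorporates two ¹⁸O atoms at
each newly formed C-terminus; a linear peptide therefore shifts by about
+4.008 Da and a cross-linked pair (two new termini) by about +8.017 Da
relative to its light-water counterpart.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

# --- constants ---------------------------------------------------------------

#: Monoisotopic residue masses (Da), standard 20 amino acids.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

WATER: float = 18.0105646837
PROTON: float = 1.00727646688
HYDROGEN: float = 1.00782503207
#: Mass excess of one ¹⁸O over one ¹⁶O atom.
O18_MINUS_O16: float = 2.004246
#: Net mass change of a direct side-chain cross-link: loss of two H atoms.
CROSSLINK_DELTA: float = -2.015650


@dataclass(frozen=True)
class Modification:
    """A residue-level mass modification.

    ``fixed`` modifications apply to every target residue of a peptide;
    ``variable`` ones are enumerated combinatorially up to
    ``max_per_peptide`` occurrences.
    """

    name: str
    targets: frozenset[str]
    delta: float
    kind: str = "variable"  # "fixed" | "variable"
    max_per_peptide: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ValueError(f"modification kind must be fixed|variable, got {self.kind!r}")
        object.__setattr__(self, "targets", frozenset(self.targets))

    @classmethod
    def from_dict(cls, d: Mapping) -> "Modification":
        return cls(
            name=d["name"],
            targets=frozenset(d["targets"]),
            delta=float(d["delta"]),
            kind=d.get("kind", "variable"),
            max_per_peptide=int(d.get("max_per_peptide", 3)),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "targets": sorted(self.targets),
            "delta": self.delta,
            "kind": self.kind,
            "max_per_peptide": self.max_per_peptide,
        }


# Standard modifications for oxidant-footprinting searches.
CARBAMIDOMETHYL = Modification("carbamidomethyl", frozenset("C"), 57.021464, kind="fixed")
NITRATION = Modification("nitration", frozenset("YW"), 44.985078)
MET_OXIDATION = Modification("met_oxidation", frozenset("M"), 15.994915)
CHLORINATION = Modification("chlorination", frozenset("Y"), 33.961028)

STANDARD_MODIFICATIONS: dict[str, Modification] = {
    m.name: m for m in (CARBAMIDOMETHYL, NITRATION, MET_OXIDATION, CHLORINATION)
}


@dataclass(frozen=True)
class Peptide:
    """A located subsequence of a mature protein chain.

    ``start``/``end`` are 1-based inclusive residue numbers on the mature
    chain; ``mods`` holds ``(position_in_peptide, Modification)`` pairs with
    1-based in-peptide positions; ``label`` is the number of ¹⁸O atoms at
    the C-terminus (0, 1 or 2).
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    mods: tuple[tuple[int, Modification], ...] = ()
    label: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with sequence length {len(self.sequence)}"
            )
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0, 1 or 2 ¹⁸O atoms, got {self.label}")
        for pos, mod in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"mod position {pos} outside peptide 1..{len(self.sequence)}")
            if self.sequence[pos - 1] not in mod.targets:
                raise ValueError(
                    f"modification {mod.name} targets {sorted(mod.targets)} but residue at "
                    f"position {pos} is {self.sequence[pos - 1]}"
                )
        object.__setattr__(self, "mods", tuple(sorted(self.mods, key=lambda pm: (pm[0], pm[1].name))))

    # -- residue bookkeeping --

    def covers(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end

    def residue_number(self, pos_in_peptide: int) -> int:
        """Mature-chain residue number of a 1-based in-peptide position."""
        return self.start + pos_in_peptide - 1

    def modifications_at(self, residue_number: int) -> tuple[Modification, ...]:
        pos = residue_number - self.start + 1
        return tuple(m for p, m in self.mods if p == pos)

    def with_label(self, label: int) -> "Peptide":
        return replace(self, label=label)

    def form_key(self) -> tuple:
        """Hashable identity of this peptide form (ignoring label state)."""
        return (
            self.protein_id,
            self.start,
            self.end,
            self.sequence,
            tuple((p, m.name) for p, m in self.mods),
        )


@dataclass(frozen=True)
class CrosslinkedPair:
    """Two peptides joined through one Tyr/Trp side chain each, −2 H.

    ``link_alpha_pos``/``link_beta_pos`` are 1-based in-peptide positions of
    the linked residues; ``link_type`` is YY, WW or YW.
    """

    alpha: Peptide
    beta: Peptide
    link_alpha_pos: int
    link_beta_pos: int
    link_type: str
    link_delta: float = CROSSLINK_DELTA

    def __post_init__(self) -> None:
        if self.link_type not in ("YY", "WW", "YW"):
            raise ValueError(f"link_type must be YY|WW|YW, got {self.link_type!r}")
        ra = self.alpha.sequence[self.link_alpha_pos - 1]
        rb = self.beta.sequence[self.link_beta_pos - 1]
        expected = {"YY": {("Y", "Y")}, "WW": {("W", "W")}, "YW": {("Y", "W"), ("W", "Y")}}
        if (ra, rb) not in expected[self.link_type]:
            raise ValueError(
                f"linked residues {ra}{self.link_alpha_pos}/{rb}{self.link_beta_pos} "
                f"inconsistent with link type {self.link_type}"
            )

    @property
    def link_alpha_residue_number(self) -> int:
        return self.alpha.residue_number(self.link_alpha_pos)

    @property
    def link_beta_residue_number(self) -> int:
        return self.beta.residue_number(self.link_beta_pos)

    @property
    def decoy(self) -> bool:
        return self.alpha.protein_id.startswith("DECOY_") or self.beta.protein_id.startswith(
            "DECOY_"
        )

    def site_key(self) -> tuple:
        """Unordered identity of the linked residue pair."""
        a = (self.alpha.protein_id, self.link_alpha_residue_number)
        b = (self.beta.protein_id, self.link_beta_residue_number)
        return tuple(sorted((a, b)))

    def form_key(self) -> tuple:
        return tuple(
            sorted(
                (
                    (self.alpha.form_key(), self.link_alpha_pos),
                    (self.beta.form_key(), self.link_beta_pos),
                )
            )
        )


# --- mass arithmetic ---------------------------------------------------------


def peptide_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass of a peptide form, including mods and label."""
    total = WATER
    for i, letter in enumerate(p.sequence):
        try:
            total += MONOISOTOPIC_RESIDUE_MASS[letter]
        except KeyError:
            raise ValueError(
                f"unknown residue letter {letter!r} at position {i + 1} of {p.sequence}"
            ) from None
        # one C-terminus per linear peptide
    total += sum(mod.delta for _, mod in p.mods)
    total += p.label * O18_MINUS_O16
    return total


def sequence_mass(sequence: str, mods: Iterable[float] = ()) -> float:
    """Neutral mass of a bare sequence plus optional modification deltas."""
    p = Peptide("_", 1, len(sequence), sequence)
    return peptide_mass(p) + sum(mods)


def mz_from_mass(mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass from observed m/z and charge; inverse of :func:`mz_from_mass`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return mz * z - z * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    return 1e6 * (observed - theoretical) / theoretical


def crosslink_mass(pair: CrosslinkedPair) -> float:
    """Neutral mass of a cross-linked pair: sum of parents plus link delta."""
    return peptide_mass(pair.alpha) + peptide_mass(pair.beta) + pair.link_delta


def label_shift(n_new_c_termini: int, o18_per_terminus: int) -> float:
    """Mass shift of the heavy channel for a given ¹⁸O incorporation state.

    A linear tryptic peptide has one new C-terminus; a cross-linked pair has
    two. Full incorporation is two ¹⁸O per terminus.
    """
    if n_new_c_termini not in (1, 2):
        raise ValueError(f"n_new_c_termini must be 1 or 2, got {n_new_c_termini}")
    if o18_per_terminus not in (0, 1, 2):
        raise ValueError(f"o18_per_terminus must be 0, 1 or 2, got {o18_per_terminus}")
    return n_new_c_termini * o18_per_terminus * O18_MINUS_O16
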