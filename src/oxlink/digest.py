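"""In-silico tryptic digestion with bounded missed cleavages.

Trypsin cleaves C-terminal to Lys/Arg except when the next residue is Pro.
``digest`` produces fully specific peptides (both termini tryptic or a chain
end) or semispecific peptides (exactly one tryptic terminus required), with
length bounds and a missed-cleavage cap, and can expand each peptide into
its fixed/variable modification forms.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

from .chem import Modification, Peptide


@dataclass(frozen=True)
class DigestSpec:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    specificity: str = "full"  # "full" | "semi"
    min_length: int = 6
    max_length: int = 45

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError("only trypsin is supported")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.specificity not in ("full", "semi"):
            raise ValueError("specificity must be full|semi")


def cleavage_sites(sequence: str) -> list[int]:
    """1-based positions after which trypsin cuts; the C-terminus is always last.

    A cut "after position i" separates residues i and i+1. K/R followed by P
    is suppressed.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    sites = [
        i + 1
        for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    sites.append(n)
    return sites


def digest(sequence: str, spec: DigestSpec, protein_id: str = "protein") -> list[Peptide]:
    """Enumerate tryptic peptides of a mature chain under ``spec``.

    Fully specific peptides are unions of 1..max_missed+1 consecutive
    zero-missed-cleavage fragments; semispecific peptides additionally keep
    exactly one tryptic terminus (the other trimmed anywhere). Chain ends
    count as tryptic termini. ``missed_cleavages`` records the number of
    internal uncut K/R sites.
    """
    sites = cleavage_sites(sequence)
    # zero-missed-cleavage fragment boundaries as (start, end), 1-based inclusive
    starts = [1] + [s + 1 for s in sites[:-1]]
    ends = sites
    n_frag = len(starts)
    internal = set(sites[:-1])

    spans: dict[tuple[int, int], int] = {}
    for i in range(n_frag):
        for j in range(i, min(i + spec.max_missed_cleavages + 1, n_frag)):
            spans[(starts[i], ends[j])] = j - i
    if spec.specificity == "semi":
        for (s, e), _ in list(spans.items()):
            # keep tryptic N-terminus, trim the C side; and vice versa
            for e2 in range(s, e):
                spans.setdefault((s, e2), _count_internal(internal, s, e2))
            for s2 in range(s + 1, e + 1):
                spans.setdefault((s2, e), _count_internal(internal, s2, e))
        # drop semi spans that exceed the missed-cleavage cap
        spans = {k: v for k, v in spans.items() if v <= spec.max_missed_cleavages}

    peptides = [
        Peptide(protein_id, s, e, sequence[s - 1 : e], missed_cleavages=mc)
        for (s, e), mc in sorted(spans.items())
        if spec.min_length <= e - s + 1 <= spec.max_length
    ]
    return peptides


def _count_internal(internal_sites: set[int], start: int, end: int) -> int:
    return sum(1 for s in internal_sites if start <= s < end)


def modified_forms(
    peptide: Peptide,
    modifications: list[Modification],
    max_variable: int = 3,
) -> list[Peptide]:
    """Expand a bare peptide into its modification forms.

    Fixed modifications are applied at every target residue of every form.
    Variable modifications are enumerated combinatorially: every subset of
    eligible (position, modification) assignments with at most one
    modification per residue, at most ``mod.max_per_peptide`` per
    modification, and at most ``max_variable`` variable mods in total.
    The unmodified (fixed-only) form is always included first.
    """
    fixed = [(i + 1, m) for m in modifications if m.kind == "fixed"
             for i, r in enumerate(peptide.sequence) if r in m.targets]
    var_slots = [(i + 1, m) for m in modifications if m.kind == "variable"
                 for i, r in enumerate(peptide.sequence) if r in m.targets]

    forms: list[Peptide] = []
    for k in range(0, min(max_variable, len(var_slots)) + 1):
        for combo in combinations(var_slots, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            per_mod: dict[str, int] = {}
            ok = True
            for _, m in combo:
                per_mod[m.name] = per_mod.get(m.name, 0) + 1
                if per_mod[m.name] > m.max_per_peptide:
                    ok = False
                    break
            if not ok:
                continue
            forms.append(replace(peptide, mods=tuple(fixed) + tuple(combo)))
    return forms
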