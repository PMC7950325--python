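"""Candidate enumeration, precursor/fragment matching and scoring for
Tyr–Tyr, Trp–Trp and Tyr–Trp cross-linked peptides.

Candidates are all unordered peptide pairs in which each chain carries at
least one residue of the required type, one candidate per eligible residue
combination. Precursors are matched in ppm space on neutral mass. Fragment
ladders are standard b/y (optionally c/z); any fragment that still contains
the linked residue carries the full mass of the partner peptide plus the
−2 H link delta. The match score is a weighted fraction of theoretical
fragments found in the spectrum, with link-retaining fragments counted
double, scaled to 0–100.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem import (
    CROSSLINK_DELTA,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON,
    WATER,
    CrosslinkedPair,
    Peptide,
    crosslink_mass,
    mass_from_mz,
    mz_from_mass,
    peptide_mass,
    ppm_error,
)

NH3 = 17.02654910112
# z+1 (z-dot) ions: y minus NH3 plus one hydrogen
ZDOT_OFFSET = -NH3 + 1.00782503207


@dataclass(frozen=True)
class Ms2Spectrum:
    """A fragment spectrum with its precursor description."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), sorted by m/z
    method_tag: str = "HCD"
    precursor_intensity: float = 0.0
    replicate: str = ""
    sample: str = ""
    fraction: str = ""

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("peak intensities must be >= 0")
        object.__setattr__(self, "peaks", pk)


@dataclass(frozen=True)
class FragmentIon:
    name: str  # e.g. "alpha.b3+1"
    chain: str  # "alpha" | "beta"
    series: str  # b | y | c | z
    index: int
    charge: int
    mz: float
    retains_link: bool


@dataclass(frozen=True)
class XlMatch:
    pair: CrosslinkedPair
    observed_mass: float
    ppm_error: float
    matched_fragments: tuple[str, ...] = ()
    score: float = 0.0
    decoy: bool = False
    spectrum_id: str = ""
    precursor_intensity: float = 0.0
    replicate: str = ""
    fraction: str = ""


# --- candidate enumeration ---------------------------------------------------

_LINK_RESIDUES = {"YY": ("Y", "Y"), "WW": ("W", "W"), "YW": ("Y", "W")}


def enumerate_candidates(
    peptides: Sequence[Peptide],
    link_rules: Sequence[str] = ("YY", "WW", "YW"),
    peptide_mass_cap: float = 6000.0,
    pair_mass_cap: float = 8000.0,
) -> list[CrosslinkedPair]:
    """All deduplicated cross-link candidates over a peptide set.

    One candidate is produced per unordered pair of peptide forms per
    eligible linked-residue combination. The longer chain is designated
    alpha. Residues already carrying a modification are not offered as link
    sites.
    """
    for rule in link_rules:
        if rule not in _LINK_RESIDUES:
            raise ValueError(f"unknown link rule {rule!r}")
    peps = [p for p in peptides if peptide_mass(p) <= peptide_mass_cap]
    masses = [peptide_mass(p) for p in peps]
    seen: set = set()
    out: list[CrosslinkedPair] = []
    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):  # a peptide is not paired with itself
            if masses[i] + masses[j] + CROSSLINK_DELTA > pair_mass_cap:
                continue
            for rule in link_rules:
                ra, rb = _LINK_RESIDUES[rule]
                for pa, pb, la, lb in _residue_combinations(peps[i], peps[j], ra, rb):
                    alpha, beta, lalpha, lbeta = _orient(pa, pb, la, lb)
                    cand = CrosslinkedPair(alpha, beta, lalpha, lbeta, rule)
                    key = (rule, cand.form_key())
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(cand)
    return out


def _link_positions(p: Peptide, residue: str) -> list[int]:
    modded = {pos for pos, _ in p.mods}
    return [i + 1 for i, r in enumerate(p.sequence) if r == residue and i + 1 not in modded]


def _residue_combinations(pa: Peptide, pb: Peptide, ra: str, rb: str):
    for la in _link_positions(pa, ra):
        for lb in _link_positions(pb, rb):
            if pa is pb and la == lb:
                continue
            yield pa, pb, la, lb
    if ra != rb:  # YW: also the swapped assignment
        for la in _link_positions(pa, rb):
            for lb in _link_positions(pb, ra):
                if pa is pb and la == lb:
                    continue
                yield pb, pa, lb, la


def _orient(pa: Peptide, pb: Peptide, la: int, lb: int):
    """Longer chain is alpha; ties broken lexicographically for determinism."""
    ka = (len(pa.sequence), pa.sequence, la)
    kb = (len(pb.sequence), pb.sequence, lb)
    if ka >= kb:
        return pa, pb, la, lb
    return pb, pa, lb, la


# --- precursor matching ------------------------------------------------------


def match_precursor(
    observed: tuple[float, int],
    candidates: Sequence[CrosslinkedPair],
    tol_ppm: float = 10.0,
) -> list[XlMatch]:
    """Candidates whose theoretical mass lies within ``tol_ppm`` of the
    observed precursor, sorted by absolute ppm error."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mz, z = observed
    obs_mass = mass_from_mz(mz, z)
    hits = []
    for cand in candidates:
        theo = crosslink_mass(cand)
        err = ppm_error(obs_mass, theo)
        if abs(err) <= tol_ppm:
            hits.append(XlMatch(cand, obs_mass, err, decoy=cand.decoy))
    hits.sort(key=lambda m: abs(m.ppm_error))
    return hits


# --- fragment ions -----------------------------------------------------------


def fragment_ions(
    pair: CrosslinkedPair,
    series: Sequence[str] = ("b", "y"),
    max_fragment_charge: int = 2,
) -> list[FragmentIon]:
    """Theoretical fragment ladder of both chains of a cross-linked pair.

    Fragments are indexed 1..n−1 per chain. N-terminal series (b, c) retain
    the link when the fragment reaches the linked position; C-terminal
    series (y, z) when it extends back to it. Link-retaining fragments gain
    the partner peptide's full mass plus the link delta; C-terminal
    fragments inherit the chain's ¹⁸O label shift.
    """
    for s in series:
        if s not in "bycz":
            raise ValueError(f"unsupported ion series {s!r}")
    ions: list[FragmentIon] = []
    chains = (
        ("alpha", pair.alpha, pair.beta, pair.link_alpha_pos),
        ("beta", pair.beta, pair.alpha, pair.link_beta_pos),
    )
    for chain_name, pep, partner, link_pos in chains:
        n = len(pep.sequence)
        partner_addition = peptide_mass(partner) + pair.link_delta
        res = [MONOISOTOPIC_RESIDUE_MASS[r] for r in pep.sequence]
        mod_at = {pos: 0.0 for pos in range(1, n + 1)}
        for pos, mod in pep.mods:
            mod_at[pos] += mod.delta
        prefix = np.cumsum([res[i] + mod_at[i + 1] for i in range(n)])
        for i in range(1, n):
            b_neutral = prefix[i - 1]
            y_neutral = prefix[-1] - prefix[i - 1] + WATER + _label_mass(pep)
            b_retains = link_pos <= i
            y_retains = link_pos > i
            for s in series:
                if s in ("b", "c"):
                    neutral = b_neutral + (NH3 if s == "c" else 0.0)
                    retains = b_retains
                elif s in ("y", "z"):
                    neutral = y_neutral + (ZDOT_OFFSET if s == "z" else 0.0)
                    retains = y_retains
                if retains:
                    neutral += partner_addition
                idx = i if s in ("b", "c") else n - i  # y/z count from the C-terminus
                for z in range(1, max_fragment_charge + 1):
                    ions.append(
                        FragmentIon(
                            name=f"{chain_name}.{s}{idx}+{z}",
                            chain=chain_name,
                            series=s,
                            index=idx,
                            charge=z,
                            mz=mz_from_mass(neutral, z),
                            retains_link=retains,
                        )
                    )
    return ions


def _label_mass(p: Peptide) -> float:
    from .chem import O18_MINUS_O16

    return p.label * O18_MINUS_O16


def linear_fragment_ions(
    peptide: Peptide, series: Sequence[str] = ("b", "y"), max_fragment_charge: int = 1
) -> list[tuple[str, float]]:
    """b/y (or c/z) ladder of a single linear peptide as (name, m/z) pairs."""
    # reuse the pair machinery with a phantom partner of zero contribution
    n = len(peptide.sequence)
    res = [MONOISOTOPIC_RESIDUE_MASS[r] for r in peptide.sequence]
    mod_at = {pos: 0.0 for pos in range(1, n + 1)}
    for pos, mod in peptide.mods:
        mod_at[pos] += mod.delta
    prefix = np.cumsum([res[i] + mod_at[i + 1] for i in range(n)])
    out = []
    for i in range(1, n):
        b = prefix[i - 1]
        y = prefix[-1] - prefix[i - 1] + WATER + _label_mass(peptide)
        for s in series:
            if s == "b":
                neutral = b
            elif s == "c":
                neutral = b + NH3
            elif s == "y":
                neutral = y
            elif s == "z":
                neutral = y + ZDOT_OFFSET
            else:
                raise ValueError(f"unsupported ion series {s!r}")
            idx = i if s in ("b", "c") else n - i
            for z in range(1, max_fragment_charge + 1):
                out.append((f"{s}{idx}+{z}", mz_from_mass(neutral, z)))
    return out


# --- scoring -----------------------------------------------------------------


def score_match(
    spectrum: Ms2Spectrum,
    fragments: Sequence[FragmentIon],
    ms2_tol: float = 0.02,
) -> tuple[float, tuple[str, ...]]:
    """Weighted fragment-coverage score on a 0–100 scale.

    Each theoretical fragment matched by any peak within ``ms2_tol`` m/z
    contributes its weight (2 if it retains the cross-link, else 1); the
    score is 100 × matched weight / total weight. Deterministic and
    invariant to uniform intensity scaling.
    """
    if not fragments:
        return 0.0, ()
    if not spectrum.peaks:
        return 0.0, ()
    peak_mz = np.array([m for m, _ in spectrum.peaks])
    matched: list[str] = []
    got = 0.0
    total = 0.0
    for frag in fragments:
        w = 2.0 if frag.retains_link else 1.0
        total += w
        idx = np.searchsorted(peak_mz, frag.mz)
        near = []
        if idx < len(peak_mz):
            near.append(abs(peak_mz[idx] - frag.mz))
        if idx > 0:
            near.append(abs(peak_mz[idx - 1] - frag.mz))
        if near and min(near) <= ms2_tol:
            got += w
            matched.append(frag.name)
    return 100.0 * got / total, tuple(matched)


# --- decoys and filtering ----------------------------------------------------


def make_decoy_peptides(peptides: Sequence[Peptide]) -> list[Peptide]:
    """Reversed-sequence decoys with the C-terminal K/R fixed in place.

    Modifications are not carried over; callers re-apply modification
    expansion to the decoy sequences.
    """
    out = []
    for p in peptides:
        seq = p.sequence
        if seq[-1] in "KR":
            rev = seq[:-1][::-1] + seq[-1]
        else:
            rev = seq[::-1]
        out.append(
            Peptide(
                "DECOY_" + p.protein_id,
                p.start,
                p.end,
                rev,
                missed_cleavages=p.missed_cleavages,
            )
        )
    return out


def filter_matches(
    matches: Sequence[XlMatch],
    score_threshold: float = 50.0,
    intensity_floor: float = 2000.0,
    require_replicates: int | None = None,
) -> list[XlMatch]:
    """Accept matches above the score threshold and intensity floor,
    optionally requiring presence in a minimum number of replicates.

    The score cut is strict (score must exceed the threshold); the
    intensity cut removes precursors strictly below the floor. Replicate
    counting is per unique cross-link form (sequences, link positions,
    modifications). Output is sorted by higher score, then smaller |ppm|.
    """
    kept = [
        m
        for m in matches
        if m.score > score_threshold and m.precursor_intensity >= intensity_floor
    ]
    if require_replicates is not None and require_replicates > 1:
        reps: dict[tuple, set[str]] = {}
        for m in kept:
            reps.setdefault(m.pair.form_key(), set()).add(m.replicate)
        kept = [m for m in kept if len(reps[m.pair.form_key()]) >= require_replicates]
    kept.sort(key=lambda m: (-m.score, abs(m.ppm_error)))
    return kept


def best_match_per_form(matches: Sequence[XlMatch]) -> list[XlMatch]:
    """Collapse matches to one best-scoring record per cross-link form."""
    best: dict[tuple, XlMatch] = {}
    for m in sorted(matches, key=lambda m: (-m.score, abs(m.ppm_error))):
        best.setdefault(m.pair.form_key(), m)
    return list(best.values())


def estimate_fdr(matches: Sequence[XlMatch], score_threshold: float = 50.0) -> float:
    """Decoy/target ratio among matches scoring above the threshold."""
    above = [m for m in matches if m.score > score_threshold]
    targets = sum(1 for m in above if not m.decoy)
    decoys = sum(1 for m in above if m.decoy)
    if targets == 0:
        return 0.0 if decoys == 0 else float("inf")
    return decoys / targets


# --- driver ------------------------------------------------------------------


def search_spectra(
    spectra: Sequence[Ms2Spectrum],
    candidates: Sequence[CrosslinkedPair],
    precursor_tol_ppm: float = 10.0,
    ms2_tol: float = 0.02,
    series: Sequence[str] = ("b", "y"),
    max_fragment_charge: int = 2,
) -> list[XlMatch]:
    """Score every spectrum against mass-matched candidates.

    Returns the best-scoring match per spectrum (ties by smaller |ppm|),
    carrying over precursor intensity, replicate and fraction provenance.
    """
    results: list[XlMatch] = []
    order = np.argsort([crosslink_mass(c) for c in candidates])
    cands = [candidates[i] for i in order]
    cand_masses = np.array([crosslink_mass(c) for c in cands])
    for spec in spectra:
        obs_mass = mass_from_mz(spec.precursor_mz, spec.precursor_charge)
        half = obs_mass * precursor_tol_ppm * 1e-6
        lo = np.searchsorted(cand_masses, obs_mass - half)
        hi = np.searchsorted(cand_masses, obs_mass + half)
        best: XlMatch | None = None
        for cand in cands[lo:hi]:
            err = ppm_error(obs_mass, crosslink_mass(cand))
            frags = fragment_ions(cand, series=series, max_fragment_charge=max_fragment_charge)
            score, matched = score_match(spec, frags, ms2_tol)
            m = XlMatch(
                cand,
                obs_mass,
                err,
                matched,
                score,
                decoy=cand.decoy,
                spectrum_id=spec.spectrum_id,
                precursor_intensity=spec.precursor_intensity,
                replicate=spec.replicate,
                fraction=spec.fraction,
            )
            if best is None or (m.score, -abs(m.ppm_error)) > (best.score, -abs(best.ppm_error)):
                best = m
        if best is not None:
            results.append(best)
    return results
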