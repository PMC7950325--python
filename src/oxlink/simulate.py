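"""Ground-truth-known synthetic data for every pipeline stage.

The generator emulates, at the processed-data level, a bottom-up LC-MS
experiment on an oxidant-treated protein: tryptic MS1 features with
log-normal abundances and Gaussian ppm-scale mass errors, planted
nitration/Met-oxidation site occupancies, planted Tyr/Trp cross-linked
pairs with −2 H link chemistry, 1:1 mixing of ¹⁶O- and ¹⁸O-digested
channels with configurable incomplete incorporation, and MGF fragment
spectra for the planted cross-links.

Abundance noise is applied at the peptide level (shared by the modified
and unmodified forms of a peptide, as ionization and loading noise is) with
a smaller independent per-form measurement jitter, so the relative site
occupancy of a planted site is an unbiased target of the downstream
estimator.

The standard test protein is a synthetic "mini-fibronectin": a ~280-residue
chain that embeds, with native tryptic context, the eight peptide
sequences of the four experimentally characterized cross-linked pairs,
plus a few additional Tyr/Trp/Met-bearing peptides for occupancy
quantification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import (
    CARBAMIDOMETHYL,
    NITRATION,
    STANDARD_MODIFICATIONS,
    CrosslinkedPair,
    Peptide,
    crosslink_mass,
    label_shift,
    mz_from_mass,
    peptide_mass,
)
from .digest import DigestSpec, cleavage_sites, digest, modified_forms
from .labeling import Ms1Feature
from .quant import PeptideQuantRecord
from .domains import DomainAnnotation
from .xlsearch import Ms2Spectrum, fragment_ions

# --- the mini-fibronectin fixture -------------------------------------------

# Segment layout: every segment is preceded by K/R and none starts with P,
# so each planted peptide is recovered by tryptic digestion with its native
# missed-cleavage structure (e.g. the internal K-P of GEWTCKPIAEK is not a
# cleavage site; WCHDNGVNYKIGEKWDR carries two missed cleavages).
_SEGMENTS: tuple[tuple[str, str], ...] = (
    ("lead", "MAGSALTPEK"),
    ("fill0", "AGSTDLEAGSTDLEK"),
    ("xl1a", "TFYSCTTEGR"),
    ("xl1b", "YSFCTDHTVLVQTR"),
    ("fill1", "ASPDLTGEASPDLTGEK"),
    ("xl2a", "GEWTCKPIAEK"),
    ("fill2", "TGSLDEATGSLDEAK"),
    ("quantY", "AYSGDTLEK"),
    ("quantM", "GMTSPELAK"),
    ("quantW", "TWADNSPLK"),
    ("fill3", "DSTGALEDSTGALEDSTGALEK"),
    ("xl4a", "VEYELSEEGDEPQYLDLPSTATSVNIPDLLPGR"),
    ("fill4", "AGTDSLEAGTDSLEK"),
    ("xl3a", "WCGTTQNYDADQK"),
    ("fill5", "LSTGADELSTGADEK"),
    ("fnI11", "WCHDNGVNYKIGEKWDRQGENGQMMSCTCLGNGK"),
    ("tail", "AGSTDLEAGSTLEK"),
)

MINI_FN_ID = "MINIFN"


@dataclass(frozen=True)
class FixtureProtein:
    protein_id: str
    sequence: str
    segment_start: Mapping[str, int]  # 1-based start of each segment
    annotations: tuple[DomainAnnotation, ...]

    def segment_residue(self, segment: str, pos_in_segment: int) -> int:
        """Mature-chain residue number of position ``pos_in_segment``
        (1-based) within a named segment."""
        return self.segment_start[segment] + pos_in_segment - 1


def mini_fibronectin() -> FixtureProtein:
    """The packaged synthetic mini-fibronectin chain with its module map."""
    starts: dict[str, int] = {}
    pos = 1
    parts = []
    for name, seg in _SEGMENTS:
        starts[name] = pos
        parts.append(seg)
        pos += len(seg)
    seq = "".join(parts)

    def span(*names: str) -> tuple[int, int]:
        s = min(starts[n] for n in names)
        e = max(starts[n] + len(dict(_SEGMENTS)[n]) - 1 for n in names)
        return s, e

    ann = (
        DomainAnnotation("FNII_1", *span("xl1a", "xl1b"), "collagen-binding"),
        DomainAnnotation("FNI_3", *span("xl2a"), "fibrin-binding-1"),
        DomainAnnotation("FNIII_2", *span("xl4a"), "self-association"),
        DomainAnnotation("FNII_2", *span("xl3a"), "collagen-binding"),
        DomainAnnotation("FNI_11", *span("fnI11"), "fibrin-binding-2"),
    )
    return FixtureProtein(MINI_FN_ID, seq, starts, ann)


def _locate_peptide(
    fixture: FixtureProtein,
    sequence: str,
    mods: Sequence[tuple[int, str]] = (),
) -> Peptide:
    """Build a located, carbamidomethylated peptide form from the fixture."""
    start = fixture.sequence.find(sequence) + 1
    if start == 0:
        raise ValueError(f"peptide {sequence} not in fixture chain")
    internal = sum(
        1 for s in cleavage_sites(fixture.sequence) if start <= s < start + len(sequence) - 1
    )
    fixed = tuple(
        (i + 1, CARBAMIDOMETHYL) for i, r in enumerate(sequence) if r == "C"
    )
    variable = tuple((p, STANDARD_MODIFICATIONS[name]) for p, name in mods)
    return Peptide(
        fixture.protein_id,
        start,
        start + len(sequence) - 1,
        sequence,
        missed_cleavages=internal,
        mods=fixed + variable,
    )


@dataclass(frozen=True)
class CrosslinkPlant:
    pair: CrosslinkedPair
    abundance: float
    fractions: tuple[str, ...] = ("unfractionated",)
    pair_id: str = ""


def table2_crosslink_plants(abundance: float = 5e6) -> tuple[CrosslinkPlant, ...]:
    """The four experimentally characterized cross-linked pairs, planted on
    the fixture chain with the modification states their observed masses
    imply (one nitration on the di-Trp and Tyr–Trp pairs)."""
    fx = mini_fibronectin()

    def pep(seq, mods=()):
        return _locate_peptide(fx, seq, mods)

    p1 = CrosslinkedPair(pep("YSFCTDHTVLVQTR"), pep("TFYSCTTEGR"), 1, 3, "YY")
    p2 = CrosslinkedPair(
        pep("WCHDNGVNYKIGEKWDR", mods=[(9, "nitration")]), pep("GEWTCKPIAEK"), 1, 3, "WW"
    )
    p3 = CrosslinkedPair(
        pep("WDRQGENGQMMSCTCLGNGK"), pep("WCGTTQNYDADQK", mods=[(8, "nitration")]), 1, 1, "WW"
    )
    p4 = CrosslinkedPair(
        pep("VEYELSEEGDEPQYLDLPSTATSVNIPDLLPGR"),
        pep("WCHDNGVNYK", mods=[(9, "nitration")]),
        3,
        1,
        "YW",
    )
    return (
        CrosslinkPlant(p1, abundance, ("dimer", "unfractionated"), "YY_372like"),
        CrosslinkPlant(p2, abundance, ("dimer",), "WW_177like"),
        CrosslinkPlant(p3, abundance, ("dimer",), "WW_445like"),
        CrosslinkPlant(p4, abundance, ("unfractionated",), "YW_754like"),
    )


def default_occupancy_map(fixture: Optional[FixtureProtein] = None) -> dict[int, tuple[str, float]]:
    """Planted true occupancies: nitration levels spanning the low/heavy
    range reported for oxidant-exposed fibronectin (mean ~12%, max ~35%),
    Met sulfoxide at moderate levels. Link-site residues are left bare."""
    fx = fixture or mini_fibronectin()
    link_sites = set()
    for plant in table2_crosslink_plants():
        link_sites.add(plant.pair.link_alpha_residue_number)
        link_sites.add(plant.pair.link_beta_residue_number)
    nit_levels = [35.0, 25.0, 18.0, 12.0, 5.0, 2.0]
    met_levels = [40.0, 10.0]
    occ: dict[int, tuple[str, float]] = {}
    yw = [i + 1 for i, r in enumerate(fx.sequence) if r in "YW" and i + 1 not in link_sites]
    ms = [i + 1 for i, r in enumerate(fx.sequence) if r == "M"]
    for k, site in enumerate(yw):
        occ[site] = ("nitration", nit_levels[k % len(nit_levels)])
    for k, site in enumerate(ms):
        occ[site] = ("met_oxidation", met_levels[k % len(met_levels)])
    return occ


# --- simulation spec ---------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic experiment.

    ``site_occupancy`` maps mature-chain residue number to (modification
    name, true RSO %); ``o18_incorporation`` is the distribution of ¹⁸O
    atoms per newly formed C-terminus in the heavy channel.
    """

    protein_id: str = MINI_FN_ID
    sequence: str = ""
    site_occupancy: Mapping[int, tuple[str, float]] = field(default_factory=dict)
    crosslink_plants: tuple[CrosslinkPlant, ...] = ()
    digest_spec: DigestSpec = field(default_factory=DigestSpec)
    area_median: float = 1e6
    area_sigma: float = 0.5  # peptide-level log-normal, natural-log units
    form_sigma: float = 0.1  # per-form measurement jitter
    ppm_sigma: float = 2.0
    charge_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.30, 3: 0.35, 4: 0.20, 5: 0.10, 6: 0.05}
    )
    mc_retention: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.5, 2: 0.25}
    )
    o18_incorporation: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.95, 1: 0.05, 0: 0.0}
    )
    noise_fraction: float = 0.10
    fragment_dropout: float = 0.3
    noise_peaks: int = 20
    rt_range: tuple[float, float] = (10.0, 110.0)
    rt_width: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for site, (mod, pct) in self.site_occupancy.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"occupancy at residue {site} out of range: {pct}")
            if mod not in STANDARD_MODIFICATIONS:
                raise ValueError(f"unknown modification {mod!r} at residue {site}")
        for dist_name in ("charge_probs", "o18_incorporation"):
            dist = getattr(self, dist_name)
            tot = sum(dist.values())
            if tot <= 0:
                raise ValueError(f"{dist_name} must have positive total probability")
            object.__setattr__(self, dist_name, {k: v / tot for k, v in dist.items()})


def default_spec(seed: int = 0) -> SimulationSpec:
    """The standard study conditions on the mini-fibronectin fixture."""
    fx = mini_fibronectin()
    return SimulationSpec(
        protein_id=fx.protein_id,
        sequence=fx.sequence,
        site_occupancy=default_occupancy_map(fx),
        crosslink_plants=table2_crosslink_plants(),
        seed=seed,
    )


# --- truth -------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationTruth:
    sites: pd.DataFrame  # protein_id, residue_number, residue, modification, true_rso_percent
    crosslinks: pd.DataFrame  # pair_id, sequences, link residues, abundance, fractions, mass


def generate_truth(spec: SimulationSpec) -> SimulationTruth:
    """Truth tables implied by a simulation spec; deterministic."""
    seq = spec.sequence or mini_fibronectin().sequence
    site_rows = [
        {
            "protein_id": spec.protein_id,
            "residue_number": site,
            "residue": seq[site - 1],
            "modification": mod,
            "true_rso_percent": pct,
        }
        for site, (mod, pct) in sorted(spec.site_occupancy.items())
    ]
    xl_rows = [
        {
            "pair_id": plant.pair_id or f"pair{i}",
            "alpha_sequence": plant.pair.alpha.sequence,
            "beta_sequence": plant.pair.beta.sequence,
            "link_residue_alpha": plant.pair.link_alpha_residue_number,
            "link_residue_beta": plant.pair.link_beta_residue_number,
            "link_type": plant.pair.link_type,
            "abundance": plant.abundance,
            "fractions": ";".join(plant.fractions),
            "theoretical_mass": crosslink_mass(plant.pair),
        }
        for i, plant in enumerate(spec.crosslink_plants, start=1)
    ]
    return SimulationTruth(
        sites=pd.DataFrame(
            site_rows,
            columns=["protein_id", "residue_number", "residue", "modification", "true_rso_percent"],
        ),
        crosslinks=pd.DataFrame(
            xl_rows,
            columns=[
                "pair_id",
                "alpha_sequence",
                "beta_sequence",
                "link_residue_alpha",
                "link_residue_beta",
                "link_type",
                "abundance",
                "fractions",
                "theoretical_mass",
            ],
        ),
    )


# --- linear-peptide form enumeration ----------------------------------------


def _peptide_forms(
    peptide: Peptide, spec: SimulationSpec
) -> list[tuple[Peptide, float]]:
    """(form, fraction-of-abundance) for every planted modification state
    of a peptide, carbamidomethyl fixed on Cys."""
    sites = [
        (i + 1, STANDARD_MODIFICATIONS[spec.site_occupancy[peptide.start + i][0]],
         spec.site_occupancy[peptide.start + i][1] / 100.0)
        for i, r in enumerate(peptide.sequence)
        if peptide.start + i in spec.site_occupancy
        and r in STANDARD_MODIFICATIONS[spec.site_occupancy[peptide.start + i][0]].targets
    ]
    fixed = tuple((i + 1, CARBAMIDOMETHYL) for i, r in enumerate(peptide.sequence) if r == "C")
    forms: list[tuple[Peptide, float]] = []
    for mask in range(1 << len(sites)):
        frac = 1.0
        mods = list(fixed)
        for k, (pos, mod, p) in enumerate(sites):
            if mask >> k & 1:
                frac *= p
                mods.append((pos, mod))
            else:
                frac *= 1.0 - p
        if frac > 0.0:
            forms.append((replace(peptide, mods=tuple(mods)), frac))
    return forms


def _retained_peptides(spec: SimulationSpec, rng: np.random.Generator) -> list[Peptide]:
    seq = spec.sequence or mini_fibronectin().sequence
    peptides = digest(seq, spec.digest_spec, spec.protein_id)
    kept = []
    for p in peptides:
        keep_p = spec.mc_retention.get(p.missed_cleavages, 0.0)
        if rng.random() < keep_p:
            kept.append(p)
    return kept


# --- quant-record simulation -------------------------------------------------


def simulate_quant_records(
    spec: SimulationSpec,
    n_replicates: int = 3,
    condition: str = "A",
    rng: Optional[np.random.Generator] = None,
) -> list[PeptideQuantRecord]:
    """Identified-peptide MS1 areas for the RSO pipeline.

    Each replicate redraws peptide retention, peptide-level abundance and
    per-form jitter; areas split between modification forms according to
    the planted occupancies.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    records: list[PeptideQuantRecord] = []
    for rep in range(1, n_replicates + 1):
        for pep in _retained_peptides(spec, rng):
            base = spec.area_median * np.exp(spec.area_sigma * rng.normal())
            for form, frac in _peptide_forms(pep, spec):
                jitter = np.exp(spec.form_sigma * rng.normal()) if spec.form_sigma > 0 else 1.0
                records.append(
                    PeptideQuantRecord(form, base * frac * jitter, condition, rep)
                )
    return records


# --- MS1 feature simulation --------------------------------------------------


def _sample(dist: Mapping[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return int(rng.choice(keys, p=probs / probs.sum()))


def _perturb(mz: float, spec: SimulationSpec, rng: np.random.Generator) -> float:
    return mz * (1.0 + spec.ppm_sigma * 1e-6 * rng.normal())


def simulate_features(
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
    sample: str = "A",
    fraction: str = "unfractionated",
) -> list[Ms1Feature]:
    """MS1 features of a 1:1 mixed ¹⁶O/¹⁸O run of one sample/fraction.

    Every retained linear peptide form and every planted cross-link whose
    fraction list contains ``fraction`` yields a light feature and a heavy
    feature shifted by the sampled ¹⁸O label state; random noise features
    are appended.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    feats: list[Ms1Feature] = []
    counter = 0

    def add(mass, shift, area, tag):
        nonlocal counter
        z = _sample(spec.charge_probs, rng)
        rt0 = rng.uniform(*spec.rt_range)
        rt = (rt0, rt0 + spec.rt_width)
        for channel, m in (("16O", mass), ("18O", mass + shift)):
            counter += 1
            feats.append(
                Ms1Feature(
                    f"{tag}_{counter}_{channel}",
                    _perturb(mz_from_mass(m, z), spec, rng),
                    z,
                    area,
                    rt[0],
                    rt[1],
                    channel=channel,
                    sample=sample,
                    fraction=fraction,
                )
            )

    for pep in _retained_peptides(spec, rng):
        base = spec.area_median * np.exp(spec.area_sigma * rng.normal())
        for form, frac in _peptide_forms(pep, spec):
            jitter = np.exp(spec.form_sigma * rng.normal()) if spec.form_sigma > 0 else 1.0
            n18 = _sample(spec.o18_incorporation, rng)
            add(peptide_mass(form), label_shift(1, n18), base * frac * jitter, "lin")

    for plant in spec.crosslink_plants:
        if fraction not in plant.fractions:
            continue
        n18a = _sample(spec.o18_incorporation, rng)
        n18b = _sample(spec.o18_incorporation, rng)
        shift = label_shift(1, n18a) + label_shift(1, n18b)
        add(crosslink_mass(plant.pair), shift, plant.abundance, f"xl_{plant.pair_id}")

    n_noise = int(round(spec.noise_fraction * len(feats) / 2))
    for i in range(n_noise):
        z = _sample(spec.charge_probs, rng)
        rt0 = rng.uniform(*spec.rt_range)
        feats.append(
            Ms1Feature(
                f"noise_{i}",
                rng.uniform(300.0, 1500.0),
                z,
                spec.area_median * np.exp(spec.area_sigma * rng.normal()),
                rt0,
                rt0 + spec.rt_width,
                channel="",
                sample=sample,
                fraction=fraction,
            )
        )
    return feats


# --- MS2 spectrum simulation -------------------------------------------------


def simulate_spectra(
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
    n_replicates: int = 3,
    fraction: Optional[str] = None,
) -> list[Ms2Spectrum]:
    """Fragment spectra of the planted cross-links (light channel).

    Each plant yields one spectrum per replicate: its theoretical b/y
    ladder with ``fragment_dropout`` peak loss, small m/z jitter and
    additive noise peaks. When ``fraction`` is given, only plants observed
    in that fraction are spoken for and spectra carry that tag; otherwise
    each plant's first listed fraction is used.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    spectra: list[Ms2Spectrum] = []
    for plant in spec.crosslink_plants:
        if fraction is not None and fraction not in plant.fractions:
            continue
        frac_tag = fraction if fraction is not None else plant.fractions[0]
        mass = crosslink_mass(plant.pair)
        frags = fragment_ions(plant.pair, series=("b", "y"), max_fragment_charge=2)
        for rep in range(1, n_replicates + 1):
            z = int(rng.integers(3, 6))
            peaks = []
            for f in frags:
                if rng.random() < spec.fragment_dropout:
                    continue
                peaks.append(
                    (f.mz + rng.uniform(-0.005, 0.005), 1e4 * np.exp(rng.normal()))
                )
            for _ in range(spec.noise_peaks):
                peaks.append((rng.uniform(200.0, 1500.0), 1e3 * np.exp(rng.normal())))
            spectra.append(
                Ms2Spectrum(
                    f"{plant.pair_id}_rep{rep}_{frac_tag}",
                    _perturb(mz_from_mass(mass, z), spec, rng),
                    z,
                    tuple(peaks),
                    method_tag="HCD",
                    precursor_intensity=plant.abundance * np.exp(0.1 * rng.normal()),
                    replicate=f"rep{rep}",
                    sample="A",
                    fraction=frac_tag,
                )
            )
    return spectra
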