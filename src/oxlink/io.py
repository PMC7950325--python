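"""Readers and writers for the pipeline's file formats.

FASTA via Biopython, MGF via pyteomics, tables via pandas CSV with
documented column schemas. Writer/reader pairs round-trip losslessly.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .chem import STANDARD_MODIFICATIONS, Modification, Peptide
from .domains import DomainAnnotation, annotations_from_frame
from .labeling import DoubletCall, Ms1Feature
from .quant import PeptideQuantRecord
from .xlsearch import Ms2Spectrum, XlMatch
from .chem import crosslink_mass, mz_from_mass

FEATURE_COLUMNS = [
    "feature_id",
    "mz",
    "charge",
    "area",
    "rt_start",
    "rt_end",
    "channel",
    "sample",
    "fraction",
]

QUANT_COLUMNS = [
    "protein_id",
    "start",
    "end",
    "sequence",
    "missed_cleavages",
    "mods",
    "label",
    "ms1_area",
    "condition",
    "replicate",
]

ANNOTATION_COLUMNS = ["module_name", "start", "end", "functional_domain"]


# --- FASTA -------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Protein chains keyed by record id; lowercase letters are uppercased
    with a warning."""
    chains: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"FASTA record {rec.id}: lowercase letters normalized to uppercase")
            seq = seq.upper()
        chains[rec.id] = seq
    if not chains:
        raise ValueError(f"no FASTA records found in {path}")
    return chains


def write_fasta(chains: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in chains.items()]
    SeqIO.write(records, str(path), "fasta")


# --- MGF ---------------------------------------------------------------------


def read_mgf(path) -> list[Ms2Spectrum]:
    """MS2 peak lists; records without a CHARGE field are rejected with a
    diagnostic naming the spectrum."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            if "charge" not in params:
                raise ValueError(f"MGF record {title!r} (index {i}) has no CHARGE field")
            charge = int(params["charge"][0])
            pepmass = params["pepmass"]
            mz = float(pepmass[0])
            intensity = float(pepmass[1]) if len(pepmass) > 1 and pepmass[1] else 0.0
            spectra.append(
                Ms2Spectrum(
                    spectrum_id=title,
                    precursor_mz=mz,
                    precursor_charge=charge,
                    peaks=tuple(zip(entry["m/z array"], entry["intensity array"])),
                    method_tag=str(params.get("method", "HCD")),
                    precursor_intensity=intensity,
                    replicate=str(params.get("replicate", "")),
                    sample=str(params.get("sample", "")),
                    fraction=str(params.get("fraction", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": [m for m, _ in s.peaks],
                "intensity array": [i for _, i in s.peaks],
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": (s.precursor_mz, s.precursor_intensity),
                    "charge": f"{s.precursor_charge}+",
                    "method": s.method_tag,
                    "replicate": s.replicate,
                    "sample": s.sample,
                    "fraction": s.fraction,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# --- MS1 feature tables ------------------------------------------------------


def features_to_frame(features: Sequence[Ms1Feature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "mz": f.mz,
                "charge": f.charge,
                "area": f.area,
                "rt_start": f.rt_start,
                "rt_end": f.rt_end,
                "channel": f.channel,
                "sample": f.sample,
                "fraction": f.fraction,
            }
            for f in features
        ],
        columns=FEATURE_COLUMNS,
    )


def frame_to_features(df: pd.DataFrame) -> list[Ms1Feature]:
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return [
        Ms1Feature(
            str(r.feature_id),
            float(r.mz),
            int(r.charge),
            float(r.area),
            float(r.rt_start),
            float(r.rt_end),
            channel="" if pd.isna(r.channel) else str(r.channel),
            sample="" if pd.isna(r.sample) else str(r.sample),
            fraction="" if pd.isna(r.fraction) else str(r.fraction),
        )
        for r in df.itertuples()
    ]


def write_features(features: Sequence[Ms1Feature], path) -> None:
    features_to_frame(features).to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> list[Ms1Feature]:
    return frame_to_features(
        pd.read_csv(path, keep_default_na=False, na_values=[], float_precision="round_trip")
    )


def doublets_to_frame(calls: Sequence[DoubletCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "light_feature_id": c.light_feature.feature_id,
                "heavy_feature_id": c.heavy_feature.feature_id,
                "light_mz": c.light_feature.mz,
                "heavy_mz": c.heavy_feature.mz,
                "charge": c.charge,
                "neutral_shift": c.neutral_shift,
                "call": c.call,
            }
            for c in calls
        ],
        columns=[
            "light_feature_id",
            "heavy_feature_id",
            "light_mz",
            "heavy_mz",
            "charge",
            "neutral_shift",
            "call",
        ],
    )


# --- peptide quant records ---------------------------------------------------


def _encode_mods(p: Peptide) -> str:
    return ";".join(f"{pos}:{mod.name}" for pos, mod in p.mods)


def _decode_mods(text: str, registry: dict[str, Modification]) -> tuple:
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        pos, name = token.split(":")
        try:
            out.append((int(pos), registry[name]))
        except KeyError:
            raise ValueError(f"unknown modification name {name!r} in quant table") from None
    return tuple(out)


def quant_records_to_frame(records: Sequence[PeptideQuantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.peptide.protein_id,
                "start": r.peptide.start,
                "end": r.peptide.end,
                "sequence": r.peptide.sequence,
                "missed_cleavages": r.peptide.missed_cleavages,
                "mods": _encode_mods(r.peptide),
                "label": r.peptide.label,
                "ms1_area": r.ms1_area,
                "condition": r.condition,
                "replicate": r.replicate,
            }
            for r in records
        ],
        columns=QUANT_COLUMNS,
    )


def frame_to_quant_records(
    df: pd.DataFrame, registry: dict[str, Modification] | None = None
) -> list[PeptideQuantRecord]:
    registry = registry or STANDARD_MODIFICATIONS
    missing = set(QUANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        pep = Peptide(
            str(r.protein_id),
            int(r.start),
            int(r.end),
            str(r.sequence),
            missed_cleavages=int(r.missed_cleavages),
            mods=_decode_mods("" if pd.isna(r.mods) else str(r.mods), registry),
            label=int(r.label),
        )
        out.append(PeptideQuantRecord(pep, float(r.ms1_area), str(r.condition), int(r.replicate)))
    return out


def write_quant_records(records: Sequence[PeptideQuantRecord], path) -> None:
    quant_records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_quant_records(path, registry=None) -> list[PeptideQuantRecord]:
    return frame_to_quant_records(
        pd.read_csv(path, keep_default_na=False, na_values=[], float_precision="round_trip"),
        registry,
    )


# --- domain annotations ------------------------------------------------------


def read_annotations(path) -> list[DomainAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return annotations_from_frame(df)


def write_annotations(annotations: Sequence[DomainAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "module_name": a.module_name,
                "start": a.start,
                "end": a.end,
                "functional_domain": a.functional_domain,
            }
            for a in annotations
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, index=False)


# --- cross-link match reports ------------------------------------------------


def matches_to_frame(matches: Sequence[XlMatch]) -> pd.DataFrame:
    """Accepted cross-link matches with columns mirroring the standard
    cross-link report: sequences, linked residues, m/z, charge, observed
    mass, ppm error, fragmentation and fraction provenance."""
    rows = []
    for m in matches:
        rows.append(
            {
                "alpha_sequence": m.pair.alpha.sequence,
                "beta_sequence": m.pair.beta.sequence,
                "alpha_mods": _encode_mods(m.pair.alpha),
                "beta_mods": _encode_mods(m.pair.beta),
                "link_type": m.pair.link_type,
                "link_residue_alpha": m.pair.link_alpha_residue_number,
                "link_residue_beta": m.pair.link_beta_residue_number,
                "theoretical_mass": crosslink_mass(m.pair),
                "observed_mass": m.observed_mass,
                "ppm_error": m.ppm_error,
                "score": m.score,
                "n_matched_fragments": len(m.matched_fragments),
                "decoy": m.decoy,
                "spectrum_id": m.spectrum_id,
                "precursor_intensity": m.precursor_intensity,
                "replicate": m.replicate,
                "fraction": m.fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "alpha_sequence",
            "beta_sequence",
            "alpha_mods",
            "beta_mods",
            "link_type",
            "link_residue_alpha",
            "link_residue_beta",
            "theoretical_mass",
            "observed_mass",
            "ppm_error",
            "score",
            "n_matched_fragments",
            "decoy",
            "spectrum_id",
            "precursor_intensity",
            "replicate",
            "fraction",
        ],
    )
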