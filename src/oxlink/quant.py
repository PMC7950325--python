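"""Relative site occupancy (RSO), coverage statistics and two-condition
footprint comparison.

RSO at a residue is the percentage of MS1 area carried by peptide forms
modified at that residue, over all forms covering it — charge states and
overlapping peptide species pooled, Met-oxidized forms included in the
denominator. Replicates are averaged at the RSO level (mean ± SD), not
pooled at the area level.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Modification, Peptide


@dataclass(frozen=True)
class PeptideQuantRecord:
    peptide: Peptide
    ms1_area: float
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ms1_area < 0:
            raise ValueError("ms1_area must be >= 0")


@dataclass(frozen=True)
class SiteOccupancy:
    protein_id: str
    residue_number: int
    residue: str
    modification: str
    rso_percent: float
    modified_area: float
    total_area: float
    condition: str = ""
    n_replicates: int = 1
    rso_sd: float = float("nan")
    low_confidence: bool = False


def rso(
    records: Sequence[PeptideQuantRecord],
    protein_id: str,
    residue_number: int,
    modification: str,
) -> Optional[SiteOccupancy]:
    """Pooled RSO of one site over a set of quant records.

    Returns None when no record covers the site (not-identified, distinct
    from 0%). A site covered only by modified forms reports 100% with a
    low-confidence flag.
    """
    covering = [
        r
        for r in records
        if r.peptide.protein_id == protein_id and r.peptide.covers(residue_number)
    ]
    if not covering:
        return None
    modified = [
        r
        for r in covering
        if any(m.name == modification for m in r.peptide.modifications_at(residue_number))
    ]
    mod_area = sum(r.ms1_area for r in modified)
    total_area = sum(r.ms1_area for r in covering)
    unmod_evidence = len(modified) < len(covering)
    pct = 100.0 * mod_area / total_area if total_area > 0 else 0.0
    residue = covering[0].peptide.sequence[residue_number - covering[0].peptide.start]
    return SiteOccupancy(
        protein_id,
        residue_number,
        residue,
        modification,
        pct,
        mod_area,
        total_area,
        condition=covering[0].condition,
        low_confidence=not unmod_evidence,
    )


def rso_table(
    records: Sequence[PeptideQuantRecord],
    modification: Modification,
    protein_id: Optional[str] = None,
) -> pd.DataFrame:
    """Per-site RSO table, replicates averaged at the RSO level.

    Rows cover every target residue of ``modification`` covered by at least
    one record. Columns: protein_id, residue_number, residue, modification,
    rso_percent (mean across replicates), rso_sd, n_replicates,
    modified_area / total_area (pooled across replicates), low_confidence,
    condition.
    """
    recs = [r for r in records if protein_id is None or r.peptide.protein_id == protein_id]
    sites: set[tuple[str, int, str]] = set()
    for r in recs:
        p = r.peptide
        for i, letter in enumerate(p.sequence):
            if letter in modification.targets:
                sites.add((p.protein_id, p.start + i, letter))
    by_rep: dict[tuple[str, int], list[PeptideQuantRecord]] = {}
    for r in recs:
        by_rep.setdefault((r.condition, r.replicate), []).append(r)

    rows = []
    for pid, resnum, letter in sorted(sites):
        per_rep = []
        pooled_mod = pooled_total = 0.0
        low_conf = False
        condition = ""
        for (cond, _rep), rr in sorted(by_rep.items()):
            occ = rso(rr, pid, resnum, modification.name)
            if occ is None:
                continue
            per_rep.append(occ.rso_percent)
            pooled_mod += occ.modified_area
            pooled_total += occ.total_area
            low_conf = low_conf or occ.low_confidence
            condition = cond
        if not per_rep:
            continue
        rows.append(
            {
                "protein_id": pid,
                "residue_number": resnum,
                "residue": letter,
                "modification": modification.name,
                "rso_percent": float(np.mean(per_rep)),
                "rso_sd": float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else np.nan,
                "n_replicates": len(per_rep),
                "modified_area": pooled_mod,
                "total_area": pooled_total,
                "low_confidence": low_conf,
                "condition": condition,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "residue_number",
            "residue",
            "modification",
            "rso_percent",
            "rso_sd",
            "n_replicates",
            "modified_area",
            "total_area",
            "low_confidence",
            "condition",
        ],
    )


# --- coverage statistics -----------------------------------------------------


def class_percentages(n_modified: int, n_not_modified: int, n_not_identified: int) -> dict:
    """Percentage conventions for a residue class census.

    ``pct_of_total`` is modified over all residues of the class;
    ``pct_of_identified`` is modified over identified (modified + detected
    unmodified) residues.
    """
    total = n_modified + n_not_modified + n_not_identified
    identified = n_modified + n_not_modified
    return {
        "total": total,
        "modified": n_modified,
        "not_modified": n_not_modified,
        "not_identified": n_not_identified,
        "pct_of_total": 100.0 * n_modified / total if total else 0.0,
        "pct_identified_of_total": 100.0 * identified / total if total else 0.0,
        "pct_of_identified": 100.0 * n_modified / identified if identified else 0.0,
    }


def coverage_stats(
    peptides: Sequence[Peptide],
    sequence: str,
    glyco_exclusion_sites: Sequence[int] = (),
    residue_classes: Mapping[str, str] = {"Y": "nitration", "W": "nitration", "M": "met_oxidation"},
) -> dict:
    """Sequence coverage and per-residue-class modification census.

    Coverage is the percentage of chain residues covered by at least one
    identified peptide; a second figure excludes a configured list of
    residue numbers (e.g. known glycosylation sites) from the denominator
    and numerator. For each residue class the census counts modified
    (carrying the class's modification in any peptide), not modified
    (covered but never modified) and not identified residues.
    """
    n = len(sequence)
    covered = np.zeros(n + 1, dtype=bool)
    modified_at: dict[int, set[str]] = {}
    for p in peptides:
        covered[p.start : p.end + 1] = True
        for pos, mod in p.mods:
            modified_at.setdefault(p.residue_number(pos), set()).add(mod.name)

    excl = set(glyco_exclusion_sites)
    all_res = set(range(1, n + 1))
    cov_pct = 100.0 * covered[1:].sum() / n if n else 0.0
    kept = sorted(all_res - excl)
    cov_excl = 100.0 * sum(covered[i] for i in kept) / len(kept) if kept else 0.0

    classes = {}
    for letter, mod_name in residue_classes.items():
        residues = [i + 1 for i, r in enumerate(sequence) if r == letter]
        n_mod = sum(1 for i in residues if mod_name in modified_at.get(i, set()))
        n_unmod = sum(
            1 for i in residues if covered[i] and mod_name not in modified_at.get(i, set())
        )
        n_nid = len(residues) - n_mod - n_unmod
        classes[letter] = class_percentages(n_mod, n_unmod, n_nid)
    return {
        "sequence_coverage_percent": cov_pct,
        "sequence_coverage_excluding_glyco_percent": cov_excl,
        "residue_classes": classes,
    }


def residue_census(sequence: str) -> dict[str, int]:
    """Counts of each residue letter in a chain."""
    return dict(Counter(sequence))


# --- condition comparison ----------------------------------------------------

_SITE_KEY = ["protein_id", "residue_number", "modification"]


def compare_conditions(rso_a: pd.DataFrame, rso_b: pd.DataFrame) -> pd.DataFrame:
    """Per-site RSO difference between two conditions (A − B).

    Positive deltas mean greater occupancy in condition A. A site present
    in only one table contributes with the other condition assumed 0% and
    is flagged (``assumed_zero_a`` / ``assumed_zero_b``).
    """
    a = rso_a[_SITE_KEY + ["residue", "rso_percent"]].rename(columns={"rso_percent": "rso_a"})
    b = rso_b[_SITE_KEY + ["residue", "rso_percent"]].rename(columns={"rso_percent": "rso_b"})
    merged = a.merge(b, on=_SITE_KEY + ["residue"], how="outer")
    merged["assumed_zero_a"] = merged["rso_a"].isna()
    merged["assumed_zero_b"] = merged["rso_b"].isna()
    merged["rso_a"] = merged["rso_a"].astype(float).fillna(0.0)
    merged["rso_b"] = merged["rso_b"].astype(float).fillna(0.0)
    merged["delta"] = merged["rso_a"] - merged["rso_b"]
    return merged.sort_values(_SITE_KEY).reset_index(drop=True)


def summarize(
    rso_tbl: pd.DataFrame,
    deltas: Optional[pd.DataFrame] = None,
    min_change_percent: float = 10.0,
) -> dict:
    """Summary statistics of an RSO table and optional condition deltas.

    ``mean_rso_of_modified`` averages across sites with RSO > 0 (None when
    no site is modified); ``flagged_sites`` lists sites whose |delta|
    exceeds ``min_change_percent``.
    """
    nonzero = rso_tbl.loc[rso_tbl["rso_percent"] > 0, "rso_percent"]
    out = {
        "n_sites": int(len(rso_tbl)),
        "n_modified_sites": int((rso_tbl["rso_percent"] > 0).sum()),
        "mean_rso_of_modified": float(nonzero.mean()) if len(nonzero) else None,
        "sites_per_modification": rso_tbl.groupby("modification")["residue_number"]
        .count()
        .to_dict(),
    }
    if deltas is not None:
        flagged = deltas.loc[deltas["delta"].abs() > min_change_percent]
        out["flagged_sites"] = [
            (row.protein_id, int(row.residue_number), row.modification, float(row.delta))
            for row in flagged.itertuples()
        ]
    return out
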