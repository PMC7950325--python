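"""Mapping of modification sites and cross-links onto protein module
architecture, and cross-link topology from SEC-fraction provenance.

Modules (e.g. the type I/II/III repeats of fibronectin) are non-overlapping
mature-chain intervals grouped into functional domains. Residues falling
between modules are labelled ``linker/interdomain``. A cross-link seen in
the SEC dimer fraction is intermolecular; one seen in the monomer fraction
(and never the dimer) is intramolecular; one seen only in the
unfractionated sample is ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

LINKER_LABEL = "linker/interdomain"

#: Occupancy bins used for schematic reports: half-open intervals,
#: lower-exclusive, matching (1,10], (10,20], (20,30], (30,100].
RSO_BINS: tuple[tuple[float, float, str], ...] = (
    (30.0, 100.0, ">30%"),
    (20.0, 30.0, "20-30%"),
    (10.0, 20.0, "10-20%"),
    (1.0, 10.0, "1-10%"),
)


@dataclass(frozen=True)
class DomainAnnotation:
    module_name: str
    start: int
    end: int
    functional_domain: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"module {self.module_name}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class TopologyCall:
    pair_id: str
    fractions_observed: frozenset[str]
    call: str  # intramolecular | intermolecular | ambiguous


def validate_annotations(annotations: Sequence[DomainAnnotation]) -> list[DomainAnnotation]:
    """Sort by start and reject overlapping module intervals."""
    anns = sorted(annotations, key=lambda a: a.start)
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.start <= prev.end:
            raise ValueError(
                f"overlapping modules {prev.module_name} ({prev.start}-{prev.end}) and "
                f"{nxt.module_name} ({nxt.start}-{nxt.end})"
            )
    return anns


def annotations_from_frame(df: pd.DataFrame) -> list[DomainAnnotation]:
    return validate_annotations(
        [
            DomainAnnotation(
                str(r.module_name), int(r.start), int(r.end), str(r.functional_domain)
            )
            for r in df.itertuples()
        ]
    )


def assign_site(
    residue_number: int,
    annotations: Sequence[DomainAnnotation],
    chain_length: Optional[int] = None,
) -> tuple[str, str]:
    """(module_name, functional_domain) of a residue, or the linker label."""
    if residue_number < 1:
        raise ValueError(f"residue number must be >= 1, got {residue_number}")
    if chain_length is not None and residue_number > chain_length:
        raise ValueError(f"residue {residue_number} beyond chain length {chain_length}")
    for ann in annotations:
        if ann.start <= residue_number <= ann.end:
            return ann.module_name, ann.functional_domain
    return LINKER_LABEL, LINKER_LABEL


def classify_topology(pair_id: str, fractions_observed: Iterable[str]) -> TopologyCall:
    """Intra/inter-molecular call from the set of SEC fractions a
    cross-link was observed in."""
    fr = frozenset(fractions_observed)
    if not fr:
        raise ValueError("fractions_observed must be non-empty")
    unknown = fr - {"monomer", "dimer", "unfractionated"}
    if unknown:
        raise ValueError(f"unknown fractions: {sorted(unknown)}")
    if "dimer" in fr:
        call = "intermolecular"
    elif "monomer" in fr:
        call = "intramolecular"
    else:
        call = "ambiguous"
    return TopologyCall(pair_id, fr, call)


def bin_rso(rso_percent: float) -> Optional[str]:
    """Occupancy bin label, or None for unmodified / trace (≤1%) sites."""
    for lo, hi, label in RSO_BINS:
        if lo < rso_percent <= hi:
            return label
    return None


def render_report(
    sites: pd.DataFrame,
    crosslinks: pd.DataFrame,
    annotations: Sequence[DomainAnnotation],
    chain_length: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Domain-level report of modification sites and cross-links.

    ``sites`` needs columns residue_number, residue, modification,
    rso_percent; ``crosslinks`` needs pair_id, residue_number_a,
    residue_number_b and optionally fractions (``;``-separated). Returns the
    binned site table, the cross-link table with module assignments and
    topology calls, and a plain-text schematic.
    """
    anns = validate_annotations(annotations)
    site_rows = []
    for r in sites.itertuples():
        module, domain = assign_site(int(r.residue_number), anns, chain_length)
        site_rows.append(
            {
                "residue_number": int(r.residue_number),
                "residue": r.residue,
                "modification": r.modification,
                "rso_percent": float(r.rso_percent),
                "rso_bin": bin_rso(float(r.rso_percent)),
                "module": module,
                "functional_domain": domain,
            }
        )
    site_df = pd.DataFrame(
        site_rows,
        columns=[
            "residue_number",
            "residue",
            "modification",
            "rso_percent",
            "rso_bin",
            "module",
            "functional_domain",
        ],
    ).sort_values("residue_number")

    xl_rows = []
    for r in crosslinks.itertuples():
        mod_a, dom_a = assign_site(int(r.residue_number_a), anns, chain_length)
        mod_b, dom_b = assign_site(int(r.residue_number_b), anns, chain_length)
        fractions = getattr(r, "fractions", "")
        topo = (
            classify_topology(str(r.pair_id), fractions.split(";")).call if fractions else ""
        )
        xl_rows.append(
            {
                "pair_id": str(r.pair_id),
                "residue_number_a": int(r.residue_number_a),
                "residue_number_b": int(r.residue_number_b),
                "module_a": mod_a,
                "module_b": mod_b,
                "functional_domain_a": dom_a,
                "functional_domain_b": dom_b,
                "topology": topo,
            }
        )
    xl_df = pd.DataFrame(
        xl_rows,
        columns=[
            "pair_id",
            "residue_number_a",
            "residue_number_b",
            "module_a",
            "module_b",
            "functional_domain_a",
            "functional_domain_b",
            "topology",
        ],
    )

    lines = ["Domain map of modification sites and cross-links", ""]
    for ann in anns:
        in_mod = site_df[(site_df.module == ann.module_name) & site_df.rso_bin.notna()]
        marks = " ".join(
            f"{r.residue}{r.residue_number}[{r.rso_bin}]" for r in in_mod.itertuples()
        )
        lines.append(
            f"{ann.module_name:>10} {ann.start:>5}-{ann.end:<5} {ann.functional_domain:<24} {marks}"
        )
    linker = site_df[(site_df.module == LINKER_LABEL) & site_df.rso_bin.notna()]
    if len(linker):
        marks = " ".join(f"{r.residue}{r.residue_number}[{r.rso_bin}]" for r in linker.itertuples())
        lines.append(f"{'linker':>10} {'':>11} {'':<24} {marks}")
    if len(xl_df):
        lines += ["", "Cross-links:"]
        for r in xl_df.itertuples():
            lines.append(
                f"  {r.pair_id}: {r.residue_number_a} ({r.module_a}) x "
                f"{r.residue_number_b} ({r.module_b}) {r.topology}"
            )
    return site_df.reset_index(drop=True), xl_df, "\n".join(lines)
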