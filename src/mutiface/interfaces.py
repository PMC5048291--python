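"""Interface catalog objects and mapping of variants onto contact positions.

An *interface* is the set of residues of one protein in contact with a
partner molecule (another protein, a small molecule or DNA/RNA) in a
structural template.  Variants landing on contact positions of a
non-excluded interface become interface-variant events — the unit every
downstream statistic counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

PARTNER_CLASSES = ("protein", "chemical", "dna_rna")

EVENT_COLUMNS = ["sample_id", "interface_id", "protein_id", "position", "ref_aa", "alt_aa"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue positions."""

    protein_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InterfaceDef:
    """One (protein, partner) interface.

    ``contacts`` maps 1-based positions of ``protein_id`` to the list of
    contact types each makes with the partner.  ``template_identity`` is the
    percent sequence identity of the protein to the structural template the
    interface was derived from; confidence tiers depend on it and on the
    partner class (see :func:`assign_confidence`).
    """

    interface_id: str
    protein_id: str
    partner_id: str
    partner_class: str
    contacts: Mapping[int, tuple[str, ...]]
    template_identity: float
    confidence: str = field(default="")

    def __post_init__(self):
        if self.partner_class not in PARTNER_CLASSES:
            raise ValueError(f"unknown partner class: {self.partner_class!r}")
        if not self.contacts:
            raise ValueError("interface has no contact positions")
        for pos, types in self.contacts.items():
            if pos < 1:
                raise ValueError(f"contact position must be 1-based: {pos}")
            if not types:
                raise ValueError(f"empty contact-type list at position {pos}")
        if not self.confidence:
            object.__setattr__(
                self,
                "confidence",
                assign_confidence(self.partner_class, self.template_identity),
            )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.contacts))

    def to_dict(self) -> dict:
        return {
            "interface_id": self.interface_id,
            "protein_id": self.protein_id,
            "partner_id": self.partner_id,
            "partner_class": self.partner_class,
            "contacts": {str(p): list(t) for p, t in self.contacts.items()},
            "template_identity": self.template_identity,
            "confidence": self.confidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InterfaceDef":
        return cls(
            interface_id=d["interface_id"],
            protein_id=d["protein_id"],
            partner_id=d["partner_id"],
            partner_class=d["partner_class"],
            contacts={int(p): tuple(t) for p, t in d["contacts"].items()},
            template_identity=float(d["template_identity"]),
            confidence=d.get("confidence", ""),
        )


def assign_confidence(partner_class: str, template_identity: float) -> str:
    """Confidence tier of an interface given its template identity.

    Protein–protein interfaces are kept only when derived from a template at
    >= 70% sequence identity (tier ``high``); anything lower is ``excluded``.
    Chemical and DNA/RNA binding sites are usually placed correctly even on
    remote templates, so they are retained down to 30% identity as
    ``medium_low`` (``high`` at >= 70%), and ``excluded`` below 30%.
    """
    if partner_class not in PARTNER_CLASSES:
        raise ValueError(f"unknown partner class: {partner_class!r}")
    if not 0.0 <= template_identity <= 100.0:
        raise ValueError("template identity must be in [0, 100]")
    if template_identity >= 70.0:
        return "high"
    if partner_class in ("chemical", "dna_rna") and template_identity >= 30.0:
        return "medium_low"
    return "excluded"


def map_variant_to_structure(
    position: int, alignment: Mapping[int, int | None]
) -> int | None:
    """Map a 1-based protein position to its template position.

    ``alignment`` covers every protein position; positions aligned to a gap
    map to ``None``.
    """
    if position < 1 or position not in alignment:
        raise ValueError(f"position {position} outside the aligned protein")
    return alignment[position]


def interface_residues_from_coords(
    coords_a: Mapping[int, np.ndarray],
    coords_b: Mapping[int, np.ndarray],
    cutoff: float = 5.0,
) -> tuple[set[int], set[int]]:
    """Contact residues of two chains under a heavy-atom distance cutoff.

    A residue of chain A is a contact iff any of its atoms lies within
    ``cutoff`` angstroms of any atom of chain B, and symmetrically for B.
    Coordinates enter as residue -> (n_atoms, 3) arrays.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not coords_a or not coords_b:
        raise ValueError("empty chain")

    def _stack(coords: Mapping[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        residues, atoms = [], []
        for res, xyz in coords.items():
            xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
            if not np.isfinite(xyz).all():
                raise ValueError("non-finite coordinates")
            residues.append(np.full(len(xyz), res))
            atoms.append(xyz)
        return np.concatenate(residues), np.vstack(atoms)

    res_a, xyz_a = _stack(coords_a)
    res_b, xyz_b = _stack(coords_b)
    close = cdist(xyz_a, xyz_b) <= cutoff
    contacts_a = set(res_a[close.any(axis=1)].tolist())
    contacts_b = set(res_b[close.any(axis=0)].tolist())
    return contacts_a, contacts_b


def contact_frame(catalog: Sequence[InterfaceDef]) -> pd.DataFrame:
    """Flatten non-excluded interfaces to (protein_id, position, interface_id)."""
    rows = [
        (iface.protein_id, pos, iface.interface_id)
        for iface in catalog
        if iface.confidence != "excluded"
        for pos in iface.contacts
    ]
    return pd.DataFrame(rows, columns=["protein_id", "position", "interface_id"])


def validate_variants(
    variants: pd.DataFrame, proteome: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Drop variants whose stated reference residue mismatches the sequence.

    Unknown proteins are an error; reference mismatches (isoform artefacts in
    real tables) are dropped with a logged count.
    """
    seqs = {p.protein_id: p.sequence for p in proteome}
    unknown = set(variants["protein_id"]) - set(seqs)
    if unknown:
        raise ValueError(f"variants reference unknown proteins: {sorted(unknown)[:5]}")
    ok = np.fromiter(
        (
            1 <= pos <= len(seqs[pid]) and seqs[pid][pos - 1] == ref
            for pid, pos, ref in zip(
                variants["protein_id"], variants["position"], variants["ref_aa"]
            )
        ),
        dtype=bool,
        count=len(variants),
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropped %d variants with reference-residue mismatches", n_bad)
    return variants.loc[ok].reset_index(drop=True)


def annotate_variants(
    variants: pd.DataFrame,
    catalog: Sequence[InterfaceDef],
    proteome: Sequence[ProteinRecord] | None = None,
    mode: str = "interface",
) -> pd.DataFrame:
    """Map variants onto interfaces, producing one event per hit.

    In ``interface`` mode a variant produces one event for every
    non-excluded interface of its protein whose contact positions include
    the variant position (a variant at a position shared by two interfaces
    yields two events).  In ``whole-protein`` control mode any variant on
    either protein of a protein–protein pair counts, regardless of position
    — the contrast that quantifies what interface knowledge adds over
    gene-level counting.

    Returns a frame with columns :data:`EVENT_COLUMNS`.
    """
    if mode not in ("interface", "whole-protein"):
        raise ValueError(f"unknown annotation mode: {mode!r}")
    if proteome is not None:
        variants = validate_variants(variants, proteome)
    cols = ["sample_id", "protein_id", "position", "ref_aa", "alt_aa"]
    v = variants[cols]

    if mode == "interface":
        cmap = contact_frame(catalog)
        events = v.merge(cmap, on=["protein_id", "position"], how="inner")
    else:
        rows = [
            (iface.protein_id, iface.interface_id)
            for iface in catalog
            if iface.confidence != "excluded"
        ] + [
            (iface.partner_id, iface.interface_id)
            for iface in catalog
            if iface.confidence != "excluded" and iface.partner_class == "protein"
        ]
        pmap = pd.DataFrame(rows, columns=["protein_id", "interface_id"]).drop_duplicates()
        events = v.merge(pmap, on="protein_id", how="inner")

    events = events[EVENT_COLUMNS]
    return events.sort_values(EVENT_COLUMNS, kind="mergesort").reset_index(drop=True)
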