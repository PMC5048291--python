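"""Statistical pair-potential scoring of interface substitutions.

A substitution at an interface residue is scored by how much it changes the
log-odds compatibility between the residue and the contact types it makes
with the partner molecule.  The potential is trained from a table of
(amino acid, contact type) co-occurrence counts observed in known
interfaces: with pseudocounted joint frequencies ``f(a, t)`` and marginals
``f(a)``, ``f(t)``,

    log_odds(a, t) = log2( f(a, t) / (f(a) * f(t)) )

and the score of mutating residue ``ref`` to ``alt`` at a position making
contacts ``T`` is ``sum_{t in T} [log_odds(alt, t) - log_odds(ref, t)]``.
Negative scores predict a disabling (interaction-weakening) change,
positive scores an enabling one.  Scores are antisymmetric in (ref, alt)
and additive along substitution paths by construction.

This scorer shares the sign convention and contract of interaction-score
servers used in the field but is trained on its own contact table; nothing
downstream depends on the specific trained values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Contact-type alphabets per partner class.  Protein partners use coarse
#: physicochemical classes of the contacted partner residue; chemical and
#: nucleic-acid partners use coarse moiety classes.
PROTEIN_CONTACT_TYPES: tuple[str, ...] = (
    "hydrophobic", "polar", "charged", "aromatic",
)
CHEMICAL_CONTACT_TYPES: tuple[str, ...] = (
    "metal", "nucleotide_moiety", "other_organic",
)
NUCLEIC_CONTACT_TYPES: tuple[str, ...] = (
    "base_A", "base_C", "base_G", "base_TU", "backbone",
)
ALL_CONTACT_TYPES: tuple[str, ...] = (
    PROTEIN_CONTACT_TYPES + CHEMICAL_CONTACT_TYPES + NUCLEIC_CONTACT_TYPES
)

CONTACT_TYPES_BY_CLASS: dict[str, tuple[str, ...]] = {
    "protein": PROTEIN_CONTACT_TYPES,
    "chemical": CHEMICAL_CONTACT_TYPES,
    "dna_rna": NUCLEIC_CONTACT_TYPES,
}


@dataclass(frozen=True)
class PairPotentialTable:
    """A trained (amino acid, contact type) log-odds potential.

    Attributes
    ----------
    counts : mapping (aa, contact_type) -> count
        The raw training counts (before pseudocounting).
    pseudocount : float
        Added to every cell of the full 20 x n_types grid before
        normalisation; guarantees finite log-odds.
    contact_types : tuple of str
        The contact-type alphabet of the table.
    log_odds : mapping (aa, contact_type) -> float
    """

    counts: Mapping[tuple[str, str], float]
    pseudocount: float
    contact_types: tuple[str, ...]
    log_odds: Mapping[tuple[str, str], float] = field(repr=False)

    def lo(self, aa: str, contact_type: str) -> float:
        try:
            return self.log_odds[(aa, contact_type)]
        except KeyError:
            raise ValueError(
                f"unknown (amino acid, contact type): ({aa!r}, {contact_type!r})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: amino_acid, contact_type, count, log_odds."""
        rows = [
            {
                "amino_acid": a,
                "contact_type": t,
                "count": float(self.counts.get((a, t), 0.0)),
                "log_odds": self.log_odds[(a, t)],
            }
            for a in AMINO_ACIDS
            for t in self.contact_types
        ]
        return pd.DataFrame(rows)


def train_pair_potential(
    contact_counts: Mapping[tuple[str, str], float],
    pseudocount: float = 1.0,
    contact_types: Sequence[str] | None = None,
) -> PairPotentialTable:
    """Train a log-odds pair potential from contact co-occurrence counts.

    Parameters
    ----------
    contact_counts : mapping (amino_acid, contact_type) -> count
        Non-negative counts; missing cells are treated as zero.
    pseudocount : float
        Positive; added to every cell of the full grid.
    contact_types : sequence of str, optional
        Alphabet of the table; defaults to :data:`ALL_CONTACT_TYPES`.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    types = tuple(contact_types) if contact_types is not None else ALL_CONTACT_TYPES
    if not types:
        raise ValueError("contact_types must be non-empty")
    for (a, t), v in contact_counts.items():
        if a not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid in counts: {a!r}")
        if t not in types:
            raise ValueError(f"unknown contact type in counts: {t!r}")
        if v < 0:
            raise ValueError(f"negative count for ({a}, {t})")
    if not any(v > 0 for v in contact_counts.values()):
        raise ValueError("contact count table has no positive entries")

    grid = np.full((len(AMINO_ACIDS), len(types)), pseudocount, dtype=float)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    t_index = {t: j for j, t in enumerate(types)}
    for (a, t), v in contact_counts.items():
        grid[aa_index[a], t_index[t]] += v

    f = grid / grid.sum()
    fa = f.sum(axis=1, keepdims=True)
    ft = f.sum(axis=0, keepdims=True)
    lo = np.log2(f / (fa * ft))

    log_odds = {
        (a, t): float(lo[i, j])
        for a, i in aa_index.items()
        for t, j in t_index.items()
    }
    return PairPotentialTable(
        counts=dict(contact_counts),
        pseudocount=float(pseudocount),
        contact_types=types,
        log_odds=log_odds,
    )


def site_score(
    ref_aa: str,
    alt_aa: str,
    contact_types: Iterable[str],
    table: PairPotentialTable,
) -> float:
    """Score a single-site substitution against the contacts it makes.

    Returns ``sum_t [log_odds(alt, t) - log_odds(ref, t)]``; negative values
    are disabling, positive enabling.
    """
    types = list(contact_types)
    if not types:
        raise ValueError("contact_types must be non-empty")
    if ref_aa not in AMINO_ACIDS or alt_aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid: {ref_aa!r} or {alt_aa!r}")
    return float(sum(table.lo(alt_aa, t) - table.lo(ref_aa, t) for t in types))


@dataclass(frozen=True)
class InterfacePerturbation:
    """Combined perturbation of one interface in one sample."""

    sample_id: str
    interface_id: str
    combined_score: float
    direction: str  # enabling | disabling | neutral
    n_sites: int


def _direction(score: float) -> str:
    if score > 0:
        return "enabling"
    if score < 0:
        return "disabling"
    return "neutral"


def combine_sample_interface(
    scored_events: Sequence[tuple[str, str, float]] | pd.DataFrame,
) -> InterfacePerturbation:
    """Combine the site scores of one (sample, interface) into one effect.

    When several variants hit the same interface in the same sample their
    site scores are summed; the sign of the sum gives the overall direction.

    Parameters
    ----------
    scored_events
        Either (sample_id, interface_id, site_score) tuples or a frame with
        those columns.  All events must share one (sample, interface).
    """
    if isinstance(scored_events, pd.DataFrame):
        rows = list(
            scored_events[["sample_id", "interface_id", "site_score"]].itertuples(
                index=False, name=None
            )
        )
    else:
        rows = list(scored_events)
    if not rows:
        raise ValueError("cannot combine an empty event set")
    samples = {r[0] for r in rows}
    interfaces = {r[1] for r in rows}
    if len(samples) != 1 or len(interfaces) != 1:
        raise ValueError("events span more than one (sample, interface)")
    total = float(math.fsum(r[2] for r in rows))
    return InterfacePerturbation(
        sample_id=rows[0][0],
        interface_id=rows[0][1],
        combined_score=total,
        direction=_direction(total),
        n_sites=len(rows),
    )


def score_events(
    events: pd.DataFrame,
    catalog: Sequence,
    table: PairPotentialTable,
) -> pd.DataFrame:
    """Attach a ``site_score`` column to an interface-event frame.

    ``events`` needs columns interface_id, position, ref_aa, alt_aa.  The
    contact types of each (interface, position) come from the catalog.
    Events at non-contact positions (whole-protein control mode) score 0.
    """
    by_id = {iface.interface_id: iface for iface in catalog}
    scores = np.empty(len(events), dtype=float)
    for k, row in enumerate(
        events[["interface_id", "position", "ref_aa", "alt_aa"]].itertuples(
            index=False, name=None
        )
    ):
        iface_id, pos, ref, alt = row
        iface = by_id[iface_id]
        types = iface.contacts.get(int(pos))
        scores[k] = 0.0 if not types else site_score(ref, alt, types, table)
    out = events.copy()
    out["site_score"] = scores
    return out


def perturbations_from_events(scored_events: pd.DataFrame) -> pd.DataFrame:
    """Aggregate scored events into per-(sample, interface) perturbations.

    Returns a frame with columns sample_id, interface_id, combined_score,
    direction, n_sites — one row per unique (sample, interface).
    """
    if scored_events.empty:
        return pd.DataFrame(
            columns=["sample_id", "interface_id", "combined_score", "direction", "n_sites"]
        )
    g = scored_events.groupby(["sample_id", "interface_id"], sort=True)
    agg = g.agg(combined_score=("site_score", "sum"), n_sites=("site_score", "size"))
    agg = agg.reset_index()
    agg["direction"] = [
        _direction(s) for s in agg["combined_score"].to_numpy()
    ]
    return agg[["sample_id", "interface_id", "combined_score", "direction", "n_sites"]]
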