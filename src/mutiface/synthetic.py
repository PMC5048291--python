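"""Synthetic cohorts with planted structure for end-to-end validation.

Emulates the four inputs of the analysis at desk scale: a proteome, an
interface catalog, a somatic-missense cohort (passenger background plus
planted interface drivers and mutually exclusive pairs), and a clinical
donor table with planted group hazards.  All planted structure is exact by
construction — a driver planted in 30 samples occupies exactly 30 — so
recovery by the downstream statistics is a sharp test, not a stochastic one.

Passenger variants are exchangeable across the positions of a protein,
which is precisely the null the shuffled background models assume.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interfaces import InterfaceDef, ProteinRecord, assign_confidence
from .scoring import (
    AMINO_ACIDS,
    CONTACT_TYPES_BY_CLASS,
    ALL_CONTACT_TYPES,
    PairPotentialTable,
    site_score,
    train_pair_potential,
)

VARIANT_COLUMNS = [
    "sample_id", "protein_id", "position", "ref_aa", "alt_aa",
    "primary_tissue", "histology",
]

CHEMICAL_PARTNERS = ("GTP", "ATP", "ZN", "MG", "CA", "NAD", "HEME")
NUCLEIC_PARTNERS = ("DNA", "RNA")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class CohortSpec:
    """Conditions of one synthetic cohort.

    planted_drivers: (interface_id, fraction of all samples, direction)
    triples; direction is "enabling" or "disabling".  exclusivity_pairs name
    pairs of planted interfaces whose driver-bearing sample sets must be
    disjoint.
    """

    n_samples: int
    cancer_types: Sequence[tuple[str, str]]
    background_rate: float
    planted_drivers: Sequence[tuple[str, float, str]] = field(default_factory=list)
    exclusivity_pairs: Sequence[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not self.cancer_types:
            raise ValueError("at least one cancer type required")
        for iface, frac, direction in self.planted_drivers:
            if not 0 < frac <= 1:
                raise ValueError(f"planted fraction for {iface} not in (0, 1]: {frac}")
            if direction not in ("enabling", "disabling"):
                raise ValueError(f"unknown forced direction: {direction!r}")
        planted = {i for i, _, _ in self.planted_drivers}
        for a, b in self.exclusivity_pairs:
            if a not in planted or b not in planted:
                raise ValueError(
                    f"exclusivity pair ({a}, {b}) must reference planted drivers"
                )


@dataclass
class ClinicalSpec:
    """Survival-time model for a synthetic donor table.

    Times are exponential with hazard = baseline_hazard x group multiplier x
    exp(beta_age * (age - 60) + beta_sex * [sex == female]); a
    ``censoring_fraction`` of donors is right-censored uniformly before
    their event time (censored donors are recorded alive).
    """

    group_hazards: Mapping[str, float]
    baseline_hazard: float = 0.01
    censoring_fraction: float = 0.2
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0}
    )
    remission_prob: float = 0.6  # P(complete remission | alive)

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if any(h <= 0 for h in self.group_hazards.values()):
            raise ValueError("group hazard multipliers must be > 0")
        if not 0.0 <= self.censoring_fraction <= 1.0:
            raise ValueError("censoring_fraction must be in [0, 1]")


def generate_proteome(
    n_proteins: int,
    length: int | tuple[int, int],
    seed,
    composition: Mapping[str, float] | None = None,
) -> list[ProteinRecord]:
    """I.i.d. protein sequences over a stated amino-acid composition.

    ``length`` is a fixed residue count or an inclusive (lo, hi) range
    sampled uniformly per protein; the default composition is uniform over
    the 20 letters (a neutral background for the shuffle nulls).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = (length, length) if isinstance(length, int) else (int(length[0]), int(length[1]))
    if lo < 10:
        raise ValueError("protein lengths must be >= 10")
    rng = _rng(seed)
    if composition is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([composition.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("composition must have positive mass")
        probs = probs / probs.sum()
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    out = []
    for i in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=n, p=probs))
        out.append(ProteinRecord(protein_id=f"P{i + 1:04d}", sequence=seq))
    return out


def generate_contact_counts(
    seed,
    contact_types: Sequence[str] = ALL_CONTACT_TYPES,
    total: int = 100_000,
    spread: float = 0.6,
) -> dict[tuple[str, str], int]:
    """A synthetic (amino acid, contact type) co-occurrence count table.

    Cell weights are log-normal with the given log-scale ``spread``, so the
    trained potential has log-odds of both signs at essentially every
    position — required for forcing planted driver directions.
    """
    rng = _rng(seed)
    w = rng.lognormal(mean=0.0, sigma=spread, size=(20, len(contact_types)))
    w = w / w.sum() * total
    return {
        (a, t): int(round(w[i, j]))
        for i, a in enumerate(AMINO_ACIDS)
        for j, t in enumerate(contact_types)
    }


def generate_interface_catalog(
    proteome: Sequence[ProteinRecord],
    n_interfaces: int,
    positions_per_interface: int,
    partner_class_mix: Mapping[str, float] | None = None,
    seed=0,
    identity_range: tuple[float, float] = (70.0, 100.0),
    contact_types_per_position: int = 2,
) -> list[InterfaceDef]:
    """Random interfaces over a proteome.

    Each interface names ``positions_per_interface`` distinct positions of
    one protein, a partner drawn per the class mix, a template identity
    uniform over ``identity_range`` and 1–``contact_types_per_position``
    contact types per position from the partner class's alphabet.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if n_interfaces < 1:
        raise ValueError("n_interfaces must be >= 1")
    min_len = min(p.length for p in proteome)
    if positions_per_interface > min_len:
        raise ValueError("positions_per_interface exceeds the shortest protein")
    mix = dict(partner_class_mix or {"protein": 0.5, "chemical": 0.4, "dna_rna": 0.1})
    classes = [c for c in ("protein", "chemical", "dna_rna") if mix.get(c, 0) > 0]
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    rng = _rng(seed)

    catalog = []
    for k in range(n_interfaces):
        prot = proteome[int(rng.integers(len(proteome)))]
        positions = rng.choice(prot.length, size=positions_per_interface, replace=False) + 1
        pclass = classes[int(rng.choice(len(classes), p=probs))]
        if pclass == "protein":
            partner = proteome[int(rng.integers(len(proteome)))].protein_id
        elif pclass == "chemical":
            partner = CHEMICAL_PARTNERS[int(rng.integers(len(CHEMICAL_PARTNERS)))]
        else:
            partner = NUCLEIC_PARTNERS[int(rng.integers(len(NUCLEIC_PARTNERS)))]
        alphabet = CONTACT_TYPES_BY_CLASS[pclass]
        contacts = {}
        for pos in sorted(int(p) for p in positions):
            n_t = int(rng.integers(1, contact_types_per_position + 1))
            types = rng.choice(len(alphabet), size=min(n_t, len(alphabet)), replace=False)
            contacts[pos] = tuple(alphabet[j] for j in sorted(types))
        identity = float(rng.uniform(*identity_range))
        catalog.append(
            InterfaceDef(
                interface_id=f"IF{k + 1:04d}",
                protein_id=prot.protein_id,
                partner_id=partner,
                partner_class=pclass,
                contacts=contacts,
                template_identity=identity,
                confidence=assign_confidence(pclass, identity),
            )
        )
    return catalog


def _driver_candidates(
    iface: InterfaceDef,
    sequence: str,
    direction: str,
    table: PairPotentialTable,
) -> list[tuple[int, str, str]]:
    """All (position, ref, alt) substitutions on the interface with the
    requested score sign."""
    want = 1 if direction == "enabling" else -1
    out = []
    for pos, types in iface.contacts.items():
        ref = sequence[pos - 1]
        for alt in AMINO_ACIDS:
            if alt == ref:
                continue
            s = site_score(ref, alt, types, table)
            if (s > 0) - (s < 0) == want:
                out.append((pos, ref, alt))
    return out


def generate_cohort(
    proteome: Sequence[ProteinRecord],
    catalog: Sequence[InterfaceDef],
    spec: CohortSpec,
    table: PairPotentialTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A cohort of samples with passenger background and planted drivers.

    Passengers are placed uniformly over all residue positions of the
    proteome (Poisson(``background_rate``) per sample) with alternates
    uniform over the 19 non-reference letters.  Each planted driver
    interface receives, in an exact ``round(fraction * N)`` samples, one
    variant at one of its contact positions whose alternate forces the
    requested direction (an error if no such substitution exists).
    Exclusivity pairs get disjoint sample subsets.

    Returns (variants, samples): samples carries the cancer-type labels and
    boolean ``planted_<interface>`` ground-truth columns.
    """
    by_id = {iface.interface_id: iface for iface in catalog}
    for iface_id, _, _ in spec.planted_drivers:
        if iface_id not in by_id:
            raise ValueError(f"planted interface {iface_id} not in catalog")
    if table is None:
        table = train_pair_potential(generate_contact_counts(spec.seed))
    rng = _rng(spec.seed)
    seqs = {p.protein_id: p.sequence for p in proteome}

    n_total = spec.n_samples * len(spec.cancer_types)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]
    tissues, histologies = [], []
    for tissue, histology in spec.cancer_types:
        tissues += [tissue] * spec.n_samples
        histologies += [histology] * spec.n_samples
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "primary_tissue": tissues, "histology": histologies}
    )

    # choose planted sample sets, honouring exclusivity disjointness
    partner_of: dict[str, list[str]] = {}
    for a, b in spec.exclusivity_pairs:
        partner_of.setdefault(a, []).append(b)
        partner_of.setdefault(b, []).append(a)
    chosen: dict[str, np.ndarray] = {}
    for iface_id, frac, _ in spec.planted_drivers:
        n_chosen = int(round(frac * n_total))
        blocked: set[int] = set()
        for other in partner_of.get(iface_id, []):
            if other in chosen:
                blocked.update(chosen[other].tolist())
        pool = np.array([i for i in range(n_total) if i not in blocked])
        if n_chosen > len(pool):
            raise ValueError(
                f"cannot plant {iface_id} in {n_chosen} samples: only "
                f"{len(pool)} samples remain outside its exclusive partners"
            )
        chosen[iface_id] = np.sort(rng.choice(pool, size=n_chosen, replace=False))

    rows: list[tuple] = []
    # planted drivers: one variant per (sample, interface)
    for iface_id, _, direction in spec.planted_drivers:
        iface = by_id[iface_id]
        cands = _driver_candidates(iface, seqs[iface.protein_id], direction, table)
        if not cands:
            raise ValueError(
                f"no {direction} substitution exists on {iface_id}; "
                "cannot force the requested direction"
            )
        for idx in chosen[iface_id]:
            pos, ref, alt = cands[int(rng.integers(len(cands)))]
            rows.append((sample_ids[idx], iface.protein_id, pos, ref, alt,
                         tissues[idx], histologies[idx]))
        samples[f"planted_{iface_id}"] = [i in set(chosen[iface_id].tolist())
                                          for i in range(n_total)]

    # passenger background: uniform over the concatenated position space
    prot_ids = [p.protein_id for p in proteome]
    lengths = np.array([p.length for p in proteome])
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total_pos = int(cum[-1])
    counts = rng.poisson(spec.background_rate, size=n_total)
    for i, k in enumerate(counts):
        if k == 0:
            continue
        flat = rng.integers(total_pos, size=k)
        for f in flat:
            j = int(np.searchsorted(cum, f, side="right") - 1)
            pos = int(f - cum[j]) + 1
            ref = seqs[prot_ids[j]][pos - 1]
            alt = AMINO_ACIDS.replace(ref, "")[int(rng.integers(19))]
            rows.append((sample_ids[i], prot_ids[j], pos, ref, alt,
                         tissues[i], histologies[i]))

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    variants = variants.sort_values(VARIANT_COLUMNS, kind="mergesort").reset_index(drop=True)
    return variants, samples


def generate_clinical(
    samples: pd.DataFrame,
    group_assignment: Mapping[str, str] | pd.Series,
    spec: ClinicalSpec,
    seed=0,
) -> pd.DataFrame:
    """Donor outcomes for a cohort under planted group hazards.

    Every sample must carry a group label present in
    ``spec.group_hazards``.  Censored donors are recorded alive; deceased
    donors carry disease status "other", alive donors remit completely with
    probability ``spec.remission_prob``.
    """
    groups = pd.Series(group_assignment)
    missing = set(samples["sample_id"]) - set(groups.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
    unknown = set(groups.loc[samples["sample_id"]]) - set(spec.group_hazards)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")

    rng = _rng(seed)
    n = len(samples)
    age = np.clip(np.round(rng.normal(60, 12, size=n)), 20, 90).astype(int)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    g = groups.loc[samples["sample_id"]].to_numpy()
    beta_age = float(spec.covariate_effects.get("age", 0.0))
    beta_sex = float(spec.covariate_effects.get("sex", 0.0))
    mult = np.array([spec.group_hazards[x] for x in g])
    hazard = (
        spec.baseline_hazard
        * mult
        * np.exp(beta_age * (age - 60) + beta_sex * (sex == "female"))
    )
    times = rng.exponential(1.0 / hazard)

    n_cens = int(round(spec.censoring_fraction * n))
    cens_idx = rng.choice(n, size=n_cens, replace=False)
    event = np.ones(n, dtype=bool)
    event[cens_idx] = False
    times = times.copy()
    times[cens_idx] = times[cens_idx] * rng.random(n_cens)

    vital = np.where(event, "deceased", "alive")
    remits = rng.random(n) < spec.remission_prob
    disease = np.where(~event & remits, "complete_remission", "other")

    clinical = pd.DataFrame(
        {
            "donor_id": ["D" + s for s in samples["sample_id"]],
            "sample_id": samples["sample_id"].to_numpy(),
            "age": age,
            "sex": sex,
            "primary_tissue": samples["primary_tissue"].to_numpy(),
            "histology": samples["histology"].to_numpy(),
            "group": g,
            "vital_status": vital,
            "disease_status": disease,
            "survival_time": times,
            "event_observed": event,
        }
    )
    return clinical
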