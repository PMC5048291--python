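"""End-to-end orchestration: simulate -> annotate -> score -> enrich ->
profiles -> subtypes -> survival, under one config and one root seed.

Every stage's randomness derives from the root seed through a
``numpy.random.SeedSequence`` spawn, so each intermediate table is
reproducible on its own; rerunning with the same config and seed writes
byte-identical TSVs.  A manifest records seeds, thresholds and row counts
per stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .clinical import (
    cox_hazard,
    km_logrank,
    match_donors,
    perturbation_groups,
    status_association,
    survival_ranksum,
)
from .enrichment import call_significant, compute_enrichment
from .interfaces import annotate_variants
from .profiles import (
    DIFFERENTIAL_TEST_NOTE,
    build_matrix,
    cancer_type_label,
    differential_across_cancers,
    select_display_set,
)
from .scoring import perturbations_from_events, score_events, train_pair_potential
from .subtypes import build_profiles, cluster_samples, mutual_exclusivity
from .synthetic import (
    ClinicalSpec,
    CohortSpec,
    generate_clinical,
    generate_cohort,
    generate_contact_counts,
    generate_interface_catalog,
    generate_proteome,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "enrich", "profiles", "subtypes", "clinical")


@dataclass
class RunConfig:
    """All knobs of a full run; serialized into the output directory."""

    outdir: str = "run"
    seed: int = 0
    # cohort
    n_proteins: int = 30
    protein_length: int = 200
    n_interfaces: int = 40
    positions_per_interface: int = 6
    partner_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"protein": 0.5, "chemical": 0.4, "dna_rna": 0.1}
    )
    n_samples_per_type: int = 75
    cancer_types: Sequence[Sequence[str]] = field(
        default_factory=lambda: [
            ["lung", "adenocarcinoma"],
            ["lung", "squamous_cell_carcinoma"],
            ["breast", "ductal_carcinoma"],
            ["large_intestine", "adenocarcinoma"],
        ]
    )
    background_rate: float = 3.0
    planted_drivers: Sequence[Sequence] = field(
        default_factory=lambda: [
            ["IF0001", 0.30, "disabling"],
            ["IF0002", 0.30, "enabling"],
            ["IF0003", 0.25, "disabling"],
        ]
    )
    exclusivity_pairs: Sequence[Sequence[str]] = field(
        default_factory=lambda: [["IF0001", "IF0002"]]
    )
    # thresholds
    q_max: float = 0.01
    min_samples: int = 20
    replicates: int = 5
    background_mode: str = "interface"
    top_types: int = 30
    top_pairs: int = 30
    depth_cutoff: float = 0.9
    cluster_metric: str = "correlation"
    exclusivity_q: float = 0.1
    mutex_min_pan: int = 20
    mutex_min_per_cancer: int = 10
    differential_min_per_type: int = 5
    # clinical
    baseline_hazard: float = 0.01
    group_hazards: Mapping[str, float] = field(
        default_factory=lambda: {"IF0001": 2.0, "IF0002": 1.0, "none": 1.0}
    )
    censoring_fraction: float = 0.2
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0}
    )
    stages: Sequence[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self):
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if not 0 < self.exclusivity_q <= 1:
            raise ValueError("exclusivity_q must be in (0, 1]")
        if self.min_samples < 0 or self.replicates < 1:
            raise ValueError("min_samples must be >= 0 and replicates >= 1")
        if self.depth_cutoff <= 0:
            raise ValueError("depth_cutoff must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))


def demo_config(outdir: str = "run", seed: int = 0) -> RunConfig:
    """The bundled demonstration configuration."""
    from importlib.resources import files

    d = json.loads(files("mutiface").joinpath("data/demo_config.json").read_text())
    d["outdir"] = outdir
    d["seed"] = seed
    return RunConfig.from_dict(d)


def validate_inputs(tables: Mapping[str, pd.DataFrame]) -> dict:
    """Schema and referential-integrity report over the run's tables.

    Checks required columns per table, that variants and clinical rows
    reference known samples (and variants known proteins when a proteome
    table is given), and flags negative survival times.  Returns
    ``{"violations": [...], "counts": {...}}``.
    """
    required = {
        "samples": ["sample_id", "primary_tissue", "histology"],
        "variants": ["sample_id", "protein_id", "position", "ref_aa", "alt_aa"],
        "clinical": ["sample_id", "survival_time", "vital_status"],
        "proteome": ["protein_id", "sequence"],
    }
    violations: list[str] = []
    counts = {name: len(df) for name, df in tables.items()}
    for name, df in tables.items():
        for col in required.get(name, []):
            if col not in df.columns:
                violations.append(f"{name}: missing column {col}")
    if not any(v.startswith("variants: missing") for v in violations):
        if "variants" in tables and "samples" in tables:
            unknown = set(tables["variants"]["sample_id"]) - set(tables["samples"]["sample_id"])
            violations += [f"variants: unknown sample {s}" for s in sorted(unknown)]
        if "variants" in tables and "proteome" in tables:
            unknown = set(tables["variants"]["protein_id"]) - set(tables["proteome"]["protein_id"])
            violations += [f"variants: unknown protein {p}" for p in sorted(unknown)]
    if "clinical" in tables and "survival_time" in tables["clinical"].columns:
        n_neg = int((tables["clinical"]["survival_time"] < 0).sum())
        if n_neg:
            violations.append(f"clinical: {n_neg} rows with negative survival time")
    if "clinical" in tables and "samples" in tables and "sample_id" in tables["clinical"].columns:
        unknown = set(tables["clinical"]["sample_id"]) - set(tables["samples"]["sample_id"])
        violations += [f"clinical: unknown sample {s}" for s in sorted(unknown)]
    return {"violations": violations, "counts": counts}


def _spawn_seeds(root_seed: int, n: int) -> list[int]:
    # keep derived seeds in int32 range for portability
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage, writing tables and a manifest to outdir.

    Returns the manifest.  Any stage failure aborts with the failing stage
    named in the raised error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    seeds = dict(zip(STAGES, _spawn_seeds(config.seed, len(STAGES))))
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": {
            "q_max": config.q_max,
            "min_samples": config.min_samples,
            "replicates": config.replicates,
            "depth_cutoff": config.depth_cutoff,
            "cluster_metric": config.cluster_metric,
            "exclusivity_q": config.exclusivity_q,
        },
        "notes": [DIFFERENTIAL_TEST_NOTE],
        "stages": {},
        "row_counts": {},
    }
    state: dict = {}
    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, seeds[stage], out, state, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_simulate(config, seed, out, state, manifest):
    proteome = generate_proteome(config.n_proteins, config.protein_length, seed)
    counts = generate_contact_counts(seed + 1)
    table = train_pair_potential(counts)
    catalog = generate_interface_catalog(
        proteome,
        config.n_interfaces,
        config.positions_per_interface,
        dict(config.partner_class_mix),
        seed=seed + 2,
    )
    spec = CohortSpec(
        n_samples=config.n_samples_per_type,
        cancer_types=[tuple(t) for t in config.cancer_types],
        background_rate=config.background_rate,
        planted_drivers=[tuple(d) for d in config.planted_drivers],
        exclusivity_pairs=[tuple(p) for p in config.exclusivity_pairs],
        seed=seed + 3,
    )
    variants, samples = generate_cohort(proteome, catalog, spec, table=table)

    group = pd.Series("none", index=samples["sample_id"], name="group")
    for iface in config.group_hazards:
        col = f"planted_{iface}"
        if col in samples.columns:
            group[samples.loc[samples[col].to_numpy(), "sample_id"]] = iface
    cspec = ClinicalSpec(
        group_hazards=dict(config.group_hazards),
        baseline_hazard=config.baseline_hazard,
        censoring_fraction=config.censoring_fraction,
        covariate_effects=dict(config.covariate_effects),
    )
    clin = generate_clinical(samples, group, cspec, seed=seed + 4)

    report = validate_inputs(
        {
            "samples": samples,
            "variants": variants,
            "clinical": clin,
            "proteome": pd.DataFrame(
                {"protein_id": [p.protein_id for p in proteome],
                 "sequence": [p.sequence for p in proteome]}
            ),
        }
    )
    if report["violations"]:
        raise ValueError(f"generated tables failed validation: {report['violations'][:5]}")

    mio.write_proteome(proteome, out / "proteome.fasta")
    mio.write_catalog(catalog, out / "catalog.json")
    mio.write_contact_counts(counts, out / "contact_counts.tsv")
    mio.write_potential(table, out / "pair_potential.tsv")
    mio.write_variants(variants, out / "variants.tsv")
    mio.write_tsv(samples, out / "samples.tsv")
    mio.write_clinical(clin, out / "clinical.tsv")
    state.update(
        proteome=proteome, catalog=catalog, table=table, variants=variants,
        samples=samples, clinical=clin,
    )
    manifest["row_counts"].update(
        variants=len(variants), samples=len(samples), clinical=len(clin),
        interfaces=len(catalog),
    )


def _stage_annotate(config, seed, out, state, manifest):
    events = annotate_variants(state["variants"], state["catalog"], state["proteome"])
    scored = score_events(events, state["catalog"], state["table"])
    pert = perturbations_from_events(scored)
    mio.write_tsv(scored, out / "events.tsv")
    mio.write_tsv(pert, out / "perturbations.tsv")
    state.update(events=scored, perturbations=pert)
    manifest["row_counts"].update(events=len(scored), perturbations=len(pert))


def _stage_enrich(config, seed, out, state, manifest):
    enr = compute_enrichment(
        state["variants"], state["proteome"], state["catalog"],
        n_samples=len(state["samples"]), seed=seed,
        replicates=config.replicates, q_max=config.q_max,
        min_samples=config.min_samples, mode=config.background_mode,
    )
    sig = call_significant(enr, q_max=config.q_max, min_samples=config.min_samples)
    mio.write_tsv(enr, out / "enrichment.tsv")
    mio.write_tsv(sig, out / "significant_interfaces.tsv")
    state.update(enrichment=enr, significant=sig)
    manifest["row_counts"].update(enrichment=len(enr), significant=len(sig))


def _stage_profiles(config, seed, out, state, manifest):
    labels = cancer_type_label(state["samples"])
    sample_types = pd.Series(labels.to_numpy(), index=state["samples"]["sample_id"])
    matrix = build_matrix(state["perturbations"], sample_types)
    type_sizes = sample_types.value_counts()
    display = select_display_set(
        matrix, state["enrichment"], type_sizes,
        top_types=config.top_types, top_pairs=config.top_pairs,
        min_samples=config.min_samples, q_max=config.q_max,
    )
    diff = differential_across_cancers(
        state["perturbations"], sample_types,
        min_per_type=config.differential_min_per_type,
    )
    mio.write_tsv(matrix.to_cell_frame(), out / "fingerprint_matrix.tsv", index=True)
    mio.write_tsv(display.to_cell_frame(), out / "display_matrix.tsv", index=True)
    (out / "display_matrix.provenance.json").write_text(
        json.dumps(display.provenance, indent=1, sort_keys=True)
    )
    diff_frame = diff.reset_index()
    diff_frame.insert(0, "note", DIFFERENTIAL_TEST_NOTE)
    mio.write_tsv(diff_frame[["interface_id", "p_differential", "note"]],
                  out / "differential_interfaces.tsv")
    state.update(matrix=matrix, display=display, sample_types=sample_types)
    manifest["row_counts"].update(
        matrix_interfaces=len(matrix.interfaces),
        display_interfaces=len(display.interfaces),
        differential=int(diff.notna().sum()),
    )


def _stage_subtypes(config, seed, out, state, manifest):
    profiles = build_profiles(state["perturbations"])
    clusters = cluster_samples(
        profiles, depth_cutoff=config.depth_cutoff, metric=config.cluster_metric
    )
    sig_ids = list(state["significant"]["interface_id"]) if len(state["significant"]) else None
    mutex = mutual_exclusivity(
        state["perturbations"], state["samples"], scope="pan-cancer",
        min_samples=config.mutex_min_pan, interface_ids=sig_ids,
        q_max=config.exclusivity_q,
    )
    mutex_pc = mutual_exclusivity(
        state["perturbations"], state["samples"], scope="per-cancer",
        min_samples=config.mutex_min_per_cancer, interface_ids=sig_ids,
        q_max=config.exclusivity_q,
    )
    mio.write_tsv(profiles, out / "sample_profiles.tsv", index=True)
    mio.write_tsv(clusters.reset_index().rename(columns={"index": "sample_id"}),
                  out / "clusters.tsv")
    mio.write_tsv(mutex, out / "mutual_exclusivity_pan.tsv")
    mio.write_tsv(mutex_pc, out / "mutual_exclusivity_per_cancer.tsv")
    state.update(clusters=clusters, mutex=mutex)
    manifest["row_counts"].update(
        clusters=int(clusters.nunique()), mutex_pairs=len(mutex),
        mutex_pairs_per_cancer=len(mutex_pc),
    )


def _stage_clinical(config, seed, out, state, manifest):
    pair = tuple(config.exclusivity_pairs[0]) if config.exclusivity_pairs else None
    clin = state["clinical"].copy()
    clin["cancer_type"] = cancer_type_label(clin)
    joined = match_donors(
        state["samples"][["sample_id"]],
        clin[["donor_id", "sample_id", "age", "sex", "vital_status",
              "disease_status", "survival_time", "cancer_type"]],
    )
    rows = []
    if pair is not None:
        groups = perturbation_groups(state["perturbations"], pair[0], pair[1])
        sub = joined[joined["sample_id"].isin(groups.index)].copy()
        sub["group"] = groups.loc[sub["sample_id"]].to_numpy()
        if sub["group"].nunique() == 2:
            a_mask = sub["group"] == pair[0]
            status_p = status_association(sub["group"], sub["vital_status"])
            u_stat, ranksum_p = survival_ranksum(
                sub.loc[a_mask, "survival_time"], sub.loc[~a_mask, "survival_time"]
            )
            comp = km_logrank(sub["survival_time"], sub["event_observed"], sub["group"])
            cox = cox_hazard(sub, "group")
            head = cox.index[0]
            rows.append(
                {
                    "contrast": f"{pair[0]}_vs_{pair[1]}",
                    "n_a": int(a_mask.sum()), "n_b": int((~a_mask).sum()),
                    "status_fisher_p": status_p,
                    "ranksum_U": u_stat, "ranksum_p": ranksum_p,
                    "logrank_p": comp.logrank_p,
                    "cox_log_hr": float(cox.loc[head, "coef"]),
                    "cox_hr": float(cox.loc[head, "exp(coef)"]),
                    "cox_hr_ci_low": float(cox.loc[head, "exp(coef) lower 95%"]),
                    "cox_hr_ci_high": float(cox.loc[head, "exp(coef) upper 95%"]),
                    "cox_p": float(cox.loc[head, "p"]),
                }
            )
            for lab, curve in comp.km_curves.items():
                mio.write_tsv(curve, out / f"km_{lab}.tsv")
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        from .enrichment import bh_fdr

        contrasts["logrank_q"] = bh_fdr(contrasts["logrank_p"].to_numpy())
    mio.write_tsv(joined, out / "clinical_matched.tsv")
    mio.write_tsv(contrasts, out / "survival_contrasts.tsv")
    state.update(contrasts=contrasts)
    manifest["row_counts"].update(
        clinical_matched=len(joined), survival_contrasts=len(contrasts)
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
    "profiles": _stage_profiles,
    "subtypes": _stage_subtypes,
    "clinical": _stage_clinical,
}
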