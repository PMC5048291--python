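"""Significantly perturbed interfaces via shuffled backgrounds.

Two permutation null models estimate how often each interface would be hit
if the observed substitutions carried no positional signal:

* **BM1** reassigns every observed substitution to a random position of the
  same protein bearing the same reference amino acid (preserving each
  protein's (ref, alt) multiset and each sample's variant count);
* **BM2** reassigns it to any position of the same protein, with the
  reference read off the sequence and a random non-reference alternate.

The per-interface background rate Pr feeds an upper-tail binomial test of
the observed count of unique perturbed samples c out of N cohort samples,
P(X >= c), X ~ Binomial(N, Pr); p-values are Benjamini–Hochberg adjusted
per background model, and an interface is called significant when q <= 0.01
under *both* models and c >= 20 unique samples (both thresholds
configurable; 10 is the conventional relaxed sample threshold).

Pr uses a (mean background count + 1) / (N + 1) pseudocount so interfaces
never hit in the background still receive a finite, conservative rate.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interfaces import InterfaceDef, ProteinRecord, annotate_variants
from .scoring import AMINO_ACIDS

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _positions_by_residue(proteome: Sequence[ProteinRecord]) -> dict[tuple[str, str], np.ndarray]:
    out: dict[tuple[str, str], list[int]] = {}
    for p in proteome:
        for i, aa in enumerate(p.sequence):
            out.setdefault((p.protein_id, aa), []).append(i + 1)
    return {k: np.array(v) for k, v in out.items()}


def shuffle_bm1(
    variants: pd.DataFrame, proteome: Sequence[ProteinRecord], seed
) -> pd.DataFrame:
    """Background model 1: same protein, same reference residue.

    Each variant keeps its sample, protein, ref and alt; its position is
    resampled uniformly among the positions of the protein whose residue
    equals ref.  Variants whose protein lacks the reference anywhere
    (malformed input) are dropped with a warning.
    """
    rng = _rng(seed)
    pools = _positions_by_residue(proteome)
    out = variants.reset_index(drop=True).copy()
    new_pos = out["position"].to_numpy().copy()
    keep = np.ones(len(out), dtype=bool)
    for (pid, ref), idx in out.groupby(["protein_id", "ref_aa"], sort=True).groups.items():
        pool = pools.get((pid, ref))
        idx = np.asarray(idx)
        if pool is None or len(pool) == 0:
            keep[idx] = False
            continue
        new_pos[idx] = pool[rng.integers(len(pool), size=len(idx))]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("BM1: dropped %d variants with no same-residue position", n_drop)
    out["position"] = new_pos
    return out.loc[keep].reset_index(drop=True)


def shuffle_bm2(
    variants: pd.DataFrame, proteome: Sequence[ProteinRecord], seed
) -> pd.DataFrame:
    """Background model 2: any position of the same protein, random change.

    Each variant keeps its sample and protein; the position is uniform over
    the protein, the reference is read off the sequence there and the
    alternate is uniform over the 19 non-reference letters.
    """
    rng = _rng(seed)
    seqs = {p.protein_id: p.sequence for p in proteome}
    out = variants.reset_index(drop=True).copy()
    new_pos = out["position"].to_numpy().copy()
    new_ref = out["ref_aa"].to_numpy().copy().astype(object)
    new_alt = out["alt_aa"].to_numpy().copy().astype(object)
    for pid, idx in out.groupby("protein_id", sort=True).groups.items():
        seq = seqs[pid]
        idx = np.asarray(idx)
        pos = rng.integers(1, len(seq) + 1, size=len(idx))
        alt_i = rng.integers(19, size=len(idx))
        for k, (p, ai) in enumerate(zip(pos, alt_i)):
            ref = seq[p - 1]
            new_pos[idx[k]] = p
            new_ref[idx[k]] = ref
            new_alt[idx[k]] = AMINO_ACIDS.replace(ref, "")[ai]
    out["position"] = new_pos
    out["ref_aa"] = new_ref
    out["alt_aa"] = new_alt
    return out


def estimate_background_rate(
    background_event_sets: Sequence[pd.DataFrame],
    n_samples: int,
    interface_ids: Sequence[str],
) -> pd.Series:
    """Per-interface background perturbation probability.

    ``Pr = (mean unique background samples with an event + 1) / (N + 1)``,
    averaged over replicate background event sets and clamped to <= 1; the
    pseudocount keeps Pr strictly positive for never-hit interfaces.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not background_event_sets:
        raise ValueError("at least one background event set required")
    acc = pd.Series(0.0, index=pd.Index(interface_ids, name="interface_id"))
    for events in background_event_sets:
        if len(events):
            counts = events.groupby("interface_id")["sample_id"].nunique()
            acc = acc.add(counts.reindex(acc.index, fill_value=0), fill_value=0.0)
    mean = acc / len(background_event_sets)
    pr = (mean + 1.0) / (n_samples + 1.0)
    return pr.clip(upper=1.0)


def binomial_pvalue(n_samples: int, c: int, pr: float) -> float:
    """Upper-tail binomial p-value P(X >= c), X ~ Binomial(N, Pr)."""
    if not 0 <= c <= n_samples:
        raise ValueError("c must be in [0, N]")
    if not 0 < pr <= 1:
        raise ValueError("Pr must be in (0, 1]")
    return float(stats.binom.sf(c - 1, n_samples, pr))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def unique_sample_counts(events: pd.DataFrame, interface_ids: Sequence[str]) -> pd.Series:
    """c per interface: unique samples with >= 1 event."""
    idx = pd.Index(interface_ids, name="interface_id")
    if len(events) == 0:
        return pd.Series(0, index=idx, dtype=int)
    counts = events.groupby("interface_id")["sample_id"].nunique()
    return counts.reindex(idx, fill_value=0).astype(int)


def compute_enrichment(
    variants: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    catalog: Sequence[InterfaceDef],
    n_samples: int,
    seed=0,
    replicates: int = 10,
    q_max: float = 0.01,
    min_samples: int = 20,
    mode: str = "interface",
) -> pd.DataFrame:
    """Full per-interface enrichment table under both background models.

    ``n_samples`` is the cohort size N (including unmutated samples).  The
    observed count c is the number of unique samples with >= 1 event on the
    interface; both backgrounds are averaged over ``replicates`` shuffles
    (one replicate reproduces the single-realization design).

    Returns one row per non-excluded interface: interface_id, N, c, pr_bm1,
    pr_bm2, p_bm1, p_bm2, q_bm1, q_bm2, significant.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _rng(seed)
    interface_ids = [i.interface_id for i in catalog if i.confidence != "excluded"]

    observed = annotate_variants(variants, catalog, mode=mode)
    c = unique_sample_counts(observed, interface_ids)

    bg_events = {"bm1": [], "bm2": []}
    for _ in range(replicates):
        bg_events["bm1"].append(
            annotate_variants(shuffle_bm1(variants, proteome, rng), catalog, mode=mode)
        )
        bg_events["bm2"].append(
            annotate_variants(shuffle_bm2(variants, proteome, rng), catalog, mode=mode)
        )

    result = pd.DataFrame({"interface_id": interface_ids, "N": n_samples, "c": c.to_numpy()})
    for model in ("bm1", "bm2"):
        pr = estimate_background_rate(bg_events[model], n_samples, interface_ids)
        p = np.array(
            [binomial_pvalue(n_samples, int(ci), float(pri)) for ci, pri in zip(c, pr)]
        )
        result[f"pr_{model}"] = pr.to_numpy()
        result[f"p_{model}"] = p
        result[f"q_{model}"] = bh_fdr(p)
    result["significant"] = (
        (result["q_bm1"] <= q_max)
        & (result["q_bm2"] <= q_max)
        & (result["c"] >= min_samples)
    )
    return result


def call_significant(
    results: pd.DataFrame, q_max: float = 0.01, min_samples: int = 20
) -> pd.DataFrame:
    """Interfaces significant under both models, ranked by unique samples.

    Keeps rows with q <= ``q_max`` in *both* background models and
    c >= ``min_samples``; ranks by c descending (interface_id breaks ties).
    """
    keep = results[
        (results["q_bm1"] <= q_max)
        & (results["q_bm2"] <= q_max)
        & (results["c"] >= min_samples)
    ]
    return keep.sort_values(
        ["c", "interface_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
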