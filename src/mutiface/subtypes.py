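"""Sample subtypes and mutual exclusivity of interface perturbations.

Samples are clustered by their vectors of combined interface scores
(hierarchical complete linkage, cut at a fixed cophenetic depth), and
pairs of interfaces are screened for mutual exclusivity — co-occurring in
fewer samples than independence predicts — with a one-tailed Fisher exact
test (lower hypergeometric tail) and Benjamini–Hochberg correction at
q < 0.1.

The clustering distance defaults to correlation distance (1 - Pearson) on
the score vectors; metric and the depth-cutoff interpretation (raw
cophenetic height) are configurable and recorded in outputs, since the
procedure this mirrors names the linkage and cutoff but not the metric.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .enrichment import bh_fdr
from .profiles import cancer_type_label


def build_profiles(
    perturbations: pd.DataFrame,
    interface_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x interfaces matrix of combined scores (0 = unperturbed).

    Rows default to the perturbed samples only, columns to the perturbed
    interfaces; pass explicit ids to densify.
    """
    mat = perturbations.pivot_table(
        index="sample_id", columns="interface_id", values="combined_score",
        aggfunc="sum", fill_value=0.0,
    )
    if interface_ids is not None:
        mat = mat.reindex(columns=list(interface_ids), fill_value=0.0)
    if sample_ids is not None:
        mat = mat.reindex(index=list(sample_ids), fill_value=0.0)
    return mat.sort_index().sort_index(axis=1)


def _distance_matrix(x: np.ndarray, metric: str) -> np.ndarray:
    d = pdist(x, metric=metric)
    if metric == "correlation" and np.isnan(d).any():
        # constant-variance rows: correlation undefined; equal rows are at
        # distance 0, anything else maximally distant
        n = x.shape[0]
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(d[k]):
                    d[k] = 0.0 if np.array_equal(x[i], x[j]) else 1.0
                k += 1
    return d


def cluster_samples(
    profiles: pd.DataFrame,
    depth_cutoff: float = 0.9,
    metric: str = "correlation",
    method: str = "complete",
) -> pd.Series:
    """Complete-linkage clusters of sample score profiles.

    The dendrogram is cut at cophenetic distance ``depth_cutoff``; labels
    are renumbered 1..k in order of first appearance so they are invariant
    to input order.
    """
    if profiles.empty:
        raise ValueError("no profiles to cluster")
    profiles = profiles.sort_index()
    if len(profiles) == 1:
        return pd.Series([1], index=profiles.index, name="cluster")
    d = _distance_matrix(profiles.to_numpy(dtype=float), metric)
    link = hierarchy.linkage(d, method=method)
    raw = hierarchy.fcluster(link, t=depth_cutoff, criterion="distance")
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        labels[i] = remap.setdefault(r, len(remap) + 1)
    return pd.Series(labels, index=profiles.index, name="cluster")


def fisher_one_tailed(n11: int, n10: int, n01: int, n00: int) -> float:
    """One-tailed Fisher exact p for mutual exclusivity.

    Given a cohort with ``n11`` samples perturbed at both interfaces,
    ``n10``/``n01`` at one only and ``n00`` at neither, returns the lower
    hypergeometric tail P(X <= n11) with the observed margins: a small
    value means fewer co-occurrences than chance, i.e. exclusivity.
    """
    for v in (n11, n10, n01, n00):
        if v < 0 or int(v) != v:
            raise ValueError("contingency cells must be non-negative integers")
    total = n11 + n10 + n01 + n00
    a_count = n11 + n10
    b_count = n11 + n01
    return float(stats.hypergeom.cdf(n11, total, a_count, b_count))


def _pair_rows(
    perturbed: Mapping[str, set], sample_pool: set, pairs, scope_label: str, cancer: str
):
    rows = []
    n_total = len(sample_pool)
    for a, b in pairs:
        sa = perturbed[a] & sample_pool
        sb = perturbed[b] & sample_pool
        n11 = len(sa & sb)
        n10 = len(sa) - n11
        n01 = len(sb) - n11
        n00 = n_total - n11 - n10 - n01
        rows.append(
            {
                "interface_a": a, "interface_b": b, "scope": scope_label,
                "cancer_type": cancer, "n11": n11, "n10": n10, "n01": n01,
                "n00": n00, "p": fisher_one_tailed(n11, n10, n01, n00),
            }
        )
    return rows


def mutual_exclusivity(
    perturbations: pd.DataFrame,
    samples: pd.DataFrame,
    scope: str = "pan-cancer",
    min_samples: int | None = None,
    interface_ids: Sequence[str] | None = None,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Screen interface pairs for mutual exclusivity.

    Pan-cancer scope tests pairs of interfaces each perturbed in at least
    20 unique samples cohort-wide; per-cancer scope tests, within each
    cancer type, pairs perturbed in at least 10 unique samples of that
    type (both defaults overridable via ``min_samples``).  ``samples`` is
    the full cohort table (so the 'neither' cell counts unmutated
    samples).  BH-FDR is applied over the whole batch; a pair is
    significant at q < ``q_max``.  ``interface_ids`` restricts the tested
    set (conventionally the both-model significant interfaces).
    """
    if scope not in ("pan-cancer", "per-cancer"):
        raise ValueError(f"unknown scope: {scope!r}")
    if min_samples is None:
        min_samples = 20 if scope == "pan-cancer" else 10
    pert = perturbations
    if interface_ids is not None:
        pert = pert[pert["interface_id"].isin(set(interface_ids))]
    perturbed: dict[str, set] = {
        iface: set(grp["sample_id"]) for iface, grp in pert.groupby("interface_id")
    }

    rows: list[dict] = []
    if scope == "pan-cancer":
        pool = set(samples["sample_id"])
        qualified = sorted(i for i, s in perturbed.items() if len(s) >= min_samples)
        pairs = [(a, b) for k, a in enumerate(qualified) for b in qualified[k + 1:]]
        rows += _pair_rows(perturbed, pool, pairs, "pan-cancer", "all")
    else:
        labels = cancer_type_label(samples)
        for cancer in sorted(labels.unique()):
            pool = set(samples.loc[labels == cancer, "sample_id"])
            qualified = sorted(
                i for i, s in perturbed.items() if len(s & pool) >= min_samples
            )
            pairs = [(a, b) for k, a in enumerate(qualified) for b in qualified[k + 1:]]
            rows += _pair_rows(perturbed, pool, pairs, "per-cancer", cancer)

    out = pd.DataFrame(
        rows,
        columns=["interface_a", "interface_b", "scope", "cancer_type",
                 "n11", "n10", "n01", "n00", "p"],
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < q_max if len(out) else []
    return out
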