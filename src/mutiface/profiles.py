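"""Cancer-type fingerprints of interface perturbation.

The fingerprint matrix crosses interfaces with cancer types (primary
tissue / histology label pairs); each cell holds the number of unique
perturbed samples and the median of their combined perturbation scores.
A compact display subset takes, from each of the most-sampled cancer
types, the most frequently perturbed interfaces, filtered by a minimum
per-type sample count and by significance in both background models.
A Kruskal–Wallis screen flags interfaces whose score distributions differ
across cancer types (the differential test is a stand-in choice: the
analysis it mirrors names no test; every output header flags it).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DIFFERENTIAL_TEST_NOTE = (
    "differential test: Kruskal-Wallis on combined scores (stand-in choice)"
)


def cancer_type_label(frame: pd.DataFrame) -> pd.Series:
    """Combined 'tissue/histology' label from the two COSMIC-style fields."""
    return frame["primary_tissue"].astype(str) + "/" + frame["histology"].astype(str)


@dataclass
class FingerprintMatrix:
    """Interfaces x cancer types: perturbed-sample counts and score medians."""

    counts: pd.DataFrame
    medians: pd.DataFrame  # NaN where counts == 0
    provenance: dict = field(default_factory=dict)

    @property
    def interfaces(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cancer_types(self) -> list[str]:
        return list(self.counts.columns)

    def to_cell_frame(self) -> pd.DataFrame:
        """Cells rendered as 'n|median' strings (median blank when n = 0)."""
        def cell(n, med):
            return f"{int(n)}|{med:.4g}" if n > 0 else "0|"
        data = {
            col: [cell(n, m) for n, m in zip(self.counts[col], self.medians[col])]
            for col in self.counts.columns
        }
        return pd.DataFrame(data, index=self.counts.index)


def build_matrix(
    perturbations: pd.DataFrame,
    sample_types: Mapping[str, str] | pd.Series,
) -> FingerprintMatrix:
    """Fingerprint matrix from per-(sample, interface) perturbations.

    ``sample_types`` maps sample_id -> cancer-type label.  Cell counts are
    unique perturbed samples (each variant counted once per sample it
    occurs in); medians use the standard midpoint convention for even
    counts and are NaN for empty cells.
    """
    types = pd.Series(sample_types)
    missing = set(perturbations["sample_id"]) - set(types.index)
    if missing:
        raise ValueError(f"samples without a cancer type: {sorted(missing)[:5]}")
    all_types = sorted(types.unique())
    df = perturbations.copy()
    df["cancer_type"] = types.loc[df["sample_id"]].to_numpy()
    counts = df.pivot_table(
        index="interface_id", columns="cancer_type", values="sample_id",
        aggfunc="nunique", fill_value=0,
    )
    medians = df.pivot_table(
        index="interface_id", columns="cancer_type", values="combined_score",
        aggfunc="median",
    )
    counts = counts.reindex(columns=all_types, fill_value=0).sort_index()
    medians = medians.reindex(index=counts.index, columns=all_types).sort_index()
    return FingerprintMatrix(counts=counts, medians=medians)


def select_display_set(
    matrix: FingerprintMatrix,
    enrichment: pd.DataFrame,
    type_sizes: Mapping[str, int] | pd.Series,
    top_types: int = 30,
    top_pairs: int = 30,
    min_samples: int = 20,
    q_max: float = 0.01,
) -> FingerprintMatrix:
    """Reduce the matrix to the headline display set.

    From each of the ``top_types`` largest cancer types (by sample count),
    take the ``top_pairs`` most perturbed interfaces; retain an interface
    only if it is perturbed in >= ``min_samples`` samples of at least one
    top type AND is significant (q <= ``q_max``) under both background
    models.  Ties in the per-type top lists break by (count desc,
    interface_id lexicographic) for determinism.
    """
    sizes = pd.Series(type_sizes)
    ranked_types = sizes.sort_values(ascending=False, kind="mergesort")
    keep_types = [t for t in ranked_types.index if t in matrix.counts.columns][:top_types]

    selected: set[str] = set()
    for t in keep_types:
        col = matrix.counts[t]
        order = sorted(col.index, key=lambda i: (-col[i], i))
        selected.update([i for i in order if col[i] > 0][:top_pairs])

    sig = set(
        enrichment.loc[
            (enrichment["q_bm1"] <= q_max) & (enrichment["q_bm2"] <= q_max),
            "interface_id",
        ]
    )
    retained = []
    for iface in sorted(selected):
        if iface not in sig:
            continue
        if matrix.counts.loc[iface, keep_types].max() >= min_samples:
            retained.append(iface)

    prov = {
        "top_types": top_types, "top_pairs": top_pairs,
        "min_samples": min_samples, "q_max": q_max,
        "n_retained": len(retained), "n_types": len(keep_types),
    }
    return FingerprintMatrix(
        counts=matrix.counts.loc[retained, keep_types],
        medians=matrix.medians.loc[retained, keep_types],
        provenance=prov,
    )


def primary_chemical_partner(
    catalog, perturbations: pd.DataFrame
) -> pd.DataFrame:
    """For proteins binding several chemicals at significant interfaces,
    mark the partner perturbed in the most unique samples as primary.

    Returns interface_id, protein_id, partner_id, n_samples, primary flag;
    non-primary chemical partners stay in the full table, the display layer
    may hide them.
    """
    counts = perturbations.groupby("interface_id")["sample_id"].nunique()
    rows = []
    for iface in catalog:
        if iface.partner_class != "chemical":
            continue
        rows.append(
            (iface.interface_id, iface.protein_id, iface.partner_id,
             int(counts.get(iface.interface_id, 0)))
        )
    df = pd.DataFrame(rows, columns=["interface_id", "protein_id", "partner_id", "n_samples"])
    if df.empty:
        df["primary"] = []
        return df
    df = df.sort_values(["protein_id", "n_samples", "interface_id"],
                        ascending=[True, False, True], kind="mergesort")
    df["primary"] = ~df.duplicated("protein_id")
    return df.reset_index(drop=True)


def differential_across_cancers(
    perturbations: pd.DataFrame,
    sample_types: Mapping[str, str] | pd.Series,
    min_per_type: int = 5,
) -> pd.Series:
    """Per-interface p-value for score differences across cancer types.

    Kruskal–Wallis on the combined-score distributions of the cancer types
    with >= ``min_per_type`` perturbed samples; NaN when fewer than two
    types qualify; p = 1 when all qualifying scores are identical.
    """
    types = pd.Series(sample_types)
    df = perturbations.copy()
    df["cancer_type"] = types.loc[df["sample_id"]].to_numpy()
    out = {}
    for iface, grp in df.groupby("interface_id"):
        groups = [
            g["combined_score"].to_numpy()
            for _, g in grp.groupby("cancer_type")
            if len(g) >= min_per_type
        ]
        if len(groups) < 2:
            out[iface] = np.nan
            continue
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            out[iface] = 1.0
            continue
        out[iface] = float(stats.kruskal(*groups).pvalue)
    s = pd.Series(out, name="p_differential")
    s.index.name = "interface_id"
    return s.sort_index()
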