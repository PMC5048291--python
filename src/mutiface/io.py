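"""TSV/JSON/FASTA readers and writers for the pipeline's tables.

TSV is the universal interchange (the mutation and donor catalogues this
emulates are TSV cultures); interface catalogs and run configs are JSON;
proteomes are FASTA.  Clinical tables are written with ICGC-style donor
column names and read back into the internal schema.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interfaces import InterfaceDef, ProteinRecord
from .scoring import PairPotentialTable, train_pair_potential
from .synthetic import VARIANT_COLUMNS

FLOAT_FORMAT = "%.10g"

ICGC_COLUMNS = {
    "donor_id": "icgc_donor_id",
    "sample_id": "submitted_sample_id",
    "age": "donor_age_at_diagnosis",
    "sex": "donor_sex",
    "vital_status": "donor_vital_status",
    "disease_status": "disease_status_last_followup",
    "survival_time": "donor_survival_time",
}


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_proteome(proteome: Sequence[ProteinRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteome(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(protein_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_catalog(catalog: Sequence[InterfaceDef], path) -> None:
    Path(path).write_text(
        json.dumps([iface.to_dict() for iface in catalog], indent=1, sort_keys=True)
    )


def read_catalog(path) -> list[InterfaceDef]:
    return [InterfaceDef.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_variants(variants: pd.DataFrame, path) -> None:
    write_tsv(variants[VARIANT_COLUMNS], path)


def read_variants(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a variant TSV; ``column_map`` translates a foreign (e.g.
    COSMIC-style) column dialect, mapping internal name -> file column."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table lacks columns: {missing}")
    return df[VARIANT_COLUMNS]


def write_clinical(clinical: pd.DataFrame, path) -> None:
    out = clinical.rename(columns=ICGC_COLUMNS)
    write_tsv(out, path)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    inverse = {v: k for k, v in ICGC_COLUMNS.items()}
    return df.rename(columns=inverse)


def write_potential(table: PairPotentialTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pseudocount={table.pseudocount!r}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_potential(path) -> PairPotentialTable:
    with open(path) as fh:
        header = fh.readline()
        pseudocount = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    counts = {
        (r.amino_acid, r.contact_type): float(r.count)
        for r in df.itertuples()
        if r.count > 0
    }
    types = tuple(dict.fromkeys(df["contact_type"]))
    return train_pair_potential(counts, pseudocount=pseudocount, contact_types=types)


def write_contact_counts(counts: Mapping[tuple[str, str], float], path) -> None:
    rows = [
        {"amino_acid": a, "contact_type": t, "count": v}
        for (a, t), v in sorted(counts.items())
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_contact_counts(path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {(r.amino_acid, r.contact_type): float(r.count) for r in df.itertuples()}
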