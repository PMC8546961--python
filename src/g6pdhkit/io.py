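"""Tabular and FASTA I/O.

Canonical tabular dialect: TSV with a single header line, tab delimiter,
decimal point, no thousands separators.  FitResult and ModelComparison are
serialized as JSON by their own ``to_json`` methods.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import GenomeMarkers, ProteinRecord
from .errors import InputError
from .fitting import ProgressCurve, RateDataset, RateObservation
from .kinetics import AssayMix, Cofactor

__all__ = [
    "rate_dataset_to_frame", "write_rate_dataset", "read_rate_dataset",
    "write_progress_curves", "read_progress_curves",
    "read_protein_fasta", "write_protein_fasta", "read_markers",
    "write_tsv",
]

_MIX_COLS = ["g6p", "nad_ox", "nadp_ox", "nadh", "nadph", "e0"]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def rate_dataset_to_frame(data: RateDataset) -> pd.DataFrame:
    rows = []
    for o in data.observations:
        row = {"replicate_id": o.replicate_id}
        row.update({c: getattr(o.mix, c) for c in _MIX_COLS})
        row["time"] = o.time
        row["v0"] = o.v0
        row["enzyme_name"] = data.enzyme_name
        row["cofactor"] = data.cofactor.value
        rows.append(row)
    return pd.DataFrame(rows)


def write_rate_dataset(data: RateDataset, path) -> None:
    write_tsv(rate_dataset_to_frame(data), path)


def read_rate_dataset(path) -> RateDataset:
    df = pd.read_csv(path, sep="\t")
    required = set(_MIX_COLS) | {"v0"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    observations = []
    for _, row in df.iterrows():
        mix = AssayMix(**{c: float(row[c]) for c in _MIX_COLS})
        observations.append(RateObservation(
            mix=mix, v0=float(row["v0"]),
            replicate_id=str(row.get("replicate_id", "r1")),
            time=float(row.get("time", 0.0) or 0.0)))
    enzyme_name = str(df["enzyme_name"].iloc[0]) if "enzyme_name" in df else ""
    cofactor = Cofactor(df["cofactor"].iloc[0]) if "cofactor" in df else Cofactor.NAD
    return RateDataset(observations=tuple(observations),
                       enzyme_name=enzyme_name, cofactor=cofactor)


def write_progress_curves(curves: Sequence[ProgressCurve], path) -> None:
    rows = []
    for i, c in enumerate(curves):
        for t, p in zip(c.times, c.product):
            row = {"curve_id": f"c{i + 1}", "time": t, "product": p, "s0": c.s0}
            row.update({col: getattr(c.mix, col) for col in _MIX_COLS})
            rows.append(row)
    write_tsv(pd.DataFrame(rows), path)


def read_progress_curves(path) -> list[ProgressCurve]:
    df = pd.read_csv(path, sep="\t")
    required = {"curve_id", "time", "product", "s0"} | set(_MIX_COLS)
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for _, sub in df.groupby("curve_id", sort=False):
        sub = sub.sort_values("time")
        mix = AssayMix(**{c: float(sub[c].iloc[0]) for c in _MIX_COLS})
        curves.append(ProgressCurve(
            times=tuple(sub["time"]), product=tuple(sub["product"]),
            mix=mix, s0=float(sub["s0"].iloc[0])))
    return curves


def read_protein_fasta(fasta_path, mapping: pd.DataFrame | None = None
                       ) -> list[ProteinRecord]:
    """FASTA records joined with the mandatory record_id -> (species, taxon)
    mapping table; records absent from the mapping get empty labels."""
    lookup = {}
    if mapping is not None:
        for col in ("record_id", "species", "taxon"):
            if col not in mapping.columns:
                raise InputError(f"mapping table lacks column {col!r}")
        lookup = {str(r.record_id): (str(r.species), str(r.taxon))
                  for r in mapping.itertuples()}
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        species, taxon = lookup.get(rec.id, ("", ""))
        records.append(ProteinRecord(record_id=rec.id, sequence=str(rec.seq),
                                     species=species, taxon=taxon))
    if not records:
        raise InputError(f"{fasta_path}: no FASTA records")
    return records


def write_protein_fasta(records, path) -> None:
    """Write (record_id, sequence) pairs or ProteinRecords as FASTA."""
    seq_records = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            rid, seq = rec.record_id, rec.sequence
        else:
            rid, seq = rec
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def read_markers(path) -> list[GenomeMarkers]:
    """Markers TSV with columns species, pfk, edd, eda (0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"species", "pfk", "edd", "eda"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [GenomeMarkers(species=str(r.species), has_pfk=bool(int(r.pfk)),
                          has_edd=bool(int(r.edd)), has_eda=bool(int(r.eda)))
            for r in df.itertuples()]
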