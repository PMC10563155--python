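"""Readers and writers: FASTA, the quant TSV dialect, configs, reports.

The quant TSV dialect is a flat, FragPipe-inspired table: the annotation
columns ``feature_id``, ``protein_id``, ``n_peptides``, ``is_contaminant``,
``is_ligand`` followed by one intensity column per sample named
``<condition>_rep<k>``; tab-separated, UTF-8, zeros or blanks meaning
missing, floats written with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .digestion import Peptide, ProteinSequence, VALID_RESIDUES
from .quant import META_COLUMNS, QuantTable, parse_sample_name

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_quant_tsv",
    "write_quant_tsv",
    "quant_table_from_frame",
    "quant_table_to_frame",
    "write_peptides_tsv",
    "read_sim_config",
]


def _header_line_numbers(path) -> dict[str, int]:
    numbers = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                rec_id = line[1:].split()[0] if line[1:].strip() else ""
                numbers.setdefault(rec_id, lineno)
    return numbers


def read_fasta(path) -> list[ProteinSequence]:
    """Read proteins from FASTA, in file order.

    The description line may carry ``role=ligand|bait|background`` (default
    background) and ``attachment=<int>`` tokens. Residues are upper-cased;
    invalid residues or an empty file raise with the offending line number.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    lines = _header_line_numbers(path)
    proteins = []
    for rec in records:
        lineno = lines.get(rec.id, 0)
        tokens = dict(t.split("=", 1) for t in rec.description.split() if "=" in t)
        role = tokens.get("role", "background")
        attachment = tokens.get("attachment")
        residues = str(rec.seq).upper()
        bad = set(residues) - VALID_RESIDUES
        if not residues or bad:
            detail = f"invalid residues {sorted(bad)}" if bad else "empty sequence"
            raise ValueError(f"{path} line {lineno}: record {rec.id!r}: {detail}")
        try:
            proteins.append(ProteinSequence(
                rec.id, residues, role=role,
                attachment_index=int(attachment) if attachment is not None else None))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from None
    return proteins


def write_fasta(proteins: list[ProteinSequence], path) -> None:
    with open(path, "w") as handle:
        for prot in proteins:
            extras = [f"role={prot.role}"]
            if prot.attachment_index is not None:
                extras.append(f"attachment={prot.attachment_index}")
            handle.write(f">{prot.id} {' '.join(extras)}\n")
            for i in range(0, len(prot.residues), 60):
                handle.write(prot.residues[i:i + 60] + "\n")


def quant_table_from_frame(frame: pd.DataFrame, level: str = "protein") -> QuantTable:
    """Build a QuantTable from a flat dialect frame (zeros read as missing)."""
    frame = frame.copy()
    if "feature_id" in frame.columns:
        if frame["feature_id"].duplicated().any():
            dupes = frame.loc[frame["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        frame = frame.set_index("feature_id")
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing annotation columns: {missing}")
    sample_cols = [c for c in frame.columns if c not in META_COLUMNS]
    for col in sample_cols:
        parse_sample_name(col)  # raises naming the offender
    meta = frame[META_COLUMNS].copy()
    for flag in ("is_contaminant", "is_ligand"):
        meta[flag] = meta[flag].map(_parse_flag)
    meta["n_peptides"] = meta["n_peptides"].astype(int)
    values = frame[sample_cols].apply(pd.to_numeric).astype(float)
    values = values.mask(values == 0.0)
    return QuantTable(meta, values, level=level, is_log2=False)


def _parse_flag(value) -> bool:
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no", ""):
            return False
        raise ValueError(f"cannot parse flag value {value!r}")
    return bool(value)


def quant_table_to_frame(table: QuantTable) -> pd.DataFrame:
    values = table.delog().values
    frame = pd.concat([table.meta, values], axis=1)
    frame.index.name = "feature_id"
    return frame.reset_index()


def read_quant_tsv(path, level: str = "protein",
                   col_map: dict[str, str] | None = None) -> QuantTable:
    """Read an intensity table in the quant TSV dialect.

    ``col_map`` renames input columns to dialect names before parsing
    (e.g. ``{"Protein": "protein_id"}``), allowing ingestion of
    search-engine exports without promising full dialect coverage.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "protein_id": str})
    if col_map:
        absent = [c for c in col_map if c not in frame.columns]
        if absent:
            raise ValueError(f"--col-map refers to absent columns: {absent}")
        frame = frame.rename(columns=col_map)
    return quant_table_from_frame(frame, level=level)


def write_quant_tsv(table: QuantTable, path) -> None:
    """Write linear intensities; missing cells as 0; 6 significant digits."""
    frame = quant_table_to_frame(table)
    sample_cols = [c for c in frame.columns if c not in META_COLUMNS + ["feature_id"]]
    frame[sample_cols] = frame[sample_cols].fillna(0.0)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_peptides_tsv(peptides: list[Peptide], path) -> None:
    """Write digestion products: coordinates, missed cleavages, acetyl flag, mass."""
    rows = [{
        "parent_id": p.parent_id, "start": p.start, "end": p.end,
        "sequence": p.sequence, "missed_cleavages": p.missed_cleavages,
        "carries_acetyl": p.carries_acetyl, "mass": p.mass,
    } for p in sorted(peptides, key=lambda p: (p.parent_id, p.start, p.end))]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_sim_config(path):
    """Read a simulation config from YAML; unknown keys are rejected.

    The ligand may be given inline as ``ligand: {id, residues, role,
    attachment_index}`` or via ``ligand_fasta: <path>`` (first record with
    role=ligand, else first record).
    """
    from .simulate import SimConfig

    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    ligand = None
    if "ligand_fasta" in raw:
        fasta = raw.pop("ligand_fasta")
        proteins = read_fasta(Path(path).parent / fasta if not Path(fasta).is_absolute() else fasta)
        ligands = [p for p in proteins if p.role == "ligand"]
        ligand = ligands[0] if ligands else proteins[0]
        if ligand.role != "ligand":
            ligand = dataclasses.replace(ligand, role="ligand")
    elif "ligand" in raw:
        entry = raw.pop("ligand")
        ligand = ProteinSequence(entry["id"], entry["residues"].upper(),
                                 role=entry.get("role", "ligand"),
                                 attachment_index=entry.get("attachment_index"))
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "conditions" in raw:
        raw["conditions"] = tuple(raw["conditions"])
    config = SimConfig(**raw)
    if ligand is not None:
        config.ligand = ligand
    config.validate()
    return config
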