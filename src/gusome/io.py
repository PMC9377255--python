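"""Readers and writers for the pipeline's file formats.

FASTA parsing is delegated to Biopython; tables are tab-delimited UTF-8
with a header row, ``.`` for missing values and no quoting.  All residue
coordinates written to disk are 1-based with closed intervals.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .types import AA_ALPHABET, ProteinRecord, RepresentativeGus, SampleMeta

MISSING = "."

#: Letters accepted in FASTA input after uppercasing.  B/J/O/U/Z and ``*``
#: are rejected: the screen needs unambiguous residues.
_REJECT = set("BJOUZ*")


class FastaError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into ProteinRecords.

    Entries are uppercased; order is preserved; duplicate ids and letters
    outside the canonical alphabet (+X) are rejected.  The description line
    is split at the first whitespace; the remainder is kept as free text.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if entry.id in seen:
            raise FastaError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        if not seq:
            raise FastaError(f"empty sequence for {entry.id!r} in {path}")
        bad = (set(seq) - AA_ALPHABET) | (set(seq) & _REJECT)
        if bad:
            raise FastaError(
                f"record {entry.id!r} contains disallowed letters "
                f"{''.join(sorted(bad))}"
            )
        desc = entry.description.split(None, 1)
        records.append(
            ProteinRecord(
                id=entry.id,
                seq=seq,
                description=desc[1] if len(desc) > 1 else "",
            )
        )
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV with header row, validating the expected columns.

    ``required`` columns must be present (SchemaError lists the missing
    names); ``numeric`` columns are parsed to floats, with a row-indexed
    error on non-numeric cells.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING],
                     keep_default_na=False, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    for col in numeric:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    """Write a TSV (tab-delimited, '.' for missing, no quoting).

    ``header_comment`` lines (prefixed '#') document conventions such as
    1-based closed coordinates and the thresholds used.
    """
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING, float_format="%.10g")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = read_table(path, required=("sample_id", "group"))
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    extras = [c for c in df.columns if c not in ("sample_id", "group")]
    return [
        SampleMeta(
            sample_id=row["sample_id"],
            group=row["group"],
            covariates=tuple((c, str(row[c])) for c in extras),
        )
        for _, row in df.iterrows()
    ]


def read_representatives(
    fasta_path: str | Path, annot_path: str | Path
) -> list[RepresentativeGus]:
    """Load the representative GUS set: sequences plus annotations.

    The annotation TSV carries one row per representative with columns
    ``id``, ``gus_class``, ``catalytic_positions`` (semicolon-separated
    ``pos:letter`` pairs, 1-based), ``loop1_window`` / ``loop2_window``
    (``start-end``, closed), optional ``fmn_segment`` and ``taxonomy``.
    """
    seqs = {r.id: r.seq for r in read_protein_fasta(fasta_path)}
    annot = read_table(
        annot_path,
        required=("id", "gus_class", "catalytic_positions", "loop1_window", "loop2_window"),
    )
    reps = []
    for _, row in annot.iterrows():
        rid = row["id"]
        if rid not in seqs:
            raise SchemaError(f"annotated representative {rid!r} missing from FASTA")
        cat = tuple(
            (int(p.split(":")[0]), p.split(":")[1])
            for p in row["catalytic_positions"].split(";")
        )
        fmn = None
        if "fmn_segment" in row and isinstance(row["fmn_segment"], str) and row["fmn_segment"]:
            a, b = row["fmn_segment"].split("-")
            fmn = (int(a), int(b))
        reps.append(
            RepresentativeGus(
                id=rid,
                seq=seqs[rid],
                gus_class=row["gus_class"],
                catalytic_positions=cat,
                loop1_window=_parse_interval(row["loop1_window"]),
                loop2_window=_parse_interval(row["loop2_window"]),
                fmn_segment=fmn,
                taxonomy=row.get("taxonomy", "") or "",
            )
        )
    return reps


def write_representatives(
    reps: Sequence[RepresentativeGus], fasta_path: str | Path, annot_path: str | Path
) -> None:
    write_protein_fasta(
        [ProteinRecord(id=r.id, seq=r.seq) for r in reps], fasta_path
    )
    rows = []
    for r in reps:
        rows.append(
            {
                "id": r.id,
                "gus_class": r.gus_class,
                "catalytic_positions": ";".join(f"{p}:{a}" for p, a in r.catalytic_positions),
                "loop1_window": f"{r.loop1_window[0]}-{r.loop1_window[1]}",
                "loop2_window": f"{r.loop2_window[0]}-{r.loop2_window[1]}",
                "fmn_segment": (
                    f"{r.fmn_segment[0]}-{r.fmn_segment[1]}" if r.fmn_segment else None
                ),
                "taxonomy": r.taxonomy or None,
            }
        )
    write_table(
        pd.DataFrame(rows),
        annot_path,
        header_comment="representative GUS annotations; positions 1-based, intervals closed",
    )


def _parse_interval(text: str) -> tuple[int, int]:
    a, b = text.split("-")
    return int(a), int(b)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
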