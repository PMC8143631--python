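"""Readers and writers for the flat-file formats the pipeline exchanges.

All tables are plain TSV so that runs are diffable and auditable.  The PSM
table dialect is::

    psm_id  peptide  proteins  is_decoy  posterior  ch1 ... chN

with ``proteins`` a semicolon-separated list of candidate protein
identifiers and ``chK`` the per-channel TMT reporter signal-to-noise.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHANNEL_RE = re.compile(r"^ch\d+$")


def channel_columns(table: pd.DataFrame) -> list[str]:
    """Return the reporter-channel columns (``ch1``..``chN``) in plex order."""
    cols = [c for c in table.columns if CHANNEL_RE.match(c)]
    return sorted(cols, key=lambda c: int(c[2:]))


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    df["proteins"] = df["proteins"].astype(str)
    return df


def write_psm_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ra_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ra_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into ``{identifier: sequence}``.

    The identifier is the header token up to the first whitespace — the
    canonical namespace shared by every table in the pipeline.
    """
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_disorder_tracks(path: str | Path) -> dict[str, "pd.Series"]:
    """Read per-residue disorder scores (TSV: protein, position, score).

    Positions are 1-based.  Returns one position-indexed series per protein.
    """
    df = pd.read_csv(path, sep="\t")
    return {
        prot: grp.set_index("position")["score"].sort_index()
        for prot, grp in df.groupby("protein")
    }


def write_disorder_tracks(tracks: Mapping[str, Iterable[float]], path: str | Path) -> None:
    rows = [
        {"protein": prot, "position": i + 1, "score": s}
        for prot, track in tracks.items()
        for i, s in enumerate(track)
    ]
    pd.DataFrame(rows, columns=["protein", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_localization(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["intracellular"] = df["intracellular"].astype(bool)
    df["secreted"] = df["secreted"].astype(bool)
    return df


def read_known_substrates(path: str | Path) -> set[str]:
    """One protein identifier per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_nucleus_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
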