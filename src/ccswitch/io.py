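"""FASTA and parameter-file round-tripping.

Registered peptides are serialized as FASTA records whose description line
carries annotation tokens with a ``key=value`` grammar::

    >CC-Di-B_RRpS offset=0 nterm=acetyl cterm=amide nflank=G cflank=GW phospho=9

Recognized keys: ``offset`` (0-6), ``nterm``/``cterm`` (free|acetyl /
free|amide), ``nflank``/``cflank`` (literal cap sequences), ``phospho``
(comma-separated 1-based indices).  Unknown tokens are rejected so typos do
not silently drop modifications.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptides import RegisteredPeptide

_KEYS = {"offset", "nterm", "cterm", "nflank", "cflank", "phospho"}


def _record(p: RegisteredPeptide) -> SeqRecord:
    tokens = [f"offset={p.register_offset}"]
    if p.n_term_mod != "free":
        tokens.append(f"nterm={p.n_term_mod}")
    if p.c_term_mod != "free":
        tokens.append(f"cterm={p.c_term_mod}")
    if p.n_flank:
        tokens.append(f"nflank={p.n_flank}")
    if p.c_flank:
        tokens.append(f"cflank={p.c_flank}")
    phospho = [str(i) for i, m in p.sidechain_mods if m == "phospho"]
    if phospho:
        tokens.append("phospho=" + ",".join(phospho))
    return SeqRecord(Seq(p.sequence), id=p.name, description=" ".join(tokens))


def write_fasta(peptides, path) -> None:
    SeqIO.write([_record(p) for p in peptides], str(path), "fasta")


def _parse(rec: SeqRecord) -> RegisteredPeptide:
    fields = dict(
        name=rec.id, sequence=str(rec.seq), register_offset=0,
        n_term_mod="free", c_term_mod="free", n_flank="", c_flank="",
        sidechain_mods=(),
    )
    desc = rec.description[len(rec.id):].strip() if rec.description else ""
    for token in desc.split():
        if "=" not in token:
            raise ValueError(f"bad annotation token {token!r} in {rec.id}")
        key, value = token.split("=", 1)
        if key not in _KEYS:
            raise ValueError(f"unknown annotation key {key!r} in {rec.id}")
        if key == "offset":
            fields["register_offset"] = int(value)
        elif key == "nterm":
            fields["n_term_mod"] = value
        elif key == "cterm":
            fields["c_term_mod"] = value
        elif key == "nflank":
            fields["n_flank"] = value
        elif key == "cflank":
            fields["c_flank"] = value
        elif key == "phospho":
            fields["sidechain_mods"] = tuple(
                (int(i), "phospho") for i in value.split(",")
            )
    return RegisteredPeptide(**fields)


def read_fasta(path) -> list:
    return [_parse(rec) for rec in SeqIO.parse(str(path), "fasta")]


def load_params_yaml(path) -> dict:
    """Load a named-mode kinetic parameter file (plain mapping)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_params_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
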