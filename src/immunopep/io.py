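"""Reading peptide-identification tables and building filtered repertoires.

The unit of input is one row of a search-engine export: a peptide sequence,
an identification confidence in [0, 100] (higher = more reliable; a cutoff of
~95 corresponds to a 5% local FDR for these searches), optional modifications
and provenance columns.  A :class:`Repertoire` is the non-redundant,
confidence-filtered, contaminant-free per-allotype set that every downstream
stage consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .constants import AMINO_ACIDS

_SEQ_RE = re.compile(rf"^[{AMINO_ACIDS}]+$")

#: Canonical column names; a dialect maps these to the file's own headers.
STANDARD_COLUMNS = ("sequence", "confidence", "modifications", "allotype", "replicate")


@dataclass(frozen=True)
class PeptideRecord:
    """One identified HLA ligand."""

    sequence: str
    confidence: float
    modifications: tuple[tuple[int, str], ...] = ()
    allotype: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise ValueError(f"invalid sequence {self.sequence!r}")
        if not 0.0 <= float(self.confidence) <= 100.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 100]")
        for pos, name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            if not name:
                raise ValueError("empty modification name")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mod_string(self) -> str:
        """Canonical sorted ``pos:name`` encoding used in identity keys."""
        return ";".join(f"{p}:{n}" for p, n in sorted(self.modifications))

    def identity_key(self, mode: str = "sequence_only") -> str:
        if mode == "sequence_only":
            return self.sequence
        if mode == "sequence_plus_modifications":
            return f"{self.sequence}|{self.mod_string()}"
        raise ValueError(f"unknown identity mode {mode!r}")


@dataclass(frozen=True)
class RowError:
    """A rejected input row, kept so nothing is dropped silently."""

    row: int
    reason: str
    value: str = ""


@dataclass
class TableReadResult:
    records: list[PeptideRecord]
    errors: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def parse_modifications(text: str) -> tuple[tuple[int, str], ...]:
    """Parse ``"4:Deamidated;7:Oxidation"`` into position/name pairs."""
    text = (text or "").strip()
    if not text:
        return ()
    mods = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        pos_s, _, name = chunk.partition(":")
        mods.append((int(pos_s), name.strip()))
    return tuple(mods)


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    default_allotype: str = "",
    default_replicate: str = "",
) -> TableReadResult:
    """Read a CSV/TSV peptide table into records plus a row-level error report.

    ``dialect`` maps canonical names (``sequence``, ``confidence``,
    ``modifications``, ``allotype``, ``replicate``) to the file's column
    headers.  ``sequence`` and ``confidence`` must resolve; the rest default.
    Rows with an invalid sequence or non-numeric confidence are returned in
    ``errors`` with their 0-based row index, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)

    def col(name: str) -> str | None:
        mapped = dialect.get(name, name)
        return mapped if mapped in df.columns else None

    seq_col, conf_col = col("sequence"), col("confidence")
    for needed, c in (("sequence", seq_col), ("confidence", conf_col)):
        if c is None:
            raise KeyError(f"required column {needed!r} not found in {path.name}")
    mod_col, allo_col, rep_col = col("modifications"), col("allotype"), col("replicate")

    records: list[PeptideRecord] = []
    errors: list[RowError] = []
    for i in range(len(df)):
        seq = str(df.iloc[i][seq_col]).strip().upper()
        conf_raw = str(df.iloc[i][conf_col]).strip()
        if not _SEQ_RE.match(seq):
            errors.append(RowError(i, "invalid sequence", seq))
            continue
        try:
            conf = float(conf_raw)
        except ValueError:
            errors.append(RowError(i, "non-numeric confidence", conf_raw))
            continue
        if not 0.0 <= conf <= 100.0:
            errors.append(RowError(i, "confidence outside [0, 100]", conf_raw))
            continue
        try:
            mods = parse_modifications(str(df.iloc[i][mod_col])) if mod_col else ()
        except ValueError:
            errors.append(RowError(i, "malformed modifications", str(df.iloc[i][mod_col])))
            continue
        try:
            rec = PeptideRecord(
                sequence=seq,
                confidence=conf,
                modifications=mods,
                allotype=str(df.iloc[i][allo_col]).strip() if allo_col else default_allotype,
                replicate=str(df.iloc[i][rep_col]).strip() if rep_col else default_replicate,
            )
        except ValueError as exc:
            errors.append(RowError(i, str(exc)))
            continue
        records.append(rec)
    return TableReadResult(records, errors)


@dataclass
class ContaminantLists:
    """Sequences excluded before motif analysis.

    ``endogenous_ligands`` are binders of the parental cell line's own HLA
    class I (HLA-C*04:01 / HLA-B*35:03 for C1R transfectants);
    ``generic_contaminants`` are recurrent artefacts of elution experiments;
    ``hla_protein_sequences`` are HLA heavy-chain/light-chain proteins whose
    tryptic-like fragments are matched as substrings.
    """

    endogenous_ligands: frozenset[str] = frozenset()
    generic_contaminants: frozenset[str] = frozenset()
    hla_protein_sequences: tuple[str, ...] = ()

    @staticmethod
    def from_files(
        endogenous: str | Path | None = None,
        generic: str | Path | None = None,
        hla_fasta: str | Path | None = None,
    ) -> "ContaminantLists":
        def read_list(p):
            if p is None:
                return frozenset()
            lines = Path(p).read_text().split()
            return frozenset(s.strip().upper() for s in lines if s.strip())

        proteins: tuple[str, ...] = ()
        if hla_fasta is not None:
            proteins = tuple(
                str(rec.seq).upper() for rec in SeqIO.parse(str(hla_fasta), "fasta")
            )
        return ContaminantLists(read_list(endogenous), read_list(generic), proteins)

    def is_contaminant(self, sequence: str) -> str | None:
        """Return the matching list's name, or None if the peptide is clean."""
        if sequence in self.endogenous_ligands:
            return "endogenous_ligands"
        if sequence in self.generic_contaminants:
            return "generic_contaminants"
        for prot in self.hla_protein_sequences:
            if sequence in prot:
                return "hla_protein_peptides"
        return None


@dataclass
class Repertoire:
    """A filtered, non-redundant per-allotype ligand set."""

    allotype: str
    records: list[PeptideRecord]
    identity_mode: str = "sequence_only"
    cutoff: float = 95.0
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.identity_key(self.identity_mode) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate identity keys in repertoire")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self, length: int | None = None) -> list[str]:
        return [r.sequence for r in self.records if length is None or r.length == length]

    def subset_by_length(self, length: int) -> "Repertoire":
        recs = [r for r in self.records if r.length == length]
        return Repertoire(self.allotype, recs, self.identity_mode, self.cutoff, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [r.sequence for r in self.records],
                "confidence": [r.confidence for r in self.records],
                "modifications": [r.mod_string() for r in self.records],
                "allotype": [r.allotype for r in self.records],
                "replicate": [r.replicate for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str | Path, allotype: str = "", **kwargs) -> "Repertoire":
        result = read_peptide_table(path, sep="\t")
        if result.errors:
            raise ValueError(f"repertoire file {path} contains invalid rows: {result.errors[:3]}")
        recs = result.records
        allo = allotype or (recs[0].allotype if recs else "")
        rep = Repertoire.__new__(Repertoire)
        rep.allotype = allo
        rep.records = recs
        rep.identity_mode = kwargs.get("identity_mode", "sequence_only")
        rep.cutoff = kwargs.get("cutoff", 0.0)
        rep.provenance = {}
        return rep


def filter_repertoire(
    records: Iterable[PeptideRecord],
    cutoff: float = 95.0,
    lists: ContaminantLists | None = None,
    identity_mode: str = "sequence_only",
    allotype: str | None = None,
) -> Repertoire:
    """Confidence-filter, decontaminate and deduplicate identified peptides.

    Records below ``cutoff`` are removed first, then any whose sequence is in
    a contaminant list, then duplicates by identity key are merged keeping the
    highest-confidence instance (ties: first occurrence).  Provenance counts
    satisfy ``n_input == n_kept + n_below_cutoff + sum(removed per list) +
    n_duplicates_merged``.
    """
    if not 0.0 <= cutoff <= 100.0:
        raise ValueError("cutoff must be in [0, 100]")
    lists = lists or ContaminantLists()
    records = list(records)
    prov = {
        "n_input": len(records),
        "n_below_cutoff": 0,
        "n_endogenous_ligands": 0,
        "n_generic_contaminants": 0,
        "n_hla_protein_peptides": 0,
        "n_duplicates_merged": 0,
    }
    best: dict[str, PeptideRecord] = {}
    for rec in records:
        if rec.confidence < cutoff:
            prov["n_below_cutoff"] += 1
            continue
        hit = lists.is_contaminant(rec.sequence)
        if hit is not None:
            prov[f"n_{hit}"] += 1
            continue
        key = rec.identity_key(identity_mode)
        if key in best:
            prov["n_duplicates_merged"] += 1
            if rec.confidence > best[key].confidence:
                best[key] = rec
        else:
            best[key] = rec
    kept = list(best.values())
    prov["n_kept"] = len(kept)
    allo = allotype if allotype is not None else (kept[0].allotype if kept else "")
    return Repertoire(allo, kept, identity_mode, cutoff, prov)
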