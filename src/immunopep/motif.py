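"""Length distributions, position-frequency matrices and proteome enrichment.

Enrichment follows the static-reference convention: for each (position,
residue) cell the observed positional proportion ``p_obs`` is compared with
its proteome-wide background ``p_ref`` through a binomial z-score

    z = (p_obs - p_ref) / sqrt(p_ref * (1 - p_ref) / n)

and, where |z| exceeds the two-sided critical value, reported as a fold
change FC = p_obs / p_ref when enriched, or as a converted fold change
FC_con = -1/FC when depleted.  Residues never observed at a position carry
the sentinel value -100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .constants import AA_INDEX, AMINO_ACIDS, swissprot_human_frequencies
from .io import Repertoire

ABSENT_SENTINEL = -100.0
DEFAULT_LENGTH_RANGE = range(8, 19)


def omega_position(length: int, offset: int = 0) -> int:
    """1-based position of the C-terminal anchor PΩ (offset 0) or PΩ-offset.

    C-terminal-anchored indexing lets anchor statistics be compared across
    peptide lengths (PΩ-2 is P7/P8/P9 of 9/10/11-mers).
    """
    pos = length - offset
    if not 1 <= pos <= length:
        raise ValueError(f"offset {offset} outside peptide of length {length}")
    return pos


def length_distribution(
    rep: Repertoire | Iterable[str],
    length_range: range = DEFAULT_LENGTH_RANGE,
) -> pd.DataFrame:
    """Counts and proportions of peptide lengths over ``length_range``.

    Lengths outside the range are pooled into an ``other`` bucket so the
    proportions always sum to 1.
    """
    seqs = rep.sequences() if isinstance(rep, Repertoire) else list(rep)
    lengths = pd.Series([len(s) for s in seqs], dtype=int)
    idx = [str(L) for L in length_range] + ["other"]
    counts = pd.Series(0, index=idx, dtype=int)
    for L, c in lengths.value_counts().items():
        key = str(L) if L in length_range else "other"
        counts[key] += int(c)
    total = counts.sum()
    props = counts / total if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "proportion": props})


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue counts/frequencies for peptides of one length."""

    length: int
    counts: pd.DataFrame  # L x 20 ints, rows = positions 1..L
    n: int

    @property
    def freqs(self) -> pd.DataFrame:
        return self.counts / self.n

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("empty position-frequency matrix")
        if not (self.counts.sum(axis=1) == self.n).all():
            raise ValueError("row counts do not sum to n")


def position_frequency_matrix(rep: Repertoire | Iterable[str], length: int) -> PositionFrequencyMatrix:
    """Tabulate residue counts at each position of all peptides of ``length``.

    Modifications are ignored: only the bare sequence enters motif analysis.
    """
    seqs = rep.sequences(length) if isinstance(rep, Repertoire) else [s for s in rep if len(s) == length]
    if not seqs:
        raise ValueError(f"no peptides of length {length}")
    counts = np.zeros((length, 20), dtype=int)
    for s in seqs:
        for pos, aa in enumerate(s):
            counts[pos, AA_INDEX[aa]] += 1
    df = pd.DataFrame(counts, index=range(1, length + 1), columns=list(AMINO_ACIDS))
    return PositionFrequencyMatrix(length, df, len(seqs))


def motif_summary(
    pfm: PositionFrequencyMatrix, min_prevalence: float = 0.10
) -> dict[int, list[tuple[str, float]]]:
    """Residues at >= ``min_prevalence`` per position, by descending prevalence.

    Mirrors the convention of depicting only residues present in at least 10%
    of ligands in sequence-motif figures.
    """
    out: dict[int, list[tuple[str, float]]] = {}
    freqs = pfm.freqs
    for pos in freqs.index:
        row = freqs.loc[pos]
        hits = row[row >= min_prevalence].sort_values(ascending=False, kind="stable")
        out[int(pos)] = [(aa, float(f)) for aa, f in hits.items()]
    return out


@dataclass
class ReferenceFrequencies:
    """Background residue frequencies (proteome-wide)."""

    freqs: pd.Series  # indexed by AMINO_ACIDS, sums to 1, all > 0
    source: str = "embedded_swissprot_means"
    skipped_letters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = self.freqs.reindex(list(AMINO_ACIDS)).astype(float)
        if self.freqs.isna().any():
            raise ValueError("reference frequencies must cover all 20 residues")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("reference frequencies must sum to 1")
        if (self.freqs <= 0).any():
            raise ValueError("reference frequencies must be strictly positive")

    def __getitem__(self, aa: str) -> float:
        return float(self.freqs[aa])


#: Floor applied to FASTA-derived frequencies so that residues absent from a
#: small background cannot produce infinite fold changes.
FREQUENCY_FLOOR = 1e-6


def background_frequencies(source: str | Path | None = None) -> ReferenceFrequencies:
    """Background frequencies from the embedded Swiss-Prot human means, or
    computed from a FASTA proteome when a path is given.

    In FASTA mode non-standard letters are skipped (and counted in the
    report), frequencies are floored at ``FREQUENCY_FLOOR`` and renormalised.
    """
    if source is None:
        return ReferenceFrequencies(swissprot_human_frequencies())
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    skipped: dict[str, int] = {}
    n_entries = 0
    for rec in SeqIO.parse(str(source), "fasta"):
        n_entries += 1
        for aa in str(rec.seq).upper():
            if aa in counts:
                counts[aa] += 1
            else:
                skipped[aa] = skipped.get(aa, 0) + 1
    total = sum(counts.values())
    if n_entries == 0 or total == 0:
        raise ValueError(f"no standard residues found in FASTA {source}")
    freqs = pd.Series(counts, dtype=float) / total
    freqs = freqs.clip(lower=FREQUENCY_FLOOR)
    freqs = freqs / freqs.sum()
    return ReferenceFrequencies(freqs, source="fasta_derived", skipped_letters=skipped)


@dataclass
class EnrichmentResult:
    """Positional enrichment of a repertoire over a proteome background.

    ``table`` is long format with one row per (position, residue):
    count, p_obs, p_ref, z, status in {enriched, depleted, absent,
    not_significant} and value (FC >= 1, FC_con <= -1, -100 for absent, or
    NaN for not-significant cells).
    """

    length: int
    n: int
    alpha: float
    table: pd.DataFrame

    def cell(self, position: int, aa: str) -> pd.Series:
        m = self.table[(self.table.position == position) & (self.table.aa == aa)]
        return m.iloc[0]

    def value(self, position: int, aa: str) -> float:
        return float(self.cell(position, aa)["value"])

    def status(self, position: int, aa: str) -> str:
        return str(self.cell(position, aa)["status"])


def enrichment_profile(
    pfm: PositionFrequencyMatrix,
    ref: ReferenceFrequencies,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Score every (position, residue) cell of a PFM against the background."""
    if pfm.n <= 0:
        raise ValueError("empty PFM")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    rows = []
    n = pfm.n
    for pos in pfm.counts.index:
        for aa in AMINO_ACIDS:
            count = int(pfm.counts.loc[pos, aa])
            p_obs = count / n
            p_ref = ref[aa]
            z = (p_obs - p_ref) / np.sqrt(p_ref * (1.0 - p_ref) / n)
            fc = p_obs / p_ref
            if count == 0:
                status, value = "absent", ABSENT_SENTINEL
            elif abs(z) < zcrit:
                status, value = "not_significant", np.nan
            elif fc >= 1.0:
                status, value = "enriched", fc
            else:
                status, value = "depleted", -1.0 / fc
            rows.append((int(pos), aa, count, p_obs, p_ref, z, status, value))
    table = pd.DataFrame(
        rows, columns=["position", "aa", "count", "p_obs", "p_ref", "z", "status", "value"]
    )
    return EnrichmentResult(pfm.length, n, alpha, table)


def enrichment_null_calibration(
    ref: ReferenceFrequencies,
    n_peptides: int,
    length: int,
    n_repertoires: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> float:
    """Fraction of significant cells when repertoires are drawn from the null.

    Each null repertoire draws every position i.i.d. from the background, so
    per-position counts are multinomial; a calibrated test flags ~alpha of
    cells as significant.
    """
    p = ref.freqs.to_numpy()
    sig = 0
    total = 0
    for _ in range(n_repertoires):
        counts = rng.multinomial(n_peptides, p, size=length)
        pfm = PositionFrequencyMatrix(
            length,
            pd.DataFrame(counts, index=range(1, length + 1), columns=list(AMINO_ACIDS)),
            n_peptides,
        )
        res = enrichment_profile(pfm, ref, alpha=alpha)
        sig += int((res.table.status.isin(["enriched", "depleted"])).sum())
        # absent cells with |z| >= zcrit also count as significant depletion
        total += len(res.table)
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        absent = res.table[res.table.status == "absent"]
        sig += int((absent.z.abs() >= zcrit).sum())
    return sig / total
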