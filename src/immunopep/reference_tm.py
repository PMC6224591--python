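"""Published thermal-stability measurements for HLA-B57-family complexes.

Mean melting temperatures (°C, with sample sd and replicate count) of
refolded HLA-peptide complexes for HLA-B*57:01, HLA-B*57:03 and HLA-B*58:01
bound to two natural nonamer ligands (LSSPVTKSF, LTVQVARVY), their PΩ-2
Arg/Lys -> Gln and PΩ -> Trp substitution variants, and the 11-mer
SAAADETLRLW.  These values are fixed experimental inputs for ΔTm
arithmetic — the melt-fitting code in :mod:`immunopep.melt` operates on raw
curves, which are not redistributed here.

Replicate schemes differ per entry (duplicates at one or two protein
concentrations); ``n`` records the pooled replicate count.
"""

from __future__ import annotations

import pandas as pd

from .melt import DeltaTm, ReplicateSummary, delta_tm

# (allotype, peptide) -> (mean Tm °C, sd °C, n replicates); None = complex
# could not be refolded.
_TM_ROWS = [
    ("B*57:01", "LSSPVTKSF", 70.6, 0.74, 4),
    ("B*57:01", "LSSPVTQSF", 70.4, 0.26, 4),
    ("B*57:01", "LSSPVTKSW", 72.6, 0.41, 4),
    ("B*57:01", "LSSPVTQSW", 73.1, 0.18, 2),
    ("B*57:01", "LTVQVARVY", 69.4, 0.18, 2),
    ("B*57:01", "LTVQVAQVY", 67.1, 0.18, 2),
    ("B*57:01", "LTVQVARVW", 72.2, 0.46, 4),
    ("B*57:01", "LTVQVAQVW", 71.0, 0.48, 4),
    ("B*57:01", "SAAADETLRLW", 67.5, 0.99, 4),
    ("B*57:03", "LSSPVTKSF", 69.2, 0.35, 4),
    ("B*57:03", "LSSPVTQSF", 69.6, 0.11, 2),
    ("B*57:03", "LSSPVTKSW", 71.0, 0.0, 4),
    ("B*57:03", "LSSPVTQSW", 71.1, 0.1, 4),
    ("B*57:03", "LTVQVARVY", 60.6, 0.67, 4),
    ("B*57:03", "LTVQVAQVY", 63.1, 0.14, 4),
    ("B*57:03", "LTVQVARVW", 69.2, 0.09, 4),
    ("B*57:03", "LTVQVAQVW", 70.9, 0.19, 4),
    ("B*57:03", "SAAADETLRLW", 61.3, 0.17, 4),
    ("B*58:01", "LSSPVTKSF", 69.3, 0.52, 4),
    ("B*58:01", "LSSPVTQSF", 70.2, 0.7, 4),
    ("B*58:01", "LSSPVTKSW", 71.8, 0.61, 4),
    ("B*58:01", "LSSPVTQSW", 73.0, 0.32, 4),
    ("B*58:01", "LTVQVARVW", 67.8, 1.12, 4),
    ("B*58:01", "LTVQVAQVW", 72.4, 0.61, 8),
    ("B*58:01", "SAAADETLRLW", 64.4, 0.67, 4),
]


def published_tm_table() -> pd.DataFrame:
    """The reference Tm table as a DataFrame."""
    return pd.DataFrame(_TM_ROWS, columns=["allotype", "peptide", "mean_tm", "sd_tm", "n"])


def published_summary(allotype: str, peptide: str) -> ReplicateSummary:
    """A :class:`ReplicateSummary` for one published (allotype, peptide) pair."""
    for allo, pep, mean, sd, n in _TM_ROWS:
        if allo == allotype and pep == peptide:
            return ReplicateSummary(sample=f"{allo}/{pep}", mean_tm=mean, sd_tm=sd, n=n)
    raise KeyError(f"no published Tm for {allotype} / {peptide}")


def published_delta_tm(allotype: str, variant: str, reference: str) -> DeltaTm:
    """ΔTm between two published complexes of the same allotype."""
    return delta_tm(published_summary(allotype, variant), published_summary(allotype, reference))


def substitution_impact_table() -> pd.DataFrame:
    """ΔTm for every PΩ-2 -> Gln and PΩ -> Trp substitution with both
    endpoints measured, reproducing the published impact columns."""
    subs = []
    for allo, pep, *_ in _TM_ROWS:
        # PΩ-2 K/R -> Q
        p_om2 = len(pep) - 3
        if pep[p_om2] in "KR":
            var = pep[:p_om2] + "Q" + pep[p_om2 + 1:]
            subs.append((allo, pep, var, "omega-2 -> Q"))
        # PΩ F/Y -> W
        if pep[-1] in "FY":
            var = pep[:-1] + "W"
            subs.append((allo, pep, var, "omega -> W"))
    rows = []
    measured = {(a, p) for a, p, *_ in _TM_ROWS}
    for allo, ref, var, kind in subs:
        if (allo, var) not in measured:
            continue
        d = published_delta_tm(allo, var, ref)
        rows.append((allo, ref, var, kind, d.delta, d.classification))
    return pd.DataFrame(
        rows, columns=["allotype", "reference", "variant", "substitution", "delta_tm", "classification"]
    )
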