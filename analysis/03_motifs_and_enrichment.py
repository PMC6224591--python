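"""Length distributions, nonamer motifs and proteome-background enrichment.

For each repertoire: the length profile (nonamers dominate by
construction), the >=10%-prevalence motif summary of 9-mers, and the
enrichment of every (position, residue) cell against the embedded human
Swiss-Prot background.  The printed contrast to look for is PΩ-2 (P7 of
9-mers): arginine enriched in W-RposE only, mirroring the secondary-anchor
difference between the real allotypes.
"""

from _cohort import RESULTS, cohort_repertoires

from immunopep.motif import (
    background_frequencies,
    enrichment_profile,
    length_distribution,
    motif_summary,
    omega_position,
    position_frequency_matrix,
)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    ref = background_frequencies()
    for name, rep in cohort_repertoires().items():
        ld = length_distribution(rep)
        ld.to_csv(RESULTS / f"length_distribution_{name}.tsv", sep="\t")
        pfm = position_frequency_matrix(rep, 9)
        pfm.freqs.to_csv(RESULTS / f"pfm_{name}_9.tsv", sep="\t")
        enr = enrichment_profile(pfm, ref)
        enr.table.to_csv(RESULTS / f"enrichment_{name}_9.tsv", sep="\t", index=False)

        p2 = [aa for aa, _ in motif_summary(pfm)[2]]
        om = [aa for aa, _ in motif_summary(pfm)[9]]
        om2 = omega_position(9, 2)
        r_cell = enr.cell(om2, "R")
        print(
            f"{name}: n9={pfm.n}, modal length "
            f"{ld['count'].drop('other').astype(int).idxmax()}, "
            f"P2 motif {p2}, PΩ motif {om}; "
            f"PΩ-2 Arg: {r_cell['status']} (value {r_cell['value']:.2f}, z {r_cell['z']:.1f})"
        )


if __name__ == "__main__":
    main()
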