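"""Generate the synthetic three-allotype cohort used by all later scripts.

Writes one identification table per allotype-like spec to results/cohort/.
The three specs share the P2 Ser/Thr/Ala bias and differ at the C-terminal
anchors: W-RposE (PΩ Trp-major, PΩ-2 Arg-enriched), F-RnegP (PΩ Phe-major,
PΩ-2 Arg-depleted/Pro-enriched) and W-EposR (PΩ Trp-major, PΩ-2
Glu-enriched).  Each table carries contaminant spikes and a low-confidence
tail so the filtering stage has real work to do.
"""

from _cohort import COHORT_DIR, N_PEPTIDES, SEED

from immunopep.simulate import b57_like_specs, simulate_repertoire


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    for name, spec in b57_like_specs(n=N_PEPTIDES, seed=SEED).items():
        df = simulate_repertoire(spec)
        path = COHORT_DIR / f"table_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        print(f"{name}: {len(df)} rows -> {path.relative_to(COHORT_DIR.parent.parent)}")
    print(f"seed {SEED}; rerunning reproduces these tables byte-for-byte")


if __name__ == "__main__":
    main()
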