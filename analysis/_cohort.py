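"""Shared helpers for the numbered analysis scripts.

The cohort is the bundled trio of allotype-like synthetic datasets
(see ``immunopep.simulate.b57_like_specs``).  Scripts read the tables written
by ``01_simulate_cohort.py``; if they are missing they are regenerated
deterministically from the same seed.
"""

from pathlib import Path

import pandas as pd

from immunopep.io import ContaminantLists, filter_repertoire, read_peptide_table
from immunopep.simulate import EXAMPLE_CONTAMINANTS, b57_like_specs, simulate_repertoire

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"
SEED = 1
N_PEPTIDES = 2000

CONTAMINANTS = ContaminantLists(generic_contaminants=frozenset(EXAMPLE_CONTAMINANTS))


def cohort_tables() -> dict[str, pd.DataFrame]:
    tables = {}
    for name, spec in b57_like_specs(n=N_PEPTIDES, seed=SEED).items():
        path = COHORT_DIR / f"table_{name}.tsv"
        if path.exists():
            tables[name] = pd.read_csv(path, sep="\t", keep_default_na=False)
        else:
            tables[name] = simulate_repertoire(spec)
    return tables


def cohort_records() -> dict[str, list]:
    records = {}
    for name in b57_like_specs(n=10, seed=SEED):
        path = COHORT_DIR / f"table_{name}.tsv"
        if not path.exists():
            COHORT_DIR.mkdir(parents=True, exist_ok=True)
            cohort_tables()[name].to_csv(path, sep="\t", index=False)
        records[name] = read_peptide_table(path, sep="\t").records
    return records


def cohort_repertoires(cutoff: float = 95.0) -> dict:
    return {
        name: filter_repertoire(recs, cutoff, CONTAMINANTS, allotype=name)
        for name, recs in cohort_records().items()
    }
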