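"""Repertoire overlap between allotypes under a confidence-rescue rule.

A peptide belongs to a dataset's *core* when identified there at confidence
>= ``primary_cutoff``.  Lower-confidence identifications (confidence >
``rescue_cutoff``) are *rescued* into the dataset's effective membership if,
and only if, the same peptide reaches the primary cutoff in at least one of
the other datasets being compared: a confident sighting elsewhere makes the
weak local identification credible.  Intersections and per-dataset unique
counts are computed over the effective sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .io import PeptideRecord


@dataclass
class OverlapResult:
    dataset_names: tuple[str, ...]
    identity_mode: str
    primary_cutoff: float
    rescue_cutoff: float
    effective: dict[str, set[str]]            # name -> effective membership keys
    core: dict[str, set[str]]                 # name -> core (>= primary) keys
    rescued: dict[str, set[str]]              # name -> rescued-only keys

    @property
    def effective_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.effective.items()}

    def intersection(self, *names: str) -> set[str]:
        names = names or self.dataset_names
        out = set(self.effective[names[0]])
        for nm in names[1:]:
            out &= self.effective[nm]
        return out

    @property
    def common_to_all(self) -> set[str]:
        return self.intersection(*self.dataset_names)

    def unique_to(self, name: str) -> set[str]:
        out = set(self.effective[name])
        for nm in self.dataset_names:
            if nm != name:
                out -= self.effective[nm]
        return out

    def counts(self) -> dict[str, int]:
        out = {f"effective_{nm}": len(self.effective[nm]) for nm in self.dataset_names}
        out.update({f"core_{nm}": len(self.core[nm]) for nm in self.dataset_names})
        out.update({f"unique_{nm}": len(self.unique_to(nm)) for nm in self.dataset_names})
        for a, b in combinations(self.dataset_names, 2):
            out[f"intersection_{a}_{b}"] = len(self.intersection(a, b))
        out["common_to_all"] = len(self.common_to_all)
        return out

    def membership_table(self) -> pd.DataFrame:
        """Long table: peptide key x dataset with core/rescued/absent status."""
        keys = sorted(set().union(*self.effective.values()))
        rows = []
        for key in keys:
            row: dict[str, object] = {"peptide": key}
            for nm in self.dataset_names:
                if key in self.core[nm]:
                    row[nm] = "core"
                elif key in self.rescued[nm]:
                    row[nm] = "rescued"
                else:
                    row[nm] = "absent"
            rows.append(row)
        return pd.DataFrame(rows)


def repertoire_overlap(
    tables: Mapping[str, Iterable[PeptideRecord]],
    primary_cutoff: float = 95.0,
    rescue_cutoff: float = 20.0,
    identity_mode: str = "sequence_only",
) -> OverlapResult:
    """Overlap of 2-3 unfiltered identification tables with rescue.

    ``tables`` maps dataset name -> iterable of records (unfiltered: the
    rescue rule needs the sub-threshold identifications).  For each dataset
    the best confidence per identity key is used.  Effective membership is

        {p : conf >= primary_cutoff}
          ∪ {p : conf > rescue_cutoff and max over other datasets >= primary}

    Rescue is evaluated against the datasets of this call only.
    """
    names = tuple(tables.keys())
    if len(names) < 2:
        raise ValueError("need at least two datasets to compare")
    best: dict[str, dict[str, float]] = {}
    for nm in names:
        conf: dict[str, float] = {}
        for rec in tables[nm]:
            key = rec.identity_key(identity_mode)
            if key not in conf or rec.confidence > conf[key]:
                conf[key] = rec.confidence
        best[nm] = conf

    core = {nm: {k for k, c in best[nm].items() if c >= primary_cutoff} for nm in names}
    rescued: dict[str, set[str]] = {}
    for nm in names:
        anchor = set().union(*(core[o] for o in names if o != nm))
        rescued[nm] = {
            k
            for k, c in best[nm].items()
            if c > rescue_cutoff and k not in core[nm] and k in anchor
        }
    effective = {nm: core[nm] | rescued[nm] for nm in names}
    return OverlapResult(
        dataset_names=names,
        identity_mode=identity_mode,
        primary_cutoff=primary_cutoff,
        rescue_cutoff=rescue_cutoff,
        effective=effective,
        core=core,
        rescued=rescued,
    )
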