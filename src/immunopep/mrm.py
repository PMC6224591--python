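"""Targeted-MS (MRM) detection validation and relative quantification.

A peptide is monitored through 3-4 precursor->fragment transitions.  Its
presence in an experiment is accepted when all transitions co-elute and the
instrument triggered a confirmatory MS/MS scan in that experiment; without a
trigger, a detection is rescued when its retention time lies within a window
of the peptide's MS/MS-validated mean RT and its transition intensity
pattern matches the spectral library (dot product on square-root-transformed
intensities).  Validated detections are quantified as the summed transition
area divided by the co-purified beta-2-microglobulin (β2m) area of that
experiment — a loading normalisation — and expressed as a proportion of the
peptide's maximum normalised area across all experiments in the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TransitionMeasurement:
    peptide: str
    fragment: str
    experiment: str
    rt_min: float
    area: float
    ms2_triggered: bool = False

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass
class LibrarySpectrum:
    peptide: str
    intensities: dict[str, float]  # fragment id -> relative intensity

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError("library spectrum has no fragments")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("library intensities must be >= 0")
        if not any(v > 0 for v in self.intensities.values()):
            raise ValueError("library spectrum needs at least one positive intensity")


@dataclass(frozen=True)
class DetectionResult:
    peptide: str
    experiment: str
    validated: bool
    basis: str  # ms2_confirmed | rt_dotp_rescued | rejected
    dotp: float = float("nan")
    rt_delta: float = float("nan")
    reason: str = ""


def spectral_dot_product(
    observed: Mapping[str, float], library: LibrarySpectrum | Mapping[str, float]
) -> float:
    """Normalised dot product of square-root intensities over the fragment union.

    Missing fragments contribute 0; the value is 1 iff the two patterns are
    proportional, 0 for disjoint fragment sets.  Requires at least two shared
    fragment ids.
    """
    lib = library.intensities if isinstance(library, LibrarySpectrum) else dict(library)
    shared = set(observed) & set(lib)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared fragment ids for a dot product")
    frags = sorted(set(observed) | set(lib))
    a = np.sqrt([max(float(observed.get(f, 0.0)), 0.0) for f in frags])
    b = np.sqrt([max(float(lib.get(f, 0.0)), 0.0) for f in frags])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def validate_detections(
    transitions: Iterable[TransitionMeasurement],
    library: Mapping[str, LibrarySpectrum],
    co_elution_tol: float = 0.2,
    rt_window: float = 1.5,
    dotp_threshold: float = 0.7,
) -> list[DetectionResult]:
    """Classify every (peptide, experiment) group of transitions.

    A group is a *candidate* only if all its transitions co-elute (RT spread
    <= ``co_elution_tol`` min).  A candidate with an MS/MS trigger in that
    experiment is ``ms2_confirmed``; otherwise it is ``rt_dotp_rescued`` iff
    its RT is within ``rt_window`` (inclusive) of the mean RT of the
    peptide's MS/MS-confirmed detections and its library dot product is
    strictly greater than ``dotp_threshold``; anything else is rejected with
    a reason.  Every monitored peptide must have 3-4 transitions configured.
    """
    df = pd.DataFrame([t.__dict__ for t in transitions])
    if df.empty:
        return []
    for pep, grp in df.groupby("peptide"):
        n_frag = grp.fragment.nunique()
        if not 3 <= n_frag <= 4:
            raise ValueError(f"peptide {pep} has {n_frag} transitions; expected 3-4")

    groups = {}
    for (pep, exp), grp in df.groupby(["peptide", "experiment"], sort=True):
        spread = grp.rt_min.max() - grp.rt_min.min()
        groups[(pep, exp)] = {
            "grp": grp,
            "co_eluting": spread <= co_elution_tol,
            "rt": float(grp.rt_min.mean()),
            "triggered": bool(grp.ms2_triggered.any()),
        }

    confirmed_rt: dict[str, list[float]] = {}
    for (pep, exp), g in groups.items():
        if g["co_eluting"] and g["triggered"]:
            confirmed_rt.setdefault(pep, []).append(g["rt"])

    results: list[DetectionResult] = []
    for (pep, exp), g in groups.items():
        if not g["co_eluting"]:
            results.append(
                DetectionResult(pep, exp, False, "rejected", reason="transitions not co-eluting")
            )
            continue
        if g["triggered"]:
            results.append(DetectionResult(pep, exp, True, "ms2_confirmed", rt_delta=0.0))
            continue
        if pep not in confirmed_rt:
            results.append(
                DetectionResult(pep, exp, False, "rejected", reason="no MS/MS-confirmed detection of this peptide")
            )
            continue
        rt_delta = g["rt"] - float(np.mean(confirmed_rt[pep]))
        observed = dict(zip(g["grp"].fragment, g["grp"].area))
        lib = library.get(pep)
        if lib is None:
            results.append(
                DetectionResult(pep, exp, False, "rejected", rt_delta=rt_delta, reason="no library spectrum")
            )
            continue
        dotp = spectral_dot_product(observed, lib)
        if abs(rt_delta) <= rt_window and dotp > dotp_threshold:
            results.append(DetectionResult(pep, exp, True, "rt_dotp_rescued", dotp, rt_delta))
        else:
            reason = "RT outside window" if abs(rt_delta) > rt_window else "dot product too low"
            results.append(DetectionResult(pep, exp, False, "rejected", dotp, rt_delta, reason))
    return results


@dataclass(frozen=True)
class AbundanceRecord:
    peptide: str
    experiment: str
    normalised_abundance: float  # sum of transition areas / β2m area
    proportion_of_max: float


def relative_abundance(
    detections: Iterable[DetectionResult],
    transitions: Iterable[TransitionMeasurement],
    norm_factors: Mapping[str, float],
) -> list[AbundanceRecord]:
    """β2m-normalised abundance of validated detections, as proportion of max.

    ``norm_factors`` maps experiment id -> β2m peak area (> 0).  The
    proportion of max is computed per peptide across all experiments present
    in the call, so the best-detected experiment reads exactly 1.
    """
    validated = {(d.peptide, d.experiment) for d in detections if d.validated}
    if not validated:
        return []
    df = pd.DataFrame([t.__dict__ for t in transitions])
    sums = df.groupby(["peptide", "experiment"])["area"].sum()
    norm: dict[tuple[str, str], float] = {}
    for pep, exp in sorted(validated):
        if exp not in norm_factors:
            raise KeyError(f"missing β2m normalisation factor for experiment {exp!r}")
        b2m = float(norm_factors[exp])
        if b2m <= 0:
            raise ValueError(f"non-positive β2m factor for experiment {exp!r}")
        norm[(pep, exp)] = float(sums.loc[(pep, exp)]) / b2m
    max_per_pep: dict[str, float] = {}
    for (pep, _exp), v in norm.items():
        max_per_pep[pep] = max(max_per_pep.get(pep, 0.0), v)
    return [
        AbundanceRecord(pep, exp, v, v / max_per_pep[pep] if max_per_pep[pep] > 0 else 0.0)
        for (pep, exp), v in norm.items()
    ]
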