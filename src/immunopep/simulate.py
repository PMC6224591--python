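"""Seeded synthetic data with the statistical structure of the real inputs.

Three generators emulate the three experimental data streams:

* :func:`simulate_repertoire` — peptide-identification tables with
  allotype-style position-specific residue profiles (anchor biases at P2,
  PΩ and PΩ-2), optional injected inter-position coupling, realistic
  confidence-score distributions and contaminant spikes;
* :func:`simulate_mrm` — MRM transition-area tables with a spectral library,
  per-experiment β2m normalisation factors, lognormal area noise and
  ground-truth abundances;
* :func:`simulate_melt` — Boltzmann-sigmoid melt curves with post-peak
  aggregation decay and Gaussian noise.

All generators are pure functions of (spec, seed): the same spec yields a
byte-identical table.  The bundled :func:`b57_like_specs` reproduce the
qualitative contrasts of the three studied allotypes — a Trp-favouring
C terminus with PΩ-2 Arg enrichment, a Phe-favouring C terminus with PΩ-2
Arg depletion, and a Trp-favouring C terminus with PΩ-2 Glu enrichment —
so the whole pipeline can be exercised end-to-end without any downloads.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AMINO_ACIDS, swissprot_human_frequencies
from .mrm import LibrarySpectrum
from .melt import MeltCurve


# ---------------------------------------------------------------------------
# repertoire simulation


@dataclass
class CouplingInjection:
    """Joint residue-pair distribution injected between two positions."""

    pos_a: int  # 1-based
    pos_b: int
    joint: dict[tuple[str, str], float]  # (residue at a, residue at b) -> prob
    weight: float  # probability of drawing the pair jointly

    def __post_init__(self) -> None:
        total = sum(self.joint.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("joint distribution must sum to 1")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("mixing weight must be in [0, 1]")


@dataclass
class RepertoireSpec:
    """Generative description of one allotype-like peptide data set."""

    n: int
    seed: int
    allotype: str = "synthetic"
    length_weights: dict[int, float] = field(
        default_factory=lambda: {8: 0.05, 9: 0.55, 10: 0.25, 11: 0.12, 12: 0.03}
    )
    # length -> L x 20 row-stochastic profile; lengths without an entry fall
    # back to the background composition at every position
    profiles: dict[int, np.ndarray] = field(default_factory=dict)
    couplings: list[CouplingInjection] = field(default_factory=list)
    # confidence model: true ligands high, spikes spread low
    ligand_confidence: tuple[float, float] = (95.0, 99.9)  # uniform range
    low_confidence_fraction: float = 0.10  # true ligands below cutoff
    low_confidence_range: tuple[float, float] = (30.0, 95.0)
    contaminant_fraction: float = 0.05
    contaminant_pool: tuple[str, ...] = ()
    replicates: tuple[str, ...] = ("rep1", "rep2", "rep3")

    def __post_init__(self) -> None:
        total = sum(self.length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length weights must sum to 1")
        for L, prof in self.profiles.items():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (L, 20):
                raise ValueError(f"profile for length {L} must be {L}x20")
            if not np.allclose(prof.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"profile rows for length {L} must sum to 1")
            self.profiles[L] = prof
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant fraction must be in [0, 1)")
        if self.contaminant_fraction > 0 and not self.contaminant_pool:
            raise ValueError("contaminant fraction > 0 requires a contaminant pool")


def uniform_background_profile(length: int) -> np.ndarray:
    """L x 20 profile with the proteome background at every position."""
    bg = swissprot_human_frequencies().to_numpy()
    return np.tile(bg, (length, 1))


def profile_with_anchors(length: int, anchors: dict[int, dict[str, float]]) -> np.ndarray:
    """Background profile with specified positions overridden.

    ``anchors`` maps a 1-based position to a partial residue distribution;
    unassigned mass at that position is spread over the remaining residues
    proportionally to the background.
    """
    prof = uniform_background_profile(length)
    bg = swissprot_human_frequencies().to_numpy()
    for pos, dist in anchors.items():
        row = np.zeros(20)
        assigned = 0.0
        for aa, p in dist.items():
            row[AA_INDEX[aa]] = p
            assigned += p
        if assigned > 1.0 + 1e-9:
            raise ValueError(f"anchor distribution at P{pos} exceeds 1")
        rest = np.array([bg[i] if row[i] == 0 else 0.0 for i in range(20)])
        if rest.sum() > 0:
            row += rest / rest.sum() * (1.0 - assigned)
        prof[pos - 1] = row / row.sum()
    return prof


def simulate_repertoire(spec: RepertoireSpec) -> pd.DataFrame:
    """Draw a peptide-identification table in the standard reader dialect.

    Positions are sampled independently from the per-length profile except at
    injected coupling pairs, where with probability equal to the mixing
    weight the residue pair is drawn jointly.  Contaminant spikes replace a
    fraction of rows with pool sequences at ligand-like confidences, so the
    contaminant filter (not the confidence filter) must remove them.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = sorted(spec.length_weights)
    weights = np.array([spec.length_weights[L] for L in lengths])
    aa = np.array(list(AMINO_ACIDS))

    rows = []
    for _ in range(spec.n):
        L = int(rng.choice(lengths, p=weights))
        prof = spec.profiles.get(L)
        if prof is None:
            prof = uniform_background_profile(L)
        residues = [aa[rng.choice(20, p=prof[pos])] for pos in range(L)]
        for inj in spec.couplings:
            if inj.pos_a <= L and inj.pos_b <= L and rng.random() < inj.weight:
                pairs = list(inj.joint.items())
                probs = np.array([p for _, p in pairs])
                idx = int(rng.choice(len(pairs), p=probs))
                (ra, rb), _ = pairs[idx]
                residues[inj.pos_a - 1] = ra
                residues[inj.pos_b - 1] = rb
        seq = "".join(residues)
        if rng.random() < spec.low_confidence_fraction:
            conf = rng.uniform(*spec.low_confidence_range)
        else:
            conf = rng.uniform(*spec.ligand_confidence)
        rows.append((seq, round(float(conf), 2)))

    # contaminant spikes
    n_cont = int(round(spec.contaminant_fraction * spec.n))
    if n_cont and not spec.contaminant_pool:
        raise ValueError("contaminant fraction > 0 requires a contaminant pool")
    for _ in range(n_cont):
        seq = spec.contaminant_pool[int(rng.integers(len(spec.contaminant_pool)))]
        conf = rng.uniform(*spec.ligand_confidence)
        rows.append((seq, round(float(conf), 2)))

    reps = [spec.replicates[int(r)] for r in rng.integers(len(spec.replicates), size=len(rows))]
    df = pd.DataFrame(
        {
            "sequence": [r[0] for r in rows],
            "confidence": [r[1] for r in rows],
            "modifications": "",
            "allotype": spec.allotype,
            "replicate": reps,
        }
    )
    return df


#: Contaminant sequences used by the bundled example specs; stand-ins for the
#: endogenous-ligand / generic-contaminant exclusion lists (synthetic, not
#: taken from any experiment).
EXAMPLE_CONTAMINANTS: tuple[str, ...] = (
    "APRTLVLLL",
    "KVLEYVIKV",
    "GLAPFTEYL",
    "SVNDFFNKL",
    "DDAGNWMNL",
    "TPGPGVRYPL",
)


def b57_like_specs(n: int = 2000, seed: int = 1) -> dict[str, RepertoireSpec]:
    """Three bundled allotype-like specs mirroring the studied contrasts.

    ``W-RposE`` (B*57:01-like): PΩ Trp-major, PΩ-2 Arg-enriched;
    ``F-RnegP`` (B*57:03-like): PΩ Phe-major, PΩ-2 Arg-depleted, Pro-enriched;
    ``W-EposR`` (B*58:01-like): PΩ Trp-major, PΩ-2 Glu-enriched.
    All share the P2 Ser/Thr/Ala/Val bias and a P2-PΩ coupling injection.
    """
    p2 = {"S": 0.35, "T": 0.20, "A": 0.15, "V": 0.08}

    def spec(name, seed_off, om2, om, major, minor):
        profiles = {}
        for L in (8, 9, 10, 11, 12):
            profiles[L] = profile_with_anchors(L, {2: p2, L - 2: om2, L: om})
        # P2 Ser/Thr pair with the major PΩ aromatic, P2 Ala/Val with the
        # minor one; the joint keeps the P2 anchor marginals close to the
        # profile while shifting the conditional PΩ distribution strongly
        inj = CouplingInjection(
            2, 9,
            {("S", major): 0.45, ("T", major): 0.20, ("A", minor): 0.20, ("V", minor): 0.15},
            0.6,
        )
        return RepertoireSpec(
            n=n,
            seed=seed + seed_off,
            allotype=name,
            profiles=profiles,
            couplings=[inj],
            contaminant_fraction=0.05,
            contaminant_pool=EXAMPLE_CONTAMINANTS,
        )

    return {
        "W-RposE": spec("W-RposE", 0, {"R": 0.12, "K": 0.07, "E": 0.08}, {"W": 0.55, "F": 0.18, "Y": 0.12}, "W", "F"),
        "F-RnegP": spec("F-RnegP", 1, {"P": 0.11, "E": 0.07, "R": 0.002}, {"F": 0.48, "W": 0.25, "Y": 0.10}, "F", "W"),
        "W-EposR": spec("W-EposR", 2, {"E": 0.14, "K": 0.02, "R": 0.002}, {"W": 0.60, "F": 0.15, "Y": 0.10}, "W", "F"),
    }


# ---------------------------------------------------------------------------
# MRM simulation


@dataclass
class MrmSimSpec:
    """Generative description of an MRM experiment set."""

    seed: int
    # peptide -> experiment -> true abundance (>= 0; 0 = absent)
    truth: dict[str, dict[str, float]]
    # peptide -> fragment -> library relative intensity
    library: dict[str, dict[str, float]]
    b2m: dict[str, float]  # experiment -> β2m area (> 0)
    area_scale: float = 1e5
    lognormal_sd: float = 0.2
    rt_means: dict[str, float] = field(default_factory=dict)  # peptide -> min
    rt_jitter_sd: float = 0.05
    ms2_trigger_prob: float = 0.9
    never_triggered: frozenset[str] = frozenset()  # peptides without MS/MS

    def __post_init__(self) -> None:
        for pep, by_exp in self.truth.items():
            if any(v < 0 for v in by_exp.values()):
                raise ValueError(f"negative abundance for {pep}")
            if pep not in self.library:
                raise ValueError(f"no library spectrum for {pep}")
            n_frag = len(self.library[pep])
            if not 3 <= n_frag <= 4:
                raise ValueError(f"peptide {pep} needs 3-4 fragments, has {n_frag}")
        if any(v <= 0 for v in self.b2m.values()):
            raise ValueError("β2m factors must be positive")


@dataclass
class MrmSimOutput:
    transitions: pd.DataFrame  # peptide, fragment, experiment, rt_min, area, ms2_triggered
    library: dict[str, LibrarySpectrum]
    norm_factors: dict[str, float]
    truth: dict[str, dict[str, float]]


def simulate_mrm(spec: MrmSimSpec) -> MrmSimOutput:
    """Areas = truth x β2m loading x fragment intensity x lognormal noise.

    Scaling areas by the experiment's β2m factor emulates loading
    differences, which the downstream β2m normalisation must remove.
    """
    rng = np.random.default_rng(spec.seed)
    b2m_ref = float(np.mean(list(spec.b2m.values())))
    rows = []
    for pep in sorted(spec.truth):
        rt_mean = spec.rt_means.get(pep, 20.0 + 0.5 * (zlib.crc32(pep.encode()) % 60))
        frags = sorted(spec.library[pep])
        intens = np.array([spec.library[pep][f] for f in frags], dtype=float)
        intens = intens / intens.max()
        for exp in sorted(spec.truth[pep]):
            truth = spec.truth[pep][exp]
            if truth <= 0:
                continue
            rt = rt_mean + rng.normal(0.0, spec.rt_jitter_sd)
            loading = spec.b2m[exp] / b2m_ref
            triggered = (
                pep not in spec.never_triggered
                and rng.random() < spec.ms2_trigger_prob
            )
            for f, inten in zip(frags, intens):
                noise = rng.lognormal(0.0, spec.lognormal_sd) if spec.lognormal_sd > 0 else 1.0
                area = spec.area_scale * truth * loading * inten * noise
                rows.append((pep, f, exp, round(float(rt), 3), float(area), bool(triggered)))
    transitions = pd.DataFrame(
        rows, columns=["peptide", "fragment", "experiment", "rt_min", "area", "ms2_triggered"]
    )
    library = {pep: LibrarySpectrum(pep, dict(frs)) for pep, frs in spec.library.items()}
    return MrmSimOutput(transitions, library, dict(spec.b2m), spec.truth)


def transitions_from_frame(df: pd.DataFrame):
    """Row-wise conversion of a transition table to measurement objects."""
    from .mrm import TransitionMeasurement

    return [
        TransitionMeasurement(
            peptide=str(r.peptide),
            fragment=str(r.fragment),
            experiment=str(r.experiment),
            rt_min=float(r.rt_min),
            area=float(r.area),
            ms2_triggered=bool(r.ms2_triggered),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# melt simulation


@dataclass
class MeltSimSpec:
    """Generative description of a dye-based melt-curve set."""

    seed: int
    tm_by_sample: dict[str, float]  # °C, within 40-85
    slope: float = 1.5              # transition width (°C)
    baseline_lower: float = 100.0
    baseline_upper: float = 1000.0
    peak_offset: float = 6.0        # °C past Tm where aggregation decay starts
    decay_rate: float = 0.04        # per °C, post-peak exponential decay
    noise_sd_fraction: float = 0.02  # of amplitude
    replicates: int = 4
    t_start: float = 35.0
    t_stop: float = 90.0
    t_step: float = 1.0

    def __post_init__(self) -> None:
        for sample, tm in self.tm_by_sample.items():
            if not 40.0 <= tm <= 85.0:
                raise ValueError(f"Tm {tm} for {sample} outside 40-85 °C")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_melt(spec: MeltSimSpec) -> list[MeltCurve]:
    """Sigmoid + post-peak decay + Gaussian noise at 1 °C steps, per replicate."""
    rng = np.random.default_rng(spec.seed)
    T = np.arange(spec.t_start, spec.t_stop + spec.t_step / 2, spec.t_step)
    amplitude = spec.baseline_upper - spec.baseline_lower
    curves = []
    for sample in sorted(spec.tm_by_sample):
        tm = spec.tm_by_sample[sample]
        for r in range(spec.replicates):
            f = spec.baseline_lower + amplitude / (1.0 + np.exp((tm - T) / spec.slope))
            t_peak = tm + spec.peak_offset
            post = T > t_peak
            f[post] = f[post] * np.exp(-spec.decay_rate * (T[post] - t_peak))
            f = f + rng.normal(0.0, spec.noise_sd_fraction * amplitude, size=T.shape)
            curves.append(MeltCurve(sample, f"rep{r + 1}", T.copy(), f))
    return curves


def melt_curves_to_frame(curves: list[MeltCurve]) -> pd.DataFrame:
    """Long-format table (sample, replicate, temp_c, fluorescence)."""
    rows = []
    for c in curves:
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append((c.sample, c.replicate, float(t), float(f)))
    return pd.DataFrame(rows, columns=["sample", "replicate", "temp_c", "fluorescence"])


def melt_curves_from_frame(df: pd.DataFrame) -> list[MeltCurve]:
    curves = []
    for (sample, rep), grp in df.groupby(["sample", "replicate"], sort=True):
        grp = grp.sort_values("temp_c")
        curves.append(
            MeltCurve(str(sample), str(rep), grp.temp_c.to_numpy(), grp.fluorescence.to_numpy())
        )
    return curves
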