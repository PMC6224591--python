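"""Orchestration: run the comparison stages over a set of datasets.

A :class:`PipelineConfig` names the input peptide tables (or asks for the
bundled synthetic cohort), the filter/analysis parameters and an output
directory.  :func:`run_pipeline` executes the requested stages in dependency
order, writes machine-readable TSV/JSON outputs stamped with the config hash
and seed, and returns the JSON summary as a dict.  Reruns with the same
inputs, config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import covariation, motif, overlap, physchem
from .io import ContaminantLists, Repertoire, filter_repertoire, read_peptide_table
from .mrm import relative_abundance, validate_detections
from .melt import NoTransitionError, FitError, fit_melt, summarize_replicates
from .simulate import (
    EXAMPLE_CONTAMINANTS,
    MeltSimSpec,
    MrmSimSpec,
    b57_like_specs,
    melt_curves_from_frame,
    simulate_melt,
    simulate_mrm,
    simulate_repertoire,
    transitions_from_frame,
)

logger = logging.getLogger("immunopep")

ALL_STAGES = ("simulate", "filter", "motif", "enrich", "covary", "pca", "overlap", "mrm", "melt")


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # dataset name -> peptide-table path; empty + "simulate" stage = bundled cohort
    datasets: dict[str, str] = field(default_factory=dict)
    dialect: dict[str, str] = field(default_factory=dict)
    synthetic_n: int = 2000
    cutoff: float = 95.0
    identity_mode: str = "sequence_only"
    contaminants_endogenous: str | None = None
    contaminants_generic: str | None = None
    contaminants_hla_fasta: str | None = None
    background_fasta: str | None = None
    lengths: tuple[int, ...] = (9, 10, 11)
    alpha: float = 0.05
    min_prevalence: float = 0.10
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    primary_cutoff: float = 95.0
    rescue_cutoff: float = 20.0
    overlap_identity_mode: str = "sequence_only"
    # optional tabular inputs for the targeted-MS / melt stages
    mrm_transitions: str | None = None
    melt_curves: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = PipelineConfig()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple) and value is not None:
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; abort naming the failing stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "init"
    try:
        tables = {}
        if "simulate" in config.stages and not config.datasets:
            stage = "simulate"
            specs = b57_like_specs(n=config.synthetic_n, seed=config.seed)
            for name, spec in specs.items():
                df = simulate_repertoire(spec)
                path = out / f"table_{name}.tsv"
                df.to_csv(path, sep="\t", index=False)
                tables[name] = path
            summary["stages"]["simulate"] = {"datasets": sorted(tables), "n_rows": int(config.synthetic_n)}
        else:
            tables = {name: Path(p) for name, p in config.datasets.items()}

        lists = ContaminantLists.from_files(
            config.contaminants_endogenous,
            config.contaminants_generic,
            config.contaminants_hla_fasta,
        )
        if not config.datasets and "simulate" in config.stages:
            lists = ContaminantLists(generic_contaminants=frozenset(EXAMPLE_CONTAMINANTS))

        raw_records: dict[str, list] = {}
        repertoires: dict[str, Repertoire] = {}
        if "filter" in config.stages:
            stage = "filter"
            info = {}
            for name, path in tables.items():
                result = read_peptide_table(path, config.dialect, default_allotype=name)
                raw_records[name] = result.records
                rep = filter_repertoire(
                    result.records, config.cutoff, lists, config.identity_mode, allotype=name
                )
                rep.write_tsv(out / f"repertoire_{name}.tsv")
                info[name] = {"read_errors": len(result.errors), **rep.provenance}
                repertoires[name] = rep
            summary["stages"]["filter"] = info

        if "motif" in config.stages and repertoires:
            stage = "motif"
            info = {}
            for name, rep in repertoires.items():
                ld = motif.length_distribution(rep)
                ld.to_csv(out / f"length_distribution_{name}.tsv", sep="\t")
                modal = ld["count"].drop("other").astype(int).idxmax()
                per_len = {}
                for L in config.lengths:
                    try:
                        pfm = motif.position_frequency_matrix(rep, L)
                    except ValueError:
                        continue
                    pfm.freqs.to_csv(out / f"pfm_{name}_{L}.tsv", sep="\t")
                    per_len[str(L)] = {
                        "n": pfm.n,
                        "motif": motif.motif_summary(pfm, config.min_prevalence),
                    }
                info[name] = {"modal_length": int(modal), "by_length": per_len}
            summary["stages"]["motif"] = info

        if "enrich" in config.stages and repertoires:
            stage = "enrich"
            ref = motif.background_frequencies(config.background_fasta)
            info = {}
            for name, rep in repertoires.items():
                per_len = {}
                for L in config.lengths:
                    try:
                        pfm = motif.position_frequency_matrix(rep, L)
                    except ValueError:
                        continue
                    res = motif.enrichment_profile(pfm, ref, alpha=config.alpha)
                    res.table.to_csv(out / f"enrichment_{name}_{L}.tsv", sep="\t", index=False)
                    om2 = motif.omega_position(L, 2)
                    per_len[str(L)] = {
                        "omega2_R_status": res.status(om2, "R"),
                        "omega2_R_value": res.value(om2, "R"),
                    }
                info[name] = per_len
            summary["stages"]["enrich"] = {"background": ref.source, "by_dataset": info}

        if "covary" in config.stages and repertoires:
            stage = "covary"
            info = {}
            for name, rep in repertoires.items():
                per_len = {}
                for L in config.lengths:
                    try:
                        cm = covariation.coupling_matrix(rep, L)
                    except ValueError:
                        continue
                    cm.values.to_csv(out / f"coupling_{name}_{L}.tsv", sep="\t")
                    top = covariation.top_coupled_pairs(cm, 3)
                    per_len[str(L)] = {"top_pairs": [[i, j, round(v, 4)] for i, j, v in top]}
                info[name] = per_len
            summary["stages"]["covary"] = info

        if "pca" in config.stages and repertoires:
            stage = "pca"
            info = {}
            for name, rep in repertoires.items():
                per_len = {}
                for L in config.lengths:
                    try:
                        fm = physchem.encode_peptides(rep, L)
                        res = physchem.pca_cluster(fm, config.k_candidates, seed=config.seed)
                    except ValueError:
                        continue
                    res.scores.iloc[:, :2].assign(cluster=res.labels).to_csv(
                        out / f"pca_scores_{name}_{L}.tsv", sep="\t", index=False
                    )
                    res.loadings.to_csv(out / f"pca_loadings_{name}_{L}.tsv", sep="\t")
                    per_len[str(L)] = {
                        "chosen_k": res.chosen_k,
                        "silhouette": {str(k): round(v, 4) for k, v in res.silhouette_by_k.items()},
                        "cluster_percentages": {str(c): round(p, 2) for c, p in res.cluster_percentages.items()},
                        "variance_fractions": [round(float(v), 4) for v in res.variance_fractions[:2]],
                    }
                info[name] = per_len
            summary["stages"]["pca"] = info

        if "overlap" in config.stages and raw_records and len(raw_records) >= 2:
            stage = "overlap"
            ov = overlap.repertoire_overlap(
                raw_records,
                primary_cutoff=config.primary_cutoff,
                rescue_cutoff=config.rescue_cutoff,
                identity_mode=config.overlap_identity_mode,
            )
            ov.membership_table().to_csv(out / "overlap_membership.tsv", sep="\t", index=False)
            summary["stages"]["overlap"] = ov.counts()

        if "mrm" in config.stages:
            stage = "mrm"
            summary["stages"]["mrm"] = _run_mrm_stage(config, out)

        if "melt" in config.stages:
            stage = "melt"
            summary["stages"]["melt"] = _run_melt_stage(config, out)
    except Exception as exc:
        summary["failed_stage"] = stage
        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    text = json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n"
    (out / "summary.json").write_text(text)
    return summary


def example_mrm_spec(seed: int) -> MrmSimSpec:
    """Small bundled MRM scenario: three experiments per three datasets."""
    peptides = [f"PEP{i:02d}" for i in range(12)]
    rng = np.random.default_rng(seed)
    experiments = [f"{allo}-e{r}" for allo in ("A", "B", "C") for r in (1, 2, 3)]
    truth = {
        pep: {exp: float(rng.uniform(0.05, 1.0)) for exp in experiments}
        for pep in peptides
    }
    library = {
        pep: {f"y{k}": float(rng.uniform(0.2, 1.0)) for k in range(3, 7)}
        for pep in peptides
    }
    b2m = {exp: float(rng.uniform(5e5, 2e6)) for exp in experiments}
    return MrmSimSpec(seed=seed, truth=truth, library=library, b2m=b2m)


def _run_mrm_stage(config: PipelineConfig, out: Path) -> dict:
    import pandas as pd

    if config.mrm_transitions:
        raise NotImplementedError(
            "external MRM tables need an accompanying library/normalisation config; "
            "use the mrm module directly"
        )
    sim = simulate_mrm(example_mrm_spec(config.seed))
    trans = transitions_from_frame(sim.transitions)
    detections = validate_detections(trans, sim.library)
    records = relative_abundance(detections, trans, sim.norm_factors)
    pd.DataFrame([r.__dict__ for r in records]).to_csv(out / "mrm_abundance.tsv", sep="\t", index=False)
    n_valid = sum(d.validated for d in detections)
    return {"n_detections": len(detections), "n_validated": int(n_valid), "n_quantified": len(records)}


def _run_melt_stage(config: PipelineConfig, out: Path) -> dict:
    import pandas as pd

    if config.melt_curves:
        df = pd.read_csv(config.melt_curves)
        curves = melt_curves_from_frame(df)
    else:
        spec = MeltSimSpec(
            seed=config.seed,
            tm_by_sample={"wildtype": 69.4, "omega2_Q": 67.1, "omega_W": 72.2},
        )
        curves = simulate_melt(spec)
    by_sample: dict[str, list] = {}
    failures = []
    for c in curves:
        try:
            res = fit_melt(c)
        except (NoTransitionError, FitError) as exc:
            failures.append(str(exc))
            continue
        by_sample.setdefault(c.sample, []).append(res)
    summaries = {s: summarize_replicates(rs) for s, rs in by_sample.items()}
    rows = [
        {"sample": s, "mean_tm": round(v.mean_tm, 2), "sd_tm": round(v.sd_tm, 3), "n": v.n}
        for s, v in sorted(summaries.items())
    ]
    pd.DataFrame(rows).to_csv(out / "melt_summary.tsv", sep="\t", index=False)
    return {"samples": rows, "n_failed_fits": len(failures)}
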